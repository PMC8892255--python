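"""Per-patient parameter estimation from a 5-point OGTT-I record.

The estimation problem is organised the way statsmodels organises its
estimators: :class:`GlucoseInsulinModel` is built from one
:class:`~glykit.records.OGTTRecord`, and its :meth:`~GlucoseInsulinModel.fit`
returns a :class:`GlucoseInsulinFit` results object carrying the best
parameter vector, the loss, every optimisation run, convergence
diagnostics and a ``summary()`` table.

Estimation details
------------------
* Basal glycemia and insulinemia are directly observed, so ``G_b`` and
  ``I_b`` are fixed to the 0-min measurements rather than fitted; the
  dose is taken from the record.
* Of the remaining parameters, a default *free* set
  (k_js, tau, k_lg, eta, k_xg, k_xgi, beta) is optimised on the log
  scale; the structural closures (k_gj, f_gi, k_xi) and the hepatic
  rates k_lambda and gamma are held at their population defaults.  Both
  sets are configurable.  The hepatic rates are structurally confounded
  on OGTT data: k_lambda only acts when glycemia dips below basal (which
  a 2-hour test barely samples), and above basal the endogenous-
  production closure makes k_xg and gamma act only through their sum, so
  freeing both would leave a flat direction in the loss.
* The loss is a least-squares loss on the sampled curves, each residual
  normalised by the subject's basal value (so the mM and pM scales carry
  equal weight) and by the assumed assay CV (default 3% glycemia, 7%
  insulinemia), making the data term a chi-square at matched noise.
* Five points per curve leave the problem sloppy: several parameter
  directions move the curves by less than measurement noise.  A weak
  log-normal ridge toward the population centres (sd 1.5 on the natural
  log scale, i.e. a +/-350% one-sigma band) regularises those directions
  without materially biasing the well-identified ones.  ``prior_sigma=None``
  turns the ridge off.  The reported ``loss`` is the full objective;
  ``data_loss`` is the curve term alone.
* The optimiser is bounded local least squares (trust-region reflective)
  launched from Latin-hypercube points in log-bound space plus the
  population centre; the best run wins and all runs are retained.
  Everything is deterministic given the seed.

Sensitivity analyses
--------------------
:func:`repeat_fit_consistency` re-runs the whole fit with different
seeds and flags parameters whose across-run coefficient of variation
exceeds a threshold as non-unique.  :func:`measurement_sensitivity`
perturbs each of the ten measurements up and down by 10% and refits
(warm-started), recording how much each parameter moves.
:func:`curve_shape_sensitivity` perturbs each *parameter* by 10% and
measures the normalised change of the simulated curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .defaults import FIT_BOUNDS, HEALTHY_DEFAULTS
from .errors import FittingError, IntegrationError, ValidationError
from .model import simulate_sampled_fast
from .params import ModelParameters
from .records import OGTTRecord

DEFAULT_FREE = ("k_js", "tau", "k_lg", "eta", "k_xg", "k_xgi", "beta")
DEFAULT_N_STARTS = 24
DEFAULT_LOSS_CV = (0.03, 0.07)  # assumed assay CVs (glycemia, insulinemia)
DEFAULT_PRIOR_SIGMA = 1.5  # log-scale sd of the ridge toward population centres
_BIG_RESIDUAL = 1e6


@dataclass
class FitRun:
    """One optimisation run (one start)."""

    params: ModelParameters | None
    loss: float
    success: bool
    n_evaluations: int
    message: str = ""


@dataclass
class GlucoseInsulinFit:
    """Results of fitting the five-compartment model to one record."""

    record: OGTTRecord
    params: ModelParameters
    loss: float  # full objective (data + ridge)
    free: tuple
    data_loss: float = 0.0  # curve term alone
    runs: list = field(default_factory=list)
    converged: bool = True
    seed: int | None = None
    at_bounds: tuple = ()
    warnings: tuple = ()
    options: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def predict(self, sample_times=None, dt: float = 0.5):
        """Model (G, I) at the record's (or given) sampling times."""
        times = self.record.times if sample_times is None else sample_times
        return simulate_sampled_fast(self.params, np.asarray(times, float), dt=dt)

    def residuals(self) -> np.ndarray:
        return _residuals(
            self.params, self.record, loss_cv=self.options.get("loss_cv", DEFAULT_LOSS_CV)
        )

    def summary(self) -> str:
        lines = [
            "Glucose-insulin model fit",
            "=" * 60,
            f"subject: {self.record.subject_id}   points: {self.record.n_points}",
            f"loss (normalised SSR): {self.loss:.6g}   runs: {self.n_runs}   "
            f"converged: {self.converged}   seed: {self.seed}",
            "-" * 60,
            f"{'parameter':<10}{'estimate':>14}  {'status':<12}",
        ]
        for name in ModelParameters.names():
            val = getattr(self.params, name)
            if name in self.free:
                status = "free"
                if name in self.at_bounds:
                    status = "free (bound)"
            elif name in ("G_b", "I_b"):
                status = "observed"
            elif name == "D":
                status = "protocol"
            else:
                status = "fixed"
            lines.append(f"{name:<10}{val:>14.6g}  {status:<12}")
        if self.warnings:
            lines.append("-" * 60)
            for w in self.warnings:
                lines.append(f"warning: {w}")
        return "\n".join(lines)


def _residuals(
    params: ModelParameters,
    record: OGTTRecord,
    dt: float = 0.5,
    loss_cv=DEFAULT_LOSS_CV,
) -> np.ndarray:
    times = np.asarray(record.times, float)
    try:
        G, I = simulate_sampled_fast(params, times, dt=dt)
    except IntegrationError:
        return np.full(2 * len(times), _BIG_RESIDUAL)
    g_obs = np.asarray(record.glycemia)
    i_obs = np.asarray(record.insulinemia)
    cv_g, cv_i = loss_cv
    res = np.concatenate(
        [
            (G - g_obs) / (cv_g * record.basal_glycemia),
            (I - i_obs) / (cv_i * record.basal_insulinemia),
        ]
    )
    return np.where(np.isfinite(res), res, _BIG_RESIDUAL)


class GlucoseInsulinModel:
    """Five-compartment glucose–insulin model bound to one OGTT record.

    Parameters
    ----------
    record : OGTTRecord
        The subject's curve (>= 5 points for the default protocol).
    free : sequence of str, optional
        Parameter names to estimate (default ``DEFAULT_FREE``).
    fixed : mapping, optional
        Values for the non-free dynamic parameters; defaults to the
        population values in :mod:`glykit.defaults`.
    bounds : mapping, optional
        Per-parameter (lo, hi) overrides of the default fitting bounds.
    dt : float
        Fixed integration step (min) of the fast simulator used inside
        the optimisation loop.
    """

    def __init__(
        self,
        record: OGTTRecord,
        free=DEFAULT_FREE,
        fixed=None,
        bounds=None,
        dt=0.5,
        loss_cv=DEFAULT_LOSS_CV,
        prior_sigma=DEFAULT_PRIOR_SIGMA,
    ):
        if record.n_points < 5:
            raise ValidationError(
                f"subject {record.subject_id!r}: need >= 5 points to fit, got {record.n_points}"
            )
        self.record = record
        self.free = tuple(free)
        for name in self.free:
            if name not in FIT_BOUNDS:
                raise ValidationError(f"parameter {name!r} cannot be fitted")
        self.bounds = dict(FIT_BOUNDS)
        if bounds:
            self.bounds.update(bounds)
        base = {k: v for k, v in HEALTHY_DEFAULTS.items() if k in FIT_BOUNDS}
        if fixed:
            base.update(fixed)
        self.fixed = {k: v for k, v in base.items() if k not in self.free}
        self.dt = dt
        self.loss_cv = tuple(loss_cv)
        self.prior_sigma = prior_sigma
        self._lo = np.log(np.array([self.bounds[n][0] for n in self.free]))
        self._hi = np.log(np.array([self.bounds[n][1] for n in self.free]))
        self._prior_center = np.log(np.array([HEALTHY_DEFAULTS[n] for n in self.free]))

    @property
    def fit_options(self) -> dict:
        return {
            "dt": self.dt,
            "loss_cv": self.loss_cv,
            "prior_sigma": self.prior_sigma,
            "bounds": self.bounds,
        }

    # -- helpers -----------------------------------------------------------
    def _assemble(self, x_log: np.ndarray) -> ModelParameters:
        vals = dict(self.fixed)
        vals.update({n: math.exp(v) for n, v in zip(self.free, x_log)})
        vals["G_b"] = self.record.basal_glycemia
        vals["I_b"] = self.record.basal_insulinemia
        vals["D"] = self.record.dose_mmol
        return ModelParameters(**vals)

    def _data_residuals(self, x_log: np.ndarray) -> np.ndarray:
        return _residuals(self._assemble(x_log), self.record, dt=self.dt, loss_cv=self.loss_cv)

    def _objective(self, x_log: np.ndarray) -> np.ndarray:
        data = self._data_residuals(x_log)
        if self.prior_sigma is None:
            return data
        ridge = (x_log - self._prior_center) / self.prior_sigma
        return np.concatenate([data, ridge])

    def _starts(self, n_starts: int, seed: int) -> np.ndarray:
        centre = np.log(
            np.array([HEALTHY_DEFAULTS[n] for n in self.free])
        ).clip(self._lo, self._hi)
        if n_starts <= 1:
            return centre[None, :]
        sampler = qmc.LatinHypercube(d=len(self.free), seed=seed)
        pts = self._lo + sampler.random(n_starts - 1) * (self._hi - self._lo)
        return np.vstack([centre, pts])

    # -- API ---------------------------------------------------------------
    def fit(
        self,
        seed: int = 0,
        n_starts: int = DEFAULT_N_STARTS,
        x0: ModelParameters | None = None,
        max_nfev: int | None = None,
    ) -> GlucoseInsulinFit:
        """Multi-start bounded least squares; best run wins.

        ``x0`` warm-starts the fit from a previous estimate (a single
        extra start at that point).
        """
        if n_starts >= 1:
            starts = self._starts(n_starts, seed)
        else:
            if x0 is None:
                raise ValidationError("n_starts=0 requires a warm start x0")
            starts = np.empty((0, len(self.free)))
        if x0 is not None:
            warm = np.log(np.array([getattr(x0, n) for n in self.free]))
            starts = np.vstack([warm.clip(self._lo, self._hi), starts])
        runs: list[FitRun] = []
        best = None
        for x_start in starts:
            try:
                sol = least_squares(
                    self._objective,
                    x_start,
                    bounds=(self._lo, self._hi),
                    method="trf",
                    xtol=1e-10,
                    ftol=1e-10,
                    gtol=1e-10,
                    max_nfev=max_nfev,
                )
                loss = float(np.sum(sol.fun**2))
                run = FitRun(
                    params=self._assemble(sol.x),
                    loss=loss,
                    success=bool(sol.status > 0),
                    n_evaluations=int(sol.nfev),
                    message=str(sol.message),
                )
            except (IntegrationError, ValidationError) as exc:  # defensive
                run = FitRun(params=None, loss=np.inf, success=False, n_evaluations=0, message=str(exc))
            runs.append(run)
            if run.success and (best is None or run.loss < best[0].loss):
                best = (run, sol.x)
        if best is None:
            raise FittingError(
                f"subject {self.record.subject_id!r}: no optimisation run converged "
                f"({len(runs)} attempted)"
            )
        run, x_best = best
        data_loss = float(np.sum(self._data_residuals(x_best) ** 2))
        at_bounds = tuple(
            n
            for n, v, lo, hi in zip(self.free, x_best, self._lo, self._hi)
            if v - lo < 1e-6 or hi - v < 1e-6
        )
        warnings = ()
        if at_bounds:
            warnings = (f"parameters at bounds: {', '.join(at_bounds)}",)
        return GlucoseInsulinFit(
            record=self.record,
            params=run.params,
            loss=run.loss,
            free=self.free,
            data_loss=data_loss,
            runs=runs,
            converged=True,
            seed=seed,
            at_bounds=at_bounds,
            warnings=warnings,
            options=self.fit_options,
        )


def fit_patient(
    record: OGTTRecord,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
    free=DEFAULT_FREE,
    fixed=None,
    **model_options,
) -> GlucoseInsulinFit:
    """Convenience wrapper: build the model and fit it in one call."""
    return GlucoseInsulinModel(record, free=free, fixed=fixed, **model_options).fit(
        seed=seed, n_starts=n_starts
    )


# ---------------------------------------------------------------------------
# repeat-fit consistency
# ---------------------------------------------------------------------------


@dataclass
class RepeatFitSummary:
    """Across-run dispersion of the estimates (uniqueness check)."""

    estimates: dict  # name -> list of per-run values
    cv: dict  # name -> coefficient of variation across runs
    non_unique: tuple  # names whose CV exceeds the threshold
    cv_threshold: float
    n_runs: int
    losses: tuple

    def unique(self) -> tuple:
        return tuple(n for n in self.cv if n not in self.non_unique)


def repeat_fit_consistency(
    record: OGTTRecord,
    n_runs: int = 5,
    seed: int = 0,
    cv_threshold: float = 0.01,
    **fit_options,
) -> RepeatFitSummary:
    """Repeat the whole multi-start fit ``n_runs`` times with fresh seeds.

    A parameter is flagged *non-unique* when its coefficient of variation
    across runs exceeds ``cv_threshold``: the data do not pin it down.
    """
    if n_runs < 5:
        raise ValidationError(f"need at least 5 repeat runs, got {n_runs}")
    fits = []
    errors = []
    for i in range(n_runs):
        try:
            fits.append(fit_patient(record, seed=seed + i, **fit_options))
        except FittingError as exc:
            errors.append(exc)
    if not fits:
        raise FittingError(f"all {n_runs} repeat runs failed: {errors[0]}")
    free = fits[0].free
    estimates = {n: [getattr(f.params, n) for f in fits] for n in free}
    cv = {}
    for n, vals in estimates.items():
        arr = np.asarray(vals)
        cv[n] = float(arr.std() / arr.mean()) if arr.mean() > 0 else float("inf")
    non_unique = tuple(n for n, c in cv.items() if c > cv_threshold)
    return RepeatFitSummary(
        estimates=estimates,
        cv=cv,
        non_unique=non_unique,
        cv_threshold=cv_threshold,
        n_runs=len(fits),
        losses=tuple(f.loss for f in fits),
    )


# ---------------------------------------------------------------------------
# measurement sensitivity (perturb the data, refit)
# ---------------------------------------------------------------------------


@dataclass
class PerturbationRefit:
    measurement: str  # "glycemia" | "insulinemia"
    time_min: float
    direction: int  # +1 | -1
    deviations: dict | None  # name -> relative deviation, None if refit failed


@dataclass
class MeasurementSensitivity:
    """Per-parameter response to +/-10% perturbations of the 10 measurements."""

    refits: list
    max_deviation: dict  # name -> max relative deviation over all refits
    sensitive: tuple  # names whose max deviation exceeds the threshold
    relative_step: float
    threshold: float

    @property
    def n_refits(self) -> int:
        return len(self.refits)


def measurement_sensitivity(
    record: OGTTRecord,
    fit: GlucoseInsulinFit,
    relative_step: float = 0.10,
    threshold: float = 0.20,
    dt: float | None = None,
) -> MeasurementSensitivity:
    """Perturb each measurement up and down and refit (warm-started).

    The default protocol perturbs all ten measurements (five glycemia,
    five insulinemia) by +/-10%, i.e. 20 refits per record.  A parameter
    is labelled measurement-sensitive when its maximum relative deviation
    across refits exceeds ``threshold``.
    """
    refits: list[PerturbationRefit] = []
    base = fit.params
    free = fit.free
    if dt is None:
        dt = fit.options.get("dt", 0.5)
    for which in ("glycemia", "insulinemia"):
        for k, t in enumerate(record.times):
            for direction in (+1, -1):
                values = np.asarray(getattr(record, which), float).copy()
                values[k] *= 1.0 + direction * relative_step
                kwargs = {
                    "subject_id": record.subject_id,
                    "times": record.times,
                    "glycemia": record.glycemia,
                    "insulinemia": record.insulinemia,
                    "dose_g": record.dose_g,
                    "source_units": record.source_units,
                }
                kwargs[which] = tuple(values)
                perturbed = OGTTRecord(**kwargs)
                try:
                    opts = dict(fit.options)
                    opts.pop("dt", None)
                    refit = GlucoseInsulinModel(
                        perturbed, free=free, fixed=fit_fixed(fit), dt=dt, **opts
                    ).fit(seed=fit.seed or 0, n_starts=0, x0=base)
                    deviations = {
                        n: abs(getattr(refit.params, n) - getattr(base, n)) / getattr(base, n)
                        for n in free
                    }
                except FittingError:
                    deviations = None
                refits.append(
                    PerturbationRefit(
                        measurement=which,
                        time_min=t,
                        direction=direction,
                        deviations=deviations,
                    )
                )
    max_dev = {
        n: max((r.deviations[n] for r in refits if r.deviations is not None), default=float("nan"))
        for n in free
    }
    sensitive = tuple(n for n, v in max_dev.items() if np.isfinite(v) and v > threshold)
    return MeasurementSensitivity(
        refits=refits,
        max_deviation=max_dev,
        sensitive=sensitive,
        relative_step=relative_step,
        threshold=threshold,
    )


def fit_fixed(fit: GlucoseInsulinFit) -> dict:
    """The fixed-parameter values a fit used (for consistent refits)."""
    return {
        n: getattr(fit.params, n)
        for n in FIT_BOUNDS
        if n not in fit.free
    }


# ---------------------------------------------------------------------------
# curve-shape sensitivity (perturb a parameter, compare curves)
# ---------------------------------------------------------------------------


@dataclass
class CurveShapeSensitivity:
    indices: dict  # name -> normalised curve-change index (NaN if undefined)
    sensitive: tuple
    relative_step: float
    threshold: float


def curve_shape_sensitivity(
    params: ModelParameters,
    parameter_names=None,
    relative_step: float = 0.10,
    threshold: float = 0.05,
    horizon_min: float = 120.0,
    dt: float = 0.5,
) -> CurveShapeSensitivity:
    """How much a +/-10% change of each parameter reshapes the (G, I) curves.

    The index for parameter p is the L2 norm of the change of the
    basal-normalised excursion curves, divided by the norm of the
    unperturbed excursion, averaged over the up and down perturbations.
    Parameters with an index above ``threshold`` are labelled sensitive.
    """
    if parameter_names is None:
        parameter_names = [n for n in ModelParameters.names() if n != "D" or params.D > 0]
    grid = np.arange(0.0, horizon_min + 1.0, 2.0)

    def excursion(p):
        G, I = simulate_sampled_fast(p, grid, dt=dt)
        return np.concatenate([(G - p.G_b) / p.G_b, (I - p.I_b) / p.I_b])

    base = excursion(params)
    base_norm = float(np.linalg.norm(base))
    indices = {}
    for name in parameter_names:
        if relative_step == 0.0:
            indices[name] = 0.0
            continue
        changes = []
        for direction in (+1, -1):
            try:
                pert = params.replace(
                    **{name: getattr(params, name) * (1.0 + direction * relative_step)}
                )
                changes.append(np.linalg.norm(excursion(pert) - base))
            except (IntegrationError, ValidationError):
                changes.append(float("nan"))
        if base_norm == 0.0:
            indices[name] = 0.0 if np.allclose(changes, 0.0) else float("inf")
        else:
            indices[name] = float(np.mean(changes) / base_norm)
    sensitive = tuple(
        n for n, v in indices.items() if np.isfinite(v) and v > threshold
    )
    return CurveShapeSensitivity(
        indices=indices,
        sensitive=sensitive,
        relative_step=relative_step,
        threshold=threshold,
    )
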