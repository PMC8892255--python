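"""Synthetic subjects, cohorts and crossover intervention studies.

The generator emulates the statistical structure of a 5-point OGTT
cohort study so that every stage of the pipeline can be exercised and
validated against known ground truth:

* per-subject physiological parameters drawn from log-logistic
  distributions whose centres and spreads follow the cohort-derived
  diagnostic ranges (healthy template) or sit on the undesirable side of
  them (non-healthy template: slower gastric emptying and intestinal
  transit, weaker insulin-dependent uptake, higher basal glycemia and
  insulinemia, reduced incretin potentiation);
* a shared latent factor in the non-healthy template that couples
  motility, transit, insulin sensitivity and pancreatic responsiveness,
  reproducing the stronger between-subsystem correlations seen in
  dysglycemic cohorts;
* curves simulated with the compartmental model and sampled at
  0/30/60/90/120 min after a 75 g dose;
* multiplicative log-normal measurement noise (mean-one), default CV 3%
  for glycemia and 7% for insulinemia, matching routine assay precision.

Structural closures (k_gj, k_xi) and the parameters a 2-hour OGTT barely
identifies (k_lambda, f_gi) are population constants in the templates,
mirroring the fitting convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrationError, ValidationError
from .intervention import Arm, InterventionStudy, SubjectArms, CONTROL_DOSE
from .model import simulate_sampled_fast
from .ndn import compute_ndns
from .params import ModelParameters, NDN_NAMES
from .records import DEFAULT_TIMES, OGTTRecord
from .units import glucose_grams_to_mmol

def shape_for_interval(lo: float, hi: float, mass: float = 0.90) -> float:
    """Log-logistic shape whose central ``mass`` interval spans (lo, hi)."""
    odds = (1.0 + mass) / (1.0 - mass)
    return 2.0 * math.log(odds) / math.log(hi / lo)


@dataclass(frozen=True)
class IndexDistribution:
    """Sampling law for one parameter: log-logistic or constant.

    ``shape=None`` makes the parameter a population constant at
    ``center``.  Draws outside ``support`` are redrawn (then clipped),
    keeping every sampled vector dynamically plausible.
    """

    center: float
    shape: float | None = None
    support: tuple | None = None

    def draw(self, rng: np.random.Generator) -> float:
        if self.shape is None:
            return self.center
        for _ in range(200):
            u = rng.uniform()
            x = self.center * (u / (1.0 - u)) ** (1.0 / self.shape)
            if self.support is None or self.support[0] <= x <= self.support[1]:
                return x
        return float(np.clip(x, *self.support))


def _spread(center, lo, hi, widen=1.5):
    return IndexDistribution(
        center=center,
        shape=shape_for_interval(lo, hi),
        support=(lo / widen, hi * widen),
    )


def _loose(center, shape=8.0, widen=3.0):
    return IndexDistribution(center=center, shape=shape, support=(center / widen, center * widen))


def _const(center):
    return IndexDistribution(center=center)


#: Healthy template: centres at the geometric midpoints of the healthy
#: diagnostic ranges; basal levels at the healthy-cohort medians with
#: spreads matched to the cohort's reported 95% intervals.
HEALTHY_TEMPLATE = {
    "k_js": _spread(0.0695, 0.0198, 0.244),
    "tau": _spread(89.4, 72.0, 111.0),
    "k_gj": _const(0.02),
    "k_lg": _spread(0.047, 0.00371, 0.602),
    "k_xg": _loose(0.015),
    "k_xgi": _spread(1.56e-4, 9.41e-6, 2.59e-3),
    "k_lambda": _const(0.01),
    "gamma": _loose(0.04),
    "f_gi": _const(2.0e-3),
    "eta": _spread(0.0508, 0.0145, 0.178),
    "beta": _loose(1.8),
    "k_xi": _const(0.05),
    "G_b": IndexDistribution(4.80, shape_for_interval(4.067, 5.40, 0.95), (3.87, 5.67)),
    "I_b": IndexDistribution(30.0, shape_for_interval(14.03, 81.67, 0.95), (11.0, 100.0)),
}

#: Non-healthy template: motility, transit and insulin-dependent uptake
#: on the undesirable side, elevated basal levels, reduced incretin
#: potentiation and pancreatic responsiveness, stronger insulin-
#: independent reliance.
NONHEALTHY_TEMPLATE = {
    "k_js": _spread(0.01407, 0.01, 0.0198),
    "tau": _spread(56.9, 45.0, 72.0),
    "k_gj": _const(0.02),
    "k_lg": _loose(0.06, shape=3.0, widen=4.0),
    "k_xg": _loose(0.025),
    "k_xgi": _loose(3.0e-6, shape=3.0, widen=30.0),
    "k_lambda": _const(0.01),
    "gamma": _loose(0.03),
    "f_gi": _const(1.2e-3),
    "eta": _loose(0.07, shape=4.0, widen=4.0),
    "beta": _loose(1.2),
    "k_xi": _const(0.05),
    "G_b": IndexDistribution(5.06, shape_for_interval(4.183, 6.389, 0.95), (3.98, 6.70)),
    "I_b": IndexDistribution(57.6, shape_for_interval(13.89, 201.5, 0.95), (13.0, 222.0)),
}

#: Shared latent factor couplings in the non-healthy state.
NONHEALTHY_LATENT = {"k_js": 0.35, "tau": 0.20, "k_xgi": 0.50, "beta": 0.35}

TEMPLATES = {"healthy": HEALTHY_TEMPLATE, "non-healthy": NONHEALTHY_TEMPLATE}
LATENT_LOADINGS = {"healthy": {}, "non-healthy": NONHEALTHY_LATENT}

#: accept simulated glycemia only below this bound (mM): wilder parameter
#: combinations are redrawn as dynamically implausible
GLYCEMIA_SANITY_MAX = 60.0


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort."""

    n: int
    template: str = "healthy"
    overrides: dict = field(default_factory=dict)  # name -> IndexDistribution
    latent_loadings: dict | None = None  # name -> loading on the shared factor
    noise_cv_glycemia: float = 0.03
    noise_cv_insulinemia: float = 0.07
    dose_g: float = 75.0
    sample_times: tuple = DEFAULT_TIMES
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"cohort size must be >= 1, got {self.n}")
        if self.template not in TEMPLATES:
            raise ConfigError(f"unknown template {self.template!r}; use {sorted(TEMPLATES)}")
        if self.noise_cv_glycemia < 0 or self.noise_cv_insulinemia < 0:
            raise ValidationError("noise CVs must be >= 0")
        if 0.0 not in self.sample_times:
            raise ValidationError("sample times must include the basal 0-min sample")
        unknown = set(self.overrides) - set(ModelParameters.names())
        if unknown:
            raise ConfigError(f"unknown parameters in overrides: {sorted(unknown)}")

    @property
    def distributions(self) -> dict:
        d = dict(TEMPLATES[self.template])
        d.update(self.overrides)
        return d

    @property
    def loadings(self) -> dict:
        if self.latent_loadings is not None:
            return dict(self.latent_loadings)
        return dict(LATENT_LOADINGS[self.template])


def _draw_one(spec: CohortSpec, rng: np.random.Generator) -> ModelParameters:
    dists = spec.distributions
    loadings = spec.loadings
    z = rng.standard_normal() if loadings else 0.0
    values = {}
    for name in ModelParameters.names():
        if name == "D":
            values[name] = glucose_grams_to_mmol(spec.dose_g)
            continue
        x = dists[name].draw(rng)
        if name in loadings:
            x *= math.exp(loadings[name] * z)
            if dists[name].support is not None:
                x = float(np.clip(x, *dists[name].support))
        values[name] = x
    return ModelParameters(**values)


def sample_parameters(spec: CohortSpec) -> list:
    """Draw ``spec.n`` parameter vectors; reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    return [_draw_one(spec, rng) for _ in range(spec.n)]


def _noise_factors(rng, cv: float, size: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size) - 0.5 * sigma * sigma)


@dataclass
class SyntheticCohort:
    """Records paired with the ground-truth parameters that made them."""

    spec: CohortSpec
    records: list  # of OGTTRecord
    parameters: list  # of ModelParameters, aligned with records
    n_resampled: int = 0

    def parameter_table(self, include_ndns: bool = True) -> pd.DataFrame:
        rows = []
        for rec, p in zip(self.records, self.parameters):
            row = {"subject_id": rec.subject_id, **p.to_dict()}
            if include_ndns:
                nd = compute_ndns(p)
                row.update({k: getattr(nd, k) for k in NDN_NAMES})
            rows.append(row)
        return pd.DataFrame(rows).set_index("subject_id")


def generate_cohort(spec: CohortSpec, id_prefix: str = "S") -> SyntheticCohort:
    """Simulate a cohort of noisy 5-point OGTT records with known truth.

    Parameter draws whose simulated glycemia leaves the physiological
    range are resampled (at most 10 times each, counted on the result).
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.sample_times, dtype=float)
    records, parameters = [], []
    n_resampled = 0
    for i in range(spec.n):
        for attempt in range(11):
            params = _draw_one(spec, rng)
            try:
                G, I = simulate_sampled_fast(params, times)
            except IntegrationError:
                n_resampled += 1
                continue
            if np.max(G) < GLYCEMIA_SANITY_MAX:
                break
            n_resampled += 1
        else:
            raise IntegrationError(
                "could not draw a dynamically plausible subject in 10 retries",
                params=params,
            )
        G = G * _noise_factors(rng, spec.noise_cv_glycemia, G.size)
        I = I * _noise_factors(rng, spec.noise_cv_insulinemia, I.size)
        records.append(
            OGTTRecord(
                subject_id=f"{id_prefix}{i + 1:03d}",
                times=tuple(times),
                glycemia=tuple(G),
                insulinemia=tuple(I),
                dose_g=spec.dose_g,
            )
        )
        parameters.append(params)
    return SyntheticCohort(
        spec=spec, records=records, parameters=parameters, n_resampled=n_resampled
    )


# ---------------------------------------------------------------------------
# intervention studies
# ---------------------------------------------------------------------------

DEFAULT_DOSES = (60.0, 120.0, 180.0)


def generate_intervention_study(
    spec: CohortSpec,
    dose_effects: dict,
    doses: tuple = DEFAULT_DOSES,
    arm_cv: float = 0.10,
    with_records: bool = True,
) -> InterventionStudy:
    """Generate a paired crossover study from per-dose parameter shifts.

    ``dose_effects`` maps dose (mg) to multiplicative parameter shifts,
    e.g. ``{180: {"tau": 1.3}}`` slows intestinal transit by 30% at the
    top dose.  Every arm (control included) receives independent
    log-normal day-to-day jitter of CV ``arm_cv`` on the spread
    parameters, so paired contrasts see realistic within-subject
    variability.  Unknown parameter names raise a configuration error.
    """
    for dose, shifts in dose_effects.items():
        if dose not in doses:
            raise ConfigError(f"dose_effects key {dose!r} is not one of the doses {doses}")
        unknown = set(shifts) - set(ModelParameters.names())
        if unknown:
            raise ConfigError(f"unknown parameters in dose_effects[{dose!r}]: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    baselines = [_draw_one(spec, rng) for _ in range(spec.n)]
    dists = spec.distributions
    jittered_names = [
        n for n in ModelParameters.names() if n != "D" and dists[n].shape is not None
    ]
    sigma = math.sqrt(math.log1p(arm_cv * arm_cv)) if arm_cv > 0 else 0.0
    times = np.asarray(spec.sample_times, dtype=float)
    subjects = []
    for i, base in enumerate(baselines):
        arms = {}
        for dose in (CONTROL_DOSE,) + tuple(doses):
            values = base.to_dict()
            if sigma > 0:
                for name in jittered_names:
                    values[name] *= math.exp(rng.normal(0.0, sigma) - 0.5 * sigma * sigma)
            for name, mult in dose_effects.get(dose, {}).items():
                values[name] *= mult
            params = ModelParameters(**values)
            record = None
            if with_records:
                G, I = simulate_sampled_fast(params, times)
                G = G * _noise_factors(rng, spec.noise_cv_glycemia, G.size)
                I = I * _noise_factors(rng, spec.noise_cv_insulinemia, I.size)
                record = OGTTRecord(
                    subject_id=f"P{i + 1:03d}",
                    times=tuple(times),
                    glycemia=tuple(G),
                    insulinemia=tuple(I),
                    dose_g=spec.dose_g,
                )
            arms[dose] = Arm(dose_mg=dose, record=record, params=params)
        subjects.append(SubjectArms(subject_id=f"P{i + 1:03d}", arms=arms))
    return InterventionStudy(subjects=subjects)
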