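"""Cohort-level distribution fitting and diagnostic-range construction.

Physiological indices are positive and right-skewed, so each index is
modelled with a two-parameter log-logistic distribution (scipy's ``fisk``
with location fixed at 0): density scale alpha > 0, shape beta > 0 and
closed-form quantile Q(p) = alpha * (p / (1 - p))**(1 / beta).

Range construction for one index proceeds exactly as the cohort study
does: fit healthy and non-healthy cohorts, test whether they differ
(two-sample Kolmogorov–Smirnov), find the direction of the non-healthy
shift (tail-occupancy comparison), take the healthy cohort's central 90%
interval, and split it at the point where the two fitted densities cross
(equal-density threshold): normal runs from that threshold toward the
healthy side, undesirable covers the remainder of the healthy interval,
abnormal lies beyond it.  A Youden-optimal ROC threshold is computed
alongside as a diagnostic — the two "closely coincide" on well-separated
cohorts but the equal-density value defines the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateDensitiesError, FittingError, ValidationError
from .ranges import RangeRow, RangeTable

DEFAULT_INTERVAL_MASS = 0.90
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# log-logistic fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogLogisticFit:
    """Two-parameter log-logistic MLE (location fixed at zero)."""

    scale: float  # alpha; also the median
    shape: float  # beta
    log_likelihood: float
    n: int

    def quantile(self, p):
        p = np.asarray(p, dtype=float)
        return self.scale * (p / (1.0 - p)) ** (1.0 / self.shape)

    def cdf(self, x):
        return stats.fisk.cdf(x, c=self.shape, scale=self.scale)

    def pdf(self, x):
        return stats.fisk.pdf(x, c=self.shape, scale=self.scale)

    @property
    def median(self) -> float:
        return self.scale


def fit_loglogistic(samples) -> LogLogisticFit:
    """Maximum-likelihood log-logistic fit to positive samples (n >= 10)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValidationError(f"need at least 10 samples, got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValidationError("log-logistic samples must be finite and > 0")
    if np.allclose(x, x[0]):
        raise FittingError("degenerate sample: all values identical")
    c, loc, scale = stats.fisk.fit(x, floc=0)
    if not (np.isfinite(c) and np.isfinite(scale) and c > 0 and scale > 0):
        raise FittingError("log-logistic MLE did not converge")
    ll = float(np.sum(stats.fisk.logpdf(x, c=c, scale=scale)))
    return LogLogisticFit(scale=float(scale), shape=float(c), log_likelihood=ll, n=int(x.size))


def central_interval(fit: LogLogisticFit, mass: float = DEFAULT_INTERVAL_MASS):
    """Central probability interval (Q((1-mass)/2), Q((1+mass)/2))."""
    if not (0.0 < mass < 1.0):
        raise ValidationError(f"interval mass must be in (0, 1), got {mass}")
    lo = float(fit.quantile((1.0 - mass) / 2.0))
    hi = float(fit.quantile((1.0 + mass) / 2.0))
    return lo, hi


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    different: bool  # at the construction alpha


def ks_compare(samples_h, samples_nh, alpha: float = DEFAULT_ALPHA) -> KSResult:
    """Two-sample Kolmogorov–Smirnov comparison of cohort distributions."""
    a = np.asarray(samples_h, dtype=float)
    b = np.asarray(samples_nh, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both cohorts must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        different=bool(res.pvalue < alpha),
    )


def _two_proportion_t(p1: float, n1: int, p2: float, n2: int) -> float:
    """p-value of a pooled two-proportion comparison referred to Student t.

    The tail-occupancy comparison is specified as a t-test on the two
    percentages; this is the pooled-variance z statistic referred to a
    t distribution with n1 + n2 - 2 degrees of freedom.
    """
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0:
        return 1.0
    t = (p1 - p2) / np.sqrt(var)
    return float(2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2))


def tail_shift_test(
    samples_h,
    samples_nh,
    tail_mass: float = DEFAULT_INTERVAL_MASS,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Direction of the non-healthy shift: 'left', 'right' or 'none'.

    The healthy cohort's 90% left-tail range (below its 90th percentile)
    and 90% right-tail range (above its 10th percentile) are computed
    from the empirical quantiles; the fraction of each cohort inside each
    range is compared between cohorts.  A significant non-healthy excess
    beyond a range boundary marks the shift direction.
    """
    a = np.asarray(samples_h, dtype=float)
    b = np.asarray(samples_nh, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both cohorts must be non-empty")
    hi = np.quantile(a, tail_mass)  # left-tail range is (-inf, hi]
    lo = np.quantile(a, 1.0 - tail_mass)  # right-tail range is [lo, inf)
    in_left_h, in_left_nh = np.mean(a <= hi), np.mean(b <= hi)
    in_right_h, in_right_nh = np.mean(a >= lo), np.mean(b >= lo)
    p_left = _two_proportion_t(in_left_h, a.size, in_left_nh, b.size)
    p_right = _two_proportion_t(in_right_h, a.size, in_right_nh, b.size)
    # non-healthy mass escaping the left-tail range means a rightward shift
    right_excess = in_left_h - in_left_nh  # fraction pushed above hi
    left_excess = in_right_h - in_right_nh  # fraction pushed below lo
    candidates = []
    if p_left < alpha and right_excess > 0:
        candidates.append(("right", p_left, right_excess))
    if p_right < alpha and left_excess > 0:
        candidates.append(("left", p_right, left_excess))
    if not candidates:
        return "none"
    return max(candidates, key=lambda c: c[2])[0]


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


def equal_density_threshold(
    fit_h: LogLogisticFit,
    fit_nh: LogLogisticFit,
    search_interval=None,
) -> float:
    """Crossing point of the two fitted densities between the medians.

    Brackets a sign change of f_h - f_nh on a dense grid between the two
    medians (or within ``search_interval``) and bisects it; with several
    roots the one nearest the healthy median is returned.
    """
    if (
        abs(fit_h.scale - fit_nh.scale) < 1e-12 * max(fit_h.scale, fit_nh.scale)
        and abs(fit_h.shape - fit_nh.shape) < 1e-12 * max(fit_h.shape, fit_nh.shape)
    ):
        raise DegenerateDensitiesError("identical fitted densities have no crossing point")
    if search_interval is None:
        lo, hi = sorted((fit_h.median, fit_nh.median))
        if hi - lo < 1e-12 * hi:  # equal medians, different shapes
            lo, hi = 0.5 * lo, 2.0 * hi
    else:
        lo, hi = search_interval
    grid = np.linspace(lo, hi, 4001)
    grid = grid[grid > 0]
    diff = fit_h.pdf(grid) - fit_nh.pdf(grid)
    sign = np.sign(diff)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size == 0:
        raise DegenerateDensitiesError(
            "densities do not cross inside the search interval"
        )
    roots = []
    for i in crossings:
        root = optimize.brentq(
            lambda x: fit_h.pdf(x) - fit_nh.pdf(x), grid[i], grid[i + 1], xtol=1e-12
        )
        roots.append(root)
    return float(min(roots, key=lambda r: abs(r - fit_h.median)))


def roc_youden_threshold(samples_h, samples_nh):
    """Youden-optimal cut over all pooled midpoints, both orientations.

    Returns ``(threshold, J, direction)`` where direction is "high" when
    values above the threshold are called non-healthy and "low"
    otherwise.  Ties are broken toward the healthy median.
    """
    a = np.asarray(samples_h, dtype=float)
    b = np.asarray(samples_nh, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both cohorts must be non-empty")
    pooled = np.unique(np.concatenate([a, b]))
    if pooled.size == 1:
        return float(pooled[0]), 0.0, "high"
    cuts = 0.5 * (pooled[:-1] + pooled[1:])
    med_h = np.median(a)
    best = None
    for cut in cuts:
        for direction in ("high", "low"):
            if direction == "high":
                sens = np.mean(b > cut)
                spec = np.mean(a <= cut)
            else:
                sens = np.mean(b < cut)
                spec = np.mean(a >= cut)
            J = float(sens + spec - 1.0)
            key = (J, -abs(cut - med_h))
            if best is None or key > best[0]:
                best = (key, float(cut), direction)
    (J, _), threshold, direction = best
    return threshold, J, direction


# ---------------------------------------------------------------------------
# range construction
# ---------------------------------------------------------------------------


@dataclass
class RangeConstruction:
    """Everything that went into one index's diagnostic-range row."""

    index: str
    fit_h: LogLogisticFit | None
    fit_nh: LogLogisticFit | None
    healthy_interval: tuple
    ks: KSResult
    direction: str  # 'left' | 'right' | 'none'
    equal_density: float | None
    youden_threshold: float | None
    youden_J: float | None
    discriminative: bool
    row: RangeRow | None
    notes: tuple = ()


def construct_range(
    index: str,
    samples_h,
    samples_nh,
    mass: float = DEFAULT_INTERVAL_MASS,
    alpha: float = DEFAULT_ALPHA,
    units: str = "-",
    process: str = "",
) -> RangeConstruction:
    """Build one diagnostic-range row from healthy and non-healthy samples."""
    samples_h = np.asarray(samples_h, dtype=float)
    samples_nh = np.asarray(samples_nh, dtype=float)
    if samples_h.size < 30 or samples_nh.size < 30:
        import warnings

        warnings.warn(
            f"{index}: fewer than 30 subjects per cohort; ranges will be unstable",
            stacklevel=2,
        )
    try:
        fit_h = fit_loglogistic(samples_h)
        fit_nh = fit_loglogistic(samples_nh)
    except FittingError as exc:
        ks = ks_compare(samples_h, samples_nh, alpha=alpha)
        return RangeConstruction(
            index=index,
            fit_h=None,
            fit_nh=None,
            healthy_interval=(float("nan"), float("nan")),
            ks=ks,
            direction="none",
            equal_density=None,
            youden_threshold=None,
            youden_J=None,
            discriminative=False,
            row=None,
            notes=(f"not discriminative: distribution fit failed ({exc})",),
        )
    interval = central_interval(fit_h, mass)
    ks = ks_compare(samples_h, samples_nh, alpha=alpha)
    direction = tail_shift_test(samples_h, samples_nh, tail_mass=mass, alpha=alpha)
    notes = []
    if not ks.different or direction == "none":
        return RangeConstruction(
            index=index,
            fit_h=fit_h,
            fit_nh=fit_nh,
            healthy_interval=interval,
            ks=ks,
            direction=direction,
            equal_density=None,
            youden_threshold=None,
            youden_J=None,
            discriminative=False,
            row=None,
            notes=("not discriminative: cohorts do not differ at the stated alpha",),
        )
    try:
        thr = equal_density_threshold(fit_h, fit_nh)
    except DegenerateDensitiesError:
        thr = None
        notes.append("densities do not cross between medians; row not built")
    youden_thr, youden_J, _ = roc_youden_threshold(samples_h, samples_nh)
    row = None
    if thr is not None:
        lo, hi = interval
        thr_clipped = float(np.clip(thr, lo, hi))
        if thr_clipped != thr:
            notes.append("equal-density threshold clipped to the healthy interval")
        if not (lo < thr_clipped < hi):
            # densities cross outside the healthy interval: no undesirable
            # zone can be drawn between threshold and interval boundary
            thr = None
            notes.append("threshold outside the healthy interval; row not built")
    if thr is not None:
        if direction == "right":  # non-healthy values are larger
            row = RangeRow(
                index=index,
                process=process,
                units=units,
                healthy=(lo, thr_clipped),
                undesirable=(thr_clipped, hi),
                abnormal_op=">",
                abnormal_bound=hi,
            )
        else:
            row = RangeRow(
                index=index,
                process=process,
                units=units,
                healthy=(thr_clipped, hi),
                undesirable=(lo, thr_clipped),
                abnormal_op="<",
                abnormal_bound=lo,
            )
    return RangeConstruction(
        index=index,
        fit_h=fit_h,
        fit_nh=fit_nh,
        healthy_interval=interval,
        ks=ks,
        direction=direction,
        equal_density=thr,
        youden_threshold=youden_thr,
        youden_J=youden_J,
        discriminative=row is not None,
        row=row,
        notes=tuple(notes),
    )


def build_range_table(
    cohort_values_h,
    cohort_values_nh,
    indices=None,
    mass: float = DEFAULT_INTERVAL_MASS,
    alpha: float = DEFAULT_ALPHA,
    units: dict | None = None,
):
    """Construct a diagnostic range table from two cohorts' index tables.

    ``cohort_values_h`` / ``cohort_values_nh`` map index name -> array of
    per-subject values (e.g. columns of a parameter table).  Returns
    ``(RangeTable, {index: RangeConstruction})``; indices whose cohorts
    do not differ are reported in the constructions but omitted from the
    table (their rows are "not discriminative").

    Raw KS p-values are accompanied by Benjamini–Hochberg q-values in the
    construction report.
    """
    units = units or {}
    if indices is None:
        indices = [k for k in cohort_values_h if k in cohort_values_nh]
    constructions = {}
    for index in indices:
        constructions[index] = construct_range(
            index,
            cohort_values_h[index],
            cohort_values_nh[index],
            mass=mass,
            alpha=alpha,
            units=units.get(index, "-"),
        )
    # BH adjustment across indices, attached to the constructions
    names = list(constructions)
    pvals = np.array([constructions[n].ks.p_value for n in names])
    order = np.argsort(pvals)
    q = np.empty_like(pvals)
    m = len(pvals)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, pvals[i] * m / (rank_idx + 1))
        q[i] = prev
    for n, qv in zip(names, q):
        constructions[n].notes = constructions[n].notes + (f"BH q-value: {qv:.4g}",)
    rows = [c.row for c in constructions.values() if c.row is not None]
    return RangeTable(rows), constructions
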