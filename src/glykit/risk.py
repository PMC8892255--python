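"""Dysglycemia risk: published logistic score, de-novo fits, metrics.

The published risk model maps six per-subject indices to the probability
of dysglycemia through a fixed-coefficient logistic score

    z = a1*eta + a2*Pi_X + a3*G_b + a4*I_b + a5*tau + a6*k_xgi + a0
    P(dysglycemia) = exp(z) / (1 + exp(z))

with the predictors on the canonical table scales (G_b in mM, I_b in pM,
tau in min, k_xgi in min^-1 pM^-1, eta as tabulated, Pi_X dimensionless)
— the coefficient magnitudes only make sense on those scales.  A subject
is labelled non-healthy when P >= 0.60 (boundary inclusive).

De-novo model building mirrors the cohort study's procedure: a logistic
regression fitted by maximum likelihood (statsmodels' Newton scoring,
i.e. IRLS), with backward elimination of the predictor carrying the
largest Wald p-value until all remaining coefficients are significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import SeparationError, ValidationError
from .ndn import compute_ndns
from .params import ModelParameters, NDNSet

#: Printed coefficients of the published simple model.
PUBLISHED_COEFFICIENTS = {
    "eta": 0.5310,
    "Pi_X": 0.1960,
    "G_b": 1.2799,
    "I_b": 0.0330,
    "tau": -0.0187,
    "k_xgi": -798.2059,
}
PUBLISHED_INTERCEPT = -6.0103
DEFAULT_RISK_THRESHOLD = 0.60

PREDICTOR_UNITS = {
    "eta": "L^-3",
    "Pi_X": "-",
    "G_b": "mM",
    "I_b": "pM",
    "tau": "min",
    "k_xgi": "min^-1 pM^-1",
}


@dataclass(frozen=True)
class RiskModel:
    """A logistic dysglycemia-risk model: coefficients + threshold."""

    coefficients: dict  # predictor name -> coefficient
    intercept: float
    threshold: float = DEFAULT_RISK_THRESHOLD
    units: dict = field(default_factory=lambda: dict(PREDICTOR_UNITS))

    @property
    def predictors(self) -> tuple:
        return tuple(self.coefficients)

    def linear_score(self, values: dict) -> float:
        missing = [n for n in self.coefficients if n not in values]
        if missing:
            raise ValidationError(f"missing risk predictors: {missing}")
        return self.intercept + sum(
            c * float(values[n]) for n, c in self.coefficients.items()
        )

    def predict(self, values: dict) -> float:
        z = self.linear_score(values)
        # numerically safe logistic
        if z >= 0:
            return 1.0 / (1.0 + math.exp(-z))
        ez = math.exp(z)
        return ez / (1.0 + ez)

    def classify(self, values: dict) -> str:
        return classify_risk(self.predict(values), self.threshold)


PUBLISHED_RISK_MODEL = RiskModel(
    coefficients=dict(PUBLISHED_COEFFICIENTS), intercept=PUBLISHED_INTERCEPT
)


def risk_predictors(params: ModelParameters, ndns: NDNSet | None = None) -> dict:
    """Assemble the published model's predictor values for one subject."""
    if ndns is None:
        ndns = compute_ndns(params)
    return {
        "eta": params.eta,
        "Pi_X": ndns.Pi_X,
        "G_b": params.G_b,
        "I_b": params.I_b,
        "tau": params.tau,
        "k_xgi": params.k_xgi,
    }


def published_risk(params: ModelParameters, ndns: NDNSet | None = None) -> float:
    """Probability of dysglycemia under the published fixed-coefficient model."""
    return PUBLISHED_RISK_MODEL.predict(risk_predictors(params, ndns))


def classify_risk(p: float, threshold: float = DEFAULT_RISK_THRESHOLD) -> str:
    """Label a probability: non-healthy iff p >= threshold (inclusive)."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"probability must be in [0, 1], got {p}")
    return "non-healthy" if p >= threshold else "healthy"


# ---------------------------------------------------------------------------
# de-novo logistic fitting
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    coefficients: dict  # includes "const" when an intercept was fitted
    std_errors: dict
    p_values: dict
    log_likelihood: float
    aic: float
    n: int
    fitted_probabilities: np.ndarray
    exog_names: tuple

    def to_risk_model(self, threshold: float = DEFAULT_RISK_THRESHOLD) -> RiskModel:
        coeffs = {k: v for k, v in self.coefficients.items() if k != "const"}
        return RiskModel(
            coefficients=coeffs,
            intercept=self.coefficients.get("const", 0.0),
            threshold=threshold,
            units={k: PREDICTOR_UNITS.get(k, "?") for k in coeffs},
        )


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.copy()
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _check_design(Xd: pd.DataFrame) -> None:
    mat = Xd.to_numpy()
    if not np.all(np.isfinite(mat)):
        raise ValidationError("design matrix contains non-finite values")
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns via QR pivoting on the correlation structure
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [Xd.columns[i] for i in range(len(diag)) if diag[i] < 1e-10 * diag.max()]
        raise ValidationError(f"singular design matrix; collinear columns: {bad or 'unknown'}")


def fit_logistic(X, y, add_intercept: bool = True) -> LogisticFit:
    """Fit a logistic regression by maximum likelihood.

    ``X`` is a DataFrame (column names become predictor names) or 2-D
    array; ``y`` holds binary labels.  Raises :class:`SeparationError`
    when the classes are perfectly separated (the MLE does not exist) and
    a validation error naming collinear columns for singular designs.
    """
    Xd = _as_frame(X)
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValidationError("need at least 2 subjects per class")
    if add_intercept:
        Xd = sm.add_constant(Xd, has_constant="add")
    _check_design(Xd)
    model = sm.Logit(y, Xd)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        if "Separation" in type(exc).__name__ or "separation" in str(exc).lower():
            raise SeparationError(f"perfect separation: {exc}") from exc
        raise
    p = np.asarray(res.predict(Xd))
    eps = 1e-10
    if np.all(p[y == 1] > 1 - eps) and np.all(p[y == 0] < eps):
        raise SeparationError("perfect separation: fitted probabilities are all 0/1")
    names = tuple(Xd.columns)
    return LogisticFit(
        coefficients=dict(zip(names, np.asarray(res.params))),
        std_errors=dict(zip(names, np.asarray(res.bse))),
        p_values=dict(zip(names, np.asarray(res.pvalues))),
        log_likelihood=float(res.llf),
        aic=float(res.aic),
        n=int(y.size),
        fitted_probabilities=p,
        exog_names=names,
    )


@dataclass
class EliminationStep:
    dropped: str
    p_value: float
    remaining: tuple


def wald_backward_eliminate(X, y, alpha: float = 0.05, add_intercept: bool = True):
    """Backward elimination on Wald p-values.

    Iteratively refits, dropping the predictor (never the intercept) with
    the largest Wald p-value while any p >= alpha.  Returns
    ``(final_fit, trace)``; if everything is eliminated the final fit is
    intercept-only (with a warning entry in the trace).
    """
    Xd = _as_frame(X)
    trace: list[EliminationStep] = []
    while True:
        if Xd.shape[1] == 0:
            fit = fit_logistic(pd.DataFrame(index=np.arange(len(y))), y, add_intercept=True)
            return fit, trace
        fit = fit_logistic(Xd, y, add_intercept=add_intercept)
        candidates = {k: v for k, v in fit.p_values.items() if k != "const"}
        worst = max(candidates, key=candidates.get)
        if candidates[worst] < alpha:
            return fit, trace
        trace.append(
            EliminationStep(
                dropped=worst,
                p_value=float(candidates[worst]),
                remaining=tuple(c for c in Xd.columns if c != worst),
            )
        )
        Xd = Xd.drop(columns=[worst])


def build_interaction_design(df: pd.DataFrame) -> pd.DataFrame:
    """Main effects plus all pairwise interaction columns ("full model")."""
    out = df.copy()
    cols = list(df.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            out[f"{a}:{b}"] = df[a] * df[b]
    return out


def build_quadratic_design(df: pd.DataFrame) -> pd.DataFrame:
    """Main effects plus squared columns ("quadratic model")."""
    out = df.copy()
    for a in df.columns:
        out[f"{a}^2"] = df[a] ** 2
    return out


# ---------------------------------------------------------------------------
# classifier metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    diagnostic_odds_ratio: float
    mcc: float
    aic: float | None = None
    haldane_corrected: bool = False


def classifier_metrics(
    probabilities,
    labels,
    threshold: float = DEFAULT_RISK_THRESHOLD,
    log_likelihood: float | None = None,
    n_parameters: int | None = None,
) -> ClassifierMetrics:
    """Confusion-matrix metrics of a probabilistic classifier at a threshold.

    The diagnostic odds ratio is (TP*TN)/(FP*FN); when any cell is zero
    it is reported with the 0.5-cell Haldane correction and flagged.
    AIC = 2k - 2*logL is attached when the fit's log-likelihood and
    parameter count are supplied.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    haldane = 0 in (tp, fp, tn, fn)
    if haldane:
        dor = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
    else:
        dor = (tp * tn) / (fp * fn)
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn) - (fp * fn)) / denom if denom else 0.0
    aic = None
    if log_likelihood is not None and n_parameters is not None:
        aic = 2.0 * n_parameters - 2.0 * log_likelihood
    return ClassifierMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        diagnostic_odds_ratio=float(dor),
        mcc=float(mcc),
        aic=aic,
        haldane_corrected=haldane,
    )
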