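"""Per-subject physiological parameter vector and dimensionless index set.

``ModelParameters`` carries the rate constants of the five-compartment
glucose–insulin model on the canonical scales (mM, pM, min, mmol of gut
glucose).  ``NDNSet`` carries the seven dimensionless numbers that
summarise each physiological subsystem on a subject-independent scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace, asdict

from .errors import ValidationError

#: Field name -> printed unit string, on the canonical (table) scales.
PARAMETER_UNITS = {
    "k_js": "min^-1",
    "tau": "min",
    "k_gj": "min^-1",
    "k_lg": "min^-1",
    "k_xg": "min^-1",
    "k_xgi": "min^-1 pM^-1",
    "k_lambda": "min^-1",
    "gamma": "min^-1",
    "f_gi": "mmol^-1",
    "eta": "L^-3",  # stored as printed; plays an inverse-distribution-volume role (mM per mmol)
    "beta": "pM min^-1 mM^-1",
    "k_xi": "min^-1",
    "G_b": "mM",
    "I_b": "pM",
    "D": "mmol",
}


@dataclass(frozen=True)
class ModelParameters:
    """Physiological parameters of one subject.

    Parameters
    ----------
    k_js : float
        Stomach-emptying rate, min^-1.
    tau : float
        Jejunal transit time, min (enters the dynamics as rate 1/tau).
    k_gj : float
        Jejunal absorption rate, min^-1 (structural closure).
    k_lg : float
        Ileal absorption rate, min^-1.
    k_xg : float
        Insulin-independent glucose consumption rate, min^-1.
    k_xgi : float
        Insulin-dependent glucose consumption rate, min^-1 pM^-1.
    k_lambda : float
        Hepatic glucose-release responsiveness below basal, min^-1.
    gamma : float
        Hepatic glucose-uptake responsiveness above basal, min^-1.
    f_gi : float
        Incretin potentiation per mmol of gut glucose.
    eta : float
        Gut-to-blood distribution factor (mM glycemia per mmol absorbed).
    beta : float
        Pancreatic responsiveness, pM min^-1 mM^-1 (structural closure).
    k_xi : float
        Insulin turnover rate, min^-1 (structural closure).
    G_b : float
        Basal glycemia, mM.
    I_b : float
        Basal insulinemia, pM.
    D : float
        Glucose dose, mmol.
    """

    k_js: float
    tau: float
    k_gj: float
    k_lg: float
    k_xg: float
    k_xgi: float
    k_lambda: float
    gamma: float
    f_gi: float
    eta: float
    beta: float
    k_xi: float
    G_b: float
    I_b: float
    D: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValidationError(f"parameter {f.name} is not finite: {v!r}")
            if f.name == "D":
                if v < 0:
                    raise ValidationError(f"dose D must be >= 0, got {v}")
            elif v <= 0:
                raise ValidationError(f"parameter {f.name} must be > 0, got {v}")

    # -- convenience -------------------------------------------------------
    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValidationError(f"unknown parameter names: {sorted(unknown)}")
        missing = names - set(d)
        if missing:
            raise ValidationError(f"missing parameter names: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def names(cls) -> list:
        return [f.name for f in fields(cls)]


NDN_NAMES = ("Pi_S", "Pi_N", "Pi_D", "Pi_B", "Pi_X", "Pi_I", "Pi_R")


@dataclass(frozen=True)
class NDNSet:
    """The seven dimensionless physiological numbers of one subject.

    Pi_S: digestive motility; Pi_N: incretin activity load; Pi_D: glucose
    distribution; Pi_B: basal uptake ratio; Pi_X: insulin activity load;
    Pi_I: pancreatic response; Pi_R: hepatic response.  ``mapping`` records
    which registered formula set produced the values.
    """

    Pi_S: float
    Pi_N: float
    Pi_D: float
    Pi_B: float
    Pi_X: float
    Pi_I: float
    Pi_R: float
    mapping: str = field(default="reference", compare=False)

    def __post_init__(self):
        for name in NDN_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"dimensionless number {name} must be finite and > 0, got {v!r}")

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in NDN_NAMES}
        d["mapping"] = self.mapping
        return d
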