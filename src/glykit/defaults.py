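"""Population-level default parameter values and fitting bounds.

The healthy defaults sit at the geometric midpoints of the cohort-derived
healthy diagnostic ranges where an index has one (k_js, tau, k_lg, eta,
k_xgi), at the healthy-cohort basal medians for G_b and I_b (86.4 mg/dL
and 4.32 uU/mL on the clinical scales), and at physiologically plausible
values chosen once for the structural closures the range table does not
cover (k_gj, k_xg, k_lambda, gamma, f_gi, beta, k_xi).  The dose default
is the standard 75 g bolus.

Fitting bounds span the full abnormal-to-healthy extent of each
tabulated index widened by a factor of 10 on the log scale; untabulated
parameters get two decades around their default.
"""

from __future__ import annotations

from .params import ModelParameters
from .units import glucose_grams_to_mmol

#: Default 75 g oral dose in mmol.
DEFAULT_DOSE_MMOL = glucose_grams_to_mmol(75.0)

#: Healthy population centres on canonical scales (mM, pM, min, mmol).
HEALTHY_DEFAULTS = {
    "k_js": 0.0695,  # geometric mid of healthy range 0.0198-0.244 min^-1
    "tau": 89.4,  # geometric mid of 72-111 min
    "k_gj": 0.02,  # jejunal absorption closure
    "k_lg": 0.047,  # geometric mid of 0.00371-0.602 min^-1
    "k_xg": 0.015,  # insulin-independent uptake
    "k_xgi": 1.56e-4,  # geometric mid of 9.41e-6-2.59e-3 min^-1 pM^-1
    "k_lambda": 0.01,  # hepatic release
    "gamma": 0.04,  # hepatic uptake
    "f_gi": 2.0e-3,  # incretin potentiation (Pi_N = f_gi*D ~ 0.83)
    "eta": 0.0508,  # geometric mid of 0.0145-0.178
    "beta": 1.8,  # pancreatic responsiveness
    "k_xi": 0.05,  # insulin turnover
    "G_b": 4.8,  # 86.4 mg/dL
    "I_b": 30.0,  # 4.32 uU/mL
    "D": DEFAULT_DOSE_MMOL,
}


def healthy_reference_parameters(**overrides) -> ModelParameters:
    """A complete healthy reference parameter vector (population centres)."""
    vals = dict(HEALTHY_DEFAULTS)
    vals.update(overrides)
    return ModelParameters(**vals)


#: (lo, hi) fitting bounds per parameter, canonical scales.
FIT_BOUNDS = {
    "k_js": (1e-3, 2.44),
    "tau": (4.5, 1110.0),
    "k_gj": (2e-4, 2.0),
    "k_lg": (3.71e-4, 16.2),
    "k_xg": (1e-4, 1.0),
    "k_xgi": (5.67e-10, 2.59e-2),
    "k_lambda": (1e-4, 1.0),
    "gamma": (1e-4, 1.0),
    "f_gi": (2e-5, 0.2),
    "eta": (1.45e-3, 69.7),
    "beta": (1.2e-2, 120.0),
    "k_xi": (5e-4, 5.0),
}
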