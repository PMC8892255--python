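"""Dimensionless physiological numbers (Pi numbers).

Each Pi number collapses a group of model parameters and the natural
scales of the problem — basal glycemia G_b, basal insulinemia I_b, the
ingested dose D, and the blood-glucose turnover time
t_c = 1 / (k_xg + k_xgi * I_b) — into one dimensionless index per
physiological subsystem:

====== ===================== ==========================================
Pi_S   digestive motility     k_js * tau
Pi_N   incretin load          f_gi * D
Pi_D   glucose distribution   eta * D / G_b
Pi_B   basal uptake ratio     (k_xgi * I_b) / k_xg
Pi_X   insulin activity load  k_xgi * I_b * t_c   (always in (0, 1))
Pi_I   pancreatic response    beta * G_b * t_c / I_b
Pi_R   hepatic response       (k_lambda + gamma) * t_c
====== ===================== ==========================================

The mapping is registered by name ("reference") and alternative formula
sets can be plugged in through :func:`register_mapping`; downstream range
classification and risk scoring consume the resulting values regardless
of which mapping produced them.
"""

from __future__ import annotations

from typing import Callable, Dict

from .errors import ConfigError, UndefinedNumberError
from .params import ModelParameters, NDNSet

_REGISTRY: Dict[str, Callable[[ModelParameters], NDNSet]] = {}


def register_mapping(name: str, fn: Callable[[ModelParameters], NDNSet]) -> None:
    """Register an alternative Pi-number mapping under ``name``."""
    _REGISTRY[name] = fn


def available_mappings() -> list:
    return sorted(_REGISTRY)


def glucose_turnover_time(params: ModelParameters) -> float:
    """Characteristic blood-glucose turnover time t_c (min)."""
    return 1.0 / (params.k_xg + params.k_xgi * params.I_b)


def _reference_mapping(p: ModelParameters) -> NDNSet:
    if p.D <= 0:
        raise UndefinedNumberError(
            "dose-scaled numbers (Pi_N, Pi_D) are undefined for D == 0"
        )
    t_c = glucose_turnover_time(p)
    return NDNSet(
        Pi_S=p.k_js * p.tau,
        Pi_N=p.f_gi * p.D,
        Pi_D=p.eta * p.D / p.G_b,
        Pi_B=(p.k_xgi * p.I_b) / p.k_xg,
        Pi_X=p.k_xgi * p.I_b * t_c,
        Pi_I=p.beta * p.G_b * t_c / p.I_b,
        Pi_R=(p.k_lambda + p.gamma) * t_c,
        mapping="reference",
    )


register_mapping("reference", _reference_mapping)


def compute_ndns(params: ModelParameters, mapping: str = "reference") -> NDNSet:
    """Map a parameter vector to its dimensionless number set.

    Pure function: the same parameters always yield the same set, and the
    values are invariant under any consistent rescaling of units.
    """
    try:
        fn = _REGISTRY[mapping]
    except KeyError:
        raise ConfigError(
            f"unknown NDN mapping {mapping!r}; available: {available_mappings()}"
        ) from None
    return fn(params)
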