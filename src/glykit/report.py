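"""End-to-end patient assessment: fit -> Pi numbers -> ranges -> risk.

One call runs the whole four-step workflow for every subject in an OGTT
table and assembles a machine-readable (JSON) and human-readable report:
fitted physiological parameters with units, dimensionless numbers,
per-index diagnostic categories against the packaged (or a user) range
table, the binary clinical label, and the dysglycemia-risk probability.
Reports are regenerable bit-identically from the same inputs, config and
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .clinical import classify_clinical
from .errors import ConfigError, GlykitError
from .fitting import GlucoseInsulinModel, curve_shape_sensitivity
from .ndn import compute_ndns
from .params import NDN_NAMES, PARAMETER_UNITS
from .ranges import RangeTable, load_reference_ranges
from .records import OGTTRecord
from .risk import DEFAULT_RISK_THRESHOLD, classify_risk, published_risk

DEFAULT_CONFIG = {
    "seed": 0,
    "n_starts": 8,
    "dt": 1.0,
    "risk_threshold": DEFAULT_RISK_THRESHOLD,
    "ndn_mapping": "reference",
    "sensitivity": False,
    "units": {"glycemia": "mg/dL", "insulinemia": "uU/mL"},
}

_CONFIG_TYPES = {
    "seed": int,
    "n_starts": int,
    "dt": (int, float),
    "risk_threshold": (int, float),
    "ndn_mapping": str,
    "sensitivity": bool,
    "units": dict,
}


def validate_config(config: dict | None) -> dict:
    """Merge a user config over the defaults, rejecting unknown/bad keys."""
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in (config or {}).items():
        if key not in _CONFIG_TYPES:
            raise ConfigError(f"unknown config key {key!r}; known: {sorted(_CONFIG_TYPES)}")
        if not isinstance(value, _CONFIG_TYPES[key]) or isinstance(value, bool) != (
            _CONFIG_TYPES[key] is bool
        ):
            raise ConfigError(
                f"config key {key!r} must be {_CONFIG_TYPES[key]}, got {type(value).__name__}"
            )
        merged[key] = value
    if not (0.0 < merged["risk_threshold"] < 1.0):
        raise ConfigError("risk_threshold must be in (0, 1)")
    return merged


@dataclass
class SubjectAssessment:
    subject_id: str
    ok: bool
    error: str | None = None
    parameters: dict = field(default_factory=dict)
    ndns: dict = field(default_factory=dict)
    range_labels: dict = field(default_factory=dict)
    clinical_label: str | None = None
    clinical_violations: list = field(default_factory=list)
    risk_probability: float | None = None
    risk_label: str | None = None
    fit_loss: float | None = None
    fit_warnings: list = field(default_factory=list)
    sensitivity: dict = field(default_factory=dict)


@dataclass
class AssessmentReport:
    config: dict
    subjects: list  # of SubjectAssessment
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "n_subjects": len(self.subjects),
            "n_failed": self.n_failed,
            "subjects": [vars(s) for s in self.subjects],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["Patient-wise glycemic health assessment", "=" * 64]
        for s in self.subjects:
            lines.append(f"subject {s.subject_id}")
            if not s.ok:
                lines.append(f"  FAILED: {s.error}")
                continue
            lines.append(
                f"  clinical: {s.clinical_label}   "
                f"risk: {s.risk_probability:.3f} ({s.risk_label})"
            )
            flagged = {k: v for k, v in s.range_labels.items() if v != "normal"}
            lines.append(f"  out-of-range indices: {flagged if flagged else 'none'}")
        lines.append("-" * 64)
        lines.append(f"{len(self.subjects)} subjects, {self.n_failed} failed")
        return "\n".join(lines)


def assess_subject(
    record: OGTTRecord,
    config: dict,
    table: RangeTable,
) -> SubjectAssessment:
    """Fit one record and assemble its full assessment."""
    try:
        fit = GlucoseInsulinModel(record, dt=config["dt"]).fit(
            seed=config["seed"], n_starts=config["n_starts"]
        )
        ndns = compute_ndns(fit.params, mapping=config["ndn_mapping"])
        values = {**fit.params.to_dict(), **{k: getattr(ndns, k) for k in NDN_NAMES}}
        range_labels = {
            idx: table.classify(idx, values[idx]) for idx in table.indices if idx in values
        }
        clinical = classify_clinical(record)
        p = published_risk(fit.params, ndns)
        assessment = SubjectAssessment(
            subject_id=record.subject_id,
            ok=True,
            parameters={
                k: {"value": v, "units": PARAMETER_UNITS[k]}
                for k, v in fit.params.to_dict().items()
            },
            ndns={k: getattr(ndns, k) for k in NDN_NAMES},
            range_labels=range_labels,
            clinical_label=clinical.label,
            clinical_violations=[vars(v) for v in clinical.violations],
            risk_probability=p,
            risk_label=classify_risk(p, config["risk_threshold"]),
            fit_loss=fit.loss,
            fit_warnings=list(fit.warnings),
        )
        if config["sensitivity"]:
            cs = curve_shape_sensitivity(fit.params)
            assessment.sensitivity = {
                "indices": cs.indices,
                "sensitive": list(cs.sensitive),
            }
        return assessment
    except GlykitError as exc:
        return SubjectAssessment(subject_id=record.subject_id, ok=False, error=str(exc))


def run_assessment(
    records,
    config: dict | None = None,
    table: RangeTable | None = None,
) -> AssessmentReport:
    """Assess every record; per-subject failures are isolated, not fatal."""
    cfg = validate_config(config)
    if table is None:
        table = load_reference_ranges()
    subjects = [assess_subject(r, cfg, table) for r in records]
    return AssessmentReport(
        config=cfg,
        subjects=subjects,
        n_failed=sum(1 for s in subjects if not s.ok),
    )
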