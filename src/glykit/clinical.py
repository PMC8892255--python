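"""Binary clinical healthy / non-healthy classification of raw OGTT curves.

The conventional rule set, evaluated on the clinical scales (mg/dL and
uU/mL): a subject is healthy iff

(i)   fasting glycemia < 100 mg/dL and fasting insulinemia < 15 uU/mL
      (strict, as the rule is phrased);
(ii)  glycemia never exceeds 160 mg/dL and does not persist above
      140 mg/dL at 2 h;
(iii) insulinemia never exceeds 100 uU/mL and does not persist above
      60 uU/mL at 2 h.

"Does not exceed" is treated as <= (boundary values pass); "after 2 h"
is evaluated at the 120-minute sample, the last one the protocol takes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .records import OGTTRecord

FASTING_GLYCEMIA_MAX = 100.0  # mg/dL, strict
FASTING_INSULINEMIA_MAX = 15.0  # uU/mL, strict
PEAK_GLYCEMIA_MAX = 160.0  # mg/dL, inclusive
FINAL_GLYCEMIA_MAX = 140.0  # mg/dL at 120 min, inclusive
PEAK_INSULINEMIA_MAX = 100.0  # uU/mL, inclusive
FINAL_INSULINEMIA_MAX = 60.0  # uU/mL at 120 min, inclusive


@dataclass(frozen=True)
class Violation:
    rule: str
    description: str
    value: float
    time_min: float


@dataclass(frozen=True)
class ClinicalLabel:
    subject_id: str
    label: str  # "healthy" | "non-healthy"
    violations: tuple = field(default_factory=tuple)

    def __post_init__(self):
        healthy = self.label == "healthy"
        if healthy != (len(self.violations) == 0):
            raise ValidationError("label must be healthy iff there are no violations")


def classify_clinical(record: OGTTRecord) -> ClinicalLabel:
    """Apply the binary clinical criteria to one OGTT record.

    The record must include the 120-min sample.  Classification is
    performed after converting to mg/dL and uU/mL, so it does not depend
    on the units the record arrived in.
    """
    if 120.0 not in record.times:
        raise ValidationError(
            f"subject {record.subject_id!r}: clinical criteria need the 120-min sample"
        )
    gly, ins = record.in_units("mg/dL", "uU/mL")
    times = record.times
    violations = []

    def check(cond, rule, description, value, time_min):
        if not cond:
            violations.append(Violation(rule, description, float(value), float(time_min)))

    check(
        gly[0] < FASTING_GLYCEMIA_MAX,
        "i",
        f"fasting glycemia must be < {FASTING_GLYCEMIA_MAX:g} mg/dL",
        gly[0],
        0.0,
    )
    check(
        ins[0] < FASTING_INSULINEMIA_MAX,
        "i",
        f"fasting insulinemia must be < {FASTING_INSULINEMIA_MAX:g} uU/mL",
        ins[0],
        0.0,
    )
    i_peak_g = int(gly.argmax())
    check(
        gly[i_peak_g] <= PEAK_GLYCEMIA_MAX,
        "ii",
        f"glycemia must not exceed {PEAK_GLYCEMIA_MAX:g} mg/dL (boundary passes)",
        gly[i_peak_g],
        times[i_peak_g],
    )
    g_final = gly[list(times).index(120.0)]
    check(
        g_final <= FINAL_GLYCEMIA_MAX,
        "ii",
        f"glycemia must not persist above {FINAL_GLYCEMIA_MAX:g} mg/dL after 2 h",
        g_final,
        120.0,
    )
    i_peak_i = int(ins.argmax())
    check(
        ins[i_peak_i] <= PEAK_INSULINEMIA_MAX,
        "iii",
        f"insulinemia must not exceed {PEAK_INSULINEMIA_MAX:g} uU/mL (boundary passes)",
        ins[i_peak_i],
        times[i_peak_i],
    )
    i_final = ins[list(times).index(120.0)]
    check(
        i_final <= FINAL_INSULINEMIA_MAX,
        "iii",
        f"insulinemia must not persist above {FINAL_INSULINEMIA_MAX:g} uU/mL after 2 h",
        i_final,
        120.0,
    )
    return ClinicalLabel(
        subject_id=record.subject_id,
        label="healthy" if not violations else "non-healthy",
        violations=tuple(violations),
    )
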