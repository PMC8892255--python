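"""OGTT records and tabular I/O.

A 5-point OGTT-insulinemia record holds paired glycemia/insulinemia
measurements at 0, 30, 60, 90 and 120 minutes after a 75 g oral glucose
bolus (other protocols are allowed as long as the basal 0-min sample is
present).  Concentrations are stored internally in mM (glucose) and pM
(insulin); CSV input in clinical units is converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .units import convert_glycemia, convert_insulinemia, glucose_grams_to_mmol

DEFAULT_TIMES = (0.0, 30.0, 60.0, 90.0, 120.0)
DEFAULT_DOSE_G = 75.0

#: units assumed when a reader is given no units config
DEFAULT_SOURCE_UNITS = {"glycemia": "mg/dL", "insulinemia": "uU/mL"}
INTERNAL_UNITS = {"glycemia": "mM", "insulinemia": "pM"}


@dataclass(frozen=True)
class OGTTRecord:
    """One subject's timed glycemia/insulinemia curve, in internal units."""

    subject_id: str
    times: tuple
    glycemia: tuple  # mM
    insulinemia: tuple  # pM
    dose_g: float = DEFAULT_DOSE_G
    source_units: Mapping[str, str] = field(default_factory=lambda: dict(INTERNAL_UNITS))

    def __post_init__(self):
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "glycemia", tuple(float(g) for g in self.glycemia))
        object.__setattr__(self, "insulinemia", tuple(float(i) for i in self.insulinemia))
        t = np.asarray(self.times)
        if len(t) == 0 or t[0] != 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: first sample must be the basal one at t=0"
            )
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"subject {self.subject_id!r}: times must be strictly increasing")
        if not (len(self.times) == len(self.glycemia) == len(self.insulinemia)):
            raise ValidationError(
                f"subject {self.subject_id!r}: times/glycemia/insulinemia lengths differ"
            )
        for name, vals in (("glycemia", self.glycemia), ("insulinemia", self.insulinemia)):
            arr = np.asarray(vals)
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValidationError(
                    f"subject {self.subject_id!r}: {name} values must be finite and > 0"
                )
        if self.dose_g < 0:
            raise ValidationError(f"subject {self.subject_id!r}: dose must be >= 0")

    # -- derived quantities -----------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def basal_glycemia(self) -> float:
        """Fasting glycemia G_b in mM."""
        return self.glycemia[0]

    @property
    def basal_insulinemia(self) -> float:
        """Fasting insulinemia I_b in pM."""
        return self.insulinemia[0]

    @property
    def dose_mmol(self) -> float:
        return glucose_grams_to_mmol(self.dose_g)

    def value_at(self, time_min: float, which: str = "glycemia") -> float:
        series = getattr(self, which)
        for t, v in zip(self.times, series):
            if t == time_min:
                return v
        raise ValidationError(
            f"subject {self.subject_id!r}: no {which} sample at t={time_min} min"
        )

    def in_units(self, glycemia_unit: str, insulinemia_unit: str):
        """Return (glycemia, insulinemia) arrays converted out of internal units."""
        g = convert_glycemia(np.asarray(self.glycemia), "mM", glycemia_unit)
        i = convert_insulinemia(np.asarray(self.insulinemia), "pM", insulinemia_unit)
        return g, i

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "time_min": self.times,
                "glycemia": self.glycemia,
                "insulinemia": self.insulinemia,
            }
        )


def _make_record(subject_id, times, gly, ins, units, dose_g) -> OGTTRecord:
    gly = convert_glycemia(np.asarray(gly, dtype=float), units["glycemia"], "mM")
    ins = convert_insulinemia(np.asarray(ins, dtype=float), units["insulinemia"], "pM")
    return OGTTRecord(
        subject_id=str(subject_id),
        times=tuple(times),
        glycemia=tuple(gly),
        insulinemia=tuple(ins),
        dose_g=dose_g,
        source_units=dict(units),
    )


def read_ogtt_table(
    path,
    units: Mapping[str, str] | None = None,
    dose_g: float = DEFAULT_DOSE_G,
) -> list[OGTTRecord]:
    """Read OGTT records from a CSV file (long or wide layout).

    Long layout: columns ``subject_id, time_min, glycemia, insulinemia``.
    Wide layout: one row per subject with ``glycemia_<t>`` /
    ``insulinemia_<t>`` columns for each sampling time t in minutes.

    ``units`` declares the units the file arrived in, e.g.
    ``{"glycemia": "mg/dL", "insulinemia": "uU/mL"}`` (the default);
    values are converted to internal units (mM, pM) on read.
    """
    units = dict(DEFAULT_SOURCE_UNITS if units is None else units)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    records: list[OGTTRecord] = []
    if {"subject_id", "time_min", "glycemia", "insulinemia"} <= cols:
        for sid, grp in df.groupby("subject_id", sort=False):
            grp = grp.sort_values("time_min")
            if not (grp["time_min"] == 0).any():
                raise ValidationError(f"subject {sid!r}: missing basal (t=0) row")
            records.append(
                _make_record(
                    sid,
                    grp["time_min"].to_numpy(),
                    grp["glycemia"].to_numpy(),
                    grp["insulinemia"].to_numpy(),
                    units,
                    dose_g,
                )
            )
        return records

    gly_cols = sorted(
        (float(c.split("_", 1)[1]), c) for c in cols if c.startswith("glycemia_")
    )
    ins_cols = sorted(
        (float(c.split("_", 1)[1]), c) for c in cols if c.startswith("insulinemia_")
    )
    if not gly_cols or "subject_id" not in cols:
        raise ValidationError(
            "unrecognised OGTT table layout: need long columns "
            "(subject_id, time_min, glycemia, insulinemia) or wide columns "
            "(subject_id, glycemia_<t>..., insulinemia_<t>...)"
        )
    times_g = [t for t, _ in gly_cols]
    times_i = [t for t, _ in ins_cols]
    if times_g != times_i:
        raise ValidationError("wide layout: glycemia and insulinemia time columns differ")
    if 0.0 not in times_g:
        raise ValidationError("wide layout: missing the basal (t=0) columns")
    for _, row in df.iterrows():
        records.append(
            _make_record(
                row["subject_id"],
                times_g,
                [row[c] for _, c in gly_cols],
                [row[c] for _, c in ins_cols],
                units,
                dose_g,
            )
        )
    return records


def write_ogtt_table(records: Sequence[OGTTRecord], path) -> None:
    """Write records as a long-format CSV in internal units (mM, pM).

    Floats are written with 17 significant digits so a read-back
    reproduces the numeric content bit-compatibly.
    """
    pd.concat([r.to_frame() for r in records], ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )
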