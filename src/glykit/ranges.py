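"""Diagnostic range tables: normal / undesirable / abnormal per index.

Each row of a :class:`RangeTable` divides the positive axis into three
zones for one physiological index.  The packaged reference table was
built from a 1198-subject cohort: the normal range runs from the
equal-density threshold toward the healthy side of the healthy cohort's
central 90% interval, the undesirable range covers the rest of that
interval on the non-healthy side, and the abnormal zone lies beyond it.

Boundary values are assigned to the healthier of the two adjacent
categories (the printed table shares its endpoints between zones, so a
tie rule is required).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .errors import ConfigError, ValidationError

CATEGORIES = ("normal", "undesirable", "abnormal")


@dataclass(frozen=True)
class RangeRow:
    """Diagnostic ranges for one parameter or dimensionless number.

    ``abnormal_op`` is "<" when abnormality lies below the undesirable
    interval and ">" when it lies above.
    """

    index: str
    process: str
    units: str
    healthy: tuple  # (lo, hi)
    undesirable: tuple  # (lo, hi)
    abnormal_op: str
    abnormal_bound: float
    discriminative: bool = True

    def __post_init__(self):
        h_lo, h_hi = self.healthy
        u_lo, u_hi = self.undesirable
        if not (h_lo < h_hi):
            raise ValidationError(f"{self.index}: healthy interval must be increasing")
        if not (u_lo < u_hi):
            raise ValidationError(f"{self.index}: undesirable interval must be increasing")
        if self.abnormal_op not in ("<", ">"):
            raise ValidationError(f"{self.index}: abnormal_op must be '<' or '>'")
        # adjacency: undesirable shares one boundary with healthy, abnormal
        # continues the undesirable interval on the non-healthy side
        if self.abnormal_op == "<":
            ok = _close(u_hi, h_lo) and _close(self.abnormal_bound, u_lo)
        else:
            ok = _close(u_lo, h_hi) and _close(self.abnormal_bound, u_hi)
        if not ok:
            raise ValidationError(
                f"{self.index}: healthy/undesirable/abnormal zones are not adjacent"
            )

    @property
    def direction(self) -> str:
        """Side on which abnormality lies: 'low' or 'high'."""
        return "low" if self.abnormal_op == "<" else "high"

    def classify(self, value: float) -> str:
        """Classify a value; boundary values take the healthier category."""
        h_lo, h_hi = self.healthy
        if self.abnormal_op == "<":
            if value >= h_lo:
                return "normal"
            if value >= self.abnormal_bound:
                return "undesirable"
            return "abnormal"
        if value <= h_hi:
            return "normal"
        if value <= self.abnormal_bound:
            return "undesirable"
        return "abnormal"


def _close(a: float, b: float, rtol: float = 1e-9) -> bool:
    return abs(a - b) <= rtol * max(abs(a), abs(b), 1e-300)


class RangeTable:
    """Ordered collection of :class:`RangeRow`, indexed by name."""

    def __init__(self, rows):
        self._rows = list(rows)
        self._by_name: Mapping[str, RangeRow] = {r.index: r for r in self._rows}
        if len(self._by_name) != len(self._rows):
            raise ValidationError("duplicate index names in range table")

    def __len__(self):
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows)

    def __contains__(self, index):
        return index in self._by_name

    def __getitem__(self, index: str) -> RangeRow:
        try:
            return self._by_name[index]
        except KeyError:
            raise ConfigError(
                f"unknown index {index!r}; known: {sorted(self._by_name)}"
            ) from None

    @property
    def indices(self) -> list:
        return [r.index for r in self._rows]

    def classify(self, index: str, value: float) -> str:
        import math

        if not math.isfinite(value):
            raise ValidationError(f"cannot classify non-finite value for {index!r}")
        return self[index].classify(value)

    def to_dict(self) -> dict:
        return {
            "rows": [
                {
                    "index": r.index,
                    "process": r.process,
                    "units": r.units,
                    "healthy": list(r.healthy),
                    "undesirable": list(r.undesirable),
                    "abnormal": {"op": r.abnormal_op, "bound": r.abnormal_bound},
                    "discriminative": r.discriminative,
                }
                for r in self._rows
            ]
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RangeTable":
        rows = []
        for raw in payload["rows"]:
            rows.append(
                RangeRow(
                    index=raw["index"],
                    process=raw.get("process", ""),
                    units=raw.get("units", "-"),
                    healthy=tuple(raw["healthy"]),
                    undesirable=tuple(raw["undesirable"]),
                    abnormal_op=raw["abnormal"]["op"],
                    abnormal_bound=float(raw["abnormal"]["bound"]),
                    discriminative=bool(raw.get("discriminative", True)),
                )
            )
        return cls(rows)


def load_reference_ranges() -> RangeTable:
    """Load the packaged cohort-derived diagnostic range table (14 rows)."""
    payload = json.loads(
        resources.files("glykit.data").joinpath("reference_ranges.json").read_text()
    )
    return RangeTable.from_dict(payload)


def classify_in_ranges(value: float, index: str, table: RangeTable) -> str:
    """Classify one value against one row of a range table."""
    return table.classify(index, value)
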