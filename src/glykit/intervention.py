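"""Dose-response assessment of a nutritional intervention across OGTTs.

A crossover intervention study gives every subject one control OGTT and
one OGTT per pre-prandial dose (e.g. 60 / 120 / 180 mg of a polyphenol
extract).  Each arm carries the subject's fitted parameters, Pi numbers
and dysglycemia-risk probability; cohort-level dose effects are paired
t-tests of each dose arm against control, and patient-level trajectories
track how risk and diagnostic-range membership move with dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .ndn import compute_ndns
from .params import ModelParameters, NDNSet, NDN_NAMES
from .ranges import RangeTable
from .records import OGTTRecord
from .risk import published_risk

CONTROL_DOSE = 0.0

#: significance stars used in dose-effect reports
STAR_LEVELS = ((0.001, "****"), (0.01, "***"), (0.05, "**"), (0.1, "*"))


def significance_stars(p: float) -> str:
    """Step function mapping a p-value to stars (p <= 0.1 earns the first)."""
    for level, stars in STAR_LEVELS:
        if p <= level:
            return stars
    return ""


@dataclass
class Arm:
    """One subject's data under one dose."""

    dose_mg: float
    record: OGTTRecord | None
    params: ModelParameters
    ndns: NDNSet = None
    risk: float = None

    def __post_init__(self):
        if self.ndns is None:
            self.ndns = compute_ndns(self.params)
        if self.risk is None:
            self.risk = published_risk(self.params, self.ndns)

    def index_value(self, index: str) -> float:
        if index in NDN_NAMES:
            return getattr(self.ndns, index)
        if index == "risk":
            return self.risk
        return getattr(self.params, index)


@dataclass
class SubjectArms:
    subject_id: str
    arms: dict  # dose_mg -> Arm

    def __post_init__(self):
        if CONTROL_DOSE not in self.arms:
            raise ValidationError(f"subject {self.subject_id!r} lacks a control arm")


@dataclass
class InterventionStudy:
    """Paired subjects-by-arms structure of a crossover study."""

    subjects: list  # of SubjectArms

    @property
    def doses(self) -> list:
        doses = sorted({d for s in self.subjects for d in s.arms})
        return doses

    @property
    def treatment_doses(self) -> list:
        return [d for d in self.doses if d != CONTROL_DOSE]

    def paired_values(self, dose: float, index: str):
        """(control, dose) value pairs for subjects having both arms."""
        ctrl, trt, ids = [], [], []
        for s in self.subjects:
            if CONTROL_DOSE in s.arms and dose in s.arms:
                ctrl.append(s.arms[CONTROL_DOSE].index_value(index))
                trt.append(s.arms[dose].index_value(index))
                ids.append(s.subject_id)
        return np.asarray(ctrl), np.asarray(trt), ids


@dataclass(frozen=True)
class DoseEffect:
    dose_mg: float
    index: str
    mean_control: float
    mean_dose: float
    mean_difference: float  # dose - control
    t_statistic: float
    p_value: float
    stars: str
    n_pairs: int
    dropped_subjects: tuple


def dose_effect_tests(
    study: InterventionStudy,
    index: str,
    paired: bool = True,
) -> list:
    """Test each dose arm against control for one index (or "risk").

    Defaults to paired tests (crossover design: each subject is their own
    control); the unpaired comparison of arm means is available with
    ``paired=False``.  Subjects missing either arm are dropped with a
    warning.  Raw p-values get significance stars; Benjamini–Hochberg
    q-values across doses are computed by callers that need them.
    """
    effects = []
    all_ids = {s.subject_id for s in study.subjects}
    for dose in study.treatment_doses:
        ctrl, trt, ids = study.paired_values(dose, index)
        dropped = tuple(sorted(all_ids - set(ids)))
        if dropped:
            import warnings

            warnings.warn(
                f"dose {dose:g} mg: dropped subjects missing an arm: {dropped}",
                stacklevel=2,
            )
        if len(ids) < 2:
            raise ValidationError(f"dose {dose:g} mg: need >= 2 paired subjects")
        if paired:
            if np.allclose(trt, ctrl):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_rel(trt, ctrl)
        else:
            t_stat, p = stats.ttest_ind(trt, ctrl)
        effects.append(
            DoseEffect(
                dose_mg=dose,
                index=index,
                mean_control=float(np.mean(ctrl)),
                mean_dose=float(np.mean(trt)),
                mean_difference=float(np.mean(trt) - np.mean(ctrl)),
                t_statistic=float(t_stat),
                p_value=float(p),
                stars=significance_stars(float(p)),
                n_pairs=len(ids),
                dropped_subjects=dropped,
            )
        )
    return effects


@dataclass(frozen=True)
class RiskTrajectory:
    subject_id: str
    doses: tuple
    risks: tuple
    monotone_decreasing: bool
    best_dose: float  # minimum risk; ties -> lowest dose
    range_transitions: dict  # index -> {dose: category}


def risk_trajectory(
    study: InterventionStudy,
    subject_id: str,
    table: RangeTable | None = None,
) -> RiskTrajectory:
    """Per-arm risk for one subject, with dose-monotonicity and best dose.

    When a range table is given, each tabulated index's category
    (normal / undesirable / abnormal) is tracked across arms as well.
    """
    subject = next((s for s in study.subjects if s.subject_id == subject_id), None)
    if subject is None:
        raise ValidationError(f"unknown subject {subject_id!r}")
    doses = sorted(subject.arms)
    if len(doses) < 2:
        raise ValidationError(f"subject {subject_id!r} needs >= 2 arms")
    risks = [subject.arms[d].risk for d in doses]
    monotone = all(b <= a + 1e-12 for a, b in zip(risks, risks[1:]))
    best_dose = min(zip(risks, doses))[1]
    transitions = {}
    if table is not None:
        for index in table.indices:
            per_dose = {}
            for d in doses:
                arm = subject.arms[d]
                try:
                    per_dose[d] = table.classify(index, arm.index_value(index))
                except AttributeError:
                    continue
            if per_dose:
                transitions[index] = per_dose
    return RiskTrajectory(
        subject_id=subject_id,
        doses=tuple(doses),
        risks=tuple(risks),
        monotone_decreasing=monotone,
        best_dose=float(best_dose),
        range_transitions=transitions,
    )


@dataclass(frozen=True)
class ResponderSplit:
    responders: tuple
    non_responders: tuple
    delta_threshold: float
    risk_changes: dict  # subject_id -> best-dose risk minus control risk


def responder_split(study: InterventionStudy, delta_threshold: float = 0.05) -> ResponderSplit:
    """Split subjects by whether any dose lowers risk by at least delta.

    A responder's best-dose risk is <= control risk - delta_threshold;
    with delta 0, any strict decrease qualifies.
    """
    responders, non_responders, changes = [], [], {}
    for s in study.subjects:
        control_risk = s.arms[CONTROL_DOSE].risk
        best = min(s.arms[d].risk for d in s.arms)
        change = best - control_risk
        changes[s.subject_id] = float(change)
        if (delta_threshold > 0 and best <= control_risk - delta_threshold) or (
            delta_threshold == 0 and best < control_risk
        ):
            responders.append(s.subject_id)
        else:
            non_responders.append(s.subject_id)
    return ResponderSplit(
        responders=tuple(responders),
        non_responders=tuple(non_responders),
        delta_threshold=delta_threshold,
        risk_changes=changes,
    )
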