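"""Dose-effect tests, risk trajectories and responder splits."""

import numpy as np
import pytest
from scipy import stats

from glykit.errors import ValidationError
from glykit.intervention import (
    Arm,
    InterventionStudy,
    SubjectArms,
    dose_effect_tests,
    responder_split,
    risk_trajectory,
    significance_stars,
)
from glykit.defaults import healthy_reference_parameters
from glykit.ranges import load_reference_ranges


def make_study(tau_by_dose, n=4, doses=(0.0, 60.0, 120.0, 180.0), jitter=None):
    """Small study where only tau varies by dose (plus optional per-subject jitter)."""
    base = healthy_reference_parameters()
    subjects = []
    for i in range(n):
        arms = {}
        for d in doses:
            tau = tau_by_dose[d] * (1.0 + (jitter[i][d] if jitter else 0.0))
            arms[d] = Arm(dose_mg=d, record=None, params=base.replace(tau=tau))
        subjects.append(SubjectArms(subject_id=f"P{i}", arms=arms))
    return InterventionStudy(subjects=subjects)


class TestStars:
    @pytest.mark.parametrize(
        "p, stars",
        [(0.2, ""), (0.1, "*"), (0.05, "**"), (0.04, "**"), (0.01, "***"),
         (0.001, "****"), (0.0005, "****")],
    )
    def test_step_function_matches_legend(self, p, stars):
        assert significance_stars(p) == stars


class TestDoseEffects:
    def test_identical_arms_show_no_effect(self):
        study = make_study({d: 89.4 for d in (0.0, 60.0, 120.0, 180.0)})
        for eff in dose_effect_tests(study, "tau"):
            assert eff.mean_difference == 0.0
            assert eff.stars == ""

    def test_paired_t_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        jitter = [
            {d: float(rng.normal(0, 0.05)) for d in (0.0, 60.0, 120.0, 180.0)}
            for _ in range(4)
        ]
        study = make_study({0.0: 89.4, 60.0: 95.0, 120.0: 100.0, 180.0: 110.0}, jitter=jitter)
        eff = dose_effect_tests(study, "tau")[-1]  # 180 mg arm
        ctrl, trt, _ = study.paired_values(180.0, "tau")
        t_ref, p_ref = stats.ttest_rel(trt, ctrl)
        # hand-computed paired t on the 4 differences
        d = trt - ctrl
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert eff.t_statistic == pytest.approx(t_ref) == pytest.approx(t_hand)
        assert eff.p_value == pytest.approx(p_ref)
        assert eff.n_pairs == 4

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(1)
        jitter = [
            {d: float(rng.normal(0, 0.05)) for d in (0.0, 60.0, 120.0, 180.0)}
            for _ in range(5)
        ]
        study = make_study({0.0: 89.4, 60.0: 95.0, 120.0: 100.0, 180.0: 110.0},
                           n=5, jitter=jitter)
        reversed_study = InterventionStudy(subjects=list(reversed(study.subjects)))
        a = dose_effect_tests(study, "tau")
        b = dose_effect_tests(reversed_study, "tau")
        for x, y in zip(a, b):
            assert x.p_value == pytest.approx(y.p_value)

    def test_too_few_pairs_rejected(self):
        study = make_study({d: 89.4 for d in (0.0, 60.0, 120.0, 180.0)}, n=1)
        with pytest.raises(ValidationError):
            dose_effect_tests(study, "tau")


class TestTrajectories:
    def test_flat_trajectory_prefers_control(self):
        study = make_study({d: 89.4 for d in (0.0, 60.0, 120.0, 180.0)})
        traj = risk_trajectory(study, "P0")
        assert len(set(traj.risks)) == 1
        assert traj.best_dose == 0.0
        assert traj.monotone_decreasing

    def test_improving_transit_and_sensitivity_lowers_risk(self):
        """tau up and k_xgi up with dose -> risk strictly decreasing."""
        base = healthy_reference_parameters()
        arms = {}
        for d, f in [(0.0, 1.0), (60.0, 1.1), (120.0, 1.2), (180.0, 1.3)]:
            arms[d] = Arm(
                dose_mg=d,
                record=None,
                params=base.replace(tau=base.tau * f, k_xgi=base.k_xgi * f),
            )
        study = InterventionStudy(subjects=[SubjectArms("P0", arms)])
        traj = risk_trajectory(study, "P0")
        assert all(b < a for a, b in zip(traj.risks, traj.risks[1:]))
        assert traj.best_dose == 180.0

    def test_out_of_range_ndns_can_outweigh_normal_basals(self):
        """Normal fasting values but abnormal internal indices: risk stays high."""
        table = load_reference_ranges()
        p = healthy_reference_parameters(
            G_b=4.9, I_b=40.0,  # inside the healthy basal ranges
            eta=2.5, tau=46.0, k_xgi=1e-6,  # distribution/motility/uptake off
        )
        arms = {0.0: Arm(0.0, None, p), 60.0: Arm(60.0, None, p)}
        study = InterventionStudy(subjects=[SubjectArms("P36", arms)])
        traj = risk_trajectory(study, "P36", table=table)
        assert traj.range_transitions["G_b"][0.0] == "normal"
        assert traj.range_transitions["I_b"][0.0] == "normal"
        assert traj.range_transitions["eta"][0.0] != "normal"
        assert traj.risks[0] >= 0.60

    def test_unknown_subject_rejected(self):
        study = make_study({d: 89.4 for d in (0.0, 60.0, 120.0, 180.0)})
        with pytest.raises(ValidationError):
            risk_trajectory(study, "nobody")


class TestResponders:
    def _study_with_changes(self, deltas):
        base = healthy_reference_parameters()
        subjects = []
        for i, delta in enumerate(deltas):
            ctrl = Arm(0.0, None, base)
            if delta <= 0.0:
                arm = Arm(60.0, None, base)
            else:
                # move tau until risk drops by ~delta (bisection)
                target = ctrl.risk - delta
                lo, hi = base.tau, base.tau * 6.0
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    arm = Arm(60.0, None, base.replace(tau=mid))
                    if arm.risk > target:
                        lo = mid
                    else:
                        hi = mid
            subjects.append(SubjectArms(f"P{i}", {0.0: ctrl, 60.0: arm}))
        return InterventionStudy(subjects=subjects)

    def test_flat_study_has_no_responders(self):
        study = make_study({d: 89.4 for d in (0.0, 60.0, 120.0, 180.0)})
        split = responder_split(study)
        assert split.responders == ()

    def test_constructed_split_counts(self):
        study = self._study_with_changes([0.10] * 4 + [0.0] * 6)
        split = responder_split(study, delta_threshold=0.05)
        assert len(split.responders) == 4
        assert len(split.non_responders) == 6

    def test_zero_threshold_counts_any_strict_decrease(self):
        study = self._study_with_changes([0.01, 0.0])
        split = responder_split(study, delta_threshold=0.0)
        assert "P0" in split.responders
        assert "P1" in split.non_responders


def test_control_arm_required():
    base = healthy_reference_parameters()
    with pytest.raises(ValidationError):
        SubjectArms("P0", {60.0: Arm(60.0, None, base)})
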