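"""Tier scoring, gating, scheme validation, and score monotonicity/bounds."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pqmchal.errors import InputError, SchemeValidationError
from pqmchal.scoring import (
    ScoringScheme,
    TierSchedule,
    apply_gates,
    default_scheme,
    load_scheme,
    score_metric,
    score_plan,
    validate_scheme,
)


def ideal_values(scheme):
    """Every metric exactly at its max-points threshold."""
    return {m.metric_id: s.ideal_threshold for m, s in scheme.metrics}


def ok_metadata():
    return {
        "delivery_min": 18.0,
        "beam_on_min": 1.5,
        "n_beams": 17,
        "n_segments": 139,
        "mu": 909,
        "experience_years": 7.0,
        "viewray_years": 1.0,
    }


class TestScoreMetric:
    def test_conformation_tiers_follow_published_bands(self, scheme):
        _, sched = scheme.find("ptv3_conformation")
        assert score_metric(0.75, sched, "higher_better")[0] == "good"
        assert score_metric(0.85, sched, "higher_better")[0] == "ideal"
        assert score_metric(0.65, sched, "higher_better")[0] == "acceptable"
        assert score_metric(0.55, sched, "higher_better")[0] == "marginal"
        assert score_metric(0.45, sched, "higher_better")[0] == "unacceptable"

    def test_boundary_value_takes_better_tier(self, scheme):
        _, sched = scheme.find("ptv3_conformation")
        tier, pts = score_metric(0.8, sched, "higher_better")
        assert tier == "ideal" and pts == sched.max_points

    def test_binary_fail_scores_zero(self, scheme):
        _, sched = scheme.find("spinal_canal_d0p1cc")
        assert score_metric(51.0, sched, "lower_better") == ("fail", 0.0)
        assert score_metric(50.0, sched, "lower_better") == ("pass", sched.max_points)

    def test_non_finite_value_rejected(self, scheme):
        _, sched = scheme.find("ptv1_d95")
        with pytest.raises(InputError):
            score_metric(float("nan"), sched, "higher_better")

    @given(st.floats(-1e-9, 1e-9), st.sampled_from([0.5, 0.6, 0.7, 0.8]))
    def test_boundary_stability_under_tiny_perturbation(self, scheme, eps, boundary):
        """Points are a step function: a +-1e-9 nudge moves at most one tier."""
        _, sched = scheme.find("ptv3_conformation")
        _, p0 = score_metric(boundary, sched, "higher_better")
        _, p1 = score_metric(boundary + eps, sched, "higher_better")
        assert abs(p1 - p0) <= sched.max_points / 4 + 1e-12
        if eps >= 0:  # improving side of the tie rule keeps the better tier
            assert p1 >= p0

    @given(
        st.floats(0, 80, allow_nan=False),
        st.floats(0.01, 5.0),
        st.sampled_from(["ptv1_d95", "parotid_left_dmean", "ptv3_conformation"]),
    )
    def test_improving_a_value_never_loses_points(self, scheme, value, delta, metric_id):
        mspec, sched = scheme.find(metric_id)
        better = value + delta if mspec.direction == "higher_better" else value - delta
        _, p0 = score_metric(value, sched, mspec.direction)
        _, p1 = score_metric(better, sched, mspec.direction)
        assert p1 >= p0


class TestGates:
    def test_overtime_plan_flagged(self, scheme):
        values = ideal_values(scheme)
        md = ok_metadata() | {"delivery_min": 22.4}
        failures = apply_gates(md, values, scheme)
        assert len(failures) == 1
        assert failures[0].gate == "delivery_time"
        assert failures[0].observed == 22.4

    def test_twenty_minutes_exactly_passes(self, scheme):
        failures = apply_gates(ok_metadata() | {"delivery_min": 20.0}, ideal_values(scheme), scheme)
        assert failures == []

    def test_hard_constraint_violation_named(self, scheme):
        values = ideal_values(scheme) | {"spinal_canal_d0p1cc": 52.0}
        failures = apply_gates(ok_metadata(), values, scheme)
        assert any(f.metric_id == "spinal_canal_d0p1cc" for f in failures)

    def test_missing_delivery_time_rejected(self, scheme):
        with pytest.raises(InputError):
            apply_gates({}, ideal_values(scheme), scheme)


class TestScorePlan:
    def test_all_ideal_plan_reaches_the_full_scale(self, scheme):
        card = score_plan(ideal_values(scheme), ok_metadata(), scheme)
        assert card.pqm == 150.0
        assert card.ptv_points == 78.0
        assert card.oar_points == 72.0
        assert card.acceptable

    def test_failed_binary_metric_contributes_zero_and_gates(self, scheme):
        values = ideal_values(scheme) | {"brainstem_d0p1cc": 55.0}
        card = score_plan(values, ok_metadata(), scheme)
        assert card.metric_points["brainstem_d0p1cc"] == 0.0
        assert not card.acceptable
        assert card.pqm == 150.0 - scheme.find("brainstem_d0p1cc")[1].max_points

    def test_missing_metric_named(self, scheme):
        values = ideal_values(scheme)
        values.pop("glottis_dmean")
        with pytest.raises(InputError, match="glottis_dmean"):
            score_plan(values, ok_metadata(), scheme)

    def test_gating_never_alters_the_numeric_score(self, scheme):
        values = ideal_values(scheme)
        fast = score_plan(values, ok_metadata() | {"delivery_min": 15.0}, scheme)
        slow = score_plan(values, ok_metadata() | {"delivery_min": 25.0}, scheme)
        assert fast.pqm == slow.pqm
        assert fast.acceptable and not slow.acceptable

    @given(st.integers(0, 2**31 - 1))
    def test_random_plans_stay_in_bounds_and_additive(self, scheme, seed):
        rng = np.random.default_rng(seed)
        values = {m.metric_id: rng.uniform(0, 80) for m, _ in scheme.metrics}
        values["ptv3_conformation"] = rng.uniform(0, 1)
        card = score_plan(values, ok_metadata(), scheme)
        assert 0.0 <= card.pqm <= 150.0
        assert card.pqm == pytest.approx(card.ptv_points + card.oar_points, abs=1e-9)
        assert card.pqm == pytest.approx(sum(card.metric_points.values()), abs=1e-9)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    def test_single_metric_improvement_never_decreases_pqm(self, scheme, seed, delta):
        rng = np.random.default_rng(seed)
        values = {m.metric_id: rng.uniform(0, 80) for m, _ in scheme.metrics}
        values["ptv3_conformation"] = rng.uniform(0, 1)
        mspec, _ = scheme.metrics[rng.integers(16)]
        base = score_plan(values, ok_metadata(), scheme).pqm
        sign = 1 if mspec.direction == "higher_better" else -1
        improved = dict(values)
        improved[mspec.metric_id] = values[mspec.metric_id] + sign * delta
        assert score_plan(improved, ok_metadata(), scheme).pqm >= base


class TestSchemeValidation:
    def test_default_scheme_is_valid_with_16_metrics(self, scheme):
        assert validate_scheme(scheme) == []
        assert len(scheme.metrics) == 16
        groups = [m.group for m, _ in scheme.metrics]
        assert groups.count("PTV") == 6 and groups.count("OAR") == 10

    def test_fifteen_metric_scheme_rejected(self, scheme):
        broken = ScoringScheme(
            metrics=scheme.metrics[:15],
            max_delivery_min=scheme.max_delivery_min,
            hard_constraints=[],
        )
        report = validate_scheme(broken)
        assert any("15" in v for v in report)

    def test_wrong_ptv_subtotal_rejected(self, scheme):
        metrics = list(scheme.metrics)
        mspec, sched = metrics[0]
        inflated = TierSchedule(
            mode=sched.mode,
            boundaries=sched.boundaries,
            tier_points=sched.tier_points[:-1] + (15.0,),
            max_points=15.0,
        )
        metrics[0] = (mspec, inflated)
        broken = ScoringScheme(metrics=metrics, max_delivery_min=20.0)
        assert any("PTV max points" in v for v in validate_scheme(broken))

    def test_non_monotone_boundaries_rejected(self, scheme):
        metrics = list(scheme.metrics)
        mspec, sched = metrics[0]
        metrics[0] = (
            mspec,
            TierSchedule(
                mode="tiered",
                boundaries=(66.5, 65.5, 64.5, 63.0),  # wrong way for higher_better
                tier_points=sched.tier_points,
                max_points=sched.max_points,
            ),
        )
        broken = ScoringScheme(metrics=metrics, max_delivery_min=20.0)
        assert any("monotone" in v for v in validate_scheme(broken))

    def test_unparseable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "scheme.json"
        bad.write_text("{not json")
        from pqmchal.errors import FormatError

        with pytest.raises(FormatError):
            load_scheme(bad)

    def test_invalid_file_lists_violations(self, tmp_path, scheme):
        raw = json.loads(
            (__import__("importlib").resources.files("pqmchal.data") / "scheme.json").read_text()
        )
        raw["metrics"] = raw["metrics"][:15]
        p = tmp_path / "short.json"
        p.write_text(json.dumps(raw))
        with pytest.raises(SchemeValidationError) as err:
            load_scheme(p)
        assert any("15" in v for v in err.value.violations)
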