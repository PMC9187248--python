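"""Unit and property tests for the five evidence-to-score rubrics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from caremcda.rubric import (
    CapacityEvidence,
    DomainAssessment,
    Environment,
    EvaluatorDisagreement,
    IntegrationEvidence,
    PatientOutcomeEvidence,
    RiskEvidence,
    RiskMatrix,
    ScoreVector,
    Success,
    WorkforceEvidence,
    classify_environment,
    classify_success,
    score_capacity,
    score_integration,
    score_patient_outcomes,
    score_risk,
    score_risk_evidence,
    score_workforce,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

DIRECTIONS = ["reduction", "none", "mixed"]
SIGNIFICANCE = ["yes", "no", "unknown"]
LEVELS = ["none", "observed", "significant"]
JUDGEMENTS = ["none", "partial", "full"]


class TestCapacity:
    @pytest.mark.parametrize(
        "direction, significant, expected",
        [
            ("reduction", "yes", 2),
            ("reduction", "no", 1),
            ("reduction", "unknown", 1),  # unreported significance is not credited
            ("none", "unknown", 0),
            ("mixed", "unknown", 0),  # shift between settings, no net proof
            ("mixed", "yes", 0),
        ],
    )
    def test_rubric_branches(self, direction, significant, expected):
        ev = CapacityEvidence(effect_direction=direction, significant=significant)
        assert score_capacity(ev) == expected

    @pytest.mark.parametrize(
        "significant, p_value, ok",
        [
            ("yes", 0.01, True),
            ("yes", 0.05, False),  # threshold itself is not significant
            ("no", 0.2, True),
            ("no", 0.01, False),
            ("unknown", 0.2, False),  # p in hand contradicts 'unknown'
            ("unknown", None, True),
        ],
    )
    def test_p_value_must_match_significance_flag(self, significant, p_value, ok):
        make = lambda: CapacityEvidence(
            effect_direction="reduction", significant=significant, p_value=p_value
        )
        if ok:
            make()
        else:
            with pytest.raises(ValidationError):
                make()

    @given(direction=st.sampled_from(DIRECTIONS))
    def test_strengthening_significance_never_lowers_score(self, direction):
        scores = [
            score_capacity(CapacityEvidence(effect_direction=direction, significant=s))
            for s in ("unknown", "no", "yes")
        ]
        assert scores == sorted(scores)


class TestPatientOutcomes:
    @pytest.mark.parametrize(
        "sat, qol, access, expected",
        [
            ("significant", "significant", True, 2.0),
            ("none", "none", True, 0.4),  # access-only projects
            ("none", "none", False, 0.0),
            ("observed", "observed", True, 1.2),
            ("observed", "significant", True, 1.6),
        ],
    )
    def test_rescaled_point_sum(self, sat, qol, access, expected):
        ev = PatientOutcomeEvidence(
            satisfaction=sat, quality_of_life=qol, access_improved=access
        )
        assert score_patient_outcomes(ev) == pytest.approx(expected)

    @given(
        sat=st.sampled_from(LEVELS),
        qol=st.sampled_from(LEVELS),
        access=st.booleans(),
    )
    def test_score_is_two_fifths_of_raw_points(self, sat, qol, access):
        ev = PatientOutcomeEvidence(
            satisfaction=sat, quality_of_life=qol, access_improved=access
        )
        assert 0 <= ev.raw_points <= 5
        assert score_patient_outcomes(ev) == pytest.approx(ev.raw_points * 0.4)


def _integration(cl, pr, og):
    pairs = {"clinical": cl, "professional": pr, "organisational": og}
    return IntegrationEvidence(
        **{
            d: DomainAssessment(evaluator_1=a, evaluator_2=b)
            for d, (a, b) in pairs.items()
        }
    )


class TestIntegration:
    def test_all_domains_fully_integrated_scores_two(self):
        ev = _integration(*[("full", "full")] * 3)
        assert score_integration(ev) == pytest.approx(2.0)

    def test_single_full_domain_scores_two_thirds(self):
        ev = _integration(("full", "full"), ("none", "none"), ("none", "none"))
        assert score_integration(ev) == pytest.approx(2 / 3)

    def test_no_evidence_scores_zero(self):
        ev = _integration(*[("none", "none")] * 3)
        assert score_integration(ev) == 0.0

    @pytest.mark.parametrize(
        "pair, points",
        [
            (("full", "full"), 2),
            (("partial", "partial"), 1),
            (("full", "partial"), 1),  # mixed judgement resolves to partial
            (("partial", "full"), 1),
            (("partial", "none"), 0),
        ],
    )
    def test_domain_points_require_agreement(self, pair, points):
        ev = _integration(pair, ("none", "none"), ("none", "none"))
        assert score_integration(ev) == pytest.approx(points / 3)

    def test_full_vs_none_disagreement_warns_and_scores_zero(self):
        ev = _integration(("full", "none"), ("none", "none"), ("none", "none"))
        with pytest.warns(EvaluatorDisagreement):
            assert score_integration(ev) == 0.0

    @given(
        judgements=st.tuples(
            *[
                st.tuples(st.sampled_from(JUDGEMENTS), st.sampled_from(JUDGEMENTS))
                for _ in range(3)
            ]
        )
    )
    def test_score_is_a_third_multiple_in_range(self, judgements):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EvaluatorDisagreement)
            s = score_integration(_integration(*judgements))
        assert any(abs(s - k / 3) < 1e-12 for k in range(7))


class TestWorkforce:
    @pytest.mark.parametrize(
        "upskilled, satisfied, worsened, expected",
        [
            (True, True, False, 2),
            (True, False, False, 1),
            (False, True, False, 1),
            (False, False, False, 0),
            (True, True, True, 0),  # gains at the expense of workload
            (True, False, True, 0),
        ],
    )
    def test_rubric_branches(self, upskilled, satisfied, worsened, expected):
        ev = WorkforceEvidence(
            upskilled=upskilled,
            satisfaction_improved=satisfied,
            workload_or_satisfaction_worsened=worsened,
        )
        assert score_workforce(ev) == expected

    @given(upskilled=st.booleans(), satisfied=st.booleans())
    def test_adding_a_gain_never_lowers_score_absent_worsening(
        self, upskilled, satisfied
    ):
        base = score_workforce(
            WorkforceEvidence(upskilled=upskilled, satisfaction_improved=satisfied)
        )
        more = score_workforce(
            WorkforceEvidence(upskilled=True, satisfaction_improved=satisfied)
        )
        assert more >= base


class TestEnvironmentAndSuccess:
    @pytest.mark.parametrize(
        "f, b, expected",
        [
            (10, 4, Environment.SUPPORTIVE),  # 10 > 1.25 * 4
            (5, 4, Environment.BALANCED),  # 5 == 1.25 * 4, not strict
            (4, 5, Environment.BALANCED),  # 5 <= 1.25 * 4
            (4, 6, Environment.HOSTILE),
            (0, 0, Environment.BALANCED),
            (1, 0, Environment.SUPPORTIVE),
        ],
    )
    def test_ratio_rule(self, f, b, expected):
        assert classify_environment(f, b) is expected

    @pytest.mark.parametrize(
        "f, b, expected",
        [
            (10, 4, Environment.SUPPORTIVE),  # share (10-4)/14 = 0.43
            (5, 3, Environment.SUPPORTIVE),  # share 0.25 exactly -> not strict
            (0, 0, Environment.BALANCED),
        ],
    )
    def test_share_rule_variant(self, f, b, expected):
        got = classify_environment(f, b, rule="share")
        if (f, b) == (5, 3):
            assert got is Environment.BALANCED
        else:
            assert got is expected

    @given(
        f=st.integers(0, 50), b=st.integers(0, 50),
        rule=st.sampled_from(["ratio", "share"]),
    )
    def test_antisymmetry_under_swapping_tallies(self, f, b, rule):
        mirror = {
            Environment.SUPPORTIVE: Environment.HOSTILE,
            Environment.HOSTILE: Environment.SUPPORTIVE,
            Environment.BALANCED: Environment.BALANCED,
        }
        assert classify_environment(b, f, rule=rule) is mirror[
            classify_environment(f, b, rule=rule)
        ]

    @pytest.mark.parametrize(
        "achieved, total, expected",
        [
            (8, 10, Success.HIGH),
            (2, 10, Success.LOW),
            (1, 2, Success.MODERATE),
            (2, 3, Success.MODERATE),  # exactly 2/3 is not 'more than'
            (1, 3, Success.MODERATE),  # exactly 1/3 is not 'less than'
            (3, 3, Success.HIGH),
            (0, 5, Success.LOW),
        ],
    )
    def test_success_thresholds_are_strict(self, achieved, total, expected):
        assert classify_success(achieved, total) is expected

    def test_zero_total_objectives_rejected(self):
        with pytest.raises(ValueError):
            classify_success(0, 0)


class TestRiskMatrix:
    def test_anchored_corners(self):
        assert score_risk(Environment.SUPPORTIVE, Success.HIGH) == 2.0
        assert score_risk(Environment.HOSTILE, Success.LOW) == 0.0

    def test_default_matrix_is_additive(self):
        assert score_risk(Environment.BALANCED, Success.MODERATE) == 1.0
        assert score_risk(Environment.SUPPORTIVE, Success.MODERATE) == 1.5
        assert score_risk(Environment.HOSTILE, Success.MODERATE) == 0.5

    def test_default_off_corner_cells_stay_in_observed_band(self):
        m = RiskMatrix()
        for env in Environment:
            for suc in Success:
                if (env, suc) in (
                    (Environment.SUPPORTIVE, Success.HIGH),
                    (Environment.HOSTILE, Success.LOW),
                ):
                    continue
                assert m[(env, suc)] in {0.5, 1.0, 1.5}

    @pytest.mark.parametrize(
        "corner, value",
        [((Environment.SUPPORTIVE, Success.HIGH), 1.5),
         ((Environment.HOSTILE, Success.LOW), 0.5)],
    )
    def test_matrices_violating_anchors_rejected(self, corner, value):
        cells = RiskMatrix().as_dict()
        cells[(corner[0].value, corner[1].value)] = value
        with pytest.raises(ValueError):
            RiskMatrix({(e, s): v for (e, s), v in cells.items()})

    def test_off_grid_cell_values_rejected(self):
        cells = RiskMatrix().as_dict()
        cells[("balanced", "moderate")] = 0.75
        with pytest.raises(ValueError):
            RiskMatrix({(e, s): v for (e, s), v in cells.items()})

    def test_evidence_to_score_path(self):
        ev = RiskEvidence(
            n_facilitators=10, n_barriers=4, objectives_achieved=9, objectives_total=10
        )
        assert score_risk_evidence(ev) == 2.0

    def test_achieved_cannot_exceed_total(self):
        with pytest.raises(ValidationError):
            RiskEvidence(
                n_facilitators=1, n_barriers=1, objectives_achieved=5, objectives_total=4
            )


class TestScoreVector:
    def test_supports_enforced(self):
        ScoreVector(
            project_id="p", capacity=2, outcomes=1.6, integration=4 / 3,
            workforce=1, risk=0.5,
        )
        for bad in (
            dict(capacity=0.5),
            dict(outcomes=0.5),
            dict(integration=0.5),
            dict(workforce=1.5),
            dict(risk=0.25),
        ):
            kwargs = dict(
                project_id="p", capacity=0, outcomes=0, integration=0,
                workforce=0, risk=0,
            )
            kwargs.update(bad)
            with pytest.raises(ValidationError):
                ScoreVector(**kwargs)

    @given(
        direction=st.sampled_from(DIRECTIONS),
        significant=st.sampled_from(SIGNIFICANCE),
        sat=st.sampled_from(LEVELS),
        qol=st.sampled_from(LEVELS),
        access=st.booleans(),
    )
    def test_every_rubric_output_is_a_legal_score(
        self, direction, significant, sat, qol, access
    ):
        ScoreVector(
            project_id="p",
            capacity=score_capacity(
                CapacityEvidence(effect_direction=direction, significant=significant)
            ),
            outcomes=score_patient_outcomes(
                PatientOutcomeEvidence(
                    satisfaction=sat, quality_of_life=qol, access_improved=access
                )
            ),
            integration=0,
            workforce=0,
            risk=0,
        )
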