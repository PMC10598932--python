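"""The two-part chemogram score: identities, oracles, and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chemogram import (
    DataError,
    DoseResponseProfile,
    ScoringConfig,
    ScoringError,
    auc_score,
    build_reference,
    final_score,
    hit_threshold_from_cohort,
    normalized_auc,
    score_cohort,
    sensitivity_score,
)
from chemogram.scoring import CohortReference
from tests.conftest import make_profiles

viability_triples = st.tuples(
    st.floats(min_value=0, max_value=120),
    st.floats(min_value=0, max_value=120),
    st.floats(min_value=0, max_value=120),
)


def profile(v, pdo="X", drug="drugA"):
    return DoseResponseProfile(pdo_id=pdo, drug=drug, viability=tuple(v))


def reference_for(*triples, drug="drugA"):
    return build_reference(
        make_profiles({f"p{i}": t for i, t in enumerate(triples)}, drug=drug)
    )


class TestNormalizedAuc:
    @pytest.mark.parametrize(
        "viability, expected",
        [((100, 100, 100), 1.0), ((0, 0, 0), 0.0), ((100, 50, 0), 0.5)],
    )
    def test_identities_and_hand_trapezoid(self, viability, expected):
        assert normalized_auc(viability) == pytest.approx(expected, abs=1e-15)

    def test_growth_stimulation_can_exceed_one(self):
        assert normalized_auc((120, 110, 105)) > 1.0

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            normalized_auc((-1, 50, 0))
        with pytest.raises(DataError):
            normalized_auc((100, 50, 0), x=(0, 0, 1))
        with pytest.raises(DataError):
            normalized_auc((100,))


class TestAucScore:
    def test_pdo_equal_to_cohort_average_scores_one(self):
        ref = reference_for((80, 50, 20), (80, 50, 20))
        assert auc_score(profile((80, 50, 20)), ref) == pytest.approx(1.0)

    def test_direct_ratio(self):
        # cohort-average normalized AUC 0.8, PDO 0.4 -> score 2
        ref = CohortReference(
            mean_profile={"drugA": np.array([80.0, 80.0, 80.0])},
            n_pdos={"drugA": 5},
        )
        assert auc_score(profile((40, 40, 40)), ref) == pytest.approx(2.0)

    def test_total_kill_capped_by_floor(self):
        ref = CohortReference(
            mean_profile={"drugA": np.array([80.0, 80.0, 80.0])},
            n_pdos={"drugA": 5},
        )
        assert auc_score(profile((0, 0, 0)), ref) == pytest.approx(80.0)

    def test_drug_absent_from_reference(self):
        ref = reference_for((80, 50, 20), (60, 40, 20))
        with pytest.raises(ScoringError):
            auc_score(profile((50, 40, 30), drug="other"), ref)

    def test_leave_one_out_removes_self_from_average(self):
        profiles = make_profiles({"a": (100, 100, 100), "b": (50, 50, 50)})
        ref = build_reference(profiles)
        config = ScoringConfig(leave_one_out=True)
        # leave-one-out reference for "b" is pure (100,100,100): score 1/0.5
        assert auc_score(profiles[1], ref, config) == pytest.approx(2.0)
        # a PDO outside the cohort falls back to the full average (0.75)
        outsider = profile((75, 75, 75), pdo="new")
        assert auc_score(outsider, ref, config) == pytest.approx(1.0)


class TestSensitivityScore:
    @pytest.mark.parametrize(
        "viability, expected",
        [((100, 100, 100), 0.0), ((0, 0, 0), 1.0), ((100, 50, 0), 0.5)],
    )
    def test_area_over_curve_fraction(self, viability, expected):
        assert sensitivity_score(profile(viability)) == pytest.approx(expected, abs=1e-15)

    @given(v=viability_triples)
    def test_bounded_above_by_one(self, v):
        assert sensitivity_score(profile(v)) <= 1.0 + 1e-12


class TestFinalScore:
    def test_sum_and_threshold(self):
        ref = reference_for((92, 92, 92), (92, 92, 92))
        cs = final_score(profile((92, 92, 92)), ref)
        # sensitivity 1 - 0.92 = 0.08; auc score 1.0
        assert cs.final_score == cs.auc_score + cs.sensitivity_score
        assert cs.final_score == pytest.approx(1.08)
        assert not cs.hit

    def test_hit_comparison_is_strict(self):
        ref = reference_for((40, 40, 40), (40, 40, 40))
        cs = final_score(profile((40, 40, 40)), ref)
        at_tie = ScoringConfig(hit_threshold=cs.final_score)
        assert not final_score(profile((40, 40, 40)), ref, at_tie).hit
        below = ScoringConfig(hit_threshold=cs.final_score * (1 - 1e-12))
        assert final_score(profile((40, 40, 40)), ref, below).hit

    def test_cohort_average_pdo_scores_one_plus_sensitivity(self):
        ref = reference_for((70, 50, 30), (70, 50, 30))
        cs = final_score(profile((70, 50, 30)), ref)
        assert cs.final_score == pytest.approx(1.0 + cs.sensitivity_score)

    @given(
        pdo=viability_triples,
        drop=st.tuples(*[st.floats(min_value=0, max_value=30)] * 3),
    )
    def test_monotone_under_pointwise_viability_drop(self, pdo, drop):
        """Killing more cells (cohort reference fixed) never lowers any score."""
        ref = CohortReference(
            mean_profile={"drugA": np.array([80.0, 60.0, 40.0])}, n_pdos={"drugA": 5}
        )
        lower = tuple(max(v - d, 0.0) for v, d in zip(pdo, drop))
        hi = final_score(profile(pdo), ref)
        lo = final_score(profile(lower), ref)
        assert lo.auc_score >= hi.auc_score - 1e-12
        assert lo.sensitivity_score >= hi.sensitivity_score - 1e-12
        assert lo.final_score >= hi.final_score - 1e-12


class TestScoreCohort:
    def test_identical_pdos_are_symmetric(self):
        profiles = make_profiles({"a": (60, 40, 20), "b": (60, 40, 20)})
        matrix = score_cohort(profiles)
        assert matrix.auc_score.loc["a", "drugA"] == pytest.approx(1.0)
        assert matrix.auc_score.loc["b", "drugA"] == pytest.approx(1.0)

    def test_order_invariance(self, rng):
        profiles = [
            profile(tuple(rng.uniform(0, 100, 3)), pdo=f"p{i}", drug=d)
            for i in range(5)
            for d in ("dA", "dB")
        ]
        m1 = score_cohort(profiles)
        shuffled = list(profiles)
        rng.shuffle(shuffled)
        m2 = score_cohort(shuffled)
        assert m1 == m2

    def test_underpopulated_drug_left_missing_with_warning(self):
        profiles = make_profiles({"a": (60, 40, 20), "b": (60, 40, 20)}) + [
            profile((50, 50, 50), pdo="a", drug="lonely")
        ]
        with pytest.warns(UserWarning, match="lonely"):
            matrix = score_cohort(profiles)
        assert matrix.final_score["lonely"].isna().all()

    def test_missing_pairs_stay_missing(self):
        profiles = make_profiles({"a": (60, 40, 20), "b": (60, 40, 20)})
        matrix = score_cohort(profiles, missing_pairs=[("c", "drugA")])
        assert np.isnan(matrix.score("c", "drugA"))
        assert matrix.n_present() == 2

    @given(data=st.data())
    def test_mean_auc_score_at_least_one(self, data):
        """Mean over PDOs of cohort/PDO AUC ratios is >= 1 (AM-HM inequality)."""
        n = data.draw(st.integers(min_value=2, max_value=6))
        triples = [
            data.draw(
                st.tuples(*[st.floats(min_value=5, max_value=100)] * 3)
            )
            for _ in range(n)
        ]
        matrix = score_cohort(make_profiles({f"p{i}": t for i, t in enumerate(triples)}))
        assert matrix.auc_score["drugA"].mean() >= 1.0 - 1e-12


class TestThresholdFromCohort:
    def test_linear_interpolation_quartile(self):
        assert hit_threshold_from_cohort([1, 2, 3, 4]) == pytest.approx(3.25)

    def test_constant_scores(self):
        assert hit_threshold_from_cohort([2.5] * 10) == pytest.approx(2.5)

    def test_near_constant_set(self):
        assert hit_threshold_from_cohort([1.9] * 100 + [5.0]) == pytest.approx(1.9)

    def test_too_few_entries(self):
        with pytest.raises(DataError):
            hit_threshold_from_cohort([1.0, 2.0, 3.0])

    def test_cohort_q3_mode_sets_matrix_threshold(self, rng):
        profiles = [
            profile(tuple(rng.uniform(5, 100, 3)), pdo=f"p{i}", drug=d)
            for i in range(6)
            for d in ("dA", "dB")
        ]
        matrix = score_cohort(profiles, ScoringConfig(threshold_mode="cohort_q3"))
        expected = hit_threshold_from_cohort(matrix)
        assert matrix.threshold == pytest.approx(expected)
        assert matrix.hit.to_numpy(dtype=bool).sum() == (
            (matrix.final_score > expected).to_numpy().sum()
        )


class TestUnitAndSpacingInvariance:
    def test_scores_invariant_to_fraction_units(self):
        percent = profile((80, 50, 20))
        fraction = profile((0.80, 0.50, 0.20))
        ref_pct = reference_for((90, 60, 30), (70, 40, 10))
        ref_frac = CohortReference(
            mean_profile={"drugA": ref_pct.mean_profile["drugA"] / 100.0},
            n_pdos=ref_pct.n_pdos,
        )
        cfg_frac = ScoringConfig(full_scale=1.0)
        assert auc_score(fraction, ref_frac, cfg_frac) == pytest.approx(
            auc_score(percent, ref_pct)
        )
        assert sensitivity_score(fraction, cfg_frac) == pytest.approx(
            sensitivity_score(percent)
        )

    def test_index_and_log10M_spacing_agree_on_uniform_panel(self, panel, rng):
        profiles = [
            profile(tuple(rng.uniform(5, 100, 3)), pdo=f"p{i}", drug=drug)
            for i in range(4)
            for drug in panel.names
        ]
        m_index = score_cohort(profiles, ScoringConfig(spacing="index"), panel=panel)
        m_log = score_cohort(profiles, ScoringConfig(spacing="log10M"), panel=panel)
        np.testing.assert_allclose(
            m_index.final_score.to_numpy(float),
            m_log.final_score.to_numpy(float),
            rtol=1e-12,
        )


class TestLinearityOracle:
    def test_auc_of_mean_curve_equals_mean_of_aucs(self, rng):
        """The trapezoid rule is linear in viabilities, so the cohort-average
        profile's AUC must equal the average of the member AUCs."""
        for _ in range(200):
            cohort = rng.uniform(0, 110, size=(rng.integers(2, 10), 3))
            lhs = normalized_auc(cohort.mean(axis=0))
            rhs = float(np.mean([normalized_auc(v) for v in cohort]))
            assert lhs == pytest.approx(rhs, abs=1e-12)
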