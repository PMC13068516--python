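"""Group aggregation, classification, stratification, rank reversal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ahp_prefs.aggregate import (
    aggregate_judgments,
    aggregate_priorities,
    classify_inconsistency,
    detect_rank_reversal,
    filter_consistent,
    stratify_by_vas,
)
from ahp_prefs.cohort import CohortWeightTable
from ahp_prefs.core import (
    PairwiseComparisonMatrix,
    PriorityVector,
    principal_eigenvector,
)
from ahp_prefs.simulate import SimulationConfig, simulate_cohort


def pv(*weights, criteria=None):
    criteria = criteria or tuple(f"c{i}" for i in range(len(weights)))
    return PriorityVector.from_raw(criteria, weights)


class TestAggregatePriorities:
    def test_idempotent_on_identical_vectors(self):
        v = pv(0.5, 0.3, 0.2)
        out = aggregate_priorities([v, v, v])
        np.testing.assert_allclose(out.weights, v.weights, atol=1e-12)

    def test_opposite_preferences_cancel(self):
        out = aggregate_priorities([pv(0.8, 0.2), pv(0.2, 0.8)])
        np.testing.assert_allclose(out.weights, [0.5, 0.5], atol=1e-12)

    def test_matches_direct_log_mean_oracle(self, rng):
        """Small-cohort brute force: exp of the mean log weight,
        renormalized, computed without the library."""
        for n_resp in (1, 2, 3):
            vectors = [pv(*rng.uniform(0.05, 1.0, 3)) for _ in range(n_resp)]
            expected = np.exp(
                np.mean([np.log(v.weights) for v in vectors], axis=0)
            )
            expected /= expected.sum()
            out = aggregate_priorities(vectors)
            np.testing.assert_allclose(out.weights, expected, atol=1e-12)

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_priorities([])
        with pytest.raises(ValueError, match="mismatch"):
            aggregate_priorities([pv(0.5, 0.5),
                                  pv(0.5, 0.5, criteria=("x", "y"))])

    def test_zero_weight_rejected_with_guidance(self):
        bad = PriorityVector(("a", "b"), np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="renormalize"):
            aggregate_priorities([bad, pv(0.5, 0.5, criteria=("a", "b"))])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_resp=st.integers(2, 6))
def test_aip_permutation_and_scale_invariance(seed, n_resp):
    """Respondent order is irrelevant, and scaling one respondent's raw
    weights before normalization changes nothing."""
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.05, 1.0, size=(n_resp, 4))
    crit = ("a", "b", "c", "d")
    vectors = [PriorityVector.from_raw(crit, r) for r in raw]
    base = aggregate_priorities(vectors)
    perm = rng.permutation(n_resp)
    shuffled = aggregate_priorities([vectors[i] for i in perm])
    np.testing.assert_allclose(shuffled.weights, base.weights, atol=1e-12)
    scaled = [PriorityVector.from_raw(crit, r * rng.uniform(0.1, 10))
              for r in raw]
    np.testing.assert_allclose(
        aggregate_priorities(scaled).weights, base.weights, atol=1e-10
    )


class TestAggregateJudgments:
    def test_identical_consistent_matrices_pass_through(self):
        m = PairwiseComparisonMatrix.from_weights(("a", "b", "c"),
                                                  (0.5, 0.3, 0.2))
        group, weights, report = aggregate_judgments([m, m])
        np.testing.assert_allclose(group.entries, m.entries, atol=1e-12)
        assert report.cr == pytest.approx(0.0, abs=1e-9)

    def test_transpose_pair_cancels_to_indifference(self):
        m = PairwiseComparisonMatrix(
            ("a", "b", "c"),
            [[1, 3, 5], [1 / 3, 1, 7], [1 / 5, 1 / 7, 1]],
        )
        mt = PairwiseComparisonMatrix(("a", "b", "c"), m.entries.T)
        group, weights, _ = aggregate_judgments([m, mt])
        np.testing.assert_allclose(group.entries, 1.0, atol=1e-12)
        np.testing.assert_allclose(weights.weights, 1 / 3, atol=1e-9)

    def test_group_matrix_is_reciprocal(self, rng):
        from ahp_prefs.core import SAATY_VALUES

        def saaty_like(n):
            iu = np.triu_indices(n, 1)
            vals = rng.choice(SAATY_VALUES, size=len(iu[0]))
            entries = np.ones((n, n))
            entries[iu] = vals
            entries[iu[1], iu[0]] = 1.0 / vals
            return PairwiseComparisonMatrix(
                tuple(f"c{i}" for i in range(n)), entries)

        mats = [saaty_like(4) for _ in range(5)]
        group, _, _ = aggregate_judgments(mats)
        np.testing.assert_allclose(group.entries * group.entries.T, 1.0,
                                   atol=1e-9)

    def test_aij_equals_aip_for_consistent_respondents(self, rng):
        crit = ("a", "b", "c", "d")
        mats, vecs = [], []
        for _ in range(6):
            w = rng.uniform(0.1, 1.0, 4)
            w /= w.sum()
            # keep ratios within the representable 9:1 band
            w = 0.5 * w + 0.5 * 0.25
            vecs.append(PriorityVector.from_raw(crit, w))
            mats.append(PairwiseComparisonMatrix.from_weights(crit, w))
        _, aij, _ = aggregate_judgments(mats)
        aip = aggregate_priorities(vecs)
        np.testing.assert_allclose(aij.weights, aip.weights, atol=1e-9)

    def test_simulated_cohort_recovers_truth_with_consistent_group(self):
        """26 noisy respondents around known weights: AIJ recovers the
        truth to within the noise tolerance and the group matrix is
        consistent at the 0.1 bound even though individuals are not."""
        cfg = SimulationConfig(n=26, sigma=0.35, seed=404)
        sim = simulate_cohort(cfg)
        _, weights, report = aggregate_judgments(sim.matrices_level1)
        np.testing.assert_allclose(
            weights.weights, cfg.level1_vector.weights, atol=0.05
        )
        assert report.cr < 0.1


class TestClassify:
    def test_fixture_reproduces_published_breakdown(self, fixture_cohort):
        b = classify_inconsistency(fixture_cohort.weights)
        assert (b.any_level, b.level1_only, b.level2_only, b.both_levels,
                b.level1_total) == (16, 3, 4, 9, 12)

    def test_all_consistent_cohort_counts_zero(self, fixture_cohort):
        f = fixture_cohort.weights.frame.copy()
        f[["cr_l1", "cr_l2"]] = 0.0
        b = classify_inconsistency(CohortWeightTable(f), threshold=0.2)
        assert b.any_level == 0 and b.level1_total == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(flags=st.lists(st.tuples(st.booleans(), st.booleans()),
                          min_size=1, max_size=40))
    def test_count_identities_hold_for_any_flag_pattern(self, flags):
        frame = pd.DataFrame({
            **{c: 0.2 for c in ("w_mortality", "w_mi", "w_stroke", "w_hf",
                                "w_ae")},
            **{c: 0.25 for c in ("w_pain", "w_dyspnea", "w_cough",
                                 "w_edema")},
            "cr_l1": 0.0, "cr_l2": 0.0,
            "inc_l1": [a for a, _ in flags],
            "inc_l2": [b for _, b in flags],
        }, index=pd.Index(range(1, len(flags) + 1), name="id"))
        b = classify_inconsistency(CohortWeightTable(frame))
        # dataclass __post_init__ would raise if the identities failed
        assert b.any_level <= b.n
        assert b.level1_total >= b.both_levels


class TestFilterAndStratify:
    def test_level1_consistent_subset_has_14_members(self, fixture_cohort):
        kept = filter_consistent(fixture_cohort.weights, level=1)
        assert len(kept) == 14
        assert not kept.frame["inc_l1"].any()

    def test_both_level_subset(self, fixture_cohort):
        kept = filter_consistent(fixture_cohort.weights, level="either")
        assert len(kept) == 26 - 16

    def test_lax_threshold_keeps_everyone(self, fixture_cohort):
        kept = filter_consistent(fixture_cohort.weights, level=1,
                                 threshold=100.0)
        assert kept.ids == fixture_cohort.weights.ids

    def test_nobody_left_is_an_error(self, fixture_cohort):
        with pytest.raises(ValueError, match="empty"):
            filter_consistent(fixture_cohort.weights, level=1,
                              threshold=-1.0)

    def test_vas_split_at_median(self, fixture_cohort):
        below, above = stratify_by_vas(fixture_cohort, 75)
        assert (len(below), len(above)) == (12, 14)
        assert max(p.vas for p in below.participants) < 75
        assert min(p.vas for p in above.participants) >= 75

    def test_zero_threshold_empties_lower_stratum(self, fixture_cohort):
        below, above = stratify_by_vas(fixture_cohort, 0)
        assert len(below) == 0 and len(above) == 26


class TestRankReversal:
    def test_self_comparison_is_empty(self):
        v = pv(0.5, 0.3, 0.2)
        assert detect_rank_reversal(v, v) == []

    def test_swap_is_detected_once(self):
        a = pv(0.5, 0.3, 0.2)
        b = pv(0.3, 0.5, 0.2)
        assert detect_rank_reversal(a, b) == [("c0", "c1")]

    def test_ties_never_count(self):
        a = pv(0.4, 0.4, 0.2)
        b = pv(0.5, 0.3, 0.2)
        assert detect_rank_reversal(a, b) == []

    def test_fixture_reversal_pattern(self, fixture_cohort):
        """The consistent-subset weighting preserves the full-cohort order;
        the low-VAS stratum (all respondents) swaps mortality and stroke,
        the study's single observed rank reversal."""
        w_all = aggregate_priorities(
            fixture_cohort.weights.level1_vectors())
        w_cons = aggregate_priorities(
            filter_consistent(fixture_cohort.weights, 1).level1_vectors())
        assert detect_rank_reversal(w_all, w_cons) == []
        below, _ = stratify_by_vas(fixture_cohort, 75)
        w_below = aggregate_priorities(below.weights.level1_vectors())
        assert detect_rank_reversal(w_all, w_below) == [
            ("mortality", "stroke")
        ]
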