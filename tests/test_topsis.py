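import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thalrisk as tr
from thalrisk import reference
from thalrisk.errors import (
    ConfigError,
    DegenerateCohortError,
    DegenerateCriterionError,
)
from thalrisk.topsis import HIGH_RISK, LOW_RISK, MEDIUM_RISK


def brute_force_closeness(weighted: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """Straight-line distances and closeness, one sample at a time."""
    out = []
    for row in weighted:
        d_plus = sum((row[j] - pos[j]) ** 2 for j in range(len(row))) ** 0.5
        d_minus = sum((row[j] - neg[j]) ** 2 for j in range(len(row))) ** 0.5
        out.append(d_minus / (d_plus + d_minus))
    return np.array(out)


def _dm(values, criteria=None, normalized=False):
    values = np.asarray(values, dtype=float)
    criteria = criteria or tuple(f"c{i}" for i in range(values.shape[1]))
    return tr.DecisionMatrix(values=values, criteria=tuple(criteria), normalized=normalized)


class TestMinmax:
    def test_closed_form(self):
        M = tr.minmax_normalize(_dm([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(M.values[:, 0], [0.0, 0.5, 1.0])

    def test_idempotent(self):
        M = tr.minmax_normalize(_dm([[2.0, 1.0], [4.0, 5.0], [6.0, 3.0]]))
        again = tr.minmax_normalize(_dm(M.values))
        np.testing.assert_allclose(again.values, M.values)

    def test_constant_criterion_rejected(self):
        with pytest.raises(DegenerateCriterionError, match="c1"):
            tr.minmax_normalize(_dm([[1.0, 7.0], [2.0, 7.0]]))

    def test_frozen_extremes_reused(self):
        fit = tr.minmax_normalize(_dm([[0.0], [10.0]]))
        new = tr.minmax_normalize(_dm([[5.0], [15.0]]), extremes=(fit.mins, fit.maxs))
        np.testing.assert_allclose(new.values[:, 0], [0.5, 1.5])  # unclipped


class TestWeighting:
    def test_uniform_weights_scale(self):
        M = _dm([[0.2, 0.4], [0.6, 0.8]], normalized=True)
        w = tr.WeightVector(criteria=("c0", "c1"), weights=np.array([0.5, 0.5]))
        W = tr.apply_weights(M, w)
        np.testing.assert_allclose(W.values, M.values * 0.5)

    def test_published_worked_product(self, ahp_weights):
        """First published record: weighted Hct entry = 0.8889 x 0.2989."""
        t10 = reference.load_table10_normalized()
        M = tr.DecisionMatrix(
            values=t10[list(ahp_weights.criteria)].to_numpy(),
            criteria=ahp_weights.criteria,
            normalized=True,
        )
        t9 = reference.load_table9_weights()
        w_published = tr.WeightVector(
            criteria=ahp_weights.criteria,
            weights=(t9.reindex(list(ahp_weights.criteria)) / t9.sum()).to_numpy(),
        )
        W = tr.apply_weights(M, w_published)
        hct = list(ahp_weights.criteria).index("Hct")
        assert W.values[0, hct] == pytest.approx(0.8889 * (0.2989 / t9.sum()), abs=1e-12)

    def test_unnormalized_matrix_rejected(self):
        w = tr.WeightVector(criteria=("c0",), weights=np.array([1.0]))
        with pytest.raises(ConfigError):
            tr.apply_weights(_dm([[1.0], [2.0]]), w)


class TestIdeals:
    def test_columnwise_extremes(self):
        pair = tr.ideals(_dm([[0.1, 0.4], [0.3, 0.2]], normalized=True))
        np.testing.assert_allclose(pair.positive, [0.3, 0.4])
        np.testing.assert_allclose(pair.negative, [0.1, 0.2])

    def test_single_sample(self):
        pair = tr.ideals(_dm([[0.3, 0.7]], normalized=True))
        np.testing.assert_allclose(pair.positive, pair.negative)

    def test_full_cohort_ideals_are_weights_and_zero(self, small_cohort, ahp_weights):
        matrix = tr.encode(small_cohort)
        _, W, pair = tr.score_cohort(matrix.values[list(ahp_weights.criteria)], ahp_weights)
        np.testing.assert_allclose(pair.positive, ahp_weights.weights, atol=1e-12)
        np.testing.assert_allclose(pair.negative, 0.0, atol=1e-12)


class TestCloseness:
    def test_ideal_and_anti_ideal_limits(self):
        W = _dm([[0.5, 0.5], [0.0, 0.0], [0.25, 0.25]], normalized=True)
        res = tr.closeness(W, tr.ideals(W))
        np.testing.assert_allclose(res.closeness, [1.0, 0.0, 0.5])

    def test_degenerate_cohort_rejected(self):
        W = _dm([[0.5, 0.5], [0.5, 0.5]], normalized=True)
        with pytest.raises(DegenerateCohortError):
            tr.closeness(W, tr.ideals(W))

    def test_published_excerpt_matches_brute_force(self, ahp_weights):
        """Pipeline closeness on the published normalized excerpt equals a
        straight-line oracle with ideals at (w_j, 0) to 1e-12."""
        t10 = reference.load_table10_normalized()
        M = tr.DecisionMatrix(
            values=t10[list(ahp_weights.criteria)].to_numpy(),
            criteria=ahp_weights.criteria,
            normalized=True,
        )
        W = tr.apply_weights(M, ahp_weights)
        pos = ahp_weights.weights.copy()
        neg = np.zeros(len(pos))
        res = tr.closeness(W, tr.IdealPair(positive=pos, negative=neg))
        oracle = brute_force_closeness(W.values, pos, neg)
        np.testing.assert_allclose(res.closeness, oracle, atol=1e-12)

    def test_weight_doubling_leaves_closeness_unchanged(self):
        rng = np.random.default_rng(0)
        vals = rng.random((20, 4))
        W1 = _dm(vals * np.array([0.4, 0.3, 0.2, 0.1]), normalized=True)
        W2 = _dm(vals * np.array([0.8, 0.6, 0.4, 0.2]), normalized=True)
        r1 = tr.closeness(W1, tr.ideals(W1))
        r2 = tr.closeness(W2, tr.ideals(W2))
        np.testing.assert_allclose(r1.closeness, r2.closeness, atol=1e-12)

    def test_monotone_in_criterion_with_fixed_ideals(self):
        base = np.array([[0.2, 0.3], [0.6, 0.1], [0.4, 0.9]])
        W = _dm(base, normalized=True)
        pair = tr.IdealPair(positive=np.array([1.0, 1.0]), negative=np.zeros(2))
        before = tr.closeness(W, pair).closeness[0]
        bumped = base.copy()
        bumped[0, 0] += 0.3
        after = tr.closeness(_dm(bumped, normalized=True), pair).closeness[0]
        assert after >= before


class TestRank:
    def test_descending_order(self):
        res = tr.TopsisResult(
            d_plus=np.zeros(3), d_minus=np.zeros(3), closeness=np.array([0.9, 0.1, 0.5])
        )
        assert tr.rank(res).ranks.tolist() == [1, 3, 2]

    def test_ties_stable_in_input_order(self):
        res = tr.TopsisResult(
            d_plus=np.zeros(4), d_minus=np.zeros(4), closeness=np.full(4, 0.4)
        )
        assert tr.rank(res).ranks.tolist() == [1, 2, 3, 4]

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30))
    def test_rank_one_is_maximum(self, values):
        res = tr.rank(
            tr.TopsisResult(
                d_plus=np.zeros(len(values)),
                d_minus=np.zeros(len(values)),
                closeness=np.array(values),
            )
        )
        assert res.closeness[res.ranks.tolist().index(1)] == max(values)


class TestStratify:
    def test_published_categories_reproduced(self):
        t11 = reference.load_table11_closeness()
        res = tr.stratify(
            tr.TopsisResult(
                d_plus=np.zeros(len(t11)),
                d_minus=np.zeros(len(t11)),
                closeness=t11["closeness"].to_numpy(),
            )
        )
        assert res.categories.tolist() == t11["risk_category"].tolist()
        assert res.category_counts() == {HIGH_RISK: 2, MEDIUM_RISK: 4, LOW_RISK: 4}

    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.7064, HIGH_RISK),
            (0.2414, LOW_RISK),
            (0.3414, MEDIUM_RISK),
            (0.6082, MEDIUM_RISK),
            (0.66, HIGH_RISK),  # boundary goes to High
            (0.33, MEDIUM_RISK),  # boundary goes to Medium
        ],
    )
    def test_threshold_rules(self, value, expected):
        res = tr.stratify(
            tr.TopsisResult(
                d_plus=np.zeros(2), d_minus=np.zeros(2), closeness=np.array([value, 0.5])
            )
        )
        assert res.categories[0] == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            tr.StratificationConfig(high=0.3, low=0.6)

    def test_permutation_equivariance(self, small_cohort, ahp_weights):
        matrix = tr.encode(small_cohort)
        frame = matrix.values[list(ahp_weights.criteria)]
        res, _, _ = tr.score_cohort(frame, ahp_weights)
        perm = np.random.default_rng(0).permutation(len(frame))
        res_p, _, _ = tr.score_cohort(frame.iloc[perm].reset_index(drop=True), ahp_weights)
        np.testing.assert_allclose(res_p.closeness, res.closeness[perm], atol=1e-12)
        assert res_p.categories.tolist() == res.categories[perm].tolist()
        np.testing.assert_array_equal(res_p.ranks, tr.rank(
            tr.TopsisResult(
                d_plus=res.d_plus[perm], d_minus=res.d_minus[perm],
                closeness=res.closeness[perm],
            )
        ).ranks)
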