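"""ReliefF weighting, ranking, selection, and the IRF sweep."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from octfuse import (
    LabeledFeatureMatrix,
    irf_select,
    rank_features,
    relieff_weights,
    select_top,
)


def brute_force_relieff_k1(X, y):
    """Independent nearest-hit/nearest-miss enumeration for k=1, m=n.

    Follows the textbook update directly: per instance subtract the
    range-normalized diff to its single nearest hit, add the prior-weighted
    diff to the single nearest miss of each other class.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    rng_ = X.max(0) - X.min(0)
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))

    def diff(a, b):
        return np.array([
            0.0 if rng_[f] == 0 else abs(a[f] - b[f]) / rng_[f]
            for f in range(p)
        ])

    def dist(a, b):
        return diff(a, b).sum()

    W = np.zeros(p)
    for i in range(n):
        hits = [j for j in range(n) if j != i and y[j] == y[i]]
        nearest_hit = min(hits, key=lambda j: (dist(X[i], X[j]), j))
        W -= diff(X[i], X[nearest_hit]) / n
        for cls in classes:
            if cls == y[i]:
                continue
            misses = [j for j in range(n) if y[j] == cls]
            nearest_miss = min(misses, key=lambda j: (dist(X[i], X[j]), j))
            W += (priors[cls] / (1 - priors[y[i]])) * diff(X[i], X[nearest_miss]) / n
    return W


class TestReliefFWeights:
    def test_hand_computed_weight(self, toy_matrix):
        """Hit diffs all 0.1; miss diffs (0.9, 0.8, 0.9, 0.8): W = 0.75."""
        w = relieff_weights(toy_matrix, k=1)
        assert w.weights == pytest.approx([0.75])

    def test_constant_feature_weight_zero(self, toy_matrix):
        X = np.hstack([toy_matrix.X, np.full((4, 1), 3.7)])
        m = LabeledFeatureMatrix(X, toy_matrix.y)
        w = relieff_weights(m, k=1)
        assert w.weights[1] == 0.0
        # and its presence does not disturb the informative feature
        assert w.weights[0] == pytest.approx(0.75)

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        """Exact agreement with the enumeration oracle on tiny instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        p = int(rng.integers(1, 4))
        X = rng.random((n, p)).round(3)
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 0]
        y[2:4] = [1, 1]   # both classes have >= 2 members
        m = LabeledFeatureMatrix(X, y)
        got = relieff_weights(m, k=1).weights
        want = brute_force_relieff_k1(X, y)
        assert got == pytest.approx(want, abs=1e-12)

    def test_weights_bounded(self, rng):
        X = rng.random((30, 5)) * 100
        y = rng.integers(0, 3, size=30)
        y[:6] = [0, 0, 1, 1, 2, 2]
        w = relieff_weights(LabeledFeatureMatrix(X, y), k=2)
        assert np.all(w.weights >= -1) and np.all(w.weights <= 1)

    def test_label_feature_outranks_noise(self):
        """A feature equal to the class label beats seeded noise features."""
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            y = np.repeat([0, 1], 20)
            X = np.column_stack([y + 0.01 * rng.standard_normal(40),
                                 rng.standard_normal(40),
                                 rng.standard_normal(40)])
            order = rank_features(LabeledFeatureMatrix(X, y), k=3).order
            wins += order[0] == 0
        assert wins >= 15

    def test_small_class_error_names_class(self):
        m = LabeledFeatureMatrix(np.zeros((3, 1)),
                                 np.array(["solo", "pair", "pair"]))
        with pytest.raises(ValueError, match="solo"):
            relieff_weights(m, k=1)


class TestRanking:
    def make(self, weights):
        """Matrix engineered so ReliefF is irrelevant; we test sort rules
        by monkeypatching weights through a pre-sorted view."""
        from octfuse.relieff import RankedIndices, ReliefFWeights
        w = ReliefFWeights(weights=np.asarray(weights, float), k=1, m=0,
                           feature_range=np.ones(len(weights)))
        order = np.argsort(-w.weights, kind="stable")
        return RankedIndices(order=order, weights=w)

    def test_descending_with_tie_rule(self):
        r = self.make([0.2, 0.9, 0.9, -0.1])
        assert r.order.tolist() == [1, 2, 0, 3]

    def test_all_equal_identity(self):
        r = self.make([0.5, 0.5, 0.5])
        assert r.order.tolist() == [0, 1, 2]

    def test_column_reversal_equivariance(self, toy_matrix, rng):
        X = np.column_stack([toy_matrix.X[:, 0],
                             rng.random(4),
                             [0, 1, 0, 1]])
        m = LabeledFeatureMatrix(X, toy_matrix.y)
        mr = LabeledFeatureMatrix(X[:, ::-1], toy_matrix.y)
        w = relieff_weights(m, k=1).weights
        wr = relieff_weights(mr, k=1).weights
        assert w == pytest.approx(wr[::-1])


class TestSelectTop:
    def setup_method(self):
        rng = np.random.default_rng(7)
        X = rng.random((10, 6))
        y = np.repeat([0, 1], 5)
        self.m = LabeledFeatureMatrix(X, y,
                                      provenance=[("e", 0, j) for j in range(6)])
        self.r = rank_features(self.m, k=2)

    def test_keep_all_is_permutation(self):
        out = select_top(self.m, self.r, 6)
        assert np.array_equal(out.X, self.m.X[:, self.r.order])
        assert [pr[2] for pr in out.provenance] == self.r.order.tolist()

    def test_keep_one_is_top_column(self):
        out = select_top(self.m, self.r, 1)
        assert np.array_equal(out.X[:, 0], self.m.X[:, self.r.order[0]])

    def test_overflow_is_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            select_top(self.m, self.r, 7)


class TestIRF:
    @staticmethod
    def margin_loss(subset):
        """Deterministic toy loss: nearest-centroid error rate."""
        X, y = subset.X, subset.y
        errs = 0
        for cls in np.unique(y):
            mu_in = X[y == cls].mean(0)
            mu_out = X[y != cls].mean(0)
            d_in = np.abs(X[y == cls] - mu_in).sum(1)
            d_out = np.abs(X[y == cls] - mu_out).sum(1)
            errs += int((d_in > d_out).sum())
        return errs / len(y)

    def test_candidate_count(self, rng):
        X = rng.random((12, 30))
        y = np.repeat([0, 1], 6)
        res = irf_select(LabeledFeatureMatrix(X, y), self.margin_loss,
                         range_lo=5, range_hi=25, k=2)
        assert len(res.candidate_lengths) == 21
        assert res.candidate_lengths[0] == 5 and res.candidate_lengths[-1] == 25

    def test_argmin_contract(self, rng):
        X = rng.random((16, 20))
        y = np.repeat([0, 1], 8)
        res = irf_select(LabeledFeatureMatrix(X, y), self.margin_loss,
                         range_lo=1, range_hi=20, k=2)
        losses = dict(zip(res.candidate_lengths.tolist(), res.losses))
        assert losses[res.best_length] == res.losses.min()
        # ties break toward the smaller length
        best = min(l for l, v in losses.items() if v == res.losses.min())
        assert res.best_length == best
        assert len(res.selected) == res.best_length

    def test_signal_in_first_features(self):
        """When the planted signal occupies the top-ranked features the loss
        is already minimal at the low end of the range."""
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 15)
        signal = y[:, None] + 0.05 * rng.standard_normal((30, 3))
        noise = rng.standard_normal((30, 17))
        m = LabeledFeatureMatrix(np.hstack([signal, noise]), y)
        res = irf_select(m, self.margin_loss, range_lo=3, range_hi=20, k=3)
        assert res.losses[0] == res.losses.min()

    def test_single_candidate_full_width(self, rng):
        X = rng.random((10, 8))
        y = np.repeat([0, 1], 5)
        m = LabeledFeatureMatrix(X, y)
        res = irf_select(m, self.margin_loss, range_lo=8, range_hi=8, k=2)
        assert res.best_length == 8
        assert res.losses == pytest.approx([self.margin_loss(m)])

    def test_deterministic(self, rng):
        X = rng.random((12, 10))
        y = np.repeat([0, 1], 6)
        m = LabeledFeatureMatrix(X, y)
        a = irf_select(m, self.margin_loss, range_lo=2, range_hi=10, k=2)
        b = irf_select(m, self.margin_loss, range_lo=2, range_hi=10, k=2)
        assert np.array_equal(a.losses, b.losses)
        assert a.best_length == b.best_length

    def test_bad_range_rejected(self, rng):
        m = LabeledFeatureMatrix(rng.random((8, 5)), np.repeat([0, 1], 4))
        with pytest.raises(ValueError, match="range"):
            irf_select(m, self.margin_loss, range_lo=2, range_hi=9, k=1)

    def test_non_finite_loss_names_length(self, rng):
        m = LabeledFeatureMatrix(rng.random((8, 5)), np.repeat([0, 1], 4))
        with pytest.raises(ValueError, match="3"):
            irf_select(m, lambda s: np.nan if s.p == 3 else 0.0,
                       range_lo=2, range_hi=4, k=1)
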