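"""Population-coding metrics vs independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfcode.codingmetrics import (
    cmi_pairs,
    separability_index,
    snc,
    weight_sparseness,
)


def _si_bruteforce(X, labels):
    """Scatter matrices by explicit double loops (independent oracle)."""
    X = np.asarray(X, float)
    classes = sorted(set(labels))
    p = X.shape[1]
    m = X.mean(axis=0)
    s_w = np.zeros((p, p))
    s_b = np.zeros((p, p))
    for c in classes:
        rows = [X[i] for i in range(len(X)) if labels[i] == c]
        mu = np.mean(rows, axis=0)
        for r in rows:
            for j in range(p):
                for k in range(p):
                    s_w[j, k] += (r[j] - mu[j]) * (r[k] - mu[k])
        for j in range(p):
            for k in range(p):
                s_b[j, k] += len(rows) * (mu[j] - m[j]) * (mu[k] - m[k])
    return np.linalg.norm(s_b, "fro") / np.linalg.norm(s_w, "fro")


class TestSeparabilityIndex:
    def test_identical_centroids_give_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        X[20:] = X[:20]  # second class is an exact copy
        labels = np.array(["a"] * 20 + ["b"] * 20)
        assert separability_index(X, labels).si == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        labels = rng.choice(["a", "b", "c"], 30)
        while len(set(labels)) < 3 or min(np.bincount(
                np.searchsorted(np.unique(labels), labels))) < 2:
            labels = rng.choice(["a", "b", "c"], 30)
        si1 = separability_index(X, labels).si
        si2 = separability_index(X + 7.3, labels).si
        assert si1 == pytest.approx(si2, rel=1e-10)

    def test_matches_bruteforce_oracle_exhaustively(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n_feat = int(rng.integers(1, 7))
            n_per = int(rng.integers(2, 8))
            n_cls = int(rng.integers(2, 4))
            X = rng.normal(size=(n_per * n_cls, n_feat))
            labels = np.repeat([f"c{i}" for i in range(n_cls)], n_per)
            fast = separability_index(X, labels).si
            slow = _si_bruteforce(X, labels)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_fixed_2d_toy_set(self):
        # 4 points per class, hand-checkable 2-D configuration
        X = np.array(
            [[0, 0], [1, 0], [0, 1], [1, 1],
             [4, 4], [5, 4], [4, 5], [5, 5]], dtype=float
        )
        labels = np.array(["a"] * 4 + ["b"] * 4)
        res = separability_index(X, labels)
        assert res.si == pytest.approx(_si_bruteforce(X, labels), abs=1e-12)
        assert res.si > 1.0  # classes far apart relative to spread

    def test_zero_within_scatter_flagged(self):
        X = np.array([[0.0, 0], [0, 0], [1, 1], [1, 1]])
        labels = np.array(["a", "a", "b", "b"])
        res = separability_index(X, labels)
        assert res.infinite_separation
        assert np.isinf(res.si)


class TestSnc:
    def test_redundant_neuron_drop_near_zero(self):
        rng = np.random.default_rng(3)
        signal = rng.normal(size=200)
        y = (signal > 0).astype(str)
        X = np.column_stack(
            [signal + rng.normal(0, 0.3, 200),
             signal + rng.normal(0, 0.3, 200),  # redundant pair
             rng.normal(size=200)]
        )
        res = snc(X, y, runs=40, rng=rng)
        assert abs(res.drops_pp[0]) < 5.0  # partner carries the signal

    def test_sole_informative_neuron_large_drop(self):
        rng = np.random.default_rng(4)
        y = np.repeat(["a", "b"], 100)
        X = rng.normal(size=(200, 5))
        X[:, 2] += 3.0 * (y == "b")
        res = snc(X, y, runs=40, rng=rng)
        assert res.drops_pp[2] > 20.0
        assert res.drops_pp[2] == max(res.drops_pp)

    def test_deterministic_given_seed(self):
        rng_data = np.random.default_rng(5)
        X = rng_data.normal(size=(60, 4))
        y = np.repeat(["a", "b"], 30)
        a = snc(X, y, runs=10, rng=np.random.default_rng(6))
        b = snc(X, y, runs=10, rng=np.random.default_rng(6))
        assert np.array_equal(a.drops_pp, b.drops_pp)

    def test_single_neuron_rejected(self):
        with pytest.raises(ValueError):
            snc(np.ones((10, 1)), np.repeat(["a", "b"], 5))


def _cmi_entropy_oracle(codes, c, n_bins, n_c):
    """H(X|C) via the direct entropy formula on the same histogram."""
    h = 0.0
    n = len(codes)
    for cls in range(n_c):
        sel = codes[c == cls]
        p_c = len(sel) / n
        if len(sel) == 0:
            continue
        counts = np.bincount(sel, minlength=n_bins) / len(sel)
        nz = counts[counts > 0]
        h += p_c * float(-(nz * np.log2(nz)).sum())
    return h


class TestCmi:
    def test_copy_neuron_equals_conditional_entropy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=300)
        X = np.column_stack([x, x])  # exact copy
        labels = rng.choice(["a", "b"], 300)
        res = cmi_pairs(X, labels, n_shuffles=0, rng=rng)
        from sfcode.codingmetrics import _digitize_uniform

        codes = _digitize_uniform(X, 10)[:, 0]
        c = (labels == "b").astype(int)
        oracle = _cmi_entropy_oracle(codes, c, 10, 2)
        assert res.raw[0, 1] == pytest.approx(oracle, abs=1e-10)

    def test_conditionally_independent_pairs_near_zero(self):
        rng = np.random.default_rng(8)
        labels = np.repeat(["a", "b"], 250)
        X = rng.normal(size=(500, 3)) + 1.5 * (labels == "b")[:, None]
        res = cmi_pairs(X, labels, n_shuffles=20, rng=rng)
        iu = np.triu_indices(3, k=1)
        assert np.abs(res.corrected[iu]).max() < 0.05

    def test_raw_cmi_nonnegative_and_symmetric(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 4))
        labels = rng.choice(["a", "b"], 200)
        res = cmi_pairs(X, labels, n_shuffles=0, rng=rng)
        assert np.all(res.raw >= -1e-12)
        assert np.allclose(res.raw, res.raw.T)

    def test_constant_neuron_pairs_are_zero(self):
        rng = np.random.default_rng(10)
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        labels = np.repeat(["a", "b"], 50)
        res = cmi_pairs(X, labels, n_shuffles=0, rng=rng)
        assert res.raw[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_estimator_consistency_on_constructed_joint(self):
        """Plug-in CMI converges to the closed-form value of a known joint."""
        # X uniform over {0, 1}; Y = X with prob q, flipped otherwise; C coin
        q = 0.9
        h_q = -(q * np.log2(q) + (1 - q) * np.log2(1 - q))
        truth = 1.0 - h_q  # I(X;Y) in bits, independent of C
        mean_errs = []
        for n in (500, 8000):
            errs = []
            for rep in range(6):
                rng = np.random.default_rng(n + rep)
                x = rng.integers(0, 2, n)
                flip = rng.random(n) > q
                yv = np.where(flip, 1 - x, x)
                c = rng.integers(0, 2, n).astype(str)
                X = np.column_stack([x, yv]).astype(float)
                res = cmi_pairs(X, c, n_bins=2, n_shuffles=0, rng=rng)
                errs.append(abs(res.raw[0, 1] - truth))
            mean_errs.append(np.mean(errs))
        assert mean_errs[1] < mean_errs[0]
        assert mean_errs[1] < 0.02


class TestWeightSparseness:
    def test_equal_magnitudes_give_zero(self):
        assert weight_sparseness(np.array([1.0, -1.0, 1.0])).s == pytest.approx(
            0.0, abs=1e-12
        )

    def test_one_hot_gives_max(self):
        w = np.zeros(10)
        w[3] = 2.5
        assert weight_sparseness(w).s == pytest.approx(1 - 1 / 10, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            weight_sparseness(np.zeros(5))

    @given(
        st.lists(
            st.floats(min_value=-10, max_value=10), min_size=2, max_size=40
        ).filter(lambda w: any(abs(v) > 1e-6 for v in w)),
        st.floats(min_value=0.1, max_value=100),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_scale_invariance(self, w, k):
        w = np.asarray(w)
        s = weight_sparseness(w).s
        assert -1e-9 <= s <= 1 - 1 / len(w) + 1e-9
        assert weight_sparseness(k * w).s == pytest.approx(s, abs=1e-9)
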