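import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import eigh

import sleepstates as ss
from sleepstates.metrics import Hypnogram, switching_rate
from sleepstates.stats import (
    _runs,
    manova_permutation_test,
    paired_t_permutation,
    paired_t_stat,
    permute_hypnogram,
    stage_dendrogram,
    stage_pair_tests,
    wilks_lambda,
)


class TestPermuteHypnogram:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariants_every_draw(self, seed):
        rng = np.random.default_rng(seed)
        run_labels = rng.choice(["W", "N1", "N2", "N3"], size=rng.integers(2, 8))
        run_lengths = rng.integers(1, 9, size=len(run_labels))
        stages = np.concatenate([[l] * n for l, n in zip(run_labels, run_lengths)])
        hyp = Hypnogram(stages.astype(object))
        perm = permute_hypnogram(hyp, seed)
        orig_runs = _runs(hyp.stages)
        # boundaries and lengths: the permuted run structure refines the
        # original boundaries (identical adjacent labels are not re-merged)
        pos = 0
        for lab, length in orig_runs:
            block = perm.stages[pos:pos + length]
            assert len(set(block.tolist())) == 1  # each original period intact
            pos += length
        perm_labels_at_runs = [perm.stages[sum(l for _, l in orig_runs[:i])]
                               for i in range(len(orig_runs))]
        assert sorted(perm_labels_at_runs) == sorted(l for l, _ in orig_runs)

    def test_single_run_unchanged(self):
        hyp = Hypnogram(np.array(["N2"] * 10, dtype=object))
        out = permute_hypnogram(hyp, 0)
        assert out.stages.tolist() == hyp.stages.tolist()

    def test_orderings_uniform(self):
        """1000 permutations of three distinct unit runs hit each of the six
        orderings 1000/6 +- 4 SE times."""
        hyp = Hypnogram(np.array(["W", "N1", "N2"], dtype=object))
        counts = {}
        root = np.random.SeedSequence(99)
        for child in root.spawn(1000):
            key = "".join(permute_hypnogram(hyp, child).stages)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        expected = 1000 / 6
        se = np.sqrt(1000 * (1 / 6) * (5 / 6))
        for v in counts.values():
            assert abs(v - expected) <= 4 * se


class TestWilksLambda:
    def test_hand_anova_decomposition(self):
        lam, _, _, _ = wilks_lambda(np.array([[0.0], [1.0], [2.0], [3.0]]),
                                    np.array(["a", "a", "b", "b"]))
        assert lam == pytest.approx(0.2, abs=1e-12)

    def test_independent_labels_lambda_near_one(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4000, 3))
        g = rng.choice(["a", "b"], 4000)
        lam, _, _, _ = wilks_lambda(X, g)
        assert lam > 0.99

    def test_perfect_separation_lambda_near_zero(self):
        X = np.vstack([np.tile([0.0, 0.0], (30, 1)) + 1e-6 * np.random.default_rng(1).standard_normal((30, 2)),
                       np.tile([5.0, 5.0], (30, 1)) + 1e-6 * np.random.default_rng(2).standard_normal((30, 2))])
        g = np.array(["a"] * 30 + ["b"] * 30)
        lam, _, _, _ = wilks_lambda(X, g)
        assert lam < 1e-6

    def test_generalized_eigenvalue_oracle(self):
        """Lambda equals prod 1/(1+lambda_i) over eigenvalues of W^{-1}B."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n, d, G = 60, 3, 3
            X = rng.standard_normal((n, d)) + rng.integers(0, G, n)[:, None] * 0.5
            g = rng.integers(0, G, n)
            X += g[:, None] * rng.uniform(0, 1)
            lam, _, W, B = wilks_lambda(X, g)
            evals = eigh(B, W, eigvals_only=True)
            oracle = np.prod(1.0 / (1.0 + evals))
            assert lam == pytest.approx(oracle, abs=1e-10)

    def test_rank_deficient_features_handled(self):
        # probabilities summing to 1: one null direction
        rng = np.random.default_rng(3)
        P = rng.dirichlet(np.ones(4), size=100)
        g = rng.choice(["a", "b"], 100)
        lam, _, _, _ = wilks_lambda(P, g)
        assert 0 < lam <= 1


class TestManovaPermutation:
    def test_planted_effect_detected(self):
        rng = np.random.default_rng(7)
        runs = [("W", 10), ("N1", 10), ("N2", 10), ("N3", 10), ("W", 10), ("N2", 10)]
        stages = np.concatenate([[s] * d for s, d in runs]).astype(object)
        shift = {"W": 0.0, "N1": 1.0, "N2": 2.0, "N3": 3.0}
        feats, hyps = [], []
        for _ in range(4):
            X = rng.standard_normal((len(stages), 2))
            X[:, 0] += np.array([shift[s] for s in stages])  # stage-state coupling
            feats.append(X)
            hyps.append(Hypnogram(stages.copy()))
        res = manova_permutation_test(feats, hyps, n_permutations=200, seed=7)
        assert res.p_value <= 0.01

    def test_observed_larger_than_all_null_gives_p_one(self):
        rng = np.random.default_rng(8)
        # single W/N2 boundary: only two orderings, both with the same groups,
        # so every null lambda equals the observed and p = 1 under add-one
        stages = np.array(["W"] * 20 + ["N2"] * 20, dtype=object)
        feats = [rng.standard_normal((40, 2))]
        res = manova_permutation_test(feats, [Hypnogram(stages)],
                                      n_permutations=50, seed=8)
        assert res.p_value == pytest.approx(1.0)


class TestPairedT:
    def test_identical_conditions(self):
        x = np.array([0.3, 0.5, 0.7])
        res = paired_t_permutation(x, x.copy(), [(x, x)])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(9)
        x, y = rng.uniform(size=8), rng.uniform(size=8)
        assert paired_t_stat(x, y) == pytest.approx(-paired_t_stat(y, x))

    def test_nan_pairs_excluded_and_counted(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([0.5, 1.0, 1.5])
        nulls = [(x, y), (np.array([1.0, np.nan, 2.0]), y), (y, x)]
        res = paired_t_permutation(x, y, nulls)
        assert res.n_excluded == 1
        assert len(res.null) == 2

    def test_planted_difference_detected(self):
        """A 0.4 sensitivity gap across participants is significant against
        the period-preserving null."""
        rng = np.random.default_rng(10)
        stages = np.concatenate([["W"] * 10, ["N1"] * 10, ["N2"] * 10, ["N3"] * 10,
                                 ["W"] * 10]).astype(object)
        paths, hyps = [], []
        for _ in range(12):
            # state 0 strongly tied to W, diffuse elsewhere
            path = rng.integers(0, 3, 50)
            w_mask = stages == "W"
            path[w_mask] = np.where(rng.uniform(size=w_mask.sum()) < 0.6, 0,
                                    path[w_mask])
            paths.append(path)
            hyps.append(Hypnogram(stages.copy()))
        tests = stage_pair_tests(paths, hyps, metric="sensitivity", K=3,
                                 n_permutations=200, seed=10)
        row = tests[(tests.state == 0) & (tests.stage_a == "W")
                    & (tests.stage_b == "N2")].iloc[0]
        assert row.p <= 0.01


class TestDendrogram:
    def test_coincident_means_merge_first(self):
        means = np.array([[0.0], [0.0], [5.0]])
        Z, labels = stage_dendrogram(means, np.eye(1))
        assert Z[0, 2] == pytest.approx(0.0)  # first merge at distance 0
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_distance_ordering(self):
        means = np.array([[0.0], [1.0], [10.0]])
        Z, _ = stage_dendrogram(means, np.eye(1))
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_merge_count(self):
        rng = np.random.default_rng(11)
        means = rng.standard_normal((4, 3))
        Z, labels = stage_dendrogram(means, np.eye(3))
        assert Z.shape[0] == 3  # stages - 1 merges
        assert len(labels) == 4


def test_switching_metric_pipeline_under_permutation():
    """Permuting the hypnogram changes within-stage switching rates while the
    run structure stays intact (integration of metrics with the null)."""
    rng = np.random.default_rng(12)
    stages = np.concatenate([["W"] * 8, ["N2"] * 8, ["W"] * 8]).astype(object)
    hyp = Hypnogram(stages, tr_seconds=1.0)
    path = rng.integers(0, 3, 24)
    obs = switching_rate(path, hyp, "W")
    perm = permute_hypnogram(hyp, 5)
    alt = switching_rate(path, perm, "W")
    assert sorted(np.unique(perm.stages)) == sorted(np.unique(stages))
    assert isinstance(obs, float) and isinstance(alt, float)
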