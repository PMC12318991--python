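import numpy as np
import pytest

from fcselect.data import FeatureDataset, edge_index_for
from fcselect.weighting import (combine_weights, compute_weight_table,
                                detect_knees, fisher_scores, generate_tasks,
                                mutual_information_scores,
                                selection_probabilities, std_scores)


def _dataset(feats, labels):
    n = 3 if feats.shape[1] == 3 else None
    if n is None:
        # pad with dummy edge index by choosing smallest N with q >= cols
        q = feats.shape[1]
        n = 2
        while n * (n - 1) // 2 < q:
            n += 1
        assert n * (n - 1) // 2 == q, "choose q = N(N-1)/2 in tests"
    return FeatureDataset(feats, labels, edge_index_for(n), n)


class TestFisher:
    def test_direct_substitution(self):
        # mu0=0, mu1=2, population sds 1 -> |2|^2 / (1+1) = 2
        x0 = np.array([-1.0, 1.0, -1.0, 1.0])
        x1 = x0 + 2.0
        feats = np.zeros((8, 3))
        feats[:, 0] = np.concatenate([x0, x1])
        labels = np.array([0] * 4 + [1] * 4)
        h = fisher_scores(_dataset(feats, labels))
        assert h[0] == pytest.approx(2.0, abs=1e-9)
        assert h[1] == 0.0 and h[2] == 0.0  # class-identical features

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        feats = rng.normal(size=(30, 6))
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        ds = FeatureDataset(feats, labels, edge_index_for(4), 4)
        h = fisher_scores(ds)
        for j in range(6):
            a = feats[labels == 0, j]
            b = feats[labels == 1, j]
            expect = abs(a.mean() - b.mean()) ** 2 / (
                a.std() ** 2 + b.std() ** 2 + 1e-12)
            assert h[j] == pytest.approx(expect, abs=1e-10)

    def test_single_class_rejected(self):
        feats = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            fisher_scores(_dataset(feats, np.zeros(10, dtype=int)))


class TestMutualInformation:
    def test_label_copy_feature_gives_label_entropy(self):
        labels = np.array([0, 1] * 10)
        feats = np.column_stack([labels.astype(float), np.zeros(20), np.zeros(20)])
        m = mutual_information_scores(_dataset(feats, labels), n_bins=2)
        assert m[0] == pytest.approx(np.log(2), abs=1e-12)

    def test_hand_computed_double_sum(self):
        # 3 bins x 2 labels with counts [[4,0],[2,2],[0,4]] over 12 samples
        z = np.repeat([0, 1, 2], 4).astype(float)
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        joint = np.array([[4, 0], [2, 2], [0, 4]]) / 12
        expect = 0.0
        for zi in range(3):
            for yi in range(2):
                p = joint[zi, yi]
                if p > 0:
                    expect += p * np.log(p / (joint[zi].sum() * joint[:, yi].sum()))
        feats = np.column_stack([z, np.zeros(12), np.zeros(12)])
        m = mutual_information_scores(_dataset(feats, y), n_bins=3)
        assert m[0] == pytest.approx(expect, abs=1e-12)

    def test_matches_sklearn_on_binned_feature(self):
        from sklearn.metrics import mutual_info_score
        rng = np.random.default_rng(5)
        feats = rng.normal(size=(60, 3))
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        ds = _dataset(feats, labels)
        m = mutual_information_scores(ds, n_bins=4)
        for j in range(3):
            edges = np.quantile(feats[:, j], np.linspace(0, 1, 5)[1:-1])
            z = np.searchsorted(edges, feats[:, j], side="left")
            assert m[j] == pytest.approx(mutual_info_score(z, labels), abs=1e-10)

    def test_label_independent_feature_scores_low(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            feats = rng.normal(size=(100, 3))
            labels = rng.permutation([0, 1] * 50)
            means.append(mutual_information_scores(_dataset(feats, labels)).mean())
        assert np.mean(means) < 0.1

    def test_normalized_variant_bounded(self):
        labels = np.array([0, 1] * 10)
        feats = np.column_stack([labels.astype(float), np.zeros(20), np.zeros(20)])
        m = mutual_information_scores(_dataset(feats, labels), n_bins=2, normalize=True)
        assert m[0] == pytest.approx(1.0, abs=1e-12)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            mutual_information_scores(
                _dataset(np.zeros((10, 3)), np.array([0, 1] * 5)), n_bins=1)


class TestStd:
    def test_constant_and_two_point_features(self):
        feats = np.zeros((4, 3))
        feats[:, 1] = [0, 2, 0, 2]   # population sd 1
        s = std_scores(_dataset(feats, np.array([0, 0, 1, 1])))
        assert s[0] == 0.0 and s[1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_oracle(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(25, 3))
        s = std_scores(_dataset(feats, np.array([0, 1] * 12 + [0])))
        for j in range(3):
            x = feats[:, j]
            assert s[j] == pytest.approx(
                np.sqrt(np.mean((x - x.mean()) ** 2)), abs=1e-12)


class TestCombine:
    def test_normalized_component_arithmetic(self):
        # components already spanning [0,1]: (1, 0.5, 0) @ (0.4,0.4,0.2) = 0.6
        h = np.array([1.0, 0.0, 0.5])
        m = np.array([0.5, 1.0, 0.0])
        s = np.array([0.0, 1.0, 0.5])
        t = combine_weights(h, m, s, (0.4, 0.4, 0.2))
        assert t.combined[0] == pytest.approx(0.6, abs=1e-12)

    def test_identical_components_tie_break_by_index(self):
        t = combine_weights(np.ones(4), np.ones(4), np.ones(4))
        assert np.array_equal(t.rank_order, [0, 1, 2, 3])
        assert np.allclose(t.combined, t.combined[0])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        h, m, s = rng.uniform(size=(3, 7))
        perm = rng.permutation(7)
        t1 = combine_weights(h, m, s)
        t2 = combine_weights(h[perm], m[perm], s[perm])
        assert np.allclose(t1.combined[perm], t2.combined)

    def test_bad_alphas_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            combine_weights(np.ones(3), np.ones(3), np.ones(3), (0.5, 0.5, 0.5))

    def test_raw_components_reproduce_literal_combination(self):
        rng = np.random.default_rng(3)
        h, m, s = rng.uniform(size=(3, 5))
        t = combine_weights(h, m, s, (0.4, 0.4, 0.2), raw_components=True)
        assert np.allclose(t.combined, 0.4 * h + 0.4 * m + 0.2 * s, atol=1e-12)


def _knee_oracle(y):
    """Exhaustive evaluation of the chord-distance maximiser."""
    if y.size < 3:
        return None
    x = np.arange(1, y.size + 1, dtype=float)
    a = (y[-1] - y[0]) / (x[-1] - x[0])
    b = y[0] - a * x[0]
    d = np.abs(y - (a * x + b)) / np.sqrt(a * a + 1)
    interior = d[1:-1]
    if interior.size == 0 or interior.max() < 1e-12:
        return None
    return int(np.argmax(interior)) + 1


class TestKnees:
    def test_single_spike_curve(self):
        part = detect_knees(np.array([4.0, 0, 0, 0, 0]))
        assert part.knee1 == 1  # x = 2 in 1-based rank coordinates
        y = np.array([4.0, 0, 0, 0, 0])
        x = np.arange(1, 6.0)
        a = (y[-1] - y[0]) / 4
        b = y[0] - a
        assert abs(y[1] - (a * 2 + b)) / np.sqrt(a**2 + 1) == pytest.approx(3 / np.sqrt(2))

    def test_linear_curve_has_no_knee(self):
        part = detect_knees(np.linspace(10, 0, 20))
        assert part.knee1 is None and part.knee2 is None
        assert set(part.strata) == {"core"}

    def test_two_elbow_staircase_matches_brute_force(self):
        y = np.array([10, 9, 4, 3.5, 3, 0.5, 0.2])
        part = detect_knees(y)
        k1 = _knee_oracle(y)
        k2 = _knee_oracle(y[k1 + 1:]) + k1 + 1
        assert part.knee1 == k1 and part.knee2 == k2

    def test_random_monotone_curves_match_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            q = rng.integers(5, 40)
            y = np.sort(rng.exponential(size=q))[::-1]
            part = detect_knees(y)
            assert part.knee1 == _knee_oracle(y)
            if part.knee1 is not None:
                sub = _knee_oracle(y[part.knee1 + 1:])
                expect2 = None if sub is None else sub + part.knee1 + 1
                assert part.knee2 == expect2

    def test_strata_partition(self):
        y = np.array([10, 9, 4, 3.5, 3, 0.5, 0.2])
        part = detect_knees(y)
        assert part.strata.size == y.size
        assert set(part.strata) <= {"core", "important", "remaining"}
        core = np.sum(part.strata == "core")
        imp = np.sum(part.strata == "important")
        assert core == part.knee1 and core + imp == part.knee2

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            detect_knees(np.array([1.0, 0.0]))


class TestSelectionProbabilities:
    def test_direct_substitution(self, tiny_dataset):
        t = combine_weights(np.array([2.0, 1, 1]), np.zeros(3), np.zeros(3),
                            (1.0, 0.0, 0.0), raw_components=True)
        p, pp = selection_probabilities(t)
        assert np.allclose(p, [0.5, 0.25, 0.25])
        assert np.allclose(pp, [1.0, 0.5, 0.5])

    def test_uniform_weights_all_one(self):
        t = combine_weights(np.ones(5), np.ones(5), np.ones(5),
                            raw_components=True)
        _, pp = selection_probabilities(t)
        assert np.allclose(pp, 1.0)

    def test_normalisation_invariants(self):
        rng = np.random.default_rng(8)
        w = rng.uniform(0.1, 5, size=30)
        t = combine_weights(w, np.zeros(30), np.zeros(30), (1.0, 0.0, 0.0),
                            raw_components=True)
        p, pp = selection_probabilities(t)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(pp) == np.argmax(w) and pp.max() == 1.0

    def test_zero_weights_rejected(self):
        t = combine_weights(np.zeros(3), np.zeros(3), np.zeros(3),
                            raw_components=True)
        with pytest.raises(ValueError, match="zero"):
            selection_probabilities(t)


class TestGenerateTasks:
    def test_threshold_rule(self):
        pp = np.array([1.0, 0.5, 0.5])
        # find seeds whose first uniform lands above/below 0.5
        for seed in range(50):
            lam = np.random.default_rng(seed).uniform()
            coll = generate_tasks(pp, 1, seed)
            expect = (lam <= pp).astype(int)
            assert np.array_equal(coll.masks[0], expect)

    def test_probability_one_feature_in_every_task(self):
        pp = np.array([1.0, 0.2, 0.1])
        coll = generate_tasks(pp, 50, seed=3)
        assert np.all(coll.masks[:, 0] == 1)

    def test_deterministic_given_seed(self):
        pp = np.random.default_rng(1).uniform(size=20)
        pp[0] = 1.0
        a = generate_tasks(pp, 8, seed=42)
        b = generate_tasks(pp, 8, seed=42)
        assert np.array_equal(a.masks, b.masks)

    def test_inclusion_frequency_tracks_p_prime(self):
        pp = np.array([1.0, 0.75, 0.5, 0.25, 0.05])
        coll = generate_tasks(pp, 10_000, seed=0)
        freq = coll.masks.mean(axis=0)
        assert np.all(np.abs(freq - pp) <= 0.02)

    def test_per_feature_mode(self):
        pp = np.array([1.0, 0.5, 0.5])
        coll = generate_tasks(pp, 2000, seed=5, mode="per_feature_lambda")
        freq = coll.masks.mean(axis=0)
        assert np.all(np.abs(freq - pp) <= 0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_tasks(np.array([1.0]), 0, seed=0)
        with pytest.raises(RuntimeError, match="nonempty"):
            generate_tasks(np.zeros(3), 1, seed=0)


class TestWeightTablePipeline:
    def test_planted_edges_outweigh_noise(self):
        from fcselect.data import SyntheticSpec, synthesize_dataset
        wins = 0
        for seed in range(20):
            ds, planted = synthesize_dataset(SyntheticSpec(effect_size=1.0, seed=seed))
            t = compute_weight_table(ds)
            mask = np.zeros(ds.n_features, bool)
            mask[planted] = True
            wins += t.combined[mask].mean() > t.combined[~mask].mean()
        assert wins == 20
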