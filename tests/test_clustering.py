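import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from delaysum.clustering import (
    SIMILARITY_FEATURES,
    bic_score,
    correlation_linkage,
    fit_gmm_bic,
    hierarchical_similarity,
    hungarian_match,
    spca_features,
)


class TestSpcaFeatures:
    def test_rank_two_matrix_captured_by_two_components(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(200, 2))
        v = rng.normal(size=(2, 50))
        X = u @ v
        f = spca_features(X, n_components=4, sparsity=None, seed=1)
        assert f.explained_variance[:2].sum() > 0.99

    def test_unconstrained_spca_matches_pca_up_to_sign(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 30)) * np.linspace(3, 0.5, 30)
        f = spca_features(X, n_components=3, sparsity=None, seed=2)
        from sklearn.decomposition import PCA

        scores = PCA(n_components=3).fit_transform(X)
        for c in range(3):
            cc = abs(np.corrcoef(f.scores[:, c], scores[:, c])[0, 1])
            assert cc > 0.999

    def test_sparsity_constraint_respected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 40))
        f = spca_features(X, n_components=5, sparsity=7, seed=3)
        nz = (f.loading_matrix != 0).sum(axis=0)
        assert np.all(nz <= 7)

    def test_row_permutation_permutes_scores(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 25))
        perm = rng.permutation(60)
        a = spca_features(X, n_components=3, sparsity=10, seed=4).scores
        b = spca_features(X[perm], n_components=3, sparsity=10, seed=4).scores
        assert np.allclose(b, a[perm], atol=1e-8)

    def test_excessive_components_rejected(self):
        with pytest.raises(ValueError):
            spca_features(np.zeros((10, 5)), n_components=5)


class TestGmmBic:
    def test_bic_formula(self):
        # ln L = -100, k = 5, n = 1000 -> 200 + 5 ln(1000)
        assert bic_score(-100.0, 5, 1000) == pytest.approx(234.539, abs=0.01)

    def test_bic_matches_sklearn(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 4))
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(3, covariance_type="diag", random_state=0).fit(X)
        ours = bic_score(gm.score(X) * 300, gm._n_parameters(), 300)
        assert ours == pytest.approx(gm.bic(X), rel=1e-9)

    def test_three_separated_gaussians_select_k3(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            centers = np.array([[0, 0], [8, 0], [0, 8]])
            X = np.vstack([
                rng.normal(c, 1.0, size=(80, 2)) for c in centers
            ])
            cm = fit_gmm_bic(X, k_range=range(2, 7), n_restarts=5, seed=seed)
            hits += cm.K == 3
        assert hits >= 9

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3))
        a = fit_gmm_bic(X, k_range=range(2, 5), n_restarts=3, seed=7)
        b = fit_gmm_bic(X, k_range=range(2, 5), n_restarts=3, seed=7)
        assert a.K == b.K
        assert np.array_equal(a.labels, b.labels)
        assert a.bic_by_k == b.bic_by_k

    def test_scale_covariance_of_labels(self):
        """Scaling every response by a positive constant leaves sPCA+GMM
        labels unchanged."""
        from delaysum.pipeline import _flash_responses

        X, _, _ = _flash_responses(150, seed=8)
        f1 = spca_features(X, n_components=10, sparsity=10, seed=1)
        f2 = spca_features(3.0 * X, n_components=10, sparsity=10, seed=1)
        a = fit_gmm_bic(f1, k_range=range(4, 8), n_restarts=3, seed=2)
        b = fit_gmm_bic(f2, k_range=range(4, 8), n_restarts=3, seed=2)
        m = hungarian_match(b.labels, a.labels)
        assert adjusted_rand_score(a.labels, m) > 0.99


class TestArchetypeRecovery:
    def test_six_archetypes_recovered(self):
        from delaysum.pipeline import _flash_responses

        X, truth, _ = _flash_responses(600, seed=17)
        feats = spca_features(X, n_components=20, sparsity=10, seed=17)
        cm = fit_gmm_bic(feats, k_range=range(2, 10), n_restarts=5, seed=17)
        assert cm.K == 6
        ti = {g: i for i, g in enumerate(sorted(set(truth)))}
        assert adjusted_rand_score([ti[g] for g in truth], cm.labels) >= 0.9


class TestHierarchicalSimilarity:
    def _table(self, rows, labels=None):
        labels = labels or [f"C{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=labels, columns=SIMILARITY_FEATURES)

    def test_identical_rows_merge_at_zero(self):
        rows = [[1, 2, 3, 4, 5], [1, 2, 3, 4, 5], [9, 9, 9, 9, 9]]
        d = hierarchical_similarity(self._table(rows))
        assert d.merge_heights()[0] == pytest.approx(0.0, abs=1e-12)

    def test_kinetic_pairs_merge_before_cross_pairs(self):
        # fast pair, slow pair, one outlier
        rows = [
            [0.1, 0.1, 4.0, 0.5, 0.9],
            [0.12, 0.12, 4.1, 0.5, 0.88],
            [1.0, 1.2, 1.0, 0.3, 0.6],
            [1.05, 1.1, 1.1, 0.3, 0.62],
            [3.0, 5.0, 0.2, 0.9, 0.1],
        ]
        labels = ["fast1", "fast2", "slow1", "slow2", "out"]
        d = hierarchical_similarity(self._table(rows, labels))
        assert d.cophenetic_distance("fast1", "fast2") < d.cophenetic_distance(
            "fast1", "slow1"
        )
        assert d.cophenetic_distance("slow1", "slow2") < d.cophenetic_distance(
            "slow1", "out"
        )

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(9)
        rows = rng.normal(size=(6, 5)).tolist()
        labels = [f"C{i}" for i in range(6)]
        d1 = hierarchical_similarity(self._table(rows, labels))
        perm = [3, 1, 5, 0, 2, 4]
        d2 = hierarchical_similarity(
            self._table([rows[i] for i in perm], [labels[i] for i in perm])
        )
        for a in labels:
            for b in labels:
                if a != b:
                    assert d1.cophenetic_distance(a, b) == pytest.approx(
                        d2.cophenetic_distance(a, b), rel=1e-9
                    )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_similarity(self._table([[1, 2, 3, 4, 5]]))


class TestCorrelationLinkage:
    def test_identical_traces_distance_zero(self):
        t = np.sin(np.linspace(0, 10, 200))
        d = correlation_linkage({"a": t, "b": t.copy(), "c": -t})
        assert d.cophenetic_distance("a", "b") == pytest.approx(0.0, abs=1e-9)

    def test_sign_inverted_pair_maximally_distant(self):
        t = np.sin(np.linspace(0, 10, 200))
        d = correlation_linkage({"a": t, "b": -t})
        assert d.merge_heights()[-1] == pytest.approx(2.0, rel=1e-6)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            correlation_linkage({"a": np.ones(50), "b": np.arange(50.0)})

    def test_blocker_condition_homogenises_fast_and_slow_pairs(self):
        """With GABA/glycine/Nav transmission blocked, G1 joins G2 and G4
        joins G5 before any cross-subgroup merge."""
        from delaysum.circuit import (
            GROUPS,
            GlutUnit,
            CircuitModel,
            apply_condition,
            group_kinetics_at,
        )
        from delaysum.stimuli import make_modulating_flash
        from delaysum.synth import unit_response

        # groups compared at a common dendritic position so only their
        # kinetics differ
        units = [
            GlutUnit(group=g, pos_um=(0.0, 0.0), kinetics=group_kinetics_at(g, 0.0))
            for g in GROUPS
        ]
        circ = CircuitModel(units=units, dendritic_diameter_um=100.0)
        blocked = apply_condition(circ, ["gaba_block", "glycine_block", "nav_block"])
        flash = make_modulating_flash(px_size_um=25.0, refresh_hz=30.0)
        traces = {}
        n_min = None
        for u in blocked.units:
            tr = unit_response(u, flash)
            traces[u.group] = tr.values
            n_min = tr.values.size if n_min is None else min(n_min, tr.values.size)
        traces = {g: v[:n_min] for g, v in traces.items()}
        d = correlation_linkage(traces)
        assert d.cophenetic_distance("G1", "G2") < d.cophenetic_distance("G1", "G5")
        assert d.cophenetic_distance("G4", "G5") < d.cophenetic_distance("G4", "G2")


class TestHungarianMatch:
    def test_permuted_labels_recovered(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        labels = np.array([2, 2, 0, 0, 1, 1])
        assert np.array_equal(hungarian_match(labels, truth), truth)
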