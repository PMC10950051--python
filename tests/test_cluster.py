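"""Similarity matrix, WPGMA linkage, elbow selection, cuts and edge lists."""

import numpy as np
import pytest

from adpanel.cluster import (Dendrogram, SimilarityMatrix, build_similarity,
                             cut_clusters, edge_list, elbow_index,
                             select_k_elbow, wpgma_linkage)
from adpanel.panel import AnalysisConfig, BiomarkerPanel
from adpanel.stats import spearman_abs


def _panel(values, names=None):
    values = np.asarray(values, float)
    names = names or [f"m{j}" for j in range(values.shape[1])]
    return BiomarkerPanel([f"s{i}" for i in range(len(values))], values,
                          np.isnan(values), names)


def _hand_wpgma(d):
    """Tiny independent WPGMA: merge closest pair, average distances."""
    d = d.copy().astype(float)
    np.fill_diagonal(d, np.inf)
    active = list(range(len(d)))
    merges = []
    while len(active) > 1:
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1:]:
                if best is None or d[a, b] < best[0]:
                    best = (d[a, b], a, b)
        h, a, b = best
        merges.append(h)
        for c in active:
            if c not in (a, b):
                d[a, c] = d[c, a] = 0.5 * (d[a, c] + d[b, c])
        active.remove(b)
    return merges


class TestSimilarity:
    def test_self_similarity_and_pair_counts(self, rng):
        values = rng.standard_normal((40, 3))
        values[:5, 0] = np.nan
        sim = build_similarity(_panel(values))
        assert np.allclose(np.diag(sim.sim), 1.0)
        assert sim.n_pairs[0, 0] == 35
        assert sim.n_pairs[0, 1] == 35

    def test_overlapping_missingness_counts(self, rng):
        values = rng.standard_normal((30, 2))
        values[:10, 0] = np.nan
        values[20:, 1] = np.nan  # both observed only on rows 10..19
        sim = build_similarity(_panel(values))
        assert sim.n_pairs[0, 1] == 10

    def test_complete_fixture_equals_bruteforce_loop(self, rng):
        values = rng.standard_normal((30, 5))
        sim = build_similarity(_panel(values))
        for i in range(5):
            for j in range(5):
                expect = 1.0 if i == j else abs(
                    np.corrcoef(np.argsort(np.argsort(values[:, i])),
                                np.argsort(np.argsort(values[:, j])))[0, 1])
                assert sim.sim[i, j] == pytest.approx(expect, abs=1e-12)

    def test_sparse_pairs_flagged_undefined(self):
        values = np.full((5, 2), np.nan)
        values[:, 0] = [1, 2, 3, 4, 5]
        values[:2, 1] = [1, 2]
        sim = build_similarity(_panel(values), min_pairs=3)
        assert np.isnan(sim.sim[0, 1])
        with pytest.raises(ValueError, match="undefined"):
            wpgma_linkage(sim)


class TestWpgma:
    def test_two_leaves(self):
        sim = SimilarityMatrix(np.array([[1.0, 0.7], [0.7, 1.0]]),
                               np.full((2, 2), 10), ["a", "b"])
        dendro = wpgma_linkage(sim)
        assert dendro.heights[0] == pytest.approx(0.3)

    def test_three_leaf_hand_linkage(self):
        # d(AB)=0.1, d(AC)=0.4, d(BC)=0.6 -> AB at 0.1, then C at 0.5
        d = np.array([[0, 0.1, 0.4], [0.1, 0, 0.6], [0.4, 0.6, 0]])
        sim = SimilarityMatrix(1 - d, np.full((3, 3), 10), list("ABC"))
        dendro = wpgma_linkage(sim)
        np.testing.assert_allclose(dendro.heights, [0.1, 0.5])
        labels = cut_clusters(dendro, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_four_leaf_ultrametric_reproduced_exactly(self):
        # ultrametric: (A,B) at 0.2, (C,D) at 0.3, root at 0.8
        d = np.array([
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.3],
            [0.8, 0.8, 0.3, 0.0],
        ])
        dendro = wpgma_linkage(SimilarityMatrix(1 - d, np.full((4, 4), 9),
                                                list("ABCD")))
        np.testing.assert_allclose(np.sort(dendro.heights), [0.2, 0.3, 0.8])

    def test_matches_hand_wpgma_on_random_matrices(self, rng):
        for _ in range(5):
            p = 6
            r = rng.random((p, p))
            d = (r + r.T) / 2
            np.fill_diagonal(d, 0)
            dendro = wpgma_linkage(SimilarityMatrix(1 - d, np.full((p, p), 9),
                                                    [f"m{i}" for i in range(p)]))
            np.testing.assert_allclose(np.sort(dendro.heights),
                                       np.sort(_hand_wpgma(d)), atol=1e-12)

    def test_heights_nondecreasing_on_metric_input(self, rng):
        pts = rng.standard_normal((8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d /= d.max()
        dendro = wpgma_linkage(SimilarityMatrix(1 - d, np.full((8, 8), 9),
                                                [f"m{i}" for i in range(8)]))
        assert np.all(np.diff(dendro.heights) >= -1e-12)

    def test_newick_export_round_trips_leaves(self, prepared):
        panel, _ = prepared
        dendro = wpgma_linkage(build_similarity(panel))
        import dendropy

        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        taxa = {leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()}
        assert taxa == set(panel.marker_names)


@pytest.fixture(scope="module")
def dendro():
    rng = np.random.default_rng(7)
    r = rng.random((9, 9))
    d = (r + r.T) / 2
    np.fill_diagonal(d, 0)
    return wpgma_linkage(SimilarityMatrix(1 - d, np.full((9, 9), 5),
                                          [f"m{i}" for i in range(9)]))


class TestCuts:

    def test_extremes(self, dendro):
        assert len(set(cut_clusters(dendro, 9))) == 9
        assert len(set(cut_clusters(dendro, 1))) == 1
        with pytest.raises(ValueError):
            cut_clusters(dendro, 0)
        with pytest.raises(ValueError):
            cut_clusters(dendro, 10)

    def test_cuts_nest(self, dendro):
        """Every k-cluster partition refines the (k-1)-cluster partition."""
        for k in range(2, 9):
            fine = cut_clusters(dendro, k)
            coarse = cut_clusters(dendro, k - 1)
            mapping = {}
            for f, c in zip(fine, coarse):
                assert mapping.setdefault(f, c) == c


class TestElbow:
    def test_rank_one_scree_selects_one(self):
        assert elbow_index(np.array([26.0, 0.5, 0.45, 0.4, 0.35])) == 1

    def test_cliff_after_fourth_eigenvalue_selects_four(self):
        scree = np.array([4.3, 3.6, 2.9, 2.4, 1.1, 1.05, 1.0, 0.95])
        assert elbow_index(scree) == 4

    def test_null_panel_selects_few(self):
        rng = np.random.default_rng(0)
        panel = _panel(rng.standard_normal((4000, 10)))
        k, scree = select_k_elbow(panel, AnalysisConfig(seed=0, n_permutations=20))
        assert k <= 2
        assert scree[0] < 1.3

    def test_rank_one_panel_selects_one(self):
        rng = np.random.default_rng(1)
        latent = rng.standard_normal(300)
        values = latent[:, None] + 0.05 * rng.standard_normal((300, 6))
        k, _ = select_k_elbow(_panel(values), AnalysisConfig(seed=1, n_permutations=20))
        assert k == 1

    def test_planted_four_blocks_recovered(self, prepared):
        panel, _ = prepared
        k, _ = select_k_elbow(panel, AnalysisConfig(seed=0, n_permutations=100))
        assert k == 4

    def test_tiny_holdout_rejected(self):
        panel = _panel(np.random.default_rng(0).standard_normal((3, 4)))
        with pytest.raises(ValueError, match="holdout"):
            select_k_elbow(panel, AnalysisConfig(seed=0, n_permutations=2))


class TestPlantedRecovery:
    def test_four_block_cut_matches_planted_labels(self):
        """Cutting the WPGMA tree at k=4 recovers the planted blocks
        (adjusted Rand >= 0.9) in at least 90% of 50 regenerated cohorts."""
        from sklearn.metrics import adjusted_rand_score

        from adpanel.markers import MARKERS
        from adpanel.panel import exclude_sparse_subjects, preprocess
        from adpanel.synth import generate_cohort, preset

        aris = []
        for seed in range(50):
            cohort = generate_cohort(preset("entire_cohort", seed=seed))
            panel, _ = exclude_sparse_subjects(cohort.panel, 0.5, cohort.labels)
            panel = preprocess(panel)
            cut = cut_clusters(wpgma_linkage(build_similarity(panel)), 4)
            blocks = cohort.truth["blocks"]
            idx = [i for i, m in enumerate(MARKERS) if blocks[m] is not None]
            truth = [blocks[MARKERS[i]] for i in idx]
            aris.append(adjusted_rand_score(truth, cut[idx]))
        aris = np.asarray(aris)
        assert np.median(aris) >= 0.9
        assert (aris >= 0.9).mean() >= 0.9


class TestEdges:
    def test_strict_threshold_semantics(self, rng):
        values = rng.standard_normal((60, 4))
        sim = build_similarity(_panel(values))
        assert edge_list(sim, 1.0) == []
        assert len(edge_list(sim, 0.0)) == 6  # p(p-1)/2 on complete data

    def test_planted_pair_only_edge(self, rng):
        x = rng.standard_normal(200)
        values = np.c_[x, x + 0.2 * rng.standard_normal(200),
                       rng.standard_normal((200, 2))]
        edges = edge_list(build_similarity(_panel(values)), 0.5)
        assert [(e[0], e[1]) for e in edges] == [("m0", "m1")]
        assert edges[0][2] > 0.9

    def test_sorted_descending(self, prepared):
        panel, _ = prepared
        edges = edge_list(build_similarity(panel), 0.3)
        sims = [e[2] for e in edges]
        assert sims == sorted(sims, reverse=True)
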