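"""PCA, supervised admixture EM, representative selection, IBS and NJ."""

import numpy as np
import pandas as pd
import pytest

from popaf import ancestry, simulate
from popaf.ancestry import (
    Tree,
    fit_pca,
    ibs_distance,
    neighbor_joining,
    panel_F,
    project,
    select_representatives,
    supervised_admixture,
    supervised_admixture_batch,
)
from popaf.cohort_af import MISSING, GenotypeMatrix, InputError
from popaf.simulate import ParameterError


def _two_pop_matrix(n_per=40, m=800, c=0.3, seed=5):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=m)
    shape = (1 - c) / c
    f = rng.beta(p * shape, (1 - p) * shape, size=(2, m))
    g = np.vstack([rng.binomial(2, f[0], size=(n_per, m)),
                   rng.binomial(2, f[1], size=(n_per, m))]).astype(np.int8)
    loci = pd.DataFrame({"chrom": ["1"] * m, "pos": np.arange(1, m + 1),
                         "ref": ["A"] * m, "alt": ["G"] * m})
    labels = ["P1"] * n_per + ["P2"] * n_per
    return GenotypeMatrix([f"S{i}" for i in range(2 * n_per)], loci, g), labels, f


class TestPCA:
    def test_pc1_separates_divergent_populations(self):
        gm, labels, _ = _two_pop_matrix()
        model = fit_pca(gm, d=2)
        pc1 = model.reference_coords[:, 0]
        a, b = pc1[:40], pc1[40:]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            max(b.min(), a.min()) > min(b.max(), a.max())
        # no overlap between the two label groups on PC1
        lo, hi = (a, b) if a.mean() < b.mean() else (b, a)
        assert lo.max() < hi.min()

    def test_projection_self_consistency(self):
        gm, _, _ = _two_pop_matrix()
        model = fit_pca(gm, d=3)
        proj = project(model, gm.genotypes)
        np.testing.assert_allclose(proj, model.reference_coords, atol=1e-8)

    def test_duplicate_sample_same_coords(self):
        gm, _, _ = _two_pop_matrix()
        model = fit_pca(gm, d=2)
        assert np.allclose(project(model, gm.genotypes[0]),
                           model.reference_coords[0], atol=1e-8)

    def test_all_missing_projects_to_origin(self):
        gm, _, _ = _two_pop_matrix()
        model = fit_pca(gm, d=2)
        g = np.full(gm.n_loci, MISSING, dtype=np.int8)
        np.testing.assert_allclose(project(model, g), 0.0)

    def test_excessive_rank_rejected(self):
        gm, _, _ = _two_pop_matrix(n_per=5, m=50)
        with pytest.raises(ParameterError):
            fit_pca(gm, d=40)

    def test_total_coord_variance_equals_eigenvalues(self):
        gm, _, _ = _two_pop_matrix()
        model = fit_pca(gm, d=4)
        total_var = model.reference_coords.var(axis=0, ddof=1).sum()
        assert total_var == pytest.approx(model.eigenvalues.sum(), rel=1e-6)

    def test_loadings_orthonormal(self):
        gm, _, _ = _two_pop_matrix()
        model = fit_pca(gm, d=3)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-6)


class TestSupervisedAdmixture:
    def test_single_population_is_unit(self):
        f = np.random.default_rng(0).uniform(0.2, 0.8, size=(1, 100))
        g = np.random.default_rng(1).binomial(2, f[0]).astype(np.int8)
        model = supervised_admixture(g, f)
        np.testing.assert_allclose(model.Q, [1.0])

    def test_separated_populations_force_vertex(self):
        m = 300
        f = np.vstack([np.full(m, 0.999), np.full(m, 0.001)])
        g = np.full(m, 2, dtype=np.int8)
        model = supervised_admixture(g, f)
        assert model.Q[0] > 0.99
        assert model.Q[1] < 0.01

    def test_loglik_nondecreasing(self, small_cohort):
        _gm, truth = small_cohort
        model = supervised_admixture(truth.true_genotypes[0], truth.pop_af)
        diffs = np.diff(model.loglik_path)
        assert (diffs >= -1e-8).all()

    def test_parameter_recovery_moderate_scale(self):
        rng = np.random.default_rng(31)
        k, m, c = 3, 8000, 0.15
        p = rng.uniform(0.05, 0.95, size=m)
        shape = (1 - c) / c
        f = np.clip(rng.beta(p * shape, (1 - p) * shape, size=(k, m)), 1e-6, 1 - 1e-6)
        q_true = np.array([0.5, 0.3, 0.2])
        g = rng.binomial(2, q_true @ f).astype(np.int8)
        model = supervised_admixture(g, f)
        assert np.abs(model.Q - q_true).mean() < 0.03

    def test_batch_agrees_with_single(self):
        rng = np.random.default_rng(8)
        f = np.clip(rng.beta(2, 2, size=(2, 2000)), 1e-6, 1 - 1e-6)
        q_true = np.array([[0.7, 0.3], [0.2, 0.8]])
        g = rng.binomial(2, q_true @ f).astype(np.int8)
        q_batch = supervised_admixture_batch(g, f, tol=1e-9, max_iter=3000)
        for i in range(2):
            single = supervised_admixture(g[i], f, tol=1e-9, max_iter=3000)
            np.testing.assert_allclose(q_batch[i], single.Q, atol=5e-3)

    def test_all_missing_rejected(self):
        with pytest.raises(InputError):
            supervised_admixture(np.full(10, MISSING, dtype=np.int8),
                                 np.full((2, 10), 0.5))

    def test_panel_F_is_clipped(self, small_cohort):
        _gm, truth = small_cohort
        panels = simulate.emit_reference_panels(truth, n_ref=10)
        f = panel_F(list(panels.values()))
        assert f.min() > 0 and f.max() < 1


class TestSelectRepresentatives:
    def test_centroid_sample_wins_with_zero_score(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0], [-2.0, 0.0], [0.0, 3.0]])
        q = np.tile([0.5, 0.5], (4, 1))
        reps = select_representatives(coords, q, ["g"] * 4, ["a", "b", "c", "d"])
        # centroid is (0, 0.75); sample a is nearest
        assert reps["g"].sample_id == "a"

    def test_symmetric_tie_broken_by_dominant_q(self):
        coords = np.array([[1.0], [-1.0]])
        q = np.array([[0.6, 0.4], [0.9, 0.1]])
        reps = select_representatives(coords, q, ["g", "g"], ["a", "b"])
        assert reps["g"].sample_id == "b"  # same distance, higher dominant Q
        assert reps["g"].score == pytest.approx(1.0)

    def test_matches_exhaustive_search(self, rng):
        n, d = 90, 2
        coords = rng.normal(size=(n, d)) + np.repeat([[0, 0], [5, 0], [0, 5]],
                                                     30, axis=0)
        q = rng.dirichlet([1, 1, 1], size=n)
        groups = np.repeat(["a", "b", "c"], 30)
        ids = [f"S{i:03d}" for i in range(n)]
        reps = select_representatives(coords, q, groups, ids)
        for grp in "abc":
            idx = [i for i in range(n) if groups[i] == grp]
            centroid = coords[idx].mean(axis=0)
            best = min(idx, key=lambda i: float(np.linalg.norm(coords[i] - centroid)))
            assert reps[grp].sample_id == ids[best]


class TestIBS:
    def test_identical_rows_distance_zero(self):
        g = np.array([[0, 1, 2], [0, 1, 2]], dtype=np.int8)
        d = ibs_distance(g)
        assert d[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        g = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
        assert ibs_distance(g)[0, 1] == 1.0

    def test_matches_per_locus_hand_tally(self, rng):
        g = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = MISSING
        d = ibs_distance(g)
        for i in range(6):
            for j in range(6):
                both = (g[i] != MISSING) & (g[j] != MISSING)
                if both.sum() == 0:
                    continue
                shared = (2 - np.abs(g[i][both].astype(int) - g[j][both])).sum()
                want = 1 - shared / (2 * both.sum())
                assert d[i, j] == pytest.approx(want)

    def test_premetric_properties(self, small_cohort):
        gm, _ = small_cohort
        d = ibs_distance(gm.genotypes[:10])
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1)).all()


def random_binary_tree(n_leaves, rng):
    """Random unrooted binary tree with uniform(0.1, 1) branch lengths,
    built by splitting random edges — independent of the NJ code under test."""
    labels = [f"T{i}" for i in range(n_leaves)]
    adj = {}

    def connect(u, v, ln):
        adj.setdefault(u, {})[v] = ln
        adj.setdefault(v, {})[u] = ln

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    center = "I0"
    for lab in labels[:3]:
        connect(lab, center, float(rng.uniform(0.1, 1)))
    n_internal = 1
    for lab in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        ln = adj[u][v]
        mid = f"I{n_internal}"
        n_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        disconnect(u, v)
        connect(u, mid, ln * split)
        connect(mid, v, ln * (1 - split))
        connect(lab, mid, float(rng.uniform(0.1, 1)))
    return Tree(adjacency=adj, leaves=labels)


class TestNeighborJoining:
    def test_additive_four_taxon_exact_recovery(self):
        # hand-built additive matrix from tree ((A:2,B:3):1,(C:4,D:5))
        labels = list("ABCD")
        d = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
                     dtype=float)
        tree = neighbor_joining(d, labels)
        dm = tree.leaf_distance_matrix().loc[labels, labels].to_numpy()
        np.testing.assert_allclose(dm, d, atol=1e-9)
        assert tree.splits() == {frozenset({"A", "B"})}

    def test_three_taxa_star_with_equal_limbs(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        tree = neighbor_joining(d, ["a", "b", "c"])
        for leaf in "abc":
            (ln,) = tree.adjacency[leaf].values()
            assert ln == pytest.approx(1.0)

    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(np.array([[0.0, 3.0], [3.0, 0.0]]), ["a", "b"])
        assert tree.adjacency["a"]["b"] == 3.0

    def test_leaf_permutation_gives_same_splits(self, rng):
        tree0 = random_binary_tree(7, rng)
        d = tree0.leaf_distance_matrix()
        perm = list(rng.permutation(tree0.leaves))
        t1 = neighbor_joining(d.loc[tree0.leaves, tree0.leaves].to_numpy(), tree0.leaves)
        t2 = neighbor_joining(d.loc[perm, perm].to_numpy(), perm)
        assert t1.splits() == t2.splits()

    def test_random_additive_matrices_round_trip(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            tree0 = random_binary_tree(n, rng)
            d = tree0.leaf_distance_matrix()
            rec = neighbor_joining(d.to_numpy(), tree0.leaves)
            dm = rec.leaf_distance_matrix().loc[tree0.leaves, tree0.leaves]
            np.testing.assert_allclose(dm.to_numpy(), d.to_numpy(), atol=1e-9)
            assert rec.splits() == tree0.splits()

    def test_agrees_with_skbio_on_noisy_matrix(self, rng):
        """Independent oracle: scikit-bio's NJ yields the same topology on a
        perturbed (non-additive) distance matrix."""
        skbio = pytest.importorskip("skbio")
        tree0 = random_binary_tree(6, rng)
        d = tree0.leaf_distance_matrix().to_numpy()
        noise = rng.uniform(0, 0.01, size=d.shape)
        d = d + (noise + noise.T) * (1 - np.eye(len(d)))
        d = (d + d.T) / 2  # exact symmetry for skbio's strict validation
        labels = tree0.leaves
        ours = neighbor_joining(d, labels)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        sk_splits = set()
        for node in sk_tree.non_tips():
            tips = frozenset(t.name for t in node.tips())
            other = frozenset(labels) - tips
            if len(tips) >= 2 and len(other) >= 2:
                sk_splits.add(min(tips, other, key=lambda s: (len(s), sorted(s))))
        assert ours.splits() == sk_splits

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InputError):
            neighbor_joining(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])
        with pytest.raises(InputError):
            neighbor_joining(np.array([[0.0, -1.0], [-1.0, 0.0]]), ["a", "b"])

    def test_newick_parseable_by_dendropy(self, rng):
        dendropy = pytest.importorskip("dendropy")
        tree0 = random_binary_tree(6, rng)
        d = tree0.leaf_distance_matrix()
        rec = neighbor_joining(d.to_numpy(), tree0.leaves)
        parsed = dendropy.Tree.get(data=rec.newick(), schema="newick")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == set(tree0.leaves)
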