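"""Nei's D_A distance, UPGMA dendrograms, and classical MDS."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from xstrkit.popcompare import (
    PopulationFrequencySet,
    classical_mds,
    da_distance,
    da_matrix,
    upgma,
)


def pop(name, **loci):
    return PopulationFrequencySet(name, {l: dict(v) for l, v in loci.items()})


def procrustes_rmsd(x, y):
    """RMSD after optimal translation + rotation/reflection (no scaling)."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    u, _, vt = np.linalg.svd(y.T @ x)
    r = u @ vt
    return float(np.sqrt(np.mean(np.sum((y @ r - x) ** 2, axis=1))))


class TestDaDistance:
    def test_identical_populations_are_at_distance_zero(self):
        a = pop("a", L1={"10": 0.4, "11": 0.6}, L2={"8": 1.0})
        b = pop("b", L1={"10": 0.4, "11": 0.6}, L2={"8": 1.0})
        assert da_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_maximal(self):
        a = pop("a", L1={"10": 1.0})
        b = pop("b", L1={"12": 1.0})
        assert da_distance(a, b) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        a = pop("a", L1={"x": 0.5, "y": 0.5})
        b = pop("b", L1={"x": 1.0})
        assert da_distance(a, b) == pytest.approx(1 - np.sqrt(0.5), abs=1e-12)

    def test_no_shared_loci_raises(self):
        with pytest.raises(ValueError, match="shared"):
            da_distance(pop("a", L1={"1": 1.0}), pop("b", L2={"1": 1.0}))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_symmetry_and_label_invariance(self, seed):
        rng = np.random.default_rng(seed)
        va = rng.dirichlet(np.ones(5))
        vb = rng.dirichlet(np.ones(5))
        labels = ["10", "11", "12", "13", "14"]
        a = pop("a", L1=dict(zip(labels, va)))
        b = pop("b", L1=dict(zip(labels, vb)))
        assert da_distance(a, b) == pytest.approx(da_distance(b, a), abs=1e-15)
        shuffled = rng.permutation(5)
        a2 = pop("a", L1={labels[i]: va[i] for i in shuffled})
        b2 = pop("b", L1={labels[i]: vb[i] for i in shuffled})
        assert da_distance(a, b) == pytest.approx(da_distance(a2, b2), abs=1e-12)

    def test_matrix_is_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(5)
        pops = [
            pop(f"p{i}", L1=dict(zip("abcd", rng.dirichlet(np.ones(4)))))
            for i in range(4)
        ]
        d = da_matrix(pops)
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.allclose(np.diag(d.to_numpy()), 0.0)


def random_ultrametric(rng, n):
    """Build an exactly ultrametric distance matrix by random agglomeration."""
    heights = np.sort(rng.uniform(0.1, 1.0, size=n - 1))
    clusters = [[i] for i in range(n)]
    d = np.zeros((n, n))
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                d[a, b] = d[b, a] = 2 * h
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return d


class TestUPGMA:
    def test_three_taxon_hand_agglomeration(self):
        d = pd.DataFrame(
            [[0, 2, 8], [2, 0, 8], [8, 8, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        assert upgma(d) == "((A:1,B:1):3,C:4);"

    def test_two_taxa_make_a_half_distance_cherry(self):
        d = pd.DataFrame([[0, 3], [3, 0]], index=["X", "Y"], columns=["X", "Y"])
        assert upgma(d) == "(X:1.5,Y:1.5);"

    def test_nan_rejected(self):
        d = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=list("AB"),
                         columns=list("AB"))
        with pytest.raises(ValueError, match="NaN"):
            upgma(d)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ultrametric_input_reproduced_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        d = random_ultrametric(rng, n)
        names = [f"t{i}" for i in range(n)]
        newick = upgma(pd.DataFrame(d, index=names, columns=names))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        # ultrametric: equal root-to-tip distance for every leaf
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9
        # cophenetic distances equal the input matrix
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                assert pdm.distance(taxa[f"t{i}"], taxa[f"t{j}"]) == pytest.approx(
                    d[i, j], abs=1e-9
                )

    @pytest.mark.parametrize("seed", [3, 4])
    def test_merge_heights_match_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        names = [f"t{i}" for i in range(8)]
        newick = upgma(pd.DataFrame(d, index=names, columns=names))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        heights_scipy = np.sort(linkage(pdist(pts), method="average")[:, 2]) / 2
        # the tree is ultrametric, so tree height minus node depth is the
        # merge height of each internal node
        internal_depths = sorted(
            max(l.distance_from_root() for l in tree.leaf_node_iter())
            - node.distance_from_root()
            for node in tree.preorder_node_iter()
            if not node.is_leaf()
        )
        assert np.allclose(internal_depths, heights_scipy, atol=1e-9)


class TestClassicalMDS:
    def test_unit_square_recovered(self):
        coords = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = squareform(pdist(coords))
        names = list("abcd")
        emb = classical_mds(pd.DataFrame(d, index=names, columns=names), dims=2)
        d_emb = squareform(pdist(emb.to_numpy()))
        assert np.allclose(d_emb, d, atol=1e-9)

    def test_zero_matrix_collapses_to_origin(self):
        names = list("abc")
        d = pd.DataFrame(np.zeros((3, 3)), index=names, columns=names)
        emb = classical_mds(d, dims=2)
        assert np.allclose(emb.to_numpy(), 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_configuration_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(9, 2))
        d = squareform(pdist(pts))
        names = [f"p{i}" for i in range(9)]
        emb = classical_mds(pd.DataFrame(d, index=names, columns=names), dims=2)
        assert procrustes_rmsd(pts, emb.to_numpy()) < 1e-8

    def test_dims_beyond_rank_rejected(self):
        pts = np.array([[0.0], [1.0], [2.0], [5.0]])  # collinear: rank 1
        d = squareform(pdist(pts))
        names = list("abcd")
        with pytest.raises(ValueError, match="rank"):
            classical_mds(pd.DataFrame(d, index=names, columns=names), dims=2)

    def test_needs_enough_populations(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            classical_mds(d, dims=2)

    def test_stress_non_increasing_in_dims(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        names = [f"p{i}" for i in range(8)]
        frame = pd.DataFrame(d, index=names, columns=names)

        def stress(dims):
            emb = classical_mds(frame, dims=dims).to_numpy()
            return float(np.sqrt(np.sum((squareform(pdist(emb)) - d) ** 2)))

        s1, s2, s3 = stress(1), stress(2), stress(3)
        assert s1 >= s2 - 1e-9 >= s3 - 2e-9

    @pytest.mark.filterwarnings("ignore::FutureWarning")
    def test_matches_smacof_on_euclidean_input(self):
        # independent route: scikit-learn's iterative metric MDS lands on the
        # same configuration (up to rigid motion) for exact Euclidean input
        from sklearn.manifold import MDS

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        names = [f"p{i}" for i in range(7)]
        ours = classical_mds(pd.DataFrame(d, index=names, columns=names), 2)
        smacof = MDS(
            n_components=2, dissimilarity="precomputed", normalized_stress=False,
            random_state=0, n_init=8, max_iter=3000, eps=1e-9,
        ).fit_transform(d)
        assert procrustes_rmsd(ours.to_numpy(), smacof) < 5e-3
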