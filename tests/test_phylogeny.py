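import numpy as np
import pytest

from smydkit.core_alignment import ColumnPolicy
from smydkit.phylogeny import (
    BootstrapConfig, DistanceMatrix, DistanceModel, SaturationError,
    bipartitions, bootstrap_support, distance_matrix, jtt_model,
    jtt_transition_matrix, neighbor_joining, pairwise_distance, path_metrics,
    robinson_foulds,
)
from smydkit.seq_io import Alignment, read_newick

from ._oracles import enumerate_topologies, ls_fit, random_additive_tree

POL = ColumnPolicy("pairwise_deletion")


class TestDistances:
    def test_identical_sequences_zero_under_every_model(self):
        for kind in ("p", "poisson", "poisson_gamma", "jtt_ml", "jtt_ml_gamma"):
            d = pairwise_distance("MKVL" * 25, "MKVL" * 25, DistanceModel(kind))
            assert d == pytest.approx(0.0, abs=1e-8)

    def test_poisson_closed_form(self):
        a, b = "A" * 100, "A" * 50 + "R" * 50
        assert pairwise_distance(a, b, DistanceModel("poisson")) == pytest.approx(
            0.6931471805599453, abs=1e-12
        )

    def test_poisson_gamma_closed_form_shape5(self):
        # a((1-p)^(-1/a)-1) at p=0.5, a=5: 5*(2^0.2 - 1), evaluated
        # independently with high-precision arithmetic
        a, b = "A" * 100, "A" * 50 + "R" * 50
        d = pairwise_distance(a, b, DistanceModel("poisson_gamma", gamma_shape=5))
        assert d == pytest.approx(0.7434917749851756, abs=1e-9)

    def test_poisson_gamma_limits(self):
        a, b = "A" * 100, "A" * 50 + "R" * 50
        dp = pairwise_distance(a, b, DistanceModel("poisson"))
        dg = pairwise_distance(a, b, DistanceModel("poisson_gamma", gamma_shape=1e6))
        assert dg == pytest.approx(dp, abs=1e-4)
        for frac in (0.1, 0.3, 0.7, 0.9):
            n1 = int(100 * frac)
            bb = "R" * n1 + "A" * (100 - n1)
            assert pairwise_distance(a, bb, DistanceModel("poisson_gamma", 5)) >= \
                pairwise_distance(a, bb, DistanceModel("poisson"))

    def test_saturation_and_empty_errors(self):
        with pytest.raises(SaturationError):
            pairwise_distance("A" * 10, "R" * 10, DistanceModel("poisson"))
        with pytest.raises(ValueError, match="usable"):
            pairwise_distance("A---", "-RRR", DistanceModel("p"))

    def test_x_counts_as_mismatch(self):
        d = pairwise_distance("AXAA", "AXAA", DistanceModel("p"))
        assert d == pytest.approx(0.25)

    def test_jtt_small_distance_agrees_with_p_distance(self):
        rng = np.random.default_rng(5)
        _, pi = jtt_model()
        a = rng.choice(20, size=5000, p=pi)
        b = a.copy()
        flip = rng.choice(5000, size=25, replace=False)
        b[flip] = (b[flip] + 1) % 20
        from smydkit.phylogeny import AA_ORDER

        sa = "".join(AA_ORDER[i] for i in a)
        sb = "".join(AA_ORDER[i] for i in b)
        dp = pairwise_distance(sa, sb, DistanceModel("p"))
        dj = pairwise_distance(sa, sb, DistanceModel("jtt_ml"))
        assert dj == pytest.approx(dp, rel=0.15)

    def test_jtt_ml_recovers_simulated_distance(self):
        # pair simulated under the JTT process at t=0.3 over 10000 sites;
        # the ML estimate must fall within 3 SE of the truth
        rng = np.random.default_rng(42)
        t_true, L = 0.3, 10000
        _, pi = jtt_model()
        P = jtt_transition_matrix(t_true)
        a = rng.choice(20, size=L, p=pi)
        u = rng.random(L)
        b = (u[:, None] < np.cumsum(P[a], axis=1)).argmax(axis=1)
        from smydkit.phylogeny import AA_ORDER

        sa = "".join(AA_ORDER[i] for i in a)
        sb = "".join(AA_ORDER[i] for i in b)
        d = pairwise_distance(sa, sb, DistanceModel("jtt_ml"))

        def loglik(t):
            Pt = jtt_transition_matrix(t)
            return float(np.log(pi[a] * Pt[a, b]).sum())

        h = 1e-4
        d2 = (loglik(d + h) - 2 * loglik(d) + loglik(d - h)) / h**2
        se = 1.0 / np.sqrt(-d2)
        assert abs(d - t_true) < 3 * se


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        al = Alignment(rows=[("a", "MKVL"), ("b", "MKVL"), ("c", "MKVL")])
        D = distance_matrix(al, DistanceModel("p"), POL)
        assert np.allclose(D.matrix, 0)

    def test_symmetry_and_row_permutation(self):
        rng = np.random.default_rng(1)
        from smydkit.phylogeny import AA_ORDER

        rows = [
            (f"t{i}", "".join(AA_ORDER[j] for j in rng.choice(20, 60)))
            for i in range(5)
        ]
        D = distance_matrix(Alignment(rows=rows), DistanceModel("p"), POL)
        assert np.allclose(D.matrix, D.matrix.T)
        perm = [3, 1, 4, 0, 2]
        D2 = distance_matrix(
            Alignment(rows=[rows[i] for i in perm]), DistanceModel("p"), POL
        )
        for i, pi_ in enumerate(perm):
            for j, pj in enumerate(perm):
                assert D2.matrix[i, j] == pytest.approx(D.matrix[pi_, pj])

    def test_error_names_offending_pair(self):
        al = Alignment(rows=[("aa", "A-"), ("bb", "-R"), ("cc", "AR")])
        with pytest.raises(ValueError, match="aa.*bb"):
            distance_matrix(al, DistanceModel("p"), POL)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(
            taxa=["a", "b", "c"],
            matrix=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
        )
        t = neighbor_joining(D)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 3.0})

    def test_fewer_than_three_taxa_errors(self):
        D = DistanceMatrix(taxa=["a", "b"], matrix=np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError, match="3"):
            neighbor_joining(D)

    def test_additive_four_taxon_vs_least_squares_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            tree = random_additive_tree(4, rng)
            D = tree.path_matrix()
            labels = [f"L{i}" for i in range(4)]
            nj = neighbor_joining(DistanceMatrix(taxa=labels, matrix=D))
            best = min(
                ((ls_fit(t, D)[0], t) for t in enumerate_topologies(4)),
                key=lambda rt: rt[0],
            )
            assert best[0] < 1e-18
            assert bipartitions(nj) == best[1].splits(labels)
            # exact branch length recovery via path distances
            pm = {a: path_metrics(nj, a) for a in labels}
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i < j:
                        assert pm[a][b][0] == pytest.approx(D[i, j], abs=1e-9)

    def test_equal_distance_matrix_total_length(self):
        # all off-diagonal distances 1: some resolved topology is returned
        # and the total length equals the least-squares optimum over the
        # three quartet topologies (brute force)
        D = np.ones((4, 4)) - np.eye(4)
        labels = list("abcd")
        nj = neighbor_joining(DistanceMatrix(taxa=labels, matrix=D))
        total = sum(
            e.length for e in nj.preorder_edge_iter() if e.length is not None
        )
        fits = [ls_fit(t, D) for t in enumerate_topologies(4)]
        # every topology fits equally; total LS length = 4*0.5 + 0 internal
        assert total == pytest.approx(2.0, abs=1e-9)
        assert min(f[0] for f in fits) == pytest.approx(max(f[0] for f in fits))

    def test_consistency_on_random_additive_matrices(self):
        # exact topology + branch-length recovery, 4-12 taxa
        rng = np.random.default_rng(99)
        for trial in range(40):
            n = int(rng.integers(4, 13))
            tree = random_additive_tree(n, rng)
            D = tree.path_matrix()
            labels = [f"L{i:02d}" for i in range(n)]
            nj = neighbor_joining(DistanceMatrix(taxa=labels, matrix=D))
            assert bipartitions(nj) == tree.splits(labels), f"trial {trial}"
            pm = {a: path_metrics(nj, a) for a in labels}
            for i in range(n):
                for j in range(i + 1, n):
                    assert pm[labels[i]][labels[j]][0] == pytest.approx(
                        D[i, j], abs=1e-9
                    )

    def test_agrees_with_scikit_bio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        tree = random_additive_tree(8, rng)
        D = tree.path_matrix()
        D = (D + D.T) / 2
        labels = [f"L{i}" for i in range(8)]
        nj = neighbor_joining(DistanceMatrix(taxa=labels, matrix=D))
        sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        import io

        buf = io.StringIO()
        sk.write(buf)
        other = read_newick(buf.getvalue().strip())
        assert robinson_foulds(nj, other) == 0


class TestSplitsAndRF:
    def test_rf_zero_against_self(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        assert robinson_foulds(t, t) == 0

    def test_rf_two_between_distinct_quartets(self):
        # hand enumeration: quartet AB|CD vs AC|BD share no non-trivial
        # splits, so the symmetric difference has 2 elements
        t1 = read_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = read_newick("((A:1,C:1):1,B:1,D:1);")
        assert robinson_foulds(t1, t2) == 2

    def test_rf_one_between_star_and_resolved(self):
        star = read_newick("(A:1,B:1,C:1,D:1);")
        res = read_newick("((A:1,B:1):1,C:1,D:1);")
        assert robinson_foulds(star, res) == 1

    def test_rf_requires_same_leaves(self):
        t1 = read_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = read_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(ValueError):
            robinson_foulds(t1, t2)


class TestBootstrap:
    def _alignment(self, rng, n=8, L=60, mut=0.25):
        from smydkit.phylogeny import AA_ORDER

        root = rng.choice(20, L)
        rows = []
        for i in range(n):
            row = root.copy()
            hit = rng.random(L) < mut
            row[hit] = rng.choice(20, int(hit.sum()))
            rows.append((f"t{i}", "".join(AA_ORDER[j] for j in row)))
        return Alignment(rows=rows)

    def test_supports_in_range_and_seed_reproducible(self):
        rng = np.random.default_rng(12)
        al = self._alignment(rng)
        model = DistanceModel("poisson_gamma", 5)
        t1 = bootstrap_support(
            al, model, POL, neighbor_joining(distance_matrix(al, model, POL)),
            BootstrapConfig(50, seed=7),
        )
        sups1 = sorted(
            n.support for n in t1.preorder_node_iter() if hasattr(n, "support")
        )
        assert sups1 and all(0 <= s <= 100 for s in sups1)
        t2 = bootstrap_support(
            al, model, POL, neighbor_joining(distance_matrix(al, model, POL)),
            BootstrapConfig(50, seed=7),
        )
        sups2 = sorted(
            n.support for n in t2.preorder_node_iter() if hasattr(n, "support")
        )
        assert sups1 == sups2

    def test_identical_column_copies_give_full_support(self):
        # every column is a copy of the same pattern: resampling cannot
        # change the distance matrix, so all original bipartitions get 100
        col = ["A", "A", "R", "R", "N", "N", "D", "D"]
        col2 = ["A", "A", "A", "A", "R", "R", "R", "R"]
        L = 30
        rows = [
            (f"t{i}", (col[i] + col2[i]) * L) for i in range(8)
        ]
        al = Alignment(rows=rows)
        model = DistanceModel("p")
        tree = neighbor_joining(distance_matrix(al, model, POL))
        tree = bootstrap_support(al, model, POL, tree, BootstrapConfig(40, seed=1))
        sups = [
            n.support for n in tree.preorder_node_iter() if hasattr(n, "support")
        ]
        assert sups and all(s == pytest.approx(100.0) for s in sups)
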