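import numpy as np
import pytest

from smydkit.seq_io import write_newick
from smydkit.synthetic_data import (
    SynthConfig, evolve_sequences, generate_family, simulate_tree,
)


class TestSimulateTree:
    def test_four_leaves_two_internal_edges(self):
        t = simulate_tree(4, seed=1)
        internal = [
            nd for nd in t.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        assert len(internal) == 2

    def test_same_seed_identical_newick(self):
        assert write_newick(simulate_tree(10, seed=5)) == write_newick(
            simulate_tree(10, seed=5)
        )

    def test_fifty_leaves_edge_counts(self):
        # rooted binary tree: 2n-2 edges, of which n-2 internal
        t = simulate_tree(50, seed=2)
        leaves = sum(1 for _ in t.leaf_node_iter())
        assert leaves == 50
        internal_edges = [
            nd for nd in t.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        assert len(internal_edges) == 48

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            simulate_tree(3, seed=1)


class TestEvolveSequences:
    def test_zero_length_branches_keep_root(self):
        t = simulate_tree(5, seed=3, divergence=0.5)
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length = 0.0
        out = evolve_sequences(t, "MKVLRAGWQE" * 10, seed=1)
        assert all(s.residues == "MKVLRAGWQE" * 10 for s in out)

    def test_fully_masked_root_never_changes(self):
        t = simulate_tree(5, seed=3, divergence=1.0)
        root = "MKVLRAGWQE" * 10
        out = evolve_sequences(t, root, mask=np.ones(len(root), bool), seed=1)
        assert all(s.residues == root for s in out)

    def test_mask_length_mismatch_errors(self):
        t = simulate_tree(4, seed=1)
        with pytest.raises(ValueError, match="mask"):
            evolve_sequences(t, "MKVL", mask=np.ones(10, bool), seed=1)

    def test_pair_p_distance_matches_twenty_state_closed_form(self):
        # two leaves at patristic distance 0.2 under the uniform 20-state
        # model: expected p = (19/20)(1 - exp(-20 d / 19))
        import dendropy

        tns = dendropy.TaxonNamespace(["x", "y"])
        tree = dendropy.Tree(taxon_namespace=tns)
        a = dendropy.Node(taxon=tns.get_taxon("x"))
        b = dendropy.Node(taxon=tns.get_taxon("y"))
        tree.seed_node.add_child(a)
        tree.seed_node.add_child(b)
        a.edge.length = 0.1
        b.edge.length = 0.1
        L = 10000
        rng = np.random.default_rng(8)
        from smydkit.phylogeny import AA_ORDER

        root = "".join(AA_ORDER[i] for i in rng.integers(0, 20, L))
        sx, sy = evolve_sequences(tree, root, model="poisson", seed=4)
        p_obs = sum(c1 != c2 for c1, c2 in zip(sx.residues, sy.residues)) / L
        d = 0.2
        p_exp = (19 / 20) * (1 - np.exp(-20 * d / 19))
        se = np.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * se


class TestGenerateFamily:
    def test_truth_coordinates_index_stated_residues(self, small_family):
        fam = small_family
        seqs = {s.id: s for s in fam.seqs}
        for sid, tr in fam.truth.per_seq.items():
            s = seqs[sid]
            for p in tr.finger.positions:
                assert s.residues[p - 1] in "CHE", (sid, p)
            if tr.extra_finger:
                for p in tr.extra_finger.positions:
                    assert s.residues[p - 1] in "CH"
            for typ, (a, b) in tr.domains.items():
                assert 1 <= a <= b <= len(s.residues)
            if tr.tract_span:
                a, b = tr.tract_span
                window = s.residues[a - 1: b]
                frac = sum(window.count(c) for c in "EDS") / len(window)
                assert frac >= 0.6

    def test_core_alignment_matches_fasta(self, small_family):
        fam = small_family
        seqs = {s.id: s for s in fam.seqs}
        for rid, row in fam.core_alignment.rows:
            a, b = fam.truth.core_span[rid]
            assert seqs[rid].residues[a - 1: b] == row

    def test_reproducibility_byte_identical(self, tmp_path):
        cfg1 = SynthConfig(seed=77, divergence=0.2, core_length=260)
        cfg2 = SynthConfig(seed=77, divergence=0.2, core_length=260)
        f1 = generate_family(cfg1)
        f2 = generate_family(cfg2)
        f1.write_outputs(tmp_path / "a")
        f2.write_outputs(tmp_path / "b")
        for name in ("family.fasta", "core_alignment.fasta",
                      "annotations.tsv", "true_tree.nwk", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_divergence_calibration_monotone(self):
        means = []
        for div in (0.05, 0.2, 0.5):
            fam = generate_family(
                SynthConfig(seed=13, divergence=div, core_length=400,
                            template_divergence=0.0)
            )
            rows = [r for _, r in fam.core_alignment.rows]
            ps = []
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    ps.append(
                        sum(a != b for a, b in zip(rows[i], rows[j])) / len(rows[i])
                    )
            means.append(np.mean(ps))
        assert means[0] < means[1] < means[2]

    def test_planted_deviation_appears_in_finger_report(self):
        from smydkit.zinc_finger import finger_report

        fam = generate_family(SynthConfig(seed=21, divergence=0.0, core_length=300))
        smyda = [s for s in fam.seqs if s.id.startswith("SMYDA")]
        tr = fam.truth.per_seq[smyda[0].id]
        a, b = tr.domains["MYND"]
        df = finger_report(smyda, region=(a, b))
        assert set(df["category"]) == {tr.finger.category}
        for devs in df["deviations"]:
            assert "spacing_long@gap12" in devs
            assert "ligand_substitution@pos3" in devs

    def test_template_counts_exceeding_taxa_error(self):
        with pytest.raises(ValueError):
            SynthConfig(seed=1, class_counts={"SMYD3": 1, "SMYD4": 1})

    def test_five_singleton_classes_scan_matches_truth(self):
        from smydkit.domain_architecture import assemble_architecture
        from smydkit.pipeline import core_from_annotations, scan_sequence
        from smydkit.zinc_finger import RelaxPolicy

        cfg = SynthConfig(
            seed=9, divergence=0.0,
            class_counts={c: 1 for c in
                          ("SMYD3", "SMYD4", "SMYD5", "SMYDA", "ATYPICAL_TPR")},
            core_length=300,
        )
        fam = generate_family(cfg)
        assert len(fam.seqs) == 5
        for s in fam.seqs:
            tr = fam.truth.per_seq[s.id]
            core = core_from_annotations(fam.annotations[s.id])
            best, extras = scan_sequence(s, core, None, RelaxPolicy())
            arch = assemble_architecture(
                s, core, best,
                [a for a in fam.annotations[s.id] if a.type in ("TPR_N", "CTD")],
                extras,
            )
            assert best.positions == tr.finger.positions
            assert best.category == tr.finger.category
            assert arch.signature == tr.signature
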