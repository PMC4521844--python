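import pytest

from smydkit.classification import (
    AnchorSet, ClassLabel, assign_classes, assign_subgroups, suggest_ortholog,
)
from smydkit.domain_architecture import Architecture
from smydkit.phylogeny import path_metrics, supports_from_labels
from smydkit.seq_io import read_newick


def _tree(newick: str):
    return supports_from_labels(read_newick(newick))


def _arch(sig: str) -> Architecture:
    return Architecture(annotations=[], signature=sig)


ANCHORS = AnchorSet(
    anchors={
        "anch3": ClassLabel("SMYD3"),
        "anch4": ClassLabel("SMYD4"),
        "anch5": ClassLabel("SMYD5"),
    }
)


def test_supported_clade_with_agreeing_architecture():
    t = _tree("(((q1:0.1,anch4:0.1)95:0.4,anch3:0.5)90:0.2,anch5:0.6,out:0.9);")
    asg = assign_classes(
        t, {"q1": _arch("TPR_N|S/ET+M|CTD")}, ANCHORS, min_support=70
    )
    by_id = {a.seq_id: a for a in asg}
    a = by_id["q1"]
    assert a.label.smyd_class == "SMYD4"
    assert a.evidence.agreement == "agree"
    assert a.evidence.clade_anchors == ["anch4"]
    assert a.evidence.clade_support == 95


def test_architecture_disagreement_demotes_to_unclassified():
    t = _tree("(((q1:0.1,anch4:0.1)95:0.4,anch3:0.5)90:0.2,anch5:0.6,out:0.9);")
    asg = assign_classes(t, {"q1": _arch("S/ET+M|E")}, ANCHORS, min_support=70)
    a = {x.seq_id: x for x in asg}["q1"]
    assert a.label.smyd_class == "UNCLASSIFIED"
    assert a.evidence.agreement == "disagree"


ANCHORS_35 = AnchorSet(
    anchors={"anch3": ClassLabel("SMYD3"), "anch5": ClassLabel("SMYD5")}
)

# q1's only supported anchored clade contains both a SMYD3 and a SMYD5
# anchor, so tree evidence is inconclusive at every support level
MIXED_TREE = "((q1:0.1,(anch3:0.2,anch5:0.2)99:0.1)98:0.3,y:0.5,out:0.9);"


def test_mixed_anchor_clades_fall_through_to_architecture():
    t = _tree(MIXED_TREE)
    asg = assign_classes(t, {"q1": _arch("S/ET+M|E")}, ANCHORS_35, min_support=70)
    a = {x.seq_id: x for x in asg}["q1"]
    assert a.label.smyd_class == "SMYD5"
    assert a.evidence.agreement == "architecture-only"


def test_no_evidence_gives_unclassified():
    t = _tree(MIXED_TREE)
    asg = assign_classes(t, {"q1": _arch("S/ET+M")}, ANCHORS_35, min_support=70)
    a = {x.seq_id: x for x in asg}["q1"]
    assert a.label.smyd_class == "UNCLASSIFIED"


def test_low_support_clades_are_ignored():
    t = _tree("(((q1:0.1,anch4:0.1)40:0.4,anch3:0.5)45:0.2,anch5:0.6,out:0.9);")
    asg = assign_classes(t, {}, ANCHORS, min_support=70)
    a = {x.seq_id: x for x in asg}["q1"]
    assert a.label.smyd_class == "UNCLASSIFIED"


def test_raising_min_support_is_monotonically_conservative():
    t = _tree("(((q1:0.1,anch4:0.1)75:0.4,anch3:0.5)72:0.2,anch5:0.6,out:0.9);")
    arch = {"q1": _arch("TPR_N|S/ET+M|CTD")}
    for lo, hi in [(50, 70), (70, 80), (80, 95)]:
        a_lo = {x.seq_id: x for x in assign_classes(t, arch, ANCHORS, lo)}["q1"]
        a_hi = {x.seq_id: x for x in assign_classes(t, arch, ANCHORS, hi)}["q1"]
        if a_lo.label.smyd_class == "UNCLASSIFIED":
            assert a_hi.label.smyd_class in ("UNCLASSIFIED", a_hi.label.smyd_class)
        if a_hi.label.smyd_class != "UNCLASSIFIED":
            # classified at high support implies classified at low support
            assert a_lo.label.smyd_class != "UNCLASSIFIED"


def test_assignments_invariant_under_leaf_relabeling():
    t1 = _tree("(((q1:0.1,anch4:0.1)95:0.4,anch3:0.5)90:0.2,anch5:0.6,zq:0.9);")
    t2 = _tree("(((zz:0.1,anch4:0.1)95:0.4,anch3:0.5)90:0.2,anch5:0.6,aq:0.9);")
    arch1 = {"q1": _arch("TPR_N|S/ET+M|CTD")}
    arch2 = {"zz": _arch("TPR_N|S/ET+M|CTD")}
    a1 = {x.seq_id: x.label.smyd_class for x in assign_classes(t1, arch1, ANCHORS)}
    a2 = {x.seq_id: x.label.smyd_class for x in assign_classes(t2, arch2, ANCHORS)}
    assert a1["q1"] == a2["zz"]
    assert a1["zq"] == a2["aq"]


def test_missing_anchor_errors():
    t = _tree("((q1:0.1,anch4:0.1)95:0.4,anch3:0.5,anch5:0.6);")
    bad = AnchorSet(anchors={"ghost": ClassLabel("SMYD3")})
    with pytest.raises(ValueError, match="ghost"):
        assign_classes(t, {}, bad)


SUB_ANCHORS = AnchorSet(
    anchors={
        "a4": ClassLabel("SMYD4", "SMYD4"),
        "a4L": ClassLabel("SMYD4", "SMYD4L"),
        "a5": ClassLabel("SMYD5"),
    }
)


def test_subgroup_assignment():
    t = _tree(
        "(((q1:0.1,a4L:0.1)90:0.3,(q2:0.2,a4:0.2)92:0.3)88:0.2,a5:0.8,out:0.9);"
    )
    base = assign_classes(t, {}, SUB_ANCHORS, min_support=70)
    refined = {
        x.seq_id: x for x in assign_subgroups(base, t, SUB_ANCHORS, min_support=70)
    }
    assert refined["q1"].label.subgroup == "SMYD4L"
    assert refined["q2"].label.subgroup == "SMYD4"


def test_subgroup_unset_without_supported_subgroup_clade():
    # only the class-level clade is supported; within it the subgroup
    # anchors are mixed, so subgroups stay unset
    t = _tree(
        "(((q1:0.1,a4L:0.1)30:0.3,(q2:0.2,a4:0.2)30:0.3)88:0.2,a5:0.8,out:0.9);"
    )
    base = assign_classes(t, {}, SUB_ANCHORS, min_support=70)
    refined = {
        x.seq_id: x for x in assign_subgroups(base, t, SUB_ANCHORS, min_support=70)
    }
    assert refined["q1"].label.smyd_class == "SMYD4"
    assert refined["q1"].label.subgroup is None
    assert refined["q2"].label.subgroup is None


class TestSuggestOrtholog:
    def test_grafted_query_finds_nearest_anchor(self):
        t = _tree("(((q1:0.01,anch4:0.01)95:0.4,anch3:0.5)90:0.2,anch5:0.6);")
        anchor, dist, sup = suggest_ortholog("q1", t, ANCHORS)
        assert anchor == "anch4"
        assert dist == pytest.approx(0.02)

    def test_equidistant_tie_broken_by_path_support(self):
        t = _tree("((q1:0.1,anch4:0.3)95:0.2,(anch3:0.3,x:0.1)40:0.2,anch5:0.9);")
        # anch4 at 0.4 via a 95-support edge-free path; anch3 at 0.4 via a
        # 40-support edge
        anchor, dist, sup = suggest_ortholog("q1", t, ANCHORS)
        assert anchor == "anch4"
        assert sup >= 95 or sup == 100

    def test_patristic_distances_match_brute_force(self):
        t = _tree("(((A:0.1,B:0.2)90:0.3,C:0.4)80:0.1,D:0.5,E:0.6);")
        pm = path_metrics(t, "A")
        # hand-summed path lengths
        assert pm["B"][0] == pytest.approx(0.3)
        assert pm["C"][0] == pytest.approx(0.8)
        assert pm["D"][0] == pytest.approx(1.0)
        assert pm["E"][0] == pytest.approx(1.1)

    def test_no_anchors_errors(self):
        t = _tree("((A:1,B:1):1,C:1,D:1);")
        with pytest.raises(ValueError):
            suggest_ortholog("A", t, AnchorSet(anchors={}))
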