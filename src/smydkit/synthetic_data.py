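"""Synthetic Smyd-like protein families with full ground truth.

The generator emulates the shape of the real data the classification
framework was designed for: a family of proteins evolved along a known
tree, each carrying an interrupted SET core with a planted cross-brace
MYND-like Zn finger, plus class-specific flanking features — an N-terminal
TPR block (Smyd4, atypical TPR-Smyd), a C-terminal TPR-fold domain (Smyd3,
Smyd4), a C-terminal acidic tract (Smyd5), an extra canonical MYND finger
(atypical TPR-Smyd), or none of these with a degenerate core finger
(SmydA).

Design choices that matter downstream:

* Sequences evolve with independent-site substitutions and **no indels**,
  so the emitted core alignment is the true (gap-free) alignment and no
  external aligner is needed.
* Background residue composition excludes Cys and His (they appear only at
  planted ligand positions, plus whatever drift introduces), mirroring the
  rarity of these residues and keeping the finger search well-posed.
* Planted diagnostic features (finger blocks, TPR repeats, acidic tract)
  are masked invariant by default; a decay option lets them mutate.
* The family tree is a caterpillar backbone over class roots (classes are
  ancient, well-separated splits) with a Yule subtree per class, scaled so
  the expected root-to-tip path equals the configured divergence.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .core_alignment import ColumnPolicy
from .domain_architecture import DomainAnnotation, TprProfile, write_annotations_tsv
from .phylogeny import AA_ORDER, jtt_model, jtt_transition_matrix
from .seq_io import Alignment, ProteinSeq, write_alignment, write_fasta, write_newick
from .zinc_finger import GAP_NAMES, Deviation, ZnPattern, categorize

_AA = np.frombuffer(AA_ORDER.encode(), dtype=np.uint8)
_IDX = {aa: i for i, aa in enumerate(AA_ORDER)}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CLASS_COUNTS = {
    "SMYD3": 4, "SMYD4": 4, "SMYD5": 4, "SMYDA": 4, "ATYPICAL_TPR": 4,
}

#: deviations planted into the SmydA core finger: a His for Cys swap at the
#: first pair-2 ligand and a stretched pair 1-2 spacer
DEFAULT_PLANTED = {"SMYDA": ("ligand_substitution:pos3:H", "spacing_long:gap12:+6")}


@dataclass
class SynthConfig:
    """Study conditions for one synthetic family."""

    seed: int
    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    smyd4_subgroup_counts: dict[str, int] | None = None
    birth_rate: float = 1.0
    divergence: float = 0.3          # expected root-to-tip substitutions/site
    model: str = "poisson"           # poisson (uniform 20-state) | jtt
    core_length: int = 300
    nflank: int = 20
    cflank: int = 20
    linker: int = 5
    ctd_length: int = 60
    tpr_repeats: int = 3
    acidic_length: int = 15
    acidic_composition: str = "E"    # E | ED | EDS
    planted_deviations: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED)
    )
    mask_features: bool = True       # invariant ligands/motifs; False = decay mode
    template_divergence: float = 0.1  # extra class-root divergence: class
                                      # templates differ even at divergence 0
    min_branch: float = 0.02
    n_species: int = 4

    def __post_init__(self) -> None:
        n = sum(self.class_counts.values())
        if n < 4:
            raise ValueError("need at least 4 taxa in total")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.model not in ("poisson", "jtt"):
            raise ValueError("model must be 'poisson' or 'jtt'")
        if self.smyd4_subgroup_counts is not None:
            self.class_counts["SMYD4"] = sum(self.smyd4_subgroup_counts.values())


@dataclass
class PlantedFinger:
    positions: tuple[int, ...]       # absolute 1-based coordinates
    deviations: tuple[Deviation, ...]
    category: str


@dataclass
class SeqTruth:
    label: str                       # class
    subgroup: str | None
    species: str
    finger: PlantedFinger
    extra_finger: PlantedFinger | None
    domains: dict[str, tuple[int, int]]
    signature: str
    tract_span: tuple[int, int] | None


@dataclass
class SyntheticTruth:
    tree: dendropy.Tree
    per_seq: dict[str, SeqTruth]
    core_span: dict[str, tuple[int, int]]   # per sequence, absolute coords

    def class_of(self, seq_id: str) -> str:
        return self.per_seq[seq_id].label

    def anchor_ids(self, per_subgroup: bool = False) -> dict[str, tuple[str, str | None]]:
        """First member of each class (and subgroup) as reference anchors."""
        chosen: dict[tuple[str, str | None], str] = {}
        for sid in sorted(self.per_seq):
            t = self.per_seq[sid]
            key = (t.label, t.subgroup if per_subgroup else None)
            chosen.setdefault(key, sid)
        return {sid: key for key, sid in chosen.items()}

    def to_jsonable(self) -> dict:
        return {
            "tree": write_newick(self.tree),
            "per_seq": {
                sid: {
                    "class": t.label,
                    "subgroup": t.subgroup,
                    "species": t.species,
                    "signature": t.signature,
                    "finger_positions": list(t.finger.positions),
                    "finger_category": t.finger.category,
                    "finger_deviations": [
                        [d.kind, d.location] for d in t.finger.deviations
                    ],
                    "domains": {k: list(v) for k, v in t.domains.items()},
                    "tract_span": list(t.tract_span) if t.tract_span else None,
                    "core_span": list(self.core_span[sid]),
                }
                for sid, t in self.per_seq.items()
            },
        }


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _yule(n: int, birth_rate: float, seed: int) -> dendropy.Tree:
    if n == 1:
        t = dendropy.Tree()
        t.seed_node.taxon = None
        return t
    return dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n,
        rng=random.Random(seed),
    )


def _scale_depth(tree: dendropy.Tree, depth: float, min_branch: float) -> None:
    dmax = max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )
    f = depth / dmax if dmax > 0 else 0.0
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = max(e.length * f, min_branch)


def simulate_tree(
    n: int, birth_rate: float = 1.0, seed: int = 0, divergence: float = 0.3
) -> dendropy.Tree:
    """A Yule (pure-birth) tree with ``n`` leaves labelled T01..Tnn, scaled so
    the deepest root-to-tip path equals ``divergence`` substitutions/site."""
    if n < 4:
        raise ValueError("simulate_tree requires n >= 4")
    tree = _yule(n, birth_rate, seed)
    _scale_depth(tree, divergence, min_branch=0.0)
    for i, lf in enumerate(tree.leaf_node_iter(), start=1):
        lf.taxon.label = f"T{i:02d}"
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _mutate(
    seq: np.ndarray, t: float, mask: np.ndarray, model: str, rng: np.random.Generator
) -> np.ndarray:
    out = seq.copy()
    free = ~mask
    if not free.any() or t <= 0:
        return out
    if model == "poisson":
        stay = 1.0 / 20.0 + (19.0 / 20.0) * np.exp(-20.0 * t / 19.0)
        hit = (rng.random(seq.shape[0]) > stay) & free
        k = int(hit.sum())
        if k:
            out[hit] = (seq[hit] + rng.integers(1, 20, size=k)) % 20
    else:
        P = jtt_transition_matrix(t)
        C = np.cumsum(P, axis=1)
        idx = np.nonzero(free)[0]
        u = rng.random(idx.shape[0])
        rows = C[seq[idx]]
        out[idx] = (u[:, None] < rows).argmax(axis=1)
    return out


def evolve_sequences(
    tree: dendropy.Tree,
    root_seq: str,
    model: str = "poisson",
    mask: np.ndarray | None = None,
    seed: int = 0,
) -> list[ProteinSeq]:
    """Evolve ``root_seq`` along the tree with independent-site substitutions.

    ``mask`` marks invariant sites (True = never mutate).  Returns one
    :class:`ProteinSeq` per leaf, in leaf-iteration order.
    """
    enc = np.array([_IDX[ch] for ch in root_seq], dtype=np.int64)
    if mask is None:
        mask = np.zeros(enc.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != enc.shape[0]:
        raise ValueError("mask length does not match root sequence length")
    rng = np.random.default_rng(seed)
    out: list[ProteinSeq] = []

    def walk(node: dendropy.Node, s: np.ndarray) -> None:
        for ch in node.child_nodes():
            s2 = _mutate(s, ch.edge.length or 0.0, mask, model, rng)
            if ch.is_leaf():
                out.append(
                    ProteinSeq(
                        id=ch.taxon.label,
                        residues="".join(AA_ORDER[i] for i in s2),
                        source="synthetic",
                    )
                )
            else:
                walk(ch, s2)

    walk(tree.seed_node, enc)
    return out


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, n: int, exclude: str = "CH") -> np.ndarray:
    """Residues drawn from JTT equilibrium frequencies with the ``exclude``
    residues zeroed out.  Cys/His are always excluded so Zn-ligand
    candidates occur only where planted (or by drift); flank and linker
    segments additionally exclude E/D/S so that C-terminal acidic tracts
    exist only where the template plants one."""
    _, pi = jtt_model()
    p = pi.copy()
    for ch in set(exclude) | {"C", "H"}:
        p[_IDX[ch]] = 0.0
    p /= p.sum()
    return rng.choice(20, size=n, p=p)


def _flank(rng: np.random.Generator, n: int) -> np.ndarray:
    return _background(rng, n, exclude="CHEDS")


def _parse_deviation(spec: str) -> tuple[str, str, str]:
    parts = spec.split(":")
    if len(parts) != 3:
        raise ValueError(f"bad deviation spec {spec!r} (kind:location:detail)")
    return parts[0], parts[1], parts[2]


def build_finger_block(
    pattern: ZnPattern,
    rng: np.random.Generator,
    planted: tuple[str, ...] = (),
) -> tuple[np.ndarray, tuple[int, ...], tuple[Deviation, ...], str]:
    """Construct a finger block matching the signature, then apply planted
    deviations.  Returns (encoded block, 1-based ligand positions within the
    block, measured deviations, category).

    Spacing deviations are expressed as ``spacing_long:gapXY:+n`` /
    ``spacing_short:gapXY:-n``; substitutions as
    ``ligand_substitution:posK:R``.
    """
    gaps = [ (lo + hi) // 2 for lo, hi in pattern.gap_bounds ]
    residues = []
    for slot in range(8):
        lig = sorted(pattern.position_ligands[slot])
        residues.append("C" if "C" in lig else lig[0])
    for spec in planted:
        kind, loc, detail = _parse_deviation(spec)
        if kind in ("spacing_long", "spacing_short"):
            k = GAP_NAMES.index(loc)
            lo, hi = pattern.gap_bounds[k]
            delta = int(detail)
            gaps[k] = (hi if delta > 0 else lo) + delta
            if gaps[k] < 0:
                raise ValueError(f"deviation {spec!r} yields negative spacer")
        elif kind == "ligand_substitution":
            slot = int(loc.removeprefix("pos")) - 1
            residues[slot] = detail
        else:
            raise ValueError(f"cannot plant deviation kind {kind!r}")

    positions: list[int] = []
    pos = 1
    for slot in range(8):
        if slot:
            pos += gaps[slot - 1]
        positions.append(pos)
        pos += 1
    length = positions[-1]
    block = _background(rng, length)
    for slot, p in enumerate(positions):
        block[p - 1] = _IDX[residues[slot]]

    # measure the planted deviations against the unrelaxed signature
    devs: list[Deviation] = []
    for slot in range(8):
        if residues[slot] not in pattern.position_ligands[slot]:
            devs.append(Deviation("ligand_substitution", f"pos{slot + 1}", residues[slot]))
    for k in range(7):
        lo, hi = pattern.gap_bounds[k]
        if gaps[k] > hi:
            devs.append(Deviation("spacing_long", GAP_NAMES[k], f"{gaps[k]} > {hi}"))
        elif gaps[k] < lo:
            devs.append(Deviation("spacing_short", GAP_NAMES[k], f"{gaps[k]} < {lo}"))
    cat = categorize(tuple(devs), 8)
    return block, tuple(positions), tuple(devs), cat


@dataclass
class _Segment:
    name: str
    arr: np.ndarray
    masked: bool = False


def _acidic_block(length: int, composition: str, rng: np.random.Generator) -> np.ndarray:
    pools = {"E": "E", "ED": "ED", "EDS": "EDS"}[composition]
    return np.array([_IDX[rng.choice(list(pools))] for _ in range(length)])


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticFamily:
    seqs: list[ProteinSeq]
    core_alignment: Alignment
    annotations: dict[str, list[DomainAnnotation]]
    truth: SyntheticTruth
    config: SynthConfig

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.seqs, outdir / "family.fasta")
        write_alignment(self.core_alignment, outdir / "core_alignment.fasta")
        write_annotations_tsv(self.annotations, outdir / "annotations.tsv")
        write_newick(self.truth.tree, outdir / "true_tree.nwk")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth.to_jsonable(), indent=1) + "\n"
        )


def _class_tree(
    cls: str, n: int, cfg: SynthConfig, seed: int, depth: float
) -> dendropy.Tree:
    if cls == "SMYD4" and cfg.smyd4_subgroup_counts:
        # backbone over subgroups, Yule within
        subs = [(k, v) for k, v in cfg.smyd4_subgroup_counts.items() if v > 0]
        roots = []
        for i, (sub, cnt) in enumerate(subs):
            st = _yule(cnt, cfg.birth_rate, seed + 101 * (i + 1))
            _scale_depth(st, depth * 0.5, cfg.min_branch)
            st.seed_node._subgroup = sub
            roots.append(st.seed_node)
        node = roots[0]
        for i, r in enumerate(roots[1:], start=1):
            parent = dendropy.Node()
            parent.add_child(node)
            node.edge.length = max(depth * 0.5 / len(subs), cfg.min_branch)
            parent.add_child(r)
            r.edge.length = max(depth * 0.5, cfg.min_branch)
            node = parent
        t = dendropy.Tree()
        t.seed_node = node
        return t
    t = _yule(n, cfg.birth_rate, seed)
    _scale_depth(t, depth, cfg.min_branch)
    return t


def generate_family(cfg: SynthConfig) -> SyntheticFamily:
    """Generate one family with full ground truth (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)
    pattern = ZnPattern.default()
    tpr = TprProfile.default()

    # --- core template shared by the family -------------------------------
    canon_block, canon_rel, canon_devs, canon_cat = build_finger_block(pattern, rng)
    max_extra = 12  # headroom for planted spacer stretches
    mynd_pad = 5
    mynd_len = mynd_pad + len(canon_block) + max_extra + mynd_pad
    set_n_len = max(30, int(cfg.core_length * 0.35))
    post_set_len = max(15, int(cfg.core_length * 0.10))
    set_c_len = cfg.core_length - set_n_len - mynd_len - post_set_len
    if set_c_len < 20:
        raise ValueError("core_length too small for the MYND segment")

    core = _background(rng, cfg.core_length)
    mynd_start = set_n_len                      # 0-based offset of MYND segment
    block_off = mynd_start + mynd_pad
    core[block_off: block_off + len(canon_block)] = canon_block
    finger_abs_core = tuple(block_off + p for p in canon_rel)  # 1-based in core

    # class-specific finger blocks (same segment, deviations applied)
    class_blocks: dict[str, tuple[np.ndarray, tuple[int, ...], tuple[Deviation, ...], str]] = {}
    for cls in cfg.class_counts:
        planted = cfg.planted_deviations.get(cls, ())
        if planted:
            blk = build_finger_block(pattern, rng, planted)
            if len(blk[0]) > len(canon_block) + max_extra:
                raise ValueError("planted spacer stretch exceeds MYND segment headroom")
            class_blocks[cls] = blk
        else:
            class_blocks[cls] = (canon_block, canon_rel, canon_devs, canon_cat)

    core_mask = np.zeros(cfg.core_length, dtype=bool)
    if cfg.mask_features:
        core_mask[mynd_start: mynd_start + mynd_len] = True

    # --- family tree: caterpillar backbone over class roots ---------------
    classes = [c for c, n in sorted(cfg.class_counts.items()) if n > 0]
    k = len(classes)
    depth_backbone = cfg.divergence * 0.5
    depth_class = cfg.divergence * 0.5
    if cfg.divergence == 0:
        cfg = SynthConfig(**{**cfg.__dict__})  # keep caller's object intact
        cfg.min_branch = 0.0
    e = depth_backbone / max(k - 1, 1)
    sub_seeds = {c: int(rng.integers(0, 2**31 - 1)) for c in classes}
    class_roots: dict[str, dendropy.Node] = {}
    for cls in classes:
        st = _class_tree(cls, cfg.class_counts[cls], cfg, sub_seeds[cls], depth_class)
        class_roots[cls] = st.seed_node

    chain: list[dendropy.Node] = [dendropy.Node() for _ in range(max(k - 1, 1))]
    for i in range(len(chain) - 1):
        chain[i].add_child(chain[i + 1])
        chain[i + 1].edge.length = e
    for i, cls in enumerate(classes):
        attach = chain[min(i, len(chain) - 1)]
        depth_here = min(i, len(chain) - 1) * e
        attach.add_child(class_roots[cls])
        class_roots[cls].edge.length = max(
            depth_backbone - depth_here, cfg.min_branch
        )
        class_roots[cls]._smyd_class = cls

    tree = dendropy.Tree()
    tree.seed_node = chain[0]

    # label leaves: CLASS_ii, assign species round-robin, record subgroup
    leaf_meta: dict[str, tuple[str, str | None, str]] = {}
    tns = dendropy.TaxonNamespace()
    for cls in classes:
        root = class_roots[cls]
        idx = 0
        for lf in (
            [root] if root.is_leaf() else list(root.leaf_iter())
        ):
            idx += 1
            name = f"{cls}_{idx:02d}"
            lf.taxon = tns.new_taxon(name)
            sub = None
            node = lf
            while node is not None and node is not root.parent_node:
                if getattr(node, "_subgroup", None):
                    sub = node._subgroup
                    break
                node = node.parent_node
            if cls == "SMYD3" and cfg.smyd4_subgroup_counts is None:
                sub = None
            species = f"sp{(idx - 1) % cfg.n_species + 1}"
            leaf_meta[name] = (cls, sub, species)
    tree.taxon_namespace = tns

    # --- phase A: evolve the core along the whole tree --------------------
    core_leafs: dict[str, np.ndarray] = {}
    class_root_cores: dict[str, np.ndarray] = {}

    def walk_core(node: dendropy.Node, s: np.ndarray) -> None:
        for ch in node.child_nodes():
            s2 = _mutate(s, ch.edge.length or 0.0, core_mask, cfg.model, rng)
            cls = getattr(ch, "_smyd_class", None)
            if cls is not None:
                blk, rel, devs, cat = class_blocks[cls]
                s2 = _mutate(s2, cfg.template_divergence, core_mask, cfg.model, rng)
                s2 = s2.copy()
                s2[block_off: block_off + len(blk)] = blk
                class_root_cores[cls] = s2
                walk_class_core(ch, s2, cls)
            elif ch.is_leaf():
                core_leafs[ch.taxon.label] = s2
            else:
                walk_core(ch, s2)

    def walk_class_core(node: dendropy.Node, s: np.ndarray, cls: str) -> None:
        if node.is_leaf():
            core_leafs[node.taxon.label] = s
            return
        for ch in node.child_nodes():
            s2 = _mutate(s, ch.edge.length or 0.0, core_mask, cfg.model, rng)
            walk_class_core(ch, s2, cls)

    walk_core(tree.seed_node, core)

    # --- phase B: class flanks evolved within each class subtree ----------
    tpr_block = np.array([_IDX[c] for c in tpr.consensus * cfg.tpr_repeats])

    def class_segments(cls: str) -> tuple[list[_Segment], dict]:
        segs: list[_Segment] = [
            _Segment("nflank", _flank(rng, cfg.nflank)),
        ]
        meta: dict = {}
        if cls in ("SMYD4", "ATYPICAL_TPR"):
            segs.append(_Segment("TPR_N", tpr_block.copy(), masked=True))
            segs.append(_Segment("linker1", _flank(rng, cfg.linker)))
        segs.append(_Segment("core", np.zeros(cfg.core_length, dtype=np.int64)))
        if cls in ("SMYD3", "SMYD4"):
            segs.append(_Segment("linker2", _flank(rng, cfg.linker)))
            segs.append(_Segment("CTD", _background(rng, cfg.ctd_length)))
            segs.append(_Segment("cflank", _flank(rng, cfg.cflank)))
        elif cls == "SMYD5":
            segs.append(_Segment("linker2", _flank(rng, cfg.linker)))
            segs.append(
                _Segment("ACIDIC", _acidic_block(cfg.acidic_length,
                                                 cfg.acidic_composition, rng),
                         masked=True)
            )
        elif cls == "ATYPICAL_TPR":
            segs.append(_Segment("linker2", _flank(rng, cfg.linker)))
            xblk, xrel, _, _ = build_finger_block(pattern, rng)
            meta["extra_rel"] = xrel
            segs.append(_Segment("MYND_EXTRA", xblk, masked=True))
            segs.append(_Segment("cflank", _flank(rng, cfg.cflank)))
        else:  # SMYDA: no shared C-terminal features
            segs.append(_Segment("cflank", _flank(rng, cfg.cflank)))
        return segs, meta

    seqs: list[ProteinSeq] = []
    per_seq: dict[str, SeqTruth] = {}
    core_span_abs: dict[str, tuple[int, int]] = {}
    annotations: dict[str, list[DomainAnnotation]] = {}
    core_rows: list[tuple[str, str]] = []

    for cls in classes:
        segs, meta = class_segments(cls)
        template = np.concatenate([s.arr for s in segs])
        mask = np.concatenate(
            [
                core_mask if s.name == "core"
                else np.full(s.arr.shape[0], s.masked and cfg.mask_features)
                for s in segs
            ]
        ).astype(bool)
        offsets: dict[str, int] = {}
        off = 0
        for s in segs:
            offsets[s.name] = off
            off += s.arr.shape[0]
        total_len = off
        core_off = offsets["core"]

        # absolute domain spans (identical for every member of the class)
        blk, rel, devs, cat = class_blocks[cls]
        spans: dict[str, tuple[int, int]] = {
            "SET_N": (core_off + 1, core_off + set_n_len),
            "MYND": (core_off + mynd_start + 1, core_off + mynd_start + mynd_len),
            "SET_C": (core_off + mynd_start + mynd_len + 1,
                      core_off + cfg.core_length - post_set_len),
            "POST_SET": (core_off + cfg.core_length - post_set_len + 1,
                         core_off + cfg.core_length),
        }
        if "TPR_N" in offsets:
            spans["TPR_N"] = (offsets["TPR_N"] + 1,
                              offsets["TPR_N"] + tpr_block.shape[0])
        if "CTD" in offsets:
            spans["CTD"] = (offsets["CTD"] + 1, offsets["CTD"] + cfg.ctd_length)
        if "ACIDIC" in offsets:
            spans["ACIDIC"] = (offsets["ACIDIC"] + 1,
                               offsets["ACIDIC"] + cfg.acidic_length)
        if "MYND_EXTRA" in offsets:
            spans["MYND_EXTRA"] = (
                offsets["MYND_EXTRA"] + 1,
                offsets["MYND_EXTRA"] + meta["extra_rel"][-1],
            )
        finger_pos = tuple(core_off + block_off + p for p in rel)
        extra = None
        if "MYND_EXTRA" in offsets:
            extra = PlantedFinger(
                positions=tuple(offsets["MYND_EXTRA"] + p for p in meta["extra_rel"]),
                deviations=(), category="canonical",
            )

        # the acidic-tract token is what the detector reports on the class
        # template (its longest-window rule may extend past the planted
        # block, shifting E -> ED/EDS)
        tract_token = None
        tract_span = spans.get("ACIDIC")
        if "ACIDIC" in spans:
            from .domain_architecture import detect_acidic_tract

            t_full = template.copy()
            t_full[core_off: core_off + cfg.core_length] = class_root_cores[cls]
            t_seq = ProteinSeq(
                id="template", residues="".join(AA_ORDER[i] for i in t_full),
                source="synthetic",
            )
            tr = detect_acidic_tract(t_seq)
            if tr is not None:
                tract_token = tr.composition_class
                tract_span = (tr.start, tr.end)
            else:
                tract_token = cfg.acidic_composition

        sig_tokens = []
        if "TPR_N" in spans:
            sig_tokens.append("TPR_N")
        sig_tokens.append("S/ET+M" if cat == "canonical" else "S/ET+m")
        if "MYND_EXTRA" in spans:
            sig_tokens.append("Mx")
        if "CTD" in spans:
            sig_tokens.append("CTD")
        if "ACIDIC" in spans:
            sig_tokens.append(tract_token)
        signature = "|".join(sig_tokens)

        # evolve the flank template along the class subtree, then splice the
        # per-leaf core evolved in phase A
        root = class_roots[cls]
        members: dict[str, np.ndarray] = {}

        def walk_full(node: dendropy.Node, s: np.ndarray) -> None:
            if node.is_leaf():
                members[node.taxon.label] = s
                return
            for ch in node.child_nodes():
                s2 = _mutate(s, ch.edge.length or 0.0, mask, cfg.model, rng)
                walk_full(ch, s2)

        walk_full(root, template)
        for name in sorted(members):
            full = members[name].copy()
            full[core_off: core_off + cfg.core_length] = core_leafs[name]
            res = "".join(AA_ORDER[i] for i in full)
            seqs.append(ProteinSeq(id=name, residues=res,
                                   species=leaf_meta[name][2], source="synthetic"))
            core_rows.append(
                (name, res[core_off: core_off + cfg.core_length])
            )
            core_span_abs[name] = (core_off + 1, core_off + cfg.core_length)
            annotations[name] = [
                DomainAnnotation(t, a, b, source="external")
                for t, (a, b) in spans.items()
                if t in ("TPR_N", "CTD", "SET_N", "MYND", "SET_C", "POST_SET")
            ]
            per_seq[name] = SeqTruth(
                label=cls,
                subgroup=leaf_meta[name][1],
                species=leaf_meta[name][2],
                finger=PlantedFinger(finger_pos, devs, cat),
                extra_finger=extra,
                domains=dict(spans),
                signature=signature,
                tract_span=tract_span,
            )

    seqs.sort(key=lambda s: s.id)
    core_rows.sort(key=lambda r: r[0])
    truth = SyntheticTruth(tree=tree, per_seq=per_seq, core_span=core_span_abs)
    return SyntheticFamily(
        seqs=seqs,
        core_alignment=Alignment(rows=core_rows),
        annotations=annotations,
        truth=truth,
        config=cfg,
    )
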