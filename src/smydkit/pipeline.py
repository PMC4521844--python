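"""End-to-end orchestration: filter -> core -> tree -> fingers -> domains ->
classify, with per-stage outputs and a summary table.

Alignment construction is deliberately external: the pipeline consumes a
user-supplied alignment (or the synthetic generator's true alignment); the
aligner is pluggable and out of scope here.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import dendropy
import pandas as pd

from . import homology_filter as hf
from .classification import (
    AnchorSet, ClassAssignment, assign_classes, assign_subgroups,
)
from .core_alignment import ColumnPolicy, CoreRegion, extract_core
from .domain_architecture import (
    Architecture, DomainAnnotation, SmydCore, architecture_class,
    assemble_architecture, read_annotations_tsv,
)
from .phylogeny import (
    BootstrapConfig, DistanceModel, bootstrap_support, distance_matrix,
    neighbor_joining,
)
from .seq_io import (
    Alignment, ProteinSeq, read_alignment, read_blast_tab, read_fasta,
    write_newick,
)
from .zinc_finger import (
    RelaxPolicy, ZnFingerHit, ZnPattern, best_finger,
    enumerate_candidate_fingers, select_disjoint,
)

logger = logging.getLogger("smydkit")


@dataclass
class PipelineConfig:
    """All stage parameters in one place.  Paths may be None when the
    corresponding stage is disabled or inputs are passed in memory."""

    out_dir: str | Path = "smydkit_out"
    seed: int = 0

    # filter stage
    run_filter: bool = False
    hits_path: str | Path | None = None
    reverse_hits_path: str | Path | None = None
    seed_ids: set[str] = field(default_factory=set)
    filter_core: tuple[str, int, int] | None = None
    evalue_max: float = 1e-7

    # inputs
    fasta_path: str | Path | None = None
    alignment_path: str | Path | None = None
    annotations_path: str | Path | None = None

    # core extraction
    run_core: bool = False
    core_reference: str | None = None
    core_span: tuple[int, int] = (18, 279)

    # tree stage
    run_tree: bool = True
    model: DistanceModel = field(default_factory=DistanceModel)
    policy: ColumnPolicy = field(default_factory=ColumnPolicy)
    bootstrap_replicates: int = 0

    # classification
    run_classify: bool = True
    anchors_path: str | Path | None = None
    anchors: AnchorSet | None = None
    min_support: float = 70.0

    # finger scan
    pattern: ZnPattern | None = None
    relax: RelaxPolicy = field(default_factory=RelaxPolicy)

    species_map: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineResult:
    verdicts: pd.DataFrame | None
    tree: dendropy.Tree | None
    fingers: dict[str, ZnFingerHit | None]
    extra_fingers: dict[str, list[ZnFingerHit]]
    architectures: dict[str, Architecture]
    assignments: list[ClassAssignment]
    summary: pd.DataFrame
    class_counts: pd.DataFrame


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _validate(cfg: PipelineConfig) -> None:
    for name in ("hits_path", "reverse_hits_path", "fasta_path",
                 "alignment_path", "annotations_path", "anchors_path"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{name} = {p} does not exist")
    if cfg.run_classify and cfg.anchors is None and cfg.anchors_path is None:
        raise ValueError("classification enabled but no anchor file given")
    if cfg.run_filter and (cfg.hits_path is None or cfg.filter_core is None):
        raise ValueError("filter stage enabled but hits/core not configured")
    if cfg.bootstrap_replicates > 0 and cfg.seed is None:
        raise ValueError("seed is mandatory when bootstrap is enabled")


def core_from_annotations(anns: list[DomainAnnotation]) -> SmydCore | None:
    spans = {a.type: (a.start, a.end) for a in anns}
    if all(t in spans for t in ("SET_N", "MYND", "SET_C", "POST_SET")):
        return SmydCore(
            set_n=spans["SET_N"], mynd=spans["MYND"],
            set_c=spans["SET_C"], post_set=spans["POST_SET"],
        )
    return None


def scan_sequence(
    seq: ProteinSeq,
    core: SmydCore | None,
    pattern: ZnPattern | None,
    relax: RelaxPolicy,
) -> tuple[ZnFingerHit | None, list[ZnFingerHit]]:
    """Best core finger plus disjoint extra fingers outside the core.

    When core coordinates are known the core-finger search is restricted to
    the MYND segment and flank searches to the regions outside the core
    (with the half-finger fallback off, to avoid noise); otherwise the whole
    sequence is scanned and the best disjoint set reported.
    """
    n = len(seq.residues)
    if core is None:
        hits = enumerate_candidate_fingers(seq, pattern, None, relax)
        chosen = select_disjoint(hits)
        return (chosen[0] if chosen else None), chosen[1:]
    pad = 5
    lo = max(1, core.mynd[0] - pad)
    hi = min(n, core.mynd[1] + pad)
    core_hits = enumerate_candidate_fingers(seq, pattern, (lo, hi), relax)
    best = best_finger(core_hits)
    flank_relax = RelaxPolicy(
        max_overshoot=relax.max_overshoot,
        max_overshoot_within=relax.max_overshoot_within,
        max_undershoot=relax.max_undershoot,
        allow_his_cys_swap=relax.allow_his_cys_swap,
        allow_glu=relax.allow_glu,
        allow_half=False,
    )
    extras: list[ZnFingerHit] = []
    for span in ((1, core.start - 1), (core.end + 1, n)):
        if span[1] - span[0] + 1 < 10:
            continue
        extras.extend(
            select_disjoint(
                enumerate_candidate_fingers(seq, pattern, span, flank_relax)
            )
        )
    return best, extras


def species_class_counts(
    assignments: list[ClassAssignment], species_map: dict[str, str]
) -> pd.DataFrame:
    """Rows = species, columns = class (with subgroup where set), cells =
    counts of classified sequences."""
    rows = []
    for a in assignments:
        col = a.label.smyd_class
        if a.label.subgroup:
            col = f"{col}/{a.label.subgroup}"
        rows.append({"species": species_map.get(a.seq_id, "unknown"), "class": col})
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    return df.groupby(["species", "class"]).size().unstack(fill_value=0)


def run_pipeline(
    cfg: PipelineConfig,
    seqs: list[ProteinSeq] | None = None,
    alignment: Alignment | None = None,
    annotations: dict[str, list[DomainAnnotation]] | None = None,
) -> PipelineResult:
    """Execute the configured stages; in-memory inputs override paths.

    Writes per-stage outputs under ``cfg.out_dir`` and returns every
    intermediate object.  A stage failure aborts with the stage name; files
    written by earlier stages are retained.
    """
    _validate(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("pipeline start %s", datetime.now(timezone.utc).isoformat())
    for name in ("fasta_path", "alignment_path", "annotations_path", "anchors_path"):
        p = getattr(cfg, name)
        if p is not None:
            logger.info("input %s=%s sha256:%s", name, p, _checksum(Path(p)))
    logger.info("params model=%s policy=%s bootstrap=%d seed=%s min_support=%s",
                cfg.model, cfg.policy, cfg.bootstrap_replicates, cfg.seed,
                cfg.min_support)

    verdicts_df = None
    try:
        if cfg.run_filter:
            hits = read_blast_tab(cfg.hits_path)
            fc = hf.FilterConfig(core=cfg.filter_core, evalue_max=cfg.evalue_max)
            verdicts = hf.filter_by_evalue_and_continuity(hits, fc)
            if cfg.reverse_hits_path is not None:
                rev = read_blast_tab(cfg.reverse_hits_path)
                verdicts = hf.reciprocal_best(verdicts, rev, cfg.seed_ids)
            verdicts_df = pd.DataFrame(
                [
                    {
                        "subject": v.subject,
                        "accepted": v.accepted,
                        **{r.rule: r.passed for r in v.reasons},
                    }
                    for v in verdicts
                ]
            )
            verdicts_df.to_csv(out / "filter_verdicts.tsv", sep="\t", index=False)
            logger.info("filter: %d/%d accepted",
                        int(verdicts_df.accepted.sum()), len(verdicts_df))
    except Exception as exc:
        raise RuntimeError(f"stage 'filter' failed: {exc}") from exc

    if seqs is None and cfg.fasta_path is not None:
        seqs = read_fasta(cfg.fasta_path)
    if alignment is None and cfg.alignment_path is not None:
        alignment = read_alignment(cfg.alignment_path)
    if annotations is None and cfg.annotations_path is not None:
        annotations = read_annotations_tsv(cfg.annotations_path)
    annotations = annotations or {}
    seqs = seqs or []

    try:
        if cfg.run_core and alignment is not None:
            block = extract_core(
                alignment,
                CoreRegion(cfg.core_reference, *cfg.core_span),
            )
            alignment = block.alignment
            if block.all_gap_ids:
                logger.info("core: all-gap rows flagged: %s", block.all_gap_ids)
    except Exception as exc:
        raise RuntimeError(f"stage 'core' failed: {exc}") from exc

    tree = None
    try:
        if cfg.run_tree and alignment is not None:
            D = distance_matrix(alignment, cfg.model, cfg.policy)
            tree = neighbor_joining(D)
            if cfg.bootstrap_replicates > 0:
                tree = bootstrap_support(
                    alignment, cfg.model, cfg.policy, tree,
                    BootstrapConfig(cfg.bootstrap_replicates, cfg.seed),
                )
            write_newick(tree, out / "nj_tree.nwk")
            logger.info("tree: %d taxa", len(D.taxa))
    except Exception as exc:
        raise RuntimeError(f"stage 'tree' failed: {exc}") from exc

    fingers: dict[str, ZnFingerHit | None] = {}
    extra_fingers: dict[str, list[ZnFingerHit]] = {}
    architectures: dict[str, Architecture] = {}
    try:
        for seq in seqs:
            anns = annotations.get(seq.id, [])
            core = core_from_annotations(anns)
            best, extras = scan_sequence(seq, core, cfg.pattern, cfg.relax)
            fingers[seq.id] = best
            extra_fingers[seq.id] = extras
            external = [a for a in anns if a.type in ("TPR_N", "CTD")]
            architectures[seq.id] = assemble_architecture(
                seq, core, best, external, extras
            )
        if seqs:
            pd.DataFrame(
                [
                    {
                        "id": s.id,
                        "finger_category": fingers[s.id].category if fingers[s.id] else "none",
                        "signature": architectures[s.id].signature,
                        "candidates": ",".join(sorted(architecture_class(architectures[s.id]))),
                    }
                    for s in seqs
                ]
            ).to_csv(out / "architectures.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'scan' failed: {exc}") from exc

    assignments: list[ClassAssignment] = []
    try:
        if cfg.run_classify and tree is not None:
            anchors = cfg.anchors or AnchorSet.from_tsv(cfg.anchors_path)
            assignments = assign_classes(tree, architectures, anchors, cfg.min_support)
            assignments = assign_subgroups(assignments, tree, anchors, cfg.min_support)
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    summary_rows = []
    for a in assignments:
        summary_rows.append(
            {
                "id": a.seq_id,
                "class": a.label.smyd_class,
                "subgroup": a.label.subgroup or "",
                "finger_category": fingers.get(a.seq_id).category
                if fingers.get(a.seq_id) else "none",
                "signature": a.evidence.architecture_signature,
                "clade_support": a.evidence.clade_support,
                "agreement": a.evidence.agreement,
            }
        )
    summary = pd.DataFrame(summary_rows)
    counts = species_class_counts(assignments, cfg.species_map)
    if not summary.empty:
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    if not counts.empty:
        counts.to_csv(out / "class_counts.tsv", sep="\t")
    logger.info("pipeline done")
    logger.removeHandler(handler)
    handler.close()
    return PipelineResult(
        verdicts=verdicts_df,
        tree=tree,
        fingers=fingers,
        extra_fingers=extra_fingers,
        architectures=architectures,
        assignments=assignments,
        summary=summary,
        class_counts=counts,
    )
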