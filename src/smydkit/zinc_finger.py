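"""Detection and categorisation of MYND-like cross-brace Zn fingers.

A MYND-type Zn finger consists of eight Zn-ligand residues (usually Cys,
more rarely His) arranged in four pairs with a cross-brace topology: pairs
1 and 3 coordinate the first Zn ion, pairs 2 and 4 the second.  Within-pair
spacing is short and nearly invariant while between-pair spacers are longer
and variable, the pair 1-2 spacer most of all.

The search enumerates every arrangement of candidate ligand residues that
satisfies a *relaxed* version of a signature pattern (bounds stretched, a
His/Cys swap or, optionally, a Glu ligand allowed) and then scores each
arrangement by its deviations from the *unrelaxed* signature.  Fingers are
categorised as canonical, partial (left or right portion intact), half
(pairs 1 and 3 only, binding a single Zn ion) or atypical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .seq_io import ProteinSeq

PAIR_OF_SLOT = (1, 1, 2, 2, 3, 3, 4, 4)  # 1-based pair index per ligand slot
#: gap index k (0..6) separates slots k and k+1; odd-position gaps are
#: within-pair spacers, even ones between-pair spacers
GAP_NAMES = ("pair1", "gap12", "pair2", "gap23", "pair3", "gap34", "pair4")
LEFT_LOCATIONS = frozenset({"pos1", "pos2", "pos3", "pos4", "pair1", "pair2", "gap12"})
RIGHT_LOCATIONS = frozenset({"pos5", "pos6", "pos7", "pos8", "pair3", "pair4", "gap34"})


@dataclass(frozen=True)
class ZnPattern:
    """A cross-brace Zn-finger signature.

    ``position_ligands`` lists the allowed residues at each of the eight
    ligand slots; spacer bounds count residues strictly between ligands.
    """

    name: str
    position_ligands: tuple[frozenset[str], ...]
    within_pair_spacers: tuple[tuple[int, int], ...]
    between_pair_spacers: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.position_ligands) != 8:
            raise ValueError("pattern must define 8 ligand slots")
        for lo, hi in self.within_pair_spacers + self.between_pair_spacers:
            if lo < 0 or lo > hi:
                raise ValueError("spacer bounds must satisfy 0 <= lo <= hi")

    @property
    def gap_bounds(self) -> tuple[tuple[int, int], ...]:
        """Bounds for the seven inter-ligand gaps, in slot order."""
        w, b = self.within_pair_spacers, self.between_pair_spacers
        return (w[0], b[0], w[1], b[1], w[2], b[2], w[3])

    @classmethod
    def from_json(cls, path: str | Path) -> "ZnPattern":
        d = json.loads(Path(path).read_text())
        return cls(
            name=d["name"],
            position_ligands=tuple(frozenset(x) for x in d["position_ligands"]),
            within_pair_spacers=tuple(tuple(x) for x in d["within_pair_spacers"]),
            between_pair_spacers=tuple(tuple(x) for x in d["between_pair_spacers"]),
        )

    @classmethod
    def default(cls) -> "ZnPattern":
        with resources.as_file(
            resources.files("smydkit.data") / "mynd_zn_pattern_synthetic.json"
        ) as p:
            return cls.from_json(p)

    def consensus_finger(self) -> str:
        """A peptide that matches the signature exactly (midpoint spacers)."""
        out: list[str] = []
        gb = self.gap_bounds
        for slot in range(8):
            if slot:
                lo, hi = gb[slot - 1]
                out.append("A" * ((lo + hi) // 2))
            lig = sorted(self.position_ligands[slot])
            out.append("C" if "C" in lig else lig[0])
        return "".join(out)


@dataclass(frozen=True)
class RelaxPolicy:
    """How far the search may stray from the signature while still reporting.

    Between-pair spacers may overshoot their upper bound by up to
    ``max_overshoot`` residues (generous, so very long pair 1-2 spacers
    remain findable).  Within-pair spacing is short and nearly invariant in
    cross-brace fingers, so it is relaxed separately and far less
    (``max_overshoot_within``).  All spacers may undershoot by up to
    ``max_undershoot``.  His/Cys swaps at ligand slots are tolerated by
    default; Glu as a ligand only when asked for.
    """

    max_overshoot: int = 100
    max_overshoot_within: int = 4
    max_undershoot: int = 3
    allow_his_cys_swap: bool = True
    allow_glu: bool = False
    allow_half: bool = True

    def ligand_universe(self, pattern: ZnPattern, slot: int) -> frozenset[str]:
        s = set(pattern.position_ligands[slot])
        if self.allow_his_cys_swap:
            s |= {"C", "H"}
        if self.allow_glu:
            s |= {"E"}
        return frozenset(s)

    def gap_bounds(self, pattern: ZnPattern) -> tuple[tuple[int, int], ...]:
        # gap order: pair1, gap12, pair2, gap23, pair3, gap34, pair4
        out = []
        for k, (lo, hi) in enumerate(pattern.gap_bounds):
            over = self.max_overshoot if k % 2 == 1 else self.max_overshoot_within
            out.append((max(0, lo - self.max_undershoot), hi + over))
        return tuple(out)


@dataclass(frozen=True)
class Deviation:
    kind: str       # spacing_long | spacing_short | ligand_substitution | missing_pair
    location: str   # pos1..pos8, pair1..pair4, gap12, gap23, gap34
    detail: str = ""


@dataclass(frozen=True)
class ZnFingerHit:
    """A candidate cross-brace Zn finger on one sequence.

    ``positions`` are 1-based ligand coordinates: eight for a full finger,
    four for a half finger (interpretable as pairs 1 and 3, binding a single
    Zn ion).  ``deviations`` are measured against the unrelaxed signature;
    ``score`` is their count (lower is better).
    """

    seq_id: str
    positions: tuple[int, ...]
    residues: tuple[str, ...]
    deviations: tuple[Deviation, ...]
    category: str  # canonical | partial_left | partial_right | half | atypical

    @property
    def score(self) -> int:
        return len(self.deviations)

    @property
    def span(self) -> tuple[int, int]:
        return self.positions[0], self.positions[-1]

    def spacers(self) -> dict[str, int]:
        """Inter-ligand gap lengths by name (full fingers only)."""
        if len(self.positions) != 8:
            return {}
        p = self.positions
        return {GAP_NAMES[k]: p[k + 1] - p[k] - 1 for k in range(7)}


def _deviations_full(
    residues: tuple[str, ...], positions: tuple[int, ...], pattern: ZnPattern
) -> tuple[Deviation, ...]:
    devs: list[Deviation] = []
    for slot in range(8):
        if residues[slot] not in pattern.position_ligands[slot]:
            devs.append(
                Deviation(
                    "ligand_substitution",
                    f"pos{slot + 1}",
                    f"{residues[slot]} at {positions[slot]} not in "
                    f"{{{','.join(sorted(pattern.position_ligands[slot]))}}}",
                )
            )
    gb = pattern.gap_bounds
    for k in range(7):
        gap = positions[k + 1] - positions[k] - 1
        lo, hi = gb[k]
        if gap > hi:
            devs.append(Deviation("spacing_long", GAP_NAMES[k], f"{gap} > {hi}"))
        elif gap < lo:
            devs.append(Deviation("spacing_short", GAP_NAMES[k], f"{gap} < {lo}"))
    return tuple(devs)


def categorize(
    deviations: tuple[Deviation, ...], n_positions: int = 8
) -> str:
    """Assign a finger category from its deviation list.

    canonical: no deviations.  half: only four ligand positions (pairs 1 and
    3).  partial_left / partial_right: the left (pairs 1-2) or right (pairs
    3-4) portion is deviation-free while the other is not; the pair 2-3
    spacer belongs to neither portion.  atypical: anything else.
    """
    if n_positions == 4:
        return "half"
    if not deviations:
        return "canonical"
    left_clean = not any(d.location in LEFT_LOCATIONS for d in deviations)
    right_clean = not any(d.location in RIGHT_LOCATIONS for d in deviations)
    if left_clean and not right_clean:
        return "partial_left"
    if right_clean and not left_clean:
        return "partial_right"
    return "atypical"


def _make_hit(
    seq: ProteinSeq, positions: tuple[int, ...], pattern: ZnPattern
) -> ZnFingerHit:
    residues = tuple(seq.residues[p - 1] for p in positions)
    devs = _deviations_full(residues, positions, pattern)
    return ZnFingerHit(
        seq_id=seq.id,
        positions=positions,
        residues=residues,
        deviations=devs,
        category=categorize(devs, len(positions)),
    )


def _half_hit(
    seq: ProteinSeq, positions: tuple[int, ...], pattern: ZnPattern
) -> ZnFingerHit:
    residues = tuple(seq.residues[p - 1] for p in positions)
    devs: list[Deviation] = [
        Deviation("missing_pair", "pair2", "no pair-2 ligands"),
        Deviation("missing_pair", "pair4", "no pair-4 ligands"),
    ]
    # the four ligands map to pattern slots 1,2,5,6
    for i, slot in enumerate((0, 1, 4, 5)):
        if residues[i] not in pattern.position_ligands[slot]:
            devs.append(
                Deviation("ligand_substitution", f"pos{slot + 1}",
                          f"{residues[i]} at {positions[i]}")
            )
    for pair_idx, (a, b) in enumerate(((0, 1), (2, 3))):
        gap = positions[b] - positions[a] - 1
        lo, hi = pattern.within_pair_spacers[0 if pair_idx == 0 else 2]
        name = "pair1" if pair_idx == 0 else "pair3"
        if gap > hi:
            devs.append(Deviation("spacing_long", name, f"{gap} > {hi}"))
        elif gap < lo:
            devs.append(Deviation("spacing_short", name, f"{gap} < {lo}"))
    return ZnFingerHit(
        seq_id=seq.id,
        positions=positions,
        residues=residues,
        deviations=tuple(devs),
        category="half",
    )


def enumerate_candidate_fingers(
    seq: ProteinSeq,
    pattern: ZnPattern | None = None,
    region: tuple[int, int] | None = None,
    relax: RelaxPolicy | None = None,
    max_hits: int | None = None,
) -> list[ZnFingerHit]:
    """Enumerate every full cross-brace finger satisfying the relaxed bounds.

    ``region`` restricts the search to a 1-based inclusive residue interval
    (default: whole sequence).  Hits are exhaustive over ligand octets within
    the relaxed bounds, deduplicated by construction, and each carries its
    deviation list relative to the unrelaxed signature.  If no full finger is
    found and the policy allows it, four-ligand half fingers (pairs 1 and 3
    only) are searched as a fallback.

    Hits are ordered by (score, first ligand position, span).
    """
    pattern = pattern or ZnPattern.default()
    relax = relax or RelaxPolicy()
    lo_r, hi_r = region if region is not None else (1, len(seq.residues))
    if not (1 <= lo_r <= hi_r <= len(seq.residues)):
        raise ValueError(
            f"region {region} outside sequence {seq.id!r} of length {len(seq.residues)}"
        )

    universes = [relax.ligand_universe(pattern, s) for s in range(8)]
    any_ligand = frozenset().union(*universes)
    cands = [
        p for p in range(lo_r, hi_r + 1) if seq.residues[p - 1] in any_ligand
    ]
    gaps = relax.gap_bounds(pattern)

    hits: list[ZnFingerHit] = []

    def extend(prefix: list[int], slot: int) -> None:
        if max_hits is not None and len(hits) >= max_hits:
            return
        if slot == 8:
            hits.append(_make_hit(seq, tuple(prefix), pattern))
            return
        if slot == 0:
            pool = cands
        else:
            lo_g, hi_g = gaps[slot - 1]
            prev = prefix[-1]
            pool = [p for p in cands if prev + 1 + lo_g <= p <= prev + 1 + hi_g]
        for p in pool:
            if seq.residues[p - 1] in universes[slot]:
                prefix.append(p)
                extend(prefix, slot + 1)
                prefix.pop()

    extend([], 0)

    if not hits and relax.allow_half:
        hits.extend(
            _enumerate_half(seq, pattern, relax, cands, universes)
        )

    hits.sort(key=lambda h: (h.score, h.positions[0], h.span[1] - h.span[0]))
    return hits


def _enumerate_half(seq, pattern, relax, cands, universes) -> list[ZnFingerHit]:
    w = pattern.within_pair_spacers
    b = pattern.between_pair_spacers
    u = relax.max_undershoot
    o = relax.max_overshoot
    ow = relax.max_overshoot_within
    pair1 = (max(0, w[0][0] - u), w[0][1] + ow)
    pair3 = (max(0, w[2][0] - u), w[2][1] + ow)
    # bridge spans gap12 + pair2 (two ligands) + gap23
    blo = max(0, b[0][0] + w[1][0] + 2 + b[1][0] - u)
    bhi = b[0][1] + w[1][1] + 2 + b[1][1] + o
    out: list[ZnFingerHit] = []
    for p1 in cands:
        if seq.residues[p1 - 1] not in universes[0]:
            continue
        for p2 in cands:
            if not (p1 + 1 + pair1[0] <= p2 <= p1 + 1 + pair1[1]):
                continue
            if seq.residues[p2 - 1] not in universes[1]:
                continue
            for p5 in cands:
                if not (p2 + 1 + blo <= p5 <= p2 + 1 + bhi):
                    continue
                if seq.residues[p5 - 1] not in universes[4]:
                    continue
                for p6 in cands:
                    if not (p5 + 1 + pair3[0] <= p6 <= p5 + 1 + pair3[1]):
                        continue
                    if seq.residues[p6 - 1] not in universes[5]:
                        continue
                    out.append(_half_hit(seq, (p1, p2, p5, p6), pattern))
    return out


def best_finger(hits: list[ZnFingerHit]) -> ZnFingerHit | None:
    """Minimum-score hit; ties by leftmost first ligand, then smallest span."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.score, h.positions[0], h.span[1] - h.span[0]))


def ss_consistency(
    hit: ZnFingerHit, ss: str | None, window: int = 6
) -> str:
    """Check a finger against secondary-structure evidence.

    ``ss`` is a per-residue string over {H, E, -}.  A cross-brace finger is
    ``supported`` when a beta-strand (E) run occurs immediately upstream of
    pair 3 and a helix (H) run overlaps the pair-3-to-pair-4 span; returns
    ``no_data`` when no prediction is supplied.
    """
    if ss is None:
        return "no_data"
    if len(hit.positions) < 8:
        return "no_data"
    p5, p8 = hit.positions[4], hit.positions[7]
    if len(ss) < p8:
        raise ValueError("secondary-structure string shorter than finger span")
    upstream = ss[max(0, p5 - 1 - window): p5 - 1]
    helix_span = ss[p5 - 1: p8]
    return "supported" if ("E" in upstream and "H" in helix_span) else "unsupported"


def select_disjoint(hits: list[ZnFingerHit]) -> list[ZnFingerHit]:
    """Greedy non-overlapping selection: best finger first, then any further
    finger whose span is disjoint from all already selected."""
    chosen: list[ZnFingerHit] = []
    for h in sorted(hits, key=lambda h: (h.score, h.positions[0], h.span[1] - h.span[0])):
        if all(h.span[1] < c.span[0] or h.span[0] > c.span[1] for c in chosen):
            chosen.append(h)
    return sorted(chosen, key=lambda h: h.positions[0])


def finger_report(
    seqs: list[ProteinSeq],
    pattern: ZnPattern | None = None,
    relax: RelaxPolicy | None = None,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Tabulate the best finger(s) per sequence.

    One row per selected (disjoint) finger: category, ligand positions,
    inter-pair spacer lengths and a deviation summary.  Sequences with no
    detectable finger get a single row with category ``none``.
    """
    cols = [
        "id", "category", "score",
        "p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8",
        "spacer12", "spacer23", "spacer34", "deviations",
    ]
    rows = []
    for seq in seqs:
        hits = enumerate_candidate_fingers(seq, pattern, region, relax)
        chosen = select_disjoint(hits)
        if not chosen:
            rows.append({"id": seq.id, "category": "none", "score": pd.NA,
                         "deviations": ""})
            continue
        for h in chosen:
            sp = h.spacers()
            row: dict = {"id": seq.id, "category": h.category, "score": h.score}
            for i, p in enumerate(h.positions, start=1):
                row[f"p{i}"] = p
            row["spacer12"] = sp.get("gap12", pd.NA)
            row["spacer23"] = sp.get("gap23", pd.NA)
            row["spacer34"] = sp.get("gap34", pd.NA)
            row["deviations"] = ";".join(
                f"{d.kind}@{d.location}" for d in h.deviations
            )
            rows.append(row)
    return pd.DataFrame(rows, columns=cols)
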