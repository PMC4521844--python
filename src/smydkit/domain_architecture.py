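"""Class-diagnostic sequence features and per-protein domain architectures.

Each Smyd class carries a characteristic arrangement of flanking features
around the interrupted SET core: a C-terminal TPR-fold domain (Smyd3,
Smyd4), an additional N-terminal TPR domain (Smyd4, atypical TPR-Smyd), a
C-terminal acidic tract of Glu / Glu+Asp / Glu+Asp+Ser (Smyd5), an extra
MYND finger outside the core (atypical TPR-Smyd C-terminally, some SmydA
N-terminally), or no shared C-terminal features at all (SmydA).

External domain annotations (e.g. PFAM/InterPro TSV exports) are
first-class inputs; the bundled TPR heuristic exists only so the synthetic
pipeline runs without external tools and is always subordinate to them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .seq_io import ProteinSeq
from .zinc_finger import ZnFingerHit

DOMAIN_TYPES = ("TPR_N", "SET_N", "MYND", "SET_C", "POST_SET", "CTD", "MYND_EXTRA", "ACIDIC")
CORE_TYPES = ("SET_N", "MYND", "SET_C", "POST_SET")
CLASS_LABELS = ("SMYD3", "SMYD4", "SMYD5", "SMYDA", "ATYPICAL_TPR", "UNCLASSIFIED")


@dataclass(frozen=True)
class AcidicTract:
    """A C-terminal-anchored acidic stretch (1-based inclusive coords)."""

    start: int
    end: int
    frac_e: float
    frac_d: float
    frac_s: float
    composition_class: str  # E | ED | EDS


def detect_acidic_tract(
    seq: ProteinSeq, min_len: int = 10, min_fraction: float = 0.6
) -> AcidicTract | None:
    """Longest window ending at the C terminus whose E+D+S content reaches
    ``min_fraction``; returns None when no window of ``min_len`` qualifies.

    The composition class is E when glutamate alone reaches the threshold,
    ED when glutamate+aspartate do, EDS otherwise.
    """
    res = seq.residues
    n = len(res)
    best_len = 0
    for L in range(min_len, n + 1):
        window = res[n - L:]
        if (window.count("E") + window.count("D") + window.count("S")) / L >= min_fraction:
            best_len = L
    if best_len == 0:
        return None
    window = res[n - best_len:]
    fe = window.count("E") / best_len
    fd = window.count("D") / best_len
    fs = window.count("S") / best_len
    if fe >= min_fraction:
        comp = "E"
    elif fe + fd >= min_fraction:
        comp = "ED"
    else:
        comp = "EDS"
    return AcidicTract(
        start=n - best_len + 1, end=n, frac_e=fe, frac_d=fd, frac_s=fs,
        composition_class=comp,
    )


@dataclass(frozen=True)
class DomainAnnotation:
    type: str
    start: int
    end: int
    source: str = "detector"  # detector | external

    def __post_init__(self) -> None:
        if self.type not in DOMAIN_TYPES:
            raise ValueError(f"unknown domain type {self.type!r}")
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad span {self.start}-{self.end} for {self.type}")


@dataclass(frozen=True)
class SmydCore:
    """Spans of the interrupted-SET core components, 1-based inclusive."""

    set_n: tuple[int, int]
    mynd: tuple[int, int]
    set_c: tuple[int, int]
    post_set: tuple[int, int]

    def __post_init__(self) -> None:
        spans = [self.set_n, self.mynd, self.set_c, self.post_set]
        for (a, b) in spans:
            if a > b:
                raise ValueError("core span start > end")
        for (_, b), (a2, _) in zip(spans, spans[1:]):
            if a2 <= b:
                raise ValueError("core spans overlap or are out of order")

    @property
    def start(self) -> int:
        return self.set_n[0]

    @property
    def end(self) -> int:
        return self.post_set[1]


@dataclass
class Architecture:
    """Ordered domain annotations plus the class-diagnostic signature.

    The signature collapses the four core components into one token:
    ``S/ET+M`` when the core finger is canonical, ``S/ET+m`` when it is
    degenerate, ``S/ET`` when no core finger was found.  Flanking tokens are
    ``TPR_N``, ``CTD``, ``Mx`` (extra MYND finger) and the acidic-tract
    composition class (``E``/``ED``/``EDS``), in N-to-C order.
    """

    annotations: list[DomainAnnotation]
    signature: str
    tract: AcidicTract | None = None
    core_finger_category: str | None = None


def _merge_same_type(anns: list[DomainAnnotation]) -> list[DomainAnnotation]:
    anns = sorted(anns, key=lambda a: (a.start, a.end, a.type))
    out: list[DomainAnnotation] = []
    for a in anns:
        if out and out[-1].type == a.type and a.start <= out[-1].end + 1:
            prev = out.pop()
            a = DomainAnnotation(
                type=a.type, start=prev.start, end=max(prev.end, a.end),
                source="external" if "external" in (prev.source, a.source) else "detector",
            )
        out.append(a)
    return out


def assemble_architecture(
    seq: ProteinSeq,
    core: SmydCore | None,
    finger: ZnFingerHit | None = None,
    external: list[DomainAnnotation] | None = None,
    extra_fingers: list[ZnFingerHit] | None = None,
    min_tract_len: int = 10,
    min_tract_fraction: float = 0.6,
) -> Architecture:
    """Merge detector outputs with external annotations into an architecture.

    ``finger`` is the best core Zn finger; any finger in ``extra_fingers``
    lying outside the core becomes a ``MYND_EXTRA`` annotation.  The acidic
    tract is detected here; TPR_N/CTD normally arrive via ``external``.
    """
    anns: list[DomainAnnotation] = []
    core_fc: str | None = None
    if core is not None:
        anns += [
            DomainAnnotation("SET_N", *core.set_n),
            DomainAnnotation("MYND", *core.mynd),
            DomainAnnotation("SET_C", *core.set_c),
            DomainAnnotation("POST_SET", *core.post_set),
        ]
    if finger is not None:
        if core is not None and not (finger.span[1] < core.mynd[0] or finger.span[0] > core.mynd[1]):
            core_fc = finger.category
        else:
            anns.append(DomainAnnotation("MYND_EXTRA", finger.span[0], finger.span[1]))
    for f in extra_fingers or []:
        if core is None or f.span[1] < core.start or f.span[0] > core.end:
            anns.append(DomainAnnotation("MYND_EXTRA", f.span[0], f.span[1]))
    tract = detect_acidic_tract(seq, min_tract_len, min_tract_fraction)
    if tract is not None:
        anns.append(DomainAnnotation("ACIDIC", tract.start, tract.end))
    anns += list(external or [])
    anns = _merge_same_type(anns)

    # build the signature in N->C order
    tokens: list[str] = []
    core_token_emitted = False
    for a in anns:
        if a.type in CORE_TYPES:
            if not core_token_emitted:
                if core_fc == "canonical":
                    tokens.append("S/ET+M")
                elif core_fc is not None:
                    tokens.append("S/ET+m")
                else:
                    tokens.append("S/ET")
                core_token_emitted = True
        elif a.type == "TPR_N":
            tokens.append("TPR_N")
        elif a.type == "CTD":
            tokens.append("CTD")
        elif a.type == "MYND_EXTRA":
            tokens.append("Mx")
        elif a.type == "ACIDIC":
            tokens.append(tract.composition_class if tract else "E")
    return Architecture(
        annotations=anns,
        signature="|".join(tokens),
        tract=tract,
        core_finger_category=core_fc,
    )


def architecture_class(arch: Architecture) -> set[str]:
    """Candidate Smyd classes implied by the architecture signature alone.

    A pure function of the signature; an empty set means the architecture is
    ambiguous and classification must fall back to tree evidence.
    """
    tokens = arch.signature.split("|") if arch.signature else []
    core_idx = next(
        (i for i, t in enumerate(tokens) if t.startswith("S/ET")), None
    )
    if core_idx is None:
        return set()
    core_token = tokens[core_idx]
    pre, post = tokens[:core_idx], tokens[core_idx + 1:]
    has_tpr_n = "TPR_N" in pre
    has_ctd = "CTD" in post
    has_acidic = any(t in {"E", "ED", "EDS"} for t in post)
    mx_c = "Mx" in post
    mx_n = "Mx" in pre
    noncanonical_core = core_token == "S/ET+m"

    if has_tpr_n and has_ctd:
        return {"SMYD4"}
    if has_ctd and not has_tpr_n:
        return {"SMYD3"}
    if has_acidic and not has_ctd and not has_tpr_n:
        return {"SMYD5"}
    if has_tpr_n and mx_c:
        return {"ATYPICAL_TPR"}
    if (not has_tpr_n and not has_ctd and not has_acidic and not mx_c
            and noncanonical_core):
        return {"SMYDA"}
    return set()


# ---------------------------------------------------------------------------
# Fallback TPR detector (subordinate to external annotations).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TprProfile:
    consensus: str
    weights: tuple[float, ...]

    @classmethod
    def default(cls) -> "TprProfile":
        with resources.as_file(
            resources.files("smydkit.data") / "tpr_profile_synthetic.json"
        ) as p:
            d = json.loads(Path(p).read_text())
        return cls(consensus=d["consensus"], weights=tuple(d["weights"]))

    def score(self, window: str) -> float:
        total = sum(self.weights)
        got = sum(
            w for ch, c, w in zip(window, self.consensus, self.weights) if ch == c
        )
        return got / total


def detect_tpr_heuristic(
    seq: ProteinSeq,
    profile: TprProfile | None = None,
    threshold: float = 0.7,
) -> list[DomainAnnotation]:
    """Flag blocks of degenerate 34-residue repeats matching the bundled
    TPR profile.  Windows scoring >= ``threshold`` are merged into blocks.
    """
    profile = profile or TprProfile.default()
    L = len(profile.consensus)
    res = seq.residues
    spans: list[tuple[int, int]] = []
    for i in range(0, len(res) - L + 1):
        if profile.score(res[i: i + L]) >= threshold:
            spans.append((i + 1, i + L))
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [DomainAnnotation("TPR_N", s, e, source="detector") for s, e in merged]


def read_annotations_tsv(path: str | Path) -> dict[str, list[DomainAnnotation]]:
    """Read external domain annotations: TSV of id, type, start, end."""
    out: dict[str, list[DomainAnnotation]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            rid, typ, s, e = parts[0], parts[1], int(parts[2]), int(parts[3])
            out.setdefault(rid, []).append(DomainAnnotation(typ, s, e, source="external"))
    return out


def write_annotations_tsv(anns: dict[str, list[DomainAnnotation]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("id\ttype\tstart\tend\n")
        for rid in sorted(anns):
            for a in anns[rid]:
                fh.write(f"{rid}\t{a.type}\t{a.start}\t{a.end}\n")
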