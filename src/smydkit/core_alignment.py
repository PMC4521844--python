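"""Reference-anchored extraction of the SET-MYND core and gap-column policies.

The study trims the family alignment to the contiguous block spanned by a
fixed residue interval of a reference sequence (human SMYD1 residues 18-279),
then handles gapped columns either globally (partial/complete deletion) or
per sequence pair (pairwise deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq_io import GAP, Alignment


@dataclass(frozen=True)
class CoreRegion:
    """Residue interval on the ungapped reference, 1-based inclusive."""

    reference_id: str
    ref_start: int = 18
    ref_end: int = 279

    def __post_init__(self) -> None:
        if not (1 <= self.ref_start <= self.ref_end):
            raise ValueError("require 1 <= ref_start <= ref_end")


@dataclass(frozen=True)
class ColumnPolicy:
    """How gapped alignment columns enter distance computations.

    ``partial_deletion`` keeps columns whose non-gap fraction is at least
    ``coverage_cutoff`` (ties kept); ``complete_deletion`` keeps only gap-free
    columns; ``pairwise_deletion`` keeps every column and defers to per-pair
    shared non-gap sites.
    """

    mode: str = "pairwise_deletion"
    coverage_cutoff: float = 0.65

    def __post_init__(self) -> None:
        if self.mode not in {"partial_deletion", "pairwise_deletion", "complete_deletion"}:
            raise ValueError(f"unknown column policy mode {self.mode!r}")
        if not (0 < self.coverage_cutoff <= 1):
            raise ValueError("coverage_cutoff must be in (0, 1]")


@dataclass
class CoreBlock:
    """Result of :func:`extract_core`."""

    alignment: Alignment
    col_start: int  # 1-based alignment column of reference residue ref_start
    col_end: int    # 1-based alignment column of reference residue ref_end
    all_gap_ids: list[str] = field(default_factory=list)


def extract_core(al: Alignment, core: CoreRegion) -> CoreBlock:
    """Slice the contiguous block of columns holding reference residues
    ``ref_start..ref_end`` (1-based, inclusive).

    Rows that are entirely gaps inside the block are retained but reported in
    ``all_gap_ids`` so callers can drop or flag them.
    """
    try:
        ref_row = al.row(core.reference_id)
    except KeyError:
        raise ValueError(f"reference id {core.reference_id!r} not in alignment") from None

    # map ungapped reference position -> 0-based alignment column
    cols = [i for i, ch in enumerate(ref_row) if ch != GAP]
    if len(cols) < core.ref_end:
        raise ValueError(
            f"reference {core.reference_id!r} has {len(cols)} residues, "
            f"shorter than ref_end={core.ref_end}"
        )
    c0 = cols[core.ref_start - 1]
    c1 = cols[core.ref_end - 1]
    block = al.subset_columns(range(c0, c1 + 1))
    all_gap = [rid for rid, s in block.rows if set(s) <= {GAP}]
    return CoreBlock(alignment=block, col_start=c0 + 1, col_end=c1 + 1, all_gap_ids=all_gap)


def apply_column_policy(
    al: Alignment, policy: ColumnPolicy
) -> tuple[list[int], dict[tuple[str, str], np.ndarray] | None]:
    """Apply a gap-column policy.

    Returns ``(kept, pair_map)`` where ``kept`` is the list of 0-based column
    indices retained globally and ``pair_map`` (pairwise deletion only) maps
    each unordered id pair to the boolean mask, over the kept columns, of
    sites where both rows are non-gap.  All-gap columns are dropped under
    every mode.
    """
    if al.n_rows == 0:
        raise ValueError("empty alignment")
    mat = np.array([list(s) for _, s in al.rows])
    nongap = mat != GAP
    frac = nongap.mean(axis=0)

    if policy.mode == "complete_deletion":
        kept = [i for i in range(al.n_cols) if frac[i] == 1.0]
        return kept, None
    if policy.mode == "partial_deletion":
        kept = [i for i in range(al.n_cols) if frac[i] >= policy.coverage_cutoff and frac[i] > 0]
        return kept, None

    kept = [i for i in range(al.n_cols) if frac[i] > 0]
    ids = al.ids
    pair_map: dict[tuple[str, str], np.ndarray] = {}
    sub = nongap[:, kept]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pair_map[(ids[i], ids[j])] = sub[i] & sub[j]
    return kept, pair_map
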