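"""Readers and writers for the formats the pipeline touches.

Protein FASTA, aligned FASTA, Clustal, 12-column BLAST tabular output and
Newick trees.  Parsing of FASTA/Clustal is delegated to Biopython and Newick
to dendropy; this module adds the strict validation the pipeline relies on
(unique ids, legal residue alphabet, rectangular alignments, numeric BLAST
fields) and normalises everything into small plain containers.

All coordinates in this package are 1-based and inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import AlignIO, SeqIO

#: The 20 standard amino acids plus X for unknown residues.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"


class SeqIOError(ValueError):
    """Raised when an input file violates a format invariant."""


@dataclass(frozen=True)
class ProteinSeq:
    """A validated protein sequence.

    ``residues`` holds uppercase one-letter codes restricted to the 20
    standard amino acids plus ``X``; gap characters are never allowed.
    """

    id: str
    residues: str
    species: str | None = None
    source: str = "unknown"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence id must be non-empty")
        if not self.residues:
            raise SeqIOError(f"sequence {self.id!r}: empty residue string")
        for pos, ch in enumerate(self.residues, start=1):
            if ch == GAP:
                raise SeqIOError(
                    f"sequence {self.id!r}: gap character '-' at position {pos}; "
                    "ungapped protein sequences may not contain gaps"
                )
            if ch not in VALID_RESIDUES:
                raise SeqIOError(
                    f"sequence {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A rectangular multiple alignment with '-' as the gap character."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.rows:
            ncol = len(self.rows[0][1])
            bad = [rid for rid, s in self.rows if len(s) != ncol]
            if bad:
                raise SeqIOError(
                    "alignment rows have unequal lengths; offending ids: "
                    + ", ".join(sorted(set(bad)))
                )
        seen: set[str] = set()
        for rid, _ in self.rows:
            if rid in seen:
                raise SeqIOError(f"duplicate row id {rid!r} in alignment")
            seen.add(rid)
        for rid, s in self.rows:
            for pos, ch in enumerate(s, start=1):
                if ch != GAP and ch not in VALID_RESIDUES:
                    raise SeqIOError(
                        f"alignment row {rid!r}: illegal character {ch!r} at column {pos}"
                    )

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def ungapped(self, rid: str) -> ProteinSeq:
        return ProteinSeq(id=rid, residues=self.row(rid).replace(GAP, ""), source="alignment")

    def subset_columns(self, cols: Sequence[int]) -> "Alignment":
        """New alignment keeping the given 0-based column indices, in order."""
        return Alignment(rows=[(rid, "".join(s[c] for c in cols)) for rid, s in self.rows])


@dataclass(frozen=True)
class BlastHitRow:
    """One line of 12-column tabular BLAST output (outfmt 6)."""

    query: str
    subject: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise SeqIOError(
                f"hit {self.query}->{self.subject}: qstart {self.qstart} > qend {self.qend}"
            )
        if self.evalue < 0:
            raise SeqIOError(f"hit {self.query}->{self.subject}: negative evalue")


def read_fasta(path: str | Path, source: str | None = None) -> list[ProteinSeq]:
    """Read a protein FASTA file into validated :class:`ProteinSeq` records.

    The id is the token up to the first whitespace; the remainder of the
    defline is stored as ``description``.  Duplicate ids and illegal residue
    characters raise :class:`SeqIOError`.
    """
    path = Path(path)
    records: list[ProteinSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            ProteinSeq(
                id=rec.id,
                residues=str(rec.seq).upper(),
                source=source or str(path),
                description=desc,
            )
        )
    return records


def write_fasta(seqs: Iterable[ProteinSeq], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            header = f">{s.id}" + (f" {s.description}" if s.description else "")
            fh.write(header + "\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> Alignment:
    """Read a multiple alignment in aligned-FASTA or Clustal format."""
    path = Path(path)
    if dialect == "aligned-fasta":
        rows: list[tuple[str, str]] = []
        for rec in SeqIO.parse(str(path), "fasta"):
            rows.append((rec.id, str(rec.seq).upper()))
    elif dialect == "clustal":
        msa = AlignIO.read(str(path), "clustal")
        rows = [(rec.id, str(rec.seq).upper()) for rec in msa]
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if not rows:
        raise SeqIOError(f"{path}: alignment contains no rows")
    return Alignment(rows=rows)


def write_alignment(al: Alignment, path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rid, s in al.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


_NUM_INT = re.compile(r"^-?\d+$")


def read_blast_tab(path: str | Path) -> list[BlastHitRow]:
    """Parse 12-column tabular BLAST output; extra columns are ignored.

    Lines starting with '#' are treated as comments.  Malformed numeric
    fields raise :class:`SeqIOError` naming the line.
    """
    path = Path(path)
    hits: list[BlastHitRow] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise SeqIOError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, got {len(parts)}"
                )
            try:
                hits.append(
                    BlastHitRow(
                        query=parts[0],
                        subject=parts[1],
                        pident=float(parts[2]),
                        length=int(parts[3]),
                        mismatch=int(parts[4]),
                        gapopen=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except (ValueError, SeqIOError) as exc:
                if isinstance(exc, SeqIOError):
                    raise
                raise SeqIOError(f"{path}:{lineno}: malformed numeric field ({exc})") from exc
    return hits


def write_blast_tab(hits: Iterable[BlastHitRow], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query, h.subject, h.pident, h.length, h.mismatch, h.gapopen,
                        h.qstart, h.qend, h.sstart, h.send, h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick trees.  Trees are dendropy.Tree objects throughout the package;
# bootstrap supports are stored as internal-node labels (percentages 0-100).
# ---------------------------------------------------------------------------

def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    s = str(path_or_string)
    try:
        p = Path(s)
        if p.exists():
            s = p.read_text()
    except OSError:  # literal Newick too long to be a file name
        pass
    try:
        tree = dendropy.Tree.get(
            data=s,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise SeqIOError(f"malformed Newick: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree to Newick; internal-node labels carry supports."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s
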