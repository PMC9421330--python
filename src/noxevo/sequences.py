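"""Protein sequence and alignment handling for NOX-family curation.

Covers FASTA I/O, pairwise identity/similarity from a raw multiple sequence
alignment, identity-threshold dataset curation against a set of canonical
reference sequences, gap-based alignment trimming, and per-column residue
frequency tables.

Coordinates are 0-based half-open internally; every user-facing report is
1-based inclusive (the convention used for residue landmarks such as H119).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: 20 standard residues plus X for an unknown residue.
ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"

#: Default similarity grouping used when counting "similar" residue pairs.
#: The groups are conventional physicochemical classes; they are configurable
#: because published identity/similarity servers do not agree on one set.
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("DE"),
    frozenset("KRH"),
    frozenset("ST"),
    frozenset("ILVM"),
    frozenset("FYW"),
    frozenset("NQ"),
    frozenset("AG"),
)

#: Default per-column gap-fraction ceiling for trimming.
DEFAULT_GAP_FRACTION = 0.5
#: Conservative preset that keeps nearly every column so lineage-specific
#: domains (EF-hands, the DUOX N-terminal extension) survive the trim.
CONSERVATIVE_GAP_FRACTION = 0.9


class SequenceError(ValueError):
    """Raised on malformed sequence or alignment input."""


@dataclass(frozen=True)
class ProteinRecord:
    """An ungapped protein sequence.

    Parameters
    ----------
    id:
        Unique identifier within a collection.
    seq:
        Amino-acid string over the 20-letter alphabet plus ``X``.
    description:
        Free-text description (FASTA header remainder).
    taxon_group:
        Optional coarse taxon label, e.g. ``Metazoa`` or ``early-divergent``.
    """

    id: str
    seq: str
    description: str = ""
    taxon_group: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if GAP in self.seq:
            raise SequenceError(
                f"record {self.id!r}: gap characters are not allowed in an "
                "unaligned sequence"
            )
        bad = sorted(set(self.seq) - ALPHABET)
        if bad:
            raise SequenceError(
                f"record {self.id!r}: illegal residue characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Alignment:
    """A multiple sequence alignment with '-' as the gap character.

    ``rows`` are aligned strings of equal length, ordered as read; ``ids``
    share the id space of :class:`ProteinRecord`.
    """

    ids: list[str]
    rows: list[str]
    descriptions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise SequenceError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise SequenceError("duplicate ids in alignment")
        if not self.descriptions:
            self.descriptions = [""] * len(self.ids)
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise SequenceError(f"rows have unequal lengths: {sorted(lengths)}")
        for rid, row in zip(self.ids, self.rows):
            bad = sorted(set(row) - ALPHABET - {GAP})
            if bad:
                raise SequenceError(f"row {rid!r}: illegal characters {bad}")

    @property
    def length(self) -> int:
        """Number of columns."""
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise KeyError(f"id {rid!r} not in alignment") from None

    def ungapped(self, rid: str) -> ProteinRecord:
        """Strip gaps from one row, recovering its :class:`ProteinRecord`."""
        i = self.ids.index(rid)
        return ProteinRecord(
            id=rid, seq=self.rows[i].replace(GAP, ""),
            description=self.descriptions[i],
        )

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def residue_to_column(self, rid: str) -> list[int]:
        """Map each ungapped residue index (0-based) of a row to its column."""
        return [j for j, c in enumerate(self.row(rid)) if c != GAP]

    def subset(self, keep_ids: Sequence[str]) -> "Alignment":
        keep = list(keep_ids)
        idx = [self.ids.index(r) for r in keep]
        return Alignment(
            ids=keep,
            rows=[self.rows[i] for i in idx],
            descriptions=[self.descriptions[i] for i in idx],
        )


@dataclass
class IdentityMatrix:
    """Pairwise identity and similarity fractions over an alignment."""

    ids: list[str]
    identity: np.ndarray
    similarity: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for m in (self.identity, self.similarity):
            if m.shape != (n, n):
                raise SequenceError("matrix shape does not match ids")

    def pair(self, id_a: str, id_b: str) -> tuple[float, float]:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.identity[i, j]), float(self.similarity[i, j])

    def to_tsv(self, which: str = "identity") -> str:
        m = self.identity if which == "identity" else self.similarity
        lines = ["\t".join(["id"] + self.ids)]
        for rid, row in zip(self.ids, m):
            lines.append("\t".join([rid] + [f"{v:.6f}" for v in row]))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FASTA I/O


def _records_from_seqio(entries, *, aligned: bool) -> tuple[list, list, list]:
    ids: list[str] = []
    seqs: list[str] = []
    descs: list[str] = []
    for rec in entries:
        seq = str(rec.seq).upper().replace("*", "")
        if rec.id in ids:
            raise SequenceError(f"duplicate id {rec.id!r} in FASTA input")
        ids.append(rec.id)
        seqs.append(seq)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        descs.append(desc)
    if not ids:
        raise SequenceError("empty FASTA input")
    return ids, seqs, descs


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read ungapped protein records from a FASTA file.

    Stop symbols (``*``) are stripped and lowercase letters uppercased.
    Duplicate ids, gaps, empty input and illegal residue characters raise
    :class:`SequenceError`.
    """
    ids, seqs, descs = _records_from_seqio(
        SeqIO.parse(str(path), "fasta"), aligned=False
    )
    return [
        ProteinRecord(id=i, seq=s, description=d)
        for i, s, d in zip(ids, seqs, descs)
    ]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for k in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[k:k + wrap] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    ids, seqs, descs = _records_from_seqio(
        SeqIO.parse(str(path), "fasta"), aligned=True
    )
    return Alignment(ids=ids, rows=seqs, descriptions=descs)


def write_alignment(alignment: Alignment, path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row, desc in zip(alignment.ids, alignment.rows, alignment.descriptions):
            fh.write(f">{rid}" + (f" {desc}" if desc else "") + "\n")
            for k in range(0, len(row), wrap):
                fh.write(row[k:k + wrap] + "\n")


# ---------------------------------------------------------------------------
# Identity / similarity


def _group_lookup(groups: Sequence[frozenset[str]]) -> dict[str, int]:
    lut: dict[str, int] = {}
    for gi, g in enumerate(groups):
        for aa in g:
            lut[aa] = gi
    return lut


def pairwise_identity(
    alignment: Alignment,
    id_a: str,
    id_b: str,
    *,
    groups: Sequence[frozenset[str]] = DEFAULT_SIMILARITY_GROUPS,
    denominator: str = "union",
) -> tuple[float, float]:
    """Identity and similarity fractions for one pair of aligned rows.

    ``denominator="union"`` scores every column where at least one of the two
    rows is non-gap (gap-gap columns are excluded); ``"ungapped_pair"``
    restricts to columns where both rows are non-gap. ``X`` never counts as a
    match. Similarity additionally counts non-identical pairs that fall in
    the same similarity group.
    """
    ra, rb = alignment.row(id_a), alignment.row(id_b)
    lut = _group_lookup(groups)
    denom = ident = simil = 0
    for ca, cb in zip(ra, rb):
        if ca == GAP and cb == GAP:
            continue
        if denominator == "ungapped_pair" and (ca == GAP or cb == GAP):
            continue
        denom += 1
        if ca == GAP or cb == GAP or ca == "X" or cb == "X":
            continue
        if ca == cb:
            ident += 1
            simil += 1
        elif lut.get(ca, -1) == lut.get(cb, -2):
            simil += 1
    if denom == 0:
        raise SequenceError(
            f"no comparable columns between {id_a!r} and {id_b!r}"
        )
    return ident / denom, simil / denom


def identity_matrix(
    alignment: Alignment,
    *,
    groups: Sequence[frozenset[str]] = DEFAULT_SIMILARITY_GROUPS,
    denominator: str = "union",
) -> IdentityMatrix:
    """All-pairs identity/similarity matrix (symmetric, unit diagonal)."""
    n = len(alignment)
    ident = np.eye(n)
    simil = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, s = pairwise_identity(
                alignment, alignment.ids[i], alignment.ids[j],
                groups=groups, denominator=denominator,
            )
            ident[i, j] = ident[j, i] = a
            simil[i, j] = simil[j, i] = s
    return IdentityMatrix(ids=list(alignment.ids), identity=ident, similarity=simil)


@dataclass(frozen=True)
class RemovalEntry:
    """One curation removal: the sequence, its best reference and identity."""

    id: str
    best_ref: str
    identity: float


def filter_by_identity(
    alignment: Alignment,
    canonical_refs: Sequence[str],
    threshold: float = 0.20,
    *,
    groups: Sequence[frozenset[str]] = DEFAULT_SIMILARITY_GROUPS,
    denominator: str = "union",
) -> tuple[Alignment, list[RemovalEntry]]:
    """Remove rows whose identity to *every* canonical reference is below
    ``threshold``.

    References themselves are always retained. Returns the retained alignment
    (original order) and a removal log.
    """
    if not canonical_refs:
        raise SequenceError("canonical reference set must be non-empty")
    for ref in canonical_refs:
        if ref not in alignment.ids:
            raise SequenceError(f"canonical reference {ref!r} not in alignment")
    if not 0 <= threshold <= 1:
        raise SequenceError("threshold must be in [0, 1]")
    refs = set(canonical_refs)
    keep: list[str] = []
    removed: list[RemovalEntry] = []
    for rid in alignment.ids:
        if rid in refs:
            keep.append(rid)
            continue
        best_ref, best = None, -1.0
        for ref in canonical_refs:
            ident, _ = pairwise_identity(
                alignment, rid, ref, groups=groups, denominator=denominator
            )
            if ident > best:
                best_ref, best = ref, ident
        if best >= threshold:
            keep.append(rid)
        else:
            removed.append(RemovalEntry(id=rid, best_ref=best_ref, identity=best))
    return alignment.subset(keep), removed


def removal_log_tsv(removed: Sequence[RemovalEntry]) -> str:
    lines = ["id\tbest_ref\tidentity"]
    for e in removed:
        lines.append(f"{e.id}\t{e.best_ref}\t{e.identity:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Trimming and column statistics


def trim_alignment(
    alignment: Alignment, max_gap_fraction: float = DEFAULT_GAP_FRACTION
) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    Returns the trimmed alignment and the kept-column map: for each trimmed
    column index, the 0-based column index in the raw alignment.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise SequenceError("max_gap_fraction must be in [0, 1]")
    n = len(alignment)
    kept = [
        j for j in range(alignment.length)
        if sum(1 for row in alignment.rows if row[j] == GAP) / n <= max_gap_fraction
    ]
    if not kept:
        raise SequenceError("trimming removed every column")
    rows = ["".join(row[j] for j in kept) for row in alignment.rows]
    trimmed = Alignment(
        ids=list(alignment.ids), rows=rows,
        descriptions=list(alignment.descriptions),
    )
    return trimmed, kept


def kept_column_map_tsv(kept: Sequence[int]) -> str:
    """Two-column TSV (trimmed_pos, raw_pos), 1-based."""
    lines = ["trimmed_pos\traw_pos"]
    for t, r in enumerate(kept):
        lines.append(f"{t + 1}\t{r + 1}")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ColumnFrequencies:
    """Residue frequencies of one alignment column among non-gap rows."""

    column: int  # 0-based raw column index
    frequencies: dict[str, float] | None  # None when the column is all-gap
    gap_fraction: float

    @property
    def all_gap(self) -> bool:
        return self.frequencies is None


def column_frequencies(
    alignment: Alignment, span: tuple[int, int] | None = None
) -> list[ColumnFrequencies]:
    """Per-column residue frequency tables over a 0-based half-open span.

    Frequencies are computed among non-gap rows and sum to 1; the gap
    fraction is reported separately. An all-gap column is flagged with
    ``frequencies=None``.
    """
    start, stop = span if span is not None else (0, alignment.length)
    if not (0 <= start <= stop <= alignment.length):
        raise SequenceError("span outside alignment")
    out: list[ColumnFrequencies] = []
    n = len(alignment)
    for j in range(start, stop):
        col = alignment.column(j)
        residues = [c for c in col if c != GAP]
        gap_frac = (n - len(residues)) / n
        if not residues:
            out.append(ColumnFrequencies(j, None, 1.0))
            continue
        freqs: dict[str, float] = {}
        for c in residues:
            freqs[c] = freqs.get(c, 0.0) + 1.0
        total = len(residues)
        out.append(
            ColumnFrequencies(j, {k: v / total for k, v in freqs.items()}, gap_frac)
        )
    return out
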