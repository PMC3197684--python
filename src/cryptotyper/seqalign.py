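"""Sequence and alignment handling for rDNA clone libraries.

This module covers the sequence-level plumbing of the genotyping pipeline:
reading and writing FASTA clone libraries with specimen/station provenance,
reconciling two independent multiple alignments of the same sequences into a
consensus alignment (keeping only columns whose homology statement agrees
between both), majority-rule consensus sequences per genotype, and the
classification of the sites of an atypical individual into synapomorphies
shared with either genotype versus private autapomorphies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
_VALID = IUPAC_CODES | {GAP}


class SeqAlignError(ValueError):
    """Raised on malformed sequence or alignment input."""


@dataclass
class SequenceRecord:
    """A single rDNA clone with its provenance.

    ``bases`` holds uppercase IUPAC nucleotides; the gap symbol ``-`` is
    only legal when the record is a row of an alignment.
    """

    id: str
    bases: str
    specimen_id: str = ""
    station_id: str = ""
    marker: str = "ITS"
    genotype: str | None = None

    def __post_init__(self) -> None:
        self.bases = normalize_bases(self.bases)
        if not self.bases:
            raise SeqAlignError(f"record {self.id!r}: empty sequence")

    @property
    def ungapped(self) -> str:
        return self.bases.replace(GAP, "")

    def description_fields(self) -> str:
        parts = []
        if self.specimen_id:
            parts.append(f"specimen={self.specimen_id}")
        if self.station_id:
            parts.append(f"station={self.station_id}")
        parts.append(f"marker={self.marker}")
        if self.genotype is not None:
            parts.append(f"genotype={self.genotype}")
        return " ".join(parts)


def normalize_bases(bases: str) -> str:
    """Uppercase, map RNA U to T, and validate against the IUPAC alphabet."""
    up = bases.upper().replace("U", "T")
    bad = set(up) - _VALID
    if bad:
        raise SeqAlignError(
            f"non-IUPAC character(s) {sorted(bad)} in sequence"
        )
    return up


def _parse_description(desc: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in desc.split()[1:]:  # first token repeats the id
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into provenance-aware records.

    Description metadata uses a ``key=value`` syntax
    (``specimen= station= marker= genotype=``).
    """
    records: list[SequenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        meta = _parse_description(rec.description)
        try:
            records.append(
                SequenceRecord(
                    id=rec.id,
                    bases=str(rec.seq),
                    specimen_id=meta.get("specimen", ""),
                    station_id=meta.get("station", ""),
                    marker=meta.get("marker", "ITS"),
                    genotype=meta.get("genotype"),
                )
            )
        except SeqAlignError as exc:
            raise SeqAlignError(f"{path}, record #{i + 1} ({rec.id}): {exc}") from exc
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write records with their provenance in the description line.

    Output is byte-deterministic for a given record list.
    """
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.description_fields()}\n")
            for k in range(0, len(rec.bases), width):
                fh.write(rec.bases[k : k + width] + "\n")


def to_biopython(records) -> list[_BioSeqRecord]:
    return [
        _BioSeqRecord(Seq(r.bases), id=r.id, description=r.description_fields())
        for r in records
    ]


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class AlignmentBlock:
    """An aligned character matrix with a retained-column mask.

    The mask marks unambiguously aligned columns (e.g. the output of an
    external block-selection run); analyses downstream operate on retained
    columns only. By default every column is retained.
    """

    rows: list[SequenceRecord]
    retained_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.rows:
            raise SeqAlignError("alignment must contain at least one row")
        L = len(self.rows[0].bases)
        for r in self.rows:
            if len(r.bases) != L:
                raise SeqAlignError(
                    f"row {r.id!r} length {len(r.bases)} != alignment length {L}"
                )
        if self.retained_mask is None:
            self.retained_mask = np.ones(L, dtype=bool)
        else:
            self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
            if self.retained_mask.shape != (L,):
                raise SeqAlignError("retained_mask length != alignment length")

    @property
    def length(self) -> int:
        return len(self.rows[0].bases)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def matrix(self) -> np.ndarray:
        """Character matrix as an (n_rows, length) array of single chars."""
        return np.array([list(r.bases) for r in self.rows], dtype="U1")

    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained_mask)

    def row(self, rec_id: str) -> SequenceRecord:
        for r in self.rows:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def take_columns(self, indices) -> "AlignmentBlock":
        indices = np.asarray(indices, dtype=int)
        mat = self.matrix()[:, indices]
        rows = []
        for rec, chars in zip(self.rows, mat):
            rows.append(
                SequenceRecord(
                    id=rec.id,
                    bases="".join(chars),
                    specimen_id=rec.specimen_id,
                    station_id=rec.station_id,
                    marker=rec.marker,
                    genotype=rec.genotype,
                )
            )
        return AlignmentBlock(rows, self.retained_mask[indices])

    def write_mask_csv(self, path) -> None:
        """Sidecar CSV of retained column indices (0-based)."""
        with open(path, "w") as fh:
            fh.write("column\n")
            for i in self.retained_indices():
                fh.write(f"{i}\n")

    @staticmethod
    def read_mask_csv(path, length: int) -> np.ndarray:
        mask = np.zeros(length, dtype=bool)
        with open(path) as fh:
            header = fh.readline()
            if header.strip() != "column":
                raise SeqAlignError(f"{path}: expected a 'column' header")
            for line in fh:
                line = line.strip()
                if line:
                    mask[int(line)] = True
        return mask


def _homology_statements(block: AlignmentBlock, id_order: list[str]) -> list[tuple]:
    """Per-column homology statements.

    A column's statement maps each sequence (in ``id_order``) to the
    0-based index of its residue in the *ungapped* sequence, or -1 where
    the column holds a gap. Two columns from different alignments of the
    same sequences are homologous statements iff these tuples are equal.
    """
    by_id = {r.id: r for r in block.rows}
    cols = np.empty((block.length, len(id_order)), dtype=np.int64)
    for j, rid in enumerate(id_order):
        bases = by_id[rid].bases
        arr = np.frombuffer(bases.encode(), dtype="S1")
        is_res = arr != b"-"
        idx = np.cumsum(is_res) - 1
        idx[~is_res] = -1
        cols[:, j] = idx
    return [tuple(row) for row in cols]


def merge_alignments(align_a: AlignmentBlock, align_b: AlignmentBlock) -> AlignmentBlock:
    """Keep the columns of ``align_a`` whose homology statement recurs in ``align_b``.

    This is the reconciliation of a manual and an automatic alignment of
    the same sequences: positions on which the two alignment methods
    disagree are treated as ambiguous and dropped. Column order follows
    ``align_a``. Raises if the two alignments do not contain the same
    sequences (ids and ungapped residues).
    """
    ids_a, ids_b = set(align_a.ids), set(align_b.ids)
    if ids_a != ids_b:
        raise SeqAlignError(
            f"alignments hold different sequence sets: {sorted(ids_a ^ ids_b)}"
        )
    for rid in align_a.ids:
        if align_a.row(rid).ungapped != align_b.row(rid).ungapped:
            raise SeqAlignError(f"sequence {rid!r} differs between the two alignments")
    order = align_a.ids
    stmts_a = _homology_statements(align_a, order)
    stmts_b = set(_homology_statements(align_b, order))
    keep = [j for j, s in enumerate(stmts_a) if s in stmts_b]
    if not keep:
        raise SeqAlignError("the two alignments share no concordant column")
    return align_a.take_columns(keep)


# ---------------------------------------------------------------------------
# Consensus and site classification
# ---------------------------------------------------------------------------


@dataclass
class ConsensusSequence:
    """Per-column majority residue at a given threshold; 'N' where no
    residue reaches it. Gap characters count toward the denominator but are
    never emitted as the consensus state."""

    symbols: str
    threshold: float = 0.6

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold <= 1.0:
            raise SeqAlignError("consensus threshold must lie in (0.5, 1]")

    def __len__(self) -> int:
        return len(self.symbols)


def consensus_sequence(
    align: AlignmentBlock, group_rows=None, threshold: float = 0.6
) -> ConsensusSequence:
    """Majority-rule consensus over a group of alignment rows.

    ``group_rows`` is an iterable of row ids (default: all rows). A column
    emits the most frequent non-gap residue if its frequency over the group
    size is >= ``threshold``, else 'N'.
    """
    if group_rows is None:
        group_rows = align.ids
    group_rows = list(group_rows)
    if not group_rows:
        raise SeqAlignError("empty consensus group")
    rows = [align.row(rid).bases for rid in group_rows]
    n = len(rows)
    out = []
    for j in range(align.length):
        counts: dict[str, int] = {}
        for s in rows:
            c = s[j]
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("N")
            continue
        best = max(counts.values())
        winners = [c for c, k in counts.items() if k == best]
        if len(winners) == 1 and best / n >= threshold:
            out.append(winners[0])
        else:
            out.append("N")
    return ConsensusSequence("".join(out), threshold)


@dataclass
class SiteClassification:
    """Counts and column positions of diagnostic sites for a query row
    compared with two group consensuses."""

    positions_synapomorphy_a: list[int]
    positions_synapomorphy_b: list[int]
    positions_autapomorphy: list[int]

    @property
    def n_synapomorphy_with_a(self) -> int:
        return len(self.positions_synapomorphy_a)

    @property
    def n_synapomorphy_with_b(self) -> int:
        return len(self.positions_synapomorphy_b)

    @property
    def n_autapomorphy(self) -> int:
        return len(self.positions_autapomorphy)

    def counts(self) -> tuple[int, int, int]:
        return (
            self.n_synapomorphy_with_a,
            self.n_synapomorphy_with_b,
            self.n_autapomorphy,
        )


def classify_sites(
    query: str,
    cons_a: ConsensusSequence,
    cons_b: ConsensusSequence,
    mask=None,
    strict_autapomorphy: bool = False,
) -> SiteClassification:
    """Classify the aligned sites of a query row against two consensuses.

    Eligible columns are those where the mask is true, both consensuses are
    called (not 'N') and the query holds a called residue (not gap/'N').
    At eligible columns where the consensuses differ, agreement with one of
    them is a synapomorphy with that group; a query residue differing from
    both consensuses is an autapomorphy. With ``strict_autapomorphy`` the
    autapomorphy count is restricted to columns where the two consensuses
    also differ from each other.
    """
    query = normalize_bases(query)
    if not (len(query) == len(cons_a) == len(cons_b)):
        raise SeqAlignError("query and consensus lengths differ")
    if mask is None:
        mask = np.ones(len(query), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(query),):
        raise SeqAlignError("mask length != sequence length")
    syn_a: list[int] = []
    syn_b: list[int] = []
    aut: list[int] = []
    for j in range(len(query)):
        q, a, b = query[j], cons_a.symbols[j], cons_b.symbols[j]
        if not mask[j] or a == "N" or b == "N" or q in (GAP, "N"):
            continue
        if a != b:
            if q == a:
                syn_a.append(j)
            elif q == b:
                syn_b.append(j)
            else:
                aut.append(j)
        elif q != a and not strict_autapomorphy:
            aut.append(j)
    return SiteClassification(syn_a, syn_b, aut)
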