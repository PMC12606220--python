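"""Assemble recovered collagen peptides into a positional alignment.

Collagen I chains are the same length across the marsupial taxa considered
here, so positional homology is taken directly from the reference coordinate
frame (concatenated COL1A1+COL1A2 of a designated reference taxon): each
recovered peptide is written into its span, unknown positions become 'X',
and no gap-admitting alignment is performed.  Overlapping peptides that
disagree at a position are resolved by majority peptide support; ties become
'X' and every conflict is logged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .collagen import CollagenSequence
from .constants import AMINO_ACIDS, UNKNOWN

_VALID = set(AMINO_ACIDS) | {UNKNOWN}


@dataclass
class RecoveredPeptideSet:
    """Peptides recovered for one taxon by LC-MS/MS sequencing.

    Each entry is (sequence, chain, start, end) with 1-based inclusive
    chain-local coordinates, chain in {"A1", "A2"}.
    """

    taxon_id: str
    peptides: list[tuple[str, str, int, int]]

    def __post_init__(self) -> None:
        for seq, chain, start, end in self.peptides:
            if chain not in ("A1", "A2"):
                raise ValueError(f"{self.taxon_id}: unknown chain {chain!r}")
            if end - start + 1 != len(seq):
                raise ValueError(
                    f"{self.taxon_id}: span {start}-{end} inconsistent with "
                    f"peptide {seq!r}"
                )


@dataclass
class AminoAcidAlignment:
    """Fixed-length positional alignment; 'X' marks unknown residues."""

    taxa: list[str]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(self.rows[t]) for t in self.taxa}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        for t in self.taxa:
            bad = set(self.rows[t]) - _VALID
            if bad:
                raise ValueError(f"{t}: invalid residues {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.taxa[0]]) if self.taxa else 0

    def column(self, j: int) -> list[str]:
        return [self.rows[t][j] for t in self.taxa]

    def subset(self, taxa: list[str]) -> "AminoAcidAlignment":
        missing = [t for t in taxa if t not in self.rows]
        if missing:
            raise KeyError(f"taxa not in alignment: {missing}")
        return AminoAcidAlignment(taxa=list(taxa), rows={t: self.rows[t] for t in taxa})


@dataclass
class AlignmentStats:
    coverage: dict[str, float]  # per-taxon % of columns != X, one decimal
    occupancy: list[int]  # per-column count of non-X residues
    n_variable_columns: int
    conflicts: list[tuple[str, str, int, str]] = field(default_factory=list)


def assemble_alignment(
    sets: list[RecoveredPeptideSet],
    reference: CollagenSequence,
) -> tuple[AminoAcidAlignment, list[tuple[str, str, int, str]]]:
    """Fill each taxon's row from its peptides on the reference frame.

    Returns the alignment and a conflict log of (taxon, chain, position,
    description) for overlapping peptides that disagreed.  Conflicted
    positions are resolved by majority peptide support, ties become 'X'.
    """
    L = len(reference.concatenated)
    chain_len = {"A1": len(reference.chain_a1), "A2": len(reference.chain_a2)}
    chain_off = {"A1": 0, "A2": reference.boundary - 1}
    conflicts: list[tuple[str, str, int, str]] = []
    rows: dict[str, str] = {}
    taxa: list[str] = []
    for pset in sets:
        votes: list[Counter] = [Counter() for _ in range(L)]
        for seq, chain, start, end in pset.peptides:
            if start < 1 or end > chain_len[chain]:
                raise ValueError(
                    f"{pset.taxon_id}: span {chain}:{start}-{end} exceeds "
                    f"reference chain length {chain_len[chain]}"
                )
            off = chain_off[chain]
            for k, residue in enumerate(seq):
                if residue != UNKNOWN:
                    votes[off + start - 1 + k][residue] += 1
        row = []
        for pos, ctr in enumerate(votes):
            if not ctr:
                row.append(UNKNOWN)
                continue
            ranked = ctr.most_common()
            if len(ranked) > 1:
                chain = "A1" if pos < chain_off["A2"] else "A2"
                local = pos + 1 - chain_off[chain]
                desc = ",".join(f"{r}x{c}" for r, c in ranked)
                if ranked[0][1] == ranked[1][1]:
                    conflicts.append((pset.taxon_id, chain, local, f"tie:{desc}"))
                    row.append(UNKNOWN)
                    continue
                conflicts.append((pset.taxon_id, chain, local, f"majority:{desc}"))
            row.append(ranked[0][0])
        rows[pset.taxon_id] = "".join(row)
        taxa.append(pset.taxon_id)
    return AminoAcidAlignment(taxa=taxa, rows=rows), conflicts


def coverage_stats(aln: AminoAcidAlignment, conflicts: list | None = None) -> AlignmentStats:
    """Per-taxon coverage (% non-X, one decimal), per-column occupancy and
    the count of variable columns (>= 2 distinct non-X residues)."""
    if not aln.taxa or aln.n_columns == 0:
        raise ValueError("empty alignment")
    L = aln.n_columns
    coverage = {
        t: round(100.0 * sum(c != UNKNOWN for c in aln.rows[t]) / L, 1)
        for t in aln.taxa
    }
    occupancy = []
    n_var = 0
    for j in range(L):
        col = [c for c in aln.column(j) if c != UNKNOWN]
        occupancy.append(len(col))
        if len(set(col)) >= 2:
            n_var += 1
    return AlignmentStats(
        coverage=coverage,
        occupancy=occupancy,
        n_variable_columns=n_var,
        conflicts=conflicts or [],
    )


# ---------------------------------------------------------------------------
# Alignment I/O

def write_alignment(aln: AminoAcidAlignment, path: str | Path, format: str = "fasta") -> None:
    if not aln.taxa:
        raise ValueError("cannot write an empty alignment")
    if format not in ("fasta", "nexus"):
        raise ValueError(f"unknown alignment format {format!r}")
    records = [
        SeqRecord(
            Seq(aln.rows[t]),
            id=t,
            description="",
            annotations={"molecule_type": "protein"},
        )
        for t in aln.taxa
    ]
    msa = MultipleSeqAlignment(records)
    AlignIO.write(msa, str(path), format)


def read_alignment(path: str | Path, format: str = "fasta") -> AminoAcidAlignment:
    if format not in ("fasta", "nexus"):
        raise ValueError(f"unknown alignment format {format!r}")
    msa = AlignIO.read(str(path), format)
    taxa = [rec.id for rec in msa]
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    return AminoAcidAlignment(taxa=taxa, rows=rows)


def write_conflict_log(conflicts: list[tuple[str, str, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tchain\tposition\tdetail\n")
        for taxon, chain, pos, detail in conflicts:
            fh.write(f"{taxon}\t{chain}\t{pos}\t{detail}\n")
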