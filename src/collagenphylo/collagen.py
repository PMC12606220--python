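"""Collagen sequences, in-silico tryptic digestion, and peptide masses.

Type I collagen is a heterotrimer of two chains, COL1A1 and COL1A2.  ZooMS
works on the tryptic peptides of these chains: bone collagen is digested with
trypsin and the resulting peptide masses are read out by MALDI-ToF.  This
module models the sequences, performs the in-silico digest (classic Keil rule:
cleave C-terminal to K or R, suppressed before P), and computes monoisotopic
peptide masses with the two modifications that dominate ancient collagen
chemistry: proline/lysine hydroxylation (+15.994915 Da per site) and
asparagine/glutamine deamidation (+0.984016 Da per site).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import (
    AMINO_ACIDS,
    DEAMIDATION_MASS,
    HYDROXYLATION_MASS,
    PROTON_MASS,
    RESIDUE_MASS,
    UNKNOWN,
    WATER_MASS,
)

_VALID = set(AMINO_ACIDS) | {UNKNOWN}


def _validate_chain(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    for i, ch in enumerate(seq, start=1):
        if ch not in _VALID:
            raise ValueError(f"{name}: invalid residue {ch!r} at position {i}")


@dataclass(frozen=True)
class CollagenSequence:
    """Per-taxon COL1A1 + COL1A2 amino-acid sequence.

    Positions are 1-based on the mature chains; ``boundary`` is the 1-based
    position of the first COL1A2 residue in the concatenated coordinate frame.
    """

    taxon_id: str
    chain_a1: str
    chain_a2: str

    def __post_init__(self) -> None:
        _validate_chain(self.chain_a1, f"{self.taxon_id}/A1")
        _validate_chain(self.chain_a2, f"{self.taxon_id}/A2")

    @property
    def concatenated(self) -> str:
        return self.chain_a1 + self.chain_a2

    @property
    def boundary(self) -> int:
        """1-based position of the first COL1A2 residue."""
        return len(self.chain_a1) + 1


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with chain-local coordinates and modification state.

    ``start``/``end`` are 1-based inclusive positions on ``chain`` ("A1" or
    "A2").  ``neutral_mass`` is monoisotopic; ``mz`` is singly protonated
    unless recomputed with :func:`peptide_mz`.
    """

    sequence: str
    chain: str
    start: int
    end: int
    missed_cleavages: int = 0
    n_hydroxylations: int = 0
    n_deamidations: int = 0
    neutral_mass: float = field(default=0.0, compare=False)
    mz: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with "
                f"peptide length {len(self.sequence)}"
            )

    def concatenated_span(self, seq: CollagenSequence) -> tuple[int, int]:
        """Span in the concatenated COL1A1+COL1A2 coordinate frame."""
        off = 0 if self.chain == "A1" else seq.boundary - 1
        return self.start + off, self.end + off


def peptide_mass(sequence: str, n_hydroxylations: int = 0, n_deamidations: int = 0) -> float:
    """Neutral monoisotopic mass (Da) of a peptide with modifications.

    Raises if the sequence is empty, contains X (mass undefined), or the
    modification counts exceed the available sites (P+K for hydroxylation,
    N+Q for deamidation).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    if n_hydroxylations < 0 or n_deamidations < 0:
        raise ValueError("modification counts must be >= 0")
    n_oh_sites = sequence.count("P") + sequence.count("K")
    n_deam_sites = sequence.count("N") + sequence.count("Q")
    if n_hydroxylations > n_oh_sites:
        raise ValueError(
            f"{n_hydroxylations} hydroxylations exceed {n_oh_sites} P/K sites"
        )
    if n_deamidations > n_deam_sites:
        raise ValueError(
            f"{n_deamidations} deamidations exceed {n_deam_sites} N/Q sites"
        )
    total = WATER_MASS
    for i, ch in enumerate(sequence, start=1):
        try:
            total += RESIDUE_MASS[ch]
        except KeyError:
            raise ValueError(
                f"mass undefined for residue {ch!r} at position {i}"
            ) from None
    return (
        total
        + n_hydroxylations * HYDROXYLATION_MASS
        + n_deamidations * DEAMIDATION_MASS
    )


def peptide_mz(neutral_mass: float, charge: int = 1) -> float:
    """m/z of a peptide at the given positive charge (MALDI default z=1)."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def _cleavage_sites(seq: str) -> list[int]:
    """0-based indices i such that trypsin cuts between seq[i] and seq[i+1].

    Keil rule: after K or R, unless the next residue is P.
    """
    sites = []
    for i in range(len(seq) - 1):
        if seq[i] in "KR" and seq[i + 1] != "P":
            sites.append(i)
    return sites


def tryptic_digest(
    seq: CollagenSequence | str,
    max_missed: int = 1,
    chain: str = "A1",
) -> list[Peptide]:
    """In-silico tryptic digest with 0..max_missed missed cleavages.

    For a :class:`CollagenSequence` both chains are digested independently
    (trypsin sees separate mature chains); peptides carry chain-local 1-based
    spans.  With ``max_missed=0`` the zero-missed peptides partition each
    chain.  Masses are filled in for fully determined peptides (no X);
    peptides containing X get NaN masses.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if isinstance(seq, CollagenSequence):
        return tryptic_digest(seq.chain_a1, max_missed, "A1") + tryptic_digest(
            seq.chain_a2, max_missed, "A2"
        )
    _validate_chain(seq, chain)
    sites = _cleavage_sites(seq)
    # Fragment boundaries: starts of zero-missed fragments (0-based).
    starts = [0] + [i + 1 for i in sites]
    ends = [i for i in sites] + [len(seq) - 1]
    peptides: list[Peptide] = []
    for i, s in enumerate(starts):
        for missed in range(0, max_missed + 1):
            j = i + missed
            if j >= len(starts):
                break
            e = ends[j]
            sub = seq[s : e + 1]
            if UNKNOWN in sub:
                mass = mz = float("nan")
            else:
                mass = peptide_mass(sub)
                mz = peptide_mz(mass, 1)
            peptides.append(
                Peptide(
                    sequence=sub,
                    chain=chain,
                    start=s + 1,
                    end=e + 1,
                    missed_cleavages=missed,
                    neutral_mass=mass,
                    mz=mz,
                )
            )
    return peptides


def theoretical_fingerprint(
    seq: CollagenSequence,
    max_missed: int = 1,
    max_hydroxylations: int = 6,
    max_deamidations: int | None = None,
    mass_window: tuple[float, float] = (800.0, 3600.0),
    hydroxylate_lysine: bool = False,
) -> list[tuple[Peptide, float]]:
    """All modified tryptic peptide variants within an m/z window.

    For each digest peptide, enumerates hydroxylation counts 0..min(#sites,
    ``max_hydroxylations``) (sites = P, optionally also K) and deamidation
    counts 0..#N+#Q (optionally capped), computes singly-protonated m/z, keeps
    variants inside ``mass_window``, deduplicates by (sequence, chain, span,
    mods) and returns them sorted by m/z.  Peptides containing X are skipped
    (their mass is undefined).
    """
    lo, hi = mass_window
    if not lo < hi:
        raise ValueError(f"mass window must satisfy min < max, got {mass_window}")
    out: dict[tuple, tuple[Peptide, float]] = {}
    for pep in tryptic_digest(seq, max_missed):
        if UNKNOWN in pep.sequence:
            continue
        oh_sites = pep.sequence.count("P")
        if hydroxylate_lysine:
            oh_sites += pep.sequence.count("K")
        deam_sites = pep.sequence.count("N") + pep.sequence.count("Q")
        if max_deamidations is not None:
            deam_sites = min(deam_sites, max_deamidations)
        for n_oh, n_deam in itertools.product(
            range(min(oh_sites, max_hydroxylations) + 1), range(deam_sites + 1)
        ):
            mass = (
                pep.neutral_mass
                + n_oh * HYDROXYLATION_MASS
                + n_deam * DEAMIDATION_MASS
            )
            mz = peptide_mz(mass, 1)
            if lo <= mz <= hi:
                variant = replace(
                    pep,
                    n_hydroxylations=n_oh,
                    n_deamidations=n_deam,
                    neutral_mass=mass,
                    mz=mz,
                )
                key = (pep.sequence, pep.chain, pep.start, n_oh, n_deam)
                out[key] = (variant, mz)
    return sorted(out.values(), key=lambda t: t[1])


# ---------------------------------------------------------------------------
# FASTA I/O — header convention ``taxon|chain`` with chain in {A1, A2}.

def read_collagen_fasta(path: str | Path) -> list[CollagenSequence]:
    chains: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            taxon, chain = rec.id.rsplit("|", 1)
        except ValueError:
            raise ValueError(
                f"{path}: header {rec.id!r} does not follow 'taxon|chain'"
            ) from None
        if chain not in ("A1", "A2"):
            raise ValueError(f"{path}: unknown chain {chain!r} in {rec.id!r}")
        if taxon not in chains:
            chains[taxon] = {}
            order.append(taxon)
        chains[taxon][chain] = str(rec.seq).upper()
    out = []
    for taxon in order:
        d = chains[taxon]
        if set(d) != {"A1", "A2"}:
            raise ValueError(f"{path}: taxon {taxon!r} missing chain(s) {sorted({'A1','A2'} - set(d))}")
        out.append(CollagenSequence(taxon, d["A1"], d["A2"]))
    return out


def write_collagen_fasta(seqs: Iterable[CollagenSequence], path: str | Path) -> None:
    records = []
    for s in seqs:
        records.append(SeqRecord(Seq(s.chain_a1), id=f"{s.taxon_id}|A1", description=""))
        records.append(SeqRecord(Seq(s.chain_a2), id=f"{s.taxon_id}|A2", description=""))
    SeqIO.write(records, str(path), "fasta")


def write_fingerprint_tsv(
    fingerprint: Sequence[tuple[Peptide, float]], path: str | Path
) -> None:
    """Export a theoretical fingerprint as tab-separated text."""
    with open(path, "w") as fh:
        fh.write(
            "peptide\tchain\tstart\tend\tmissed\tnOH\tnDeam\tneutral_mass\tmz\n"
        )
        for pep, mz in fingerprint:
            fh.write(
                f"{pep.sequence}\t{pep.chain}\t{pep.start}\t{pep.end}\t"
                f"{pep.missed_cleavages}\t{pep.n_hydroxylations}\t"
                f"{pep.n_deamidations}\t{pep.neutral_mass:.6f}\t{mz:.6f}\n"
            )
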