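"""Aligned multi-FASTA and metadata I/O with diploid genotype conventions.

Heterozygous positions in direct diploid Sanger reads are carried as the
six two-base IUPAC ambiguity codes; ``-`` marks alignment gaps and ``N``
unknown bases.  Short deletions can be recoded as shared pseudo-substitution
columns (see :func:`fill_deletion_columns`).

Coordinates are 0-based internally; add one for reports.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Ploidy",
    "GenotypeSequence",
    "LocusAlignment",
    "SpecimenRecord",
    "AlignmentError",
    "AMBIG",
    "CODE_FOR_PAIR",
    "BASES",
    "read_locus_fasta",
    "write_locus_fasta",
    "read_metadata",
    "write_metadata",
    "heterozygous_sites",
    "fill_deletion_columns",
    "fill_base",
]

#: two-base IUPAC ambiguity codes and the base pairs they encode
AMBIG: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}
CODE_FOR_PAIR: dict[frozenset[str], str] = {pair: c for c, pair in AMBIG.items()}
BASES = frozenset("ACGT")
_HAPLOID_OK = BASES | {"-", "N"}
_DIPLOID_OK = _HAPLOID_OK | set(AMBIG)


class AlignmentError(ValueError):
    """Invalid alignment input (ragged lengths, bad symbols, bad gaps)."""


class Ploidy(str, Enum):
    HAPLOID = "haploid"
    DIPLOID = "diploid"


@dataclass(frozen=True)
class GenotypeSequence:
    """One specimen's aligned sequence at one locus.

    Diploid loci may carry two-base IUPAC codes at heterozygous sites;
    haploid loci may not.
    """

    specimen_id: str
    locus: str
    seq: str
    ploidy: Ploidy = Ploidy.DIPLOID

    def __post_init__(self) -> None:
        ok = _DIPLOID_OK if self.ploidy is Ploidy.DIPLOID else _HAPLOID_OK
        for i, ch in enumerate(self.seq):
            if ch not in ok:
                raise AlignmentError(
                    f"{self.specimen_id}/{self.locus}: disallowed symbol "
                    f"{ch!r} at column {i}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class LocusAlignment:
    """All specimens' aligned sequences for one locus."""

    locus: str
    ploidy: Ploidy
    sequences: tuple[GenotypeSequence, ...]
    codon_framed: bool = False

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            offender = max(self.sequences, key=len)
            raise AlignmentError(
                f"{self.locus}: ragged alignment; {offender.specimen_id} has "
                f"length {len(offender)}, others {sorted(lengths - {len(offender)})}"
            )
        for s in self.sequences:
            if s.ploidy is not self.ploidy:
                raise AlignmentError(f"{s.specimen_id}: ploidy mismatch with locus")
            if s.locus != self.locus:
                raise AlignmentError(f"{s.specimen_id}: locus mismatch")
        if self.codon_framed and self.length % 3 != 0:
            raise AlignmentError(
                f"{self.locus}: codon-framed alignment length {self.length} "
                "not divisible by 3"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def get(self, specimen_id: str) -> GenotypeSequence:
        for s in self.sequences:
            if s.specimen_id == specimen_id:
                return s
        raise KeyError(specimen_id)


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata row: a-priori species label, locality, optional karyotype."""

    specimen_id: str
    species_label: str = "unknown"
    locality_id: int = 0
    karyotype_formula: Optional[str] = None
    stated_2n: Optional[tuple[int, int]] = None


def read_locus_fasta(path: str | Path, locus: str, ploidy: Ploidy | str,
                     codon_framed: bool = False) -> LocusAlignment:
    """Read one locus from aligned multi-FASTA; headers carry specimen ids."""
    ploidy = Ploidy(ploidy)
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs.append(
            GenotypeSequence(
                specimen_id=rec.id, locus=locus,
                seq=str(rec.seq).upper(), ploidy=ploidy,
            )
        )
    if not seqs:
        raise AlignmentError(f"{path}: no FASTA records")
    return LocusAlignment(locus=locus, ploidy=ploidy, sequences=tuple(seqs),
                          codon_framed=codon_framed)


def write_locus_fasta(aln: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.seq), id=s.specimen_id, description="")
        for s in aln.sequences
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


_METADATA_COLS = ["specimen_id", "species", "locality", "karyotype", "stated_2n"]


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen metadata TSV.

    Columns: ``specimen_id species locality`` plus optional ``karyotype``
    (Rb formula, possibly ranged) and ``stated_2n`` (int or ``lo-hi``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"specimen_id", "species", "locality"}
    missing = required - set(df.columns)
    if missing:
        raise AlignmentError(f"{path}: metadata missing columns {sorted(missing)}")
    records = []
    seen = set()
    for _, row in df.iterrows():
        sid = row["specimen_id"]
        if sid in seen:
            raise AlignmentError(f"{path}: duplicate specimen_id {sid}")
        seen.add(sid)
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                species_label=row["species"] or "unknown",
                locality_id=int(row["locality"]) if row["locality"] else 0,
                karyotype_formula=row.get("karyotype") or None,
                stated_2n=_parse_2n(row.get("stated_2n", "")),
            )
        )
    return records


def write_metadata(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        s2n = ""
        if r.stated_2n is not None:
            lo, hi = r.stated_2n
            s2n = str(lo) if lo == hi else f"{lo}-{hi}"
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "species": r.species_label,
                "locality": r.locality_id,
                "karyotype": r.karyotype_formula or "",
                "stated_2n": s2n,
            }
        )
    pd.DataFrame(rows, columns=_METADATA_COLS).to_csv(path, sep="\t", index=False)


def _parse_2n(text: str) -> Optional[tuple[int, int]]:
    text = (text or "").strip()
    if not text:
        return None
    if "-" in text:
        lo, hi = text.split("-", 1)
        return (int(lo), int(hi))
    return (int(text), int(text))


def heterozygous_sites(g: GenotypeSequence) -> list[tuple[int, str]]:
    """0-based positions of two-base IUPAC codes, ascending."""
    if g.ploidy is not Ploidy.DIPLOID:
        raise ValueError(f"{g.specimen_id}: heterozygous_sites requires a diploid sequence")
    return [(i, ch) for i, ch in enumerate(g.seq) if ch in AMBIG]


def fill_base(seed: int, locus: str, column: int, absent: frozenset[str] | set[str]) -> str:
    """Deterministic per-column choice of a fill base among absent ones.

    Keyed on (seed, locus, column) so the choice is independent of scan
    order and reproducible by any cooperating producer of the alignment.
    """
    if not absent:
        raise AlignmentError(f"{locus} column {column}: no absent base to fill with")
    return random.Random(f"{seed}:{locus}:{column}").choice(sorted(absent))


def fill_deletion_columns(
    aln: LocusAlignment, seed: int, max_fill_len: int = 5
) -> tuple[LocusAlignment, dict[int, str]]:
    """Recode short deletions as shared pseudo-substitution columns.

    Every gap column is replaced, in all gapped sequences, by one base
    drawn (seeded, per column) from the bases *not* observed at that
    column in any ungapped sequence, so a k-column deletion becomes k
    diagnostic sites shared by its carriers.  Only plain A/C/G/T
    observations count when computing the absent set: an ambiguity code
    at a former gap column is itself the het-indel signature of a
    carrier and must not veto the fill base.

    Returns the new alignment and the per-column fill decisions; the
    input is not modified.  Errors on gap runs longer than
    ``max_fill_len`` and on columns where all four bases are observed.
    """
    if not aln.sequences:
        return aln, {}
    length = aln.length
    gap_cols: set[int] = set()
    for s in aln.sequences:
        run = 0
        for i, ch in enumerate(s.seq + "\x00"):  # sentinel flushes final run
            if ch == "-":
                run += 1
                gap_cols.add(i)
            else:
                if run > max_fill_len:
                    raise AlignmentError(
                        f"{s.specimen_id}/{aln.locus}: gap run of length {run} "
                        f"ending at column {i - 1} exceeds max_fill_len={max_fill_len}"
                    )
                run = 0
    if not gap_cols:
        return aln, {}

    fills: dict[int, str] = {}
    for c in sorted(gap_cols):
        observed = {s.seq[c] for s in aln.sequences if s.seq[c] != "-"} & BASES
        absent = BASES - observed
        if not absent:
            raise AlignmentError(
                f"{aln.locus} column {c}: all four bases observed; cannot fill gap"
            )
        fills[c] = fill_base(seed, aln.locus, c, absent)

    new_seqs = []
    for s in aln.sequences:
        chars = list(s.seq)
        for c in gap_cols:
            if chars[c] == "-":
                chars[c] = fills[c]
        new_seqs.append(replace(s, seq="".join(chars)))
    return replace(aln, sequences=tuple(new_seqs)), fills
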