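"""Resolve diploid genotypes into haplotype pairs by homozygote subtraction.

Heterozygous genotypes are phased against the pool of sequences observed
in fully homozygous specimens: a pool haplotype compatible with the
genotype is "subtracted", leaving the complementary allele.  Candidate
references are preferred first by locality, then by global frequency;
if more than one distinct decomposition survives, the genotype stays
unresolved rather than being phased arbitrarily.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .seqio import (
    AMBIG,
    BASES,
    CODE_FOR_PAIR,
    GenotypeSequence,
    LocusAlignment,
    Ploidy,
    SpecimenRecord,
    heterozygous_sites,
)

__all__ = [
    "Haplotype",
    "PhasedGenotype",
    "PhaseStatus",
    "PhaseResult",
    "homozygote_pool",
    "subtract",
    "recombine",
    "phase_all",
]


class Provenance(str, Enum):
    OBSERVED_HOMOZYGOTE = "observed_homozygote"
    DEDUCED = "deduced"
    SIMULATED = "simulated"


class PhaseStatus(str, Enum):
    HOMOZYGOUS = "homozygous"
    PHASED_BY_REFERENCE = "phased_by_reference"
    UNRESOLVED = "unresolved"


@dataclass
class Haplotype:
    """A fully resolved allele; the node unit of haplotype networks."""

    hap_id: str
    locus: str
    seq: str
    provenance: Provenance = Provenance.OBSERVED_HOMOZYGOTE
    frequency: int = 0          # allele copies across phased genotypes
    carriers: list[str] = field(default_factory=list)
    hom_carriers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [ch for ch in self.seq if ch in AMBIG]
        if bad:
            raise ValueError(f"haplotype {self.hap_id} carries ambiguity codes")


@dataclass(frozen=True)
class PhasedGenotype:
    specimen_id: str
    locus: str
    hap_a: str
    hap_b: str
    status: PhaseStatus
    reference_used: Optional[str] = None


@dataclass
class PhaseResult:
    """Phased genotypes plus the haplotype registry (pool + deduced)."""

    genotypes: list[PhasedGenotype]
    haplotypes: dict[str, Haplotype]

    def seq_of(self, hap_id: str) -> str:
        return self.haplotypes[hap_id].seq


def homozygote_pool(aln: LocusAlignment) -> list[Haplotype]:
    """Unique sequences among zero-heterozygous-site genotypes.

    Returned sorted by descending homozygote frequency then sequence,
    with ids ``<locus>_H1, _H2, ...``.  An empty pool is allowed.
    """
    carriers: dict[str, list[str]] = {}
    for g in aln.sequences:
        if aln.ploidy is Ploidy.DIPLOID and heterozygous_sites(g):
            continue
        carriers.setdefault(g.seq, []).append(g.specimen_id)
    ordered = sorted(carriers.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        Haplotype(
            hap_id=f"{aln.locus}_H{i + 1}",
            locus=aln.locus,
            seq=seq,
            provenance=Provenance.OBSERVED_HOMOZYGOTE,
            hom_carriers=list(carr),
        )
        for i, (seq, carr) in enumerate(ordered)
    ]


def subtract(genotype: GenotypeSequence, ref: Haplotype | str) -> Optional[str]:
    """Deduct ``ref`` from a genotype, returning the complementary allele.

    At each heterozygous site the complement takes the base of the IUPAC
    pair not carried by the reference; elsewhere it equals the genotype.
    Returns ``None`` when the reference is not a component of this
    genotype (conflict at a homozygous site, or a heterozygous code that
    does not contain the reference base).
    """
    ref_seq = ref.seq if isinstance(ref, Haplotype) else ref
    if len(ref_seq) != len(genotype.seq):
        raise ValueError("reference/genotype length mismatch")
    out = []
    for g, r in zip(genotype.seq, ref_seq):
        if g == "N":
            out.append("N")
        elif g in BASES or g == "-":
            if r != g:
                return None
            out.append(g)
        else:  # two-base ambiguity code
            pair = AMBIG[g]
            if r not in pair:
                return None
            (other,) = pair - {r}
            out.append(other)
    return "".join(out)


def recombine(seq_a: str, seq_b: str) -> str:
    """Site-wise genotype of two alleles: base where equal, IUPAC where not."""
    if len(seq_a) != len(seq_b):
        raise ValueError("allele length mismatch")
    out = []
    for a, b in zip(seq_a, seq_b):
        if a == b:
            out.append(a)
        elif "N" in (a, b):
            out.append("N")
        else:
            out.append(CODE_FOR_PAIR[frozenset((a, b))])
    return "".join(out)


def phase_all(
    aln: LocusAlignment,
    metadata: Sequence[SpecimenRecord] = (),
    pool: Optional[list[Haplotype]] = None,
) -> PhaseResult:
    """Phase every genotype of a locus against the homozygote pool.

    Homozygotes phase trivially.  For heterozygotes, each pool haplotype
    is tried as reference; compatible references are narrowed first to
    those observed as homozygotes in the specimen's own locality, then
    to the highest global homozygote frequency.  If exactly one distinct
    (reference, complement) pair survives, the genotype is phased and a
    complement absent from the pool is registered as a deduced haplotype
    (id suffixed ``*``).  Anything else stays unresolved.
    """
    if pool is None:
        pool = homozygote_pool(aln)
    locality_of = {m.specimen_id: m.locality_id for m in metadata}
    hap_localities = {
        h.hap_id: {locality_of.get(c) for c in h.hom_carriers} - {None}
        for h in pool
    }
    hom_freq = {h.hap_id: len(h.hom_carriers) for h in pool}
    registry: dict[str, Haplotype] = {h.hap_id: h for h in pool}
    by_seq: dict[str, str] = {h.seq: h.hap_id for h in pool}
    n_deduced = 0
    genotypes: list[PhasedGenotype] = []

    def _register_deduced(seq: str) -> str:
        nonlocal n_deduced
        if seq in by_seq:
            return by_seq[seq]
        n_deduced += 1
        hap_id = f"{aln.locus}_D{n_deduced}*"
        registry[hap_id] = Haplotype(
            hap_id=hap_id, locus=aln.locus, seq=seq, provenance=Provenance.DEDUCED
        )
        by_seq[seq] = hap_id
        return hap_id

    for g in aln.sequences:
        het = heterozygous_sites(g) if aln.ploidy is Ploidy.DIPLOID else []
        if not het:
            hap_id = by_seq.get(g.seq)
            if hap_id is None:
                # haploid locus, or homozygote carrying N (absent from pool key)
                hap_id = _register_deduced(g.seq)
            genotypes.append(
                PhasedGenotype(g.specimen_id, aln.locus, hap_id, hap_id,
                               PhaseStatus.HOMOZYGOUS)
            )
        else:
            candidates = [
                (h, comp) for h in pool
                if (comp := subtract(g, h)) is not None
            ]
            loc = locality_of.get(g.specimen_id)
            if loc is not None:
                local = [c for c in candidates if loc in hap_localities[c[0].hap_id]]
                if local:
                    candidates = local
            if candidates:
                top = max(hom_freq[h.hap_id] for h, _ in candidates)
                candidates = [c for c in candidates if hom_freq[c[0].hap_id] == top]
            pairs = {frozenset((h.seq, comp)) for h, comp in candidates}
            if len(pairs) == 1:
                ref, comp = candidates[0]
                comp_id = _register_deduced(comp)
                a, b = sorted((ref.hap_id, comp_id), key=lambda hid: registry[hid].seq)
                genotypes.append(
                    PhasedGenotype(g.specimen_id, aln.locus, a, b,
                                   PhaseStatus.PHASED_BY_REFERENCE,
                                   reference_used=ref.hap_id)
                )
            else:
                genotypes.append(
                    PhasedGenotype(g.specimen_id, aln.locus, "", "",
                                   PhaseStatus.UNRESOLVED)
                )

    # allele frequencies and carrier lists over resolved genotypes
    for pg in genotypes:
        if pg.status is PhaseStatus.UNRESOLVED:
            continue
        for hid in (pg.hap_a, pg.hap_b):
            registry[hid].frequency += 1
            if pg.specimen_id not in registry[hid].carriers:
                registry[hid].carriers.append(pg.specimen_id)
    return PhaseResult(genotypes=genotypes, haplotypes=registry)
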