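"""Per-specimen genetic classification and mito-nuclear discordance report.

A-priori species labels come from metadata (karyotype/morphology) and are
never inferred from the locus being called, which keeps the hybrid and
introgression calls non-circular.  The ancestral-polymorphism vs recent
introgression distinction is deliberately not decided: specimens matching
that pattern carry a single combined candidate flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .network import FFR
from .phasing import PhasedGenotype, PhaseStatus
from .seqio import BASES, LocusAlignment, SpecimenRecord

__all__ = [
    "CallType",
    "LocusCall",
    "SummaryFlag",
    "SpecimenSummary",
    "label_ffrs",
    "call_locus",
    "discordance_report",
    "fixed_differences",
]


class CallType(str, Enum):
    PURE = "pure"
    HETEROSPECIFIC_HETEROZYGOTE = "heterospecific_heterozygote"
    HETEROSPECIFIC_HOMOZYGOTE = "heterospecific_homozygote"
    INTRASPECIFIC_LINEAGE_HETEROZYGOTE = "intraspecific_lineage_heterozygote"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class LocusCall:
    specimen_id: str
    locus: str
    call: CallType
    species: Optional[str] = None       # FFR species for pure / heterospecific_homozygote
    evidence: tuple[str, ...] = ()      # FFR ids of the two alleles

    @property
    def label(self) -> str:
        """Report label, e.g. ``pure_alaicus``."""
        if self.call is CallType.PURE and self.species:
            return f"pure_{self.species}"
        return self.call.value


class SummaryFlag(str, Enum):
    CONCORDANT = "concordant"
    MITO_NUCLEAR_DISCORDANT = "mito-nuclear discordant"
    HYBRID_CANDIDATE = "interspecific hybrid candidate"
    INTROGRESSION_CANDIDATE = "introgression/ancestral-polymorphism candidate"


@dataclass
class SpecimenSummary:
    specimen_id: str
    species_label: str
    mt_clade_species: Optional[str]
    locus_calls: dict[str, LocusCall]
    flag: SummaryFlag
    karyotype_consistent: Optional[bool] = None


def label_ffrs(
    ffrs: Sequence[FFR], metadata: Sequence[SpecimenRecord]
) -> dict[str, Optional[str]]:
    """Majority a-priori species label per FFR; ties or no labels -> None."""
    species_of = {m.specimen_id: m.species_label for m in metadata}
    labels: dict[str, Optional[str]] = {}
    for ffr in ffrs:
        tally: dict[str, int] = {}
        for sid in ffr.members:
            sp = species_of.get(sid, "unknown")
            if sp not in ("unknown", ""):
                tally[sp] = tally.get(sp, 0) + 1
        ffr.species_composition = dict(sorted(tally.items()))
        if not tally:
            labels[ffr.ffr_id] = None
            continue
        best = max(tally.values())
        winners = [sp for sp, n in tally.items() if n == best]
        labels[ffr.ffr_id] = winners[0] if len(winners) == 1 else None
    return labels


def call_locus(
    phased: PhasedGenotype,
    ffr_of_hap: Mapping[str, str],
    ffr_labels: Mapping[str, Optional[str]],
    specimen_species: str,
) -> LocusCall:
    """Classify one phased genotype from the FFRs of its two alleles."""
    if phased.status is PhaseStatus.UNRESOLVED:
        return LocusCall(phased.specimen_id, phased.locus, CallType.UNRESOLVED)
    ffr_a = ffr_of_hap[phased.hap_a]
    ffr_b = ffr_of_hap[phased.hap_b]
    sp_a = ffr_labels.get(ffr_a)
    sp_b = ffr_labels.get(ffr_b)
    evidence = tuple(sorted({ffr_a, ffr_b}))
    if sp_a is not None and sp_b is not None and sp_a != sp_b:
        return LocusCall(phased.specimen_id, phased.locus,
                         CallType.HETEROSPECIFIC_HETEROZYGOTE, evidence=evidence)
    if ffr_a != ffr_b:
        # two distinct pools of one species (or unlabeled): within-species lineages
        return LocusCall(phased.specimen_id, phased.locus,
                         CallType.INTRASPECIFIC_LINEAGE_HETEROZYGOTE,
                         species=sp_a or sp_b, evidence=evidence)
    if sp_a is None:
        return LocusCall(phased.specimen_id, phased.locus, CallType.UNRESOLVED,
                         evidence=evidence)
    if specimen_species not in ("unknown", "") and sp_a != specimen_species:
        return LocusCall(phased.specimen_id, phased.locus,
                         CallType.HETEROSPECIFIC_HOMOZYGOTE, species=sp_a,
                         evidence=evidence)
    return LocusCall(phased.specimen_id, phased.locus, CallType.PURE,
                     species=sp_a, evidence=evidence)


def _summary_flag(
    calls: Sequence[LocusCall], species: str, mt_species: Optional[str]
) -> SummaryFlag:
    """Total rule table over nuclear calls and the mt clade label."""
    kinds = {c.call for c in calls}
    if CallType.HETEROSPECIFIC_HETEROZYGOTE in kinds:
        return SummaryFlag.HYBRID_CANDIDATE
    mt_concordant = mt_species is None or species in ("unknown", "") or mt_species == species
    if CallType.HETEROSPECIFIC_HOMOZYGOTE in kinds and mt_concordant:
        return SummaryFlag.INTROGRESSION_CANDIDATE
    nuclear = [c.species for c in calls
               if c.call in (CallType.PURE, CallType.HETEROSPECIFIC_HOMOZYGOTE)
               and c.species]
    if nuclear and mt_species is not None:
        majority = max(set(nuclear), key=lambda sp: (nuclear.count(sp), sp))
        if majority != mt_species:
            return SummaryFlag.MITO_NUCLEAR_DISCORDANT
    if not mt_concordant:
        return SummaryFlag.MITO_NUCLEAR_DISCORDANT
    return SummaryFlag.CONCORDANT


def discordance_report(
    calls: Sequence[LocusCall],
    mt_clades: Sequence[FFR],
    metadata: Sequence[SpecimenRecord],
    mt_labels: Optional[Mapping[str, Optional[str]]] = None,
    karyotype_ok: Optional[Mapping[str, Optional[bool]]] = None,
) -> list[SpecimenSummary]:
    """Combine nuclear locus calls with mt clade membership per specimen."""
    if mt_labels is None:
        mt_labels = label_ffrs(mt_clades, metadata)
    mt_of_specimen: dict[str, Optional[str]] = {}
    for clade in mt_clades:
        for sid in clade.members:
            mt_of_specimen[sid] = mt_labels.get(clade.ffr_id)
    by_specimen: dict[str, dict[str, LocusCall]] = {}
    for c in calls:
        by_specimen.setdefault(c.specimen_id, {})[c.locus] = c
    out = []
    for m in metadata:
        specimen_calls = by_specimen.get(m.specimen_id, {})
        if not specimen_calls:
            continue
        mt_sp = mt_of_specimen.get(m.specimen_id)
        flag = _summary_flag(list(specimen_calls.values()), m.species_label, mt_sp)
        out.append(
            SpecimenSummary(
                specimen_id=m.specimen_id,
                species_label=m.species_label,
                mt_clade_species=mt_sp,
                locus_calls=dict(sorted(specimen_calls.items())),
                flag=flag,
                karyotype_consistent=(karyotype_ok or {}).get(m.specimen_id),
            )
        )
    return out


def fixed_differences(
    group_a: Sequence[str], group_b: Sequence[str], length: Optional[int] = None
) -> list[int]:
    """Aligned positions where the two allele groups are fixed for
    different bases.  Non-base symbols (N, gaps) are excluded per site;
    a site fixed in one group but empty in the other does not count.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    n = length if length is not None else len(group_a[0])
    out = []
    for i in range(n):
        a_bases = {s[i] for s in group_a} & BASES
        b_bases = {s[i] for s in group_b} & BASES
        if len(a_bases) == 1 and len(b_bases) == 1 and a_bases != b_bases:
            out.append(i)
    return out
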