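"""Synthetic multilocus diploid cohorts with truth tables.

The generator emulates the regime the downstream procedures presume: per
locus, two diverged allele pools (species A and B) separated by a small
Poisson number of fixed substitutions, low within-pool polymorphism
realised as private variants on the second allele of heterozygous pure
specimens (star genealogy around each pool consensus), a lineage-specific
short deletion defining an "E" sublineage of species A at one locus, and
a haploid mitochondrial locus whose clade can be made to disagree with
the nuclear pools.

Specimen classes: pure A / pure B (two same-pool alleles), F1 hybrids
(one consensus allele of each species), introgressed homozygotes (labelled
A, both alleles B at the target locus), W/E heterozygotes and E homozygotes
(the within-A sublineage structure at the deletion locus).

Heterozygous sites are emitted as IUPAC codes.  A heterozygous indel is
emitted as the code pairing the non-deleted allele's base with the
deterministic per-column fill base (:func:`haploweb.seqio.fill_base`),
so re-reading the FASTA and filling gaps with the same seed reproduces
the truth alleles bit-exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .seqio import (
    BASES,
    CODE_FOR_PAIR,
    GenotypeSequence,
    LocusAlignment,
    Ploidy,
    SpecimenRecord,
    fill_base,
    write_locus_fasta,
    write_metadata,
)

__all__ = ["LocusSpec", "SimConfig", "LocusSim", "Cohort", "simulate_locus",
           "make_cohort", "write_cohort", "DEFAULT_LOCI"]

_BASES = "ACGT"


@dataclass(frozen=True)
class LocusSpec:
    name: str
    length: int
    ploidy: Ploidy = Ploidy.DIPLOID
    codon_framed: bool = False
    has_deletion: bool = False          # E sublineage with gap run exists here
    introgression_target: bool = False  # locus where introgressed specimens are B/B


#: mt + two nuclear loci with lengths mimicking a mitochondrial gene, a
#: codon-framed nuclear exon and a joined two-fragment nuclear locus
DEFAULT_LOCI: tuple[LocusSpec, ...] = (
    LocusSpec("mt", 1143, Ploidy.HAPLOID, codon_framed=True),
    LocusSpec("nuc1", 1404, Ploidy.DIPLOID, codon_framed=True,
              introgression_target=True),
    LocusSpec("nuc2", 970, Ploidy.DIPLOID, has_deletion=True),
)


@dataclass
class SimConfig:
    seed: int = 0
    loci: tuple[LocusSpec, ...] = DEFAULT_LOCI
    divergence_expected: float = 3.0     # E[fixed diffs] between species pools
    mt_divergence_expected: float = 12.0
    we_divergence_expected: float = 2.0  # W vs E substitutions besides the deletion
    min_fixed: int = 1                   # floor on realized fixed diffs when rate > 0
    het_private_rate: float = 0.5        # E[private subs] on a het second allele
    p_het: float = 0.4                   # P(pure specimen heterozygous at a locus)
    mt_private_rate: float = 0.8
    deletion_len: int = 3
    deletion_start: int = 6
    n_pure_a: int = 8
    n_pure_b: int = 8
    n_f1: int = 0
    n_introgressed: int = 0
    n_we_het: int = 0
    n_e_hom: int = 0
    n_mt_discordant: int = 0
    species_a: str = "alaicus"
    species_b: str = "tancrei"

    def __post_init__(self) -> None:
        counts = (self.n_pure_a, self.n_pure_b, self.n_f1, self.n_introgressed,
                  self.n_we_het, self.n_e_hom, self.n_mt_discordant)
        if any(c < 0 for c in counts):
            raise ValueError("cohort composition counts must be non-negative")
        if self.divergence_expected < self.het_private_rate:
            raise ValueError(
                "interspecies divergence must exceed within-pool diversity"
            )
        if self.deletion_len > 5:
            raise ValueError("deletion longer than fillable gap run")
        if (self.n_we_het or self.n_e_hom) and not any(
            s.has_deletion for s in self.loci
        ):
            raise ValueError("W/E classes need a deletion-bearing locus")
        if self.n_introgressed and not any(s.introgression_target for s in self.loci):
            raise ValueError("introgressed class needs a target locus")
        if self.n_mt_discordant > self.n_pure_a:
            raise ValueError("mt-discordant specimens are drawn from pure A")


@dataclass
class LocusSim:
    """Per-locus truth: pool consensus alleles and deletion bookkeeping."""

    spec: LocusSpec
    ancestral: str
    raw: dict[str, str]        # pool -> allele with gaps as '-' (E only)
    filled: dict[str, str]     # pool -> allele after deterministic fill
    fixed_sites: list[int]
    gap_cols: list[int]
    fills: dict[int, str]


def _poisson_count(rng: np.random.Generator, lam: float, min_fixed: int) -> int:
    k = int(rng.poisson(lam)) if lam > 0 else 0
    if lam > 0:
        k = max(k, min_fixed)
    return k


def _mutate(seq: str, positions, rng: np.random.Generator) -> str:
    chars = list(seq)
    for p in positions:
        alt = [b for b in _BASES if b != chars[p]]
        chars[p] = alt[rng.integers(len(alt))]
    return "".join(chars)


def simulate_locus(cfg: SimConfig, spec: LocusSpec,
                   rng: np.random.Generator) -> LocusSim:
    """Ancestral sequence, two diverged pools, optional E sublineage."""
    ancestral = "".join(_BASES[i] for i in rng.integers(4, size=spec.length))
    gap_cols = (
        list(range(cfg.deletion_start, cfg.deletion_start + cfg.deletion_len))
        if spec.has_deletion else []
    )
    mutable = [i for i in range(spec.length) if i not in gap_cols]
    lam = (cfg.mt_divergence_expected if spec.ploidy is Ploidy.HAPLOID
           else cfg.divergence_expected)
    k = min(_poisson_count(rng, lam, cfg.min_fixed), len(mutable))
    fixed_sites = sorted(rng.choice(mutable, size=k, replace=False).tolist()) if k else []
    pool_a = ancestral
    pool_b = _mutate(ancestral, fixed_sites, rng)
    raw = {"A": pool_a, "B": pool_b}
    fills: dict[int, str] = {}
    if spec.has_deletion:
        free = [i for i in mutable if i not in fixed_sites]
        kw = min(_poisson_count(rng, cfg.we_divergence_expected, cfg.min_fixed),
                 len(free))
        we_sites = rng.choice(free, size=kw, replace=False).tolist() if kw else []
        e_seq = _mutate(pool_a, we_sites, rng)
        e_chars = list(e_seq)
        for c in gap_cols:
            observed = {raw["A"][c], raw["B"][c]} & BASES
            fills[c] = fill_base(cfg.seed, spec.name, c, BASES - observed)
            e_chars[c] = "-"
        raw["E"] = "".join(e_chars)
    filled = {
        pool: "".join(fills[i] if ch == "-" else ch for i, ch in enumerate(seq))
        for pool, seq in raw.items()
    }
    return LocusSim(spec=spec, ancestral=ancestral, raw=raw, filled=filled,
                    fixed_sites=fixed_sites, gap_cols=gap_cols, fills=fills)


@dataclass
class Cohort:
    config: SimConfig
    alignments: dict[str, LocusAlignment]
    metadata: list[SpecimenRecord]
    loci: dict[str, LocusSim]
    truth: dict


def _genotype_string(a: str, b: str, fills: dict[int, str]) -> str:
    out = []
    for i, (x, y) in enumerate(zip(a, b)):
        if x == y:
            out.append(x)
        elif "-" in (x, y):
            base = y if x == "-" else x
            out.append(CODE_FOR_PAIR[frozenset((base, fills[i]))])
        else:
            out.append(CODE_FOR_PAIR[frozenset((x, y))])
    return "".join(out)


def make_cohort(cfg: SimConfig) -> Cohort:
    """Assemble diploid genotypes, metadata and the truth table."""
    rng = np.random.default_rng(cfg.seed)
    loci = {spec.name: simulate_locus(cfg, spec, rng) for spec in cfg.loci}

    specimens: list[tuple[str, str]] = []  # (specimen_id, class)
    specimens += [(f"a{i + 1:02d}", "pure_a") for i in range(cfg.n_pure_a)]
    specimens += [(f"b{i + 1:02d}", "pure_b") for i in range(cfg.n_pure_b)]
    specimens += [(f"f{i + 1:02d}", "f1") for i in range(cfg.n_f1)]
    specimens += [(f"i{i + 1:02d}", "introgressed") for i in range(cfg.n_introgressed)]
    specimens += [(f"w{i + 1:02d}", "we_het") for i in range(cfg.n_we_het)]
    specimens += [(f"e{i + 1:02d}", "e_hom") for i in range(cfg.n_e_hom)]
    discordant = {f"a{i + 1:02d}" for i in range(cfg.n_mt_discordant)}

    _LOCALITY = {"pure_a": (3, 4, 5, 6), "pure_b": (11, 12, 13, 14), "f1": (1,),
                 "introgressed": (7,), "we_het": (3, 4, 5, 6), "e_hom": (9,)}
    _KARYO = {
        "pure_a": ("2Rb(2.11)", 52), "we_het": ("2Rb(2.11)", 52),
        "e_hom": ("2Rb(2.11)", 52), "introgressed": ("2Rb(2.11)", 52),
        "pure_b": ("", 54), "f1": ("1Rb(2.11)", 53),
    }

    def _pools_for(cls: str, spec: LocusSpec) -> tuple[str, str]:
        if cls == "f1":
            return ("A", "B")
        if cls == "pure_b":
            return ("B", "B")
        if cls == "introgressed" and spec.introgression_target:
            return ("B", "B")
        if cls == "we_het" and spec.has_deletion:
            return ("A", "E")
        if cls == "e_hom" and spec.has_deletion:
            return ("E", "E")
        return ("A", "A")

    alleles: dict[str, dict[str, tuple[str, str]]] = {n: {} for n in loci}
    pools_truth: dict[str, dict[str, tuple[str, str]]] = {n: {} for n in loci}
    rows: dict[str, list[GenotypeSequence]] = {n: [] for n in loci}
    metadata: list[SpecimenRecord] = []
    mt_lineage: dict[str, str] = {}

    for idx, (sid, cls) in enumerate(specimens):
        locs = _LOCALITY[cls]
        formula, stated = _KARYO[cls]
        metadata.append(
            SpecimenRecord(
                specimen_id=sid,
                species_label=cfg.species_b if cls == "pure_b" else cfg.species_a,
                locality_id=locs[idx % len(locs)],
                karyotype_formula=formula or None,
                stated_2n=(stated, stated),
            )
        )
        for name, sim in loci.items():
            spec = sim.spec
            if spec.ploidy is Ploidy.HAPLOID:
                lineage = "B" if cls == "pure_b" or sid in discordant else "A"
                mt_lineage[sid] = lineage
                n_priv = int(rng.poisson(cfg.mt_private_rate))
                free = [i for i in range(spec.length) if i not in sim.fixed_sites]
                priv = rng.choice(free, size=min(n_priv, len(free)),
                                  replace=False).tolist()
                seq = _mutate(sim.raw[lineage], priv, rng)
                alleles[name][sid] = (seq, seq)
                pools_truth[name][sid] = (lineage, lineage)
                rows[name].append(GenotypeSequence(sid, name, seq, Ploidy.HAPLOID))
                continue
            pa, pb = _pools_for(cls, spec)
            raw_a, raw_b = sim.raw[pa], sim.raw[pb]
            if cls in ("pure_a", "pure_b") or (
                cls in ("introgressed", "we_het", "e_hom")
                and (pa, pb) == ("A", "A")
            ):
                # within-pool diversity: private substitutions on allele 2
                if rng.random() < cfg.p_het:
                    n_priv = int(rng.poisson(cfg.het_private_rate))
                    protected = set(sim.fixed_sites) | set(sim.gap_cols)
                    free = [i for i in range(spec.length) if i not in protected]
                    priv = rng.choice(free, size=min(n_priv, len(free)),
                                      replace=False).tolist()
                    raw_b = _mutate(raw_b, priv, rng)
            geno = _genotype_string(raw_a, raw_b, sim.fills)
            rows[name].append(GenotypeSequence(sid, name, geno, Ploidy.DIPLOID))
            fill = lambda s: "".join(
                sim.fills[i] if ch == "-" else ch for i, ch in enumerate(s)
            )
            pair = tuple(sorted((fill(raw_a), fill(raw_b))))
            alleles[name][sid] = pair
            pools_truth[name][sid] = (pa, pb)

    alignments = {
        name: LocusAlignment(
            locus=name, ploidy=sim.spec.ploidy,
            sequences=tuple(rows[name]), codon_framed=sim.spec.codon_framed,
        )
        for name, sim in loci.items()
    }
    truth = {
        "seed": cfg.seed,
        "classes": {sid: cls for sid, cls in specimens},
        "species": {m.specimen_id: m.species_label for m in metadata},
        "mt_lineage": mt_lineage,
        "alleles": alleles,
        "pools": pools_truth,
        "fixed_sites": {n: s.fixed_sites for n, s in loci.items()},
        "gap_columns": {n: s.gap_cols for n, s in loci.items()},
        "fills": {n: {str(c): b for c, b in s.fills.items()} for n, s in loci.items()},
        "expected_pools": {
            n: sorted({p for pair in pools_truth[n].values() for p in pair})
            for n in loci
        },
    }
    return Cohort(config=cfg, alignments=alignments, metadata=metadata,
                  loci=loci, truth=truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> list[Path]:
    """Emit ``locus_<name>.fasta``, ``metadata.tsv`` and ``truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, aln in sorted(cohort.alignments.items()):
        p = outdir / f"locus_{name}.fasta"
        write_locus_fasta(aln, p)
        written.append(p)
    p = outdir / "metadata.tsv"
    write_metadata(cohort.metadata, p)
    written.append(p)
    p = outdir / "truth.json"
    with open(p, "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    written.append(p)
    return written
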