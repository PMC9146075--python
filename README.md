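# haploweb

Haplotype-web species delimitation for multilocus Sanger data, built as a
tested, fully synthetic-data-capable pipeline:

- **seqio** — aligned multi-FASTA and metadata I/O; heterozygous sites as
  two-base IUPAC codes; short deletions recoded as shared diagnostic
  columns filled with a seeded, per-column absent base.
- **phasing** — deterministic phasing of diploid genotypes by subtracting
  homozygote-pool references, with locality-then-frequency preference;
  ambiguous cases stay unresolved, deduced alleles carry a `*` suffix.
- **network** — epsilon-0 minimum-spanning networks (all tied MST edges),
  heterozygote arcs, field-for-recombination (FFR) delimitation with
  hybrid-bridge detection, distance-threshold clades for haploid loci,
  and the multilocus conspecificity matrix with majority consensus
  clusters.
- **karyotype** — Robertsonian-fusion arithmetic on a 2n = 54 base
  complement: formula parsing, diploid numbers (incl. mosaic ranges),
  F1 prediction, and stated-vs-computed consistency checks.
- **classify** — per-locus calls (pure / heterospecific heterozygote or
  homozygote / intraspecific lineage heterozygote) and the per-specimen
  summary: hybrid candidate, introgression/ancestral-polymorphism
  candidate, mito-nuclear discordant, or concordant.
- **simdata** — seeded cohort simulator (two diverged allele pools per
  locus, within-pool star-genealogy polymorphism, a lineage-specific
  3-nt deletion, F1 hybrids, introgressed homozygotes, W/E lineage
  heterozygotes, discordant mitochondria) with a complete truth table.
- **cli** — `haploweb` command with `simulate`, `phase`, `haploweb`,
  `consensus`, `classify` and `run` subcommands; `run` writes a
  checksummed artifact manifest and is byte-deterministic per seed.

## Quick start

```sh
# emit a synthetic cohort with two F1 hybrids and one introgressed specimen
haploweb simulate --seed 7 --out sim --f1 2 --introgressed 1

# run the whole pipeline
cat > config.json <<'EOF'
{
  "metadata": "sim/metadata.tsv",
  "fill_seed": 7,
  "loci": [
    {"name": "mt",   "path": "sim/locus_mt.fasta", "ploidy": "haploid", "codon_framed": true},
    {"name": "nuc1", "path": "sim/locus_nuc1.fasta", "codon_framed": true},
    {"name": "nuc2", "path": "sim/locus_nuc2.fasta"}
  ]
}
EOF
haploweb run --config config.json --out out
```

Outputs include phased haplotype TSV/FASTA per locus, GraphML/DOT
haplowebs, FFR membership, the conspecificity matrix with consensus
clusters, per-locus calls, the specimen discordance report, and
`manifest.json` with SHA-256 checksums of every artifact.

## Input conventions

- Per-locus aligned multi-FASTA over `A C G T R Y S W K M N -`; haploid
  loci may not carry ambiguity codes; three-peak sites are invalid.
- Metadata TSV columns: `specimen_id species locality karyotype stated_2n`
  (karyotype as e.g. `2Rb(2.11),1-2Rb(3.10)`, stated_2n as `51` or `50-51`).
- Coordinates are 0-based internally and 1-based in reports.
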