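# pacce

Analysis pipeline for photoaffinity-competition chemoproteomics: from
probe-modified peptide observations with SILAC channel intensities to
RNA-sensitive cysteine (RS-Cys) calls, domain/overlap enrichment statistics,
and structure-based Cys-RNA proximity validation. A synthetic-data module
generates ground-truth proteomes, in-silico digests, SILAC PSM tables with
planted competition effects, and toy protein-RNA coordinate files, so every
stage is testable without external data.

## Modules

- `pacce.simulate` — synthetic proteomes with planted RNA-sensitive
  cysteines, tryptic digests (fully/half-tryptic, missed cleavages), SILAC
  PSM tables with a multiplicative competition model and lognormal noise,
  and toy PDB files with planted minimum Cys-RNA distances.
- `pacce.sites` — PSM table I/O with score filtering and adduct-mass
  labeling, SILAC ratio (SR) computation with orientation and capping,
  peptide-to-protein-site mapping, per-replicate median / cross-replicate
  mean site aggregation, and residue-selectivity reporting.
- `pacce.calling` — RS-Cys classification (mean PACCE SR >= 2 by default)
  with one-tailed exact Mann-Whitney U significance against the 1:1 mixing
  control, computed by exhaustive enumeration for small designs (all 84
  orderings for 3-vs-6 replicates); base-competition calls (SR >= 5) and
  RNase-control comparisons.
- `pacce.enrichment` — two-sided exact binomial domain enrichment with
  Benjamini-Hochberg correction (enriched at Q < 0.01), hypergeometric
  set-overlap significance, average-down site harmonization, and IDR joins.
- `pacce.structure` — PDB parsing (first model, highest-occupancy altloc),
  composition-based chain typing, author-to-reference residue renumbering,
  minimum SG-to-RNA-atom Euclidean distances over all residue instances, and
  distance summaries by RS class.
- `pacce.pipeline` / `pacce.cli` — orchestration with provenance, TSV stage
  outputs, a JSON summary, and a human-readable report.

## CLI

```sh
pacce simulate --seed 1 --outdir out/sim
pacce quantify --psm out/sim/psm.tsv --fasta out/sim/proteome.fasta --out out/sites.tsv
pacce call --sites out/sites.tsv --sr-threshold 2 --out out/calls.tsv
pacce enrich --calls out/calls.tsv --background out/sites.tsv \
    --domains out/sim/domains.tsv --out out/enrichment.tsv
pacce distance --pdb structure.pdb --renumber-map map.tsv --out out/distances.tsv
pacce run --seed 1 --outdir out/run        # full synthetic pipeline + report
```

`pacce run` accepts a TOML config (`--config`) with top-level analysis
thresholds (`sr_threshold`, `q_cutoff`, `resolution_max`, ...) and a
`[simulation]` table (`n_proteins`, `noise_cv`, `rs_fraction`,
`rnase_mode`, ...).

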