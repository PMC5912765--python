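# domssr

Diversity analysis for dominant SSR (band presence/absence) genotype panels:

- **genotype_io** — CSV/TSV genotype tables (`PRIMER.SIZE` band labels),
  group metadata, square-CSV/PHYLIP distance matrices, Newick trees.
- **synthetic_data** — seeded simulator for panels with group structure,
  private bands, admixed hybrids and missing data, plus a fixed worked
  example (`toy6`).
- **marker_stats** — per-primer PIC, multiplex ratio *n*, polymorphic
  fraction β, effective multiplex ratio *E = nβ*, marker index
  *MI = PIC·E*, resolving power *Rp*, distinct-profile counts, and
  per-group gene diversity *D*.
- **allele_accounting** — group presence sets, exclusive (private) alleles,
  focal-group absence reports with source attribution, and tracing of
  source-exclusive alleles into a target group.
- **dissimilarity** — Jaccard-complement distances (pairwise deletion for
  missing cells), within/between group summaries, extreme pairs.
- **amova** — one-level AMOVA on binary profiles (squared-Euclidean =
  mismatch distances), Φ<sub>ST</sub> with a permutation test.
- **trees_ordination** — Neighbor-Joining with band-bootstrap bipartition
  supports; PCoA with negative-eigenvalue reporting and optional Cailliez
  correction.
- **marker_sufficiency** — bootstrap CV% of pairwise dissimilarities over a
  marker-count grid, power-law/exponential decay fit, and the minimum
  marker count for a CV threshold.
- **evanno_support** — Evanno ΔK and best-K selection from (K, run, lnP)
  tables.

## CLI

Everything is reachable through one entry point:

```sh
domssr simulate   --config sim.yaml --out-prefix panel
domssr stats      --genotypes panel.genotypes.csv --groups panel.groups.csv \
                  --subset all --subset G1 --out stats.csv
domssr accounting --genotypes ... --groups ... --focal G1 --trace G2:hybrid --out ledger/
domssr dist       --genotypes ... --out-matrix d.csv --format square-csv --summary summary.csv --groups ...
domssr amova      --genotypes ... --groups ... --contrast G1:G2 --perms 1023 --seed 1 --out amova.csv
domssr nj         --genotypes ... --boot 1000 --seed 1 --out tree.nwk
domssr pcoa       --genotypes ... --axes 2 --out-prefix pcoa
domssr sufficiency --genotypes ... --step 3 --reps 1000 --threshold 10 --seed 1 --out cv.csv
domssr evanno     --input lnp.csv --out evanno.csv
domssr run        --config analysis.yaml
```

`domssr run` executes the whole pipeline (stats → accounting → distances →
AMOVA → tree/PCoA → sufficiency) from a YAML config and writes a bundle
with a `manifest.json` recording seeds and parameters; one global seed is
fanned out deterministically to per-stage seeds.

Example `analysis.yaml`:

```yaml
genotypes: panel.genotypes.csv
groups: panel.groups.csv
outdir: out
seed: 1
contrasts: [[G1, G2]]
focal_group: G1
amova_permutations: 1023
tree_bootstraps: 1000
```

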