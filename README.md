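# trimix

Supervised trihybrid ancestry analysis for admixed cohorts genotyped at a
small panel of biallelic ancestry-informative markers (AIMs).

Given a genotype matrix (0/1/2 counts of the short allele at each locus) and
fixed reference allele frequencies for three ancestral populations
(European, African, Amerindian), the package:

- **estimates** each individual's ancestry proportions by maximum
  likelihood (EM on the binomial admixture likelihood, plus a
  boundary-aware quasi-Newton polish);
- **summarizes** per-(region, color-category) cohorts: component means,
  standard errors, ternary and Cartesian plot coordinates;
- **weights** color-category means by census composition to produce a
  color-independent regional "total ancestry";
- **tests** pairwise differences between cohorts via a Monte Carlo
  randomization test of the Euclidean distance between cohort mean points
  in the (European, African) plane, with Bonferroni control;
- **simulates** reference panels (Balding–Nichols divergence) and admixed
  cohorts (Dirichlet ancestry, binomial genotypes) with known ground truth,
  so every stage is verifiable end to end.

Packaged fixture tables (`trimix/data/`) carry the published census
percentages and per-category ancestry means used by the weighting stage.

## Command line

```sh
trimix simulate --config config.yaml --out simdir/
trimix estimate --genotypes simdir/genotypes.tsv --panel simdir/panel.tsv --out ancestry.tsv
trimix summarize --ancestry ancestry.tsv --out summary.csv
trimix total-ancestry --out totals.csv                  # packaged tables by default
trimix disttest --ancestry ancestry.tsv --out dist --cycles 10000 --seed 1 --color Brown
trimix run --config config.yaml                         # full pipeline + manifest
```

Example pipeline config:

```yaml
seed: 1
out_dir: out
n_cycles: 10000
alpha: 0.05
simulate:
  n_loci: 40
  fst: 0.15
  cohorts:
    - {region: North, color: Brown, n: 100, dirichlet: [3, 1, 1]}
    - {region: South, color: Brown, n: 100, dirichlet: [1, 1, 3]}
census: {North: [30, 60, 10], South: [70, 20, 10]}   # or "builtin", or a CSV path
```

Setting `paper_tables: true` skips simulation/estimation and runs the
census-weighting stage on the packaged printed tables. Every run writes a
`manifest.json` (config hash, seed, version) sufficient to reproduce all
outputs byte-for-byte.

## File formats

All formats are plain TSV/CSV with `#`-prefixed provenance comments:
genotypes (`id`, `region`, `color`, one column per locus; `NA` = missing),
reference panels (`locus_id` + one frequency column per population),
per-individual ancestry estimates, cohort summaries, census tables, and
distance matrices (D above the diagonal, p below). A reader for the classic
two-row-per-individual STRUCTURE genotype dialect is included.

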