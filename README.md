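# transchrom

Analysis toolkit for studying how a *trans*-acting locus coordinates
heterochromatin (H3K9me3), active chromatin (H3K27ac, ATAC), 3D contact
frequency (HiChIP PET counts) and gene expression across inbred mouse strains
(B6, D2), their F1 hybrid, and reciprocal congenic lines (B6-13D2, D2-13B6).

The package provides, as composable library modules plus a CLI:

- **`simulate`** — a seeded synthetic-data generator producing multi-strain,
  multi-assay negative-binomial count matrices with planted *cis* (additive)
  and *trans* (dominant-repressive) effects, spatially planted trans-target
  peaks near designated eGene TSSs, and a ground-truth table for
  parameter-recovery testing.
- **`core_io`** — typed genomic primitives (intervals, interactions, genes,
  count matrices, sample sheets) and strict plain-text readers/writers
  (BED, BEDPE, TSV). All coordinates are 0-based half-open.
- **`normdiff`** — native TMM normalization, the high-confidence interaction
  filter (midpoint span > 5 kb AND >= 4 counts in >= 2 samples), a
  method-of-moments common NB dispersion estimator, an exact conditional NB
  differential test (binomial split at phi = 0), and Benjamini-Hochberg FDR.
- **`qtl`** — differential-interaction anchor overlap with QTL targets,
  permutation enrichment against a peak universe, interaction-strength vs
  QTL-effect Pearson correlation, allele-concordance chi-squared, and
  per-factor Fisher binding-site enrichment.
- **`signature`** — cross-assay fold-change tables, ATAC/H3K9me3 discordance
  calls (opposing significant changes), the trans-vs-cis discordance odds
  ratio, and the promoter connectivity / expression quartile ANOVA.
- **`rad`** — spatial (region-associated-differential) binomial enrichment of
  focal peaks near focal gene TSSs in strand-aware signed-distance bins
  (100 kb bins spanning -500 kb..+500 kb, p0 = M_focal/N_total).
- **`dominance`** — per-feature dominance coefficients
  d = (F1 - midparent)/(high parent - midparent), repressive-allele
  classification from signed QTL effects, and trans-vs-cis rank-sum contrast.
- **`congenic`** — signed direction predictions for parent -> congenic
  comparisons from repressive-allele calls, observed direction scoring, exact
  binomial validation, and validated-vs-not effect-size contrast.
- **`pipeline`** — end-to-end orchestration with a single global seed,
  per-stage derived seeds, and a hash-carrying JSON run report.

## CLI

```sh
transchrom simulate --seed 1 --outdir sim/            # synthetic dataset
transchrom diff-interactions --counts sim/counts_PET.tsv \
    --samples sim/samples.tsv --bedpe sim/interactions.bedpe --out di.tsv
transchrom diff-peaks --counts sim/counts_ATAC.tsv --samples sim/samples.tsv \
    --assay ATAC --out atac_diff.tsv
transchrom rad --genes sim/genes.tsv --peaks sim/peaks.bed \
    --focal-genes fg.txt --focal-peaks fp.txt --out rad.tsv
transchrom dominance --counts sim/counts_ATAC.tsv --samples sim/samples.tsv \
    --targets sim/qtl_targets.tsv --out-table d.tsv --out-comparison d.json
transchrom run --seed 1 --outdir run/                 # full pipeline
```

Run `transchrom --help` or `transchrom <command> --help` for all options.

## Tests

```sh
python -m pytest -q tests/
```

The suite (~1 min) includes per-module unit tests, hypothesis property tests,
and `tests/test_acceptance.py`, which implements the acceptance criteria:
independent brute-force oracle equivalence for every statistical primitive,
NB exact-test type-I calibration, TMM properties, end-to-end parameter
recovery on the default synthetic configuration, null-generator
falsification, and the hand-derived interaction-filter fixture.

## Conventions and caveats

- Interaction span is measured **midpoint to midpoint** (anchor-width
  invariant); this interacts with the 5 kb confidence filter.
- All parsers reject malformed input with the offending line named; 1-based
  coordinates are never auto-detected.
- The differential test is a single-common-dispersion exact conditional NB
  test; it matches the statistical family, not the numerics, of
  edgeR/DESeq2-style tools.
- RAD distance bins are half-open `(lo, hi]`, ascending from -window, with
  the first bin closed below; a distance of exactly 0 falls in
  `(-bin_width, 0]`.
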