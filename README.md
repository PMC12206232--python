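# mloykit

Quantification of mosaic loss of chromosome Y (mLOY) in blood and tissue,
with the downstream statistics used to relate Y loss to fibrotic lung
disease. The package covers three measurement routes and their analyses:

- **SNP arrays** (`mloykit.array_mloy`) — per-subject medians of X/Y-probe
  log-R ratios (mLRRX/mLRRY), derivative log-ratio spread (DLRS) quality
  control at Q3 + 1.5 IQR, sex-aneuploidy exclusion, batch-median
  adjustment, the `100 * (1 - 2**mLRRY)` percent transformation, and a
  detection threshold derived from the lower tail of the experimental-noise
  confidence interval (default 99%).
- **Digital PCR** (`mloykit.dpcr_mloy`) — Poisson inversion of partition
  counts for a Y target and its X homologue, the copy-ratio estimator
  `(1 - lambda_Y/lambda_X) * 100%`, percentile-bootstrap CIs, and the
  40% high-mLOY category.
- **Single-cell RNA-seq** (`mloykit.sc_loy`) — QC (mito fraction,
  expressed-gene bounds, read-depth gate), LOY calling by complete absence
  of male-specific-region (MSY) transcripts, marker-based hierarchical
  cell-type annotation, per-type case/control Fisher enrichment, and
  percent-LOY summaries with exact binomial CIs.

Two analysis layers sit on top:

- `mloykit.fibro_sig` — LOY-vs-WT differential expression (rank-sum + BH),
  binned-control module scores (TGF-signaling / fibroblast-activation style
  gene sets, GMT input), per-lineage score tests, detection-based logistic
  likelihood-ratio tests, hypergeometric over-representation, and the
  donor-level %LOY-vs-fibroblast-activation regression.
- `mloykit.cohort_epi` — logistic / Cox / linear model orchestration for
  incidence, survival and lung function, product-of-paths mediation with a
  percentile bootstrap, median imputation of exposures, and the
  male-excess attribution decomposition (which share of the male-female
  excess in events falls in the mLOY-carrier group).

Every stage is testable offline: `mloykit.synthdata` generates seeded
synthetic inputs (array intensities, dPCR plates, droplet scRNA-seq counts
with donor structure and LOY-coupled profibrotic up-regulation, cohort
outcome tables) together with ground-truth sidecars.

## Command line

The console script `mloykit` exposes one subcommand per stage:

```sh
mloykit synth array --outdir demo --n 200 --seed 1   # synthetic cohort + truth
mloykit array demo/probes.csv --out estimates.csv --min-reference 20
mloykit synth dpcr --outdir demo
mloykit dpcr demo/plates.csv --out dpcr.csv --boot 2000 --seed 1
mloykit synth sc --outdir demo_sc --n 300 --seed 2
mloykit sc demo_sc --out calls.csv --enrichment-out enrichment.csv \
    --mito-max 1.0 --genes-min 0 --genes-max 100000
mloykit score demo_sc --set FIBROBLAST_ACTIVATION --out scores.csv --seed 3
mloykit dge demo_sc --out dge.csv --min-reads 4000
mloykit synth epi --outdir demo_epi --n 50000 --seed 4
mloykit epi demo_epi/cohort.csv --model survival --mloy percent --out fit.csv
```

Single-cell input is a 10x-style directory (`matrix.mtx`, `features.tsv`,
`barcodes.tsv`, optional `cells.csv` metadata). The shipped MSY gene list
(`--msy-list`) and the illustrative GMT gene sets are overridable.

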