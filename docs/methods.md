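# Methods

## Scope and data model

The pipeline starts from count matrices, not reads: a features × cells RNA
matrix and a 7-protein ADT matrix (CD99 plus the six typing markers CD19,
CD14, CD16, CD56, CD8, CD4) in the 10x MatrixMarket dialect, with a per-cell
sample sheet (donor, library-prep batch, sequencing batch). RNA and ADT are
kept as separate matrices sharing barcodes; they are normalized differently
and never concatenated. Gene region classes (MSY / PAR / X non-PAR /
autosome) come from a static annotation table shipped with the package;
symbols absent from it default to autosome with a warning, so arbitrary 10x
feature files process without a live annotation service.

## QC

Three per-cell criteria on the RNA assay, with literal boundary semantics:
`n_genes <= 2000` (cells expressing *more than* 2000 genes are treated as
suspected doublets), `n_umi >= 2500`, and mitochondrial percentage inside
the closed interval [1.5, 5.0] (0–100 scale; "MT-"-prefixed symbols).
A rejected cell reports the first failing criterion in the fixed order
genes → umi → mito. `pct_mito` of an all-zero cell is defined as 0; such a
cell fails the UMI criterion anyway. ADT counts of rejected cells are
discarded before normalization: cells are filtered first, then both assays
are normalized over kept cells only.

## Normalization

* RNA: `ln(1 + count * 10^4 / cell_total)`. Zero maps to zero; values are
  invariant to per-cell depth scaling.
* ADT: centered log-ratio per cell across the panel,
  `ln(1+c_i) - mean_j ln(1+c_j)`. The per-cell margin treats the panel as
  the measured composition; values sum to zero per cell by construction
  (asserted at 1e-9). The per-feature (across cells) margin also exists in
  the ecosystem; per-cell is this package's default. Note that per-cell CLR
  is compositional: a genuine change in one protein mechanically shifts the
  other panel members' CLR by 1/p of the log change in the opposite
  direction. With p = 7 and the largest injected CD99 effect (−0.31), this
  leakage is ≤ 0.05 CLR units — visible as a small positive bias on the
  null marker rows at large n (see "Limitations").
* Min-max 0–1 scaling per cell-type group exists for display tables only
  and never feeds a statistic; a constant group maps to zero with a warning.

Natural logarithms are used throughout, so `percent = 100*(exp(logFC)-1)`;
−0.31 → −26.7 % (a "27 % decrease").

## LOY calling

A QC-passed cell is LOY iff its summed raw count over the MSY gene set is
zero while its autosomal count is positive; any MSY transcript makes it
NORMAL; no evidence at all (both sums zero) is UNDETERMINED and excluded
downstream. Raw counts are used because the rule is about transcript
presence, not abundance. PAR genes — CD99 above all — are excluded from the
MSY sum: their X-linked copy is retained in LOY cells, so including them
would mask true LOY. Any positive autosomal count satisfies the autosomal
clause; no extra floor is imposed beyond QC. Per-type LOY percentages carry
Wilson 95% intervals.

## Cell typing

Marker-score typing on CLR values: a cell is assigned the type of its
largest typing-marker CLR when that marker is positive and at least `margin`
(default 0.5) above the runner-up; otherwise OTHER. The one biologically
double-positive pair, CD14/CD16 (intermediate monocytes), is special-cased:
when those two are the top pair *and both stand out from the rest of the
panel* (runner-up at least `margin` above the third-best marker), the larger
value decides. Requiring the runner-up to clear the panel is what makes the
exception mean "double-high"; without it, marker-negative cells whose noise
happens to rank CD16 and CD14 first would enter the monocyte groups and act
as high-leverage points in the per-type tests. OTHER cells are excluded from
per-type tests but enter the pooled model as their own category. This
replaces a graph-clustering + marker-overlay workflow; the inference needs
labels, not a clustering algorithm.

## Differential tests

Per cell type, CD99 and the type's own autosomal marker are tested in both
assays (24 tests total; the autosomal markers are negative controls).

* **Protein (ADT)**: 1-df likelihood-ratio test between logistic models of
  LOY membership, covariates + analyte vs covariates. Direction is the sign
  of the analyte coefficient; effect magnitude is reported as the
  covariate-free average CLR difference. Regressing group on analyte keeps
  the model in the logistic family without distributional assumptions on
  CLR values.
* **RNA**: two-part hurdle for zero-inflated expression. Part one, logistic
  detection (`value > 0 ~ group + covariates`); part two, Gaussian on the
  positive log-normalized values. Part LRT statistics add; each estimable
  part contributes one df (a part with no variation, too few positive
  cells, or a single-group positive set contributes zero). All-zero
  analytes give p = 1 with a warning.
* **Effect size**: average natural-log fold change. RNA group means are
  taken on the de-logged scale and re-logged with pseudocount 1
  (`ln(mean(exp(x)-1)+1)` per group); ADT is the difference of CLR group
  means. Every result row satisfies `pct = 100*(exp(logFC)-1)` exactly.

Covariates: donor, library-prep batch, sequencing batch (categorical),
UMI count and mitochondrial % (continuous, standardized within each fit).
Batches are nested within donors in the default study design, so the batch
dummies are aliased; rank-deficient columns are dropped deterministically in
column order with a logged warning. Perfect separation in a logistic fit
falls back to a small-ridge penalized fit with a warning. A per-type test
needs at least 20 cells in each group (configurable); below that the row is
emitted with NA p. No minimum fold-change or detection-fraction prefilters
are applied — every analyte row is tested.

All raw p-values from every (cell type × analyte × assay) test are adjusted
together with Benjamini–Hochberg as one family. The pooled model is a single
logistic regression `LOY ~ analyte + donor + batches + n_umi + pct_mito +
cell_type` over all determined cells (OTHER included as a category),
reported as the Wald z and two-sided p of the analyte coefficient.

## Synthetic CITE-seq generator

The generator emulates the pooled four-donor design: 1,250 cells per donor
(5,000 total by default; any scale via `n_cells_per_donor`), donors 1–2 in
library batch 1 with pilot sequencing, donors 3–4 in batch 2, with
sequencing-batch depth scale factors 0.9/1.1.

* **Populations**: B 12 %, CD14 monocytes 20 %, CD16 monocytes 5 %, NK 10 %,
  CD8 T 15 %, CD4 T 30 %, plus 8 % marker-negative OTHER cells that exercise
  the typing margin rule. Per-type LOY fractions default to 5.6 / 15.2 /
  15.0 / 20.9 / 8.6 / 2.4 % (OTHER 10 %).
* **RNA**: ~236 genes (CD99, six markers, 12 equally weighted MSY genes at
  0.6 % of the transcriptome, four X genes, 13 MT genes, 200 lognormal
  background genes). Per-cell depth is LogNormal(ln 5000, 0.4) times the
  batch factor; mitochondrial fraction is Beta(10, 300), placing ~92 % of
  cells inside the QC window so that roughly a tenth of cells fail at least
  one criterion. Counts are gamma-Poisson (negative binomial, dispersion
  θ = 10). LOY cells have all MSY means set to zero and the CD99 mean
  multiplied by `exp(logfc_type)` (defaults −0.32 … −0.05 per type). The
  MSY budget (expected total ≈ 30 at median depth, ≈ 15 at the QC floor)
  makes a false zero astronomically unlikely post-QC, so the caller is
  exact when the explicit `msy_dropout` knob is 0; dropout and depth are
  independent dials for studying the caller's failure modes.
* **ADT**: 7 proteins, own-type marker mean 150, background 8, CD99 60,
  NB dispersion 10, per-cell size factor LogNormal(0, 0.3). The LOY CD99
  multiplier is **solved numerically** (exact NB pmf, Gauss–Hermite over the
  size factor) so that the expected per-cell CLR difference between LOY and
  normal cells equals the configured log fold change (defaults from the
  per-type protein effects, e.g. −0.31 in B cells). A naive `exp(logfc)`
  count multiplier would be attenuated by the CLR centering (factor
  (p−1)/p) and the ln(1+x) pseudocount, and the analysis-side estimator
  would not target the configured value.
* **Doublets**: 1 % of barcodes are sums of two same-donor cells' counts
  (both assays). A doublet is truly LOY only if both components are.
* **Determinism**: one `numpy` Generator seeded from `config.seed` drives
  everything; identical configs give byte-identical outputs. The config
  serializes to a flat INI for provenance and round-trips exactly.

What the generator does **not** model: ambient RNA, UMI collisions,
realistic transcriptome-wide gene counts, empirical protein co-expression
(each type elevates only its own marker), donor-level LOY heterogeneity, or
RNA–ADT depth coupling. Passing tests therefore demonstrate correctness of
the inference chain under a faithful but idealized data-generating process,
not performance on real data.

## Numerical choices and degenerate inputs

Logistic fits use IRLS (statsmodels GLM/Binomial, up to 200 iterations);
Gaussian LRTs use `n·ln(RSS_red/RSS_full)` from least squares. LRT
statistics are clipped at zero. Constant analytes return p = 1 (no
information). CLR requires at least two proteins. BH adjustment is the
standard step-up with monotonicity enforcement, capped at 1, validated
against a brute-force textbook implementation. All statistics are
deterministic given the data — only the generator consumes randomness.

## Test problem sizes

The acceptance-style checks run at deliberately chosen sizes: caller
exactness on 10,000 cells; type-I error on 500 replicates of 2,000 cells
(both tests stay inside the 99% binomial envelope [0.025, 0.075] at
α = 0.05); effect recovery over 100 seeds at 5,000 cells (mean recovered
B-cell CD99 protein logFC within ±0.05 of −0.31, the B row BH-significant
in ≥ 90 % of seeds, each autosomal-marker protein row BH-nonsignificant in
≥ 90 % of seeds). The end-to-end reproduction script runs once at the full
study scale (~14,400 cells).

## Known limitations

* Per-cell CLR leakage (above) plus margin-typing on CLR values couples the
  null marker rows weakly to the injected CD99 effect; the resulting
  positive bias on autosomal-marker rows is ≤ 0.05 CLR units and visible
  only in the far tail of the per-type tests. Typing from an independent
  modality (e.g. RNA clustering) would decouple them entirely.
* The hurdle's Gaussian part assumes approximate normality of positive
  log-expression; no shrinkage of the continuous variance is applied.
* The LOY caller is deterministic presence/absence; a probabilistic caller
  modeling dropout explicitly would be the natural extension for shallow
  data.
* Batch effects enter the generator only as depth scale factors; the
  covariate machinery is exercised, but not against gene-specific batch
  distortions.
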