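# Methods

This note documents the statistical models, parameter choices and
numerical conventions of the package, and what the synthetic data do and
do not establish about real data.

## Single-cell substrate and normalization

Expression lives in an AnnData (cells × genes) with per-cell labels
`condition` (malignant / normal), `subtype` (TNBC, ER+, HER2+; "none" for
normal cells) and `patient`.  Counts are normalized per cell as
`ln(1 + s·c/ total)` with scale factor s = 10⁴ (the standard log-normalization
constant); cells with zero total counts are rejected rather than silently
dropped.  Normalization is exactly invariant to per-cell scaling and
order-preserving within a cell, both property-tested.

Variable genes are ranked by the variance-stabilized standardized
variance: a lowess trend (frac 0.3) of log10 variance on log10 mean of the
raw counts predicts each gene's SD; counts are standardized by that SD,
clipped at √n_cells, and genes are ordered by the variance of the clipped
values (ties broken by gene name).  This is the "vst" ranking popularized
by single-cell toolkits, implemented here directly on the lowess trend.
The default selection size is 3000, clamped to the gene count of small
fixtures.

## Hurdle differential expression

Per gene and contrast the test has two parts sharing one design matrix
(intercept, group, patient dummies):

* detection — logistic regression of 1{value > 0}; likelihood-ratio
  chi-square for the group column (1 df);
* magnitude — Gaussian linear model on the positive values;
  LR chi-square n·ln(RSS₀/RSS₁) (1 df).

The chi-squares and degrees of freedom of the components that are
identifiable are summed and referred to χ².  A gene detected in no cell
gets p = 1, LFC 0 and an "undetected" flag; with no zeros the test
reduces exactly to the magnitude component, with all positive values tied
it reduces to the detection component (both covered by tests against
closed-form oracles).

The patient covariate enters both components as fixed effects.  When any
patient level lies entirely inside one contrast group the covariate is
collinear with the group effect, so it is dropped for that contrast with
a warning.  This is the situation of the malignant-vs-normal contrasts
(patients are nested in condition); the covariate earns its keep in
designs where patients span both groups, and the null-calibration checks
split cells into pseudo-groups within patients for exactly that reason.
Under that null the empirical rate of p < 0.05 is ≈ 0.04–0.06 at 1000
genes and 200 cells per group.

The reported effect size is `log2((mean expm1(A) + ε)/(mean expm1(B) + ε))`
with pseudocount ε = 1/n of the smaller group, which keeps group-exclusive
genes finite.

Direction calls use adjusted p-values per contrast (Benjamini–Hochberg by
default, Bonferroni available), strict threshold padj < α with α = 0.05,
and a minimum |LFC| of 0.25 (a conventional single-cell reporting cutoff;
both configurable).  A call is `up`/`down` only when both criteria hold;
padj exactly equal to α is `ns`.

## Repositioning plan

The panel annotation table (shipped in `amp_reposition/data/`) lists each
panel gene's therapeutic role and its repositioning plane: Down for genes
that promote the malignancy when over-expressed (B2M, SLPI), Up for genes
whose loss removes a benefit (PIGR, DEFB1, LTF, CLU, S100A7, SCGB2A1),
None for genes that are markers or behave ambivalently.  A Down-plane gene
enters the plan only if at least one contrast calls it up (there must be
something to reverse); an Up-plane gene enters if at least one contrast
calls it down or leaves it unchanged (any non-up observation is compatible
with raising it).  An empty plan is an error.

## Correlation modules, enrichment, guard sets

For each plan target, Pearson r against every other variable gene across
all cells; two-sided p from the t transform with n−2 df; Bonferroni over
the partner tests of that candidate (per-candidate families).  Partners
are retained when r > 0.3 — a signed threshold, since the guard logic
targets co-upregulated partners — and padj < 0.05, keeping the top 50 by r
(ties by gene name).  Constant partners are skipped and counted;
a zero-variance candidate yields an empty, flagged module.

Enrichment is the one-sided hypergeometric upper tail of the module/term
overlap within the universe of measured genes (not the union of the
collection — unmeasured genes cannot inflate significance), BH-adjusted
across terms, reporting terms with padj < 0.05 sorted by padj and
truncated to the top 5.  The implementation agrees with exhaustive
enumeration on small universes to nine digits.

Guard sets mechanize the "do not harm the MHC complex" inspection: the
union of genes of a candidate's enriched terms whose names match any
configured pattern (default `MHC`, case-insensitive regex), intersected
with measured genes, minus the candidate itself.

## Drug scoring and selection

Perturbagen samples are first filtered to the configured dose and
duration ("10 uM" / "24 h" by default) for treatments and controls alike;
drugs losing all replicates are reported.  The drug score is
log2(mean of treatment replicates) − log2(mean of control samples), means
on the linear scale.  The caller must know the scale of its input matrix:
applying this to already-log data silently computes something else, and
log2-of-mean ≠ mean-of-log2 (unit-tested).  The pseudocount defaults to 0
because the generator guarantees positive values; real data with zeros
must set it.

Per target, drugs are sorted by the target's LFC (descending for Up,
ascending for Down, ties by drug id) and the top k kept.  The library
default is k = 50, the conventional reporting depth for perturbagen
screens (20 is the other commonly used value; both are plain parameters).
The pipeline's default config uses k = 10, proportionate to its 60-drug
synthetic panel.  A ranked drug is excluded when its panel-conflict score
(sum of anti-plane LFC magnitudes over the other plan targets) exceeds τ.
Conflict is magnitude-weighted rather than a sign count, so τ = 0
reproduces strict sign-based exclusion while positive τ tolerates noise;
the pipeline default τ = 0.5 absorbs the ±0.1-per-gene replicate noise of
the fixture.  Raising τ can only keep more drugs (property-tested).

For each target the surviving drug with the smallest guard conflict is
flagged recommended (ties: larger |target LFC|, then drug id); targets
without guard sets therefore recommend their strongest surviving drug.
Excluded rows are kept with the reason naming the compromised genes.

## Synthetic data

The single-cell generator draws gene base means log-normally (sd 0.5)
around `base_mean` (default 2 counts), negative-binomial counts with shape
`dispersion` (default 2), independent Bernoulli dropout (default rate
0.3), and a per-patient log-scale shift (sd `batch_sd`, default 0.1).
Planted log2 effects multiply malignant-condition means by 2^δ before
dropout, so the empirical log2 ratio of condition means is calibrated to δ
(checked at two sample sizes).  Co-expression is planted by a shared
per-cell log-normal latent factor between a candidate and its partners;
the default factor sd of 2.0 yields Pearson r ≈ 0.4–0.5 on log-normalized
counts at these count depths — comparable to strong co-expression modules
such as B2M–HLA in epithelial data — comfortably above the 0.3 retention
threshold.  Malignant patients cycle through the subtype list; each
patient belongs to one condition, as in a real case/control cohort.

The perturbagen generator emits linear-scale values
`baseline · 2^effect · exp(N(0, noise_sd))` with per-drug replicates and a
DMSO pseudo-drug as controls (≥ 2 control replicates enforced).  The
default fixture plants, among 55 null drugs, one clean and one
guard-suppressing Down-drug per Down target and Up-drugs for the Up
targets; "clean" drugs mildly raise the guard genes (+0.3), mirroring the
guard-sparing profiles the selection step is meant to find, while the
dirty drug suppresses them (−1.5).

All three generators derive their streams from one master seed via fixed
`SeedSequence` spawn keys (0 single-cell, 1 perturbagen, 2 gene sets), so
stages can be regenerated independently and identical configs are
byte-identical.

What the synthetic data do **not** contain: UMI/read-level structure,
library-size confounding between conditions, realistic cell-type mixtures
or doublets, cross-platform batch (the reason the real analysis needs
anchor-based integration), dose–response structure, or the moderated
replicate collapsing of real L1000 level-5 data.  Passing tests therefore
establish the correctness and calibration of the statistics on data
satisfying the stated model, not robustness to those real-world artifacts.

## Problem sizes and determinism

The shipped default pipeline fixture uses 500 genes, 900 cells per
condition over 3 patients each, 60 drugs × 3 replicates with 6 DMSO
controls, and 20 gene-set terms; a full run takes a few seconds.  The
recomputation script (`scripts/acceptance.py`) uses 1000 genes × 400
cells for the null calibration and 20-seed sweeps for the recovery rates.
Every randomized quantity is driven by the `--seed` argument; the
pipeline writes a manifest with SHA-256 hashes of all outputs, and two
runs with the same config are bit-identical (floats are serialized with a
fixed `%.10g` format to keep text outputs stable).

## Known limitations

* The hurdle test is a desk-scale analogue of MAST: no cellular-detection
  -rate covariate, no shrinkage of the continuous variance; its null
  calibration is verified by simulation rather than inherited.
* The plan-consistency rule treats any non-up call as compatible with the
  Up plane; panels with genuinely contradictory subtype behavior will
  still enter the plan if one contrast supports it.
* Guard derivation is name-pattern-based; it finds only terms the
  collection names accordingly.
* Per-candidate (not global) Bonferroni families for the correlation
  filter; with ~3000 variable genes the difference is a constant factor of
  the number of candidates.
* The conflict tolerance τ and ranking depth k trade off precision and
  recall of the final table and have no universal default; the shipped
  values suit the fixture's noise scale and panel size.
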