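# amp-reposition

Signature-based drug repositioning for immunomodulatory-peptide (AMP) genes
that are deregulated in malignant versus normal breast epithelial cells.

Many endogenous antimicrobial/immunomodulatory peptides are deregulated in
breast cancer: some that favor tumor elimination (e.g. PIGR, DEFB1, LTF,
CLU, S100A7, SCGB2A1) are lost in malignant epithelium, while others that
promote progression or shield the tumor (B2M, SLPI) are over-expressed.
This package implements, as a tested and reusable pipeline, an analysis
that

1. tests an AMP panel for differential expression per tumor-subtype
   contrast (TNBC / ER+ / HER2+ vs normal epithelium) with a two-part
   hurdle test, and turns the calls plus each gene's known role in cancer
   biology into a *repositioning plan* — which genes a drug should push Up
   and which Down;
2. extracts each target's correlated-gene module (Pearson *r* > 0.3,
   Bonferroni-adjusted *p* < 0.05, top 50 partners among the most variable
   genes), tests modules for gene-set enrichment (one-sided hypergeometric,
   Benjamini–Hochberg, top 5 terms), and derives *guard sets* — genes such
   as the MHC/HLA complex around B2M that a repurposed drug must not
   co-suppress;
3. scores drug perturbagens against DMSO controls by the replicate-
   aggregated log2 fold change, ranks drugs per target in the planned
   direction, excludes drugs with contradictory effects on the rest of the
   panel, and flags per target the surviving drug with the least guard-set
   damage.

Because the original patient cohorts and the LINCS L1000 perturbagen
corpus are external resources, the package ships a synthetic-data module
that generates all inputs with the statistical structure the analysis
assumes (negative-binomial counts with dropout and patient batch shifts,
planted fold changes and co-expression, a DMSO-controlled perturbagen
matrix with planted drug effects, GMT gene sets). Every stage is therefore
testable end-to-end without any download.

## The scores

For drug *d* and gene *g*, with treatment replicates *T(d)* and control
samples *C*, the drug score is the log2-of-mean fold change

```
LFC(g, d) = log2( mean_{s in T(d)} x(g, s) ) − log2( mean_{s in C} x(g, s) )
```

(replicate means on the linear scale — note log2-of-mean ≠ mean-of-log2).
For a plan P mapping genes to planes (s(g) = +1 for Up, −1 for Down), the
panel-conflict score of drug *d* evaluated for target *t* is the total
anti-plane movement inflicted on the other targets,

```
conflict(d, t) = Σ_{g ∈ P, g ≠ t}  max(0, −s(g) · LFC(g, d))
```

and a ranked drug is excluded when conflict exceeds the tolerance τ.  The
guard-conflict score of *d* for a Down-plane target with guard set *H* is
the total guard suppression `Σ_{h ∈ H} max(0, −LFC(h, d))`; the surviving
drug minimizing it is flagged *recommended*.

The hurdle DE test combines a logistic detection component (count > 0) and
a Gaussian component on the positive log-normalized values, both with a
patient fixed effect where identifiable; the two likelihood-ratio
chi-squares and their degrees of freedom are summed.

## Worked example

```
$ amp-reposition run-all --out-dir out --seed 1
pipeline complete; manifest with 17 rows in out
```

The run simulates the fixture, writes every stage artifact (counts MTX +
TSVs, perturbagen CSV + metadata, GMT, `deg.tsv`, `plan.tsv`,
`modules.tsv`, `enrichment.tsv`, `guards.tsv`, `drug_lfc.csv`,
`candidates.tsv`, `guard_detail.tsv`, `manifest.tsv`).  The derived plan
covers the eight actionable panel genes (B2M, SLPI: Down; PIGR, DEFB1,
LTF, CLU, S100A7, SCGB2A1: Up), and the recommended rows of
`candidates.tsv` read:

```
target_gene plane         drug_id  target_lfc  panel_conflict  guard_conflict
       PIGR    Up    DRUG_PIGR_UP    2.063852        0.081037             0.0
      DEFB1    Up   DRUG_PANEL_UP    1.660198        0.031037             0.0
        LTF    Up   DRUG_PANEL_UP    1.685823        0.031037             0.0
        CLU    Up   DRUG_PANEL_UP    1.475834        0.031037             0.0
    SCGB2A1    Up   DRUG_PANEL_UP    1.357258        0.031037             0.0
       SLPI  Down DRUG_SLPI_CLEAN   -1.902776        0.309324             0.0
     S100A7    Up   DRUG_PANEL_UP    1.659558        0.031037             0.0
        B2M  Down  DRUG_B2M_CLEAN   -2.060280        0.132713             0.0
```

`target_lfc` is the drug's log2 fold change on its own target (close to
the planted effects of ±1.5–2.5), `panel_conflict` the residual anti-plane
movement on the other seven targets (all below the default tolerance
τ = 0.5), and `guard_conflict` the damage to the MHC guard genes derived
for B2M and SLPI — zero for the recommended drugs, while the planted
guard-suppressing drug `DRUG_B2M_DIRTY` survives the ranking but is never
recommended.  Re-running with the same seed reproduces every output
byte-for-byte (compare `manifest.tsv` hashes).

The same stages are available individually (`simulate`, `deg`,
`correlate`, `enrich`, `reposition`) and as library functions
(`amp_reposition.hurdle_deg_test`, `compute_drug_lfc`, ...).

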