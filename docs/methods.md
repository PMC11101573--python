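# Methods

## ssGSEA scoring

Each sample is scored independently (sample independence is a tested
invariant). Genes are ranked ascending by expression with average ranks on
ties, so the top gene has rank N. Walking genes from highest to lowest
expression — expression ties broken lexicographically by gene identifier so
results are bit-reproducible — the enrichment score of set S is

    ES = Σ_{j=1..N} [ P_in(j) − P_out(j) ]
    P_in(j)  = Σ_{i≤j, i∈S} rank_i^α / Σ_{i∈S} rank_i^α
    P_out(j) = #{i≤j, i∉S} / (N − |S|)

Parameters: `alpha` (default 0.25, the convention of the dominant published
ssGSEA implementation; α = 0 gives the plain ECDF difference used in the
hand-checkable examples), `normalize` (default on: the whole score matrix is
divided by its global max − min; downstream median splits are invariant to
this within one run, so the choice is inconsequential for stratification),
and `min_set_overlap` (default 2: sets with fewer measured genes are skipped
with a warning). A set covering every measured gene is an error because the
out-of-set ECDF is undefined. The vectorized implementation is validated to
1e-10 against a naive double-loop oracle on hundreds of random instances.

## Surrogate-gene discovery

Within each stratum (tumor type by default; any label column can serve, e.g.
cohort), each gene's log₂(FPKM+1) expression is Pearson-correlated with each
pathway score. P-values come from the Student-t reference distribution with
n−2 df; strata with fewer than 3 samples are skipped; zero-variance vectors
yield an undefined-correlation sentinel that never counts. Per gene and
pathway the number of strata with r > 0 and p ≤ 0.05 is counted and summed
over pathways. **No multiple-testing correction is applied** — the count of
nominally significant strata is itself the ranking statistic. Ranking is by
descending aggregate count, then descending mean r over all
(stratum, pathway) pairs, then gene identifier: a deterministic total order.
A `require_all_pathways` switch instead counts a stratum once only when all
three pathways are simultaneously significant; the default is the per-pathway
sum. Both readings are defensible for "aggregated"; the sum is the default
because it uses strictly more information and degrades gracefully when one
pathway is noisy.

## Biomarker evaluation

* **Median split.** Within each cohort, `high` iff score strictly above that
  cohort's median; ties at the median go to `low` (a convention — the split
  rule only fixes which side the boundary patients land on). Pooled analyses
  concatenate per-cohort labels and run a single fit on the pooled data
  rather than a stratified model; with per-cohort medians this removes
  cohort-level location shifts before pooling.
* **Response.** ORR = (#CR + #PR)/#evaluable, RECIST `NA` excluded from the
  denominator. Responder = CR/PR or SD maintained strictly more than
  6 months; SD patients without a recorded duration are unadjudicated and
  excluded with a warning. Long-term survival = OS > 36 months; patients
  censored at ≤ 36 months are unevaluable and excluded from the denominator
  (an `include_early_censored` switch gives the naive denominator instead).
* **Survival.** Kaplan–Meier, two-group log-rank (χ² with 1 df), and a
  univariate Cox fit with Efron tie handling (Breslow available), all backed
  by `lifelines`; HR = exp(β̂) with Wald 95% CI. Perfect separation surfaces
  as a non-convergence error rather than a silently huge coefficient.
* **Discrimination.** ROC-AUC as the rank (Mann–Whitney) statistic with ties
  counting one half, validated exactly against the O(n²) pairwise oracle.

## TME context statistics

Ratios are of mean log₂(FPKM+1) over marker panels (pro- vs
anti-inflammatory cytokines; CD8 vs Treg / M1-macrophage / MDSC). A sample
whose denominator panel has zero expression gets an undefined sentinel and is
excluded. Values are z-scored within tumor type (population SD; a constant
stratum maps to zeros so every sample stays representable) before the
two-group comparison. The comparison is the two-sided Wilcoxon–Mann–Whitney
rank-sum test — the design is unpaired, so a signed-rank test is not
applicable; exact enumeration is used when both groups have ≤ 25 tie-free
observations, the tie-corrected normal approximation otherwise. The cytokine
panels ship as editable defaults (pro: IFNG, IL1A, IL1B, IL2; anti: TGFB1,
IL10, IL4, IL11 — cytokine names mapped to HGNC symbols); the cell-type
marker panels (CD8A/CD8B; FOXP3/IL2RA/CTLA4; NOS2/CD80/CD86;
ITGAM/CD33/ARG1) are this package's compact defaults, not a published
deconvolution signature, and should be replaced with the user's panels for
real analyses. Hot/cold signature scoring simply delegates to the ssGSEA
kernel.

## Synthetic study design

The generator draws, per sample s in tumor type k, a latent immune activity
A_s ~ N(μ_k, 1) with μ_k ~ N(0, 0.5). Log₂ expression of gene g is
b_g + load_g·A_s + batch_{g,k} + ε, with baselines b_g ~ U(3, 8), stratum
batch offsets (SD 0.5) so that within-stratum correlation genuinely differs
from pooled correlation, and noise ε ~ N(0, 0.4). Pathway members (three
disjoint sets of 30/20/25 genes out of 200) have loadings |N(0.5, 0.05)|;
one non-pathway gene — the planted surrogate — has loading 0.9; all other
genes are pure noise. Values are exponentiated to a linear FPKM scale
(log-normal) so the pipeline's log transform is exercised. Survival is
exponential with hazard 0.03·exp(−0.7·A_s) per month (median OS ≈ 23 months
at average activity, a realistic ICB figure) with independent exponential
censoring tuned to ≈ 20%; response is RECIST-coded with
P(CR/PR) = logistic(1.5·A_s − 1), the remainder split evenly between SD and
PD, and SD durations exponential with mean 6 months. Three cohorts cycle
across the 6 × 20 samples so each cohort spans every tumor type (≈ 40
patients per cohort).

The noise SD (0.4) and loading spread (0.05) are the generator's own design
constants, fixed so that the planted gene's advantage (loading 0.9 vs mean
0.5) is resolvable at 20 samples per stratum — the regime the discovery
procedure is specified to operate in. What the generator does **not**
emulate: negative-binomial count noise, library-size and gene-length
effects, real pathway co-membership structure, non-proportional hazards, or
correlated censoring. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of a planted signal, not
performance on real cohorts.

## Numerical choices and degenerate inputs

Duplicate gene rows on input collapse by max (configurable to mean) with a
warning; duplicate collapse is idempotent. Gene identifiers match
case-sensitively with no alias mapping. Missing expression values are
rejected outright (ranks are undefined on missing data). Perfect
correlations report p = 0 exactly. Cox convergence follows lifelines'
Newton–Raphson defaults; degenerate fits (huge standard errors) are turned
into errors. All randomness flows through a single integer seed per
simulated study; every pipeline output is a pure function of
(inputs, config, seed), which the determinism test checks byte-for-byte.

## Problem sizes

The reference study is 200 genes × 120 samples; recovery experiments run 20
independent seeds and calibration checks use 100–2000 replicates (Cox
recovery at n = 2000, null calibrations at n = 500). These sizes make every
statistical property measurable with comfortable margins while keeping the
full suite fast to run.

## Known limitations

* The pooled hazard ratio uses label-pooling plus a single Cox fit, not a
  cohort-stratified model; with strong cohort-level baseline-hazard
  differences the two can diverge.
* The long-term-survival denominator treats early-censored patients as
  unevaluable; with heavy early censoring the rate estimate is biased toward
  patients with longer follow-up.
* Marker panels and hot/cold signatures are placeholders for user-supplied
  biology; results on real data depend entirely on those inputs.
* ssGSEA scores are compared within a run; scores from runs with different
  gene universes or normalization settings are not comparable.
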