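# surrogene

Scoring immune pathway activity in bulk tumor transcriptomes, discovering a
single surrogate gene for that activity, and evaluating either as a biomarker
of immune-checkpoint-blockade (ICB) outcome.

## The problem

Interferon-driven immune signaling (IFN-α/β, IFN-γ, IL-15) in the tumor
microenvironment predicts benefit from ICB therapy, but a multi-gene pathway
score is impractical to assay clinically. The analysis implemented here asks
three questions:

1. **How active is each pathway in each tumor?** Answered with single-sample
   gene-set enrichment (ssGSEA): genes are ranked by expression within a
   sample and a gene set *S* is scored by the integrated difference of the
   rank-weighted in-set ECDF and the unweighted out-of-set ECDF,

   ES(S) = Σ_j [ P_in(j) − P_out(j) ],  P_in(j) = Σ_{i≤j, i∈S} r_i^α / Σ_{i∈S} r_i^α,

   with rank-weight exponent α = 0.25 by default.
2. **Which single gene tracks all three pathways pan-cancer?** Within each
   tumor type, every gene's log₂(FPKM+1) expression is Pearson-correlated
   with each pathway's ssGSEA score; per gene, the number of tumor types with
   a significantly positive correlation (r > 0, p ≤ 0.05) is summed over the
   three pathways and genes are ranked by that aggregate count (ties: mean r,
   then gene ID).
3. **Is the resulting score a useful ICB biomarker?** Patients are split at
   each cohort's median score; groups are compared by objective response rate
   (CR+PR), responder rate (CR/PR or SD held > 6 months), long-term survival
   (OS > 36 months), Kaplan–Meier curves with the log-rank test, a univariate
   Cox hazard ratio (Efron ties), and ROC-AUC versus the responder label.

Because the real ICB cohorts and pan-cancer compendia require external
downloads, the package ships a synthetic-data module that generates
multi-cohort expression with a latent immune-activity axis driving three
planted pathways, one planted surrogate gene, exponential survival and
logistic response — so every stage is testable and reproducible offline.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
reference dataset (seed 0) and write their tables to `results/`:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_score_pathways.py
python analysis/03_discover_surrogate.py
python analysis/04_tme_context.py
python analysis/05_evaluate_biomarker.py
```

`03_discover_surrogate.py` prints the correlation-count ranking; the planted
surrogate gene comes out on top:

```
gene_id  rank  aggregate_count  mean_r  ...
  G0075     1               18  0.8822
  G0051     2               18  0.8136
...
planted gene G0075: rank 1, significant in 18/18 stratum-pathway pairs, mean r = 0.882
```

`05_evaluate_biomarker.py` then evaluates that gene as a biomarker
(per-cohort median split, pooled statistics):

```
 scope group  n   orr  responder_rate  long_term_rate    hr          hr_ci  logrank_p   auc
pooled  high 60 0.600           0.683           0.630 0.377 [0.240, 0.592]   0.000011 0.667
pooled   low 60 0.267           0.467           0.222 0.377 [0.240, 0.592]   0.000011 0.667
```

Read: the high-expression group has a pooled hazard ratio of 0.38 (95% CI
0.24–0.59, log-rank p ≈ 1e-5) — i.e. high surrogate-gene expression is
protective — plus roughly twice the objective response rate of the low
group, exactly the direction and structure the generator planted.

The same stages are available as a CLI (`surrogene simulate|score|discover|
tme|evaluate|run-all`); `run-all` takes a YAML config naming the expression
TSV, the GMT gene sets, the clinical TSV and an output directory, and writes
all stage tables plus a manifest of input hashes and parameters (keys:
`expression_path`, `gene_sets_path`, `clinical_path`, `out_dir`, optional
`ssgsea: {alpha, normalize, min_set_overlap}` and threshold overrides).

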