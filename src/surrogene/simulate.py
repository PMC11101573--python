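"""Synthetic multi-cohort tumor transcriptomes with outcomes.

The generator emulates the statistical structure the analysis assumes about
pan-cancer immunotherapy data, so every pipeline stage is testable without
downloading cohorts:

* a per-sample latent immune-activity axis ``A`` with tumor-type-specific
  means (so within-stratum and pooled correlations differ, as in real
  pan-cancer data);
* three disjoint immune pathway gene sets whose members load positively on
  ``A`` (plus a stratum batch offset), giving the pathways coherent ssGSEA
  scores driven by ``A``;
* one planted *surrogate* gene outside all pathways with a high loading on
  ``A`` — the gene the discovery procedure should rank first;
* log-normal expression on the linear FPKM scale, so the pipeline's
  log2(x+1) step is exercised;
* exponential overall survival whose log-hazard is linear in ``A``
  (negative coefficient = protective immune activity), with independent
  exponential censoring;
* RECIST response with P(CR/PR) a logistic function of ``A``, the remainder
  split between SD and PD, and SD durations drawn exponentially.

Ground truth (latent activities, the surrogate's identity, the true hazard
and response coefficients) is returned separately and is never visible to
the analysis modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    write_clinical,
    write_expression,
    write_gmt,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate", "make_fixture_suite"]

PATHWAY_NAMES = ("IFN_ALPHA_BETA_SIGNALING", "IFNG_PATHWAY", "IL15_SIGNALING")

# Survival-time scale: baseline hazard 0.03 / month corresponds to a median
# OS of ~23 months for an average-activity patient, a realistic ICI figure.
BASELINE_HAZARD = 0.03


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic multi-cohort experiment.

    Defaults describe the reference condition used throughout the tests:
    3 cohorts over 6 tumor types × 20 samples (120 tumors), 200 genes of
    which three disjoint pathways of 30/20/25 genes load on the latent
    immune axis, one planted surrogate gene with loading 0.9, a protective
    log-hazard of −0.7 per activity unit, 20% censoring, and a logistic
    response slope of 1.5.
    """

    n_cohorts: int = 3
    n_strata: int = 6
    samples_per_stratum: int = 20
    n_genes: int = 200
    pathway_sizes: tuple[int, int, int] = (30, 20, 25)
    surrogate_loading: float = 0.9
    background_loading_mean: float = 0.5
    background_loading_sd: float = 0.05
    noise_sd: float = 0.4
    stratum_mean_sd: float = 0.5
    batch_sd: float = 0.5
    hazard_beta: float = -0.7
    censor_rate: float = 0.2
    response_slope: float = 1.5
    response_intercept: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cohorts", "n_strata", "samples_per_stratum", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.pathway_sizes) != 3 or any(s <= 0 for s in self.pathway_sizes):
            raise ValueError("pathway_sizes must be three positive integers")
        if sum(self.pathway_sizes) + 1 > self.n_genes:
            raise ValueError(
                "n_genes must exceed the pathway genes plus the surrogate gene"
            )
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.noise_sd <= 0 or self.background_loading_sd < 0:
            raise ValueError("noise parameters must be positive")


@dataclass
class GroundTruth:
    """What the generator actually planted; for test assertions only."""

    latent_activity: dict[str, float]
    surrogate_gene_id: str
    hazard_beta: float
    response_slope: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def simulate(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionMatrix, GeneSetCollection, ClinicalTable, GroundTruth]:
    """Draw one synthetic study; fully reproducible for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_strata * cfg.samples_per_stratum

    sample_ids = [f"P{i:04d}" for i in range(n_samples)]
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    strata = np.repeat([f"T{k:02d}" for k in range(cfg.n_strata)], cfg.samples_per_stratum)
    # cohorts cycle within each stratum so every cohort spans every tumor type
    cohorts = np.array(
        [f"C{(i % cfg.n_cohorts) + 1}" for i in range(cfg.samples_per_stratum)]
        * cfg.n_strata
    )

    # latent immune activity with stratum-specific means
    mu_k = rng.normal(0.0, cfg.stratum_mean_sd, size=cfg.n_strata)
    stratum_idx = np.repeat(np.arange(cfg.n_strata), cfg.samples_per_stratum)
    activity = rng.normal(mu_k[stratum_idx], 1.0)

    # gene architecture: three disjoint pathways, then the surrogate gene
    perm = rng.permutation(cfg.n_genes)
    bounds = np.cumsum((0,) + tuple(cfg.pathway_sizes))
    pathway_members = [perm[bounds[i]:bounds[i + 1]] for i in range(3)]
    surrogate_idx = int(perm[bounds[-1]])
    surrogate_gene = gene_ids[surrogate_idx]

    loadings = np.zeros(cfg.n_genes)
    for members in pathway_members:
        loadings[members] = np.abs(
            rng.normal(cfg.background_loading_mean, cfg.background_loading_sd, size=members.size)
        )
    loadings[surrogate_idx] = cfg.surrogate_loading

    baselines = rng.uniform(3.0, 8.0, size=cfg.n_genes)
    batch = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_genes, cfg.n_strata))
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))
    log_expr = (
        baselines[:, None]
        + loadings[:, None] * activity[None, :]
        + batch[:, stratum_idx]
        + noise
    )
    fpkm = np.exp2(log_expr)  # log-normal on the linear scale

    expr = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=fpkm, value_space="linear"
    )
    sets = GeneSetCollection(
        [
            GeneSet(PATHWAY_NAMES[i], "synthetic immune pathway",
                    frozenset(gene_ids[g] for g in pathway_members[i]))
            for i in range(3)
        ]
    )

    # exponential survival, log-hazard linear in activity; exponential censoring
    rate = BASELINE_HAZARD * np.exp(cfg.hazard_beta * activity)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        rate_c = BASELINE_HAZARD * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    os_months = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    # RECIST: P(objective response) logistic in activity; SD/PD split remainder
    p_resp = 1.0 / (1.0 + np.exp(-(cfg.response_slope * activity + cfg.response_intercept)))
    is_resp = rng.random(n_samples) < p_resp
    u = rng.random(n_samples)
    recist = np.where(is_resp, np.where(u < 0.3, "CR", "PR"), np.where(u < 0.5, "SD", "PD"))
    duration = np.full(n_samples, np.nan)
    sd_mask = recist == "SD"
    duration[sd_mask] = rng.exponential(6.0, size=int(sd_mask.sum()))

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "patient_id": sample_ids,
                "cohort_id": cohorts,
                "tumor_type": strata,
                "os_months": os_months,
                "event": event,
                "recist": recist,
                "response_duration_months": duration,
            }
        )
    )
    truth = GroundTruth(
        latent_activity={s: float(a) for s, a in zip(sample_ids, activity)},
        surrogate_gene_id=surrogate_gene,
        hazard_beta=cfg.hazard_beta,
        response_slope=cfg.response_slope,
    )
    return expr, sets, clinical, truth


def make_fixture_suite(
    out_dir: str | Path,
    config: SimulationConfig = SimulationConfig(),
) -> dict[str, Path]:
    """Write a small on-disk study (expression TSV, GMT, clinical TSV,
    ground-truth JSON) re-readable by the io module."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, sets, clinical, truth = simulate(config)
    paths = {
        "expression": out / "expression.tsv",
        "gene_sets": out / "pathways.gmt",
        "clinical": out / "clinical.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_expression(expr, paths["expression"])
    write_gmt(sets, paths["gene_sets"])
    write_clinical(clinical, paths["clinical"])
    paths["ground_truth"].write_text(truth.to_json())
    return paths
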