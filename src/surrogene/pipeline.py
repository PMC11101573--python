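"""End-to-end pipeline: score → discover → tme → evaluate.

``run_all`` wires the stages over on-disk inputs and writes TSV outputs plus
a JSON manifest (input hashes, parameters, package version) so a run can be
reproduced and audited.  All stage outputs are pure functions of
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarker import evaluate_split, median_split, roc_auc, responder_labels
from .discovery import correlate_gene_pathways, rank_surrogates, ranking_to_frame
from .io_formats import read_clinical, read_expression, read_gmt
from .ssgsea import SsgseaParams, score_matrix
from .tme import (
    compare_groups,
    default_cell_type_panels,
    default_cytokine_panels,
    group_ratio,
    zscore_within,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths and analysis constants for a full run.

    The response and survival thresholds (6 and 36 months) and the
    significance thresholds (p <= 0.05, r > 0) are the analysis constants
    used throughout; they are exposed here so a run records them.
    """

    expression_path: str
    gene_sets_path: str
    clinical_path: str
    out_dir: str
    value_space: str = "linear"
    ssgsea: SsgseaParams = field(default_factory=SsgseaParams)
    p_threshold: float = 0.05
    r_threshold: float = 0.0
    responder_sd_months: float = 6.0
    long_term_months: float = 36.0
    split_gene: str | None = None  # None = top-ranked gene from discovery
    stratum_column: str = "tumor_type"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} is not a mapping")
        ss = raw.pop("ssgsea", {})
        try:
            return cls(ssgsea=SsgseaParams(**ss), **raw)
        except TypeError as exc:
            raise ValueError(f"bad config {path}: {exc}") from exc

    def validate_paths(self) -> None:
        for name in ("expression_path", "gene_sets_path", "clinical_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config: RunConfig) -> Path:
    """Execute the full analysis; returns the report directory.

    Stages: ssGSEA pathway scoring, surrogate-gene discovery, TME context
    statistics for the split gene, and biomarker evaluation (per-cohort and
    pooled median splits with response metrics, log-rank, Cox HR, AUC).
    Any stage failure aborts with the stage name and cause.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load")
        expr = read_expression(config.expression_path, value_space=config.value_space)
        sets = read_gmt(config.gene_sets_path)
        clinical = read_clinical(config.clinical_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    try:
        stage("score")
        scores = score_matrix(expr, sets, config.ssgsea)
        _write_tsv(
            scores.to_frame().reset_index(names="sample_id"), out / "pathway_scores.tsv"
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'score' failed: {exc}") from exc

    try:
        stage("discover")
        strata = clinical.strata(config.stratum_column)
        correlations = correlate_gene_pathways(expr, scores, strata)
        ranking = rank_surrogates(
            correlations, r_threshold=config.r_threshold, p_threshold=config.p_threshold
        )
        ranking_df = ranking_to_frame(ranking)
        _write_tsv(ranking_df, out / "surrogate_ranking.tsv")
        split_gene = config.split_gene or ranking[0].gene_id
    except Exception as exc:
        raise RuntimeError(f"stage 'discover' failed: {exc}") from exc

    try:
        stage("tme")
        cf = clinical.frame.set_index("patient_id")
        gene_expr = pd.Series(expr.gene_row(split_gene), index=expr.sample_ids)
        med_by_type = gene_expr.groupby(cf.loc[gene_expr.index, config.stratum_column]).median()
        tme_group = pd.Series(
            np.where(
                gene_expr
                > med_by_type.loc[cf.loc[gene_expr.index, config.stratum_column]].to_numpy(),
                "high",
                "low",
            ),
            index=gene_expr.index,
        )
        pro, anti = default_cytokine_panels()
        panels = default_cell_type_panels()
        ratios = {"pro_vs_anti_cytokines": (pro, anti)}
        for other in ("treg", "m1_macrophage", "mdsc"):
            if "cd8_t" in panels and other in panels:
                ratios[f"cd8_vs_{other}"] = (panels["cd8_t"], panels[other])
        rows = []
        for name, (num, den) in ratios.items():
            try:
                raw = group_ratio(expr, num, den)
            except ValueError as exc:
                logger.warning("ratio %s skipped: %s", name, exc)
                continue
            z = zscore_within(raw, cf[config.stratum_column].to_dict())
            stat, p = compare_groups(z.to_numpy(), tme_group.loc[z.index].to_numpy())
            rows.append(
                {
                    "statistic_name": name,
                    "mean_z_high": float(z[tme_group == "high"].mean()),
                    "mean_z_low": float(z[tme_group == "low"].mean()),
                    "rank_sum_stat": stat,
                    "p_value": p,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "tme_statistics.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'tme' failed: {exc}") from exc

    try:
        stage("evaluate")
        scores_series = pd.Series(
            np.log2(expr.gene_row(split_gene) + 1.0)
            if expr.value_space == "linear"
            else expr.gene_row(split_gene),
            index=expr.sample_ids,
        )
        cohorts = pd.Series(
            cf.loc[scores_series.index, "cohort_id"].to_numpy(), index=scores_series.index
        )
        assignments = median_split(scores_series, cohorts)
        groups_df = pd.DataFrame(
            [(a.patient_id, a.cohort_id, a.score, a.group) for a in assignments],
            columns=["patient_id", "cohort_id", "score", "group"],
        )
        _write_tsv(groups_df, out / "group_assignments.tsv")

        metric_rows = []
        km_rows = []
        cohort_ids = sorted(groups_df["cohort_id"].unique())
        for scope, subset in [("pooled", assignments)] + [
            (c, [a for a in assignments if a.cohort_id == c]) for c in cohort_ids
        ]:
            result = evaluate_split(clinical.frame, subset)
            pids = [a.patient_id for a in subset]
            sub_clin = cf.loc[pids]
            resp = responder_labels(
                sub_clin["recist"], sub_clin["response_duration_months"],
                sd_months=config.responder_sd_months,
            )
            auc = roc_auc(scores_series.loc[pids].to_numpy(), resp.to_numpy())
            fit = result["fit"]
            for g in ("high", "low"):
                s = result["response"][g]
                metric_rows.append(
                    {
                        "scope": scope, "group": g, "n": s.n, "orr": s.orr,
                        "responder_rate": s.responder_rate,
                        "long_term_rate": s.long_term_rate,
                        "hr": fit.hr, "hr_ci_low": fit.hr_ci_low,
                        "hr_ci_high": fit.hr_ci_high, "cox_p": fit.cox_p,
                        "logrank_p": fit.logrank_p, "auc": auc,
                    }
                )
                times, surv = result["km"][g]
                for t, sv in zip(times, surv):
                    km_rows.append(
                        {"scope": scope, "group": g, "time_months": t, "survival": sv}
                    )
        _write_tsv(pd.DataFrame(metric_rows), out / "evaluation_metrics.tsv")
        _write_tsv(pd.DataFrame(km_rows), out / "km_curves.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "inputs": {
            "expression": _sha256(config.expression_path),
            "gene_sets": _sha256(config.gene_sets_path),
            "clinical": _sha256(config.clinical_path),
        },
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("ssgsea",)
            },
            "ssgsea": dataclasses.asdict(config.ssgsea),
        },
        "split_gene": split_gene,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
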