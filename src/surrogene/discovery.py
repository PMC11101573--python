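"""Surrogate-gene discovery by correlation-count ranking.

The procedure asks: which single gene best tracks the activity of a panel of
immune pathways across many tumor types?  Within each stratum (tumor type or
cohort), each gene's log expression is correlated (Pearson) with each
pathway's ssGSEA score.  For every gene the number of strata with a
significantly positive correlation (r > 0, p <= 0.05, unadjusted) is counted
per pathway and summed across pathways; genes are ranked by that aggregate
count, ties broken by descending mean r and then gene identifier.

No multiple-testing correction is applied in the counting step — the count
of nominally significant strata is itself the ranking statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix
from .ssgsea import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "StratumCorrelation",
    "RankingResult",
    "pearson_r_p",
    "correlate_gene_pathways",
    "rank_surrogates",
]


@dataclass(frozen=True)
class StratumCorrelation:
    """Pearson correlation of one gene with one pathway score in one stratum."""

    gene_id: str
    stratum_id: str
    pathway_name: str
    n: int
    r: float
    p: float


@dataclass(frozen=True)
class RankingResult:
    """Per-gene significant-stratum counts and final rank (1 = best)."""

    gene_id: str
    per_pathway_counts: dict[str, int]
    aggregate_count: int
    mean_r: float
    rank: int


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r and two-sided p from the Student-t reference
    distribution with n-2 degrees of freedom.

    Returns ``(nan, nan)`` as an undefined-correlation sentinel when either
    vector has zero variance; such pairs are excluded from counting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 for a defined p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance vector; correlation undefined")
        return (float("nan"), float("nan"))
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    if abs(r) >= 1.0 - 1e-12:  # perfectly linear: the t statistic diverges
        return (1.0 if r > 0 else -1.0, 0.0)
    return r, p


def _bulk_pearson(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided t-test p of each row of X against y.

    Vectorized equivalent of calling :func:`pearson_r_p` per row; rows (or a
    y) with zero variance yield NaN.
    """
    n = y.size
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    r[(sx == 0)] = np.nan
    if sy == 0:
        r[:] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


def correlate_gene_pathways(
    expr: ExpressionMatrix,
    scores: ScoreMatrix,
    strata: Mapping[str, str],
    log_transform: bool = True,
    min_stratum_size: int = 3,
) -> list[StratumCorrelation]:
    """Correlate every gene with every pathway score within every stratum.

    Expression is log2(x+1)-transformed first when the matrix is in linear
    (FPKM) space and ``log_transform`` is on.  Strata with fewer than
    ``min_stratum_size`` samples are skipped with a warning.
    """
    if log_transform:
        expr = expr.log2p1()
    sample_pos = {s: i for i, s in enumerate(scores.sample_ids)}
    missing = [s for s in expr.sample_ids if s not in sample_pos]
    if missing:
        raise ValueError(f"samples missing from score matrix: {missing[:5]}")

    by_stratum: dict[str, list[str]] = {}
    for s in expr.sample_ids:
        by_stratum.setdefault(str(strata[s]), []).append(s)

    results: list[StratumCorrelation] = []
    analyzed = 0
    expr_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    for stratum, samples in by_stratum.items():
        if len(samples) < min_stratum_size:
            logger.warning(
                "stratum %r has %d samples (< %d); skipped",
                stratum, len(samples), min_stratum_size,
            )
            continue
        analyzed += 1
        cols = [expr_pos[s] for s in samples]
        X = expr.values[:, cols]
        score_rows = [sample_pos[s] for s in samples]
        for pathway in scores.set_names:
            y = scores.scores[score_rows, scores.set_names.index(pathway)]
            r, p = _bulk_pearson(X, y)
            for gi, gene in enumerate(expr.gene_ids):
                results.append(
                    StratumCorrelation(
                        gene_id=gene,
                        stratum_id=stratum,
                        pathway_name=pathway,
                        n=len(samples),
                        r=float(r[gi]),
                        p=float(p[gi]),
                    )
                )
    if analyzed == 0:
        raise ValueError(f"no stratum has >= {min_stratum_size} samples")
    return results


def rank_surrogates(
    correlations: list[StratumCorrelation],
    r_threshold: float = 0.0,
    p_threshold: float = 0.05,
    require_all_pathways: bool = False,
) -> list[RankingResult]:
    """Rank genes by their aggregate count of significantly positive strata.

    Per gene and pathway, count strata with ``r > r_threshold`` and
    ``p <= p_threshold`` (undefined correlations excluded); the aggregate is
    the sum over pathways.  With ``require_all_pathways``, a stratum counts
    once only when significant for every pathway simultaneously.  Ranking is
    by descending aggregate count, then descending mean r over all
    (stratum, pathway) pairs, then gene identifier — a deterministic total
    order with ranks 1..G.
    """
    if not correlations:
        raise ValueError("no correlations to rank")
    df = pd.DataFrame(
        {
            "gene": [c.gene_id for c in correlations],
            "stratum": [c.stratum_id for c in correlations],
            "pathway": [c.pathway_name for c in correlations],
            "r": [c.r for c in correlations],
            "p": [c.p for c in correlations],
        }
    )
    df["sig"] = (df["r"] > r_threshold) & (df["p"] <= p_threshold)
    df.loc[df["r"].isna() | df["p"].isna(), "sig"] = False

    counts = (
        df.groupby(["gene", "pathway"])["sig"].sum().astype(int).unstack(fill_value=0)
    )
    if require_all_pathways:
        all_sig = (
            df.groupby(["gene", "stratum"])["sig"].all().groupby("gene").sum().astype(int)
        )
        aggregate = all_sig
    else:
        aggregate = counts.sum(axis=1)
    mean_r = df.groupby("gene")["r"].mean()

    order = pd.DataFrame(
        {"aggregate": aggregate, "mean_r": mean_r.reindex(aggregate.index)}
    ).sort_values(
        by=["aggregate", "mean_r"], ascending=[False, False], kind="mergesort"
    )
    # stable mergesort + sorted index gives the lexicographic gene-id tie-break
    order = order.loc[
        sorted(order.index)
    ].sort_values(by=["aggregate", "mean_r"], ascending=[False, False], kind="mergesort")

    results = []
    for rank, gene in enumerate(order.index, start=1):
        results.append(
            RankingResult(
                gene_id=gene,
                per_pathway_counts={pw: int(counts.loc[gene, pw]) for pw in counts.columns},
                aggregate_count=int(order.loc[gene, "aggregate"]),
                mean_r=float(order.loc[gene, "mean_r"]),
                rank=rank,
            )
        )
    return results


def ranking_to_frame(results: list[RankingResult]) -> pd.DataFrame:
    """Tabular view of a ranking: one row per gene, rank order."""
    rows = []
    for r in results:
        row = {"gene_id": r.gene_id, "rank": r.rank, "aggregate_count": r.aggregate_count,
               "mean_r": r.mean_r}
        for pw, c in r.per_pathway_counts.items():
            row[f"count[{pw}]"] = c
        rows.append(row)
    return pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
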