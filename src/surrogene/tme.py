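"""Tumor-microenvironment context statistics.

Given a high/low split of tumors by a biomarker, these statistics ask whether
the high group looks immunologically "hot": a higher ratio of pro- to
anti-inflammatory cytokine expression, more cytotoxic CD8 T cells relative to
suppressive populations (Tregs, M1 macrophages/TAMs, MDSCs), and higher
hot-signature enrichment scores.

Ratios are of mean log2(FPKM+1) over marker panels; values are standardized
(z-scored) within each tumor type before the two-group comparison so that
tumor-type composition differences do not masquerade as group differences.
The two-group test is the two-sided Wilcoxon–Mann–Whitney rank-sum test
(the design is unpaired, so a signed-rank test would not apply).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection
from .ssgsea import ScoreMatrix, SsgseaParams, score_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "default_cytokine_panels",
    "default_cell_type_panels",
    "group_ratio",
    "zscore_within",
    "compare_groups",
    "hot_cold_scores",
]


def default_cytokine_panels() -> tuple[GeneSet, GeneSet]:
    """Pro- and anti-inflammatory cytokine panels.

    Pro: IFN-γ, IL-1 (expanded to IL1A/IL1B) and IL-2; anti: TGFB1, IL10,
    IL4 and IL11.  The cytokine names are mapped to HGNC symbols here; the
    panels are plain gene sets and can be replaced by any GMT.
    """
    pro = GeneSet("pro_inflammatory_cytokines", "IFN-g, IL-1, IL-2",
                  frozenset({"IFNG", "IL1A", "IL1B", "IL2"}))
    anti = GeneSet("anti_inflammatory_cytokines", "TGFB1, IL-10, IL-4, IL-11",
                   frozenset({"TGFB1", "IL10", "IL4", "IL11"}))
    return pro, anti


def default_cell_type_panels() -> GeneSetCollection:
    """Marker panels for the four cell populations used in the CD8 ratios.

    These marker lists are this package's editable defaults — compact,
    widely used lineage markers — not a published deconvolution signature.
    """
    return GeneSetCollection(
        [
            GeneSet("cd8_t", "cytotoxic CD8 T cells", frozenset({"CD8A", "CD8B"})),
            GeneSet("treg", "regulatory T cells", frozenset({"FOXP3", "IL2RA", "CTLA4"})),
            GeneSet("m1_macrophage", "M1 macrophages / TAMs",
                    frozenset({"NOS2", "CD80", "CD86"})),
            GeneSet("mdsc", "myeloid-derived suppressor cells",
                    frozenset({"ITGAM", "CD33", "ARG1"})),
        ]
    )


def group_ratio(
    expr: ExpressionMatrix,
    numerator: GeneSet,
    denominator: GeneSet,
) -> pd.Series:
    """Per-sample ratio of mean log2(FPKM+1) over two marker panels.

    Samples whose denominator panel mean is <= 0 (all-zero FPKM) get NaN
    (undefined sentinel) and are excluded downstream, with a logged count.
    Panels are restricted to measured genes; a panel with no measured genes
    raises.
    """
    log_expr = expr.log2p1()
    num_idx = expr.gene_indices(numerator.genes)
    den_idx = expr.gene_indices(denominator.genes)
    if num_idx.size == 0 or den_idx.size == 0:
        raise ValueError(
            f"panel {numerator.name if num_idx.size == 0 else denominator.name!r} "
            "has no measured genes"
        )
    num_mean = log_expr.values[num_idx].mean(axis=0)
    den_mean = log_expr.values[den_idx].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den_mean > 0, num_mean / den_mean, np.nan)
    n_undef = int(np.isnan(ratio).sum())
    if n_undef:
        logger.warning(
            "%d samples with non-positive denominator panel mean excluded "
            "from %s/%s ratio", n_undef, numerator.name, denominator.name,
        )
    return pd.Series(ratio, index=expr.sample_ids, name=f"{numerator.name}/{denominator.name}")


def zscore_within(values: pd.Series | np.ndarray, strata: Mapping[str, str] | Sequence[str]) -> pd.Series:
    """Standardize values within each stratum (tumor type).

    Uses the population (n-denominator) standard deviation; a constant
    stratum maps to zeros so every sample stays representable.  Processing
    strata jointly or one at a time gives identical results.
    """
    if isinstance(values, pd.Series):
        s = values.astype(float)
    else:
        s = pd.Series(np.asarray(values, dtype=float))
    if isinstance(strata, Mapping):
        labels = pd.Series([strata[i] for i in s.index], index=s.index)
    else:
        labels = pd.Series(list(strata), index=s.index)

    out = pd.Series(np.nan, index=s.index, dtype=float)
    for _, idx in labels.groupby(labels).groups.items():
        vals = s.loc[idx]
        mask = vals.notna()
        sd = vals[mask].std(ddof=0)
        if mask.sum() == 0:
            continue
        if sd == 0 or np.isnan(sd):
            out.loc[idx[mask]] = 0.0
        else:
            out.loc[idx[mask]] = (vals[mask] - vals[mask].mean()) / sd
    return out


def compare_groups(values: np.ndarray, labels: Sequence[str]) -> tuple[float, float]:
    """Two-sided rank-based comparison of 'high' vs 'low' groups.

    Wilcoxon–Mann–Whitney rank-sum: exact enumeration when both groups have
    <= 25 samples and the data are tie-free, normal approximation with tie
    correction otherwise.  Returns (U statistic of the 'high' group, p).
    NaN values are dropped.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    high = values[labels == "high"]
    low = values[labels == "low"]
    if high.size == 0 or low.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(values).size < values.size
    method = "exact" if (max(high.size, low.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(high, low, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def hot_cold_scores(
    expr: ExpressionMatrix,
    signatures: GeneSetCollection,
    params: SsgseaParams = SsgseaParams(),
) -> ScoreMatrix:
    """ssGSEA scores for hot/cold microenvironment signatures.

    Thin delegation to :func:`surrogene.ssgsea.score_matrix`: one column per
    signature that passes the overlap filter (skipped signatures are logged
    there).
    """
    return score_matrix(expr, signatures, params)
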