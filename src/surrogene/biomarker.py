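"""Biomarker stratification and outcome evaluation.

A candidate biomarker (a gene's expression or a pathway enrichment score) is
evaluated the way immune-checkpoint-blockade cohorts are analyzed:

* **median split** — within each cohort, patients scoring above that cohort's
  median go to the ``high`` group, the rest (ties included) to ``low``;
  pooled analyses concatenate the per-cohort labels.
* **response metrics** — objective response rate (CR+PR over evaluable),
  responder rate (CR/PR or SD held > 6 months), and long-term survival rate
  (overall survival > 36 months among evaluable patients).
* **survival statistics** — Kaplan–Meier curves, the two-group log-rank test,
  and a univariate Cox proportional-hazards fit (Efron tie handling) giving
  the hazard ratio with a Wald 95% CI.
* **discrimination** — ROC-AUC of the score against the responder label,
  computed as the Mann–Whitney rank statistic (ties count 1/2).

Survival machinery is backed by ``lifelines``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "GroupAssignment",
    "SurvivalFit",
    "ResponseSummary",
    "median_split",
    "orr",
    "responder_labels",
    "long_term_fraction",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "roc_auc",
]

#: months of stable disease beyond which an SD patient counts as a responder
RESPONDER_SD_MONTHS = 6.0
#: months of overall survival defining long-term survival
LONG_TERM_MONTHS = 36.0


@dataclass(frozen=True)
class GroupAssignment:
    patient_id: str
    cohort_id: str
    score: float
    group: str  # "high" | "low"


@dataclass(frozen=True)
class SurvivalFit:
    """Log-rank and univariate Cox results for a two-group comparison."""

    logrank_chi2: float
    logrank_p: float
    cox_beta: float
    cox_se: float
    hr: float
    hr_ci_low: float
    hr_ci_high: float
    cox_p: float


@dataclass(frozen=True)
class ResponseSummary:
    group: str
    n: int
    orr: float
    responder_rate: float
    long_term_rate: float


def median_split(
    scores: pd.Series,
    cohorts: pd.Series,
) -> list[GroupAssignment]:
    """Split patients into high/low groups at each cohort's median score.

    ``group == "high"`` iff the score is strictly above the cohort median;
    ties at the median go to ``low``.  Pooled analyses simply concatenate the
    per-cohort assignments.  A cohort with fewer than 2 scored patients is an
    error.
    """
    scores = scores.astype(float)
    out: list[GroupAssignment] = []
    for cohort, idx in cohorts.groupby(cohorts).groups.items():
        vals = scores.loc[idx]
        if len(vals) < 2:
            raise ValueError(f"cohort {cohort!r} has {len(vals)} patients; need >= 2")
        med = float(vals.median())
        for pid, v in vals.items():
            out.append(
                GroupAssignment(
                    patient_id=str(pid),
                    cohort_id=str(cohort),
                    score=float(v),
                    group="high" if v > med else "low",
                )
            )
    return out


def orr(recist: Sequence[str]) -> float:
    """Objective response rate: (#CR + #PR) / #evaluable.

    Patients with RECIST ``NA`` are excluded from the denominator (logged).
    Returns NaN when no patient is evaluable.
    """
    labels = pd.Series(list(recist), dtype=str)
    evaluable = labels[labels != "NA"]
    n_excluded = len(labels) - len(evaluable)
    if n_excluded:
        logger.info("ORR: excluded %d patients with RECIST NA", n_excluded)
    if evaluable.empty:
        logger.warning("ORR undefined: no evaluable patients")
        return float("nan")
    return float(evaluable.isin(["CR", "PR"]).mean())


def responder_labels(
    recist: Sequence[str],
    response_duration_months: Sequence[float],
    sd_months: float = RESPONDER_SD_MONTHS,
) -> pd.Series:
    """Responder flag per patient: CR/PR, or SD maintained strictly longer
    than ``sd_months`` (default 6).

    SD patients with a missing duration cannot be adjudicated and get NaN
    (excluded with a warning); RECIST NA patients get NaN too.
    """
    recist = pd.Series(list(recist), dtype=str)
    dur = pd.Series(list(response_duration_months), dtype=float)
    out = pd.Series(np.nan, index=recist.index, dtype=object)
    out[recist.isin(["CR", "PR"])] = True
    out[recist.isin(["PD"])] = False
    sd = recist == "SD"
    out[sd & dur.notna() & (dur > sd_months)] = True
    out[sd & dur.notna() & (dur <= sd_months)] = False
    n_missing_sd = int((sd & dur.isna()).sum())
    if n_missing_sd:
        logger.warning(
            "%d SD patients lack a response duration; excluded from responder rate",
            n_missing_sd,
        )
    return out


def long_term_fraction(
    os_months: Sequence[float],
    event: Sequence[int],
    threshold_months: float = LONG_TERM_MONTHS,
    include_early_censored: bool = False,
) -> float:
    """Fraction of evaluable patients surviving beyond ``threshold_months``.

    A patient observed past the threshold (event or censored) counts as a
    long-term survivor.  A patient who died at or before the threshold counts
    against.  A patient censored at or before the threshold is unevaluable
    and is excluded (logged), unless ``include_early_censored`` puts them in
    the denominator (the naive reading).  NaN when nobody is evaluable.
    """
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(event, dtype=int)
    long_term = t > threshold_months
    died_early = (~long_term) & (e == 1)
    censored_early = (~long_term) & (e == 0)
    n_excluded = int(censored_early.sum())
    if include_early_censored:
        denom = len(t)
    else:
        if n_excluded:
            logger.info(
                "long-term survival: %d patients censored at <= %.0f months excluded",
                n_excluded, threshold_months,
            )
        denom = int(long_term.sum() + died_early.sum())
    if denom == 0:
        logger.warning("long-term survival undefined: no evaluable patients")
        return float("nan")
    return float(long_term.sum() / denom)


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan–Meier product-limit estimator.

    Returns ``(times, survival)`` step-function coordinates starting at
    (0, 1).  All-censored data give a flat curve at 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no observations")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p-value.

    Undefined (NaN, NaN) when there are no events at all.  The statistic is
    symmetric in the two groups.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        logger.warning("log-rank undefined: zero events")
        return (float("nan"), float("nan"))
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(
    covariate: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    ties: str = "efron",
) -> SurvivalFit:
    """Univariate Cox proportional-hazards fit.

    Newton–Raphson on the partial likelihood with Efron tie handling
    (``ties="breslow"`` available).  Returns the log-hazard coefficient, its
    standard error, HR = exp(beta) with a Wald 95% CI and two-sided p, plus
    the log-rank comparison left as NaN (this function fits the continuous
    covariate; see :func:`evaluate_split` for the grouped analysis).

    A constant covariate or a monotone (perfectly separating) likelihood
    raises with a diagnostic.
    """
    x = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance; Cox fit undefined")
    if e.sum() == 0:
        raise ValueError("need at least one event")
    df = pd.DataFrame({"x": x, "T": t, "E": e})
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
    except ConvergenceError as exc:
        raise ValueError(f"Cox fit did not converge (monotone likelihood?): {exc}") from exc
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        raise ValueError("Cox fit degenerate (perfect separation suspected)")
    from scipy import stats as _st

    z = beta / se
    p = float(2 * _st.norm.sf(abs(z)))
    return SurvivalFit(
        logrank_chi2=float("nan"),
        logrank_p=float("nan"),
        cox_beta=beta,
        cox_se=se,
        hr=float(np.exp(beta)),
        hr_ci_low=float(np.exp(beta - 1.96 * se)),
        hr_ci_high=float(np.exp(beta + 1.96 * se)),
        cox_p=p,
    )


def roc_auc(scores: Sequence[float], responder: Sequence[bool]) -> float:
    """ROC-AUC of a score against the responder label.

    Rank statistic (ties count 0.5), equal to the Mann–Whitney U estimator.
    NaN patients (unadjudicated responders) are dropped; a single-class input
    yields NaN.
    """
    s = np.asarray(scores, dtype=float)
    y = pd.Series(list(responder))
    keep = y.notna().to_numpy() & np.isfinite(s)
    s, y = s[keep], y[keep].astype(bool).to_numpy()
    if y.size == 0 or y.all() or (~y).all():
        logger.warning("AUC undefined: only one class present")
        return float("nan")
    return float(roc_auc_score(y, s))


# ---------------------------------------------------------------------------
# grouped evaluation convenience
# ---------------------------------------------------------------------------


def evaluate_split(
    clinical: pd.DataFrame,
    assignments: list[GroupAssignment],
) -> dict:
    """Full high-vs-low evaluation of a split: response summaries per group,
    log-rank test, and a Cox fit on the binary group indicator (high = 1).

    ``clinical`` must carry the :class:`~surrogene.io_formats.ClinicalTable`
    columns indexed by patient.  Returns a dict with ``response`` (two
    :class:`ResponseSummary`), ``fit`` (:class:`SurvivalFit`), and ``km``
    (per-group step-function coordinates).
    """
    groups = pd.Series({a.patient_id: a.group for a in assignments})
    df = clinical.set_index("patient_id").loc[groups.index].copy()
    df["group"] = groups

    summaries = {}
    km = {}
    for g in ("high", "low"):
        sub = df[df["group"] == g]
        resp = responder_labels(sub["recist"], sub["response_duration_months"])
        summaries[g] = ResponseSummary(
            group=g,
            n=len(sub),
            orr=orr(sub["recist"]),
            responder_rate=float(resp.dropna().astype(bool).mean()) if resp.notna().any() else float("nan"),
            long_term_rate=long_term_fraction(sub["os_months"], sub["event"]),
        )
        km[g] = km_estimate(sub["os_months"], sub["event"])

    hi = df[df["group"] == "high"]
    lo = df[df["group"] == "low"]
    chi2, p_lr = logrank_test(hi["os_months"], hi["event"], lo["os_months"], lo["event"])
    indicator = (df["group"] == "high").astype(float)
    cox = cox_univariate(indicator, df["os_months"], df["event"])
    fit = SurvivalFit(
        logrank_chi2=chi2,
        logrank_p=p_lr,
        cox_beta=cox.cox_beta,
        cox_se=cox.cox_se,
        hr=cox.hr,
        hr_ci_low=cox.hr_ci_low,
        hr_ci_high=cox.hr_ci_high,
        cox_p=cox.cox_p,
    )
    return {"response": summaries, "fit": fit, "km": km}
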