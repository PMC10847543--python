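"""NAC response analysis: per-cycle tumor-size ratios and pCR prediction.

For each measurement model (LAM, DAM, MSM, DLM) the tumor size after N
cycles of neoadjuvant chemotherapy is divided by the pre-NAC size
(Ratio N); the percentage reduction 1 - Ratio N at a given cycle is the
predictor of pathological complete response.  AUCs use the Mann-Whitney
statistic with midrank tie handling; confidence intervals and AUC
comparisons use DeLong's covariance-based method for correlated ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .phantom import MEASUREMENT_MODELS, CohortRecord


# ---------------------------------------------------------------------------
# size ratios
# ---------------------------------------------------------------------------

def size_ratios(record: CohortRecord, model: str) -> np.ndarray:
    """Ratio N = size after N cycles / pre-NAC size, for N = 1..n_cycles."""
    if model not in record.measurements:
        raise KeyError(f"model {model!r} not in record (has {list(record.measurements)})")
    values = np.asarray(record.measurements[model], dtype=float)
    baseline = values[0]
    if baseline <= 0:
        raise ValueError("pre-NAC baseline size must be positive")
    return values[1:] / baseline


def ratio_table(cohort: list[CohortRecord], model: str) -> pd.DataFrame:
    """Per-patient Ratio N table (rows: patients; columns: cycle 1..N)."""
    rows = {}
    n_max = max(r.n_cycles for r in cohort)
    for rec in cohort:
        ratios = size_ratios(rec, model)
        rows[rec.patient_id] = np.concatenate(
            [ratios, np.full(n_max - len(ratios), np.nan)])
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"ratio_{c}" for c in range(1, n_max + 1)])
    df.insert(0, "pcr", [rec.pcr_label for rec in cohort])
    return df


# ---------------------------------------------------------------------------
# AUC / DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney probability P(score+ > score-), ties 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = _midrank(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (V10 per positive, V01 per negative)."""
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = _midrank(pos), _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC estimate)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return auc, float(var)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class DeLongComparison:
    z: float
    p: float
    paired: bool
    auc_a: float
    auc_b: float


def pcr_roc(reductions, labels) -> ROCResult:
    """ROC for predicting pCR from percentage tumor-size reduction.

    Orientation: larger reduction scores toward pCR, so a useful predictor
    gives AUC >= 0.5.  The 95% CI is the DeLong asymptotic normal interval
    truncated to [0,1].
    """
    reductions = np.asarray(reductions, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    auc, var = delong_variance(reductions, labels)
    half = 1.959963984540054 * np.sqrt(var)
    fpr, tpr, thr = roc_curve(labels, reductions)
    return ROCResult(auc=auc, ci95=(max(0.0, auc - half), min(1.0, auc + half)),
                     n_pos=int(labels.sum()), n_neg=int((~labels).sum()),
                     fpr=fpr, tpr=tpr, thresholds=thr)


def delong_compare(scores_a, scores_b, labels, paired: bool = True,
                   labels_b=None) -> DeLongComparison:
    """DeLong test for the difference between two AUCs.

    ``paired=True`` (same patients scored twice) uses the covariance of the
    structural components; ``paired=False`` treats the two ROC curves as
    independent (``labels_b`` defaults to ``labels``).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if paired:
        if scores_a.shape != scores_b.shape:
            raise ValueError("paired comparison requires equal-length score vectors")
        auc_a, v10a, v01a = _delong_components(scores_a, labels)
        auc_b, v10b, v01b = _delong_components(scores_b, labels)
        m, n = len(v10a), len(v01a)
        var_a = np.var(v10a, ddof=1) / m + np.var(v01a, ddof=1) / n
        var_b = np.var(v10b, ddof=1) / m + np.var(v01b, ddof=1) / n
        cov = (np.cov(v10a, v10b, ddof=1)[0, 1] / m
               + np.cov(v01a, v01b, ddof=1)[0, 1] / n)
        var_diff = var_a + var_b - 2 * cov
    else:
        lb = labels if labels_b is None else np.asarray(labels_b, dtype=bool)
        auc_a, var_a = delong_variance(scores_a, labels)
        auc_b, var_b = delong_variance(scores_b, lb)
        var_diff = var_a + var_b
    if var_diff <= 0:
        z = 0.0
    else:
        z = float((auc_a - auc_b) / np.sqrt(var_diff))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongComparison(z=z, p=p, paired=paired, auc_a=auc_a, auc_b=auc_b)


# ---------------------------------------------------------------------------
# cohort-level tables
# ---------------------------------------------------------------------------

def _cycle_predictor(cohort, model: str, cycle: int):
    """(reductions, labels, patient_ids) at one cycle, restricted to
    patients measured at that cycle."""
    red, lab, ids = [], [], []
    for rec in cohort:
        if rec.n_cycles >= cycle:
            red.append(1.0 - size_ratios(rec, model)[cycle - 1])
            lab.append(rec.pcr_label)
            ids.append(rec.patient_id)
    return np.asarray(red), np.asarray(lab, dtype=bool), ids


def per_cycle_auc_table(cohort: list[CohortRecord], model: str):
    """AUC per NAC cycle plus pairwise DeLong p-values between cycles.

    Mixed 6/8-cycle cohorts are handled by restricting each cycle's ROC to
    the patients measured at that cycle; cross-cycle comparisons are paired
    on the common patient subset.  Cycles with a single outcome class are
    flagged (NaN row) rather than computed.

    Returns ``(auc_frame, pairwise_p_frame, roc_results)``.
    """
    n_max = max(r.n_cycles for r in cohort)
    cycles = list(range(1, n_max + 1))
    rows, rocs = [], {}
    for c in cycles:
        red, lab, _ = _cycle_predictor(cohort, model, c)
        if len(np.unique(lab)) < 2:
            rows.append({"cycle": c, "auc": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "n": len(lab)})
            continue
        roc = pcr_roc(red, lab)
        rocs[c] = roc
        rows.append({"cycle": c, "auc": roc.auc, "ci_lo": roc.ci95[0],
                     "ci_hi": roc.ci95[1], "n": roc.n_pos + roc.n_neg})
    auc_frame = pd.DataFrame(rows).set_index("cycle")

    pair_p = pd.DataFrame(np.nan, index=cycles, columns=cycles)
    for i in cycles:
        for j in cycles:
            if j <= i or i not in rocs or j not in rocs:
                continue
            red_i, lab_i, ids_i = _cycle_predictor(cohort, model, i)
            red_j, lab_j, ids_j = _cycle_predictor(cohort, model, j)
            common = sorted(set(ids_i) & set(ids_j))
            sel_i = [ids_i.index(pid) for pid in common]
            sel_j = [ids_j.index(pid) for pid in common]
            lab = lab_i[sel_i]
            if len(np.unique(lab)) < 2:
                continue
            cmp = delong_compare(red_i[sel_i], red_j[sel_j], lab, paired=True)
            pair_p.loc[i, j] = pair_p.loc[j, i] = cmp.p
    return auc_frame, pair_p, rocs


def model_comparison_table(cohort: list[CohortRecord], cycle: int | None = None,
                           models=MEASUREMENT_MODELS):
    """Final-cycle (or given-cycle) AUC per measurement model plus pairwise
    DeLong p-values between models on the same patients."""
    aucs, preds = {}, {}
    for model in models:
        c = cycle or min(r.n_cycles for r in cohort)
        red, lab, _ = _cycle_predictor(cohort, model, c)
        preds[model] = (red, lab)
        aucs[model] = pcr_roc(red, lab)
    pair = pd.DataFrame(np.nan, index=list(models), columns=list(models))
    for i, mi in enumerate(models):
        for mj in models[i + 1:]:
            cmp = delong_compare(preds[mi][0], preds[mj][0], preds[mi][1], paired=True)
            pair.loc[mi, mj] = pair.loc[mj, mi] = cmp.p
    table = pd.DataFrame({
        "auc": {m: aucs[m].auc for m in models},
        "ci_lo": {m: aucs[m].ci95[0] for m in models},
        "ci_hi": {m: aucs[m].ci95[1] for m in models},
    })
    return table, pair, aucs


def group_residual_summary(cohort: list[CohortRecord], model: str) -> pd.DataFrame:
    """Per-cycle mean +/- sd of Ratio N for the pCR and non-pCR groups."""
    df = ratio_table(cohort, model)
    rows = []
    for cycle_col in df.columns[1:]:
        c = int(cycle_col.split("_")[1])
        for group, sub in df.groupby("pcr"):
            vals = sub[cycle_col].dropna()
            rows.append({"cycle": c, "group": "pCR" if group else "non-pCR",
                         "mean_ratio": vals.mean(), "sd_ratio": vals.std(ddof=1),
                         "n": len(vals)})
    return pd.DataFrame(rows)
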