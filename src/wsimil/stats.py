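"""Evaluation statistics: Pearson correlation with BH correction, ROC/AUC,
confusion matrices, Harrell's concordance index, and a patient-level
cross-validation splitter.

Per-protein regression quality is scored as the Pearson r between measured
and predicted levels; a protein counts as significantly predicted when its
Benjamini–Hochberg adjusted p-value falls below alpha (FDR control across
the panel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult", "pearson", "bh_adjust", "correlation_panel",
    "roc_auc", "confusion_and_accuracy", "c_index", "kfold",
]


@dataclass
class CorrelationResult:
    protein: str
    r: float
    p: float
    p_adj: float = np.nan
    significant: bool = False


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p-value (t-transform, n-2 df).

    Raises ValueError for n < 3 or zero variance rather than returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals, alpha: float = 0.05):
    """Benjamini–Hochberg step-up: adjusted p-values and the rejection set.

    Returns (p_adj, reject) arrays; empty input gives empty arrays.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def correlation_panel(measured: pd.DataFrame, predicted: pd.DataFrame,
                      alpha: float = 0.05) -> list[CorrelationResult]:
    """Per-protein Pearson r between measured and predicted panels, with BH
    correction across the panel. Columns are proteins, rows are patients."""
    names = list(measured.columns)
    results = []
    for name in names:
        r, p = pearson(measured[name].to_numpy(), predicted[name].to_numpy())
        results.append(CorrelationResult(protein=name, r=r, p=p))
    p_adj, reject = bh_adjust([c.p for c in results], alpha=alpha)
    for c, pa, rej in zip(results, p_adj, reject):
        c.p_adj = float(pa)
        c.significant = bool(rej)
    return results


def roc_auc(scores, labels) -> float:
    """AUC via the rank (Mann–Whitney) formulation; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(skm.roc_auc_score(labels, scores))


def confusion_and_accuracy(pred, true):
    """2x2 confusion counts (tn, fp, fn, tp) and accuracy."""
    pred = np.asarray(pred).astype(int)
    true = np.asarray(true).astype(int)
    if pred.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    cm = skm.confusion_matrix(true, pred, labels=[0, 1])
    acc = float(np.trace(cm)) / len(true)
    return cm, acc


def c_index(risk_scores, times, events) -> float:
    """Harrell's concordance index over admissible pairs.

    A pair (i, j) is admissible when the earlier observed time carries an
    event; concordant when the earlier-failing member has the higher risk
    score; score ties count 1/2.
    """
    risk = np.asarray(risk_scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    n = len(risk)
    conc = 0.0
    npairs = 0
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            # i failed at times[i]; j must still be at risk past that time
            if times[j] > times[i] or (times[j] == times[i] and events[j] == 0):
                npairs += 1
                if risk[i] > risk[j]:
                    conc += 1.0
                elif risk[i] == risk[j]:
                    conc += 0.5
    if npairs == 0:
        raise ValueError("no comparable pairs for concordance")
    return conc / npairs


def kfold(manifest: pd.DataFrame, k: int, seed: int) -> pd.Series:
    """Patient-level k-fold assignment: all slides of a patient land in the
    same fold (no leakage); fold sizes in patients differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    patients = manifest["patient_id"].unique()
    if k > len(patients):
        raise ValueError(f"k={k} exceeds number of patients ({len(patients)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(patients))
    fold_of = {}
    for rank, idx in enumerate(perm):
        fold_of[patients[idx]] = rank % k
    return manifest["patient_id"].map(fold_of).rename("fold")
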