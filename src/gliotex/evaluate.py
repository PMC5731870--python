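"""Evaluation statistics for the CD3 infiltration classifier.

Covers the complete result-level analysis: ROC AUC (Mann-Whitney form,
ties counted one half) with stratified-bootstrap percentile confidence
intervals; confusion-matrix rates with exact (Clopper-Pearson) binomial
accuracy intervals; Spearman concordance between continuous predictions
and CD3 measurements; a covariate-adjusted multivariate linear regression
of CD3 on the model predictions plus clinical and volumetric covariates;
per-variable Kruskal-Wallis train/test balance tests; and a paired
bootstrap test for the difference between two models' AUCs on the same
cases.  "High infiltration" is the positive class throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the normalized Mann-Whitney U statistic; ties count 1/2."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(s)  # average ranks resolve ties at 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile CI of the AUC from a class-stratified bootstrap.

    Cases are resampled within each class independently, so every
    bootstrap sample retains both classes.
    """
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    lab = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    for b in range(n_boot):
        sp = pos[rng.integers(0, len(pos), len(pos))]
        sn = neg[rng.integers(0, len(neg), len(neg))]
        aucs[b] = roc_auc(np.concatenate([sp, sn]), lab)
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def roc_curve_points(
    scores: Sequence[float], labels: Sequence[int]
) -> pd.DataFrame:
    """FPR/TPR pairs at every distinct score threshold (descending)."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int(len(y) - y.sum()), 1)
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    keep = np.append(np.diff(s) != 0, True)
    return pd.DataFrame(
        {
            "threshold": np.concatenate([[np.inf], s[keep]]),
            "fpr": np.concatenate([[0.0], fp[keep] / n_neg]),
            "tpr": np.concatenate([[0.0], tp[keep] / n_pos]),
        }
    )


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with high infiltration as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionMatrix":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((t == 1) & (p == 1)).sum()),
            fp=int(((t == 0) & (p == 1)).sum()),
            tn=int(((t == 0) & (p == 0)).sum()),
            fn=int(((t == 1) & (p == 0)).sum()),
        )


def confusion_metrics(cm: ConfusionMatrix, ci_level: float = 0.95) -> Dict[str, float]:
    """Accuracy (with exact Clopper-Pearson CI), sensitivity, specificity
    and classifier false-discovery rate FP/(TP+FP).

    An empty predicted-positive set leaves FDR as NaN with a flag entry.
    """
    out: Dict[str, float] = {}
    correct = cm.tp + cm.tn
    out["accuracy"] = correct / cm.total
    lo, hi = proportion_confint(correct, cm.total, alpha=1 - ci_level, method="beta")
    out["accuracy_ci_low"] = float(lo)
    out["accuracy_ci_high"] = float(hi)
    out["sensitivity"] = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else float("nan")
    out["specificity"] = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else float("nan")
    if cm.tp + cm.fp:
        out["fdr"] = cm.fp / (cm.tp + cm.fp)
    else:
        out["fdr"] = float("nan")
        out["fdr_undefined"] = 1.0
    return out


# ---------------------------------------------------------------------------
# concordance / balance / adjustment
# ---------------------------------------------------------------------------

def spearman_concordance(
    scores: Sequence[float], y_continuous: Sequence[float]
) -> Tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y_continuous, dtype=np.float64)
    if len(s) < 3:
        raise ValueError("need n >= 3")
    if np.all(s == s[0]) or np.all(y == y[0]):
        raise ValueError("constant vector; rank correlation undefined")
    res = stats.spearmanr(s, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis_balance(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    variables: Sequence[str],
) -> Dict[str, float]:
    """Two-group Kruskal-Wallis p-value per variable.

    A variable constant across all samples is reported as NaN (flagged by
    omission of a finite p) rather than an error.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    out: Dict[str, float] = {}
    for v in variables:
        a = np.asarray(group_a[v], dtype=np.float64)
        b = np.asarray(group_b[v], dtype=np.float64)
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            out[v] = float("nan")
            continue
        out[v] = float(stats.kruskal(a, b).pvalue)
    return out


#: Table layout of the covariate-adjusted regression (order of reporting).
ADJUSTMENT_VARIABLES = (
    "age",
    "gender",
    "kps",
    "flair_tumor_volume",
    "flair_total_intensity",
    "t1post_tumor_volume",
    "t1post_total_intensity",
    "model_prediction",
)


def covariate_adjusted_regression(
    y: Sequence[float],
    predictions: Sequence[float],
    covariates: pd.DataFrame,
) -> Dict[str, float]:
    """Per-term p-values of one multivariate linear model of continuous CD3.

    The design contains age, gender, KPS, both tumor volumes, both total
    intensities and the model predictions (plus an intercept).  ``gender``
    may be coded as strings ("F"/"M") or numerically.
    """
    y = np.asarray(y, dtype=np.float64)
    pred = np.asarray(predictions, dtype=np.float64)
    needed = [v for v in ADJUSTMENT_VARIABLES if v != "model_prediction"]
    missing = [v for v in needed if v not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    X = covariates[needed].copy()
    if X["gender"].dtype == object:
        X["gender"] = (X["gender"].astype(str).str.upper() == "M").astype(float)
    X = X.astype(np.float64)
    X["model_prediction"] = pred
    if len(y) <= X.shape[1] + 1:
        raise ValueError("not enough cases for the multivariate model")
    design = sm.add_constant(X, has_constant="add")
    # scale columns to unit norm before the rank test so that columns of
    # very different magnitude (mm^3 volumes vs binary gender) are
    # comparable; otherwise numerical rank detection is unreliable
    arr = design.to_numpy()
    norms = np.linalg.norm(arr, axis=0)
    norms[norms == 0] = 1.0
    scaled = arr / norms
    rank = np.linalg.matrix_rank(scaled)
    if rank < design.shape[1]:
        # name offending columns: those whose removal restores full rank
        bad = []
        for j, c in enumerate(design.columns):
            if c == "const":
                continue
            sub = np.delete(scaled, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(c)
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    fit = sm.OLS(y, design).fit()
    return {v: float(fit.pvalues[v]) for v in ADJUSTMENT_VARIABLES}


# ---------------------------------------------------------------------------
# AUC comparison
# ---------------------------------------------------------------------------

def compare_auc_bootstrap(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Two-sided p for a difference in AUC between two models on the same
    cases, via a paired case bootstrap.

    The observed difference is standardized by the bootstrap standard
    error of the difference and referred to the normal distribution.
    Identical score vectors give p = 1.
    """
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("score vectors and labels must align case-wise")
    d_obs = roc_auc(a, y) - roc_auc(b, y)
    rng = np.random.default_rng(seed)
    diffs = []
    n = len(y)
    while len(diffs) < n_boot:
        idx = rng.integers(0, n, n)
        yy = y[idx]
        if yy.min() == yy.max():  # degenerate resample: redraw
            continue
        diffs.append(roc_auc(a[idx], yy) - roc_auc(b[idx], yy))
    sd = float(np.std(diffs, ddof=1))
    if sd == 0:
        return 1.0 if d_obs == 0 else 0.0
    z = d_obs / sd
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Bundle of the headline evaluation quantities."""

    auc: float
    auc_ci: Tuple[float, float]
    accuracy: float
    accuracy_ci: Tuple[float, float]
    sensitivity: float
    specificity: float
    fdr: float
    spearman_rho: float
    spearman_p: float
    confusion: ConfusionMatrix = None
    adjustment_p: Dict[str, float] = field(default_factory=dict)
    balance_p: Dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fdr": self.fdr,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "confusion": vars(self.confusion) if self.confusion else None,
            "adjustment_p": self.adjustment_p,
            "balance_p": self.balance_p,
        }
        return json.dumps(d, indent=1)

    def to_text(self) -> str:
        cm = self.confusion
        lines = [
            "Confusion matrix (rows: predicted, cols: actual; positive = high infiltration)",
            f"              low   high",
            f"  pred low   {cm.tn:4d}  {cm.fn:4d}",
            f"  pred high  {cm.fp:4d}  {cm.tp:4d}",
            "",
            f"AUC          {self.auc:.3f}  CI [{self.auc_ci[0]:.2f}, {self.auc_ci[1]:.2f}]",
            f"accuracy     {100 * self.accuracy:.1f}%  CI [{self.accuracy_ci[0]:.3f}, {self.accuracy_ci[1]:.3f}]",
            f"sensitivity  {100 * self.sensitivity:.1f}%",
            f"specificity  {100 * self.specificity:.2f}%",
            f"FDR          {100 * self.fdr:.1f}%" if np.isfinite(self.fdr) else "FDR          undefined",
            f"Spearman rho {self.spearman_rho:.3f} (p = {self.spearman_p:.4g})",
        ]
        if self.adjustment_p:
            lines += ["", "Covariate-adjusted regression (p per term):"]
            lines += [f"  {k:24s} {v:.4f}" for k, v in self.adjustment_p.items()]
        if self.balance_p:
            lines += ["", "Train/test balance (Kruskal-Wallis p per variable):"]
            lines += [f"  {k:24s} {v:.4f}" for k, v in self.balance_p.items()]
        return "\n".join(lines)


def evaluate_predictions(
    scores: Sequence[float],
    labels_pred: Sequence[int],
    y_true: Sequence[int],
    y_continuous: Optional[Sequence[float]] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalReport:
    """Assemble the standard report for one evaluated cohort."""
    cm = ConfusionMatrix.from_predictions(y_true, labels_pred)
    metrics = confusion_metrics(cm)
    auc = roc_auc(scores, y_true)
    ci = auc_bootstrap_ci(scores, y_true, n_boot=n_boot, seed=seed)
    if y_continuous is not None:
        rho, p = spearman_concordance(scores, y_continuous)
    else:
        rho, p = float("nan"), float("nan")
    return EvalReport(
        auc=auc,
        auc_ci=ci,
        accuracy=metrics["accuracy"],
        accuracy_ci=(metrics["accuracy_ci_low"], metrics["accuracy_ci_high"]),
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        fdr=metrics["fdr"],
        spearman_rho=rho,
        spearman_p=p,
        confusion=cm,
    )
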