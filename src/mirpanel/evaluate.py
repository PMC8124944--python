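"""Frozen-panel evaluation: ROC/AUC, cutoffs, confusion metrics, trends."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._stats import candidate_thresholds, jonckheere_statistic, rank_auc, roc_points
from .diffexpr import _as_positive
from .panels import PanelModel

DEFAULT_SPECIFICITY_TARGET = 0.90
DEFAULT_SENSITIVITY_TARGET = 0.80


@dataclass
class CutoffReport:
    mode: str  # high_specificity | high_sensitivity
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    ci: dict = field(default_factory=dict)  # metric -> (lo, hi)
    undefined: list = field(default_factory=list)

    def as_row(self) -> dict:
        row = {"mode": self.mode, "cutoff": self.cutoff, "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}
        for m in ("sensitivity", "specificity", "ppv", "npv"):
            row[m] = getattr(self, m)
            lo, hi = self.ci.get(m, (np.nan, np.nan))
            row[f"{m}_ci_lo"], row[f"{m}_ci_hi"] = lo, hi
        return row


@dataclass
class TrendReport:
    grouping: str
    summaries: pd.DataFrame  # group, n, median, q1, q3
    statistic: float
    p_value: float
    n_excluded: int


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """Tie-corrected rank AUC plus the full ROC operating-point sweep."""
    positive = _as_positive(labels)
    scores = np.asarray(scores, dtype=float)
    auc = rank_auc(scores, positive)
    pts = roc_points(scores, positive)
    curve = pd.DataFrame(pts, columns=["threshold", "fpr", "tpr"])
    return auc, curve


def choose_cutoff(scores, labels, mode: str, target: float | None = None) -> float:
    """Operating-point selection on the observed-score threshold grid.

    high_specificity: smallest threshold with specificity >= target
    (maximizes sensitivity subject to the specificity constraint);
    high_sensitivity: largest threshold with sensitivity >= target.
    """
    positive = _as_positive(labels)
    scores = np.asarray(scores, dtype=float)
    if target is None:
        target = DEFAULT_SPECIFICITY_TARGET if mode == "high_specificity" else DEFAULT_SENSITIVITY_TARGET
    thresholds = candidate_thresholds(scores)
    finite = thresholds[np.isfinite(thresholds)]
    n_pos, n_neg = positive.sum(), (~positive).sum()
    best_attainable = -np.inf
    if mode == "high_specificity":
        for t in finite:  # ascending
            spec = ((scores < t) & ~positive).sum() / n_neg
            best_attainable = max(best_attainable, spec)
            if spec >= target:
                return float(t)
    elif mode == "high_sensitivity":
        for t in finite[::-1]:  # descending
            sens = ((scores >= t) & positive).sum() / n_pos
            best_attainable = max(best_attainable, sens)
            if sens >= target:
                return float(t)
    else:
        raise ValueError(f"unknown cutoff mode {mode!r}")
    raise ValueError(
        f"{mode} target {target:g} unattainable on the finite threshold grid; "
        f"best attainable is {best_attainable:g}"
    )


def confusion_metrics(scores, labels, cutoff: float, mode: str = "custom") -> CutoffReport:
    """Confusion-table metrics at a cutoff (score >= cutoff calls positive),
    with Wilson 95% confidence intervals."""
    positive = _as_positive(labels)
    scores = np.asarray(scores, dtype=float)
    called = scores >= cutoff
    tp = int((called & positive).sum())
    fp = int((called & ~positive).sum())
    tn = int((~called & ~positive).sum())
    fn = int((~called & positive).sum())
    metrics = {
        "sensitivity": (tp, tp + fn),
        "specificity": (tn, tn + fp),
        "ppv": (tp, tp + fp),
        "npv": (tn, tn + fn),
    }
    values: dict[str, float | None] = {}
    ci: dict[str, tuple[float, float]] = {}
    undefined: list[str] = []
    for name, (num, den) in metrics.items():
        if den == 0:
            values[name] = None
            undefined.append(name)
        else:
            values[name] = num / den
            lo, hi = proportion_confint(num, den, alpha=0.05, method="wilson")
            ci[name] = (float(lo), float(hi))
    return CutoffReport(mode=mode, cutoff=float(cutoff), tp=tp, fp=fp, tn=tn, fn=fn, ci=ci, undefined=undefined, **values)


def trend_by_group(
    scores,
    groups,
    grouping: str = "group",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> TrendReport:
    """Ordered-trend analysis of scores across ordinal groups.

    Jonckheere-Terpstra statistic with a seeded permutation null
    (one-sided, increasing trend). Missing group values are excluded and
    counted.
    """
    scores = np.asarray(scores, dtype=float)
    groups = pd.Series(list(groups))
    known = groups.notna().to_numpy()
    n_excluded = int((~known).sum())
    x = scores[known]
    g = groups[known].to_numpy()
    levels = np.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least 2 nonempty ordered groups")
    stat = jonckheere_statistic(x, g)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if jonckheere_statistic(rng.permutation(x), g) >= stat:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    rows = []
    for lev in levels:
        vals = x[g == lev]
        rows.append(
            {
                "group": lev,
                "n": len(vals),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
            }
        )
    return TrendReport(
        grouping=grouping,
        summaries=pd.DataFrame(rows),
        statistic=stat,
        p_value=float(p),
        n_excluded=n_excluded,
    )


@dataclass
class EvaluationResult:
    control_definition: str  # benign | benign+normal
    auc: float
    roc: pd.DataFrame
    scores: pd.Series
    cutoff_reports: dict[str, CutoffReport]


def evaluate_frozen(
    model: PanelModel,
    normalized: pd.DataFrame,
    labels: pd.Series,
    include_normals: bool = False,
    specificity_target: float = DEFAULT_SPECIFICITY_TARGET,
    sensitivity_target: float = DEFAULT_SENSITIVITY_TARGET,
) -> EvaluationResult:
    """Score an evaluation set with a frozen panel and summarize performance.

    Controls are benign samples, optionally widened to include
    normal-mammogram samples; malignant samples are cases throughout.
    """
    labels = pd.Series(labels, index=normalized.index) if not isinstance(labels, pd.Series) else labels
    controls = {"benign", "normal"} if include_normals else {"benign"}
    mask = labels.isin(controls | {"malignant"}).to_numpy()
    sub = normalized.loc[mask]
    sub_labels = labels.loc[mask]
    scores = model.score(sub)
    auc, curve = roc_auc(scores.to_numpy(), sub_labels)
    reports = {}
    for mode, target in (
        ("high_specificity", specificity_target),
        ("high_sensitivity", sensitivity_target),
    ):
        try:
            cut = choose_cutoff(scores.to_numpy(), sub_labels, mode, target)
        except ValueError:
            continue
        rep = confusion_metrics(scores.to_numpy(), sub_labels, cut, mode=mode)
        reports[mode] = rep
    return EvaluationResult(
        control_definition="benign+normal" if include_normals else "benign",
        auc=auc,
        roc=curve,
        scores=scores,
        cutoff_reports=reports,
    )
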