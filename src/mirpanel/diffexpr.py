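"""Global geometric-mean normalization and differential expression.

Expression is log2-transformed and centred per sample by the mean log2
value over the retained miRNAs (equivalently: divided by the sample's
geometric mean), removing sample-level scale. Group comparison uses the
pooled-variance two-sample t-test with Benjamini-Hochberg adjustment,
and each miRNA additionally gets a single-marker ROC AUC.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._stats import rank_auc
from .quantify import ExpressionMatrix

FDR_ALPHA = 0.05


def global_geomean_normalize(expression: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-sample centred log2 matrix: log2(x_ij) - mean_i log2(x_ij).

    Requires strictly positive input (quantification floors guarantee it).
    Row means of the result are 0 by construction.
    """
    values = expression.values if isinstance(expression, ExpressionMatrix) else expression
    arr = values.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("normalization requires strictly positive expression values")
    log2 = np.log2(arr)
    centred = log2 - log2.mean(axis=1, keepdims=True)
    return pd.DataFrame(centred, index=values.index, columns=values.columns)


def single_marker_auc(values: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> float:
    """AUC of one miRNA for malignant-vs-benign, oriented 'higher in malignant'."""
    positive = _as_positive(labels)
    return rank_auc(np.asarray(values, dtype=float), positive)


def _as_positive(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == "malignant"


def differential_expression(
    normalized: pd.DataFrame,
    labels: pd.Series,
    alpha: float = FDR_ALPHA,
) -> pd.DataFrame:
    """Per-miRNA DE table: log2fc, pooled t-test p, BH q, single-marker AUC.

    log2fc is the malignant-minus-benign difference of group means on the
    normalized log2 scale. Zero-pooled-variance miRNAs get p = 1 with a
    flag rather than NaN.
    """
    positive = _as_positive(labels)
    if positive.sum() < 2 or (~positive).sum() < 2:
        raise ValueError("need >=2 samples per group")
    x = normalized.to_numpy(dtype=float)
    mal, ben = x[positive], x[~positive]
    log2fc = mal.mean(axis=0) - ben.mean(axis=0)
    with warnings.catch_warnings():
        # zero pooled variance is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = sps.ttest_ind(mal, ben, axis=0, equal_var=True)
    zero_var = ~np.isfinite(p)
    p = np.where(zero_var, 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    auc = np.array([rank_auc(x[:, j], positive) for j in range(x.shape[1])])
    out = pd.DataFrame(
        {
            "mirna_id": normalized.columns,
            "log2fc": log2fc,
            "t": t_stat,
            "p": p,
            "q": q,
            "auc_single": np.maximum(auc, 1.0 - auc),
            "direction": np.where(log2fc > 0, "up", "down"),
            "significant": q < alpha,
            "zero_variance": zero_var,
        }
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)
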