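"""Multi-miRNA panel construction.

Panels of a target size are selected by sequential forward floating
selection (SFFS) inside repeated stratified two-fold cross-validation,
with a ridge-stabilized logistic model scoring each candidate subset by
its training AUC. Selection frequencies over all round x fold entries
define the final panel, which is refit once on the full input with frozen
feature standardization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Hashable, Sequence

import numpy as np
import pandas as pd

from ._logistic import DEFAULT_RIDGE, fit_logistic, predict_logit, predict_proba
from ._stats import rank_auc
from .diffexpr import _as_positive

DEFAULT_ROUNDS = 200
PANEL_SIZES = tuple(range(2, 9))


@dataclass
class PanelModel:
    """Frozen logistic panel: ordered miRNAs, coefficients, standardization."""

    mirnas: list[str]
    coefficients: np.ndarray
    intercept: float
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        k = len(self.mirnas)
        if not (len(self.coefficients) == len(self.means) == len(self.sds) == k):
            raise ValueError("panel fields must all have length k")
        if (self.sds <= 0).any():
            raise ValueError("standardization SDs must be positive")

    def score(self, normalized: pd.DataFrame | pd.Series) -> pd.Series | float:
        """Biomarker score in (0,1) from per-sample-normalized log2 values."""
        if isinstance(normalized, pd.Series):
            return float(self.score(normalized.to_frame().T).iloc[0])
        missing = [m for m in self.mirnas if m not in normalized.columns]
        if missing:
            raise KeyError(f"panel miRNAs absent from input: {missing}")
        z = (normalized[self.mirnas].to_numpy(dtype=float) - self.means) / self.sds
        p = predict_proba(self.intercept, self.coefficients, z)
        return pd.Series(p, index=normalized.index, name="score")

    def to_json(self) -> str:
        return json.dumps(
            {
                "mirnas": self.mirnas,
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PanelModel":
        d = json.loads(text)
        return cls(
            mirnas=list(d["mirnas"]),
            coefficients=np.array(d["coefficients"]),
            intercept=float(d["intercept"]),
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
        )


@dataclass
class PanelSearchResult:
    strategy: str
    k: int
    rounds: pd.DataFrame  # round, fold, selected, test_auc
    median_auc: float
    selection_frequency: pd.Series
    optimal_panel: PanelModel
    resubstitution_auc: float


def forward_selection(
    candidates: Sequence[Hashable],
    k: int,
    objective: Callable[[tuple], float],
) -> tuple[tuple, float]:
    """Plain greedy forward selection (no floating); baseline for SFFS."""
    candidates = list(candidates)
    if not 1 <= k <= len(candidates):
        raise ValueError(f"k must lie in [1, {len(candidates)}]")
    cur: tuple = ()
    score = -np.inf
    for _ in range(k):
        remaining = [c for c in candidates if c not in cur]
        scores = [objective(cur + (c,)) for c in remaining]
        i = int(np.argmax(scores))
        cur = cur + (remaining[i],)
        score = float(scores[i])
    return cur, score


def sffs(
    candidates: Sequence[Hashable],
    k: int,
    objective: Callable[[tuple], float],
    overshoot: int = 1,
) -> tuple[tuple, float]:
    """Sequential forward floating selection of a subset of exactly size k.

    Repeatedly adds the candidate that maximizes the objective, then
    conditionally removes features while removal improves on the best known
    score at the smaller size. The search runs up to size k + overshoot so
    floating can repair subsets at the target size itself, and it is seeded
    with the plain forward-selection path, so its result never scores below
    plain forward selection. Ties break by candidate-list order.

    Returns (best subset of size k, its objective value).
    """
    candidates = list(candidates)
    if not 1 <= k <= len(candidates):
        raise ValueError(f"k must lie in [1, {len(candidates)}]")
    cache: dict[frozenset, float] = {}

    def obj(subset: tuple) -> float:
        key = frozenset(subset)
        if key not in cache:
            cache[key] = float(objective(tuple(subset)))
        return cache[key]

    best: dict[int, tuple[float, tuple]] = {}

    def record(subset: tuple, score: float) -> None:
        size = len(subset)
        if size not in best or score > best[size][0]:
            best[size] = (score, subset)

    # seed with the greedy path (shares the cache, so this costs nothing
    # extra unless floating later diverges from it)
    cur: tuple = ()
    for _ in range(k):
        remaining = [c for c in candidates if c not in cur]
        scores = [obj(cur + (c,)) for c in remaining]
        i = int(np.argmax(scores))
        cur = cur + (remaining[i],)
        record(cur, scores[i])

    limit = min(k + max(overshoot, 0), len(candidates))
    cur = ()
    max_steps = 40 * limit * len(candidates) + 100
    for _ in range(max_steps):
        remaining = [c for c in candidates if c not in cur]
        scores = [obj(cur + (c,)) for c in remaining]
        i = int(np.argmax(scores))
        cur = cur + (remaining[i],)
        record(cur, scores[i])
        # floating backward: remove while strictly improving the best known
        while len(cur) > 2:
            drop_scores = [obj(tuple(f for f in cur if f != c)) for c in cur]
            j = int(np.argmax(drop_scores))
            size = len(cur) - 1
            if drop_scores[j] <= best[size][0]:
                break
            cur = tuple(f for f in cur if f != cur[j])
            record(cur, drop_scores[j])
        if len(cur) >= limit:
            score_k, subset_k = best[k]
            return subset_k, score_k
    raise RuntimeError("SFFS failed to terminate")  # pragma: no cover


def focused_candidates(de: pd.DataFrame) -> list[str]:
    """Significant miRNAs (BH q < alpha), ordered by ascending p."""
    sig = de.loc[de["significant"]].sort_values("p", kind="stable")
    if sig.empty:
        raise ValueError(
            "no significantly differential miRNAs; the focused strategy is "
            "not applicable — use the unbiased strategy instead"
        )
    return sig["mirna_id"].tolist()


def unbiased_candidates(retained: Sequence[str]) -> list[str]:
    """All miRNAs passing the expression filter."""
    return list(retained)


def _stratified_half_split(positive: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random half/half split preserving the class ratio to +/-1 sample."""
    a_parts, b_parts = [], []
    for cls in (True, False):
        idx = np.flatnonzero(positive == cls)
        idx = rng.permutation(idx)
        half = len(idx) // 2
        a_parts.append(idx[:half])
        b_parts.append(idx[half:])
    return np.sort(np.concatenate(a_parts)), np.sort(np.concatenate(b_parts))


def _fit_auc_objective(Ztr: np.ndarray, ytr: np.ndarray, ridge: float) -> Callable[[tuple], float]:
    def objective(subset: tuple) -> float:
        cols = list(subset)
        b0, beta = fit_logistic(Ztr[:, cols], ytr, ridge=ridge)
        return rank_auc(predict_logit(b0, beta, Ztr[:, cols]), ytr)

    return objective


def cv_panel_search(
    normalized: pd.DataFrame,
    labels: pd.Series,
    candidates: Sequence[str],
    k: int,
    rounds: int = DEFAULT_ROUNDS,
    seed: int = 0,
    strategy: str = "unbiased",
    ridge: float = DEFAULT_RIDGE,
) -> PanelSearchResult:
    """Repeated stratified two-fold CV panel search at one panel size.

    Per round: random half/half stratified split; each half serves once as
    training fold (SFFS + logistic fit with fold-frozen standardization)
    and once as test fold (AUC of the frozen model). The optimal panel is
    the top-k miRNAs by selection frequency, refit on the full input.
    """
    candidates = list(candidates)
    if not 1 <= k <= len(candidates):
        raise ValueError(f"k must lie in [1, {len(candidates)}]")
    X = normalized[candidates].to_numpy(dtype=float)
    y = _as_positive(labels).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")

    records = []
    counts = np.zeros(len(candidates))
    for r, child in enumerate(np.random.SeedSequence(seed).spawn(rounds)):
        rng = np.random.default_rng(child)
        half_a, half_b = _stratified_half_split(y.astype(bool), rng)
        for fold, (tr, te) in enumerate(((half_a, half_b), (half_b, half_a))):
            Xtr, ytr = X[tr], y[tr]
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Ztr = (Xtr - mu) / sd
            Zte = (X[te] - mu) / sd
            objective = _fit_auc_objective(Ztr, ytr, ridge)
            subset, _ = sffs(range(len(candidates)), k, objective)
            cols = list(subset)
            b0, beta = fit_logistic(Ztr[:, cols], ytr, ridge=ridge)
            test_auc = rank_auc(predict_logit(b0, beta, Zte[:, cols]), y[te])
            counts[cols] += 1
            records.append(
                {
                    "round": r,
                    "fold": fold,
                    "selected": ";".join(candidates[c] for c in subset),
                    "test_auc": test_auc,
                }
            )
    rounds_df = pd.DataFrame(records)
    freq = pd.Series(counts / (2 * rounds), index=candidates, name="selection_frequency")
    order = np.lexsort((np.arange(len(candidates)), -freq.to_numpy()))
    top_idx = sorted(order[:k])  # candidate-list order within the panel
    top = [candidates[i] for i in top_idx]
    optimal = fit_panel(normalized, labels, top, ridge=ridge)
    resub = rank_auc(
        predict_logit(optimal.intercept, optimal.coefficients,
                      (normalized[top].to_numpy(dtype=float) - optimal.means) / optimal.sds),
        y,
    )
    return PanelSearchResult(
        strategy=strategy,
        k=k,
        rounds=rounds_df,
        median_auc=float(rounds_df["test_auc"].median()),
        selection_frequency=freq,
        optimal_panel=optimal,
        resubstitution_auc=float(resub),
    )


def fit_panel(
    normalized: pd.DataFrame,
    labels: pd.Series,
    mirnas: Sequence[str],
    ridge: float = DEFAULT_RIDGE,
) -> PanelModel:
    """Fit a frozen logistic panel on the given miRNAs."""
    mirnas = list(mirnas)
    X = normalized[mirnas].to_numpy(dtype=float)
    y = _as_positive(labels).astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    b0, beta = fit_logistic((X - mu) / sd, y, ridge=ridge)
    return PanelModel(mirnas=mirnas, coefficients=beta, intercept=b0, means=mu, sds=sd)
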