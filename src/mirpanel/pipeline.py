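"""End-to-end study replica.

simulate -> quantify -> hemolysis QC -> expression filter -> normalize ->
differential expression -> focused + unbiased panel sweeps (k = 2..8) ->
optimal-panel choice by Validation AUC -> frozen evaluation with and
without normal controls -> cutoffs and clinicopathological trends.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import differential_expression, global_geomean_normalize
from .evaluate import evaluate_frozen, trend_by_group
from .panels import (
    DEFAULT_ROUNDS,
    PANEL_SIZES,
    PanelSearchResult,
    cv_panel_search,
    focused_candidates,
    unbiased_candidates,
)
from .qc import expression_filter, flag_hemolysis
from .quantify import quantify_cohort
from .synthetic import CohortConfig, annotations_to_frame, generate_cohort, generate_standard_curve_plate


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    rounds: int
    panel_sizes: list[int]
    version: str = __version__
    stage_seconds: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


@dataclass
class StudyResult:
    manifest: RunManifest
    annotations: pd.DataFrame
    qc_report: pd.DataFrame
    retained: list[str]
    de: pd.DataFrame
    searches: dict  # (strategy, k) -> PanelSearchResult
    panel_summary: pd.DataFrame
    optimal_key: tuple
    optimal_search: PanelSearchResult
    evaluations: dict  # name -> EvaluationResult
    trends: dict  # grouping -> TrendReport


def _timed(stage_seconds: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            stage_seconds[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Timer()


def select_optimal(panel_summary: pd.DataFrame, tol: float = 1e-6) -> tuple[str, int]:
    """Pick (strategy, k) maximizing Validation AUC; AUC ties within `tol`
    prefer the smaller panel."""
    ordered = panel_summary.sort_values(["k", "strategy"], kind="stable")
    best_auc = ordered["validation_auc"].max()
    best = ordered.loc[ordered["validation_auc"] >= best_auc - tol].iloc[0]
    return str(best["strategy"]), int(best["k"])


def run_study(
    config: CohortConfig,
    rounds: int = DEFAULT_ROUNDS,
    panel_sizes: tuple = PANEL_SIZES,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    trend_permutations: int = 10_000,
) -> StudyResult:
    """Execute the whole discovery-to-validation workflow on one synthetic
    cohort and return all intermediate and final artifacts."""
    seed = config.seed if seed is None else seed
    manifest = RunManifest(
        config=config.to_flat_dict(), seed=seed, rounds=rounds, panel_sizes=list(panel_sizes)
    )
    sec = manifest.stage_seconds

    with _timed(sec, "simulate"):
        ct_table, annotations, truth = generate_cohort(config)
        standards, _ = generate_standard_curve_plate(config)
        ann = annotations_to_frame(annotations)

    with _timed(sec, "quantify"):
        expression, curves, recovery, collapsed = quantify_cohort(ct_table, standards)

    with _timed(sec, "qc"):
        qc_report = flag_hemolysis(collapsed)
        excluded = set(qc_report.loc[qc_report["hemolysed_call"], "sample_id"])
        kept = [s for s in expression.samples if s not in excluded]
        expression = expression.subset_samples(kept)
        ann_kept = ann.loc[kept]

    with _timed(sec, "expression_filter"):
        retained = expression_filter(expression)
        if not retained:
            raise StageError("stage 'expression_filter' failed: no miRNA passes the filter")

    with _timed(sec, "normalize"):
        normalized = global_geomean_normalize(expression.subset_mirnas(retained))
        disc = ann_kept.index[ann_kept["cohort"] == "discovery"].tolist()
        valid = ann_kept.index[ann_kept["cohort"] == "validation"].tolist()
        labels = ann_kept["diagnosis"]

    with _timed(sec, "differential_expression"):
        de = differential_expression(normalized.loc[disc], labels.loc[disc])

    searches: dict = {}
    panel_rows = []
    strategy_candidates = {}
    try:
        strategy_candidates["focused"] = focused_candidates(de)
    except ValueError as err:
        manifest.config["focused_strategy_note"] = str(err)
    strategy_candidates["unbiased"] = unbiased_candidates(retained)

    with _timed(sec, "panel_search"):
        search_seed = np.random.SeedSequence(seed).spawn(1)[0].entropy
        for strategy, cands in strategy_candidates.items():
            for k in panel_sizes:
                if k > len(cands):
                    continue
                res = cv_panel_search(
                    normalized.loc[disc],
                    labels.loc[disc],
                    cands,
                    k=k,
                    rounds=rounds,
                    seed=int(search_seed) % (2**32),
                    strategy=strategy,
                )
                val_eval = evaluate_frozen(res.optimal_panel, normalized.loc[valid], labels.loc[valid])
                searches[(strategy, k)] = res
                panel_rows.append(
                    {
                        "strategy": strategy,
                        "k": k,
                        "median_cv_auc": res.median_auc,
                        "resubstitution_auc": res.resubstitution_auc,
                        "validation_auc": val_eval.auc,
                        "panel": ";".join(res.optimal_panel.mirnas),
                    }
                )
    panel_summary = pd.DataFrame(panel_rows)
    if panel_summary.empty:
        raise StageError("stage 'panel_search' failed: no panel could be built")

    with _timed(sec, "select_optimal"):
        optimal_key = select_optimal(panel_summary)
        optimal_search = searches[optimal_key]
        model = optimal_search.optimal_panel

    with _timed(sec, "evaluate"):
        normals = ann_kept.index[ann_kept["cohort"] == "normal"].tolist()
        evaluations = {
            "discovery": evaluate_frozen(model, normalized.loc[disc], labels.loc[disc]),
            "validation": evaluate_frozen(model, normalized.loc[valid], labels.loc[valid]),
        }
        if normals:
            vn = valid + normals
            evaluations["validation+normals"] = evaluate_frozen(
                model, normalized.loc[vn], labels.loc[vn], include_normals=True
            )
            pooled = disc + valid + normals
            evaluations["pooled+normals"] = evaluate_frozen(
                model, normalized.loc[pooled], labels.loc[pooled], include_normals=True
            )

    with _timed(sec, "trends"):
        pooled_scores = model.score(normalized)
        mal = ann_kept.loc[labels == "malignant"]
        trends = {}
        for grouping, column in (("size_class", "size_class"), ("stage", "stage"), ("node_class", "node_class")):
            groups = mal[column]
            if column == "size_class":
                order = {"<=10mm": 0, "11-20mm": 1, ">20mm": 2}
                groups = groups.map(order)
            if groups.notna().sum() < 2 or groups.dropna().nunique() < 2:
                continue
            trends[grouping] = trend_by_group(
                pooled_scores.loc[mal.index].to_numpy(),
                groups,
                grouping=grouping,
                n_permutations=trend_permutations,
                seed=seed,
            )

    result = StudyResult(
        manifest=manifest,
        annotations=ann,
        qc_report=qc_report,
        retained=retained,
        de=de,
        searches=searches,
        panel_summary=panel_summary,
        optimal_key=optimal_key,
        optimal_search=optimal_search,
        evaluations=evaluations,
        trends=trends,
    )
    if out_dir is not None:
        write_bundle(result, Path(out_dir))
    return result


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(result: StudyResult, out_dir: Path) -> None:
    """Write the result bundle (all plain text) and record digests."""
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def save(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        files[name] = path

    save("annotations.csv", lambda p: result.annotations.to_csv(p, index=False))
    save("qc_report.csv", lambda p: result.qc_report.to_csv(p, index=False))
    save("retained_mirnas.txt", lambda p: p.write_text("\n".join(result.retained) + "\n"))
    save("differential_expression.csv", lambda p: result.de.to_csv(p, index=False))
    save("panel_summary.csv", lambda p: result.panel_summary.to_csv(p, index=False))
    save("optimal_panel.json", lambda p: p.write_text(result.optimal_search.optimal_panel.to_json()))
    for (strategy, k), res in result.searches.items():
        save(f"rounds_{strategy}_k{k}.csv", lambda p, res=res: res.rounds.to_csv(p, index=False))

    eval_rows = []
    for name, ev in result.evaluations.items():
        row = {"cohort": name, "controls": ev.control_definition, "auc": ev.auc}
        for mode, rep in ev.cutoff_reports.items():
            for key, val in rep.as_row().items():
                if key != "mode":
                    row[f"{mode}_{key}"] = val
        eval_rows.append(row)
    save("evaluation.csv", lambda p: pd.DataFrame(eval_rows).to_csv(p, index=False))

    trend_rows = []
    for grouping, tr in result.trends.items():
        for _, srow in tr.summaries.iterrows():
            trend_rows.append(
                {
                    "grouping": grouping,
                    "group": srow["group"],
                    "n": srow["n"],
                    "median": srow["median"],
                    "q1": srow["q1"],
                    "q3": srow["q3"],
                    "statistic": tr.statistic,
                    "p_value": tr.p_value,
                    "n_excluded": tr.n_excluded,
                }
            )
    save("trends.csv", lambda p: pd.DataFrame(trend_rows).to_csv(p, index=False))

    result.manifest.output_digests = {name: _digest(path) for name, path in sorted(files.items())}
    (out_dir / "manifest.json").write_text(result.manifest.to_json())
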