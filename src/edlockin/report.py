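"""Rendering of evaluation outputs: subgroup tables, curves and heatmaps.

Everything written here is deterministic for identical inputs: tables are
CSV with fixed column order and float formatting, figures are drawn with a
fixed style.  Tables carry both raw fractions and the half-up 2-decimal
values that printed tables use.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .lockin import LockInResults
from .metrics import DIMENSION_LEVELS

__all__ = ["render_report"]

_FLOAT_FMT = "%.6g"


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT, encoding="utf-8")


def _metric_evolution_figure(results: LockInResults, path: Path) -> None:
    mot = results.metrics_over_time
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col, style in (("precision", "-o"), ("recall", "-s"), ("accuracy", "-^")):
        ax.plot(mot["t_minutes"], mot[col], style, label=col, markersize=3)
    ax.set_xlabel("minutes since arrival")
    ax.set_ylabel("metric under lock-in")
    ax.set_ylim(0, 1)
    ax.legend(loc="lower right")
    ax.set_title("Prediction quality over the stay (irreversible decisions)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _paired_bars_figure(results: LockInResults, dimension: str, path: Path) -> None:
    table = results.stratification_table(dimension)
    joined = results.decisions_joined()
    tp = joined[joined["outcome_class"] == "TP"]
    med_clin = tp.groupby(dimension)["clinician_decision_minutes"].median()
    med_ai = tp.groupby(dimension)["ai_decision_minutes"].median()
    levels = [lv for lv in DIMENSION_LEVELS[dimension] if lv in set(table[dimension])]
    x = range(len(levels))
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.bar([i - 0.2 for i in x], [med_clin.get(lv, float("nan")) for lv in levels],
           width=0.4, label="clinician")
    ax.bar([i + 0.2 for i in x], [med_ai.get(lv, float("nan")) for lv in levels],
           width=0.4, label="model")
    ax.set_xticks(list(x))
    ax.set_xticklabels(levels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("median minutes to admission decision (TP visits)")
    ax.set_title(f"Decision time by {dimension}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _heatmap_figure(matrix: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=7)
    ax.set_xlabel(matrix.columns.name)
    ax.set_ylabel(matrix.index.name)
    fig.colorbar(im, ax=ax, label="median minutes saved (TP)")
    ax.set_title(
        f"Coherence: {matrix.index.name} × {matrix.columns.name}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(
    results: LockInResults,
    out_dir,
    figure_format: str = "png",
    figures: bool = True,
) -> dict[str, Path]:
    """Write the full evaluation report to ``out_dir``.

    Emits per-dimension subgroup tables, the metric-evolution series, all
    six pairwise coherence crosstabs, the per-visit decision table, and
    (optionally) figures.  Returns a name -> path manifest of artifacts.
    """
    if results is None or results.decisions is None:
        raise ValueError("render_report: missing lock-in results")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    figdir = out / "figures"
    artifacts: dict[str, Path] = {}

    decs = results.decisions.copy()
    p = out / "decisions.csv"
    _write_csv(decs, p)
    artifacts["decisions"] = p

    p = out / "metrics_over_time.csv"
    _write_csv(results.metrics_over_time, p)
    artifacts["metrics_over_time"] = p

    dim_to_name = {
        "age_group": "table_age.csv",
        "specialty": "table_specialty.csv",
        "triage": "table_triage.csv",
        "part_of_day": "table_partofday.csv",
    }
    for dim, fname in dim_to_name.items():
        table = results.stratification_table(dim)
        p = out / fname
        _write_csv(table, p)
        artifacts[fname[:-4]] = p

    for a, b in itertools.combinations(DIMENSION_LEVELS, 2):
        matrix = results.coherence(a, b)
        p = out / f"coherence_{a}_{b}.csv"
        _write_csv(matrix, p, index=True)
        artifacts[f"coherence_{a}_{b}"] = p

    ts = results.time_saved_summary()
    ai = results.ai_decision_time_summary()
    overall = pd.DataFrame([{
        "n": results.confusion.n,
        "tp": results.confusion.tp, "tn": results.confusion.tn,
        "fp": results.confusion.fp, "fn": results.confusion.fn,
        "n_tp": 0 if ts is None else ts.n,
        "time_saved_median": None if ts is None else ts.median,
        "time_saved_q1": None if ts is None else ts.q1,
        "time_saved_q3": None if ts is None else ts.q3,
        "ai_decision_median": None if ai is None else ai.median,
        "ai_decision_q1": None if ai is None else ai.q1,
        "ai_decision_q3": None if ai is None else ai.q3,
    }])
    p = out / "overall.csv"
    _write_csv(overall, p)
    artifacts["overall"] = p

    if figures:
        figdir.mkdir(exist_ok=True)
        p = figdir / f"metric_evolution.{figure_format}"
        _metric_evolution_figure(results, p)
        artifacts["fig_metric_evolution"] = p
        for dim in DIMENSION_LEVELS:
            p = figdir / f"decision_time_{dim}.{figure_format}"
            _paired_bars_figure(results, dim, p)
            artifacts[f"fig_decision_time_{dim}"] = p
        for a, b in itertools.combinations(DIMENSION_LEVELS, 2):
            p = figdir / f"coherence_{a}_{b}.{figure_format}"
            _heatmap_figure(results.coherence(a, b), p)
            artifacts[f"fig_coherence_{a}_{b}"] = p
    return artifacts
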