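"""Figure rendering for pipeline reports.

Each renderer takes the numeric artifacts (DataFrames/Series) and writes a
PNG and an SVG; none of them mutates its inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import seaborn as sns

logger = logging.getLogger(__name__)

__all__ = ["render_reports"]


def _save(fig, out_dir: Path, stem: str) -> list[Path]:
    paths = []
    for ext in ("png", "svg"):
        p = out_dir / f"{stem}.{ext}"
        fig.savefig(p, bbox_inches="tight", dpi=120)
        paths.append(p)
    plt.close(fig)
    return paths


def _pathway_heatmap(counts, out_dir):
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * counts.shape[1]), max(3, 0.25 * counts.shape[0])))
    sns.heatmap(counts, annot=False, cmap="viridis", ax=ax, cbar_kws={"label": "copy number"})
    ax.set_title("Pathway gene-family copy numbers")
    return _save(fig, out_dir, "pathway_heatmap")


def _presence_absence(binary, ratio, out_dir):
    fig, (ax_top, ax) = plt.subplots(
        2, 1, figsize=(max(4, 0.3 * binary.shape[1]), max(4, 0.25 * binary.shape[0]) + 1.5),
        gridspec_kw={"height_ratios": [1, 4]}, sharex=False,
    )
    if ratio is not None:
        ax_top.bar(range(len(ratio)), ratio.to_numpy(), color="tab:blue")
        ax_top.set_xticks([])
        ax_top.set_ylabel("pathway / total")
    else:
        ax_top.axis("off")
    sns.heatmap(binary, cmap=["#3b0f70", "#fde725"], cbar=False, ax=ax)
    ax.set_title("Pathway family presence (yellow) / absence (purple)")
    return _save(fig, out_dir, "presence_absence")


def _rarity_bars(totals, out_dir):
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(totals)), 3))
    ax.bar(totals.index, totals.to_numpy(), color="tab:orange")
    ax.set_ylabel("summed inverse count")
    ax.set_title("Per-sequence amino-acid rarity")
    plt.setp(ax.get_xticklabels(), rotation=90)
    return _save(fig, out_dir, "rarity_totals")


def _importance_distribution(importance_result, top, out_dir):
    import pandas as pd

    mat = pd.DataFrame(
        importance_result.importance_matrix, columns=importance_result.family_ids
    )
    sub = mat.loc[:, top]
    fig, ax = plt.subplots(figsize=(max(5, 0.35 * len(top)), 4))
    sns.boxplot(data=sub, ax=ax, fliersize=1)
    ax.set_ylabel("feature importance")
    ax.set_title("Importance distribution over iterations (top families)")
    plt.setp(ax.get_xticklabels(), rotation=90)
    return _save(fig, out_dir, "importance_distribution")


def _class_balance(balance, out_dir):
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.bar(["0", "1"], [balance[0], balance[1]], color=["tab:gray", "tab:green"])
    ax.set_ylabel("species")
    ax.set_title("Label class balance")
    return _save(fig, out_dir, "class_balance")


def _null_comparison(frame, out_dir):
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, metric in zip(axes, ("accuracy", "auc")):
        sns.kdeplot(data=frame, x=metric, hue="arm", fill=True, ax=ax, warn_singular=False)
        ax.set_title(f"true vs permuted labels: {metric}")
    return _save(fig, out_dir, "null_comparison")


def _selected_heatmap(normalized_selected, out_dir):
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * normalized_selected.shape[1]), max(3, 0.25 * normalized_selected.shape[0]))
    )
    sns.heatmap(normalized_selected, cmap="mako", ax=ax, cbar_kws={"label": "normalized count"})
    ax.set_title("Selected families, normalized copy numbers")
    return _save(fig, out_dir, "selected_heatmap")


def render_reports(artifacts: dict, out_dir) -> list[Path]:
    """Render every figure whose inputs are present; skip (and log) the rest.

    Recognized artifact keys: ``pathway_counts``, ``presence`` (+ optional
    ``ratio``), ``rarity_totals``, ``importance`` (+ ``selected``),
    ``class_balance``, ``null_frame``, ``selected_normalized``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    renderers = [
        ("pathway_counts", lambda: _pathway_heatmap(artifacts["pathway_counts"], out)),
        ("presence", lambda: _presence_absence(artifacts["presence"], artifacts.get("ratio"), out)),
        ("rarity_totals", lambda: _rarity_bars(artifacts["rarity_totals"], out)),
        ("importance", lambda: _importance_distribution(
            artifacts["importance"],
            artifacts.get("selected")
            or list(artifacts["importance"].mean_importance.nlargest(20).index),
            out)),
        ("class_balance", lambda: _class_balance(artifacts["class_balance"], out)),
        ("null_frame", lambda: _null_comparison(artifacts["null_frame"], out)),
        ("selected_normalized", lambda: _selected_heatmap(artifacts["selected_normalized"], out)),
    ]
    for key, render in renderers:
        if key not in artifacts or artifacts[key] is None:
            logger.warning("skipping figure %s: artifact missing", key)
            continue
        written.extend(render())
    return written
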