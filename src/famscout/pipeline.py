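"""End-to-end orchestration: matrix -> labels -> mining -> reports.

``run_pipeline`` wires the stages together, writes every numeric artifact as
TSV/JSON, records a manifest sufficient to reproduce the run (config, seed,
input checksums, package version), and optionally renders the report
figures.  Each stage failure aborts with a stage-tagged error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .labeling import assign_labels, class_balance, write_labels
from .matrix import (
    FamilyCountMatrix,
    normalize_counts,
    pathway_ratio,
    presence_absence,
    read_count_matrix,
    read_pathway_map,
    read_annotations,
    build_matrix_from_annotations,
    subset_families,
    cluster_order,
)
from .mining import (
    MiningConfig,
    iterative_importance,
    null_comparison,
    ridge_rank,
    select_top_k,
)
from .rarity import inverse_counts, read_alignment, write_profile, rank_divergent

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, knobs, and output location for one pipeline run."""

    out_dir: str
    matrix_path: str | None = None
    totals_path: str | None = None
    annotations: dict[str, str] | None = None  # species -> annotation TSV
    scope: str = "33090"
    pathway_map_path: str | None = None
    alignment_path: str | None = None
    marker_families: list[str] = field(default_factory=list)
    min_present: int = 2
    normalize: str = "per_family_max"
    mining: MiningConfig = field(default_factory=MiningConfig)
    seed: int = 0
    make_figures: bool = True


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage tagging
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


def _write_tsv(df, path, float_format="%.10g"):
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


@_stage("matrix")
def _load_matrix(cfg: RunConfig) -> FamilyCountMatrix:
    if cfg.matrix_path:
        return read_count_matrix(cfg.matrix_path, cfg.totals_path)
    if cfg.annotations:
        records = {
            sp: read_annotations(path) for sp, path in cfg.annotations.items()
        }
        return build_matrix_from_annotations(records, cfg.scope)
    raise ValueError("RunConfig needs matrix_path or annotations")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full mining pipeline and write the report bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": [],
        "inputs": {},
        "config": {
            "normalize": cfg.normalize,
            "marker_families": cfg.marker_families,
            "min_present": cfg.min_present,
            "scope": cfg.scope,
            "mining": asdict(cfg.mining),
        },
    }
    for key in ("matrix_path", "totals_path", "pathway_map_path", "alignment_path"):
        p = getattr(cfg, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    matrix = _load_matrix(cfg)
    manifest["stages"].append("matrix")
    manifest["n_species"] = matrix.n_species
    manifest["n_families"] = matrix.n_families

    artifacts: dict = {}

    if cfg.pathway_map_path:
        pmap = read_pathway_map(cfg.pathway_map_path)
        sub = _stage("pathway")(subset_families)(matrix, pmap)
        pa = presence_absence(sub)
        artifacts["pathway_counts"] = sub.counts
        artifacts["presence"] = pa
        sub.counts.rename_axis("species").reset_index().pipe(
            _write_tsv, out / "pathway_counts.tsv"
        )
        pa.rename_axis("species").reset_index().pipe(
            _write_tsv, out / "pathway_presence.tsv"
        )
        if matrix.species_totals is not None:
            ratio = _stage("pathway")(pathway_ratio)(matrix, pmap)
            artifacts["ratio"] = ratio
            ratio.rename_axis("species").reset_index().pipe(
                _write_tsv, out / "pathway_ratio.tsv"
            )
        manifest["stages"].append("pathway")

    if not cfg.marker_families:
        raise PipelineError("labeling", ValueError("no marker families configured"))
    lv = _stage("labeling")(assign_labels)(matrix, cfg.marker_families, cfg.min_present)
    write_labels(lv, out / "labels.tsv")
    balance = class_balance(lv)
    artifacts["class_balance"] = balance
    manifest["stages"].append("labeling")
    manifest["class_balance"] = {str(k): v for k, v in balance.items()}

    # learners see the normalized matrix with marker columns removed: the
    # labels are derived from the markers, which would otherwise dominate
    feature_cols = [f for f in matrix.family_ids if f not in set(cfg.marker_families)]
    X = _stage("normalize")(normalize_counts)(matrix, cfg.normalize)[feature_cols]

    cfg.mining.base_seed = cfg.seed
    ridge = _stage("mining")(ridge_rank)(X, lv, cfg.mining.ridge_alpha)
    _write_tsv(ridge.ranked(), out / "ridge_ranking.tsv")

    importance = _stage("mining")(iterative_importance)(X, lv, cfg.mining)
    _write_tsv(importance.summary(), out / "importance.tsv")
    selected = select_top_k(importance, min(cfg.mining.top_k, len(feature_cols)))
    (out / "selected_families.txt").write_text("\n".join(selected) + "\n")
    artifacts["importance"] = importance
    artifacts["selected"] = selected
    manifest["stages"].append("mining")
    manifest["selected_families"] = selected

    null = _stage("null_comparison")(null_comparison)(X, lv, selected, cfg.mining)
    _write_tsv(null.as_frame(), out / "null_comparison.tsv")
    summary = null.summary()
    with open(out / "null_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["null_frame"] = null.as_frame()
    manifest["stages"].append("null_comparison")
    manifest["null_summary"] = summary

    sel_norm = X[selected]
    row_order = cluster_order(sel_norm, "rows") if len(sel_norm) > 1 else [0]
    sel_norm = sel_norm.iloc[row_order]
    artifacts["selected_normalized"] = sel_norm
    sel_norm.rename_axis("species").reset_index().pipe(
        _write_tsv, out / "selected_normalized.tsv"
    )

    if cfg.alignment_path:
        aln = _stage("rarity")(read_alignment)(cfg.alignment_path)
        profile = inverse_counts(aln)
        write_profile(profile, out / "rarity_positions.tsv", out / "rarity_totals.tsv")
        artifacts["rarity_totals"] = profile.totals
        manifest["stages"].append("rarity")
        manifest["most_divergent"] = rank_divergent(profile).iloc[0]["seq_id"]

    if cfg.make_figures:
        from .plots import render_reports

        figures = _stage("figures")(render_reports)(artifacts, out / "figures")
        manifest["figures"] = [str(p.name) for p in figures]
        manifest["stages"].append("figures")

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
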