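"""Marker-based binary labels for species.

The semi-supervised ingredient of the pipeline: a binary class label is
derived from the copy-number matrix itself, by asking whether a species
carries at least ``min_present`` *distinct* marker gene-family clusters
(e.g. phenylalanine ammonia-lyase clusters).  Species meeting the criterion
get label 1, the rest 0; the labels then supervise feature mining over the
remaining families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import FamilyCountMatrix

__all__ = ["LabelVector", "assign_labels", "class_balance", "write_labels", "read_labels"]


@dataclass
class LabelVector:
    """Per-species 0/1 labels with the marker rule that produced them."""

    species_ids: list[str]
    labels: np.ndarray
    marker_families: list[str] = field(default_factory=list)
    min_present: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.species_ids),):
            raise ValueError("labels must align with species_ids")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0 or 1")
        if self.min_present < 1:
            raise ValueError("min_present must be >= 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.species_ids, name="label")


def assign_labels(
    m: FamilyCountMatrix,
    marker_families: list[str],
    min_present: int = 2,
    mode: str = "distinct",
) -> LabelVector:
    """Label species by marker-cluster presence.

    In the default ``distinct`` mode, ``label[s] = 1`` iff at least
    ``min_present`` distinct marker families have count >= 1 in species
    ``s`` — extra copies of a single cluster do not substitute for a second
    cluster.  ``mode="count_copies"`` instead thresholds the summed copy
    number over the marker families (the alternative reading of "multiple
    marker families"); it is provided for comparison, not as the default.
    Marker families absent from the matrix are treated as all-zero columns.
    """
    if not marker_families:
        raise ValueError("marker_families must be non-empty")
    markers = m.counts.reindex(columns=list(marker_families), fill_value=0)
    if mode == "distinct":
        score = (markers >= 1).sum(axis=1)
    elif mode == "count_copies":
        score = markers.sum(axis=1)
    else:
        raise ValueError(f"unknown labeling mode {mode!r}")
    labels = (score >= min_present).astype(np.int64).to_numpy()
    return LabelVector(m.species_ids, labels, list(marker_families), min_present)


def class_balance(lv: LabelVector) -> dict[int, int]:
    """Tally of 0 and 1 labels; warns when one class is empty."""
    n1 = int(lv.labels.sum())
    balance = {0: len(lv.labels) - n1, 1: n1}
    if len(lv.labels) and (balance[0] == 0 or balance[1] == 0):
        import logging

        logging.getLogger(__name__).warning(
            "single-class label vector (%s); downstream classification is degenerate",
            balance,
        )
    return balance


def write_labels(lv: LabelVector, path) -> None:
    """Emit species/label pairs as two-column TSV."""
    lv.as_series().rename_axis("species").reset_index().to_csv(path, sep="\t", index=False)


def read_labels(path) -> LabelVector:
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    return LabelVector(list(df["species"]), df["label"].to_numpy())
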