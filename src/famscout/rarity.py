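"""Inverse-count amino-acid rarity over protein alignments.

For each sequence ``s`` and alignment column ``p`` the raw statistic is the
number of sequences (including ``s``) sharing ``s``'s residue at ``p``; the
rarity score is ``N - count``, where ``N`` is the number of sequences in the
alignment.  A residue shared by everyone scores 0; a private residue scores
``N - 1``.  Gap cells score 0 and gapped sequences never participate in a
column's residue tally.  Per-sequence totals rank sequences by how many rare
residues they carry — the signature of a divergent family member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinAlignment",
    "RarityProfile",
    "read_alignment",
    "inverse_counts",
    "rank_divergent",
    "write_profile",
]

GAP = "-"


@dataclass
class ProteinAlignment:
    """Aligned protein sequences: equal-length uppercase rows, '-' gaps."""

    seq_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one sequence")
        if len(self.seq_ids) != len(self.rows):
            raise ValueError("seq_ids and rows must align")
        if len(set(self.seq_ids)) != len(self.seq_ids):
            dup = next(s for i, s in enumerate(self.seq_ids) if s in self.seq_ids[:i])
            raise ValueError(f"duplicate sequence ID: {dup!r}")
        L = len(self.rows[0])
        ragged = [sid for sid, r in zip(self.seq_ids, self.rows) if len(r) != L]
        if ragged:
            raise ValueError(f"ragged alignment; offending IDs: {ragged}")
        self.rows = [r.upper() for r in self.rows]
        for sid, r in zip(self.seq_ids, self.rows):
            if "." in r:
                raise ValueError(
                    f"sequence {sid!r} uses '.'; only '-' gaps are supported"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])


@dataclass
class RarityProfile:
    """Per-cell inverse counts and per-sequence totals."""

    seq_ids: list[str]
    residues: np.ndarray  # N x L characters
    counts: np.ndarray    # N x L ints; 0 at gap cells
    inverse: np.ndarray   # N x L ints; 0 at gap cells
    n_sequences: int

    @property
    def totals(self) -> pd.Series:
        return pd.Series(
            self.inverse.sum(axis=1), index=self.seq_ids, name="rarity_total"
        )

    def per_position_frame(self) -> pd.DataFrame:
        """Long-form table (positions 1-based) for plotting/export."""
        n, L = self.inverse.shape
        return pd.DataFrame(
            {
                "seq_id": np.repeat(self.seq_ids, L),
                "position": np.tile(np.arange(1, L + 1), n),
                "residue": self.residues.ravel(),
                "count": self.counts.ravel(),
                "inverse": self.inverse.ravel(),
            }
        )


def read_alignment(path) -> ProteinAlignment:
    """Read an aligned FASTA; lowercase residues are uppercased."""
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq))
    if not ids:
        raise ValueError(f"{path}: no FASTA records found")
    return ProteinAlignment(ids, rows)


def inverse_counts(aln: ProteinAlignment, per_column_n: bool = False) -> RarityProfile:
    """Compute the rarity profile of an alignment.

    For each non-gap cell, ``count`` is the number of sequences carrying the
    same residue in that column (gapped sequences excluded from the tally)
    and ``inverse = N - count`` with ``N`` the alignment size.  With
    ``per_column_n=True``, ``N`` is instead the number of non-gap sequences
    in that column, so fully-gapped columns cannot inflate rarity.
    """
    arr = aln.to_array()
    N, L = arr.shape
    counts = np.zeros((N, L), dtype=np.int64)
    inverse = np.zeros((N, L), dtype=np.int64)
    for p in range(L):
        col = arr[:, p]
        nongap = col != GAP
        if not nongap.any():
            continue
        vals, inv_idx, cts = np.unique(col[nongap], return_inverse=True, return_counts=True)
        cell_counts = cts[inv_idx]
        counts[nongap, p] = cell_counts
        n_ref = int(nongap.sum()) if per_column_n else N
        inverse[nongap, p] = n_ref - cell_counts
    return RarityProfile(list(aln.seq_ids), arr, counts, inverse, N)


def rank_divergent(profile: RarityProfile) -> pd.DataFrame:
    """Sequences ranked by total rarity, descending; ties by sequence ID."""
    df = profile.totals.rename_axis("seq_id").reset_index()
    df = df.sort_values(
        ["rarity_total", "seq_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def write_profile(profile: RarityProfile, per_position_path, totals_path) -> None:
    profile.per_position_frame().to_csv(per_position_path, sep="\t", index=False)
    rank_divergent(profile).to_csv(totals_path, sep="\t", index=False)
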