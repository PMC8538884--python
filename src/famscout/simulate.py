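"""Synthetic benchmarks with planted ground truth.

Two generators make every pipeline stage testable without any download:

* :func:`simulate_matrix` builds a species x family copy-number matrix that
  mimics an ortholog-cluster count table — heavily zero-inflated,
  overdispersed counts (zero-inflated negative binomial), a small set of
  marker columns whose presence pattern drives an imbalanced binary label,
  and a planted set of signal families whose counts are shifted by an
  additive effect in label-1 species.

* :func:`simulate_alignment` builds a toy protein alignment: background
  sequences mutate off a random consensus at a low rate, one designated
  sequence mutates at an elevated rate toward non-consensus residues, so it
  accumulates rare residues by construction.

Both are deterministic given their seed, and both return their ground truth
alongside the data.  :func:`write_fixtures` materializes a small fixture
bundle (TSV/FASTA/JSON) in the exact dialects the readers accept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import LabelVector, write_labels
from .matrix import FamilyCountMatrix, write_count_matrix, write_species_totals
from .rarity import ProteinAlignment

__all__ = [
    "MatrixSimSpec",
    "AlignmentSimSpec",
    "simulate_matrix",
    "simulate_alignment",
    "write_fixtures",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MatrixSimSpec:
    """Study conditions for the synthetic count matrix.

    Defaults emulate a plant-clade ortholog-cluster table at desk scale:
    40 species, 500 noise families, 10 planted signal families with an
    additive shift of 3 copies in label-1 species, 3 marker clusters with a
    quarter of species carrying at least ``min_present`` of them (an
    imbalanced label), and zero-inflated negative-binomial background counts
    (zero-inflation 0.3, mean 2, dispersion 1 — sparse with occasional
    bursts, as real copy-number tables are).
    """

    n_species: int = 40
    n_noise_families: int = 500
    n_signal_families: int = 10
    n_marker_families: int = 3
    label1_fraction: float = 0.25
    min_present: int = 2
    effect_size: int = 3
    pi0: float = 0.3
    mu: float = 2.0
    dispersion: float = 1.0
    baseline_genome_size: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must be in [0, 1]")
        if self.mu <= 0 or self.dispersion <= 0:
            raise ValueError("mu and dispersion must be positive")
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        n1 = round(self.label1_fraction * self.n_species)
        if n1 < 2 or self.n_species - n1 < 2:
            raise ValueError(
                f"label1_fraction={self.label1_fraction} leaves a class with "
                "fewer than 2 species"
            )
        if self.n_signal_families > 0 and n1 == 0:
            raise ValueError("signal families require at least one label-1 species")
        if self.n_marker_families < self.min_present:
            raise ValueError("need at least min_present marker families")


@dataclass
class AlignmentSimSpec:
    """Study conditions for the toy alignment with one planted divergent row."""

    n_seqs: int = 6
    length: int = 100
    background_rate: float = 0.05
    divergent_index: int = 0
    divergent_rate: float = 0.5
    gap_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_rate", "divergent_rate", "gap_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.n_seqs < 1:
            raise ValueError("n_seqs must be >= 1")
        if not (0 <= self.divergent_index < self.n_seqs):
            raise ValueError("divergent_index out of range")


def _zinb(rng: np.random.Generator, shape, pi0: float, mu: float, k: float) -> np.ndarray:
    """Zero-inflated negative binomial draws (mean mu, dispersion k)."""
    p = k / (k + mu)
    counts = rng.negative_binomial(k, p, size=shape)
    zeros = rng.random(size=shape) < pi0
    counts[zeros] = 0
    return counts.astype(np.int64)


def simulate_matrix(
    spec: MatrixSimSpec,
) -> tuple[FamilyCountMatrix, LabelVector, list[str]]:
    """Draw a matrix with planted markers and signal families.

    Returns the matrix (marker + signal + noise columns, plus per-species
    total gene counts), the true label vector, and the list of signal family
    IDs.  Marker columns are constructed so that exactly the intended
    species carry at least ``min_present`` distinct markers; signal columns
    are a background draw plus ``effect_size`` in every label-1 species.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species
    species = [f"sp{i + 1:03d}" for i in range(n)]
    n1 = round(spec.label1_fraction * n)
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.choice(n, size=n1, replace=False)] = 1

    marker_ids = [f"MK{i + 1:03d}" for i in range(spec.n_marker_families)]
    signal_ids = [f"SIG{i + 1:03d}" for i in range(spec.n_signal_families)]
    noise_ids = [f"FAM{i + 1:04d}" for i in range(spec.n_noise_families)]

    markers = np.zeros((n, spec.n_marker_families), dtype=np.int64)
    for i in range(n):
        if labels[i] == 1:
            n_present = rng.integers(spec.min_present, spec.n_marker_families + 1)
        else:
            n_present = rng.integers(0, spec.min_present)
        present = rng.choice(spec.n_marker_families, size=n_present, replace=False)
        markers[i, present] = 1 + rng.poisson(0.7, size=n_present)

    noise = _zinb(rng, (n, spec.n_noise_families), spec.pi0, spec.mu, spec.dispersion)
    signal = _zinb(rng, (n, spec.n_signal_families), spec.pi0, spec.mu, spec.dispersion)
    signal[labels == 1] += spec.effect_size

    counts = pd.DataFrame(
        np.hstack([markers, signal, noise]),
        index=pd.Index(species, name="species"),
        columns=marker_ids + signal_ids + noise_ids,
        dtype=np.int64,
    )
    row_sums = counts.sum(axis=1).to_numpy()
    totals = pd.Series(
        row_sums
        + spec.baseline_genome_size
        + rng.integers(0, 5000, size=n),
        index=counts.index,
        name="total_genes",
    )
    matrix = FamilyCountMatrix(counts, totals)
    truth = LabelVector(species, labels, marker_ids, spec.min_present)
    return matrix, truth, signal_ids


def simulate_alignment(spec: AlignmentSimSpec) -> tuple[ProteinAlignment, str]:
    """Draw a toy alignment; returns it with the divergent sequence's ID."""
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(AMINO_ACIDS))
    consensus = rng.choice(len(alphabet), size=spec.length)
    seqs = np.empty((spec.n_seqs, spec.length), dtype="<U1")
    for i in range(spec.n_seqs):
        rate = spec.divergent_rate if i == spec.divergent_index else spec.background_rate
        residues = consensus.copy()
        mutate = rng.random(spec.length) < rate
        # substitute with a uniformly drawn non-consensus residue
        offsets = rng.integers(1, len(alphabet), size=int(mutate.sum()))
        residues[mutate] = (residues[mutate] + offsets) % len(alphabet)
        seqs[i] = alphabet[residues]
    if spec.gap_prob > 0:
        gaps = rng.random((spec.n_seqs, spec.length)) < spec.gap_prob
        seqs[gaps] = "-"
    ids = [f"seq{i + 1}" for i in range(spec.n_seqs)]
    rows = ["".join(row) for row in seqs]
    return ProteinAlignment(ids, rows), ids[spec.divergent_index]


def write_alignment_fasta(aln: ProteinAlignment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, row in zip(aln.seq_ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def write_fixtures(
    out_dir,
    matrix_spec: MatrixSimSpec | None = None,
    alignment_spec: AlignmentSimSpec | None = None,
) -> dict:
    """Write the standard small fixture bundle and return its manifest.

    Emits the count matrix, species totals, true labels, a marker list, a
    toy pathway map over the marker/signal families, an aligned FASTA with a
    planted divergent sequence, and a JSON manifest recording the specs and
    ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mspec = matrix_spec or MatrixSimSpec(
        n_species=12, n_noise_families=30, n_signal_families=4, seed=7
    )
    aspec = alignment_spec or AlignmentSimSpec(seed=7)
    matrix, truth, signal_ids = simulate_matrix(mspec)
    aln, divergent_id = simulate_alignment(aspec)

    write_count_matrix(matrix, out / "matrix.tsv")
    write_species_totals(matrix.species_totals, out / "species_totals.tsv")
    write_labels(truth, out / "labels.tsv")
    (out / "markers.txt").write_text("\n".join(truth.marker_families) + "\n")
    with open(out / "pathway_map.tsv", "w", encoding="utf-8") as fh:
        fh.write("ko_id\tfamily_id\n")
        for fam in truth.marker_families:
            fh.write(f"K00001\t{fam}\n")
        for fam in signal_ids:
            fh.write(f"K00002\t{fam}\n")
    write_alignment_fasta(aln, out / "alignment.fasta")

    manifest = {
        "matrix_spec": asdict(mspec),
        "alignment_spec": asdict(aspec),
        "truth": {
            "labels": {s: int(l) for s, l in zip(truth.species_ids, truth.labels)},
            "marker_families": truth.marker_families,
            "signal_families": signal_ids,
            "divergent_seq": divergent_id,
        },
        "files": [
            "matrix.tsv",
            "species_totals.tsv",
            "labels.tsv",
            "markers.txt",
            "pathway_map.tsv",
            "alignment.fasta",
        ],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
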