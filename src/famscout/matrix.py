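"""Species x gene-family copy-number matrices.

The central object is :class:`FamilyCountMatrix`: rows are species, columns
are ortholog-cluster (gene-family) identifiers, and each cell holds the
number of gene copies that species carries in that family.  Matrices are
either read from TSV or aggregated from per-gene ortholog-group annotation
tables.  On top of the matrix this module provides the standard
comparative-genomics summaries: pathway subsetting, presence/absence,
pathway-gene-to-genome ratios, normalization for heatmap display, and
deterministic hierarchical leaf ordering.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyCountMatrix",
    "PathwayMap",
    "AnnotationRecord",
    "read_count_matrix",
    "write_count_matrix",
    "read_species_totals",
    "write_species_totals",
    "read_pathway_map",
    "read_annotations",
    "build_matrix_from_annotations",
    "subset_families",
    "presence_absence",
    "pathway_ratio",
    "normalize_counts",
    "cluster_order",
]

SPECIES_COLUMN = "species"


class MatrixFormatError(ValueError):
    """Raised when a count-matrix file violates the expected dialect."""


@dataclass
class FamilyCountMatrix:
    """Species x gene-family copy numbers, optionally with genome sizes.

    Parameters
    ----------
    counts
        DataFrame indexed by species ID with one column per family ID;
        entries are non-negative integers (gene copies per family).
    species_totals
        Optional per-species total gene count (genome-wide), required for
        ratio computations.  Must dominate any row sum over families.
    """

    counts: pd.DataFrame
    species_totals: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise MatrixFormatError(f"duplicate species ID: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise MatrixFormatError(f"duplicate family ID: {dup!r}")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.all(np.equal(np.mod(values, 1), 0)):
                    raise MatrixFormatError("counts must be integral")
                self.counts = self.counts.astype(np.int64)
                values = self.counts.to_numpy()
            if (values < 0).any():
                i, j = np.argwhere(values < 0)[0]
                raise MatrixFormatError(
                    f"negative count at species {idx[i]!r}, family {cols[j]!r}"
                )
        if self.species_totals is not None:
            totals = self.species_totals.reindex(idx)
            if totals.isna().any():
                missing = totals.index[totals.isna()][0]
                raise MatrixFormatError(f"missing total gene count for {missing!r}")
            if (totals <= 0).any():
                bad = totals.index[totals <= 0][0]
                raise MatrixFormatError(f"non-positive total gene count for {bad!r}")
            row_sums = self.counts.sum(axis=1)
            if ((totals - row_sums) < 0).any():
                bad = totals.index[(totals - row_sums) < 0][0]
                raise MatrixFormatError(
                    f"total gene count for {bad!r} is below its family row sum"
                )
            self.species_totals = totals.astype(np.int64)

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_families(self) -> int:
        return self.counts.shape[1]


@dataclass
class PathwayMap:
    """Mapping from pathway-gene (KEGG-orthology style) IDs to family IDs.

    ``entries`` preserves insertion order; each value is the non-empty list
    of ortholog-cluster IDs assigned to that pathway gene.
    """

    entries: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ko, fams in self.entries.items():
            if not fams:
                raise ValueError(f"pathway entry {ko!r} has no families")
            if any(not f for f in fams):
                raise ValueError(f"pathway entry {ko!r} contains an empty family ID")
            if len(set(fams)) != len(fams):
                raise ValueError(f"pathway entry {ko!r} lists a family twice")

    def family_list(self) -> list[str]:
        """Families in listing order, duplicates across entries removed.

        A family shared by two pathway entries is kept at its first listing
        position; the duplicate listing is logged (it would otherwise be
        double-counted in pathway sums).
        """
        seen: dict[str, str] = {}
        out: list[str] = []
        for ko, fams in self.entries.items():
            for fam in fams:
                if fam in seen:
                    logger.warning(
                        "family %s listed under both %s and %s; counted once",
                        fam, seen[fam], ko,
                    )
                    continue
                seen[fam] = ko
                out.append(fam)
        return out


@dataclass
class AnnotationRecord:
    """One gene's ortholog-group assignments, emapper style.

    ``og_assignments`` holds ``(cluster_id, taxon_scope_id)`` pairs: the same
    gene is assigned to nested clusters at several taxonomic depths, and a
    scope (e.g. ``"33090"`` for Viridiplantae) selects one depth.
    """

    gene_id: str
    og_assignments: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        for pair in self.og_assignments:
            if len(pair) != 2 or not pair[0] or not pair[1]:
                raise ValueError(
                    f"malformed OG assignment {pair!r} for gene {self.gene_id!r}"
                )


def read_count_matrix(
    path, totals_path=None
) -> FamilyCountMatrix:
    """Read a species x family count matrix from TSV.

    The first header cell is ``species``; remaining headers are family IDs.
    Every body cell must parse as a non-negative integer.  Row and column
    order are preserved.  Raises :class:`MatrixFormatError` naming the
    offending ID or cell coordinates on any violation.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise MatrixFormatError(f"{path}: empty file") from None
        family_ids = header[1:]
        seen_fams = set()
        for fam in family_ids:
            if fam in seen_fams:
                raise MatrixFormatError(f"{path}: duplicate family ID {fam!r}")
            seen_fams.add(fam)
        species_ids: list[str] = []
        rows: list[list[int]] = []
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0]):
                continue
            sp, cells = row[0], row[1:]
            if sp in species_ids:
                raise MatrixFormatError(f"{path}: duplicate species ID {sp!r}")
            if len(cells) != len(family_ids):
                raise MatrixFormatError(
                    f"{path}: row {sp!r} has {len(cells)} cells, "
                    f"expected {len(family_ids)}"
                )
            parsed = []
            for fam, cell in zip(family_ids, cells):
                try:
                    value = int(cell)
                except ValueError:
                    raise MatrixFormatError(
                        f"{path}: non-integer count {cell!r} at species {sp!r}, "
                        f"family {fam!r}"
                    ) from None
                if value < 0:
                    raise MatrixFormatError(
                        f"{path}: negative count at species {sp!r}, family {fam!r}"
                    )
                parsed.append(value)
            species_ids.append(sp)
            rows.append(parsed)
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(species_ids), len(family_ids)),
        index=pd.Index(species_ids, name=SPECIES_COLUMN),
        columns=family_ids,
    )
    totals = read_species_totals(totals_path) if totals_path is not None else None
    return FamilyCountMatrix(counts, totals)


def write_count_matrix(m: FamilyCountMatrix, path) -> None:
    """Write the matrix back to the TSV dialect ``read_count_matrix`` accepts."""
    out = m.counts.copy()
    out.index.name = SPECIES_COLUMN
    out.to_csv(path, sep="\t")


def read_species_totals(path) -> pd.Series:
    """Read a two-column TSV ``species<TAB>total_genes`` into a Series."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] != 2:
        raise MatrixFormatError(f"{path}: expected two columns (species, total)")
    series = pd.Series(
        df.iloc[:, 1].to_numpy(dtype=np.int64),
        index=pd.Index(df.iloc[:, 0], name=SPECIES_COLUMN),
        name="total_genes",
    )
    return series


def write_species_totals(totals: pd.Series, path) -> None:
    df = totals.rename("total_genes").rename_axis(SPECIES_COLUMN).reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_pathway_map(path) -> PathwayMap:
    """Read a TSV of ``ko_id<TAB>family_id`` pairs (one pair per line)."""
    entries: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise MatrixFormatError(f"{path}: empty pathway map")
        for row in reader:
            if not row or (len(row) == 1 and not row[0]):
                continue
            if len(row) < 2:
                raise MatrixFormatError(f"{path}: malformed pathway line {row!r}")
            ko, fam = row[0], row[1]
            entries.setdefault(ko, [])
            if fam in entries[ko]:
                raise MatrixFormatError(
                    f"{path}: family {fam!r} listed twice under {ko!r}"
                )
            entries[ko].append(fam)
    return PathwayMap(entries)


def read_annotations(path, gene_col: str = "gene_id", og_col: str = "eggNOG_OGs") -> list[AnnotationRecord]:
    """Parse an emapper-style annotation TSV into :class:`AnnotationRecord`s.

    The OG column holds comma-separated ``CLUSTER@TAXID`` tokens; lines
    starting with ``#`` are comments.
    """
    records: list[AnnotationRecord] = []
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if gene_col not in df.columns or og_col not in df.columns:
        raise MatrixFormatError(
            f"{path}: expected columns {gene_col!r} and {og_col!r}, "
            f"found {list(df.columns)}"
        )
    for _, row in df.iterrows():
        raw = row[og_col]
        pairs: list[tuple[str, str]] = []
        if isinstance(raw, str) and raw and raw != "-":
            for token in raw.split(","):
                token = token.strip()
                if not token:
                    continue
                cluster, _, taxid = token.partition("@")
                if not cluster or not taxid:
                    raise MatrixFormatError(
                        f"{path}: malformed OG token {token!r} for gene "
                        f"{row[gene_col]!r}"
                    )
                pairs.append((cluster, taxid))
        records.append(AnnotationRecord(str(row[gene_col]), pairs))
    return records


def build_matrix_from_annotations(
    records_by_species: dict[str, list[AnnotationRecord]], scope: str
) -> FamilyCountMatrix:
    """Aggregate per-gene annotations into a copy-number matrix at one scope.

    ``counts[s, f]`` is the number of genes of species ``s`` assigned to
    cluster ``f`` at taxonomic scope ``scope``; genes with no assignment at
    that scope contribute nothing.  Family columns are the union over
    species, sorted lexicographically; species keep their input order.
    """
    tallies: dict[str, dict[str, int]] = {}
    families: set[str] = set()
    for sp, records in records_by_species.items():
        tally: dict[str, int] = {}
        for rec in records:
            for cluster, taxid in rec.og_assignments:
                if taxid == scope:
                    tally[cluster] = tally.get(cluster, 0) + 1
                    families.add(cluster)
        tallies[sp] = tally
    family_ids = sorted(families)
    counts = pd.DataFrame(
        [[tallies[sp].get(f, 0) for f in family_ids] for sp in tallies],
        index=pd.Index(list(tallies), name=SPECIES_COLUMN),
        columns=family_ids,
        dtype=np.int64,
    )
    return FamilyCountMatrix(counts)


def subset_families(m: FamilyCountMatrix, pmap: PathwayMap) -> FamilyCountMatrix:
    """Restrict columns to the pathway's families, in pathway listing order.

    Families absent from the matrix are materialized as all-zero columns:
    absence of a pathway family in a species (or clade) is itself signal and
    must stay visible in downstream displays.
    """
    wanted = pmap.family_list()
    counts = m.counts.reindex(columns=wanted, fill_value=0).astype(np.int64)
    return FamilyCountMatrix(counts, m.species_totals)


def presence_absence(m: FamilyCountMatrix) -> pd.DataFrame:
    """Binary matrix: 1 where the species carries >= 1 copy, else 0."""
    return (m.counts >= 1).astype(np.int64)


def pathway_ratio(m: FamilyCountMatrix, pmap: PathwayMap) -> pd.Series:
    """Per-species ratio of pathway gene copies to total gene count.

    Families listed under several pathway entries are counted once.  Requires
    ``species_totals``.
    """
    if m.species_totals is None:
        raise ValueError("pathway_ratio requires species_totals")
    fams = pmap.family_list()
    sub = m.counts.reindex(columns=fams, fill_value=0)
    ratio = sub.sum(axis=1) / m.species_totals
    return ratio.rename("pathway_ratio")


_NORMALIZE_METHODS = ("per_family_max", "per_species_total")


def normalize_counts(m: FamilyCountMatrix, method: str = "per_family_max") -> pd.DataFrame:
    """Scale counts for cross-species comparison.

    ``per_family_max`` divides each column by its maximum over species
    (all-zero columns stay zero), so every family spans [0, 1] and copy
    number patterns are comparable family by family.  ``per_species_total``
    divides each row by the species' total gene count, expressing counts as
    genome fractions.
    """
    if method == "per_family_max":
        col_max = m.counts.max(axis=0)
        denom = col_max.replace(0, 1)
        return m.counts / denom
    if method == "per_species_total":
        if m.species_totals is None:
            raise ValueError("per_species_total normalization requires species_totals")
        return m.counts.div(m.species_totals, axis=0)
    raise ValueError(
        f"unknown normalization method {method!r}; expected one of {_NORMALIZE_METHODS}"
    )


def cluster_order(values, axis: str = "rows") -> list[int]:
    """Leaf order of average-linkage (UPGMA) clustering on Euclidean distance.

    Deterministic for a given input; with a single item the order is ``[0]``.
    ``values`` may be a DataFrame or 2-D array; ``axis`` selects ``"rows"``
    or ``"columns"``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("cluster_order expects a 2-D matrix")
    if axis == "columns":
        arr = arr.T
    elif axis != "rows":
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    n = arr.shape[0]
    if n == 0:
        raise ValueError("cannot order an empty axis")
    if n == 1:
        return [0]
    link = hierarchy.linkage(pdist(arr, metric="euclidean"), method="average")
    return [int(i) for i in hierarchy.leaves_list(link)]
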