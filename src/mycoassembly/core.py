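"""Domain types: OTU table, sample metadata, phylogeny wrapper.

The sample x OTU count table is the central object of every stage. Internally
samples are rows (pandas DataFrame of non-negative integers); distance
matrices are scikit-bio :class:`~skbio.stats.distance.DistanceMatrix` objects,
which enforce symmetry and a zero diagonal on construction.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .errors import (
    CoordinateError,
    DuplicateIdError,
    MissingTaxonError,
    NegativeCountError,
    NewickError,
    NonIntegerCountError,
)

__all__ = ["OtuTable", "SampleMetadata", "Phylogeny", "DistanceMatrix"]

#: metadata columns interpreted as numeric environmental variables
ENV_COLUMNS = (
    "latitude",
    "longitude",
    "altitude",
    "MAT",
    "MAP",
    "N",
    "P",
    "NP_ratio",
    "Ca",
    "Mg",
)


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise DuplicateIdError(f"duplicate {what} ids: {sorted(dups)}")
    return ids


class OtuTable:
    """Sample x OTU table of non-negative integer read counts.

    Parameters
    ----------
    counts
        2-D array-like or DataFrame, samples as rows.
    sample_ids, otu_ids
        Unique identifiers; taken from the DataFrame index/columns if omitted.
    lineage
        Optional map OTU id -> lineage label (e.g. ``"/Tomentella-Thelephora"``).
    """

    def __init__(
        self,
        counts,
        sample_ids: Sequence[str] | None = None,
        otu_ids: Sequence[str] | None = None,
        lineage: Mapping[str, str] | None = None,
    ):
        if isinstance(counts, pd.DataFrame):
            if sample_ids is None:
                sample_ids = list(counts.index.astype(str))
            if otu_ids is None:
                otu_ids = list(counts.columns.astype(str))
            counts = counts.to_numpy()
        arr = np.asarray(counts)
        if arr.ndim != 2:
            raise ValueError("counts must be 2-D (samples x OTUs)")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            as_float = arr.astype(float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.floor(as_float)):
                bad = np.argwhere(~np.isfinite(as_float) | (as_float != np.floor(as_float)))[0]
                raise NonIntegerCountError(
                    f"non-integer count at row {bad[0]}, column {bad[1]}: {arr[tuple(bad)]!r}"
                )
            arr = as_float.astype(np.int64)
        arr = arr.astype(np.int64, copy=True)
        if arr.size and arr.min() < 0:
            r, c = np.argwhere(arr < 0)[0]
            raise NegativeCountError(f"negative count at row {r}, column {c}: {arr[r, c]}")
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(arr.shape[0])]
        if otu_ids is None:
            otu_ids = [f"OTU{i}" for i in range(arr.shape[1])]
        sample_ids = _check_unique(sample_ids, "sample")
        otu_ids = _check_unique(otu_ids, "OTU")
        if len(sample_ids) != arr.shape[0] or len(otu_ids) != arr.shape[1]:
            raise ValueError(
                f"id lists ({len(sample_ids)} x {len(otu_ids)}) do not match "
                f"count grid {arr.shape}"
            )
        self._df = pd.DataFrame(arr, index=sample_ids, columns=otu_ids)
        self.lineage = dict(lineage) if lineage else None

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> np.ndarray:
        """Copy of the count grid (samples x OTUs, int64)."""
        return self._df.to_numpy(copy=True)

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def n_samples(self) -> int:
        return self._df.shape[0]

    @property
    def n_otus(self) -> int:
        return self._df.shape[1]

    def sample_sums(self) -> pd.Series:
        return self._df.sum(axis=1)

    def otu_sums(self) -> pd.Series:
        return self._df.sum(axis=0)

    def drop_empty_otus(self) -> "OtuTable":
        """Return a table without all-zero OTU columns."""
        keep = self._df.columns[(self._df > 0).any(axis=0)]
        return self.select_otus(list(keep))

    def select_samples(self, ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self._df.loc[list(ids)], lineage=self.lineage)

    def select_otus(self, ids: Sequence[str]) -> "OtuTable":
        lin = {o: self.lineage[o] for o in ids if o in self.lineage} if self.lineage else None
        return OtuTable(self._df[list(ids)], lineage=lin)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self._df.equals(other._df)
            and self.lineage == other.lineage
        )

    def __repr__(self) -> str:
        return f"<OtuTable {self.n_samples} samples x {self.n_otus} OTUs>"


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample metadata: host species, site, coordinates and environment.

    ``table`` is indexed by sample id with columns ``host_species``, ``site``
    and the numeric variables in :data:`ENV_COLUMNS` (any subset); per-site
    soil/climate values are expected to be broadcast to their samples.
    """

    table: pd.DataFrame

    def __post_init__(self):
        _check_unique(list(self.table.index.astype(str)), "sample")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        if "latitude" in self.table:
            lat = self.table["latitude"].astype(float)
            if ((lat < -90) | (lat > 90)).any():
                raise CoordinateError("latitude outside [-90, 90]")
        if "longitude" in self.table:
            lon = self.table["longitude"].astype(float)
            if ((lon < -180) | (lon > 180)).any():
                raise CoordinateError("longitude outside [-180, 180]")

    def require_samples(self, sample_ids: Sequence[str]) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")

    def aligned(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        self.require_samples(sample_ids)
        return self.table.loc[list(sample_ids)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


class Phylogeny:
    """Rooted phylogeny with branch lengths, backed by a dendropy tree."""

    def __init__(self, tree: dendropy.Tree, require_lengths: bool = True):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise NewickError("tree has unlabeled tips")
        _check_unique(labels, "tip")
        if require_lengths:
            for edge in tree.preorder_edge_iter():
                if edge.head_node is tree.seed_node:
                    continue
                if edge.length is None:
                    raise NewickError(
                        f"missing branch length above node "
                        f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                    )
                if edge.length < 0:
                    raise NewickError("negative branch length")
        self.tip_labels = labels

    @classmethod
    def from_newick(cls, newick: str, require_lengths: bool = True) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parser error types
            raise NewickError(f"could not parse Newick: {exc}") from exc
        return cls(tree, require_lengths=require_lengths)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, suppress_annotations=True
        ).strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def cophenetic(self) -> DistanceMatrix:
        """Patristic distance matrix d_ij = branch-length path between tips."""
        pdm = self._tree.phylogenetic_distance_matrix()
        labels = self.tip_labels
        taxa = {t.label: t for t in self._tree.taxon_namespace if t.label in set(labels)}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        return DistanceMatrix(d, ids=labels)

    def check_covers(self, otu_ids: Sequence[str]) -> None:
        missing = sorted(set(otu_ids) - set(self.tip_labels))
        if missing:
            raise MissingTaxonError(f"OTUs absent from tree: {missing[:10]}")
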