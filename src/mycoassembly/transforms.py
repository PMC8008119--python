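"""Elementary community transformations.

Rarefaction (seeded subsampling without replacement), relative-abundance /
Hellinger / presence-absence transforms, Bray-Curtis dissimilarity and
great-circle geographic distances.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio.stats.distance import DistanceMatrix

from .core import OtuTable, SampleMetadata
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

TRANSFORM_MODES = ("relative_abundance", "hellinger", "presence_absence")


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample's reads without replacement to a common depth.

    Each retained sample's counts are a multivariate-hypergeometric draw from
    its reads, so every output row sums exactly to ``depth``. Samples with
    fewer than ``depth`` reads are dropped with a logged warning; OTU columns
    left all-zero are removed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    counts = table.counts
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped
        )
    out = []
    kept_ids = []
    for i, sid in enumerate(table.sample_ids):
        if not keep[i]:
            continue
        row = counts[i]
        if totals[i] == depth:
            out.append(row)
        else:
            out.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    if not out:
        raise DegenerateInputError(f"no sample reaches rarefaction depth {depth}")
    rarefied = OtuTable(np.vstack(out), kept_ids, table.otu_ids, lineage=table.lineage)
    return rarefied.drop_empty_otus()


def transform(table: OtuTable, mode: str) -> pd.DataFrame:
    """Real-valued community grid (samples x OTUs).

    ``relative_abundance`` rows sum to 1 (all-zero rows stay zero);
    ``hellinger`` is the square root of relative abundance, so each non-empty
    row has unit sum of squares; ``presence_absence`` is 0/1.
    """
    if mode not in TRANSFORM_MODES:
        raise ValueError(f"unknown transform mode {mode!r}; choose from {TRANSFORM_MODES}")
    counts = table.counts.astype(float)
    if mode == "presence_absence":
        grid = (counts > 0).astype(float)
    else:
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)
        grid = np.sqrt(rel) if mode == "hellinger" else rel
    return pd.DataFrame(grid, index=table.sample_ids, columns=table.otu_ids)


def bray_curtis(grid: pd.DataFrame, on_empty_pair: str = "error") -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(u,v) = 1 - 2 sum(min(u,v)) / (sum u + sum v).

    A pair of all-zero rows makes the statistic undefined: raised as
    :class:`DegenerateInputError` by default, or set to NaN with
    ``on_empty_pair="nan"`` (in which case a plain DataFrame is returned,
    since a validated DistanceMatrix cannot carry missing entries).
    """
    x = np.asarray(grid, dtype=float)
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires non-negative input rows")
    totals = x.sum(axis=1)
    empty = np.flatnonzero(totals == 0)
    if empty.size >= 2:
        ids = list(grid.index[empty])
        if on_empty_pair == "error":
            raise DegenerateInputError(
                f"Bray-Curtis undefined between all-zero samples: {ids}"
            )
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        denom = totals[i] + totals[i + 1 :]
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(denom > 0, 1.0 - 2.0 * shared / np.where(denom > 0, denom, 1), np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    if np.isnan(d).any():
        return pd.DataFrame(d, index=grid.index, columns=grid.index)
    return DistanceMatrix(d, ids=list(grid.index))


def geographic_distances(meta: SampleMetadata, ids=None) -> DistanceMatrix:
    """Great-circle (haversine) distances in km on a sphere of radius 6371 km."""
    df = meta.table if ids is None else meta.aligned(ids)
    lat = np.radians(df["latitude"].astype(float).to_numpy())
    lon = np.radians(df["longitude"].astype(float).to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against fp noise
    return DistanceMatrix(d, ids=list(df.index))


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def expected_rarefied_counts(table: OtuTable, depth: int) -> np.ndarray:
    """E[count] after rarefaction: depth * c_sk / sum(c_s) per retained sample."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    keep = totals[:, 0] >= depth
    return depth * counts[keep] / totals[keep]


def condensed(dm: DistanceMatrix) -> np.ndarray:
    """Lower-triangle entries of a distance matrix as a condensed vector."""
    return squareform(dm.data, checks=False)
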