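"""Plant-fungus preference analysis at a single site.

Builds a plant x OTU presence-count interaction matrix, computes the
standardized Kullback-Leibler specialization index d' for each fungal OTU and
each plant, and a two-dimensional preference score (2DP) for every
plant-fungus pair: the standardized effect size of the observed co-occurrence
count against a fixed-marginal (Patefield) randomization null. P-values are
two-sided randomization ranks, BH-FDR adjusted within each family (OTUs,
plants, pairs); pairs with 2DP > 1.6 are flagged as strong preferences.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .core import OtuTable, SampleMetadata
from .errors import DegenerateInputError

STRONG_PREFERENCE_2DP = 1.6


@dataclasses.dataclass
class InteractionMatrix:
    """Plant species x OTU presence counts at one site.

    Entry a_ij = number of samples of plant j in which OTU i occurs; bounded
    by the per-plant sample count.
    """

    counts: pd.DataFrame  # rows = OTUs, columns = plant species
    samples_per_plant: pd.Series

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValueError("interaction counts must be non-negative integers")
        cap = self.samples_per_plant.reindex(self.counts.columns)
        if (self.counts.gt(cap, axis=1)).any().any():
            raise ValueError("occurrence count exceeds per-plant sample count")

    @property
    def otu_ids(self):
        return list(self.counts.index)

    @property
    def plant_ids(self):
        return list(self.counts.columns)


def build_interaction_matrix(
    table: OtuTable, meta: SampleMetadata, site: str
) -> InteractionMatrix:
    """Presence counts per plant x OTU restricted to one site.

    OTUs absent from the site are removed (zero rows dropped).
    """
    md = meta.aligned(table.sample_ids)
    if site not in set(md["site"]):
        raise KeyError(f"site {site!r} absent from metadata")
    sel = md.index[md["site"] == site]
    hosts = md.loc[sel, "host_species"]
    if hosts.nunique() < 2:
        raise DegenerateInputError(f"site {site!r} has fewer than 2 plant species")
    presence = (table.select_samples(list(sel)).to_dataframe() > 0).astype(int)
    counts = presence.groupby(hosts).sum().T  # OTUs x plants
    counts = counts.loc[counts.sum(axis=1) > 0]
    per_plant = hosts.value_counts().reindex(counts.columns)
    return InteractionMatrix(counts, per_plant)


def filter_abundant(matrix: InteractionMatrix, min_occurrence: int = 3) -> InteractionMatrix:
    """Keep OTUs whose total occurrences reach ``min_occurrence``."""
    if min_occurrence < 1:
        raise ValueError("min_occurrence must be >= 1")
    keep = matrix.counts.sum(axis=1) >= min_occurrence
    if not keep.any():
        raise DegenerateInputError(
            f"no OTU reaches min_occurrence={min_occurrence}"
        )
    return InteractionMatrix(matrix.counts.loc[keep], matrix.samples_per_plant)


def _dprime_rows(a: np.ndarray, strict: bool = True) -> np.ndarray:
    """d' per row of an interaction array (see :func:`dprime`).

    With ``strict=False`` zero-total focal rows yield NaN instead of an error
    (needed when scoring null draws whose column margins are free).
    """
    focal_totals = a.sum(axis=1)
    if np.any(focal_totals == 0):
        if strict:
            raise DegenerateInputError("focal row/column with zero total")
        out = np.full(a.shape[0], np.nan)
        ok = focal_totals > 0
        if ok.any():
            # zero rows contribute nothing to margins, so dropping them is exact
            out[ok] = _dprime_rows(a[ok], strict=True)
        return out
    grand = a.sum()
    q = a.sum(axis=0) / grand
    out = np.zeros(a.shape[0])
    for i in range(a.shape[0]):
        p = a[i] / focal_totals[i]
        nz = p > 0
        d = np.sum(p[nz] * np.log(p[nz] / q[nz]))
        dmax = np.log(grand / focal_totals[i])
        out[i] = d / dmax if dmax > 0 else 0.0
    return np.clip(out, 0.0, 1.0)


def dprime(matrix: InteractionMatrix, axis: str = "otus") -> pd.Series:
    """Standardized specialization index d' per OTU (rows) or plant (columns).

    For focal i with interactions a_ij: d_i = sum_j p_ij ln(p_ij / q_j) with
    p_ij = a_ij / A_i and q_j the partner's share of the grand total;
    d' = d_i / ln(grand_total / A_i), bounded in [0, 1].
    """
    if axis not in ("otus", "plants"):
        raise ValueError("axis must be 'otus' or 'plants'")
    a = matrix.counts.to_numpy(dtype=float)
    if axis == "plants":
        a = a.T
        ids = matrix.plant_ids
    else:
        ids = matrix.otu_ids
    return pd.Series(_dprime_rows(a), index=ids, name="dprime")


def _patefield_draws(matrix: InteractionMatrix, n_rand: int, rng) -> np.ndarray:
    """(n_rand, otus, plants) tables with row and column sums preserved."""
    a = matrix.counts.to_numpy()
    rt = stats.random_table(a.sum(axis=1), a.sum(axis=0))
    return rt.rvs(n_rand, method="patefield", random_state=rng)


def _shuffle_draws(matrix: InteractionMatrix, n_rand: int, rng) -> np.ndarray:
    """Alternative null: shuffle each OTU's occurrences across plants,
    respecting per-plant sample capacities (row totals kept, columns free)."""
    a = matrix.counts.to_numpy()
    caps = matrix.samples_per_plant.to_numpy()
    n_otus, n_plants = a.shape
    slots = np.repeat(np.arange(n_plants), caps)
    draws = np.empty((n_rand, n_otus, n_plants), dtype=int)
    for r in range(n_rand):
        for i in range(n_otus):
            chosen = rng.choice(slots.size, size=int(a[i].sum()), replace=False)
            draws[r, i] = np.bincount(slots[chosen], minlength=n_plants)
    return draws


def _rank_p_two_sided(null: np.ndarray, obs: float) -> float:
    """(1 + hits)/(1 + n) two-sided randomization p."""
    n = null.shape[0]
    p_hi = (1 + np.sum(null >= obs)) / (n + 1)
    p_lo = (1 + np.sum(null <= obs)) / (n + 1)
    return min(1.0, 2 * min(p_hi, p_lo))


@dataclasses.dataclass
class PreferenceResult:
    """Standardized d' per OTU and plant, per-pair 2DP, FDR p, strong flags."""

    otu_table: pd.DataFrame
    plant_table: pd.DataFrame
    pair_table: pd.DataFrame
    two_dp: pd.DataFrame  # OTUs x plants, Fig-7-style heat matrix
    n_rand: int
    seed: int
    null_model: str

    @property
    def strong_pairs(self) -> pd.DataFrame:
        return self.pair_table[self.pair_table["strong"]]


def standardized_preference(
    matrix: InteractionMatrix,
    n_rand: int = 1000,
    seed: int = 0,
    null_model: str = "patefield",
) -> PreferenceResult:
    """Randomization-standardized preference scores.

    d'_SES = (d'_obs - mean_null) / sd_null per OTU and per plant;
    2DP_ij = (a_ij - mean_null_ij) / sd_null_ij per pair. Cells with zero
    null variance are flagged undefined (NaN p) and excluded from their FDR
    family.
    """
    if n_rand < 99:
        raise ValueError("n_rand must be >= 99")
    rng = np.random.default_rng(seed)
    if null_model == "patefield":
        draws = _patefield_draws(matrix, n_rand, rng)
    elif null_model == "shuffle":
        draws = _shuffle_draws(matrix, n_rand, rng)
    else:
        raise ValueError(f"unknown null_model {null_model!r}")

    obs = matrix.counts.to_numpy(dtype=float)

    obs_d_otu = dprime(matrix, "otus").to_numpy()
    obs_d_plant = dprime(matrix, "plants").to_numpy()
    null_d_otu = np.stack([_dprime_rows(d.astype(float), strict=False) for d in draws])
    null_d_plant = np.stack([_dprime_rows(d.T.astype(float), strict=False) for d in draws])

    def ses_and_p(null: np.ndarray, observed: np.ndarray):
        mean = np.nanmean(null, axis=0)
        sd = np.nanstd(null, axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ses = np.where(sd > 0, (observed - mean) / sd, np.nan)
        p = np.array(
            [
                _rank_p_two_sided(null[np.isfinite(null[:, i]), i], observed[i])
                if sd[i] > 0
                else np.nan
                for i in range(len(observed))
            ]
        )
        return ses, p

    ses_otu, p_otu = ses_and_p(null_d_otu, obs_d_otu)
    ses_plant, p_plant = ses_and_p(null_d_plant, obs_d_plant)

    null_mean = draws.mean(axis=0)
    null_sd = draws.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        two_dp = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)
    p_pair = np.full(obs.shape, np.nan)
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            if null_sd[i, j] > 0:
                p_pair[i, j] = _rank_p_two_sided(draws[:, i, j], obs[i, j])

    otu_table = pd.DataFrame(
        {
            "dprime": obs_d_otu,
            "dprime_ses": ses_otu,
            "p_raw": p_otu,
            "p_fdr": _fdr_with_nan(p_otu),
        },
        index=matrix.otu_ids,
    )
    plant_table = pd.DataFrame(
        {
            "dprime": obs_d_plant,
            "dprime_ses": ses_plant,
            "p_raw": p_plant,
            "p_fdr": _fdr_with_nan(p_plant),
        },
        index=matrix.plant_ids,
    )
    rows = []
    flat_p = p_pair.ravel()
    flat_fdr = _fdr_with_nan(flat_p)
    k = 0
    for i, otu in enumerate(matrix.otu_ids):
        for j, plant in enumerate(matrix.plant_ids):
            rows.append(
                {
                    "otu": otu,
                    "plant": plant,
                    "observed": obs[i, j],
                    "two_dp": two_dp[i, j],
                    "p_raw": flat_p[k],
                    "p_fdr": flat_fdr[k],
                    "strong": bool(two_dp[i, j] > STRONG_PREFERENCE_2DP)
                    if np.isfinite(two_dp[i, j])
                    else False,
                }
            )
            k += 1
    pair_table = pd.DataFrame(rows)
    two_dp_df = pd.DataFrame(two_dp, index=matrix.otu_ids, columns=matrix.plant_ids)
    return PreferenceResult(
        otu_table, plant_table, pair_table, two_dp_df, n_rand, seed, null_model
    )


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj


def _fdr_with_nan(p: np.ndarray) -> np.ndarray:
    """BH over the finite entries only; NaN (undefined) entries stay NaN."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = fdr_adjust(p[mask])
    return out
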