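"""Phylogenetic community structure and assembly-process inference.

Within-sample mean nearest taxon distance (MNTD) and its standardized effect
size (NTI), between-sample phylogenetic turnover (betaMNTD) and its
standardized effect size (betaNTI), with a taxa-label-shuffle null model:
tip labels of the cophenetic distance matrix are permuted across the OTUs
present in the analysed table, the default 999 times. |betaNTI| > 2 is read
as deterministic assembly (environmental filtering when positive), otherwise
stochastic; NTI is sign-flipped so that phylogenetic clustering gives
NTI > 0.

The all-pair betaNTI nulls reuse the same label shuffles across pairs (one
shuffle = one null replicate for every pair), which keeps replicates coherent
between pairs and the computation vectorizable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix

from .core import OtuTable, Phylogeny
from .errors import DegenerateInputError

BNTI_THRESHOLD = 2.0

#: null sds below this relative tolerance are treated as zero (the label
#: shuffle can reproduce the observed statistic exactly up to summation order)
_SD_RTOL = 1e-9


def _effective_sd(sd: np.ndarray, mean: np.ndarray) -> np.ndarray:
    return np.where(sd > _SD_RTOL * np.maximum(np.abs(mean), 1.0), sd, 0.0)


@dataclasses.dataclass
class SesResult:
    """Observed statistic against a null distribution."""

    observed: float
    null_mean: float
    null_sd: float
    ses: float  # signed standardized effect size; NaN when null sd == 0
    p_value: float
    n_null: int
    seed: int | None = None


@dataclasses.dataclass
class AssemblySummary:
    """Assembly-process verdict from betaNTI bins and the mean-NTI t-test."""

    n_pairs: int
    frac_bnti_above_2: float
    frac_bnti_within: float
    frac_bnti_below_minus2: float
    mean_nti: float | None = None
    nti_t_statistic: float | None = None
    nti_t_pvalue: float | None = None

    def __post_init__(self):
        total = self.frac_bnti_above_2 + self.frac_bnti_within + self.frac_bnti_below_minus2
        if self.n_pairs and abs(total - 1.0) > 1e-9:
            raise ValueError("betaNTI bin fractions must sum to 1")


def _aligned_distances(table: OtuTable, tree: Phylogeny) -> tuple[OtuTable, np.ndarray]:
    """Canonicalize OTU order (sorted ids) so the label-shuffle null — and
    hence every output — is invariant to the input column order."""
    tree.check_covers(table.otu_ids)
    table = table.select_otus(sorted(table.otu_ids))
    dm = tree.cophenetic()
    idx = [list(dm.ids).index(o) for o in table.otu_ids]
    return table, dm.data[np.ix_(idx, idx)]


def _relative_abundance(table: OtuTable) -> np.ndarray:
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    return np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)


def mntd(abundances, d: np.ndarray, abundance_weighted: bool = True) -> float:
    """Mean nearest taxon distance within one community.

    ``abundances`` is the full-length abundance vector aligned with ``d``;
    taxa with zero abundance are absent. Weighted: sum_i f_i * min_{j != i}
    d_ij over present taxa with f_i the within-sample relative abundances;
    unweighted: arithmetic mean of the nearest-taxon distances.
    """
    a = np.asarray(abundances, dtype=float)
    idx = np.flatnonzero(a > 0)
    if idx.size < 2:
        raise DegenerateInputError("MNTD undefined for a community with < 2 taxa")
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    nn = sub.min(axis=1)
    if abundance_weighted:
        w = a[idx] / a[idx].sum()
        return float(np.sum(w * nn))
    return float(nn.mean())


def bmntd(abund_k, abund_l, d: np.ndarray, abundance_weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance (betaMNTD) for one pair.

    0.5 * [sum_{i in k} f_ik min_{j in l} d_ij + sum_{j in l} f_jl min_{i in k} d_ij];
    shared taxa contribute distance 0.
    """
    ak = np.asarray(abund_k, dtype=float)
    al = np.asarray(abund_l, dtype=float)
    ik = np.flatnonzero(ak > 0)
    il = np.flatnonzero(al > 0)
    if ik.size == 0 or il.size == 0:
        raise DegenerateInputError("betaMNTD undefined for an empty community")
    nn_k = d[np.ix_(ik, il)].min(axis=1)
    nn_l = d[np.ix_(ik, il)].min(axis=0)
    if abundance_weighted:
        wk = ak[ik] / ak[ik].sum()
        wl = al[il] / al[il].sum()
        return float(0.5 * (np.sum(wk * nn_k) + np.sum(wl * nn_l)))
    return float(0.5 * (nn_k.mean() + nn_l.mean()))


def _bmntd_all_pairs(F: np.ndarray, present: list[np.ndarray], d: np.ndarray) -> np.ndarray:
    """Square betaMNTD matrix for all sample pairs (abundance vectors in F).

    Uses the nearest-taxon map M[l, i] = min_{j in l} d_ij so that the
    directed term is a single matrix product.
    """
    n, t = F.shape
    M = np.empty((n, t))
    for l in range(n):
        M[l] = d[:, present[l]].min(axis=1)
    A = F @ M.T  # A[k, l] = sum_i F[k, i] * M[l, i]
    return 0.5 * (A + A.T)


def nti(
    table: OtuTable,
    tree: Phylogeny,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Nearest taxon index per sample.

    NTI = -(MNTD_obs - mean_null) / sd_null, so clustering (observed MNTD
    smaller than the null) gives NTI > 0. Samples with < 2 taxa are returned
    with NaN and flagged in the ``defined`` column.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    table, d = _aligned_distances(table, tree)
    counts = table.counts.astype(float)
    rng = np.random.default_rng(seed)
    t = d.shape[0]
    ok = (counts > 0).sum(axis=1) >= 2
    obs = np.full(table.n_samples, np.nan)
    for k in np.flatnonzero(ok):
        obs[k] = mntd(counts[k], d, abundance_weighted)
    nulls = np.full((n_null, table.n_samples), np.nan)
    for r in range(n_null):
        perm = rng.permutation(t)
        d_null = d[np.ix_(perm, perm)]
        for k in np.flatnonzero(ok):
            nulls[r, k] = mntd(counts[k], d_null, abundance_weighted)
    mean = nulls.mean(axis=0)
    sd = _effective_sd(nulls.std(axis=0, ddof=1), mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = np.where(sd > 0, (obs - mean) / sd, 0.0)
    ses[~ok] = np.nan
    nti_vals = -ses
    p = np.full(table.n_samples, np.nan)
    for k in np.flatnonzero(ok):
        if sd[k] > 0:
            lo = (1 + np.sum(nulls[:, k] <= obs[k])) / (n_null + 1)
            hi = (1 + np.sum(nulls[:, k] >= obs[k])) / (n_null + 1)
            p[k] = min(1.0, 2 * min(lo, hi))
        else:
            p[k] = 1.0
    return pd.DataFrame(
        {
            "mntd_obs": obs,
            "null_mean": mean,
            "null_sd": sd,
            "nti": nti_vals,
            "p_value": p,
            "defined": ok & (sd > 0),
        },
        index=table.sample_ids,
    )


@dataclasses.dataclass
class BntiResult:
    """Per-pair betaNTI table plus the deterministic/stochastic summary."""

    pairs: pd.DataFrame
    bmntd_observed: DistanceMatrix
    summary: AssemblySummary
    n_null: int
    seed: int

    def bnti_values(self) -> np.ndarray:
        return self.pairs["bnti"].to_numpy()


def bnti(
    table: OtuTable,
    tree: Phylogeny,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> BntiResult:
    """betaNTI for every sample pair with a shared taxa-shuffle null.

    betaNTI = (betaMNTD_obs - mean_null) / sd_null keeps the raw sign:
    values > 2 indicate greater-than-expected phylogenetic turnover
    (deterministic, divergent filtering), < -2 lower than expected, and
    |betaNTI| <= 2 stochastic assembly. Pairs with zero null variance are
    flagged undefined and excluded from the bin fractions.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    table, d = _aligned_distances(table, tree)
    counts = table.counts.astype(float)
    if (counts.sum(axis=1) == 0).any():
        raise DegenerateInputError("betaNTI undefined with empty samples")
    if abundance_weighted:
        F = _relative_abundance(table)
    else:
        pres = counts > 0
        F = pres / pres.sum(axis=1, keepdims=True)
    present = [np.flatnonzero(counts[k] > 0) for k in range(table.n_samples)]
    obs = _bmntd_all_pairs(F, present, d)
    rng = np.random.default_rng(seed)
    t = d.shape[0]
    n = table.n_samples
    iu = np.triu_indices(n, 1)
    null_tri = np.empty((n_null, iu[0].size))
    for r in range(n_null):
        perm = rng.permutation(t)
        null_tri[r] = _bmntd_all_pairs(F, present, d[np.ix_(perm, perm)])[iu]
    mean = null_tri.mean(axis=0)
    sd = _effective_sd(null_tri.std(axis=0, ddof=1), mean)
    obs_tri = obs[iu]
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = np.where(sd > 0, (obs_tri - mean) / sd, np.nan)
    sample_ids = table.sample_ids
    pairs = pd.DataFrame(
        {
            "sample_1": [sample_ids[i] for i in iu[0]],
            "sample_2": [sample_ids[j] for j in iu[1]],
            "bmntd_obs": obs_tri,
            "null_mean": mean,
            "null_sd": sd,
            "bnti": ses,
            "defined": sd > 0,
        }
    )
    finite = ses[np.isfinite(ses)]
    npairs = finite.size
    if npairs:
        above = float(np.mean(finite > BNTI_THRESHOLD))
        below = float(np.mean(finite < -BNTI_THRESHOLD))
        within = 1.0 - above - below
    else:
        above = below = within = 0.0
    summary = AssemblySummary(
        n_pairs=npairs,
        frac_bnti_above_2=above,
        frac_bnti_within=within,
        frac_bnti_below_minus2=below,
    )
    dm_obs = DistanceMatrix(obs - np.diag(np.diag(obs)), ids=sample_ids)
    return BntiResult(pairs, dm_obs, summary, n_null, seed)


def mean_nti_test(nti_values) -> tuple[float, float]:
    """One-sample two-sided t-test of the mean NTI against 0."""
    vals = np.asarray(nti_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise DegenerateInputError("mean NTI test needs >= 2 finite values")
    if np.all(vals == vals[0]):
        raise DegenerateInputError("mean NTI test undefined: zero variance")
    t, p = stats.ttest_1samp(vals, 0.0)
    return float(t), float(p)


def summarize_assembly(nti_table: pd.DataFrame, bnti_result: BntiResult) -> AssemblySummary:
    """Combine per-sample NTI and per-pair betaNTI into one assembly verdict."""
    s = bnti_result.summary
    vals = nti_table.loc[nti_table["defined"], "nti"]
    t, p = mean_nti_test(vals.to_numpy())
    return AssemblySummary(
        n_pairs=s.n_pairs,
        frac_bnti_above_2=s.frac_bnti_above_2,
        frac_bnti_within=s.frac_bnti_within,
        frac_bnti_below_minus2=s.frac_bnti_below_minus2,
        mean_nti=float(vals.mean()),
        nti_t_statistic=t,
        nti_t_pvalue=p,
    )
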