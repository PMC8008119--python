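"""Distance-based permutation inference.

One-factor PerMANOVA (pseudo-F and R^2 from squared-distance partitioning),
PERMDISP (homogeneity of multivariate dispersions around group centroids or
spatial medians), Mantel and partial Mantel correlations, and environmental
vector fitting onto ordination axes. All p-values use the
(1 + hits) / (1 + n_perm) convention and are reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from skbio.stats.distance import DistanceMatrix

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int | None
    method: str
    effect_size: float | None = None  # R^2 where defined

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise ValueError(f"{self.method}: non-finite statistic")


def _group_indices(groups) -> tuple[np.ndarray, list]:
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    codes = np.array([labels.index(g) for g in groups])
    return codes, labels


# ---------------------------------------------------------------------------
# PerMANOVA


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """One-factor permutational multivariate analysis of variance.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)); R^2 = SS_between/SS_total;
    p by permuting sample labels.
    """
    codes, labels = _group_indices(groups)
    a = len(labels)
    if a < 2:
        raise ValueError("PerMANOVA requires >= 2 groups")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = len(codes)
    if n != dm.shape[0]:
        raise ValueError("groups length does not match distance matrix")
    d2 = dm.data**2

    def pseudo_f(c):
        ss_total, ss_within = _permanova_ss(d2, c, a)
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_between / ss_total

    f_obs, r2 = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_p, _ = pseudo_f(rng.permutation(codes))
        if f_p >= f_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermutationTestResult(f_obs, p, n_perm, seed, "permanova", effect_size=r2)


# ---------------------------------------------------------------------------
# PERMDISP


def _full_embedding(dm: DistanceMatrix):
    """PCoA embedding keeping real and imaginary axes separately."""
    d = dm.data
    a = -0.5 * d**2
    centred = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigvals, eigvecs = np.linalg.eigh(centred)
    scale = max(np.abs(eigvals).max(), 1.0)
    pos = eigvals > 1e-10 * scale
    neg = eigvals < -1e-10 * scale
    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return real, imag


def _geometric_median(x: np.ndarray, n_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld iteration for the spatial (L1) median."""
    if x.shape[0] == 1:
        return x[0]
    m = x.mean(axis=0)
    for _ in range(n_iter):
        d = np.linalg.norm(x - m, axis=1)
        if np.any(d < 1e-12):
            return m
        w = 1.0 / d
        new = (x * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def permdisp(
    dm: DistanceMatrix,
    groups,
    center: str = "median",
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of multivariate dispersion homogeneity.

    Samples are embedded by PCoA; each sample's distance to its group centre
    (spatial median by default, centroid optionally) is computed with
    imaginary-axis contributions subtracted in the squared distances; the
    ANOVA F on those distances is assessed by permuting them across groups.
    Groups of size 1 are excluded with a warning.
    """
    if center not in ("median", "centroid"):
        raise ValueError("center must be 'median' or 'centroid'")
    codes, labels = _group_indices(groups)
    sizes = np.bincount(codes, minlength=len(labels))
    singletons = [labels[g] for g in range(len(labels)) if sizes[g] == 1]
    if singletons:
        logger.warning("permdisp: excluding singleton group(s) %s", singletons)
        keep = np.isin(codes, [g for g in range(len(labels)) if sizes[g] > 1])
        ids = [i for i, k in zip(dm.ids, keep) if k]
        dm = dm.filter(ids)
        codes, labels = _group_indices(np.asarray(groups)[keep])
    if len(labels) < 2:
        raise DegenerateInputError("permdisp needs >= 2 groups of size > 1")
    real, imag = _full_embedding(dm)
    dists = np.empty(len(codes))
    for g in range(len(labels)):
        idx = np.flatnonzero(codes == g)
        if center == "centroid":
            cr = real[idx].mean(axis=0)
            ci = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        else:
            cr = _geometric_median(real[idx])
            ci = _geometric_median(imag[idx]) if imag.size else np.zeros(0)
        sq = ((real[idx] - cr) ** 2).sum(axis=1)
        if imag.size:
            sq = sq - ((imag[idx] - ci) ** 2).sum(axis=1)
        dists[idx] = np.sqrt(np.clip(sq, 0.0, None))

    def anova_f(z, c):
        grand = z.mean()
        ss_b = sum(
            np.sum(c == g) * (z[c == g].mean() - grand) ** 2 for g in range(len(labels))
        )
        ss_w = sum(np.sum((z[c == g] - z[c == g].mean()) ** 2) for g in range(len(labels)))
        df_b, df_w = len(labels) - 1, len(z) - len(labels)
        if ss_w == 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    f_obs = anova_f(dists, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if anova_f(dists, rng.permutation(codes)) >= f_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermutationTestResult(float(f_obs), p, n_perm, seed, f"permdisp_{center}")


# ---------------------------------------------------------------------------
# Mantel / partial Mantel


def _prep_matrix(dm: DistanceMatrix, method: str) -> np.ndarray:
    d = dm.data.copy()
    if method == "spearman":
        tri = squareform(d, checks=False)
        ranked = stats.rankdata(tri)
        d = squareform(ranked, checks=False)
    return d


def _tri(d: np.ndarray) -> np.ndarray:
    return d[np.triu_indices(d.shape[0], 1)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise DegenerateInputError("Mantel undefined for a constant matrix")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "pearson",
) -> PermutationTestResult:
    """Mantel correlation between two distance matrices.

    Pearson (or Spearman, via rank-transformed entries) correlation of the
    lower-triangle entries; one-tailed (greater) p by permuting the rows and
    columns of the second matrix jointly.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if list(dm1.ids) != list(dm2.ids):
        raise ValueError("distance matrices must share identical ids in order")
    d1 = _prep_matrix(dm1, method)
    d2 = _prep_matrix(dm2, method)
    x = _tri(d1)
    r_obs = _pearson(x, _tri(d2))
    rng = np.random.default_rng(seed)
    n = d1.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pearson(x, _tri(d2[np.ix_(perm, perm)])) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermutationTestResult(r_obs, p, n_perm, seed, f"mantel_{method}")


def _residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    z0 = z - z.mean()
    denom = np.dot(z0, z0)
    if denom == 0:
        return y - y.mean()
    beta = np.dot(y - y.mean(), z0) / denom
    return y - y.mean() - beta * z0


def partial_mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    dm3: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "pearson",
) -> PermutationTestResult:
    """Partial Mantel correlation r(D1, D2 | D3).

    Both D1 and D2 entries are residualized on D3; the residual correlation
    is tested by permuting the rows/columns of D2 (simple method). If D1
    carries no variance beyond D3 the partial r is 0 by convention.
    """
    for other in (dm2, dm3):
        if list(dm1.ids) != list(other.ids):
            raise ValueError("distance matrices must share identical ids in order")
    d1 = _prep_matrix(dm1, method)
    d2 = _prep_matrix(dm2, method)
    d3 = _prep_matrix(dm3, method)
    x = _residualize(_tri(d1), _tri(d3))
    z = _tri(d3)

    def partial_r(y_tri):
        y = _residualize(y_tri, z)
        sx, sy = x.std(), y.std()
        if sx < 1e-12 or sy < 1e-12:
            return 0.0
        return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))

    r_obs = partial_r(_tri(d2))
    rng = np.random.default_rng(seed)
    n = d1.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if partial_r(_tri(d2[np.ix_(perm, perm)])) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermutationTestResult(r_obs, p, n_perm, seed, f"partial_mantel_{method}")


# ---------------------------------------------------------------------------
# Environmental vector fitting


def envfit_vectors(
    ordination,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Fit numeric variables onto ordination axes.

    Each variable is regressed on the first ``n_axes`` axis scores; r^2 is the
    fitted-variance fraction, the direction is the unit-norm coefficient
    vector, and p comes from permuting the variable across samples.
    """
    scores = ordination.coordinates.iloc[:, :n_axes].to_numpy()
    scores = scores - scores.mean(axis=0)
    rng = np.random.default_rng(seed)
    rows = []
    for name in variables.columns:
        v = variables[name].to_numpy(dtype=float)
        if np.std(v) == 0:
            raise DegenerateInputError(f"envfit: variable {name!r} is constant")
        v0 = v - v.mean()

        def r2_of(vec):
            beta, *_ = np.linalg.lstsq(scores, vec, rcond=None)
            fitted = scores @ beta
            return float(np.sum(fitted**2) / np.sum(vec**2)), beta

        r2_obs, beta = r2_of(v0)
        direction = beta / np.linalg.norm(beta) if np.linalg.norm(beta) > 0 else beta
        hits = 0
        for _ in range(n_perm):
            r2_p, _ = r2_of(rng.permutation(v0))
            if r2_p >= r2_obs:
                hits += 1
        row = {"variable": name, "r2": r2_obs, "p_value": (1 + hits) / (n_perm + 1)}
        for k in range(n_axes):
            row[f"direction_{k+1}"] = direction[k]
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
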