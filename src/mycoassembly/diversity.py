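"""Alpha-diversity summaries and univariate group comparisons.

Per-sample OTU richness, sample-based accumulation curves (exact
hypergeometric expectation or random permutations), the Kruskal-Wallis test
with Conover-Iman post-hoc comparisons and a compact letters display, and the
shared/unique OTU partition behind Venn-style summaries.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import OtuTable
from .preference import fdr_adjust  # BH adjustment shared across modules

logger = logging.getLogger(__name__)


def richness(table: OtuTable, warn_unrarefied: bool = True) -> pd.Series:
    """Number of OTUs with count > 0 per sample."""
    sums = table.sample_sums()
    if warn_unrarefied and sums.nunique() > 1:
        warnings.warn(
            "richness computed on a table with unequal sample depths; "
            "rarefy first for comparable values",
            UserWarning,
            stacklevel=2,
        )
    return (table.to_dataframe() > 0).sum(axis=1).rename("richness")


def accumulation_curve(
    table: OtuTable,
    method: str = "exact",
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expected OTU richness as samples are added.

    ``exact`` uses the hypergeometric expectation
    E[S_k] = sum_j (1 - C(n - m_j, k)/C(n, k)) where m_j is the number of
    samples containing OTU j; ``random`` averages over permuted sample
    orderings and also returns the across-permutation standard deviation.
    """
    if method not in ("exact", "random"):
        raise ValueError(f"method must be 'exact' or 'random', got {method!r}")
    presence = table.counts > 0
    n = presence.shape[0]
    ks = np.arange(1, n + 1)
    if method == "exact":
        m = presence.sum(axis=0)  # samples containing each OTU

        def log_comb(a, b):
            return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

        mean = np.empty(n)
        for idx, k in enumerate(ks):
            with np.errstate(invalid="ignore"):
                log_absent = np.where(
                    n - m >= k, log_comb(n - m, k) - log_comb(n, k), -np.inf
                )
            mean[idx] = np.sum(1.0 - np.exp(log_absent))
        return pd.DataFrame({"samples": ks, "mean_richness": mean})
    if n_perm < 1:
        raise ValueError("random method requires n_perm >= 1")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm, n))
    for p in range(n_perm):
        order = rng.permutation(n)
        seen = np.cumsum(presence[order], axis=0) > 0
        curves[p] = seen.sum(axis=1)
    return pd.DataFrame(
        {
            "samples": ks,
            "mean_richness": curves.mean(axis=0),
            "sd_richness": curves.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(n),
        }
    )


@dataclasses.dataclass
class GroupTestResult:
    """Omnibus statistic plus post-hoc pairwise table and letters display."""

    statistic: float
    df: int
    p_value: float
    group_sizes: dict[str, int]
    posthoc: pd.DataFrame | None = None
    letters: dict[str, str] | None = None


def _ranks_and_ties(values: np.ndarray):
    ranks = stats.rankdata(values)
    n = len(values)
    # tie-corrected total rank variance
    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4) / (n - 1)
    return ranks, s2


def kruskal_wallis(values, groups) -> GroupTestResult:
    """Kruskal-Wallis rank-sum test with tie correction.

    Defined as H = 0 when every observation is identical (fully tied).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    sizes = {g: int(np.sum(groups == g)) for g in labels}
    if any(s == 0 for s in sizes.values()):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return GroupTestResult(0.0, len(labels) - 1, 1.0, sizes)
    samples = [values[groups == g] for g in labels]
    h, p = stats.kruskal(*samples)
    return GroupTestResult(float(h), len(labels) - 1, float(p), sizes)


def conover_posthoc(values, groups, p_adjust: str | None = None, alpha: float = 0.05):
    """Conover-Iman pairwise comparisons following Kruskal-Wallis.

    t statistics on mean ranks with the pooled tie-corrected rank variance,
    on N - k degrees of freedom; two-sided p, optionally BH/Holm adjusted.
    Returns (pairwise DataFrame, letters display).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    sizes = np.array([np.sum(groups == g) for g in labels])
    if (sizes == 0).any():
        raise ValueError("empty group")
    n = len(values)
    k = len(labels)
    ranks, s2 = _ranks_and_ties(values)
    mean_ranks = np.array([ranks[groups == g].mean() for g in labels])
    h = kruskal_wallis(values, groups).statistic
    # pooled variance shrinks when H is large (Conover & Iman 1979)
    scale = s2 * (n - 1 - h) / (n - k) if n > k else np.nan
    rows = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(labels), 2):
        se = np.sqrt(max(scale, 0.0) * (1 / sizes[i] + 1 / sizes[j]))
        t = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), df=n - k) if se > 0 else 1.0
        rows.append({"group_1": gi, "group_2": gj, "statistic": t, "p_raw": min(p, 1.0)})
    tab = pd.DataFrame(rows)
    if p_adjust is None:
        tab["p_adjusted"] = tab["p_raw"]
    elif p_adjust == "bh":
        tab["p_adjusted"] = fdr_adjust(tab["p_raw"].to_numpy())
    elif p_adjust == "holm":
        tab["p_adjusted"] = _holm(tab["p_raw"].to_numpy())
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    letters = letters_display(labels, tab, alpha=alpha)
    return tab, letters


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def letters_display(labels, pairwise: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Compact letters: groups sharing no letter differ significantly.

    Letters are the maximal cliques of the non-significance graph, assigned
    in group order (greedy insertion; ties broken by group order).
    """
    labels = list(labels)
    idx = {g: i for i, g in enumerate(labels)}
    n = len(labels)
    adj = np.eye(n, dtype=bool)
    for _, row in pairwise.iterrows():
        ns = row["p_adjusted"] >= alpha
        i, j = idx[row["group_1"]], idx[row["group_2"]]
        adj[i, j] = adj[j, i] = ns
    cliques: list[frozenset] = []

    def bron_kerbosch(r, p, x):
        if not p and not x:
            cliques.append(frozenset(r))
            return
        for v in sorted(p):
            nv = {u for u in range(n) if adj[v, u] and u != v}
            bron_kerbosch(r | {v}, p & nv, x & nv)
            p = p - {v}
            x = x | {v}

    bron_kerbosch(set(), set(range(n)), set())
    cliques.sort(key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for letter, clique in zip(alphabet, cliques):
        for i in sorted(clique):
            out[labels[i]] += letter
    return out


def otu_partition(table: OtuTable, groups) -> dict[frozenset, int]:
    """Count OTUs present in exactly each subset of groups (Venn partition).

    ``groups`` maps every sample id to exactly one group label. Cell counts
    sum to the number of OTUs present anywhere.
    """
    groups = dict(groups) if not isinstance(groups, pd.Series) else groups.to_dict()
    unassigned = [s for s in table.sample_ids if s not in groups]
    if unassigned:
        raise ValueError(f"samples without a group: {unassigned}")
    df = table.to_dataframe()
    membership = pd.Series({s: groups[s] for s in table.sample_ids})
    present_in = {}
    for g in pd.unique(membership):
        sub = df.loc[membership[membership == g].index]
        present_in[g] = set(sub.columns[(sub > 0).any(axis=0)])
    partition: dict[frozenset, int] = {}
    all_groups = list(present_in)
    observed = set().union(*present_in.values()) if present_in else set()
    for otu in observed:
        key = frozenset(g for g in all_groups if otu in present_in[g])
        partition[key] = partition.get(key, 0) + 1
    return partition
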