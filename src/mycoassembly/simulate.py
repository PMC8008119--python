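"""Seeded synthetic-data generators emulating the study design.

Defaults mirror the field study the package is built around: 63 root-tip
samples of 5 host species across 8 sites on a ~1,900 km transect, rarefied
to 1,055 reads, ~288 OTUs with a lognormal (sigma = 1.5) metacommunity
abundance distribution whose 30 most abundant OTUs hold ~70% of reads.

Three community generators cover the downstream stages:

* :func:`gen_neutral_table` draws communities from the Sloan neutral
  sampling model with known migration rate m (calibration/recovery for the
  neutral fit and the betaNTI null).
* :func:`gen_host_structured_table` mixes a shared OTU pool with
  host-specific pools at a tunable preference strength, optionally assigning
  host pools to clades of a supplied tree (habitat filtering), with
  Dirichlet-multinomial sampling and distance-decay site structure.
* :func:`gen_spatial_sites` lays sites on a transect with exponential
  distance decay of community similarity.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import dataclasses
import random

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .core import OtuTable, Phylogeny, SampleMetadata
from .errors import ConfigError

TRANSECT_KM = 1900.0


@dataclasses.dataclass
class SimulationConfig:
    """Study-design knobs for the community generators."""

    seed: int
    n_samples: int = 63
    n_otus: int = 288
    depth: int = 1055
    lognormal_mean: float = 0.0
    lognormal_sigma: float = 1.5
    migration_rate: float = 0.1
    n_hosts: int = 5
    n_sites: int = 8
    preference_strength: float = 0.5
    clade_filtering: bool = False
    spatial_decay: float = 0.001  # per km
    dirichlet_concentration: float = 50.0

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not 0 < self.migration_rate <= 1:
            raise ConfigError("migration_rate must lie in (0, 1]")
        if not 0 <= self.preference_strength <= 1:
            raise ConfigError("preference_strength must lie in [0, 1]")
        if self.spatial_decay < 0:
            raise ConfigError("spatial_decay must be >= 0")
        if self.depth < 1 or self.n_otus < 2 or self.n_samples < 1:
            raise ConfigError("n_samples, n_otus, depth must be positive")


def gen_tree(n_tips: int, seed: int, ultrametric: bool = True) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` labelled tips.

    The ultrametric option rescales so every root-to-tip depth equals 1.
    """
    if n_tips < 3:
        raise ValueError("gen_tree requires n_tips >= 3")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU{i+1}"
    if ultrametric:
        tree.seed_node.edge.length = 0.0
        depths = {
            leaf: leaf.distance_from_root() for leaf in tree.leaf_node_iter()
        }
        max_depth = max(depths.values())
        for leaf, depth in depths.items():
            leaf.edge.length += max_depth - depth
        # normalize total depth to 1
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= max_depth
    return Phylogeny(tree)


def metacommunity_shares(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Lognormal relative abundances normalised to the simplex."""
    raw = rng.lognormal(config.lognormal_mean, config.lognormal_sigma, config.n_otus)
    return raw / raw.sum()


def gen_neutral_table(config: SimulationConfig) -> OtuTable:
    """Communities from the Sloan neutral sampling model with known m.

    Per sample, each OTU's local relative abundance is drawn from
    Beta(N*m*p, N*m*(1-p)) and the draws are normalised to the simplex. The
    local community of N individuals is then realised directly from those
    proportions: counts = floor(N*x), with the remaining reads allocated to
    already-present OTUs by largest fractional part. Every row sums exactly
    to N and an OTU is detected precisely when its proportion clears the
    model's detection limit of one read (d = 1/N); a further binomial
    read-resampling stage would double-count sampling noise and bias the
    fitted migration rate upward.
    """
    rng = np.random.default_rng(config.seed)
    p = metacommunity_shares(config, rng)
    N, m = config.depth, config.migration_rate
    a = np.clip(N * m * p, 1e-8, None)
    b = np.clip(N * m * (1 - p), 1e-8, None)
    counts = np.empty((config.n_samples, config.n_otus), dtype=np.int64)
    for s in range(config.n_samples):
        x = rng.beta(a, b)
        total = x.sum()
        if total == 0:
            x, total = p, 1.0
        x = x / total
        base = np.floor(N * x).astype(np.int64)
        deficit = N - int(base.sum())
        if deficit > 0:
            frac = N * x - base
            present = base > 0
            if present.any():
                frac = np.where(present, frac, -1.0)  # keep detection at 1/N
            order = np.argsort(-frac, kind="stable")
            extra = np.zeros(config.n_otus, dtype=np.int64)
            remaining = deficit
            while remaining > 0:
                take = min(remaining, order.size)
                extra[order[:take]] += 1
                remaining -= take
            base = base + extra
        counts[s] = base
    return OtuTable(counts, otu_ids=[f"OTU{i+1}" for i in range(config.n_otus)]).drop_empty_otus()


def _two_deep_clades(tree: Phylogeny) -> list[list[str]]:
    """Tip labels of the most balanced deep bipartition of the tree.

    Pure-birth root splits are frequently very lopsided (e.g. 97:3), which
    leaves one "clade" with too few taxa to carry a habitat-filtering
    signal; instead, the internal edge whose clade best bisects the tip set
    defines the two pools (the clade below it vs everything else)."""
    all_tips = set(tree.tip_labels)
    best, best_score = None, -1
    for node in tree.dendropy_tree.preorder_internal_node_iter():
        if node is tree.dendropy_tree.seed_node:
            continue
        clade = [leaf.taxon.label for leaf in node.leaf_iter()]
        score = min(len(clade), len(all_tips) - len(clade))
        if score > best_score:
            best, best_score = clade, score
    if best is None or best_score == 0:
        raise ValueError("tree has no internal bipartition")
    rest = sorted(all_tips - set(best))
    groups = [best, rest]
    groups.sort(key=len, reverse=True)
    return groups


def gen_spatial_sites(
    n_sites: int, decay: float, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Site coordinates on a ~1,900 km transect plus the expected community
    similarity matrix exp(-decay * distance_km)."""
    if n_sites < 3:
        raise ValueError("gen_spatial_sites requires n_sites >= 3")
    if decay < 0:
        raise ValueError("decay must be >= 0")
    rng = np.random.default_rng(seed)
    # evenly spaced along a meridian with jitter; 1 deg latitude ~ 111.195 km
    span_deg = TRANSECT_KM / 111.19492664455873
    lats = 40.0 + np.linspace(0, span_deg, n_sites)
    lats += rng.normal(0, span_deg / (10 * n_sites), n_sites)
    lons = np.full(n_sites, 115.0) + rng.normal(0, 0.1, n_sites)
    coords = pd.DataFrame(
        {"latitude": lats, "longitude": lons},
        index=[f"site{i+1}" for i in range(n_sites)],
    )
    km = 111.19492664455873 * np.abs(lats[:, None] - lats[None, :])
    similarity = np.exp(-decay * km)
    return coords, similarity


def gen_host_structured_table(
    config: SimulationConfig, tree: Phylogeny | None = None
) -> tuple[OtuTable, SampleMetadata]:
    """Host-structured communities with tunable preference strength.

    Each host's mean profile mixes a shared metacommunity pool with a
    host-specific pool (mixture weight = preference strength). With
    ``clade_filtering`` the host-specific pools concentrate on the two deep
    clades of ``tree`` (hosts alternate between clades), producing the
    between-clade turnover that habitat filtering creates. Counts are
    Dirichlet-multinomial at the configured depth; samples are spread over
    sites on the transect and site profiles mix with exponential distance
    decay.
    """
    if config.n_hosts < 2:
        raise ConfigError("n_hosts must be >= 2")
    rng = np.random.default_rng(config.seed)
    n_otus = tree.n_tips if tree is not None else config.n_otus
    otu_ids = tree.tip_labels if tree is not None else [f"OTU{i+1}" for i in range(n_otus)]
    cfg = dataclasses.replace(config, n_otus=n_otus)
    shared = metacommunity_shares(cfg, rng)

    host_pools = np.empty((config.n_hosts, n_otus))
    if config.clade_filtering:
        if tree is None:
            raise ConfigError("clade_filtering requires a tree")
        clades = _two_deep_clades(tree)
        index = {o: i for i, o in enumerate(otu_ids)}
        for h in range(config.n_hosts):
            members = [index[o] for o in clades[h % 2]]
            pool = np.full(n_otus, 1e-6)
            pool[members] = rng.dirichlet(np.ones(len(members)))
            host_pools[h] = pool / pool.sum()
    else:
        for h in range(config.n_hosts):
            raw = rng.lognormal(config.lognormal_mean, config.lognormal_sigma, n_otus)
            mask = rng.random(n_otus) < 0.3  # each host prefers a sparse OTU subset
            raw = raw * np.where(mask, 1.0, 1e-3)
            host_pools[h] = raw / raw.sum()

    w = config.preference_strength
    host_means = (1 - w) * shared + w * host_pools

    coords, _ = gen_spatial_sites(config.n_sites, config.spatial_decay, config.seed + 1)
    site_ids = list(coords.index)
    site_pos = coords["latitude"].to_numpy() * 111.19492664455873
    # site-specific multiplicative field: Ornstein-Uhlenbeck along the
    # transect, so corr(site i, site j) = exp(-decay * |pos_i - pos_j|)
    order = np.argsort(site_pos)
    site_effects = np.empty((config.n_sites, n_otus))
    prev = rng.normal(0, 1, n_otus)
    site_effects[order[0]] = prev
    for a, b in zip(order[:-1], order[1:]):
        rho = np.exp(-config.spatial_decay * abs(site_pos[b] - site_pos[a]))
        prev = rho * prev + np.sqrt(max(1 - rho**2, 0)) * rng.normal(0, 1, n_otus)
        site_effects[b] = prev

    hosts = [f"host{h+1}" for h in range(config.n_hosts)]
    sample_hosts = [hosts[i % config.n_hosts] for i in range(config.n_samples)]
    sample_sites = [site_ids[(i // config.n_hosts) % config.n_sites] for i in range(config.n_samples)]
    counts = np.empty((config.n_samples, n_otus), dtype=np.int64)
    for i in range(config.n_samples):
        h = hosts.index(sample_hosts[i])
        s = site_ids.index(sample_sites[i])
        mean = host_means[h] * np.exp(0.5 * site_effects[s])
        mean = mean / mean.sum()
        alpha = np.clip(config.dirichlet_concentration * mean, 1e-6, None)
        profile = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(config.depth, profile)
    sample_ids = [f"S{i+1:02d}" for i in range(config.n_samples)]
    table = OtuTable(counts, sample_ids, otu_ids)
    env = pd.DataFrame(
        {
            "host_species": sample_hosts,
            "site": sample_sites,
            "latitude": [coords.loc[s, "latitude"] for s in sample_sites],
            "longitude": [coords.loc[s, "longitude"] for s in sample_sites],
        },
        index=sample_ids,
    )
    site_env = {}
    for j, s in enumerate(site_ids):
        lat = coords.loc[s, "latitude"]
        site_env[s] = {
            "altitude": 800 + 40 * j + rng.normal(0, 20),
            "MAT": 8.0 - 0.45 * (lat - 40.0) + rng.normal(0, 0.3),
            "MAP": 420.0 - 8.0 * (lat - 40.0) + rng.normal(0, 15),
            "N": max(rng.normal(2.0, 0.5), 0.1),
            "P": max(rng.normal(0.6, 0.15), 0.05),
            "Ca": max(rng.normal(6.0, 1.5), 0.5),
            "Mg": max(rng.normal(2.5, 0.6), 0.2),
        }
        site_env[s]["NP_ratio"] = site_env[s]["N"] / site_env[s]["P"]
    for col in ("altitude", "MAT", "MAP", "N", "P", "NP_ratio", "Ca", "Mg"):
        env[col] = [site_env[s][col] for s in sample_sites]
    return table, SampleMetadata(env)


def default_study_fixture(seed: int):
    """The default 63-sample study-shaped dataset: tree, table, metadata.

    The OTU tree covers the generated OTU pool; communities are
    host-structured at moderate preference strength without clade filtering.
    """
    config = SimulationConfig(seed=seed)
    tree = gen_tree(config.n_otus, seed=seed + 101)
    table, meta = gen_host_structured_table(config, tree)
    return config, tree, table, meta
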