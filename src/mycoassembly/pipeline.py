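"""End-to-end orchestration of the community-assembly analysis.

Runs the full analysis shape on any conforming dataset: rarefaction ->
alpha-diversity group tests -> host/spatial eigenvectors -> Bray-Curtis on
Hellinger data -> PerMANOVA / PERMDISP / envfit / Mantel -> NTI / betaNTI ->
Sloan neutral fit -> single-site preference analysis, writing a TSV/JSON
bundle whose content is byte-identical across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assembly, diversity, io, neutral, ordination, permtests, preference
from .core import OtuTable, Phylogeny, SampleMetadata
from .errors import ConfigError, DegenerateInputError
from .transforms import bray_curtis, geographic_distances, rarefy, transform

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    """Inputs, sizes and seeds for one pipeline run."""

    otu_table: str | None = None
    otu_tree: str | None = None
    host_tree: str | None = None
    metadata: str | None = None
    out_dir: str = "results"
    depth: int = 1055
    seed: int = 0
    n_perm: int = 999
    n_null: int = 999
    n_rand: int = 1000
    preference_site: str | None = None
    min_occurrence: int = 3
    conover_adjust: str | None = "bh"

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        for path in (self.otu_table, self.otu_tree, self.host_tree, self.metadata):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input file does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs before it are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_json(obj, path: Path):
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _perm_result_dict(res: permtests.PermutationTestResult) -> dict:
    return {
        "statistic": res.statistic,
        "effect_size_r2": res.effect_size,
        "p_value": res.p_value,
        "n_perm": res.n_perm,
        "seed": res.seed,
        "method": res.method,
    }


def load_inputs(config: RunConfig):
    """Read the four inputs declared in the config (all must be set)."""
    missing = [
        name
        for name in ("otu_table", "otu_tree", "host_tree", "metadata")
        if getattr(config, name) is None
    ]
    if missing:
        raise ConfigError(f"config missing input paths: {missing}")
    table = io.read_otu_table(config.otu_table)
    otu_tree = io.read_newick(config.otu_tree)
    host_tree = io.read_newick(config.host_tree)
    meta = io.read_metadata(config.metadata)
    return table, otu_tree, host_tree, meta


def host_distance_matrix(host_tree: Phylogeny, meta: SampleMetadata, sample_ids):
    """Sample-level distance matrix of host cophenetic distances."""
    from skbio.stats.distance import DistanceMatrix

    coph = host_tree.cophenetic()
    hosts = meta.aligned(sample_ids)["host_species"]
    ids = list(coph.ids)
    pos = {h: ids.index(h) for h in hosts.unique()}
    n = len(sample_ids)
    d = np.zeros((n, n))
    hv = [pos[h] for h in hosts]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = coph.data[hv[i], hv[j]]
    return DistanceMatrix(d, ids=list(sample_ids))


def run_pipeline(
    config: RunConfig,
    table: OtuTable | None = None,
    otu_tree: Phylogeny | None = None,
    host_tree: Phylogeny | None = None,
    meta: SampleMetadata | None = None,
) -> dict:
    """Execute every analysis stage and write the report bundle.

    In-memory objects can be passed directly (as the CLI's simulate path
    does); otherwise they are read from the config's input paths. Returns the
    machine-readable report dict (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if table is None or otu_tree is None or host_tree is None or meta is None:
        table, otu_tree, host_tree, meta = load_inputs(config)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "parameters": {
            "depth": config.depth,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "n_null": config.n_null,
            "n_rand": config.n_rand,
            "min_occurrence": config.min_occurrence,
            "conover_adjust": config.conover_adjust,
        },
        "stages": {},
        "notes": {
            "random_forest": "variable-importance ranking is an external, "
            "optional step not computed by this pipeline"
        },
    }

    def stage(name):
        def decorator(fn):
            try:
                logger.info("stage %s", name)
                report["stages"][name] = fn()
                _write_json(report, out / "report.json")
            except Exception as exc:
                _write_json(report, out / "report.json")
                raise StageError(name, exc) from exc

        return decorator

    state: dict = {}

    @stage("rarefaction")
    def _():
        rt = rarefy(table, config.depth, seed=config.seed)
        state["table"] = rt
        io.write_otu_table(rt, out / "rarefied_table.tsv")
        return {
            "depth": config.depth,
            "seed": config.seed,
            "n_samples": rt.n_samples,
            "n_otus": rt.n_otus,
        }

    @stage("diversity")
    def _():
        rt = state["table"]
        md = meta.aligned(rt.sample_ids)
        hosts = md["host_species"]
        rich = diversity.richness(rt, warn_unrarefied=False)
        rich.to_frame().to_csv(out / "richness.tsv", sep="\t")
        kw = diversity.kruskal_wallis(rich.to_numpy(), hosts.to_numpy())
        posthoc, letters = diversity.conover_posthoc(
            rich.to_numpy(), hosts.to_numpy(), p_adjust=config.conover_adjust
        )
        posthoc.to_csv(out / "conover_posthoc.tsv", sep="\t", index=False)
        curves = {}
        for host in sorted(hosts.unique()):
            sub = rt.select_samples(list(hosts[hosts == host].index)).drop_empty_otus()
            curves[host] = diversity.accumulation_curve(sub, method="exact")
        pd.concat(curves, names=["host_species", "row"]).to_csv(
            out / "accumulation_curves.tsv", sep="\t"
        )
        partition = diversity.otu_partition(rt, hosts.to_dict())
        part_rows = [
            {"groups": "+".join(sorted(k)), "n_otus": v}
            for k, v in sorted(partition.items(), key=lambda kv: "+".join(sorted(kv[0])))
        ]
        pd.DataFrame(part_rows).to_csv(out / "otu_partition.tsv", sep="\t", index=False)
        return {
            "mean_richness": float(rich.mean()),
            "se_richness": float(rich.std(ddof=1) / np.sqrt(len(rich))),
            "kruskal_wallis": {"H": kw.statistic, "df": kw.df, "p_value": kw.p_value},
            "letters": letters,
        }

    @stage("eigenvectors")
    def _():
        rt = state["table"]
        host_pcoa = ordination.pcoa(host_tree.cophenetic())
        host_pcoa.coordinates.to_csv(out / "host_pcoa_eigenvectors.tsv", sep="\t")
        geo = geographic_distances(meta, rt.sample_ids)
        state["geo"] = geo
        spat = ordination.pcnm(geo)
        spat.coordinates.to_csv(out / "pcnm_eigenvectors.tsv", sep="\t")
        state["host_pcoa"], state["pcnm"] = host_pcoa, spat
        return {
            "host_axes": host_pcoa.n_axes,
            "pcnm_axes": spat.n_axes,
            "pcnm_eigenvalues_all_positive": bool((spat.eigenvalues > 0).all()),
        }

    @stage("dissimilarity")
    def _():
        rt = state["table"]
        bc = bray_curtis(transform(rt, "hellinger"))
        state["bc"] = bc
        io.write_distance_matrix(bc, out / "bray_curtis.tsv")
        return {"transform": "hellinger", "n_samples": bc.shape[0]}

    @stage("community_tests")
    def _():
        rt = state["table"]
        md = meta.aligned(rt.sample_ids)
        hosts = md["host_species"].to_numpy()
        bc = state["bc"]
        res = {}
        res["permanova_host"] = _perm_result_dict(
            permtests.permanova(bc, hosts, n_perm=config.n_perm, seed=config.seed + 1)
        )
        res["permdisp_host"] = _perm_result_dict(
            permtests.permdisp(bc, hosts, n_perm=config.n_perm, seed=config.seed + 2)
        )
        host_d = host_distance_matrix(host_tree, meta, rt.sample_ids)
        geo = state["geo"]
        res["mantel_host_phylogeny"] = _perm_result_dict(
            permtests.mantel(bc, host_d, n_perm=config.n_perm, seed=config.seed + 3)
        )
        res["mantel_geographic"] = _perm_result_dict(
            permtests.mantel(bc, geo, n_perm=config.n_perm, seed=config.seed + 4)
        )
        res["partial_mantel_host_given_geo"] = _perm_result_dict(
            permtests.partial_mantel(
                bc, host_d, geo, n_perm=config.n_perm, seed=config.seed + 5
            )
        )
        res["partial_mantel_geo_given_host"] = _perm_result_dict(
            permtests.partial_mantel(
                bc, geo, host_d, n_perm=config.n_perm, seed=config.seed + 6
            )
        )
        comm_pcoa = ordination.pcoa(bc)
        comm_pcoa.coordinates.to_csv(out / "community_pcoa.tsv", sep="\t")
        env_cols = [
            c
            for c in ("altitude", "MAT", "MAP", "N", "P", "NP_ratio", "Ca", "Mg")
            if c in md.columns
        ]
        variables = md[env_cols].astype(float)
        # host phylogenetic and spatial eigenvectors join the fitted variables
        hp = state["host_pcoa"].coordinates
        for col in hp.columns[: min(3, hp.shape[1])]:
            variables[f"host_{col}"] = [
                hp.loc[h, col] for h in md["host_species"]
            ]
        pcnm_coords = state["pcnm"].coordinates
        for col in pcnm_coords.columns[: min(3, pcnm_coords.shape[1])]:
            variables[col] = pcnm_coords[col].to_numpy()
        variables = variables.loc[:, variables.std() > 0]
        envfit = permtests.envfit_vectors(
            comm_pcoa, variables, n_perm=config.n_perm, seed=config.seed + 7
        )
        envfit.to_csv(out / "envfit.tsv", sep="\t")
        return res

    @stage("phylogenetic_assembly")
    def _():
        rt = state["table"]
        nti_tab = assembly.nti(
            rt, otu_tree, n_null=config.n_null, seed=config.seed + 8
        )
        nti_tab.to_csv(out / "nti_per_sample.tsv", sep="\t")
        bres = assembly.bnti(rt, otu_tree, n_null=config.n_null, seed=config.seed + 9)
        bres.pairs.to_csv(out / "bnti_per_pair.tsv", sep="\t", index=False)
        summ = assembly.summarize_assembly(nti_tab, bres)
        payload = dataclasses.asdict(summ)
        _write_json(payload, out / "assembly_summary.json")
        return payload

    @stage("neutral_model")
    def _():
        fit = neutral.fit_sloan(state["table"])
        fit.per_otu.to_csv(out / "sloan_per_otu.tsv", sep="\t")
        payload = {
            "m": fit.m,
            "r_squared": fit.rsquared,
            "N": fit.N,
            "detection_limit": fit.detection_limit,
            "classes": fit.classify_otus(),
            "interpretation": fit.interpretation(),
        }
        _write_json(payload, out / "sloan_fit.json")
        return payload

    @stage("preference")
    def _():
        rt = state["table"]
        md = meta.aligned(rt.sample_ids)
        site = config.preference_site
        if site is None:
            # default to the site with most host species, ties by sample count
            per_site = md.groupby("site").agg(
                hosts=("host_species", "nunique"), n=("host_species", "size")
            )
            site = per_site.sort_values(["hosts", "n"], ascending=False).index[0]
        im = preference.build_interaction_matrix(rt, meta, site)
        im = preference.filter_abundant(im, config.min_occurrence)
        pres = preference.standardized_preference(
            im, n_rand=config.n_rand, seed=config.seed + 10
        )
        pres.otu_table.to_csv(out / "preference_otus.tsv", sep="\t")
        pres.plant_table.to_csv(out / "preference_plants.tsv", sep="\t")
        pres.pair_table.to_csv(out / "preference_pairs.tsv", sep="\t", index=False)
        pres.two_dp.to_csv(out / "preference_2dp_matrix.tsv", sep="\t")
        otu_sig = pres.otu_table["p_fdr"] < 0.05
        plant_sig = pres.plant_table["p_fdr"] < 0.05
        return {
            "site": site,
            "min_occurrence": config.min_occurrence,
            "n_otus_tested": len(pres.otu_table),
            "n_plants": len(pres.plant_table),
            "frac_otus_significant": float(otu_sig.mean()),
            "frac_plants_significant": float(plant_sig.mean()),
            "frac_pairs_strong": float(pres.pair_table["strong"].mean()),
            "null_model": pres.null_model,
        }

    _write_json(report, out / "report.json")
    recorded = dataclasses.asdict(config)
    recorded.pop("out_dir")  # not part of the analysis; keeps bundles comparable
    io.write_report_tables({}, out, summary={"config": recorded, "seed": config.seed})
    return report
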