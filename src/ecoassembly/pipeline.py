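"""End-to-end orchestration: data → diversity → niche → assembly → NCM →
network → Mantel, from a single configuration.

The configuration either points at input files (OTU table TSV, newick
tree, metadata CSV) or requests the synthetic study layout; all the
analysis constants (|r| > 0.7, q < 0.01, |βNTI| = 2, |RC| = 0.95, 999
randomizations, top-500 taxa) live in one defaults block and are
overridable.  Every stochastic stage receives a seed derived
deterministically from the run seed, so identical configurations produce
byte-identical reports.  The report is validated against a pydantic model
whose JSON schema ships with the package.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from . import diversity as div
from . import envassoc, network, neutral, niche, nullmodels
from .community_data import (
    OtuTable,
    SampleMetadata,
    align,
    cophenetic_distances,
    read_metadata,
    read_newick,
    read_otu_table,
    write_metadata,
    write_newick,
    write_otu_table,
)
from .synthetic import generate_study_layout

logger = logging.getLogger(__name__)

ALL_STAGES = ("diversity", "niche", "assembly", "ncm", "network", "mantel")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the study's constants."""

    seed: int = 0
    out_dir: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    # inputs: either file paths ...
    otu_path: str | None = None
    tree_path: str | None = None
    meta_path: str | None = None
    # ... or the synthetic layout
    simulate: bool = True
    n_taxa: int = 400
    community_size: int = 5000
    n_sites: int = 15
    # analysis constants
    r_threshold: float = 0.7
    q_threshold: float = 0.01
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    n_null: int = 999
    n_perm: int = 999
    top_k: int = 500
    weighted_bnti: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


# --- report schema ---------------------------------------------------------

class TestResultModel(BaseModel):
    statistic: float
    p_value: float
    n_perm: int


class PartitionModel(BaseModel):
    fractions: dict[str, float]
    n_pairs: int
    mean_bnti: float | None = None


class DiversityModel(BaseModel):
    alpha_group_means: dict[str, dict[str, float]]
    kruskal_shannon: dict[str, float]
    permanova: TestResultModel
    anosim: TestResultModel
    beta_dispersion_mean: dict[str, float]


class NicheModel(BaseModel):
    community_breadth_group_means: dict[str, float]
    kruskal: dict[str, float]


class NcmModel(BaseModel):
    m: float
    Nm: float
    r_squared: float
    N: float
    detection_limit: float
    n_taxa: int


class SubnetworkModel(BaseModel):
    n_nodes: int
    n_edges: int
    graph_density: float | None = None
    average_degree: float | None = None


class NetworkModel(BaseModel):
    topology: dict[str, float | int | None]
    n_modules: int
    subnetworks: dict[str, SubnetworkModel]


class MantelModel(BaseModel):
    r: float
    p_value: float
    n_perm: int
    controlled: str | None = None


class PipelineReport(BaseModel):
    config: dict
    seeds: dict[str, int]
    n_samples: int
    n_taxa: int
    diversity: DiversityModel | None = None
    niche: NicheModel | None = None
    assembly: dict[str, PartitionModel] | None = None
    ncm: dict[str, NcmModel] | None = None
    network: NetworkModel | None = None
    mantel: dict[str, MantelModel] | None = None


def _clean(obj):
    """Replace NaN/inf with None so the report is strict JSON."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


# --- stages ----------------------------------------------------------------

def _load_inputs(config: RunConfig):
    if config.otu_path is not None:
        missing = [
            name
            for name, p in (
                ("otu_path", config.otu_path),
                ("meta_path", config.meta_path),
            )
            if p is None
        ]
        if missing:
            raise ValueError(f"missing required inputs: {missing}")
        table = read_otu_table(config.otu_path)
        meta = read_metadata(config.meta_path)
        tree = read_newick(config.tree_path) if config.tree_path else None
        if "assembly" in config.stages and tree is None:
            raise ValueError("assembly stage requires tree_path")
        table, tree, meta = align(table, tree, meta)
        return table, tree, meta
    if not config.simulate:
        raise ValueError("no inputs: set otu_path/... or simulate=True")
    return generate_study_layout(
        seed=config.seed, n_taxa=config.n_taxa,
        N=config.community_size, n_sites=config.n_sites,
    )


def _stage_diversity(table, meta, config, seed):
    groups = meta.groups().loc[table.sample_ids]
    alpha = div.alpha_frame(div.alpha_indices(table))
    means = alpha.groupby(groups).mean()
    h, p = div.kruskal_wallis(alpha["shannon"], groups)
    bc = div.bray_curtis(table)
    per = div.permanova(bc, groups, n_perm=config.n_perm, seed=seed)
    ano = div.anosim(bc, groups, n_perm=config.n_perm, seed=seed + 1)
    disp = div.beta_dispersion(bc, groups)
    return dict(
        alpha_group_means={
            g: {c: float(means.loc[g, c]) for c in means.columns}
            for g in means.index
        },
        kruskal_shannon=dict(H=h, p_value=p),
        permanova=dict(statistic=per.statistic, p_value=per.p_value, n_perm=per.n_perm),
        anosim=dict(statistic=ano.statistic, p_value=ano.p_value, n_perm=ano.n_perm),
        beta_dispersion_mean={g: float(v.mean()) for g, v in disp.items()},
    ), alpha


def _stage_niche(table, meta):
    groups = meta.groups().loc[table.sample_ids]
    b = niche.community_breadth(table)
    h, p = div.kruskal_wallis(b.loc[table.sample_ids], groups)
    return dict(
        community_breadth_group_means={
            str(g): float(b[groups == g].mean()) for g in groups.unique()
        },
        kruskal=dict(H=h, p_value=p),
    ), b


def _stage_assembly(table, tree, meta, config, seed):
    groups = meta.groups().loc[table.sample_ids]
    pairs, partitions = nullmodels.assembly_partition(
        table, tree, groups, n_null=config.n_null,
        weighted=config.weighted_bnti, seed=seed,
        bnti_threshold=config.bnti_threshold, rc_threshold=config.rc_threshold,
    )
    report = {}
    for g, part in partitions.items():
        sub = pairs[(pairs["group"] == g) & np.isfinite(pairs["bnti"])]
        report[g] = dict(
            fractions=part.fractions, n_pairs=part.n_pairs,
            mean_bnti=float(sub["bnti"].mean()),
        )
    return report, pairs


def _stage_ncm(table, meta):
    groups = meta.groups().loc[table.sample_ids]
    out = {}
    for g in groups.unique():
        sub = table.subset(samples=[s for s in table.sample_ids if groups[s] == g])
        fit = neutral.ncm_fit(sub)
        out[str(g)] = dict(
            m=fit.m, Nm=fit.Nm, r_squared=fit.r_squared, N=fit.N,
            detection_limit=fit.detection_limit, n_taxa=fit.n_taxa,
        )
    return out


def _stage_network(table, meta, config, seed):
    groups = meta.groups().loc[table.sample_ids]
    top = network.select_top_taxa(table, k=config.top_k)
    G = network.spearman_edges(
        top, r_threshold=config.r_threshold, q_threshold=config.q_threshold
    )
    topo = network.network_topology(G, seed=seed)
    modules, _ = network.detect_modules(G, seed=seed)
    subs = {}
    for g in groups.unique():
        sg = network.extract_subnetwork(
            G, top, [s for s in table.sample_ids if groups[s] == g]
        )
        subs[str(g)] = dict(
            n_nodes=sg.number_of_nodes(), n_edges=sg.number_of_edges(),
            graph_density=float(
                network.nx.density(sg)) if sg.number_of_nodes() > 1 else None,
            average_degree=(
                2 * sg.number_of_edges() / sg.number_of_nodes()
                if sg.number_of_nodes() else None
            ),
        )
    return dict(
        topology={k: v for k, v in asdict(topo).items()},
        n_modules=len(set(modules.values())) if modules else 0,
        subnetworks=subs,
    ), G


def _stage_mantel(table, meta, config, seed):
    env_ok = meta.frame[meta.env_columns].notna().all(axis=1)
    samples = [s for s in table.sample_ids if env_ok.get(s, False)]
    if len(samples) < 5:
        raise ValueError("mantel stage needs >= 5 samples with complete covariates")
    sub = table.subset(samples=samples)
    sub_meta = meta.subset(samples)
    bc = div.bray_curtis(sub)
    env = envassoc.env_distance(sub_meta)
    geo = envassoc.haversine_matrix(sub_meta.coords(), ids=samples)
    simple = envassoc.mantel(bc, env, n_perm=config.n_perm, seed=seed)
    partial = envassoc.partial_mantel(
        bc, env, geo, n_perm=config.n_perm, seed=seed + 1, controlled_name="geography"
    )
    return dict(
        community_vs_env=dict(r=simple.r, p_value=simple.p_value, n_perm=simple.n_perm),
        community_vs_env_given_geo=dict(
            r=partial.r, p_value=partial.p_value, n_perm=partial.n_perm,
            controlled=partial.controlled,
        ),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in dependency order and return the report.

    With ``config.out_dir`` set, also writes the input data, per-stage
    tables, and ``report.json``.  Raises on the first stage failure, naming
    the stage; partial outputs written so far are preserved.
    """
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    t0 = time.time()
    table, tree, meta = _load_inputs(config)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        s: int(c.generate_state(1)[0] % 2**30)
        for s, c in zip(ALL_STAGES, ss.spawn(len(ALL_STAGES)))
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_otu_table(table, out_dir / "otu_table.tsv")
        write_metadata(meta, out_dir / "metadata.csv")
        if tree is not None:
            write_newick(tree, out_dir / "tree.nwk")
    report: dict = dict(
        config=_clean(asdict(config)),
        seeds=stage_seeds,
        n_samples=table.n_samples,
        n_taxa=table.n_taxa,
    )
    artifacts: dict = {}
    for stage in [s for s in ALL_STAGES if s in config.stages]:
        t = time.time()
        try:
            if stage == "diversity":
                report[stage], artifacts["alpha"] = _stage_diversity(
                    table, meta, config, stage_seeds[stage]
                )
            elif stage == "niche":
                report[stage], artifacts["community_b"] = _stage_niche(table, meta)
            elif stage == "assembly":
                if tree is None:
                    raise ValueError("assembly stage requires a tree")
                report[stage], artifacts["pairs"] = _stage_assembly(
                    table, tree, meta, config, stage_seeds[stage]
                )
            elif stage == "ncm":
                report[stage] = _stage_ncm(table, meta)
            elif stage == "network":
                report[stage], artifacts["graph"] = _stage_network(
                    table, meta, config, stage_seeds[stage]
                )
            elif stage == "mantel":
                report[stage] = _stage_mantel(table, meta, config, stage_seeds[stage])
        except Exception:
            logger.error("stage %r failed", stage)
            raise
        logger.info(
            "stage %s done in %.1fs (seed %d)",
            stage, time.time() - t, stage_seeds[stage],
        )
    report = _clean(report)
    PipelineReport(**report)  # schema validation
    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2, allow_nan=False)
        if "alpha" in artifacts:
            artifacts["alpha"].to_csv(out_dir / "alpha_diversity.tsv", sep="\t")
        if "community_b" in artifacts:
            artifacts["community_b"].to_csv(out_dir / "community_niche_breadth.tsv", sep="\t")
        if "pairs" in artifacts:
            artifacts["pairs"].to_csv(out_dir / "assembly_pairs.tsv", sep="\t", index=False)
        if "graph" in artifacts:
            edges = pd.DataFrame(
                [
                    dict(source=u, target=v, **d)
                    for u, v, d in artifacts["graph"].edges(data=True)
                ]
            )
            edges.to_csv(out_dir / "network_edges.tsv", sep="\t", index=False)
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return report


def report_json(report: dict) -> str:
    """Canonical JSON serialization of a report (sorted keys)."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=False)
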