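"""Config-driven orchestration of the full community-assembly analysis.

One :func:`run_pipeline` call reproduces the analysis flow per season
(wet / dry / all) and per rarity subcommunity (total / dominant / ART / CRT):
alpha diversity, Bray-Curtis matrices, PCoA, ANOSIM between seasons,
distance-decay against dendritic and straight-line distance, per-variable
Mantel tests, the neutral-model fit with partitioning and per-partition
migration rates, and RDA variation partitioning against PCNM and/or AEM
spatial predictors.  Every stochastic step's seed is recorded and the
resolved configuration is embedded in the JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alpha as alpha_mod
from .beta import (
    DistanceMatrix,
    RiverNetwork,
    anosim,
    bray_curtis,
    distance_decay,
    env_distances,
    geo_distances,
    mantel_test,
    pcoa,
    transform_env,
)
from .eigenfunctions import aem_from_network, pcnm_vectors
from .ncm import (
    NcmFitError,
    bootstrap_ci,
    fit_ncm,
    ncm_input_from_table,
    partition_migration_rates,
)
from .otu import OtuTable, hellinger_transform, rarefy, read_otu_table
from .rarity import classify_taxa, select_category
from .otu import relative_abundance
from .varpart import forward_select, varpart2, vif_filter

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

COMMUNITIES = ("total", "dominant", "ART", "CRT")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Fully serialisable description of one pipeline run."""

    otu_table: str | None = None  # TSV path; None if tables passed in memory
    env_table: str | None = None  # TSV, samples x variables
    network_edges: str | None = None
    network_nodes: str | None = None
    season_column: str = "season"
    rare_threshold: float = 1e-4
    abundant_threshold: float = 1e-2
    rarefaction_depth: int | None = None  # None = min sample sum
    rarefaction_seed: int = 1
    ncm_envelope: str = "binomial"
    bootstrap_replicates: int = 1000
    run_bootstrap: bool = False
    permutations: int = 999
    permutation_seed: int = 1
    spatial_mode: str = "both"  # pcnm | aem | both
    forward_selection: bool = True
    output_dir: str = "riverneutral_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _season_tables(table: OtuTable, season_column: str) -> dict[str, OtuTable]:
    out: dict[str, OtuTable] = {"all": table}
    if table.sample_meta is not None and season_column in table.sample_meta.columns:
        for season, idx in table.sample_meta.groupby(season_column).groups.items():
            out[str(season)] = table.subset_samples(list(idx))
    return out


def _community_tables(table: OtuTable) -> dict[str, OtuTable]:
    assign = classify_taxa(relative_abundance(table))
    import warnings as _w

    out = {"total": table}
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        out["dominant"] = select_category(assign, table, "AAT", "CAT", "CRAT")
        out["ART"] = select_category(assign, table, "ART")
        out["CRT"] = select_category(assign, table, "CRT")
    return out, assign


def run_pipeline(
    config: PipelineConfig,
    table: OtuTable | None = None,
    env: pd.DataFrame | None = None,
    network: RiverNetwork | None = None,
) -> dict:
    """Execute every stage and write the report bundle.

    Inputs may be given as paths in the config or directly in memory.  Any
    stage failure aborts with the stage name; partial outputs are retained
    in the output directory.  Returns the JSON-serialisable summary report.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "stages": {},
        "seasons": {},
    }
    t_start = time.time()

    def stage(name):
        logger.info("stage %s", name)
        report["stages"][name] = {"status": "running"}

        class _Ctx:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is None:
                    report["stages"][name] = {
                        "status": "ok",
                        "seconds": round(time.time() - self.t0, 3),
                    }
                    return False
                report["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_report(report, outdir)
                raise PipelineError(name, exc) from exc

        return _Ctx()

    with stage("load"):
        if table is None:
            if config.otu_table is None:
                raise ValueError("no OTU table given (config.otu_table or in-memory)")
            table = read_otu_table(config.otu_table)
        if env is None and config.env_table:
            env = pd.read_csv(config.env_table, sep="\t", index_col=0)
        if network is None and config.network_edges and config.network_nodes:
            network = RiverNetwork.read(config.network_edges, config.network_nodes)

    with stage("rarefy"):
        depth = config.rarefaction_depth or int(table.sample_sums().min())
        table = rarefy(table, depth, seed=config.rarefaction_seed)
        report["rarefaction_depth"] = depth

    have_coords = (
        table.sample_meta is not None
        and {"longitude", "latitude"} <= set(table.sample_meta.columns)
    )

    seasons = _season_tables(table, config.season_column)
    perm_seed = config.permutation_seed

    # season contrast (ANOSIM wet vs dry on the pooled table) per community
    with stage("anosim_seasons"):
        report["anosim_seasons"] = {}
        meta = table.sample_meta
        if meta is not None and config.season_column in meta.columns and (
            meta[config.season_column].nunique() >= 2
        ):
            communities_all, _ = _community_tables(table)
            for cname, ctab in communities_all.items():
                if ctab.n_otus == 0 or (ctab.sample_sums() == 0).any():
                    report["anosim_seasons"][cname] = {"status": "skipped",
                                                       "reason": "empty community"}
                    continue
                dm = bray_curtis(ctab)
                groups = meta.loc[ctab.sample_ids, config.season_column]
                res = anosim(dm, groups, permutations=config.permutations,
                             seed=perm_seed)
                report["anosim_seasons"][cname] = res
        else:
            report["anosim_seasons"] = {"status": "skipped",
                                        "reason": "no season labels"}

    for season, stab in seasons.items():
        sreport: dict = {"n_samples": stab.n_samples, "n_otus": stab.n_otus,
                         "communities": {}}
        report["seasons"][season] = sreport

        with stage(f"{season}/alpha"):
            adf = alpha_mod.alpha_indices(stab)
            adf.to_csv(outdir / f"alpha_{season}.tsv", sep="\t", lineterminator="\n")
            sreport["alpha_mean"] = adf.mean(numeric_only=True).round(6).to_dict()

        with stage(f"{season}/rarity"):
            communities, assign = _community_tables(stab)
            assign.category.rename_axis("otu_id").to_frame().to_csv(
                outdir / f"rarity_{season}.tsv", sep="\t", lineterminator="\n"
            )
            sreport["rarity_counts"] = assign.counts().to_dict()

        geo_euclid = geo_dendritic = None
        if have_coords:
            with stage(f"{season}/geo_distances"):
                meta = stab.sample_meta
                geo_euclid = geo_distances(meta)
                geo_euclid.write(outdir / f"dist_euclid_{season}.tsv")
                if network is not None:
                    geo_dendritic = geo_distances(meta, network=network)
                    geo_dendritic.write(outdir / f"dist_dendritic_{season}.tsv")

        env_season = None
        if env is not None:
            env_season = env.loc[[s for s in stab.sample_ids if s in env.index]]
            if len(env_season) != stab.n_samples:
                env_season = None

        for cname, ctab in communities.items():
            creport: dict = {"n_otus": ctab.n_otus}
            sreport["communities"][cname] = creport
            if ctab.n_otus == 0 or (ctab.sample_sums() == 0).any():
                creport["status"] = "skipped (empty community)"
                continue

            with stage(f"{season}/{cname}/beta"):
                dm = bray_curtis(ctab)
                dm.write(outdir / f"bray_{season}_{cname}.tsv")
                ord_res = pcoa(dm)
                creport["pcoa_axis_variance"] = [
                    round(float(v), 6) for v in ord_res["proportion_explained"][:3]
                ]

            if geo_euclid is not None:
                with stage(f"{season}/{cname}/distance_decay"):
                    sim = DistanceMatrix(1 - dm.values, dm.labels, "bray-curtis-sim")
                    creport["distance_decay"] = {}
                    for tag, gdm in (
                        ("euclid", geo_euclid),
                        ("dendritic", geo_dendritic),
                    ):
                        if gdm is None:
                            creport["distance_decay"][tag] = {"status": "skipped"}
                            continue
                        creport["distance_decay"][tag] = distance_decay(
                            sim, gdm, permutations=config.permutations, seed=perm_seed
                        )
            else:
                creport["distance_decay"] = {"status": "skipped",
                                             "reason": "no coordinates"}

            if env_season is not None:
                with stage(f"{season}/{cname}/mantel_env"):
                    creport["mantel_env"] = {}
                    for col in env_season.columns:
                        edm = env_distances(env_season[[col]])
                        creport["mantel_env"][col] = mantel_test(
                            dm, edm, permutations=config.permutations, seed=perm_seed
                        )
            else:
                creport["mantel_env"] = {"status": "skipped",
                                         "reason": "no environment table"}

            with stage(f"{season}/{cname}/ncm"):
                try:
                    # subcommunity rows no longer sum to the rarefied depth;
                    # the detection limit stays one read at that depth
                    inp = ncm_input_from_table(ctab, N=depth)
                    fit = fit_ncm(inp, envelope=config.ncm_envelope)
                    creport["ncm"] = {
                        "Nm": fit.Nm,
                        "m": fit.m,
                        "r2": fit.r2,
                        "detection_limit": fit.detection_limit,
                        "envelope": fit.envelope,
                        "partition_counts": fit.partition_counts(),
                    }
                    assert abs(fit.m - fit.Nm / fit.N) < 1e-12
                    fit.to_frame(inp).to_csv(
                        outdir / f"ncm_{season}_{cname}.tsv", sep="\t",
                        lineterminator="\n",
                    )
                    if config.run_bootstrap:
                        ci = bootstrap_ci(
                            inp, fit, replicates=config.bootstrap_replicates,
                            seed=perm_seed,
                        )
                        creport["ncm"]["bootstrap"] = ci
                    import warnings as _w

                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        mrates = partition_migration_rates(ctab, fit.partition, N=depth)
                    creport["ncm"]["partition_m"] = {
                        k: (None if pd.isna(v) else float(v))
                        for k, v in mrates["m"].items()
                    }
                except (NcmFitError, ValueError) as err:
                    creport["ncm"] = {"status": "skipped", "reason": str(err)}

            if env_season is not None and geo_euclid is not None:
                with stage(f"{season}/{cname}/varpart"):
                    creport["varpart"] = _varpart_stage(
                        ctab, env_season, geo_euclid, network, config, perm_seed
                    )
            else:
                creport["varpart"] = {"status": "skipped",
                                      "reason": "needs environment and coordinates"}

    report["elapsed_seconds"] = round(time.time() - t_start, 3)
    _write_report(report, outdir)
    return report


def _varpart_stage(ctab, env_season, geo_euclid, network, config, seed) -> dict:
    import warnings as _w

    y = hellinger_transform(ctab).to_numpy()
    xenv = transform_env(env_season)
    xenv = (xenv - xenv.mean()) / xenv.std(ddof=1).replace(0, 1.0)
    n = y.shape[0]
    max_p = max(n - 2, 1)

    out = {}
    spatial_sets = {}
    if config.spatial_mode in ("pcnm", "both"):
        spatial_sets["pcnm"] = pcnm_vectors(geo_euclid).vectors
    if config.spatial_mode in ("aem", "both") and network is not None:
        spatial_sets["aem"] = aem_from_network(
            network, sites=list(ctab.sample_ids)
        ).vectors
    for tag, xspa in spatial_sets.items():
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            xe, removed_env = vif_filter(xenv)
            xs, removed_spa = vif_filter(xspa)
            if config.forward_selection:
                sel_env = forward_select(
                    y, xe.iloc[:, :max_p], permutations=min(config.permutations, 199),
                    seed=seed,
                )
                sel_spa = forward_select(
                    y, xs.iloc[:, :max_p], permutations=min(config.permutations, 199),
                    seed=seed + 1,
                )
            else:
                sel_env = list(xe.columns[:max_p])
                sel_spa = list(xs.columns[:max_p])
            res = varpart2(y, xe[sel_env], xs[sel_spa])
        out[tag] = {
            "fractions": {k: float(v) for k, v in res.fractions.items()},
            "selected_env": sel_env,
            "selected_spatial": sel_spa,
            "vif_removed_env": removed_env,
            "vif_removed_spatial": removed_spa,
            "negative_fractions_flag": res.has_negative_fractions,
        }
    if not spatial_sets:
        out = {"status": "skipped", "reason": "no spatial predictors available"}
    return out


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            v = float(o)
            return None if np.isnan(v) else v
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def _sanitize(obj):
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(_sanitize(report), fh, indent=1, cls=_JsonEncoder, sort_keys=True)
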