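"""End-to-end orchestration: ingest or simulate, then run every analysis stage.

``run_full`` executes, in dependency order: filtering and normalization;
rarefied alpha diversity with two-way ANOVA and longitudinal trend tests;
Bray-Curtis beta diversity with PERMANOVA (seasonal and season-stratified
reach tests) and dispersion homogeneity; distance-decay against dam
counts; per-season Mantel families over environmental variables with
BH-FDR; MRM with spatial plus multivariate environmental distance;
betaNTI/RC_Bray process partitioning per season; Sloan neutral-model
fits per season; and SPEC-OCCU specialists, core sets and detected-set
overlaps. Results are returned as an :class:`AnalysisReport` and
optionally written as a directory of TSVs plus a YAML manifest.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rivasm import assembly, diversity, neutral, simulate, spatial, specocc
from rivasm._seeding import child_seed
from rivasm.tables import (
    CommunityTable,
    filter_otus,
    rarefy,
    read_community_table,
    read_env_table,
    read_metadata,
    read_taxonomy,
    tss_normalize,
)
from rivasm.spatial import read_dam_geometry
from rivasm.trees import prune_to_table, read_tree

__all__ = ["RunConfig", "AnalysisReport", "run_full", "validate_inputs", "load_bundle"]

ENV_VARIABLES = ["Tem", "DO", "pH", "EC", "Chla", "TN", "TP", "NH4", "NO3", "NO2", "COD", "DIN"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Either ``input_dir`` (a fixture bundle directory) or ``preset`` (a
    simulation scenario) must be given. Null/permutation counts and
    thresholds default to the conventional values (999 permutations,
    |betaNTI| = 2, |RC| = 0.95, Spec/Occ = 0.7, rarefaction depth 15000).
    """

    input_dir: str | None = None
    preset: str | None = None
    sim_overrides: dict = field(default_factory=dict)
    rarefaction_depth: int = 15000
    n_perm: int = 999
    bnti_nulls: int = 999
    rc_nulls: int = 999
    bnti_thresh: float = 2.0
    rc_thresh: float = 0.95
    spec_min: float = 0.7
    occ_min: float = 0.7
    core_occ_min: float = 0.7
    env_variables: list = field(default_factory=lambda: list(ENV_VARIABLES))
    seed: int = 0
    out_dir: str | None = None
    stages: tuple = ("alpha", "beta", "spatial", "assembly", "ncm", "specocc")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


@dataclass
class AnalysisReport:
    tables: dict          # name -> DataFrame
    summaries: dict       # name -> dict of scalars
    config: RunConfig
    log: list


def load_bundle(input_dir) -> dict:
    """Read a fixture-bundle directory through the standard readers."""
    p = Path(input_dir)
    bundle = {
        "table": read_community_table(p / "table.tsv"),
        "tree": read_tree(p / "tree.nwk"),
        "metadata": read_metadata(p / "metadata.tsv"),
        "env": read_env_table(p / "env.tsv"),
        "taxonomy": read_taxonomy(p / "taxonomy.tsv"),
        "geometry": read_dam_geometry(p / "dam_geometry.tsv"),
    }
    return bundle


def validate_inputs(bundle: dict, strict: bool = False) -> list:
    """Cross-check registries between table, metadata, tree, taxonomy and
    geometry; returns the list of problems (empty when consistent)."""
    problems = []
    table = bundle["table"]
    meta = bundle["metadata"]
    t_samples = set(table.sample_ids)
    m_samples = set(meta["sample_id"].astype(str))
    for s in sorted(t_samples - m_samples):
        problems.append(f"sample {s} in table but not metadata")
    for s in sorted(m_samples - t_samples):
        problems.append(f"sample {s} in metadata but not table")
    if "tree" in bundle and bundle["tree"] is not None:
        leaves = {t.name for t in bundle["tree"].tips()}
        missing = sorted(set(table.otu_ids) - leaves)
        if missing:
            problems.append(f"{len(missing)} OTUs missing from tree: {missing[:5]}")
    if "taxonomy" in bundle and bundle["taxonomy"] is not None:
        extra = sorted(set(bundle["taxonomy"].index) - set(table.otu_ids))
        if extra:
            problems.append(f"{len(extra)} taxonomy entries not in table")
    if "geometry" in bundle and bundle["geometry"] is not None:
        known = set(bundle["geometry"]["reach"].astype(str))
        bad = sorted(set(meta["reach"].astype(str)) - known)
        if bad:
            problems.append(f"reaches missing from dam geometry: {bad}")
    if strict and problems:
        raise ValueError("input validation failed:\n" + "\n".join(problems))
    return problems


def _season_frame(meta: pd.DataFrame, season: str) -> pd.DataFrame:
    return meta[meta["season"].astype(str) == season]


def run_full(config: RunConfig) -> AnalysisReport:
    """Run the full analysis; see the module docstring for the stages."""
    log = []

    def stage(name):
        log.append({"stage": name, "time": time.time()})

    if config.input_dir is not None:
        bundle = load_bundle(config.input_dir)
        truth = None
    elif config.preset is not None:
        stage("simulate")
        sim_cfg = simulate.preset(
            config.preset, seed=child_seed(config.seed, "simulate"), **config.sim_overrides
        )
        sim = simulate.simulate_survey(sim_cfg)
        bundle = {
            "table": sim["table"],
            "tree": sim["tree"],
            "metadata": sim["metadata"],
            "env": sim["env"],
            "taxonomy": simulate.synthetic_taxonomy(sim["tree"], seed=sim_cfg.seed),
            "geometry": sim["geometry"],
        }
        truth = sim["truth"]
    else:
        raise ValueError("RunConfig needs input_dir or preset")

    problems = validate_inputs(bundle)
    if problems:
        raise ValueError("inconsistent inputs:\n" + "\n".join(problems))

    table: CommunityTable = bundle["table"]
    meta = bundle["metadata"].loc[table.sample_ids]
    seasons = sorted(meta["season"].astype(str).unique())

    stage("filter")
    table, removed = filter_otus(table, drop_singletons=True)
    tree = prune_to_table(bundle["tree"], table)
    tables = {}
    summaries = {"filter": {"n_otus": table.n_otus, "n_removed": len(removed),
                            "n_samples": table.n_samples}}

    rel = tss_normalize(table)

    # ---- alpha diversity (rarefied) -------------------------------------
    if "alpha" in config.stages:
        stage("alpha")
        rare = rarefy(table, config.rarefaction_depth, seed=child_seed(config.seed, "rarefy"))
        rare = rare.drop_empty_otus()
        alpha = diversity.alpha_diversity(rare, prune_to_table(tree, rare))
        alpha = alpha.join(meta[["season", "reach", "replicate"]])
        tables["alpha_diversity"] = alpha.reset_index()
        anova_rows = []
        for index_name in ("shannon", "chao1", "faith_pd"):
            res = diversity.two_way_anova_partial_eta2(
                alpha[index_name], alpha["season"], alpha["reach"]
            )
            res = res.reset_index().rename(columns={"index": "term"})
            res.insert(0, "diversity_index", index_name)
            anova_rows.append(res)
        tables["alpha_anova"] = pd.concat(anova_rows, ignore_index=True)
        trend_rows = []
        reach_order = {r: i for i, r in enumerate(bundle["geometry"]["reach"].astype(str))}
        for season in seasons:
            sub = alpha[alpha["season"] == season]
            pos = [reach_order[r] for r in sub["reach"].astype(str)]
            for index_name in ("shannon", "chao1", "faith_pd"):
                res = diversity.spearman_trend(sub[index_name], pos)
                trend_rows.append({"season": season, "diversity_index": index_name, **res})
        tables["alpha_trend"] = pd.DataFrame(trend_rows)

    # ---- beta diversity --------------------------------------------------
    stage("beta")
    bc = diversity.bray_curtis(rel)
    pc = diversity.pcoa(bc, n_axes=4)
    tables["pcoa_scores"] = pc.coordinates.reset_index(names="sample_id")
    perm_rows = []
    if "beta" in config.stages:
        res = diversity.permanova(
            bc, meta["season"], n_perm=config.n_perm, seed=child_seed(config.seed, "perm_season")
        )
        perm_rows.append({"test": "season", "season": "both", "pseudo_F": res.pseudo_f,
                          "R2": res.r2, "p": res.p_perm, "n_perm": res.n_permutations})
        summaries["permanova_season"] = {"F": res.pseudo_f, "R2": res.r2, "p": res.p_perm}
        for season in seasons:
            sm = _season_frame(meta, season)
            bc_s = bc.filter(list(sm["sample_id"]))
            res = diversity.permanova(
                bc_s, sm["reach"], n_perm=config.n_perm,
                seed=child_seed(config.seed, "perm_reach", season),
            )
            perm_rows.append({"test": "reach", "season": season, "pseudo_F": res.pseudo_f,
                              "R2": res.r2, "p": res.p_perm, "n_perm": res.n_permutations})
            summaries[f"permanova_reach_{season}"] = {
                "F": res.pseudo_f, "R2": res.r2, "p": res.p_perm
            }
            disp = diversity.betadisper(
                bc_s, sm["reach"], n_perm=config.n_perm,
                seed=child_seed(config.seed, "disp", season),
            )
            summaries[f"betadisper_reach_{season}"] = {"F": disp.f, "p": disp.p_perm}
        tables["permanova"] = pd.DataFrame(perm_rows)

    # ---- spatial / environmental matrix statistics ----------------------
    if "spatial" in config.stages:
        stage("spatial")
        ddr_rows, mantel_frames, mrm_rows = [], [], []
        for season in seasons:
            sm = _season_frame(meta, season)
            bc_s = bc.filter(list(sm["sample_id"]))
            dams = spatial.dam_distance_matrix(bundle["geometry"], sm)
            fit = spatial.distance_decay(
                bc_s, dams, n_perm=config.n_perm, seed=child_seed(config.seed, "ddr", season)
            )
            ddr_rows.append({"season": season, "slope": fit.slope, "intercept": fit.intercept,
                             "r_mantel": fit.r_mantel, "p": fit.p_perm, "R2": fit.r2})
            summaries[f"ddr_{season}"] = {"slope": fit.slope, "r": fit.r_mantel,
                                          "p": fit.p_perm, "R2": fit.r2}
            fam = spatial.mantel_family(
                bc_s, bundle["env"], config.env_variables, season, sm,
                n_perm=config.n_perm, seed=child_seed(config.seed, "mantel", season),
            )
            mantel_frames.append(fam)
            env_multi = spatial.env_distance(
                bundle["env"], config.env_variables, season, metadata=sm
            )
            res = spatial.mrm(
                bc_s, {"dams": dams, "env": env_multi},
                n_perm=config.n_perm, seed=child_seed(config.seed, "mrm", season),
            )
            for name in res.coefficients.index:
                mrm_rows.append({"season": season, "term": name,
                                 "coefficient": res.coefficients[name],
                                 "p": res.p_perm[name], "R2": res.r2})
        tables["ddr"] = pd.DataFrame(ddr_rows)
        tables["mantel"] = pd.concat(mantel_frames, ignore_index=True)
        tables["mrm"] = pd.DataFrame(mrm_rows)

    # ---- null-model assembly partitioning --------------------------------
    if "assembly" in config.stages:
        stage("assembly")
        call_frames = []
        for season in seasons:
            sm = _season_frame(meta, season)
            # keep the full OTU registry: the betaNTI null shuffles taxa
            # across the tips of the whole regional phylogeny, not just the
            # taxa detected within this season
            sub = table.select_samples(list(sm["sample_id"]))
            bnti = assembly.beta_nti(
                sub, tree, n_null=config.bnti_nulls,
                seed=child_seed(config.seed, "bnti", season),
            )
            rc = assembly.rc_bray(
                sub.drop_empty_otus(), n_null=config.rc_nulls,
                seed=child_seed(config.seed, "rc", season),
            )
            calls = bnti.merge(rc, on=["sample_i", "sample_j"])
            calls = assembly.partition_processes(
                calls, bnti_thresh=config.bnti_thresh, rc_thresh=config.rc_thresh
            )
            calls.insert(0, "season", season)
            call_frames.append(calls)
            frac = assembly.summarize_fractions(calls)
            summaries[f"assembly_{season}"] = {
                **{k: float(v) for k, v in frac.fractions.items()},
                "deterministic": frac.deterministic,
                "stochastic": frac.stochastic,
                "n_pairs": frac.n_pairs,
                "n_na": frac.n_na,
            }
        tables["assembly_calls"] = pd.concat(call_frames, ignore_index=True)
        tables["assembly_fractions"] = pd.DataFrame(
            [{"season": s, **summaries[f"assembly_{s}"]} for s in seasons]
        )

    # ---- Sloan neutral model ---------------------------------------------
    if "ncm" in config.stages:
        stage("ncm")
        ncm_rows = []
        for season in seasons:
            sm = _season_frame(meta, season)
            sub = table.select_samples(list(sm["sample_id"])).drop_empty_otus()
            fit = neutral.ncm_fit(neutral.ncm_prepare(sub))
            rep = neutral.ncm_report(fit)
            ncm_rows.append({"season": season, **rep})
            summaries[f"ncm_{season}"] = rep
        tables["ncm"] = pd.DataFrame(ncm_rows)

    # ---- SPEC-OCCU, specialists, core and detected sets -------------------
    if "specocc" in config.stages:
        stage("specocc")
        records = specocc.spec_occ(table, meta["season"])
        records = specocc.classify_specialists(
            records, spec_min=config.spec_min, occ_min=config.occ_min
        )
        tables["spec_occ"] = records
        spec_counts = (
            records[records["is_specialist"]].groupby("group").size().to_dict()
        )
        summaries["specialists"] = {s: int(spec_counts.get(s, 0)) for s in seasons}
        cores = specocc.core_sets(table, meta["season"], occ_min=config.core_occ_min)
        detected = specocc.detected_sets(table, meta["season"])
        if len(seasons) == 2:
            a, b = seasons
            core_overlap = specocc.overlap_report(
                cores[a].members, cores[b].members, a, b
            )
            det_overlap = specocc.overlap_report(detected[a], detected[b], a, b)
            summaries["core_overlap"] = core_overlap
            summaries["detected_overlap"] = det_overlap
            shared_core = cores[a].members & cores[b].members
            if shared_core:
                comp = specocc.phylum_composition(shared_core, bundle["taxonomy"])
                tables["shared_core_phyla"] = comp.reset_index()
        tables["core_sets"] = pd.DataFrame(
            [{"season": s, "n_core": len(cores[s].members)} for s in seasons]
        )

    stage("done")
    report = AnalysisReport(tables=tables, summaries=summaries, config=config, log=log)
    if config.out_dir is not None:
        _write_report(report, truth_included=config.preset is not None)
    return report


def _write_report(report: AnalysisReport, truth_included: bool = False) -> None:
    out = Path(report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "config": report.config.to_dict(),
        "summaries": _plain(report.summaries),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    lines = ["# Analysis summary", ""]
    for name, vals in report.summaries.items():
        lines.append(f"## {name}")
        for k, v in vals.items():
            lines.append(f"- {k}: {v:.4g}" if isinstance(v, float) else f"- {k}: {v}")
        lines.append("")
    (out / "summary.md").write_text("\n".join(lines))


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj
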