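"""Synthetic metacommunities with known assembly regimes.

The generator emulates a cascade-dammed river survey: 10 ordered reaches
separated by dams (9 in total by default), sampled in two seasons with 4
replicate hosts per reach, yielding 80 samples with library sizes in the
tens of thousands and a lognormal regional species-abundance
distribution over ~10^3 taxa.

The generative model plants the three processes the analysis pipeline is
meant to detect:

* **selection** -- each taxon carries a Brownian-motion trait on the
  simulated phylogeny (phylogenetically conserved niche optimum); reach
  expected composition is the regional pool filtered by a Gaussian
  trait-environment match of width ``sigma_sel`` against a longitudinal
  environmental gradient whose amplitude differs by season;
* **dispersal** -- reach compositions are mixed through a dam-permeability
  kernel ``rho ** (number of dams between reaches)``, so low ``rho``
  plants distance decay with dam count and dispersal limitation;
* **drift** -- each host's community is a Dirichlet-multinomial draw
  around the reach expectation, with the concentration parameter setting
  the strength of neutral wobble.

A separate explicit source-sink simulator (``simulate_neutral``)
implements the classic neutral local-community model (per-birth
immigration probability m from a fixed pool) for neutral-model recovery
experiments; by default it samples the exact stationary law of that
process (Dirichlet-multinomial with immigration concentration
``m (N - 1)/(1 - m)``), with optional explicit Moran generations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from rivasm._seeding import rng_for
from rivasm.tables import CommunityTable, compute_din, write_community_table

__all__ = [
    "SimConfig",
    "SimTruth",
    "preset",
    "simulate_tree",
    "simulate_traits_bm",
    "simulate_environment",
    "simulate_metacommunity",
    "simulate_survey",
    "simulate_neutral",
    "synthetic_taxonomy",
    "dam_geometry_frame",
    "generate_fixture_bundle",
]

SEASONS = ("summer", "winter")

# Season parameter sets mirroring the inferred seasonal process contrast:
# winter = stronger, more heterogeneous environmental gradient, stronger
# conserved-trait selection, weaker dam mixing, weaker drift; summer =
# weak gradient, weak selection, high mixing, strong drift. ``mix_frac``
# is the immigrant fraction of each reach's expected composition and
# ``rho`` the per-dam permeability shaping where immigrants come from.
_SUMMER_LIKE = {"sigma_sel": 2.0, "rho": 0.9, "mix_frac": 0.6,
                "env_amplitude": 0.25, "dirichlet_conc": 400.0,
                "reach_noise_sd": 0.8}
_WINTER_LIKE = {"sigma_sel": 0.35, "rho": 0.5, "mix_frac": 0.1,
                "env_amplitude": 0.45, "dirichlet_conc": 200.0,
                "reach_noise_sd": 0.6}
_NEUTRAL = {"sigma_sel": math.inf, "rho": 1.0, "mix_frac": 1.0,
            "env_amplitude": 1.0, "dirichlet_conc": 300.0,
            "reach_noise_sd": 1.0}
_DISPERSAL = {"sigma_sel": math.inf, "rho": 0.3, "mix_frac": 0.1,
              "env_amplitude": 1.0, "dirichlet_conc": 300.0,
              "reach_noise_sd": 1.0}


@dataclass
class SimConfig:
    """Full description of one simulated survey.

    Per-season parameters are mappings from season name to value. The
    defaults reproduce the study design: 10 reaches x 2 seasons x 4
    replicates, one dam per adjacent reach pair (9 dams), library sizes
    lognormal around ~30k truncated at 15k, and a heavy-tailed lognormal
    regional abundance distribution over 2000 taxa so that per-sample
    detected richness is a realistic fraction of the regional pool.
    """

    n_taxa: int = 2000
    n_reaches: int = 10
    seasons: tuple = SEASONS
    n_replicates: int = 4
    dams_per_segment: int = 1
    lib_meanlog: float = math.log(30000.0)
    lib_sdlog: float = 0.3
    lib_min: int = 15000
    pool_sdlog: float = 2.5
    sel_floor: float = 0.002
    sel_exponent: float = 4.0
    bm_rate: float = 1.0
    bm_tip_attenuation: float = 0.1
    bm_attenuate_below: int = 30
    env_noise: float = 0.1
    tree_model: str = "birth_death"
    radiation_clades: int = 10
    radiation_rate: float = 8.0
    sigma_sel: dict = field(default_factory=lambda: {"summer": _SUMMER_LIKE["sigma_sel"],
                                                     "winter": _WINTER_LIKE["sigma_sel"]})
    rho: dict = field(default_factory=lambda: {"summer": _SUMMER_LIKE["rho"],
                                               "winter": _WINTER_LIKE["rho"]})
    mix_frac: dict = field(default_factory=lambda: {"summer": _SUMMER_LIKE["mix_frac"],
                                                    "winter": _WINTER_LIKE["mix_frac"]})
    env_amplitude: dict = field(default_factory=lambda: {"summer": _SUMMER_LIKE["env_amplitude"],
                                                         "winter": _WINTER_LIKE["env_amplitude"]})
    dirichlet_conc: dict = field(default_factory=lambda: {"summer": _SUMMER_LIKE["dirichlet_conc"],
                                                          "winter": _WINTER_LIKE["dirichlet_conc"]})
    reach_noise_sd: dict = field(default_factory=lambda: {"summer": _SUMMER_LIKE["reach_noise_sd"],
                                                          "winter": _WINTER_LIKE["reach_noise_sd"]})
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3 or self.n_reaches < 2 or self.n_replicates < 1:
            raise ValueError("invalid design sizes")
        for season in self.seasons:
            if not (0.0 <= self.rho[season] <= 1.0):
                raise ValueError("dam permeability rho must lie in [0, 1]")
            if not (0.0 <= self.mix_frac[season] <= 1.0):
                raise ValueError("mixing fraction must lie in [0, 1]")
            if not (self.sigma_sel[season] > 0):
                raise ValueError("selection width must be positive (inf = no selection)")

    @property
    def reaches(self):
        return [f"S{i + 1}" for i in range(self.n_reaches)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seasons"] = list(d["seasons"])
        for k, v in list(d.items()):
            if isinstance(v, dict):
                d[k] = {kk: (None if vv == math.inf else vv) for kk, vv in v.items()}
        return d


def preset(name: str, **overrides) -> SimConfig:
    """Named scenario configurations.

    ``"study"`` (default two-season contrast), ``"winter-like"`` /
    ``"summer-like"`` (that season's regime applied to both seasons),
    ``"neutral"``, ``"selection"``, ``"dispersal-limited"``.
    """
    per_season = {
        "study": None,
        "winter-like": _WINTER_LIKE,
        "summer-like": _SUMMER_LIKE,
        "neutral": _NEUTRAL,
        "dispersal-limited": _DISPERSAL,
        # strong conserved selection under a shared (flat) environment
        "selection": {"sigma_sel": 0.35, "rho": 1.0, "mix_frac": 0.3,
                      "env_amplitude": 0.0, "dirichlet_conc": 200.0,
                      "reach_noise_sd": 0.6},
    }
    if name not in per_season:
        raise ValueError(f"unknown preset {name!r}")
    cfg = SimConfig(**overrides)
    params = per_season[name]
    if params is not None:
        for key in ("sigma_sel", "rho", "mix_frac", "env_amplitude", "dirichlet_conc",
                    "reach_noise_sd"):
            setattr(cfg, key, {s: params[key] for s in cfg.seasons})
    return cfg


@dataclass
class SimTruth:
    """Ground truth of a simulated survey (for recovery tests)."""

    expected_composition: dict   # (season, reach) -> expected relative abundances
    traits: pd.Series            # standardized niche optima per taxon
    env_scores: dict             # season -> per-reach latent gradient value
    regime: str


# ---------------------------------------------------------------------------
# phylogeny and traits
# ---------------------------------------------------------------------------

def _otu_ids(n):
    width = max(4, len(str(n)))
    return [f"OTU{i + 1:0{width}d}" for i in range(n)]


def simulate_tree(
    n_taxa: int,
    model: str = "birth_death",
    seed: int = 0,
    radiation_clades: int = 8,
    radiation_rate: float = 8.0,
) -> TreeNode:
    """Random binary rooted ultrametric tree with positive branch lengths.

    ``"coalescent"`` merges random lineage pairs backward in time at
    Kingman waiting times (trait variance concentrated in the two deepest
    clades). ``"birth_death"`` grows a pure-birth tree forward in time
    with an episodic rate: the per-lineage birth rate is 1 until
    ``radiation_clades`` lineages exist, then jumps to ``radiation_rate``.
    This mimics OTU-level 16S phylogenies -- a deep backbone of distinct
    lineages, each capped by a tight recent radiation -- so that traits
    evolving by Brownian motion on the tree are strongly conserved within
    the backbone clades (the phylogenetic signal nearest-taxon null
    models rely on). Both models are ultrametric.
    """
    if n_taxa < 3:
        raise ValueError("need at least three taxa")
    rng = rng_for(seed, "tree", model)
    if model == "coalescent":
        nodes = [TreeNode(name=name, length=0.0) for name in _otu_ids(n_taxa)]
        ages = [0.0] * n_taxa
        t = 0.0
        while len(nodes) > 1:
            k = len(nodes)
            t += rng.exponential(2.0 / (k * (k - 1)))
            i, j = sorted(rng.choice(k, size=2, replace=False))
            right, age_r = nodes.pop(j), ages.pop(j)
            left, age_l = nodes.pop(i), ages.pop(i)
            left.length = t - age_l
            right.length = t - age_r
            nodes.append(TreeNode(children=[left, right], length=0.0))
            ages.append(t)
        root = nodes[0]
        root.length = None
        return root
    if model != "birth_death":
        raise ValueError(f"unknown tree model {model!r}")
    # forward-time pure-birth process with an episodic rate shift; every
    # surviving lineage is extended to the present (ultrametric)
    root = TreeNode(length=None)
    birth = {id(root): 0.0}
    tips = [root]
    t = 0.0
    while len(tips) < n_taxa:
        k = len(tips)
        per_lineage = 1.0 if k < radiation_clades else radiation_rate
        t += rng.exponential(1.0 / (per_lineage * k))
        idx = int(rng.integers(k))
        node = tips.pop(idx)
        node.length = (t - birth[id(node)]) if node.parent is not None else None
        for _ in range(2):
            child = TreeNode(length=0.0)
            birth[id(child)] = t
            node.append(child)
            tips.append(child)
    per_lineage = 1.0 if len(tips) < radiation_clades else radiation_rate
    t_end = t + rng.exponential(1.0 / (per_lineage * len(tips)))
    names = iter(_otu_ids(n_taxa))
    for tip in tips:
        tip.length = t_end - birth[id(tip)]
        tip.name = next(names)
    return root


def simulate_traits_bm(
    tree: TreeNode,
    rate: float = 1.0,
    root_value: float = 0.0,
    seed: int = 0,
    tip_attenuation: float = 1.0,
    attenuate_below: int = 30,
) -> pd.Series:
    """Brownian-motion trait evolution along branches.

    Each child's trait is the parent's plus a Normal(0, rate * branch
    length) step, giving phylogenetically conserved leaf traits with
    covariance equal to shared path length times the rate.

    ``tip_attenuation`` < 1 multiplies the rate on branches subtending
    fewer than ``attenuate_below`` tips, concentrating trait divergence on
    the deep backbone. This models niche traits (oxygen tolerance, habitat
    association) that are conserved at coarse taxonomic levels while
    closely related OTUs share essentially the same optimum.
    """
    rng = rng_for(seed, "traits_bm")
    n_tips = {}
    for node in tree.postorder(include_self=True):
        n_tips[id(node)] = 1 if node.is_tip() else sum(n_tips[id(c)] for c in node.children)
    values = {id(tree): float(root_value)}
    for node in tree.preorder(include_self=False):
        eff = max(rate, 0.0) * (node.length or 0.0)
        if n_tips[id(node)] < attenuate_below:
            eff *= tip_attenuation
        values[id(node)] = values[id(node.parent)] + rng.normal(0.0, math.sqrt(eff))
    return pd.Series({tip.name: values[id(tip)] for tip in tree.tips()})


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

# (base, slope on the latent gradient, noise sd) per measured variable;
# units follow routine water chemistry (deg C, mg/L, uS/cm, ug/L).
_ENV_VARS = {
    "Tem": {"summer": (26.0, 1.0, 0.3), "winter": (10.0, 1.0, 0.3)},
    "DO": {"summer": (7.0, -0.5, 0.2), "winter": (9.5, -0.5, 0.2)},
    "pH": {"summer": (7.8, 0.15, 0.05), "winter": (7.9, 0.15, 0.05)},
    "EC": {"summer": (320.0, 40.0, 10.0), "winter": (380.0, 40.0, 10.0)},
    "Chla": {"summer": (12.0, 3.0, 1.0), "winter": (5.0, 3.0, 1.0)},
    "TN": {"summer": (2.2, 0.5, 0.1), "winter": (2.8, 0.5, 0.1)},
    "TP": {"summer": (0.12, 0.03, 0.01), "winter": (0.08, 0.03, 0.01)},
    "NH4": {"summer": (0.35, 0.08, 0.02), "winter": (0.30, 0.08, 0.02)},
    "NO3": {"summer": (1.4, 0.35, 0.05), "winter": (1.9, 0.35, 0.05)},
    "NO2": {"summer": (0.05, 0.01, 0.004), "winter": (0.04, 0.01, 0.004)},
    "COD": {"summer": (16.0, 3.0, 1.0), "winter": (11.0, 3.0, 1.0)},
}


def simulate_environment(config: SimConfig, seed: int | None = None):
    """Latent longitudinal gradient plus a measured physicochemical table.

    Returns ``(env_table, env_scores)``: the latent per-reach gradient
    value ``e_r`` (monotone downstream-to-upstream trend scaled by the
    season's amplitude, plus noise) and an environmental table whose
    columns are affine functions of ``e_r`` with measurement noise; DIN is
    appended as the sum of its nitrogen components.
    """
    seed = config.seed if seed is None else seed
    rng = rng_for(seed, "environment")
    scores = {}
    rows = []
    base_grad = np.linspace(-1.0, 1.0, config.n_reaches)
    for season in config.seasons:
        amp = config.env_amplitude[season]
        e = amp * base_grad + rng.normal(0.0, config.env_noise * max(amp, 1e-12),
                                         config.n_reaches)
        scores[season] = e
        for r, reach in enumerate(config.reaches):
            row = {"reach": reach, "season": season}
            for var, params in _ENV_VARS.items():
                base, slope, noise = params[season]
                val = base + slope * e[r] + rng.normal(0.0, noise)
                row[var] = max(val, 1e-6) if var != "Tem" else val
            rows.append(row)
    env = compute_din(pd.DataFrame(rows))
    return env, scores


# ---------------------------------------------------------------------------
# metacommunity sampling
# ---------------------------------------------------------------------------

def dam_geometry_frame(config: SimConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reach": config.reaches,
            "dams_to_next": [config.dams_per_segment] * (config.n_reaches - 1) + [0],
        }
    )


def _reach_dam_counts(config: SimConfig) -> np.ndarray:
    cum = np.arange(config.n_reaches) * config.dams_per_segment
    return np.abs(cum[:, None] - cum[None, :]).astype(float)


def simulate_metacommunity(config: SimConfig, tree: TreeNode, traits: pd.Series,
                           env_scores: dict, seed: int | None = None):
    """Sample the survey's count table from the planted assembly regime.

    Returns ``(CommunityTable, metadata, SimTruth)``. See the module
    docstring for the generative model.
    """
    seed = config.seed if seed is None else seed
    otus = [t.name for t in tree.tips()]
    if len(otus) != config.n_taxa:
        raise ValueError("tree leaf count does not match config.n_taxa")
    rng_pool = rng_for(seed, "pool")
    pool = np.exp(rng_pool.normal(0.0, config.pool_sdlog, config.n_taxa))
    pool /= pool.sum()
    z = traits.loc[otus].to_numpy()
    z = (z - z.mean()) / z.std()
    dam_counts = _reach_dam_counts(config)

    expected = {}
    columns = {}
    meta_rows = []
    for season in config.seasons:
        sigma = config.sigma_sel[season]
        rho = config.rho[season]
        mix = config.mix_frac[season]
        conc = config.dirichlet_conc[season]
        e = np.asarray(env_scores[season], dtype=float)
        # selection: Gaussian trait-environment match around each reach optimum
        if math.isinf(sigma):
            w = np.tile(pool, (config.n_reaches, 1))
        else:
            # imperfect filtering: a small floor lets every taxon retain a
            # trickle of presence (transient immigrants from diet/water),
            # as observed in real gut communities
            delta = np.abs(z[None, :] - e[:, None]) / sigma
            gauss = np.exp(-0.5 * delta**config.sel_exponent)
            filt = config.sel_floor + (1.0 - config.sel_floor) * gauss
            w = pool[None, :] * filt
        # reach-level compositional noise (priority effects / unmeasured factors)
        noise_sd = config.reach_noise_sd[season]
        if noise_sd > 0:
            rng_reach = rng_for(seed, "reach_noise", season)
            w = w * np.exp(rng_reach.normal(0.0, noise_sd, size=w.shape))
        w /= w.sum(axis=1, keepdims=True)
        # dispersal: a fraction ``mix`` of each reach's expected composition
        # is immigrant, sourced from other reaches with weight rho**dams
        if mix > 0 and config.n_reaches > 1:
            kernel = np.power(max(rho, 0.0), dam_counts) if rho > 0 else np.eye(
                config.n_reaches
            )
            np.fill_diagonal(kernel, 0.0)
            row_sums = kernel.sum(axis=1, keepdims=True)
            kernel = np.divide(kernel, row_sums, out=np.zeros_like(kernel),
                               where=row_sums > 0)
            immigrants = kernel @ w
            w_mixed = (1.0 - mix) * w + mix * immigrants
        else:
            w_mixed = w
        w_mixed /= w_mixed.sum(axis=1, keepdims=True)
        for r, reach in enumerate(config.reaches):
            expected[(season, reach)] = w_mixed[r].copy()
            for rep in range(1, config.n_replicates + 1):
                sid = f"{season[:2]}_{reach}_r{rep}"
                rng = rng_for(seed, "fish", season, reach, rep)
                alpha = np.maximum(conc * w_mixed[r], 1e-9)
                x = rng.dirichlet(alpha)
                lib = 0
                while lib < config.lib_min:
                    lib = int(round(float(
                        np.exp(rng.normal(config.lib_meanlog, config.lib_sdlog))
                    )))
                columns[sid] = rng.multinomial(lib, x)
                meta_rows.append(
                    {"sample_id": sid, "season": season, "reach": reach, "replicate": rep}
                )
    counts = np.column_stack([columns[m["sample_id"]] for m in meta_rows])
    table = CommunityTable(counts, otus, [m["sample_id"] for m in meta_rows])
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    sigmas = [config.sigma_sel[s] for s in config.seasons]
    mixes = [config.mix_frac[s] for s in config.seasons]
    if all(math.isinf(s) for s in sigmas):
        regime = "neutral" if all(mx >= 0.99 for mx in mixes) else "dispersal_limited"
    else:
        regime = "selection" if all(mx >= 0.25 for mx in mixes) else "mixed"
    truth = SimTruth(
        expected_composition=expected,
        traits=pd.Series(z, index=otus),
        env_scores=env_scores,
        regime=regime,
    )
    return table, metadata, truth


def simulate_survey(config: SimConfig):
    """Convenience wrapper: tree, traits, environment, and counts in one call.

    Returns a dict with keys ``table, metadata, tree, traits, env,
    env_scores, geometry, truth``.
    """
    tree = simulate_tree(
        config.n_taxa,
        model=config.tree_model,
        seed=config.seed,
        radiation_clades=config.radiation_clades,
        radiation_rate=config.radiation_rate,
    )
    traits = simulate_traits_bm(
        tree,
        rate=config.bm_rate,
        seed=config.seed,
        tip_attenuation=config.bm_tip_attenuation,
        attenuate_below=config.bm_attenuate_below,
    )
    env, scores = simulate_environment(config)
    table, metadata, truth = simulate_metacommunity(config, tree, traits, scores)
    return {
        "table": table,
        "metadata": metadata,
        "tree": tree,
        "traits": traits,
        "env": env,
        "env_scores": scores,
        "geometry": dam_geometry_frame(config),
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# explicit neutral source-sink simulator
# ---------------------------------------------------------------------------

def simulate_neutral(
    N: int,
    m: float,
    pool_p,
    n_samples: int,
    generations: int = 0,
    seed: int = 0,
    init: str = "stationary",
) -> CommunityTable:
    """Neutral local communities of N individuals coupled to a source pool.

    The process: each replaced individual is an immigrant drawn from
    ``pool_p`` with probability ``m``, otherwise a local birth
    proportional to local abundances. ``init="stationary"`` samples the
    exact stationary distribution of this process (Dirichlet-multinomial
    with concentration ``m (N - 1)/(1 - m)`` times the pool), so no
    burn-in is needed; ``init="pool"`` starts from a multinomial pool draw
    and requires ``generations`` of explicit dynamics to equilibrate. One
    generation performs N replacement events in batches of N/10.
    """
    if N < 100:
        raise ValueError("N must be at least 100")
    if not (0.0 < m <= 1.0):
        raise ValueError("immigration probability m must lie in (0, 1]")
    p = np.asarray(pool_p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("pool_p must be a probability vector")
    n_taxa = len(p)
    cols = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for s in range(n_samples):
        rng = rng_for(seed, "neutral", s)
        if init == "stationary":
            if m >= 1.0:
                counts = rng.multinomial(N, p)
            else:
                conc = m * (N - 1) / (1.0 - m)
                x = rng.dirichlet(np.maximum(conc * p, 1e-300))
                counts = rng.multinomial(N, x)
        elif init == "pool":
            counts = rng.multinomial(N, p)
        else:
            raise ValueError(f"unknown init {init!r}")
        batch = max(1, N // 10)
        for _ in range(int(generations)):
            replaced = 0
            while replaced < N:
                k = min(batch, N - replaced)
                deaths = rng.multivariate_hypergeometric(counts, k)
                counts = counts - deaths
                n_imm = rng.binomial(k, m)
                if n_imm:
                    counts = counts + rng.multinomial(n_imm, p)
                n_birth = k - n_imm
                if n_birth:
                    local = counts.sum()
                    counts = counts + rng.multinomial(n_birth, counts / local)
                replaced += k
        cols[:, s] = counts
    width = max(3, len(str(n_samples)))
    sample_ids = [f"N{s + 1:0{width}d}" for s in range(n_samples)]
    return CommunityTable(cols, _otu_ids(n_taxa), sample_ids)


# ---------------------------------------------------------------------------
# fixture bundle writer
# ---------------------------------------------------------------------------

_PHYLA = (
    "Proteobacteria",
    "Firmicutes",
    "Planctomycetota",
    "Actinobacteriota",
    "Chloroflexi",
    "Bacteroidota",
    "Cyanobacteria",
    "Verrucomicrobiota",
)


def synthetic_taxonomy(tree: TreeNode, seed: int = 0) -> pd.DataFrame:
    """Assign phylum labels to contiguous clades of the tree (synthetic
    lineages; ranks below phylum are per-OTU placeholders)."""
    tips = [t.name for t in tree.tips()]
    rng = rng_for(seed, "taxonomy")
    cuts = np.sort(rng.choice(np.arange(1, len(tips)), size=len(_PHYLA) - 1, replace=False))
    blocks = np.split(np.arange(len(tips)), cuts)
    rows = {}
    for phylum, idx in zip(_PHYLA, blocks):
        for i in idx:
            rows[tips[i]] = {
                "phylum": phylum,
                "class": "unclassified",
                "order": "unclassified",
                "family": "unclassified",
                "genus": f"genus_{tips[i]}",
            }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("otu_id")


def generate_fixture_bundle(config: SimConfig, out_dir) -> dict:
    """Simulate a survey and write every file the pipeline reads.

    Writes ``table.tsv, tree.nwk, metadata.tsv, env.tsv, taxonomy.tsv,
    dam_geometry.tsv, truth_env_scores.tsv`` and a ``manifest.yaml``
    recording the seed, the full configuration, and file checksums.
    Returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_survey(config)
    paths = {
        "table": out / "table.tsv",
        "tree": out / "tree.nwk",
        "metadata": out / "metadata.tsv",
        "env": out / "env.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "geometry": out / "dam_geometry.tsv",
        "truth": out / "truth_env_scores.tsv",
    }
    write_community_table(sim["table"], paths["table"])
    sim["tree"].write(str(paths["tree"]), format="newick")
    sim["metadata"].to_csv(paths["metadata"], sep="\t", index=False)
    sim["env"].to_csv(paths["env"], sep="\t", index=False)
    synthetic_taxonomy(sim["tree"], seed=config.seed).to_csv(paths["taxonomy"], sep="\t")
    sim["geometry"].to_csv(paths["geometry"], sep="\t", index=False)
    truth_rows = [
        {"season": season, "reach": reach, "env_score": float(val)}
        for season, arr in sim["env_scores"].items()
        for reach, val in zip(config.reaches, arr)
    ]
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    checksums = {
        name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in paths.items()
    }
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "checksums": checksums,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    paths["manifest"] = out / "manifest.yaml"
    return {k: str(v) for k, v in paths.items()}
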