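"""Phylogenetic and taxonomic null models for community-assembly inference.

For every sample pair the framework computes

* abundance-weighted beta mean-nearest-taxon distance (betaMNTD) and its
  standardized effect size betaNTI, where the null shuffles taxa across
  the tips of the phylogeny (equivalently, jointly permutes the rows and
  columns of the patristic matrix);
* abundance-weighted Raup-Crick on Bray-Curtis (RC_Bray), where the null
  reassembles each community preserving its observed richness and total
  abundance, drawing occurrences weighted by metacommunity occupancy and
  filling abundances weighted by metacommunity relative abundance;

and then assigns an assembly process: |betaNTI| > 2 indicates selection
(sign separates heterogeneous from homogeneous), otherwise |RC| > 0.95
indicates a dispersal process (sign separates limitation from
homogenization), and the remainder is undominated ("drift").

All null loops are deterministic for a given seed and independent of pair
evaluation order: the betaNTI tip shuffles are drawn once from the seed
and reused for every pair, and each RC pair uses a child seed derived
from its sorted sample ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from rivasm._seeding import rng_for
from rivasm.tables import CommunityTable
from rivasm.trees import patristic_matrix

__all__ = [
    "beta_mntd",
    "beta_nti",
    "null_assemble",
    "rc_bray",
    "partition_processes",
    "summarize_fractions",
    "ProcessFractions",
    "PROCESSES",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

_SELECTION = PROCESSES[:2]


def beta_mntd(rel_i, rel_j, pdm: DistanceMatrix, weighted: bool = True) -> float:
    """Beta mean-nearest-taxon distance between two communities.

    ``rel_i``/``rel_j`` are abundance vectors aligned to ``pdm.ids``. Each
    present taxon contributes the patristic distance to its nearest taxon
    in the other community (zero for shared taxa), weighted by its
    within-community relative abundance (or equally when unweighted).
    """
    x = np.asarray(rel_i, dtype=float)
    y = np.asarray(rel_j, dtype=float)
    d = np.asarray(pdm.data, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("empty community")
    pi, pj = np.flatnonzero(x > 0), np.flatnonzero(y > 0)
    min_i = d[np.ix_(pi, pj)].min(axis=1)
    min_j = d[np.ix_(pj, pi)].min(axis=1)
    if weighted:
        wi = x[pi] / x[pi].sum()
        wj = y[pj] / y[pj].sum()
    else:
        wi = np.full(len(pi), 1.0 / len(pi))
        wj = np.full(len(pj), 1.0 / len(pj))
    return float(0.5 * ((wi * min_i).sum() + (wj * min_j).sum()))


def _all_pairs(sample_ids):
    return list(combinations(sample_ids, 2))


def _mntd_all_pairs(F: np.ndarray, D: np.ndarray, present_idx) -> np.ndarray:
    """betaMNTD for every sample pair at once.

    ``F`` is taxa x samples relative abundance; ``present_idx[j]`` indexes
    the taxa present in sample j. M[k, j] = min distance from taxon k to
    any taxon present in j; then betaMNTD = 0.5 (A + A^T) with A = F^T M.
    """
    n_taxa, n_samp = F.shape
    M = np.empty((n_taxa, n_samp))
    for j, idx in enumerate(present_idx):
        M[:, j] = D[:, idx].min(axis=1)
    A = F.T @ M
    return 0.5 * (A + A.T)


def beta_nti(
    table: CommunityTable,
    tree,
    pair_set=None,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """betaNTI for sample pairs: z-score of betaMNTD against tip-shuffle nulls.

    ``tree`` may be a (pruned) ``TreeNode`` or a precomputed patristic
    ``DistanceMatrix``. Returns a DataFrame with one row per pair:
    ``sample_i, sample_j, beta_mntd_obs, beta_nti, note``. Pairs whose null
    distribution has zero variance (e.g. a star phylogeny) get NaN with an
    explanatory note.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    # canonical taxon order makes results bit-identical under relabeling
    # (permuting table rows together with tree leaves)
    table = table.select_otus(sorted(table.otu_ids))
    if isinstance(tree, TreeNode):
        pdm = patristic_matrix(tree, table.otu_ids)
    else:
        pdm = tree.filter(table.otu_ids)
    D = np.asarray(pdm.data, dtype=float)
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("empty sample column")
    if weighted:
        F = counts / totals
    else:
        pres = (counts > 0).astype(float)
        F = pres / pres.sum(axis=0)
    present_idx = [np.flatnonzero(counts[:, j] > 0) for j in range(table.n_samples)]

    obs = _mntd_all_pairs(F, D, present_idx)
    rng = rng_for(seed, "beta_nti")
    n = table.n_samples
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    for _ in range(int(n_null)):
        perm = rng.permutation(table.n_otus)
        B = _mntd_all_pairs(F, D[np.ix_(perm, perm)], present_idx)
        acc += B
        acc2 += B * B
    mean = acc / n_null
    var = (acc2 - n_null * mean * mean) / (n_null - 1)
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)

    if pair_set is None:
        pair_set = _all_pairs(table.sample_ids)
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    rows = []
    for a, b in pair_set:
        i, j = pos[str(a)], pos[str(b)]
        if sd[i, j] > 0:
            z = (obs[i, j] - mean[i, j]) / sd[i, j]
            note = ""
        else:
            z = np.nan
            note = "zero null variance"
        rows.append(
            {
                "sample_i": str(a),
                "sample_j": str(b),
                "beta_mntd_obs": obs[i, j],
                "beta_nti": z,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def null_assemble(rng, richness: int, total: int, w_occ, w_ab, n_draws: int) -> np.ndarray:
    """Draw ``n_draws`` null communities with fixed richness and total count.

    Occurrences are a weighted sample without replacement from ``w_occ``
    (Gumbel top-k); each drawn taxon gets one individual and the remaining
    ``total - richness`` individuals are multinomial with probabilities
    proportional to ``w_ab`` over the drawn taxa. This is the generative
    procedure behind the Raup-Crick null and is exposed so calibration
    experiments can assemble "observed" communities from the same process.
    """
    w_occ = np.asarray(w_occ, dtype=float)
    w_ab = np.asarray(w_ab, dtype=float)
    n_taxa = len(w_occ)
    if not (0 < richness <= (w_occ > 0).sum()):
        raise ValueError("richness must be positive and not exceed the occurring pool")
    if total < richness:
        raise ValueError("total must be at least the richness")
    with np.errstate(divide="ignore"):
        keys = np.log(w_occ)[None, :] + rng.gumbel(size=(n_draws, n_taxa))
    chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    mask = np.zeros((n_draws, n_taxa), dtype=bool)
    mask[np.arange(n_draws)[:, None], chosen] = True
    base = mask.astype(np.int64)
    if total > richness:
        P = w_ab * mask
        P = P / P.sum(axis=1, keepdims=True)
        base += rng.multinomial(total - richness, P)
    return base


def rc_bray(
    table: CommunityTable,
    pair_set=None,
    n_null: int = 999,
    seed: int = 0,
    occurrence_weighting: str = "occupancy",
    abundance_weighting: str = "abundance",
    metacommunity: tuple | None = None,
) -> pd.DataFrame:
    """Abundance-weighted Raup-Crick deviation of Bray-Curtis, in [-1, 1].

    For each pair, each null draw rebuilds both communities: occurrences
    are sampled without replacement (weighted by metacommunity occupancy),
    then remaining individuals are assigned by a multinomial weighted by
    metacommunity relative abundance restricted to the drawn taxa. RC is
    the rescaled fraction of null Bray-Curtis values below the observed
    one, ties counted at half weight. Equiprobable weightings are exposed
    for sensitivity analysis.

    By default the metacommunity weights are the table's own occupancies
    and total abundances; ``metacommunity=(w_occ, w_ab)`` substitutes
    externally defined weights (e.g. a regional pool, or the generating
    weights in calibration experiments).
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    if metacommunity is None:
        table = table.select_otus(sorted(table.otu_ids))
    counts = table.counts
    if metacommunity is not None:
        occ, ab = (np.asarray(w, dtype=float) for w in metacommunity)
        if len(occ) != table.n_otus or len(ab) != table.n_otus:
            raise ValueError("metacommunity weights must match the OTU registry")
    else:
        occ = (counts > 0).sum(axis=1).astype(float)
        ab = counts.sum(axis=1).astype(float)
    if (occ > 0).sum() < 2:
        raise ValueError("metacommunity has fewer than two occurring OTUs")
    w_occ = occ if occurrence_weighting == "occupancy" else (occ > 0).astype(float)
    w_ab = ab if abundance_weighting == "abundance" else (ab > 0).astype(float)

    if pair_set is None:
        pair_set = _all_pairs(table.sample_ids)
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    tol = 1e-12

    rows = []
    for a, b in pair_set:
        i, j = pos[str(a)], pos[str(b)]
        xi, xj = counts[:, i], counts[:, j]
        if xi.sum() == 0 or xj.sum() == 0:
            raise ValueError("empty community in pair")
        key = tuple(sorted((str(a), str(b))))
        rng = rng_for(seed, "rc_bray", *key)
        obs = np.abs(xi - xj).sum() / (xi + xj).sum()
        ni = null_assemble(rng, int((xi > 0).sum()), int(xi.sum()), w_occ, w_ab, n_null)
        nj = null_assemble(rng, int((xj > 0).sum()), int(xj.sum()), w_occ, w_ab, n_null)
        bc_null = np.abs(ni - nj).sum(axis=1) / (ni + nj).sum(axis=1)
        less = int((bc_null < obs - tol).sum())
        equal = int((np.abs(bc_null - obs) <= tol).sum())
        rc = 2.0 * ((less + 0.5 * equal) / n_null) - 1.0
        rows.append(
            {"sample_i": str(a), "sample_j": str(b), "bray_curtis_obs": obs, "rc_bray": rc}
        )
    return pd.DataFrame(rows)


def partition_processes(
    calls: pd.DataFrame,
    bnti_thresh: float = 2.0,
    rc_thresh: float = 0.95,
) -> pd.DataFrame:
    """Assign an assembly process per pair from (betaNTI, RC_Bray).

    betaNTI beyond +/- ``bnti_thresh`` indicates selection and RC is not
    consulted; otherwise RC beyond +/- ``rc_thresh`` indicates a dispersal
    process, and the remainder is undominated. NaN inputs yield NaN.
    """
    out = calls.copy()
    procs = []
    for z, rc in zip(out["beta_nti"], out["rc_bray"]):
        if not np.isfinite(z) or not np.isfinite(rc):
            procs.append(np.nan)
        elif z > bnti_thresh:
            procs.append("heterogeneous_selection")
        elif z < -bnti_thresh:
            procs.append("homogeneous_selection")
        elif rc > rc_thresh:
            procs.append("dispersal_limitation")
        elif rc < -rc_thresh:
            procs.append("homogenizing_dispersal")
        else:
            procs.append("undominated")
    out["process"] = procs
    return out


@dataclass
class ProcessFractions:
    fractions: pd.Series     # per process, over non-NA pairs; sums to 1
    deterministic: float     # heterogeneous + homogeneous selection
    stochastic: float        # dispersal + homogenizing + undominated
    n_pairs: int
    n_na: int


def summarize_fractions(calls: pd.DataFrame, by: str | None = None):
    """Process fractions over non-NA pairs, optionally per group column."""
    if by is not None:
        return {
            g: summarize_fractions(sub) for g, sub in calls.groupby(by, sort=True)
        }
    valid = calls["process"].dropna()
    n_na = len(calls) - len(valid)
    if len(valid) == 0:
        raise ValueError("no non-NA assembly calls to summarize")
    frac = valid.value_counts(normalize=True).reindex(list(PROCESSES), fill_value=0.0)
    det = float(frac[list(_SELECTION)].sum())
    return ProcessFractions(
        fractions=frac,
        deterministic=det,
        stochastic=float(1.0 - det),
        n_pairs=int(len(valid)),
        n_na=int(n_na),
    )
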