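"""Alpha and beta diversity, ordination, and group tests.

Alpha diversity follows the usual amplicon conventions: Shannon entropy in
nats, Chao1 with the bias-corrected branch when doubletons are absent, and
Faith's phylogenetic diversity as the branch length of the minimal subtree
spanning the taxa present in a sample (rooted variant by default). Beta
diversity is Bray-Curtis on TSS relative abundances; group structure is
tested with a permutational MANOVA (Anderson's pseudo-F) and dispersion
homogeneity with a PCoA-space distance-to-centroid test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix, TreeNode

from rivasm._seeding import rng_for
from rivasm.tables import CommunityTable, tss_normalize

__all__ = [
    "shannon",
    "chao1",
    "faith_pd",
    "alpha_diversity",
    "rarefaction_curve",
    "bray_curtis",
    "pcoa",
    "PcoaResult",
    "permanova",
    "PermanovaResult",
    "betadisper",
    "DispersionResult",
    "two_way_anova_partial_eta2",
    "spearman_trend",
]


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(abundances) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats); zeros are ignored."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    p = p[p > 0]  # guard subnormal underflow in the division
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Chao1 richness estimate from integer counts.

    Classic form S + F1^2/(2 F2); bias-corrected S + F1(F1-1)/(2(F2+1))
    when no doubletons are observed.
    """
    x = np.asarray(counts)
    if not np.allclose(x, np.rint(np.asarray(x, dtype=float))):
        raise ValueError("chao1 requires integer counts")
    x = np.rint(np.asarray(x, dtype=float)).astype(np.int64)
    if (x < 0).any():
        raise ValueError("negative counts")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def faith_pd(counts, otu_ids, tree: TreeNode, include_root: bool = True) -> float:
    """Faith's PD: branch length of the minimal subtree covering present taxa.

    With ``include_root`` (default) the subtree is anchored at the tree
    root, so a single present taxon contributes its full root-to-tip path.
    """
    x = np.asarray(counts, dtype=float)
    present = {str(o) for o, c in zip(otu_ids, x) if c > 0}
    if not present:
        return 0.0
    tip_names = {t.name for t in tree.tips()}
    missing = present - tip_names
    if missing:
        raise ValueError(f"present taxa absent from tree: {sorted(missing)[:5]}")
    pd_sum = 0.0
    covered = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            covered[id(node)] = node.name in present
        else:
            covered[id(node)] = any(covered[id(c)] for c in node.children)
    if include_root:
        for node in tree.traverse(include_self=False):
            if covered[id(node)]:
                pd_sum += node.length or 0.0
    else:
        # exclude the unbranched stem above the MRCA of the present taxa
        mrca = tree if len(present) > 1 else None
        if len(present) == 1:
            return 0.0
        mrca = tree.lca([n for n in tree.tips() if n.name in present])
        for node in mrca.traverse(include_self=False):
            if covered[id(node)]:
                pd_sum += node.length or 0.0
    return float(pd_sum)


def alpha_diversity(table: CommunityTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Shannon, Chao1 and (if a tree is given) Faith's PD per sample.

    Intended for rarefied count tables so indices are comparable across
    samples.
    """
    records = {}
    # precompute tip coverage bitmaps once for PD over many samples
    rel = table.counts.astype(float)
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rec = {"shannon": shannon(rel[:, j]), "chao1": chao1(col)}
        if tree is not None:
            rec["faith_pd"] = faith_pd(col, table.otu_ids, tree)
        records[sid] = rec
    return pd.DataFrame.from_dict(records, orient="index").rename_axis("sample_id")


def rarefaction_curve(table: CommunityTable, depths, reps: int = 10, seed: int = 0) -> pd.DataFrame:
    """Mean observed OTU richness per sample at each subsampling depth.

    Uses the analytic hypergeometric expectation
    ``E[S] = sum_i (1 - C(T - n_i, depth)/C(T, depth))`` rather than Monte
    Carlo draws when ``reps`` is 0; otherwise averages ``reps`` random
    without-replacement subsamples.
    """
    depths = [int(d) for d in depths]
    if not depths:
        raise ValueError("empty depth list")
    libs = table.library_sizes()
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        total = int(libs[sid])
        for depth in depths:
            if depth > total:
                raise ValueError(f"depth {depth} exceeds library size of {sid}")
            if reps == 0:
                # E[richness] via hypergeometric absence probabilities
                nz = col[col > 0].astype(float)
                with np.errstate(over="ignore"):
                    log_absent = (
                        scipy.special.gammaln(total - nz + 1)
                        - scipy.special.gammaln(total - nz - depth + 1)
                        - scipy.special.gammaln(total + 1)
                        + scipy.special.gammaln(total - depth + 1)
                    )
                p_absent = np.where(total - nz >= depth, np.exp(log_absent), 0.0)
                mean_s = float((1.0 - p_absent).sum())
            else:
                rng = rng_for(seed, "rarecurve", sid, depth)
                vals = [
                    int((rng.multivariate_hypergeometric(col, depth) > 0).sum())
                    for _ in range(reps)
                ]
                mean_s = float(np.mean(vals))
            rows.append({"sample_id": sid, "depth": depth, "mean_richness": mean_s})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(rel: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns of a relative-
    abundance table: BC(x, y) = sum|x-y| / sum(x+y)."""
    mat = np.asarray(rel, dtype=float).T  # samples x taxa
    if mat.shape[0] < 2:
        raise ValueError("need at least two samples")
    if (mat.sum(axis=1) <= 0).any():
        raise ValueError("zero-sum sample column")
    condensed = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(c) for c in rel.columns])


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes (positive-eigenvalue axes)
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray


def _gower_eigh(d: DistanceMatrix):
    """Gower-centered eigendecomposition of a squared-distance matrix."""
    a = -0.5 * np.asarray(d.data, dtype=float) ** 2
    n = a.shape[0]
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigvals, eigvecs = np.linalg.eigh(centered)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinates analysis (metric MDS).

    Negative eigenvalues (non-Euclidean input) are reported, not corrected;
    coordinates are returned for positive-eigenvalue axes only.
    """
    eigvals, eigvecs = _gower_eigh(d)
    pos = eigvals > 1e-10 * max(1.0, abs(eigvals[0]))
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    prop = eigvals / eigvals[pos].sum()
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA / betadisper
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_perm: float
    n_permutations: int
    ss_between: float
    ss_within: float
    ss_total: float


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """(pseudo-F, R2) from a squared-distance matrix and group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_total <= 0:
        raise ValueError("total sum of squares is zero (all samples identical)")
    f = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else math.inf
    return f, ss_between / ss_total, ss_between, ss_within, ss_total


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm=999,
    seed: int = 0,
    strata=None,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) with label permutation.

    ``n_perm="exhaustive"`` enumerates every permutation of the sample
    labels (small n only) and reports the exact enumeration p-value.
    ``strata`` restricts random permutations to occur within blocks.
    """
    labels = pd.Series(list(groups)).astype(str).to_numpy()
    n = len(d.ids)
    if len(labels) != n:
        raise ValueError("group length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    d2 = np.asarray(d.data, dtype=float) ** 2
    f_obs, r2, ssb, ssw, sst = _permanova_stats(d2, codes, len(uniq))

    if n_perm == "exhaustive":
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            f_p, *_ = _permanova_stats(d2, codes[list(perm)], len(uniq))
            count += f_p >= f_obs - 1e-12
            total += 1
        return PermanovaResult(f_obs, r2, count / total, total, ssb, ssw, sst)

    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng_for(seed, "permanova")
    if strata is not None:
        strata = pd.Series(list(strata)).astype(str).to_numpy()
        blocks = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    count = 0
    for _ in range(n_perm):
        perm = np.arange(n)
        if strata is None:
            rng.shuffle(perm)
        else:
            for idx in blocks:
                perm[idx] = idx[rng.permutation(len(idx))]
        f_p, *_ = _permanova_stats(d2, codes[perm], len(uniq))
        count += f_p >= f_obs - 1e-12
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(f_obs, r2, p, n_perm, ssb, ssw, sst)


@dataclass
class DispersionResult:
    distances: pd.Series          # per-sample distance to its group centroid
    group_means: pd.Series
    f: float
    p_perm: float
    n_permutations: int
    excluded: list


def betadisper(d: DistanceMatrix, groups, n_perm=999, seed: int = 0) -> DispersionResult:
    """Multivariate dispersion homogeneity test (centroid variant).

    Samples are embedded by PCoA keeping negative-eigenvalue ("imaginary")
    axes; squared distance to the group centroid is the real-part squared
    distance minus the imaginary-part squared distance, floored at zero.
    The F statistic is a one-way ANOVA on these distances; significance
    comes from permuting the distances among samples.
    """
    labels = pd.Series(list(groups)).astype(str).to_numpy()
    ids = list(d.ids)
    eigvals, eigvecs = _gower_eigh(d)
    tol = 1e-10 * max(1.0, abs(eigvals).max())
    pos, neg = eigvals > tol, eigvals < -tol
    c_real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    c_imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])

    excluded = []
    dists, keep_labels, keep_ids = [], [], []
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            excluded.append(str(g))
            continue
        cen_r = c_real[idx].mean(axis=0)
        cen_i = c_imag[idx].mean(axis=0) if c_imag.size else np.zeros(0)
        for i in idx:
            z2 = ((c_real[i] - cen_r) ** 2).sum()
            if c_imag.size:
                z2 -= ((c_imag[i] - cen_i) ** 2).sum()
            dists.append(math.sqrt(max(z2, 0.0)))
            keep_labels.append(str(g))
            keep_ids.append(ids[i])

    dists = np.asarray(dists)
    keep_labels = np.asarray(keep_labels)
    uniq = np.unique(keep_labels)
    if len(uniq) < 2:
        raise ValueError("betadisper needs at least two groups of size >= 2")

    def anova_f(y, lab):
        grand = y.mean()
        ssb = sum(len(y[lab == g]) * (y[lab == g].mean() - grand) ** 2 for g in uniq)
        ssw = sum(((y[lab == g] - y[lab == g].mean()) ** 2).sum() for g in uniq)
        if ssw <= 0 and ssb <= 0:
            raise ValueError("all dispersions are zero; F undefined")
        if ssw <= 0:
            return math.inf
        return (ssb / (len(uniq) - 1)) / (ssw / (len(y) - len(uniq)))

    f_obs = anova_f(dists, keep_labels)
    rng = rng_for(seed, "betadisper")
    n_perm = int(n_perm)
    count = 0
    for _ in range(n_perm):
        f_p = anova_f(dists[rng.permutation(len(dists))], keep_labels)
        count += f_p >= f_obs - 1e-12
    p = (count + 1) / (n_perm + 1)
    means = pd.Series({g: dists[keep_labels == g].mean() for g in uniq})
    return DispersionResult(
        distances=pd.Series(dists, index=keep_ids),
        group_means=means,
        f=f_obs,
        p_perm=p,
        n_permutations=n_perm,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# univariate statistics on diversity indices
# ---------------------------------------------------------------------------

def two_way_anova_partial_eta2(y, factor_a, factor_b) -> pd.DataFrame:
    """Two-way ANOVA (type-II sums of squares) with partial eta-squared.

    Returns a DataFrame indexed by term (``A``, ``B``, ``A:B``, ``Residual``)
    with columns ``sum_sq``, ``df``, ``F``, ``p``, ``partial_eta2``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"y": np.asarray(y, dtype=float), "A": list(factor_a), "B": list(factor_b)}
    )
    for f in ("A", "B"):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f} has fewer than two levels")
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    if model.df_resid > 0:
        table = sm.stats.anova_lm(model, typ=2)
        table = table.rename(index={"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"})
    else:
        # saturated design (one observation per cell): build the type-II
        # table by nested least-squares model comparisons
        table = _anova2_nested(df)
    # snap numerically-zero sums of squares (exactly-additive or noise-free
    # designs) so effect sizes are 0/1 rather than ratios of rounding error
    tol = 1e-12 * max(table["sum_sq"].max(), 1e-300)
    table.loc[table["sum_sq"] < tol, "sum_sq"] = 0.0
    ss_resid = table.loc["Residual", "sum_sq"]
    with np.errstate(invalid="ignore"):
        table["partial_eta2"] = table["sum_sq"] / (table["sum_sq"] + ss_resid)
    table.loc[table["sum_sq"] == 0.0, "partial_eta2"] = 0.0
    table.loc["Residual", "partial_eta2"] = np.nan
    table = table.rename(columns={"PR(>F)": "p"})
    return table[["sum_sq", "df", "F", "p", "partial_eta2"]]


def _anova2_nested(df: pd.DataFrame) -> pd.DataFrame:
    """Type-II sums of squares by nested OLS comparisons (no inference)."""
    y = df["y"].to_numpy()
    n = len(y)

    def dummies(col):
        levels = sorted(df[col].unique())
        return np.column_stack([(df[col] == lv).astype(float) for lv in levels[1:]])

    one = np.ones((n, 1))
    A, B = dummies("A"), dummies("B")
    AB = np.column_stack(
        [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    )

    def rss(*parts):
        X = np.column_stack(parts)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(one, A, B, AB)
    rows = {
        "A": (rss(one, B) - rss(one, A, B), A.shape[1]),
        "B": (rss(one, A) - rss(one, A, B), B.shape[1]),
        "A:B": (rss(one, A, B) - rss_full, AB.shape[1]),
        "Residual": (rss_full, n - 1 - A.shape[1] - B.shape[1] - AB.shape[1]),
    }
    out = pd.DataFrame(
        {"sum_sq": [v[0] for v in rows.values()], "df": [float(v[1]) for v in rows.values()]},
        index=list(rows),
    )
    out["F"] = np.nan
    out["PR(>F)"] = np.nan
    return out


def spearman_trend(values, positions) -> dict:
    """Spearman rank correlation of a variable against an ordered position.

    For n <= 9 the p-value is exact (full enumeration of rank
    permutations, two-sided); larger n uses the t approximation.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(positions, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least three observations")
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        raise ValueError("constant input; correlation undefined")
    rho, p_t = scipy.stats.spearmanr(x, y)
    if n <= 9:
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        obs = abs(np.dot(rx, (ry - ry.mean()) / ry.std()) / n)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            ryp = ry[list(perm)]
            r = abs(np.dot(rx, (ryp - ryp.mean()) / ryp.std()) / n)
            count += r >= obs - 1e-12
            total += 1
        return {"rho": float(rho), "p": count / total}
    return {"rho": float(rho), "p": float(p_t)}
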