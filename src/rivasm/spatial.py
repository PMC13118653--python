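"""Dam-count spatial distances, distance-decay, Mantel/MRM, and FDR families.

Spatial separation along the cascade is measured as the number of dams
between two reaches (path-additive along the reach order). Distance-decay
regresses Bray-Curtis dissimilarity on dam counts over unfolded
upper-triangle entries, with significance from the standard Mantel
permutation scheme (simultaneous row+column permutation of one matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from rivasm._seeding import rng_for

__all__ = [
    "read_dam_geometry",
    "reach_dam_distance",
    "dam_distance_matrix",
    "distance_decay",
    "DdrFit",
    "env_distance",
    "mantel",
    "MantelResult",
    "mantel_family",
    "mrm",
    "MrmResult",
    "bh_fdr",
]


def read_dam_geometry(path, sep: str = "\t") -> pd.DataFrame:
    """Reach order with dam counts between adjacent reaches.

    Expects columns ``reach`` (rows in downstream-to-upstream order) and
    ``dams_to_next`` (dams between this reach and the next one; the last
    row's value is ignored and may be 0 or empty).
    """
    df = pd.read_csv(path, sep=sep)
    if "reach" not in df.columns or "dams_to_next" not in df.columns:
        raise ValueError("dam geometry needs 'reach' and 'dams_to_next' columns")
    df["reach"] = df["reach"].astype(str)
    df["dams_to_next"] = df["dams_to_next"].fillna(0).astype(int)
    if (df["dams_to_next"] < 0).any():
        raise ValueError("negative dam counts")
    return df


def reach_dam_distance(geometry: pd.DataFrame) -> DistanceMatrix:
    """Reach-level dam-count distance: sum of intervening-segment counts."""
    reaches = list(geometry["reach"])
    seg = geometry["dams_to_next"].to_numpy()
    # cumulative dams from the first reach up to each reach
    cum = np.concatenate([[0], np.cumsum(seg[:-1])])
    mat = np.abs(cum[:, None] - cum[None, :]).astype(float)
    return DistanceMatrix(mat, ids=reaches)


def dam_distance_matrix(geometry: pd.DataFrame, metadata: pd.DataFrame) -> DistanceMatrix:
    """Sample-level dam-count distance from reach geometry and metadata."""
    rd = reach_dam_distance(geometry)
    reach_index = {r: i for i, r in enumerate(rd.ids)}
    unknown = sorted(set(metadata["reach"].astype(str)) - set(reach_index))
    if unknown:
        raise ValueError(f"reaches absent from geometry: {unknown}")
    idx = [reach_index[str(r)] for r in metadata["reach"]]
    mat = np.asarray(rd.data)[np.ix_(idx, idx)]
    return DistanceMatrix(mat, ids=list(metadata["sample_id"].astype(str)))


def _triangles(*mats):
    n = mats[0].shape[0]
    iu = np.triu_indices(n, k=1)
    return [m[iu] for m in mats]


def _aligned(dx: DistanceMatrix, dy: DistanceMatrix):
    if list(dx.ids) != list(dy.ids):
        dy = dy.filter(dx.ids)
    return np.asarray(dx.data, float), np.asarray(dy.data, float)


@dataclass
class MantelResult:
    r: float
    p_perm: float
    n_permutations: int
    variable: str = ""
    q: float = float("nan")


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "pearson",
    alternative: str = "two-sided",
    variable: str = "",
) -> MantelResult:
    """Mantel test: correlation of unfolded upper triangles with a
    row+column permutation null on the second matrix."""
    mx, my = _aligned(dx, dy)
    n = mx.shape[0]
    iu = np.triu_indices(n, k=1)
    x, y = mx[iu], my[iu]
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("degenerate (constant) distance triangle")
    corr = scipy.stats.pearsonr if method == "pearson" else scipy.stats.spearmanr
    r_obs = float(corr(x, y)[0])
    rng = rng_for(seed, "mantel", variable)
    count = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        yp = my[np.ix_(perm, perm)][iu]
        r_p = corr(x, yp)[0]
        if alternative == "greater":
            count += r_p >= r_obs - 1e-12
        elif alternative == "less":
            count += r_p <= r_obs + 1e-12
        else:
            count += abs(r_p) >= abs(r_obs) - 1e-12
    p = (count + 1) / (int(n_perm) + 1)
    return MantelResult(r=r_obs, p_perm=p, n_permutations=int(n_perm), variable=variable)


@dataclass
class DdrFit:
    slope: float       # Bray-Curtis units per dam
    intercept: float
    r_mantel: float
    p_perm: float
    r2: float
    n_pairs: int


def distance_decay(
    bc: DistanceMatrix,
    dams: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> DdrFit:
    """Distance-decay of community dissimilarity with dam count.

    OLS of unfolded Bray-Curtis on dam counts gives slope/intercept/R2;
    the p-value is a Mantel permutation test of the correlation.
    """
    mb, md = _aligned(bc, dams)
    y, x = _triangles(mb, md)
    if np.allclose(x, x[0]):
        raise ValueError("constant dam distances; decay undefined")
    if np.allclose(y, y[0]):
        # flat dissimilarities: zero decay, no correlation to test
        return DdrFit(slope=0.0, intercept=float(y[0]), r_mantel=0.0,
                      p_perm=1.0, r2=0.0, n_pairs=len(x))
    slope, intercept = np.polyfit(x, y, 1)
    r = float(scipy.stats.pearsonr(x, y)[0])
    res = mantel(bc, dams, n_perm=n_perm, seed=seed, alternative=alternative, variable="ddr")
    return DdrFit(
        slope=float(slope),
        intercept=float(intercept),
        r_mantel=r,
        p_perm=res.p_perm,
        r2=r * r,
        n_pairs=len(x),
    )


def env_distance(
    env: pd.DataFrame,
    variables,
    season: str,
    metadata: pd.DataFrame | None = None,
    ddof: int = 0,
) -> DistanceMatrix:
    """Environmental distance for one season.

    Each variable is z-scored within the season (population SD by default);
    the distance is Euclidean over the z-scored vector (for a single
    variable this is |z_i - z_j|). With ``metadata`` given, reach values are
    broadcast to samples and the matrix is sample-level.
    """
    if isinstance(variables, str):
        variables = [variables]
    sub = env[env["season"].astype(str) == str(season)].set_index("reach")
    z = {}
    for v in variables:
        if v not in sub.columns:
            raise ValueError(f"variable {v!r} absent from environmental table")
        vals = sub[v].astype(float)
        sd = vals.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"variable {v!r} has zero variance in season {season!r}")
        z[v] = (vals - vals.mean()) / sd
    zdf = pd.DataFrame(z)
    if metadata is not None:
        md = metadata[metadata["season"].astype(str) == str(season)]
        pts = zdf.loc[[str(r) for r in md["reach"]]].to_numpy()
        ids = list(md["sample_id"].astype(str))
    else:
        pts = zdf.to_numpy()
        ids = [str(r) for r in zdf.index]
    diff = pts[:, None, :] - pts[None, :, :]
    mat = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(mat, ids=ids)


def mantel_family(
    bc: DistanceMatrix,
    env: pd.DataFrame,
    variables,
    season: str,
    metadata: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel tests of community dissimilarity against each environmental
    variable within one season, BH-FDR adjusted as one family."""
    results = []
    for v in variables:
        dv = env_distance(env, v, season, metadata=metadata)
        res = mantel(bc, dv, n_perm=n_perm, seed=seed, variable=v)
        results.append(res)
    qs = bh_fdr([r.p_perm for r in results])
    rows = []
    for res, q in zip(results, qs):
        res.q = q
        rows.append(
            {"variable": res.variable, "r": res.r, "p": res.p_perm, "q": q, "season": season}
        )
    return pd.DataFrame(rows)


@dataclass
class MrmResult:
    coefficients: pd.Series    # per predictor (plus intercept)
    r2: float
    p_perm: pd.Series
    n_permutations: int


def mrm(
    dy: DistanceMatrix,
    predictors: dict,
    n_perm: int = 999,
    seed: int = 0,
) -> MrmResult:
    """Multiple regression on distance matrices.

    ``predictors`` maps names to DistanceMatrix objects. Coefficients come
    from OLS on unfolded upper triangles; per-coefficient p-values from
    permuting the response matrix's rows and columns jointly.
    """
    if not predictors:
        raise ValueError("need at least one predictor matrix")
    names = list(predictors)
    my = np.asarray(dy.data, float)
    n = my.shape[0]
    iu = np.triu_indices(n, k=1)
    xs = []
    for name in names:
        _, mx = _aligned(dy, predictors[name])
        xs.append(mx[iu])
    X = np.column_stack([np.ones(len(xs[0]))] + xs)
    cond = np.linalg.cond(X)
    if cond > 1e8:
        warnings.warn(f"predictor matrices nearly collinear (condition number {cond:.2g})")
    y = my[iu]

    def fit(yv):
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        sst = ((yv - yv.mean()) ** 2).sum()
        r2 = 1.0 - (resid**2).sum() / sst if sst > 0 else np.nan
        return beta, r2

    beta_obs, r2 = fit(y)
    rng = rng_for(seed, "mrm")
    counts = np.zeros(len(beta_obs))
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        yp = my[np.ix_(perm, perm)][iu]
        beta_p, _ = fit(yp)
        counts += np.abs(beta_p) >= np.abs(beta_obs) - 1e-12
    pvals = (counts + 1) / (int(n_perm) + 1)
    index = ["intercept"] + names
    return MrmResult(
        coefficients=pd.Series(beta_obs, index=index),
        r2=float(r2),
        p_perm=pd.Series(pvals, index=index),
        n_permutations=int(n_perm),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
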