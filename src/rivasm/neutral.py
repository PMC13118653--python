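"""Sloan neutral community model: fit, envelope, and OTU partitioning.

The model predicts a taxon's detection frequency across samples from its
mean relative abundance p via the stationary Beta law of a local
community of size N coupled to a source pool with per-birth immigration
probability m:

    freq_pred(p) = 1 - BetaCDF(d; N m p, N m (1 - p)),

evaluated at the detection limit d. Detection in count data means at
least one read out of N, i.e. a relative abundance above the midpoint
between zero and one read, so the default detection limit applies a
continuity correction, d = 0.5/N; fitting the continuous Beta law at the
raw single-read abundance d = 1/N systematically overestimates m, and
that convention remains available through the ``detection_limit``
argument. m is estimated by nonlinear least squares of observed
frequencies on p; the single composite parameter is Nm. The 95% envelope
uses Wilson binomial prediction bounds around the fitted curve at the
realized number of samples, and OTUs are partitioned as above / neutral /
below the envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import beta as beta_dist
from statsmodels.stats.proportion import proportion_confint

from rivasm.tables import CommunityTable, tss_normalize

__all__ = ["ncm_prepare", "ncm_fit", "ncm_report", "NcmInput", "NcmFit", "predicted_frequency"]


@dataclass
class NcmInput:
    data: pd.DataFrame       # per OTU: mean_rel_abund, freq
    n: float                 # community size (mean library size)
    detection_limit: float   # d, default 1/N
    n_samples: int


@dataclass
class NcmFit:
    m: float
    nm: float
    r2: float
    n: float
    detection_limit: float
    n_samples: int
    data: pd.DataFrame       # adds predicted, lower, upper, partition


def ncm_prepare(table: CommunityTable, detection_limit: float | None = None) -> NcmInput:
    """Per-OTU mean TSS relative abundance and occurrence frequency.

    N is the mean library size of the table (equal to the rarefaction
    depth if the table was rarefied); OTUs absent from every sample are
    excluded. The detection limit defaults to the continuity-corrected
    0.5/N (see the module docstring).
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    rel = tss_normalize(table)
    mean_p = rel.mean(axis=1)
    freq = (table.counts > 0).mean(axis=1)
    df = pd.DataFrame(
        {"mean_rel_abund": mean_p.to_numpy(), "freq": freq}, index=table.otu_ids
    )
    df = df[df["freq"] > 0]
    if df.empty:
        raise ValueError("no occurring OTUs")
    n = float(table.library_sizes().mean())
    d = 0.5 / n if detection_limit is None else float(detection_limit)
    return NcmInput(data=df, n=n, detection_limit=d, n_samples=table.n_samples)


def predicted_frequency(p, n: float, m: float, d: float) -> np.ndarray:
    """Neutral prediction: probability a taxon exceeds the detection limit."""
    p = np.asarray(p, dtype=float)
    nm = n * m
    a = np.clip(nm * p, 1e-12, None)
    b = np.clip(nm * (1.0 - p), 1e-12, None)
    return 1.0 - beta_dist.cdf(d, a, b)


def ncm_fit(inp: NcmInput, alpha: float = 0.05) -> NcmFit:
    """Estimate m by least squares of observed frequency on the Beta-law curve."""
    df = inp.data
    p = df["mean_rel_abund"].to_numpy()
    f = df["freq"].to_numpy()
    if len(df) < 10 or (p.max() / p.min()) < 10:
        import warnings

        warnings.warn("few OTUs or narrow abundance range; m estimate may be unstable")

    def sse(log_m):
        pred = predicted_frequency(p, inp.n, float(np.exp(log_m)), inp.detection_limit)
        return ((f - pred) ** 2).sum()

    res = minimize_scalar(sse, bounds=(np.log(1e-8), 0.0), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"neutral-model fit did not converge: {res.message}")
    m = float(np.clip(np.exp(res.x), 1e-8, 1.0))
    pred = predicted_frequency(p, inp.n, m, inp.detection_limit)
    sst = ((f - f.mean()) ** 2).sum()
    r2 = 1.0 - ((f - pred) ** 2).sum() / sst if sst > 0 else np.nan

    k = np.clip(pred * inp.n_samples, 0, inp.n_samples)
    lower, upper = proportion_confint(k, inp.n_samples, alpha=alpha, method="wilson")
    partition = np.where(f > upper, "above", np.where(f < lower, "below", "neutral"))
    out = df.copy()
    out["predicted"] = pred
    out["lower"] = lower
    out["upper"] = upper
    out["partition"] = partition
    return NcmFit(
        m=m,
        nm=inp.n * m,
        r2=float(r2),
        n=inp.n,
        detection_limit=inp.detection_limit,
        n_samples=inp.n_samples,
        data=out,
    )


def ncm_report(fit: NcmFit) -> dict:
    """Headline summary: R2, m, Nm and envelope partition counts."""
    counts = fit.data["partition"].value_counts()
    return {
        "m": fit.m,
        "Nm": fit.nm,
        "R2": fit.r2,
        "N": fit.n,
        "n_otus": int(len(fit.data)),
        "above": int(counts.get("above", 0)),
        "neutral": int(counts.get("neutral", 0)),
        "below": int(counts.get("below", 0)),
    }
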