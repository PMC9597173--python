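"""Synthetic CpG maps, methylation landscapes, feature tracks and reads.

Emulates the statistical structure of the real inputs the downstream analysis
assumes: CpG positions with region-specific spacing (median inter-CpG distance
~10 bp in CpG islands, ~161 bp intergenic), a bimodal spatially correlated
parental methylation landscape f in [0, 1], per-site feature tracks
(bulk methylation q, 500-bp CpG density r, accessibility s), and read-level
pulse-chase bisulfite observations at chase timepoints 0/1/4/16 h with uniform
1-h pulse jitter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from . import TIMEPOINTS_H

__all__ = [
    "gen_cpg_positions",
    "gen_landscape",
    "gen_feature_tracks",
    "gen_replibs_reads",
    "cpg_density",
]

#: CpG dinucleotides cannot overlap, so adjacent cytosines are >= 2 bp apart.
MIN_SPACING = 2


def gen_cpg_positions(
    n_sites: int,
    median_spacing: float = 10,
    seed: int | np.random.Generator = 0,
    start: int = 0,
) -> np.ndarray:
    """Generate strictly increasing CpG cytosine coordinates.

    Inter-CpG gaps are drawn from a shifted geometric distribution with
    minimum 2 bp, parameterized so the distribution's median equals
    ``median_spacing``. The memoryless gap model reproduces the regional
    median spacings observed in real annotation classes with one parameter.

    Parameters
    ----------
    n_sites
        Number of CpG sites (>= 1).
    median_spacing
        Target median inter-CpG distance in bp (>= 2).
    seed
        Seed or generator for reproducible draws.
    start
        Coordinate of the first site.

    Returns
    -------
    ndarray of int64, strictly increasing positions.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if median_spacing < MIN_SPACING:
        raise ValueError(f"median_spacing must be >= {MIN_SPACING} bp")
    rng = np.random.default_rng(seed)
    if n_sites == 1:
        return np.array([start], dtype=np.int64)
    if median_spacing == MIN_SPACING:
        gaps = np.full(n_sites - 1, MIN_SPACING, dtype=np.int64)
    else:
        # gap = 1 + G with G ~ Geometric(p) on {1, 2, ...}; the median of G
        # is ceil(-1 / log2(1 - p)). The half-unit offset keeps the CDF at
        # the target strictly above 1/2, so the sample median does not sit
        # on a probability-one-half boundary.
        p = 1.0 - 2.0 ** (-1.0 / max(median_spacing - 1.5, 1.0))
        gaps = 1 + rng.geometric(p, size=n_sites - 1).astype(np.int64)
    return start + np.concatenate([[0], np.cumsum(gaps)])


def gen_landscape(
    positions: np.ndarray,
    corr_length: float = 500.0,
    meth_mean: float = 0.8,
    seed: int | np.random.Generator = 0,
    steepness: float = 4.0,
) -> np.ndarray:
    """Generate a bimodal, spatially correlated methylation landscape.

    A latent Gaussian field with exponential autocorrelation of length
    ``corr_length`` (an AR(1) process in genomic distance) is squashed through
    a steep logistic centred at the normal quantile of ``1 - meth_mean``,
    producing per-site methylation fractions with mass near 0 and near 1 and
    mean close to ``meth_mean``.

    Parameters
    ----------
    positions
        Sorted CpG coordinates.
    corr_length
        Autocorrelation length of the latent field in bp; 0 gives
        spatially independent sites.
    meth_mean
        Target mean methylation fraction, in (0, 1).
    steepness
        Logistic slope; larger values give a harder 0/1 dichotomy.
    """
    if corr_length < 0:
        raise ValueError("corr_length must be >= 0")
    if not 0.0 < meth_mean < 1.0:
        raise ValueError("meth_mean must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(positions)
    z = np.empty(n)
    eps = rng.standard_normal(n)
    z[0] = eps[0]
    if corr_length == 0:
        z = eps
    else:
        gaps = np.diff(np.asarray(positions, dtype=float))
        rho = np.exp(-gaps / corr_length)
        innov = np.sqrt(1.0 - rho**2)
        for i in range(1, n):
            z[i] = rho[i - 1] * z[i - 1] + innov[i - 1] * eps[i]
    threshold = _calibrated_threshold(meth_mean, steepness)
    return expit(steepness * (z - threshold))


def _calibrated_threshold(meth_mean: float, steepness: float) -> float:
    """Logistic centre c such that E[expit(s(Z - c))] = meth_mean, Z ~ N(0,1).

    A plain threshold at the normal quantile biases the mean because the
    logistic is not a step function; this solves for the exact centre by
    quadrature over the standard-normal latent marginal.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    zg = np.linspace(-8, 8, 2001)
    w = norm.pdf(zg)
    w /= w.sum()

    def mean_at(c):
        return float(np.sum(w * expit(steepness * (zg - c)))) - meth_mean

    lo, hi = ndtri(1.0 - meth_mean) - 4.0, ndtri(1.0 - meth_mean) + 4.0
    return brentq(mean_at, lo, hi)


def cpg_density(positions: np.ndarray, window: int = 500) -> np.ndarray:
    """Count other CpGs within a centred window of each site.

    The count excludes the site itself and uses a window of total width
    ``window`` bp (i.e. +/- window/2 around the cytosine).
    """
    pos = np.asarray(positions)
    half = window / 2.0
    hi = np.searchsorted(pos, pos + half, side="right")
    lo = np.searchsorted(pos, pos - half, side="left")
    return (hi - lo - 1).astype(np.int64)


def gen_feature_tracks(
    positions: np.ndarray,
    landscape: np.ndarray,
    seed: int | np.random.Generator = 0,
    window: int = 500,
    s_base: float = 2.0,
    s_slope: float = 1.5,
    s_noise: float = 0.2,
) -> pd.DataFrame:
    """Generate the per-site feature triple (q, r, s).

    q is the bulk methylation level (taken equal to the landscape), r the
    local CpG density (neighbours within a 500 bp centred window), and s a
    non-negative accessibility score constructed as a smoothed positive
    signal anticorrelated with methylation, mimicking the negative
    methylation-accessibility trend of open chromatin.
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(landscape, dtype=float)
    r = cpg_density(positions, window=window)
    smooth_q = pd.Series(q).rolling(25, center=True, min_periods=1).mean().to_numpy()
    s = np.clip(s_base - s_slope * smooth_q + s_noise * rng.standard_normal(len(q)), 0.0, None)
    return pd.DataFrame({"q": q, "r": r, "s": s})


def gen_replibs_reads(
    k: np.ndarray,
    f: np.ndarray,
    depth: float | np.ndarray = 30.0,
    seed: int | np.random.Generator = 0,
    timepoints: tuple[float, ...] = TIMEPOINTS_H,
    fragment_sites: int = 1,
) -> pd.DataFrame:
    """Sample read-level pulse-chase observations from kinetic ground truth.

    Each read at chase time ``t`` observes the nascent strand at a jittered
    post-replication age ``tau = t + U[0, 1]`` h (the 1-h labelling pulse
    makes the true age uncertain within the window) and is methylated with
    probability ``f * (1 - exp(-k * tau))``.

    Parameters
    ----------
    k, f
        Per-site remethylation rate (1/h) and plateau fraction.
    depth
        Mean total read depth per site summed over timepoints. Per-site,
        per-timepoint depths are Poisson with mean ``depth / n_timepoints``.
    fragment_sites
        When > 1, consecutive sites are grouped into read fragments of this
        many CpGs sharing one sampled age per timepoint draw, reproducing the
        read-length artefact of fragment-based sequencing.

    Returns
    -------
    DataFrame with columns ``site`` (index into the site list), ``t_chase_h``
    and ``call`` (1 = methylated).
    """
    depth_arr = np.broadcast_to(np.asarray(depth, dtype=float), np.shape(k))
    if np.any(depth_arr < 0):
        raise ValueError("depth must be >= 0")
    if fragment_sites < 1:
        raise ValueError("fragment_sites must be >= 1")
    rng = np.random.default_rng(seed)
    k = np.asarray(k, dtype=float)
    f = np.asarray(f, dtype=float)
    n = len(k)
    per_tp = depth_arr / len(timepoints)
    frames = []
    frag_id = np.arange(n) // fragment_sites
    n_frags = int(frag_id[-1]) + 1 if n else 0
    for t in timepoints:
        if fragment_sites == 1:
            counts = rng.poisson(per_tp)
            site_idx = np.repeat(np.arange(n), counts)
            tau = t + rng.random(site_idx.size)
        else:
            # whole fragments are sampled; all member CpGs of a fragment
            # share one jittered age, as on a physical sequencing read
            frag_mean = np.bincount(frag_id, weights=per_tp, minlength=n_frags)
            frag_mean /= np.bincount(frag_id, minlength=n_frags)
            frag_counts = rng.poisson(frag_mean)
            members = [np.flatnonzero(frag_id == g) for g in range(n_frags)]
            site_chunks, tau_chunks = [], []
            for g, c in enumerate(frag_counts):
                for _ in range(c):
                    site_chunks.append(members[g])
                    tau_chunks.append(np.full(members[g].size, t + rng.random()))
            site_idx = (
                np.concatenate(site_chunks) if site_chunks else np.empty(0, dtype=int)
            )
            tau = np.concatenate(tau_chunks) if tau_chunks else np.empty(0)
        p = f[site_idx] * -np.expm1(-k[site_idx] * tau)
        call = (rng.random(site_idx.size) < p).astype(np.int8)
        frames.append(
            pd.DataFrame({"site": site_idx, "t_chase_h": t, "call": call})
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["site", "t_chase_h"], kind="stable").reset_index(drop=True)
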