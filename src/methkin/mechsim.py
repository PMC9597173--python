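"""Stochastic simulation of post-replication maintenance methylation.

Two candidate DNMT1 mechanisms act on a strand of CpGs whose parental
methylation is drawn from an input landscape:

* distributive - the enzyme binds each hemimethylated CpG independently with
  rate k_f; catalysis and unbinding are merged into one reaction (k_off >>
  k_cat), so methylation times are independent Exponential(k_f) draws.
* processive - after catalysing at a CpG the enzyme can stay DNA-bound and
  reach neighbouring targets by 1D diffusion (sliding) with diffusion
  coefficient D and unbinding rate k_off. The competition between reaching
  the nearest remaining target left or right and unbinding is resolved by
  closed-form splitting probabilities of diffusion-with-killing, with decay
  length lambda = sqrt(D / k_off). Sliding is instantaneous on the hour
  scale of the readouts, so a processive chain executes atomically at the
  firing time of the clock that started it.

Readouts emulate WGBS (each replicate observed at an independent U[0, 24] h
time, fractions averaged over replicates) and pulse-chase bisulfite reads
(binary nascent state at t_chase + U[0, 1] h for chase times 0/1/4/16 h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import TIMEPOINTS_H

__all__ = [
    "SimulationParams",
    "init_state",
    "splitting_probs",
    "simulate_distributive",
    "simulate_processive",
    "simulate_replicates",
    "readout_wgbs",
    "readout_replibs",
]

DEFAULT_KF = 0.7     # 1/h; ~half the targets methylated within the first hour
DEFAULT_LAMBDA = 36.0  # bp; sliding length sqrt(D/k_off)


@dataclass
class SimulationParams:
    """Parameters of one maintenance-methylation simulation."""

    mechanism: str = "processive"          # "distributive" | "processive"
    k_f: float = DEFAULT_KF                # de novo binding rate per target (1/h)
    lam: float = DEFAULT_LAMBDA            # sliding length sqrt(D/k_off) (bp)
    t_end: float = 17.0                    # simulated horizon (h)
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.mechanism not in ("distributive", "processive"):
            raise ValueError("mechanism must be 'distributive' or 'processive'")
        if self.k_f < 0 or self.t_end < 0 or self.n_replicates < 1:
            raise ValueError("rates, horizon and replicate count must be non-negative")
        if self.mechanism == "processive" and not self.lam >= 0:
            raise ValueError("processive mechanism requires lambda >= 0")

    @classmethod
    def from_diffusion(cls, D: float, k_off: float, **kw) -> "SimulationParams":
        """Build processive parameters from D (bp^2/s) and k_off (1/s)."""
        if D <= 0 or k_off <= 0:
            raise ValueError("D and k_off must be > 0")
        return cls(mechanism="processive", lam=math.sqrt(D / k_off), **kw)


def init_state(landscape: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample parental methylation: Bernoulli(f_i) per site, independently.

    The nascent strand starts fully unmethylated; only sites with a
    methylated parent are maintenance targets.
    """
    f = np.asarray(landscape, dtype=float)
    return rng.random(f.shape) < f


def splitting_probs(d_left: float | None, d_right: float | None, lam: float):
    """Splitting probabilities for a 1D diffuser with unbinding.

    An enzyme released at a just-methylated site sees its nearest remaining
    targets at distances ``d_left`` and ``d_right`` (either may be None when
    absent). Solving D u'' = k_off u with absorbing boundaries gives

        P_right = sinh(d_left/lam) / sinh((d_left + d_right)/lam)
        P_left  = sinh(d_right/lam) / sinh((d_left + d_right)/lam)

    and P_unbind = 1 - P_left - P_right. One-sided: P_reach = exp(-d/lam).
    The lam -> inf limit is the gambler's-ruin split d_left/(d_left+d_right).
    """
    for d in (d_left, d_right):
        if d is not None and d <= 0:
            raise ValueError("target distances must be > 0")
    if lam <= 0:
        # degenerate diffusion: the enzyme can never reach a neighbour
        return (0.0, 0.0, 1.0) if (d_left or d_right) else (0.0, 0.0, 1.0)
    if d_left is None and d_right is None:
        return (0.0, 0.0, 1.0)
    if d_left is None:
        pr = math.exp(-d_right / lam)
        return (0.0, pr, 1.0 - pr)
    if d_right is None:
        pl = math.exp(-d_left / lam)
        return (pl, 0.0, 1.0 - pl)
    # numerically stable sinh ratios: sinh(a)/sinh(b) = e^{a-b} (1-e^{-2a})/(1-e^{-2b})
    total = d_left + d_right
    pr = math.exp((d_left - total) / lam) * (-math.expm1(-2 * d_left / lam)) / (
        -math.expm1(-2 * total / lam))
    pl = math.exp((d_right - total) / lam) * (-math.expm1(-2 * d_right / lam)) / (
        -math.expm1(-2 * total / lam))
    return (pl, pr, max(1.0 - pl - pr, 0.0))


def simulate_distributive(
    positions: np.ndarray,
    parental: np.ndarray,
    k_f: float,
    t_end: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Methylation times under independent rebinding.

    Each hemimethylated target acquires nascent methylation at an independent
    Exponential(k_f) time, truncated at ``t_end``. Returns per-site times
    (h), inf where the site never methylates within the horizon.
    """
    tau = np.full(len(positions), np.inf)
    targets = np.flatnonzero(parental)
    if targets.size == 0 or k_f <= 0:
        return tau
    t = rng.exponential(1.0 / k_f, size=targets.size)
    t[t > t_end] = np.inf
    tau[targets] = t
    return tau


def simulate_processive(
    positions: np.ndarray,
    parental: np.ndarray,
    k_f: float,
    lam: float,
    t_end: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Methylation times under sliding-with-unbinding processivity.

    Every remaining target holds an Exponential(k_f) de novo binding clock.
    When a clock fires, the site methylates and the enzyme iterates a
    processive chain: the nearest remaining targets left and right compete
    per the diffusion splitting probabilities; a reached target methylates
    at the same clock time (sliding is instantaneous at hour scale), leaves
    the pending set, and the chain continues from it until the enzyme
    unbinds. Beyond the strand ends the enzyme unbinds.
    """
    n = len(positions)
    tau = np.full(n, np.inf)
    targets = np.flatnonzero(parental)
    m = targets.size
    if m == 0 or k_f <= 0:
        return tau
    pos = np.asarray(positions, dtype=np.int64)[targets]
    fire = rng.exponential(1.0 / k_f, size=m)
    order = np.argsort(fire, kind="stable")
    # doubly linked list over remaining targets (ordinal indexing)
    nxt = np.arange(1, m + 1)
    prv = np.arange(-1, m - 1)
    alive = np.ones(m, dtype=bool)

    def unlink(i: int) -> None:
        alive[i] = False
        a, b = prv[i], nxt[i]
        if a >= 0:
            nxt[a] = b
        if b < m:
            prv[b] = a

    for i in order:
        t = fire[i]
        if t > t_end:
            break
        if not alive[i]:
            continue
        tau[targets[i]] = t
        unlink(i)
        cur = i
        while True:
            left, right = prv[cur], nxt[cur]
            d_l = float(pos[cur] - pos[left]) if left >= 0 else None
            d_r = float(pos[right] - pos[cur]) if right < m else None
            p_l, p_r, _ = splitting_probs(d_l, d_r, lam)
            u = rng.random()
            if u < p_l:
                cur = left
            elif u < p_l + p_r:
                cur = right
            else:
                break
            tau[targets[cur]] = t
            unlink(cur)
    return tau


def simulate_replicates(
    positions: np.ndarray,
    landscape: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run replicate strands; parental states are resampled per replicate.

    Returns ``(parental, tau)`` arrays of shape (n_replicates, n_sites);
    ``tau`` is inf where a site never methylates within the horizon.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = len(positions)
    parental = np.empty((params.n_replicates, n), dtype=bool)
    tau = np.empty((params.n_replicates, n))
    for r in range(params.n_replicates):
        parental[r] = init_state(landscape, rng)
        if params.mechanism == "distributive":
            tau[r] = simulate_distributive(positions, parental[r], params.k_f,
                                           params.t_end, rng)
        else:
            tau[r] = simulate_processive(positions, parental[r], params.k_f,
                                         params.lam, params.t_end, rng)
    return parental, tau


def readout_wgbs(
    tau: np.ndarray,
    rng: np.random.Generator,
    t_end: float,
    t_max: float = 24.0,
) -> np.ndarray:
    """Bulk-methylation emulation: per-site fraction over replicate strands.

    Each replicate is observed at an independent uniform time in
    [0, ``t_max``] h, reflecting the unsynchronized post-replication ages of
    bulk cells; the per-site methylated fraction averages the binary states
    over replicates.
    """
    if t_end < t_max:
        raise ValueError(f"simulation horizon {t_end} h is shorter than the "
                         f"{t_max} h readout window")
    n_rep = tau.shape[0]
    t_obs = rng.uniform(0.0, t_max, size=n_rep)
    states = tau <= t_obs[:, None]
    return states.mean(axis=0)


def readout_replibs(
    tau: np.ndarray,
    depth: float | np.ndarray = 30.0,
    rng: np.random.Generator | None = None,
    timepoints: tuple[float, ...] = TIMEPOINTS_H,
) -> pd.DataFrame:
    """Pulse-chase read emulation from simulated trajectories.

    Per site and chase timepoint, ``Poisson(depth / n_timepoints)`` reads are
    drawn; each read picks a replicate uniformly and observes the nascent
    state at age ``t_chase + U[0, 1]`` h. Returns the same schema as the
    kinetic-truth read generator (columns site, t_chase_h, call).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n_rep, n_sites = tau.shape
    depth_arr = np.broadcast_to(np.asarray(depth, dtype=float), (n_sites,))
    if np.any(depth_arr < 0):
        raise ValueError("depth must be >= 0")
    per_tp = depth_arr / len(timepoints)
    frames = []
    for t in timepoints:
        counts = rng.poisson(per_tp)
        site_idx = np.repeat(np.arange(n_sites), counts)
        rep = rng.integers(0, n_rep, size=site_idx.size)
        t_sample = t + rng.random(site_idx.size)
        call = (tau[rep, site_idx] <= t_sample).astype(np.int8)
        frames.append(pd.DataFrame({"site": site_idx, "t_chase_h": t, "call": call}))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["site", "t_chase_h"], kind="stable").reset_index(drop=True)
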