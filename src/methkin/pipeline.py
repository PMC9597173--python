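"""End-to-end reproducible pipeline: synth -> simulate -> infer -> correlate
-> decompose.

A single global seed is fanned out to named per-stage streams (via
``numpy.random.SeedSequence`` keyed on the stage name), so any stage can be
re-run independently yet reproducibly. All intermediates are plain-text TSV /
BED / bedGraph; every stage logs its parameters and derived seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, synthgen
from .corrfuncs import distance_correlation, loess_smooth, mean_magnitude
from .decompose import decompose_correlation
from .inference import filter_inferable, fit_reads
from .mechsim import SimulationParams, readout_replibs, readout_wgbs, simulate_replicates

log = logging.getLogger("methkin")

__all__ = ["PipelineConfig", "stage_seed", "stage_rng", "run_pipeline"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed and name."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage))


@dataclass
class PipelineConfig:
    """Parameters of the full synthetic-data pipeline."""

    seed: int = 0
    out_dir: str = "results/pipeline"
    chrom: str = "chrS"
    # synth
    n_sites: int = 25_000
    median_spacing: float = 10.0
    corr_length: float = 500.0
    meth_mean: float = 0.8
    # simulate
    mechanism: str = "processive"
    k_f: float = 0.7
    lam: float = 36.0
    t_end: float = 24.0
    n_replicates: int = 10
    # reads / inference
    depth: float = 30.0
    k_max: float = 10.0
    min_reads: int = 10
    # correlate / decompose
    d_max: int = 1000
    span: float = 100.0
    min_pairs: int = 50
    n_clusters: int = 8
    n_shuffles: int = 10
    fit_window: int = 100
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        extra = data.pop("extra")
        data.update(extra)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order, writing intermediates and a summary.

    Returns the artefact directory. Identical config and seed reproduce
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed}

    def _stage(name):
        seed = stage_seed(config.seed, name)
        log.info("stage %s: seed=%d", name, seed)
        summary.setdefault("stage_seeds", {})[name] = seed
        return np.random.default_rng(seed)

    try:
        # --- synth -----------------------------------------------------
        rng = _stage("synth")
        positions = synthgen.gen_cpg_positions(config.n_sites,
                                               config.median_spacing, rng)
        landscape = synthgen.gen_landscape(positions, config.corr_length,
                                           config.meth_mean, rng)
        features = synthgen.gen_feature_tracks(positions, landscape, rng)
        io.write_methylation(out / "landscape.bedgraph", config.chrom,
                             positions, landscape)
        features.assign(chrom=config.chrom, pos=positions).to_csv(
            out / "features.tsv", sep="\t", index=False, float_format="%.6g")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'synth' failed: {exc}") from exc

    try:
        # --- simulate --------------------------------------------------
        rng = _stage("simulate")
        params = SimulationParams(mechanism=config.mechanism, k_f=config.k_f,
                                  lam=config.lam, t_end=config.t_end,
                                  n_replicates=config.n_replicates)
        parental, tau = simulate_replicates(positions, landscape, params, rng)
        wgbs = readout_wgbs(tau, rng, t_end=config.t_end)
        io.write_methylation(out / "wgbs.bedgraph", config.chrom, positions, wgbs)
        reads = readout_replibs(tau, depth=config.depth, rng=rng)
        io.write_reads(out / "reads.tsv", reads, config.chrom, positions)
        summary["n_reads"] = int(len(reads))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    try:
        # --- infer-rates -----------------------------------------------
        rates = fit_reads(reads, n_sites=len(positions), k_max=config.k_max,
                          min_reads=config.min_reads)
        io.write_rates(out / "rates.tsv", rates, config.chrom, positions)
        summary["n_inferable"] = int(len(filter_inferable(rates)))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'infer-rates' failed: {exc}") from exc

    try:
        # --- correlate -------------------------------------------------
        keep = filter_inferable(rates)
        k_vals = np.full(len(positions), np.nan)
        k_vals[keep] = rates["k"].to_numpy()[keep]
        corr_rate = distance_correlation(positions, k_vals, d_max=config.d_max,
                                         min_pairs=config.min_pairs,
                                         meta={"quantity": "rate"})
        loess_smooth(corr_rate, span=config.span)
        corr_state = distance_correlation(positions, wgbs, d_max=config.d_max,
                                          min_pairs=config.min_pairs,
                                          meta={"quantity": "state_bulk"})
        loess_smooth(corr_state, span=config.span)
        corr = pd.concat([corr_rate.to_frame(), corr_state.to_frame()],
                         ignore_index=True)
        corr.to_csv(out / "correlation.tsv", sep="\t", index=False,
                    float_format="%.6g")
        summary["rate_magnitude"] = float(mean_magnitude(corr_rate))
        summary["state_magnitude"] = float(mean_magnitude(corr_state))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'correlate' failed: {exc}") from exc

    try:
        # --- decompose -------------------------------------------------
        dec = decompose_correlation(
            positions, k_vals, features[["q", "r", "s"]].to_numpy(),
            d_max=config.d_max, n_clusters=config.n_clusters,
            n_shuffles=config.n_shuffles, min_pairs=config.min_pairs,
            window=config.fit_window, seed=stage_seed(config.seed, "decompose"))
        dec.to_frame().to_csv(out / "decomposition.tsv", sep="\t", index=False,
                              float_format="%.6g")
        if dec.fit is not None and dec.fit.converged:
            summary["decay_constant_per_bp"] = dec.fit.decay_constant
            summary["decay_length_bp"] = dec.fit.decay_length
            summary["d_over_koff_bp2"] = dec.fit.d_over_koff
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'decompose' failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out
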