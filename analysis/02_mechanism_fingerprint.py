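#!/usr/bin/env python
"""Distributive vs processive maintenance: the rate-correlation fingerprint.

Simulates both mechanisms on the same bimodal landscape, emulates bulk
(WGBS-like) and pulse-chase readouts, infers per-site rates, and contrasts
the distance-resolved correlation of rates and states. The distributive
mechanism should leave rates uncorrelated at all distances, while the
processive mechanism imprints an exponentially decaying rate correlation;
bulk state correlation follows the input landscape under both.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from methkin import synthgen
from methkin.corrfuncs import distance_correlation, loess_smooth, mean_magnitude
from methkin.inference import filter_inferable, fit_reads
from methkin.mechsim import (
    SimulationParams,
    readout_replibs,
    readout_wgbs,
    simulate_replicates,
)
from methkin.pipeline import stage_rng


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-sites", type=int, default=10_000)
    ap.add_argument("--out-dir", type=Path,
                    default=Path("results/02_mechanism_fingerprint"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rng = stage_rng(args.seed, "fingerprint-sites")
    pos = synthgen.gen_cpg_positions(args.n_sites, 10, seed=rng)
    land = synthgen.gen_landscape(pos, corr_length=500.0, meth_mean=0.8, seed=rng)

    frames, summary = [], []
    for mechanism in ("distributive", "processive"):
        sim_rng = stage_rng(args.seed, f"fingerprint-{mechanism}")
        params = SimulationParams(mechanism=mechanism, k_f=0.7, lam=36.0,
                                  t_end=24.0, n_replicates=10)
        _, tau = simulate_replicates(pos, land, params, sim_rng)
        wgbs = readout_wgbs(tau, sim_rng, t_end=24.0)
        reads = readout_replibs(tau, depth=30.0, rng=sim_rng)
        rates = fit_reads(reads, n_sites=len(pos))
        keep = filter_inferable(rates)
        k_vals = np.full(len(pos), np.nan)
        k_vals[keep] = rates["k"].to_numpy()[keep]

        for quantity, values in (("rate", k_vals), ("state_bulk", wgbs)):
            cf = distance_correlation(pos, values, d_max=1000, min_pairs=50,
                                      meta={"mechanism": mechanism,
                                            "quantity": quantity})
            loess_smooth(cf, span=100.0)
            frames.append(cf.to_frame())
            summary.append({"mechanism": mechanism, "quantity": quantity,
                            "magnitude_1kbp": mean_magnitude(cf),
                            "magnitude_100bp": mean_magnitude(cf, 2, 100)})

    pd.concat(frames, ignore_index=True).to_csv(
        args.out_dir / "correlation_functions.tsv", sep="\t", index=False,
        float_format="%.6g")
    table = pd.DataFrame(summary)
    table.to_csv(args.out_dir / "magnitudes.tsv", sep="\t", index=False,
                 float_format="%.4g")
    print(table.to_string(index=False))
    dist = table.query("mechanism == 'distributive' and quantity == 'rate'")
    proc = table.query("mechanism == 'processive' and quantity == 'rate'")
    print(f"\nsub-100 bp rate-correlation magnitude: distributive "
          f"{dist['magnitude_100bp'].iloc[0]:.4f} (no coupling) vs processive "
          f"{proc['magnitude_100bp'].iloc[0]:.4f} -- only the processive "
          "mechanism leaves a short-range rate-correlation fingerprint.")


if __name__ == "__main__":
    main()
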