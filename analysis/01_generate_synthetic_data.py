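#!/usr/bin/env python
"""Generate the synthetic study inputs: CpG maps, landscapes, features, reads.

Produces a CGI-like (median spacing ~10 bp) and an intergenic-like (~161 bp)
site map, each with a bimodal spatially correlated methylation landscape,
per-site feature tracks (q, r, s) and kinetic-truth pulse-chase reads, and
writes them as bedGraph/TSV under the output directory.
"""

import argparse
from pathlib import Path

import numpy as np

from methkin import io, synthgen
from methkin.pipeline import stage_rng


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-sites", type=int, default=20_000)
    ap.add_argument("--out-dir", type=Path,
                    default=Path("results/01_synthetic_data"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for label, spacing in (("cgi_like", 10), ("intergenic_like", 161)):
        rng = stage_rng(args.seed, f"synth-{label}")
        pos = synthgen.gen_cpg_positions(args.n_sites, spacing, seed=rng)
        land = synthgen.gen_landscape(pos, corr_length=500.0, meth_mean=0.8,
                                      seed=rng)
        feats = synthgen.gen_feature_tracks(pos, land, seed=rng)
        k_true = rng.lognormal(np.log(0.7), 0.5, args.n_sites)
        reads = synthgen.gen_replibs_reads(k_true, land, depth=30.0, seed=rng)

        io.write_methylation(args.out_dir / f"{label}.landscape.bedgraph",
                             "chrS", pos, land)
        feats.assign(chrom="chrS", pos=pos).to_csv(
            args.out_dir / f"{label}.features.tsv", sep="\t", index=False,
            float_format="%.6g")
        io.write_reads(args.out_dir / f"{label}.reads.tsv", reads, "chrS", pos)

        gaps = np.diff(pos)
        print(f"{label}: {args.n_sites} sites, median spacing "
              f"{np.median(gaps):.0f} bp, mean methylation {land.mean():.3f}, "
              f"{len(reads)} reads "
              f"(pooled methylated fraction {reads['call'].mean():.3f})")
    print(f"wrote inputs to {args.out_dir}")


if __name__ == "__main__":
    main()
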