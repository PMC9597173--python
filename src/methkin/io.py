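"""Plain-text readers and writers for the pipeline's interchange formats.

All coordinates are 0-based, half-open. Regions travel as BED, methylation
landscapes as bedGraph (chrom, start, end, fraction), and reads, rates,
features, correlation and decomposition tables as TSV with headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_bed",
    "merge_intervals",
    "promoters_from_genes",
    "read_methylation",
    "write_methylation",
    "write_bed",
    "read_reads",
    "write_reads",
    "read_rates",
    "write_rates",
]


class BedFormatError(ValueError):
    """A malformed line in a BED/bedGraph file, reported with its number."""


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union of [start, end) intervals as a sorted, non-overlapping array."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def read_bed(path: str | Path, merge: bool = True) -> dict[str, np.ndarray]:
    """Read a 3+ column BED file into per-chromosome interval arrays.

    Returns ``{chrom: (m, 2) int array}``; intervals are merged per
    chromosome by default. Malformed lines raise with their line number.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise BedFormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            per_chrom.setdefault(parts[0], []).append((start, end))
    out = {}
    for chrom, ivs in per_chrom.items():
        arr = np.asarray(ivs, dtype=np.int64)
        out[chrom] = merge_intervals(arr) if merge else arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    return out


def promoters_from_genes(
    genes: pd.DataFrame,
    upstream: int = 2000,
    downstream: int = 200,
) -> dict[str, np.ndarray]:
    """Promoter intervals spanning TSS-upstream to TSS+downstream.

    ``genes`` needs columns chrom, start, end, strand; the TSS is ``start``
    on '+' and ``end`` on '-'. Output intervals are merged per chromosome
    and clipped at 0.
    """
    rows: dict[str, list[tuple[int, int]]] = {}
    for rec in genes.itertuples(index=False):
        if rec.strand == "+":
            tss = rec.start
            iv = (max(tss - upstream, 0), tss + downstream)
        elif rec.strand == "-":
            tss = rec.end
            iv = (max(tss - downstream, 0), tss + upstream)
        else:
            raise ValueError(f"invalid strand {rec.strand!r}")
        rows.setdefault(rec.chrom, []).append(iv)
    return {c: merge_intervals(np.asarray(v, dtype=np.int64)) for c, v in rows.items()}


def read_methylation(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph of per-CpG methylation fractions.

    Returns a DataFrame (chrom, pos, fraction) sorted by (chrom, pos); the
    cytosine coordinate is the interval start. Duplicate positions and
    fractions outside [0, 1] are rejected.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise BedFormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                pos = int(parts[1])
                frac = float(parts[3])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: malformed record") from exc
            if not 0.0 <= frac <= 1.0:
                raise BedFormatError(
                    f"{path}:{lineno}: methylation fraction {frac} outside [0, 1]")
            rows.append((parts[0], pos, frac))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "fraction"])
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if df.duplicated(["chrom", "pos"]).any():
        raise BedFormatError(f"{path}: duplicate CpG positions")
    return df


def write_methylation(path: str | Path, chrom: str, positions: np.ndarray,
                      fractions: np.ndarray) -> None:
    """Write a landscape as bedGraph; each CpG covers [pos, pos + 2)."""
    pos = np.asarray(positions, dtype=np.int64)
    df = pd.DataFrame({
        "chrom": chrom, "start": pos, "end": pos + 2,
        "fraction": np.asarray(fractions, dtype=float),
    })
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_bed(path: str | Path, intervals: dict[str, np.ndarray],
              name: str = ".") -> None:
    """Write per-chromosome intervals as 6-column BED (score 0, strand '.')."""
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t.\n")


def write_reads(path: str | Path, reads: pd.DataFrame, chrom: str,
                positions: np.ndarray) -> None:
    """Write read-level observations as TSV (chrom, pos, t_chase_h, call)."""
    pos = np.asarray(positions, dtype=np.int64)
    out = pd.DataFrame({
        "chrom": chrom,
        "pos": pos[reads["site"].to_numpy()],
        "t_chase_h": reads["t_chase_h"],
        "call": reads["call"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_reads(path: str | Path, positions: np.ndarray | None = None
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a reads TSV; returns (reads with ``site`` index, position vector).

    When ``positions`` is omitted the site list is the sorted unique set of
    read positions (sites without reads are then unknown to the caller).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "t_chase_h", "call"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if positions is None:
        positions = np.sort(df["pos"].unique())
    pos = np.asarray(positions, dtype=np.int64)
    site = np.searchsorted(pos, df["pos"].to_numpy())
    if np.any(site >= len(pos)) or np.any(pos[np.clip(site, 0, len(pos) - 1)]
                                          != df["pos"].to_numpy()):
        raise ValueError(f"{path}: read position absent from the site list")
    out = pd.DataFrame({"site": site, "t_chase_h": df["t_chase_h"],
                        "call": df["call"]})
    return out, pos


def write_rates(path: str | Path, rates: pd.DataFrame, chrom: str,
                positions: np.ndarray) -> None:
    """Write per-site estimates as TSV (chrom, pos, k_per_h, f, status, ...)."""
    pos = np.asarray(positions, dtype=np.int64)
    out = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "k_per_h": rates["k"], "f": rates["f"], "status": rates["status"],
        "loglik": rates["loglik"], "n_reads": rates["n_reads"],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_rates(path: str | Path) -> pd.DataFrame:
    """Read a rates TSV back into the fitting schema (k, f, status, ...)."""
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"k_per_h": "k"})
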