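"""Mean replication timing (MRT) from 6-fraction Repli-Seq signal.

Repli-Seq sorts S-phase cells into 6 FACS fractions (1 = earliest). The
MRT of a genomic bin is the signal-weighted mean of the fraction
midpoints on a unit-length S phase:

    MRT = sum_i w_i s_i / sum_i s_i,   w_i = (i - 0.5) / 6,

so MRT lies in [1/12, 11/12]; bins with zero total signal are missing.
Timing categories split [0, 1] into six equal intervals (left-closed,
the last one closed): categories 1-2 are early, 3-4 mid and 5-6 late
S phase.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import Origin
from .intervals import GenomeLayout

N_FRACTIONS = 6


def fraction_weights(n: int = N_FRACTIONS) -> np.ndarray:
    """Fraction midpoints on a unit S phase: (i - 0.5) / n for i=1..n."""
    return (np.arange(1, n + 1) - 0.5) / n


@dataclasses.dataclass
class FractionTrack:
    """Binned signal for one S-phase fraction (1 = earliest)."""

    fraction_index: int
    bin_size: int
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not 1 <= self.fraction_index <= N_FRACTIONS:
            raise ValueError("fraction_index must be 1..6")
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"negative signal on {chrom}")
            self.values[chrom] = arr


@dataclasses.dataclass
class TimingProfile:
    """Per-bin MRT in [0, 1]; NaN where no fraction has signal."""

    bin_size: int
    mrt: dict[str, np.ndarray]

    def category(self, chrom: str, position: int) -> int | None:
        """Timing category (1..6) of the bin containing *position*."""
        if chrom not in self.mrt:
            return None
        b = position // self.bin_size
        arr = self.mrt[chrom]
        if b >= len(arr) or np.isnan(arr[b]):
            return None
        return mrt_category(float(arr[b]))

    def value(self, chrom: str, position: int) -> float:
        if chrom not in self.mrt:
            return float("nan")
        b = position // self.bin_size
        arr = self.mrt[chrom]
        return float(arr[b]) if b < len(arr) else float("nan")


def mrt_category(mrt: float) -> int:
    """1 + floor(6 * MRT), capped at 6 (bins left-closed, last closed)."""
    if not 0.0 <= mrt <= 1.0:
        raise ValueError("MRT must be in [0, 1]")
    return min(int(np.floor(6 * mrt)) + 1, 6)


def timing_group(category: int) -> str:
    """Collapse six categories into early (1-2) / mid (3-4) / late (5-6)."""
    if category in (1, 2):
        return "early"
    if category in (3, 4):
        return "mid"
    if category in (5, 6):
        return "late"
    raise ValueError(f"invalid timing category {category}")


def compute_mrt(tracks: Sequence[FractionTrack], weights: np.ndarray | None = None) -> TimingProfile:
    """MRT per bin from exactly six consistently binned fraction tracks."""
    if len(tracks) != N_FRACTIONS:
        raise ValueError(f"expected {N_FRACTIONS} fraction tracks, got {len(tracks)}")
    tracks = sorted(tracks, key=lambda t: t.fraction_index)
    if [t.fraction_index for t in tracks] != list(range(1, N_FRACTIONS + 1)):
        raise ValueError("fraction indices must be exactly 1..6")
    bin_size = tracks[0].bin_size
    chroms = set(tracks[0].values)
    for t in tracks[1:]:
        if t.bin_size != bin_size or set(t.values) != chroms:
            raise ValueError("fraction tracks disagree on binning")
    w = fraction_weights() if weights is None else np.asarray(weights, dtype=float)
    mrt: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n = len(tracks[0].values[chrom])
        sig = np.zeros((N_FRACTIONS, n))
        for i, t in enumerate(tracks):
            if len(t.values[chrom]) != n:
                raise ValueError(f"fraction tracks disagree on bin count for {chrom}")
            sig[i] = t.values[chrom]
        total = sig.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (w[:, None] * sig).sum(axis=0) / total
        vals[total == 0] = np.nan
        mrt[chrom] = vals
    return TimingProfile(bin_size=bin_size, mrt=mrt)


def assign_timing(origins: Sequence[Origin], profile: TimingProfile) -> int:
    """Label each origin with the MRT/category of its midpoint bin.

    Mutates origin labels in place (``mrt``, ``timing_category``,
    ``timing_group``); origins falling in missing bins stay unlabeled.
    Returns the number of unlabeled origins (the "no-timing" tally).
    """
    n_missing = 0
    for o in origins:
        cat = profile.category(o.chrom, o.midpoint)
        if cat is None:
            n_missing += 1
            continue
        o.labels["mrt"] = profile.value(o.chrom, o.midpoint)
        o.labels["timing_category"] = cat
        o.labels["timing_group"] = timing_group(cat)
    return n_missing


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def write_bedgraph(values: dict[str, np.ndarray], bin_size: int, path: str | Path) -> None:
    """Write a binned track as bedGraph (NaN bins omitted)."""
    with open(path, "w") as fh:
        for chrom, arr in values.items():
            for i, v in enumerate(arr):
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{format(float(v), '.6g')}\n")


def read_bedgraph(path: str | Path, layout: GenomeLayout, bin_size: int) -> dict[str, np.ndarray]:
    """Read a bedGraph whose intervals align to the given bin grid."""
    values = {
        c: np.zeros(-(-layout.length(c) // bin_size)) for c in layout.chrom_names
    }
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in values:
            raise ValueError(f"unknown chromosome {chrom!r} in {path}")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(starts % bin_size) or np.any((ends - starts) != bin_size):
            # tolerate a short final bin at the chromosome end
            bad = (starts % bin_size != 0) | (
                (ends - starts != bin_size) & (ends != layout.length(str(chrom)))
            )
            if np.any(bad):
                raise ValueError(f"{path}: intervals not aligned to {bin_size}-bp grid")
        values[str(chrom)][starts // bin_size] = sub["value"].to_numpy()
    return values


def read_fraction_tracks(
    paths: Sequence[str | Path], layout: GenomeLayout, bin_size: int
) -> list[FractionTrack]:
    """Read six bedGraphs ordered earliest to latest fraction."""
    if len(paths) != N_FRACTIONS:
        raise ValueError(f"expected {N_FRACTIONS} bedGraph paths")
    return [
        FractionTrack(i + 1, bin_size, read_bedgraph(p, layout, bin_size))
        for i, p in enumerate(paths)
    ]
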