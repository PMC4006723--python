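"""Read-start profiles and Poisson segmentation of the coverage process.

The detection model sees SNS sequencing as a marked point process: read-
bearing sites arrive along the genome as a Poisson process with a
position-dependent intensity (the coverage process), and each occupied
site carries a geometric number of read starts (PCR/ligation
multiplicity). Detection thresholds must adapt to regional coverage, so
the coverage process is segmented into regions of constant intensity
with a penalized Poisson changepoint model; each segment supplies the
local background rate, and segments of extremely low coverage are
flagged for exclusion.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomeLayout, IntervalSet, read_bed


class ReadStartProfile:
    """Sparse per-position read-start counts, per chromosome.

    Positions are stored sorted with counts >= 1; duplicate read starts
    are retained as per-site multiplicities (they carry the geometric
    part of the noise model and must not be deduplicated).
    """

    def __init__(self, positions: Mapping[str, np.ndarray], counts: Mapping[str, np.ndarray]):
        self.positions: dict[str, np.ndarray] = {}
        self.counts: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom in positions:
            pos = np.asarray(positions[chrom], dtype=np.int64)
            cnt = np.asarray(counts[chrom], dtype=np.int64)
            if len(pos) != len(cnt):
                raise ValueError("positions/counts length mismatch")
            if np.any(cnt < 1):
                raise ValueError("stored counts must be >= 1")
            order = np.argsort(pos, kind="mergesort")
            self.positions[chrom] = pos[order]
            self.counts[chrom] = cnt[order]
            self._cum[chrom] = np.concatenate([[0], np.cumsum(cnt[order])])

    @classmethod
    def from_positions(cls, reads: Mapping[str, np.ndarray]) -> "ReadStartProfile":
        """Build from raw per-read start positions (repeats allowed)."""
        positions, counts = {}, {}
        for chrom, arr in reads.items():
            arr = np.asarray(arr, dtype=np.int64)
            pos, cnt = np.unique(arr, return_counts=True)
            positions[chrom] = pos
            counts[chrom] = cnt
        return cls(positions, counts)

    @classmethod
    def from_bed(cls, path: str | Path, layout: GenomeLayout | None = None) -> "ReadStartProfile":
        """Interpret BED interval starts as read-start positions."""
        iset = read_bed(path, layout=layout)
        reads: dict[str, np.ndarray] = {}
        for chrom, sub in iset.df.groupby("chrom", sort=False):
            reads[str(chrom)] = sub["start"].to_numpy()
        return cls.from_positions(reads)

    @property
    def total_reads(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def chrom_total(self, chrom: str) -> int:
        return int(self.counts.get(chrom, np.zeros(0, dtype=np.int64)).sum())

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of read starts in [start, end)."""
        if chrom not in self.positions:
            return 0
        pos, cum = self.positions[chrom], self._cum[chrom]
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return int(cum[j] - cum[i])

    def window_counts(self, chrom: str, starts: np.ndarray, width: int) -> np.ndarray:
        """Read counts of many same-width windows at once."""
        if chrom not in self.positions:
            return np.zeros(len(starts), dtype=np.int64)
        pos, cum = self.positions[chrom], self._cum[chrom]
        i = np.searchsorted(pos, starts, side="left")
        j = np.searchsorted(pos, starts + width, side="left")
        return cum[j] - cum[i]

    def to_bed(self, path: str | Path) -> None:
        """One BED line per read start (multiplicities expanded)."""
        with open(path, "w") as fh:
            for chrom in self.positions:
                pos = np.repeat(self.positions[chrom], self.counts[chrom])
                for p in pos:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\n")


@dataclasses.dataclass
class BinnedCounts:
    """Read-start counts per fixed-size bin; the tail bin is padded so
    totals are conserved exactly."""

    bin_size: int
    counts: dict[str, np.ndarray]

    def n_bins(self, chrom: str) -> int:
        return len(self.counts[chrom])


def bin_reads(profile: ReadStartProfile, bin_size: int, layout: GenomeLayout) -> BinnedCounts:
    """Count read starts per [k*b, (k+1)*b) bin; conserves total reads."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    counts: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        n = -(-layout.length(chrom) // bin_size)  # ceil
        if chrom in profile.positions:
            idx = profile.positions[chrom] // bin_size
            counts[chrom] = np.bincount(idx, weights=profile.counts[chrom], minlength=n).astype(
                np.int64
            )
        else:
            counts[chrom] = np.zeros(n, dtype=np.int64)
    return BinnedCounts(bin_size=bin_size, counts=counts)


@dataclasses.dataclass
class CoverageSegment:
    """Constant-intensity region of the coverage process."""

    chrom: str
    start: int
    end: int
    lambda_hat: float  # reads per bp
    n_reads: int
    low_coverage_flag: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class NoiseModel:
    """Compound-Poisson background: read-bearing sites arrive at
    ``lambda_sites`` per bp, each carrying Geometric(``p_geom``) reads
    (support 1, 2, ...; mean 1/p)."""

    p_geom: float
    lambda_sites: float

    def __post_init__(self) -> None:
        if not (0 < self.p_geom <= 1):
            raise ValueError("p_geom must be in (0, 1]")
        if self.lambda_sites < 0:
            raise ValueError("lambda_sites must be >= 0")

    @property
    def reads_per_bp(self) -> float:
        return self.lambda_sites / self.p_geom


# ---------------------------------------------------------------------------
# Poisson changepoint segmentation
# ---------------------------------------------------------------------------

def _seg_cost(cum: np.ndarray, s, t):
    """Negative Poisson log-likelihood (up to a data-only constant) of
    a single-rate segment over bins [s, t). Vectorized in s."""
    S = cum[t] - cum[s]
    n = t - s
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = S - S * np.log(np.where(S > 0, S / n, 1.0))
    return np.where(S > 0, cost, 0.0)


def segment_fixed_k(y: np.ndarray, k: int, min_size: int = 1) -> tuple[list[int], float]:
    """Exact dynamic-programming segmentation into exactly k segments.

    Returns (breakpoints, cost): breakpoints are the k-1 interior bin
    indices at which a new segment starts; cost is the minimized
    negative log-likelihood. O(k n^2); intended for moderate n and for
    validating the penalized solver.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k * min_size > n:
        raise ValueError("too many segments for the series length")
    cum = np.concatenate([[0.0], np.cumsum(y)])
    INF = np.inf
    # D[j, t] = best cost of splitting y[:t] into j segments
    D = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=np.int64)
    D[0, 0] = 0.0
    for j in range(1, k + 1):
        tmin = j * min_size
        for t in range(tmin, n + 1):
            s_lo, s_hi = (j - 1) * min_size, t - min_size
            s = np.arange(s_lo, s_hi + 1)
            vals = D[j - 1, s] + _seg_cost(cum, s, t)
            i = int(np.argmin(vals))
            D[j, t] = vals[i]
            back[j, t] = s[i]
    bps: list[int] = []
    t = n
    for j in range(k, 1, -1):
        t = int(back[j, t])
        bps.append(t)
    return sorted(bps), float(D[k, n])


def _pelt(y: np.ndarray, penalty: float, min_size: int = 1) -> list[int]:
    """Penalized optimal partitioning with pruning (PELT).

    Minimizes sum of segment costs + penalty per segment; pruning uses
    cost subadditivity of the Poisson likelihood and is delayed by
    ``min_size`` so the minimum-length constraint stays exact.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    cum = np.concatenate([[0.0], np.cumsum(y)])
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=np.int64)
    cand: list[int] = [0]
    pending: dict[int, set[int]] = {}
    for t in range(min_size, n + 1):
        if t in pending:
            drop = pending.pop(t)
            cand = [s for s in cand if s not in drop]
        if t - min_size >= min_size and np.isfinite(F[t - min_size]):
            cand.append(t - min_size)
        s_arr = np.asarray(cand)
        vals = F[s_arr] + _seg_cost(cum, s_arr, t)
        i = int(np.argmin(vals))
        F[t] = vals[i] + penalty
        prev[t] = s_arr[i]
        # schedule pruning: s hopeless now stays hopeless for t' >= t+min_size
        hopeless = s_arr[vals > F[t]]
        if len(hopeless):
            pending.setdefault(t + min_size, set()).update(int(s) for s in hopeless)
    bps: list[int] = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            bps.append(s)
        t = s
    return sorted(bps)


def segment_coverage(
    counts: BinnedCounts,
    layout: GenomeLayout,
    max_segments: int = 50,
    penalty_scale: float = 2.0,
    min_segment_bins: int = 50,
    low_coverage_frac: float = 0.1,
) -> list[CoverageSegment]:
    """Segment binned coverage into constant-intensity regions.

    Per chromosome, changepoints minimize the negative Poisson
    log-likelihood with a BIC-style penalty ``penalty_scale * log(n)``
    per segment (solved exactly by penalized DP with pruning; for a
    constant per-segment penalty this equals fixed-K DP followed by
    penalized selection of K). A minimum segment length keeps the
    segmentation at the regional-coverage scale so that kb-scale peaks
    are not absorbed as their own background. Segments with intensity
    below ``low_coverage_frac`` times the genome-wide mean are flagged
    low-coverage (excluded from detection downstream).
    """
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")
    total_reads = sum(int(c.sum()) for c in counts.counts.values())
    total_bp = sum(layout.length(c) for c in counts.counts)
    genome_rate = total_reads / total_bp if total_bp else 0.0
    segments: list[CoverageSegment] = []
    b = counts.bin_size
    for chrom, y in counts.counts.items():
        n = len(y)
        chrom_len = layout.length(chrom)
        if n == 0:
            continue
        if y.sum() == 0:
            segments.append(CoverageSegment(chrom, 0, chrom_len, 0.0, 0, True))
            continue
        min_size = min(min_segment_bins, max(1, n // 2))
        penalty = penalty_scale * np.log(n)
        bps = _pelt(y, penalty=penalty, min_size=min_size)
        while len(bps) + 1 > max_segments:
            penalty *= 2.0
            bps = _pelt(y, penalty=penalty, min_size=min_size)
        bounds = [0] + bps + [n]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            start = lo * b
            end = min(hi * b, chrom_len)
            n_reads = int(y[lo:hi].sum())
            lam = n_reads / (end - start)
            segments.append(CoverageSegment(chrom, start, end, lam, n_reads, False))
    floor = low_coverage_frac * genome_rate
    for seg in segments:
        if seg.lambda_hat < floor:
            seg.low_coverage_flag = True
    return segments


def estimate_noise(profile: ReadStartProfile, segments: Sequence[CoverageSegment]) -> NoiseModel:
    """Method-of-moments noise fit from background segments.

    The per-site multiplicity is Geometric(p); p_hat = 1 / mean
    multiplicity over occupied sites inside non-low-coverage segments;
    lambda_sites is the occupied-site density over the same span.
    """
    background = [s for s in segments if not s.low_coverage_flag]
    if not background:
        raise ValueError("no non-low-coverage segment available")
    mult_sum = 0
    n_sites = 0
    span = 0
    for seg in background:
        if seg.chrom not in profile.positions:
            span += seg.length
            continue
        pos = profile.positions[seg.chrom]
        cnt = profile.counts[seg.chrom]
        i = np.searchsorted(pos, seg.start, side="left")
        j = np.searchsorted(pos, seg.end, side="left")
        mult_sum += int(cnt[i:j].sum())
        n_sites += j - i
        span += seg.length
    if n_sites == 0:
        raise ValueError("no occupied sites in background segments")
    p_hat = min(1.0, n_sites / mult_sum)
    return NoiseModel(p_geom=p_hat, lambda_sites=n_sites / span)


def segments_to_intervalset(segments: Sequence[CoverageSegment]) -> IntervalSet:
    """Segments as BED6+-style rows: chrom start end id lambda_hat flag."""
    import pandas as pd

    rows = [
        (s.chrom, s.start, s.end, f"seg_{i + 1}", s.lambda_hat, int(s.low_coverage_flag))
        for i, s in enumerate(segments)
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    df = df.rename(columns={"score": "lambda_hat", "strand": "low_coverage"})
    return IntervalSet(df, label="segments")
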