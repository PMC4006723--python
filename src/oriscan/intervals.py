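"""Genome coordinates, interval algebra and BED/chrom.sizes I/O.

Conventions used throughout the package:

* all coordinates are 0-based, half-open ``[start, end)`` (BED native);
* two intervals overlap iff they share at least 1 bp; strand is ignored
  for every overlap/association operation (SNS reads are pooled across
  strands, and none of the feature associations are strand-conditioned);
* interval sets carry arbitrary extra columns ("annotations") so that
  read counts, efficiencies and labels survive interval algebra.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

CORE_COLUMNS = ("chrom", "start", "end")
_BED_EXTRA_NAMES = ("name", "score", "strand")


class BedParseError(ValueError):
    """Malformed BED input; message carries the 1-based line number."""


@dataclasses.dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and their lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        for name in self.chrom_names:
            if name not in self.chrom_lengths:
                raise ValueError(f"missing length for chromosome {name!r}")
            if self.chrom_lengths[name] <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")

    @classmethod
    def from_dict(cls, lengths: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), dict(lengths))

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column ``name<TAB>length`` file."""
        lengths: dict[str, int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}: line {i}: expected 'name<TAB>length'")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {i}: bad length {parts[1]!r}") from exc
        return cls.from_dict(lengths)

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f"{name}\t{self.chrom_lengths[name]}\n")

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths[c] for c in self.chrom_names))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclasses.dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff a and b share >= 1 bp (strand ignored)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class IntervalSet:
    """A labeled collection of intervals backed by a pandas DataFrame.

    The frame always holds ``chrom``, ``start``, ``end``; any further
    columns are opaque annotations that the algebra preserves or
    aggregates as documented per operation.
    """

    def __init__(self, df: pd.DataFrame, label: str = "", layout: GenomeLayout | None = None):
        df = df.reset_index(drop=True).copy()
        for col in CORE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
        if len(bad):
            i = int(bad[0])
            raise ValueError(
                f"invalid interval at row {i}: start={df.at[i, 'start']} end={df.at[i, 'end']}"
            )
        if layout is not None:
            unknown = set(df["chrom"].unique()) - set(layout.chrom_names)
            if unknown:
                raise ValueError(f"unknown chromosome(s): {sorted(unknown)}")
            for chrom, sub in df.groupby("chrom", sort=False):
                if len(sub) and int(sub["end"].max()) > layout.length(str(chrom)):
                    raise ValueError(f"interval beyond end of {chrom}")
        # reorder so the 3 core columns come first
        extras = [c for c in df.columns if c not in CORE_COLUMNS]
        self._df = df[list(CORE_COLUMNS) + extras]
        self.label = label

    # -- construction -------------------------------------------------
    @classmethod
    def from_intervals(cls, intervals: Iterable[Interval], label: str = "") -> "IntervalSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        if df.empty:
            df = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        return cls(df, label=label)

    @classmethod
    def empty(cls, label: str = "") -> "IntervalSet":
        return cls(pd.DataFrame({"chrom": [], "start": [], "end": []}), label=label)

    # -- accessors ----------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.to_intervals())

    def to_intervals(self) -> list[Interval]:
        strands = (
            self._df["strand"].astype(str).tolist()
            if "strand" in self._df.columns
            else ["."] * len(self._df)
        )
        return [
            Interval(c, int(s), int(e), st if st in "+-" else ".")
            for c, s, e, st in zip(self._df["chrom"], self._df["start"], self._df["end"], strands)
        ]

    def sorted(self) -> "IntervalSet":
        df = self._df.sort_values(["chrom", "start", "end"], kind="mergesort")
        return IntervalSet(df, label=self.label)

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self._df["chrom"]))

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends), sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self._df.groupby("chrom", sort=False):
            order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
            out[str(chrom)] = (
                sub["start"].to_numpy()[order],
                sub["end"].to_numpy()[order],
            )
        return out

    def total_bp(self) -> int:
        """Total bp covered by the merged footprint."""
        total = 0
        for starts, ends in merged_footprint(self).values():
            total += int((ends - starts).sum())
        return total

    def same_intervals(self, other: "IntervalSet") -> bool:
        a = self.sorted().df[list(CORE_COLUMNS)].reset_index(drop=True)
        b = other.sorted().df[list(CORE_COLUMNS)].reset_index(drop=True)
        return a.equals(b)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, layout: GenomeLayout | None = None, label: str | None = None) -> IntervalSet:
    """Read BED3+ text; extra columns kept as annotations, order retained.

    narrowPeak files parse as BED6+4. Malformed lines raise
    :class:`BedParseError` with a 1-based line number; chromosomes absent
    from *layout* raise a ``ValueError`` naming them.
    """
    path = Path(path)
    rows: list[list[str]] = []
    ncols = None
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise BedParseError(f"{path}: line {i}: expected >= 3 tab-separated fields")
        if ncols is None:
            ncols = len(parts)
        elif len(parts) != ncols:
            raise BedParseError(f"{path}: line {i}: inconsistent column count")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise BedParseError(f"{path}: line {i}: non-integer coordinates") from exc
        if not (0 <= start < end):
            raise BedParseError(f"{path}: line {i}: invalid interval [{start}, {end})")
        rows.append(parts)
    if not rows:
        return IntervalSet.empty(label=label if label is not None else path.stem)
    ncols = len(rows[0])
    names = list(CORE_COLUMNS) + [
        _BED_EXTRA_NAMES[j] if j < len(_BED_EXTRA_NAMES) else f"extra_{j + 4}"
        for j in range(ncols - 3)
    ]
    df = pd.DataFrame(rows, columns=names)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    for col in names[3:]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return IntervalSet(df, label=label if label is not None else path.stem, layout=layout)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED text: core columns then annotations, tab-separated."""
    df = iset.df.copy()
    floats = df.select_dtypes(include=["float"]).columns
    for col in floats:
        df[col] = df[col].map(lambda v: format(v, ".6g"))
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def merged_footprint(iset: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Union of the set per chromosome as sorted, disjoint (starts, ends)."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (starts, ends) in iset.by_chrom().items():
        if len(starts) == 0:
            continue
        run_end = np.maximum.accumulate(ends)
        # new run where the start exceeds (or touches) every previous end
        new = np.ones(len(starts), dtype=bool)
        new[1:] = starts[1:] > run_end[:-1]
        grp = np.cumsum(new) - 1
        ms = starts[new]
        me = np.zeros(grp[-1] + 1, dtype=np.int64)
        np.maximum.at(me, grp, ends)
        out[chrom] = (ms, me)
    return out


def merge_within(iset: IntervalSet, gap: int) -> IntervalSet:
    """Transitively merge intervals whose edge-to-edge distance is < gap.

    Overlapping intervals count as distance 0 (with ``gap=0`` only
    strictly overlapping intervals merge). Numeric annotations are
    summed across merged members; ``name`` values are comma-joined;
    an ``efficiency`` column, if present alongside ``n_reads``, is
    recomputed as reads per bp of the merged interval.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if len(iset) == 0:
        return IntervalSet(iset.df, label=iset.label)
    df = iset.sorted().df
    parts = []
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        new = np.ones(len(sub), dtype=bool)
        # signed distance next.start - running max end; merge iff < gap
        new[1:] = (starts[1:] - run_end[:-1]) >= gap
        grp = np.cumsum(new) - 1
        sub = sub.assign(_grp=grp)
        agg: dict[str, object] = {"start": "min", "end": "max"}
        for col in sub.columns:
            if col in ("chrom", "start", "end", "_grp"):
                continue
            if pd.api.types.is_numeric_dtype(sub[col]):
                agg[col] = "sum"
            elif col == "name":
                agg[col] = lambda s: ",".join(map(str, s))
            else:
                agg[col] = "first"
        merged = sub.groupby("_grp", sort=True).agg(agg).reset_index(drop=True)
        merged.insert(0, "chrom", chrom)
        parts.append(merged)
    out = pd.concat(parts, ignore_index=True)
    if "efficiency" in out.columns and "n_reads" in out.columns:
        out["efficiency"] = out["n_reads"] / (out["end"] - out["start"])
    return IntervalSet(out, label=iset.label)


def overlaps_any(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Boolean per query interval: does it overlap >= 1 bp of subject?"""
    foot = merged_footprint(subject)
    hits = np.zeros(len(query), dtype=bool)
    df = query.df
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in foot:
            continue
        fs, fe = foot[chrom]
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        # the rightmost footprint block starting before the query end
        idx = np.searchsorted(fs, qe, side="left")
        hit = (idx > 0) & (fe[np.maximum(idx - 1, 0)] > qs)
        hits[sub.index.to_numpy()] = hit
    return hits


def count_overlapping(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per query interval, the number of subject intervals it overlaps."""
    counts = np.zeros(len(query), dtype=np.int64)
    by = subject.by_chrom()
    for chrom, sub in query.df.groupby("chrom", sort=False):
        if chrom not in by:
            continue
        ss, se = by[chrom]
        se_sorted = np.sort(se)
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        n_start_before = np.searchsorted(ss, qe, side="left")
        n_end_before = np.searchsorted(se_sorted, qs, side="right")
        counts[sub.index.to_numpy()] = n_start_before - n_end_before
    return counts


def distance_to_nearest(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Edge-to-edge distance (bp) from each query to the nearest subject.

    0 for any overlap; NaN for queries on chromosomes with no subject
    interval. Raises if the subject set is empty.
    """
    if len(subject) == 0:
        raise ValueError("subject set is empty")
    by = subject.by_chrom()
    out = np.full(len(query), np.nan)
    for chrom, sub in query.df.groupby("chrom", sort=False):
        if chrom not in by:
            continue
        ss, se = by[chrom]
        se_sorted = np.sort(se)
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        # nearest subject entirely to the left: largest end <= qs
        li = np.searchsorted(se_sorted, qs, side="right")
        left = np.where(li > 0, qs - se_sorted[np.maximum(li - 1, 0)], np.inf)
        # nearest subject entirely to the right: smallest start >= qe
        ri = np.searchsorted(ss, qe, side="left")
        right = np.where(ri < len(ss), ss[np.minimum(ri, len(ss) - 1)] - qe, np.inf)
        dist = np.minimum(left, right).astype(float)
        # any overlap -> 0
        foot_s, foot_e = merged_footprint_arrays(ss, se)
        idx = np.searchsorted(foot_s, qe, side="left")
        overlap = (idx > 0) & (foot_e[np.maximum(idx - 1, 0)] > qs)
        dist[overlap] = 0.0
        out[sub.index.to_numpy()] = dist
    return out


def merged_footprint_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals given as start-sorted arrays."""
    if len(starts) == 0:
        return starts, ends
    run_end = np.maximum.accumulate(ends)
    new = np.ones(len(starts), dtype=bool)
    new[1:] = starts[1:] > run_end[:-1]
    grp = np.cumsum(new) - 1
    ms = starts[new]
    me = np.zeros(grp[-1] + 1, dtype=np.int64)
    np.maximum.at(me, grp, ends)
    return ms, me


def subtract(a: IntervalSet, b: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Footprint of a minus footprint of b, per chromosome (annotations dropped)."""
    fa = merged_footprint(a)
    fb = merged_footprint(b)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (as_, ae) in fa.items():
        if chrom not in fb:
            out[chrom] = (as_, ae)
            continue
        bs, be = fb[chrom]
        res_s: list[int] = []
        res_e: list[int] = []
        for s, e in zip(as_, ae):
            cur = int(s)
            j0 = np.searchsorted(be, cur, side="right")
            for j in range(j0, len(bs)):
                if bs[j] >= e:
                    break
                if bs[j] > cur:
                    res_s.append(cur)
                    res_e.append(int(bs[j]))
                cur = max(cur, int(be[j]))
                if cur >= e:
                    break
            if cur < e:
                res_s.append(cur)
                res_e.append(int(e))
        out[chrom] = (np.asarray(res_s, dtype=np.int64), np.asarray(res_e, dtype=np.int64))
    return out


@dataclasses.dataclass
class MappabilityMask:
    """Regions of the genome where reads can be uniquely placed.

    Normalized on construction: per chromosome, sorted and disjoint.
    All randomization nulls sample from this space.
    """

    mappable: IntervalSet

    def __post_init__(self) -> None:
        foot = merged_footprint(self.mappable)
        rows = []
        for chrom, (starts, ends) in foot.items():
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s), int(e)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        if df.empty:
            df = pd.DataFrame({"chrom": [], "start": [], "end": []})
        self.mappable = IntervalSet(df, label=self.mappable.label or "mappable")

    @classmethod
    def whole_genome(cls, layout: GenomeLayout) -> "MappabilityMask":
        df = pd.DataFrame(
            {
                "chrom": list(layout.chrom_names),
                "start": 0,
                "end": [layout.chrom_lengths[c] for c in layout.chrom_names],
            }
        )
        return cls(IntervalSet(df, label="mappable"))

    def total_bp(self) -> int:
        return self.mappable.total_bp()

    def allowed_space(self, exclude: IntervalSet | None = None) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Mask minus the footprint of *exclude* (sampling space for nulls)."""
        if exclude is None or len(exclude) == 0:
            return merged_footprint(self.mappable)
        return subtract(self.mappable, exclude)
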