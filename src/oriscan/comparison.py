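"""Comparison of origin maps: overlap fractions, randomization-based
expected overlap, and constitutive/common/specific classification.

Expected overlaps follow the randomization scheme used for method
cross-validation: to judge the observed fraction of set A overlapping
set B, B is replaced by sets of random intervals with B's exact length
multiset, placed uniformly on the mappable genome minus B's own
footprint, and the overlap fraction is averaged over the random sets.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .intervals import IntervalSet, MappabilityMask, overlaps_any


@dataclasses.dataclass
class OverlapReport:
    n_A: int
    n_B: int
    frac_A_in_B: float
    frac_B_in_A: float
    expected_A_in_B: float | None = None
    expected_B_in_A: float | None = None
    n_randomizations: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def overlap_report(a: IntervalSet, b: IntervalSet) -> OverlapReport:
    """Observed mutual overlap fractions (>= 1 bp, strand-blind)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("overlap_report requires non-empty sets")
    return OverlapReport(
        n_A=len(a),
        n_B=len(b),
        frac_A_in_B=float(overlaps_any(a, b).mean()),
        frac_B_in_A=float(overlaps_any(b, a).mean()),
    )


# ---------------------------------------------------------------------------
# uniform placement on the allowed space
# ---------------------------------------------------------------------------

def _space_table(space: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    rows = []
    for chrom, (starts, ends) in space.items():
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def sample_intervals(
    space: dict[str, tuple[np.ndarray, np.ndarray]],
    lengths: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Place intervals of the given lengths uniformly over all start
    positions that keep each interval inside one allowed block.

    Placement is rejection-free: per length, blocks shorter than the
    interval are dropped and the start is drawn uniformly over the
    remaining start positions (block choice is therefore proportional
    to the allowed space it contributes).
    """
    tab = _space_table(space)
    if tab.empty:
        raise ValueError("empty sampling space")
    seg_chrom = tab["chrom"].to_numpy()
    seg_start = tab["start"].to_numpy()
    seg_len = (tab["end"] - tab["start"]).to_numpy()
    lengths = np.asarray(lengths, dtype=np.int64)
    out_chrom = np.empty(len(lengths), dtype=object)
    out_start = np.empty(len(lengths), dtype=np.int64)
    for ell in np.unique(lengths):
        sel = np.nonzero(lengths == ell)[0]
        nstarts = np.maximum(seg_len - ell + 1, 0)
        total = int(nstarts.sum())
        if total == 0:
            raise ValueError(f"no allowed block can hold an interval of length {ell}")
        cum = np.cumsum(nstarts)
        u = rng.integers(0, total, size=len(sel))
        seg_idx = np.searchsorted(cum, u, side="right")
        offset = u - (cum[seg_idx] - nstarts[seg_idx])
        out_chrom[sel] = seg_chrom[seg_idx]
        out_start[sel] = seg_start[seg_idx] + offset
    return pd.DataFrame(
        {"chrom": out_chrom, "start": out_start, "end": out_start + lengths}
    )


def _hit_fraction_of_queries(
    query: IntervalSet, rand_df: pd.DataFrame
) -> float:
    """Fraction of query intervals overlapping >= 1 random interval."""
    rand = IntervalSet(rand_df)
    return float(overlaps_any(query, rand).mean())


def expected_overlap(
    a: IntervalSet,
    b: IntervalSet,
    mask: MappabilityMask,
    n_sets: int = 50,
    seed: int | None = None,
) -> tuple[float, float]:
    """Randomization-expected (frac_A_in_B, frac_B_in_A).

    expected frac_B_in_A: B's origins kept, A replaced by ``n_sets``
    random sets with A's exact lengths on mask minus A's footprint;
    the mean fraction of B hitting a random set. Symmetric for the
    other direction.
    """
    rng = np.random.default_rng(seed)

    def one_direction(fixed: IntervalSet, randomized: IntervalSet) -> float:
        # an empty randomized set yields empty random sets: expectation 0
        if len(fixed) == 0 or len(randomized) == 0:
            return 0.0
        space = mask.allowed_space(exclude=randomized)
        lengths = (randomized.df["end"] - randomized.df["start"]).to_numpy()
        vals = []
        for _ in range(n_sets):
            rand_df = sample_intervals(space, lengths, rng)
            vals.append(_hit_fraction_of_queries(fixed, rand_df))
        return float(np.mean(vals))

    exp_B_in_A = one_direction(b, a)  # A randomized
    exp_A_in_B = one_direction(a, b)  # B randomized
    return exp_A_in_B, exp_B_in_A


def overlap_report_with_null(
    a: IntervalSet,
    b: IntervalSet,
    mask: MappabilityMask,
    n_sets: int = 50,
    seed: int | None = None,
) -> OverlapReport:
    rep = overlap_report(a, b)
    rep.expected_A_in_B, rep.expected_B_in_A = expected_overlap(
        a, b, mask, n_sets=n_sets, seed=seed
    )
    rep.n_randomizations = n_sets
    return rep


# ---------------------------------------------------------------------------
# constitutive / common / specific classification
# ---------------------------------------------------------------------------

CONSTITUTIVE = "constitutive"
COMMON = "common"
SPECIFIC = "specific"


def classify_sharing(sets: list[IntervalSet], focal: IntervalSet) -> pd.DataFrame:
    """Label each focal origin by how widely it is shared across maps.

    constitutive: overlaps >= 1 origin in every other set; specific:
    overlaps none; common: in between. Returns a frame aligned with the
    focal set carrying ``sharing_class`` and ``n_cell_lines`` (the
    number of maps, including the focal one, in which the origin is
    present).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    others = [s for s in sets if s is not focal]
    if len(others) == len(sets):
        raise ValueError("focal set must be one of the provided sets")
    hits = np.zeros(len(focal), dtype=np.int64)
    for other in others:
        hits += overlaps_any(focal, other).astype(np.int64)
    n_other = len(others)
    cls = np.where(hits == n_other, CONSTITUTIVE, np.where(hits == 0, SPECIFIC, COMMON))
    return pd.DataFrame({"sharing_class": cls, "n_cell_lines": hits + 1})
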