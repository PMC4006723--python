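"""Association of origins with genomic and chromatin features.

Covers: G-quadruplex motif scanning (Quadparser-style, four G-runs of
length >= 3 separated by loops of 1..loop_max arbitrary bases, on either
strand), per-origin G4 density, randomization-based enrichment of
origins in feature tracks with empirical p-values, and stratified
summaries of origin efficiency / length / density by timing category,
CGI status and chromatin-mark combinations.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comparison import sample_intervals
from .detection import Origin
from .intervals import IntervalSet, MappabilityMask, overlaps_any

_VALID_CHARS = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")

OPEN_MARKS_DEFAULT = ("H2AZ", "H3K9ac", "H3K4me3")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _g4_pattern(loop_max: int) -> re.Pattern[str]:
    # G-runs of >= 3; loops of 1..loop_max arbitrary bases (N allowed in
    # loops, never inside a run). Backtracking order of the regex engine
    # (runs and loops greedy, longest-first) is the documented dialect.
    return re.compile(r"G{3,}(?:[ACGTN]{1,%d}G{3,}){3}" % loop_max)


def scan_g4_string(seq: str, loop_max: int) -> list[tuple[int, int]]:
    """Leftmost-greedy, non-overlapping plus-strand motif spans in *seq*.

    After a match, scanning resumes at its end, so same-strand matches
    never overlap.
    """
    if loop_max < 1:
        raise ValueError("loop_max must be >= 1")
    seq = seq.upper()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return [(m.start(), m.end()) for m in _g4_pattern(loop_max).finditer(seq)]


def scan_g4_sequences(sequences: Mapping[str, str], loop_max: int) -> IntervalSet:
    """Scan both strands of each sequence for G4 motifs.

    Plus-strand motifs come from the sequence itself; minus-strand
    motifs (the C-run analog) are found by scanning the reverse
    complement with the same rule and mirroring coordinates, which makes
    the scanner exactly strand-symmetric. Motifs on opposite strands may
    overlap each other.
    """
    rows = []
    for chrom, seq in sequences.items():
        seq = seq.upper()
        n = len(seq)
        for s, e in scan_g4_string(seq, loop_max):
            rows.append((chrom, s, e, f"G4_{loop_max}", 0, "+"))
        for s, e in scan_g4_string(revcomp(seq), loop_max):
            rows.append((chrom, n - e, n - s, f"G4_{loop_max}", 0, "-"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    return IntervalSet(df, label=f"G4_loop{loop_max}").sorted()


def scan_g4(fasta: str | Path | Mapping[str, str], loop_max: int) -> IntervalSet:
    """G4 motifs from a FASTA file (or an in-memory name->sequence map)."""
    if isinstance(fasta, (str, Path)):
        from Bio import SeqIO

        sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    else:
        sequences = dict(fasta)
    return scan_g4_sequences(sequences, loop_max)


def g4_density(
    origins: Sequence[Origin], motifs: IntervalSet, window: int = 5000
) -> np.ndarray:
    """Number of motifs overlapping the window centered on each origin
    midpoint (individual motifs counted, even if they overlap)."""
    if window <= 0:
        raise ValueError("window must be > 0")
    counts = np.zeros(len(origins), dtype=np.int64)
    by = motifs.by_chrom()
    half = window // 2
    for i, o in enumerate(origins):
        if o.chrom not in by:
            continue
        ms, me = by[o.chrom]
        me_sorted = np.sort(me)
        ws = o.midpoint - half
        we = ws + window
        counts[i] = int(
            np.searchsorted(ms, we, side="left") - np.searchsorted(me_sorted, ws, side="right")
        )
    return counts


# ---------------------------------------------------------------------------
# randomization-based enrichment
# ---------------------------------------------------------------------------

ENRICHED = "enriched"
DEPLETED = "depleted"
NS = "ns"


@dataclasses.dataclass
class EnrichmentResult:
    feature_label: str
    stratum: str
    n_origins: int
    observed_pct: float
    expected_pct: float
    empirical_p: float
    direction: str


def _overlap_pct(df: pd.DataFrame, feat_foot: dict[str, tuple[np.ndarray, np.ndarray]]) -> float:
    hits = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in feat_foot:
            continue
        fs, fe = feat_foot[chrom]
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        idx = np.searchsorted(fs, qe, side="left")
        hits[sub.index.to_numpy()] = (idx > 0) & (fe[np.maximum(idx - 1, 0)] > qs)
    return 100.0 * hits.mean() if len(df) else float("nan")


def enrichment_test(
    origins: Sequence[Origin],
    feature: IntervalSet,
    mask: MappabilityMask,
    strata: Mapping[str, np.ndarray] | None = None,
    n_intervals: int = 100_000,
    n_reps: int = 1000,
    seed: int | None = None,
    feature_label: str | None = None,
    sig_level: float = 0.05,
) -> list[EnrichmentResult]:
    """Observed vs expected percentage of origins overlapping a feature.

    The null samples ``n_reps`` replicates of ``n_intervals`` random
    intervals of the origins' average length, uniformly on the mappable
    genome minus the origin footprint; each replicate records the
    percentage of its intervals overlapping the feature.
    ``empirical_p`` is the smaller of the two add-one one-sided
    p-values (bounded below by 1/(n_reps+1)); direction is called by
    the two one-sided tests at ``sig_level/2`` each, uncorrected across
    strata.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not origins:
        raise ValueError("no origins")
    from .detection import origins_to_intervalset

    oset = origins_to_intervalset(origins)
    from .intervals import merged_footprint

    feat_foot = merged_footprint(feature)
    space = mask.allowed_space(exclude=oset)
    mean_len = int(round(np.mean([o.length for o in origins])))
    rng = np.random.default_rng(seed)
    null_pct = np.empty(n_reps)
    lengths = np.full(n_intervals, mean_len, dtype=np.int64)
    for r in range(n_reps):
        rand_df = sample_intervals(space, lengths, rng)
        null_pct[r] = _overlap_pct(rand_df, feat_foot)
    if strata is None:
        strata = {"all": np.ones(len(origins), dtype=bool)}
    results: list[EnrichmentResult] = []
    label = feature_label or feature.label or "feature"
    for name, sel in strata.items():
        sel = np.asarray(sel, dtype=bool)
        if sel.sum() == 0:
            import warnings

            warnings.warn(f"stratum {name!r} is empty; skipped", stacklevel=2)
            continue
        sub = oset.df.loc[sel]
        obs = _overlap_pct(sub, feat_foot)
        p_hi = (1 + int((null_pct >= obs).sum())) / (n_reps + 1)
        p_lo = (1 + int((null_pct <= obs).sum())) / (n_reps + 1)
        p = min(p_hi, p_lo)
        if p < sig_level / 2:
            direction = ENRICHED if p_hi < p_lo else DEPLETED
        else:
            direction = NS
        results.append(
            EnrichmentResult(
                feature_label=label,
                stratum=str(name),
                n_origins=int(sel.sum()),
                observed_pct=float(obs),
                expected_pct=float(null_pct.mean()),
                empirical_p=float(p),
                direction=direction,
            )
        )
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


# ---------------------------------------------------------------------------
# stratified summaries
# ---------------------------------------------------------------------------

def annotate_origins(
    origins: Sequence[Origin],
    marks: Mapping[str, IntervalSet],
    cgi: IntervalSet | None = None,
    open_marks: Sequence[str] = OPEN_MARKS_DEFAULT,
) -> pd.DataFrame:
    """Per-origin table: efficiency, length, timing labels, CGI status
    and one boolean association column per mark (any >= 1 bp overlap
    with that mark's peaks). ``OpenMarks`` is association with any of
    the configured open-chromatin marks."""
    from .detection import origins_to_intervalset

    oset = origins_to_intervalset(origins)
    df = pd.DataFrame(
        {
            "chrom": [o.chrom for o in origins],
            "start": [o.start for o in origins],
            "end": [o.end for o in origins],
            "length": [o.length for o in origins],
            "n_reads": [o.n_reads for o in origins],
            "efficiency": [o.efficiency for o in origins],
            "timing_category": [o.labels.get("timing_category") for o in origins],
            "timing_group": [o.labels.get("timing_group") for o in origins],
        }
    )
    for name, track in marks.items():
        df[name] = overlaps_any(oset, track)
    present_open = [m for m in open_marks if m in marks]
    if present_open:
        df["OpenMarks"] = df[list(present_open)].any(axis=1)
    if cgi is not None:
        df["CGI"] = overlaps_any(oset, cgi)
    return df


def mark_pair_class(df: pd.DataFrame, mark_a: str, mark_b: str) -> pd.Series:
    """Partition origins by a pair of marks: both / a-only / b-only /
    neither (the bar logic of simultaneous-mark comparisons)."""
    for m in (mark_a, mark_b):
        if m not in df.columns:
            raise ValueError(f"unknown mark {m!r}")
    a = df[mark_a].astype(bool)
    b = df[mark_b].astype(bool)
    out = np.where(a & b, "both", np.where(a, f"{mark_a}_only", np.where(b, f"{mark_b}_only", "neither")))
    return pd.Series(out, index=df.index, name="pair_class")


def stratum_footprint_mb(
    mask: MappabilityMask, timing_profile, category: int
) -> float:
    """Mappable Mb whose timing bin falls in the given category (the
    density denominator)."""
    total = 0
    b = timing_profile.bin_size
    foot = mask.allowed_space()
    for chrom, arr in timing_profile.mrt.items():
        if chrom not in foot:
            continue
        cats = np.full(len(arr), -1)
        ok = ~np.isnan(arr)
        cats[ok] = np.minimum(np.floor(6 * arr[ok]).astype(int) + 1, 6)
        sel = np.nonzero(cats == category)[0]
        if len(sel) == 0:
            continue
        bs, be = foot[chrom]
        for i in sel:
            lo, hi = i * b, (i + 1) * b
            j0 = np.searchsorted(be, lo, side="right")
            for j in range(j0, len(bs)):
                if bs[j] >= hi:
                    break
                total += min(hi, int(be[j])) - max(lo, int(bs[j]))
    return total / 1e6


def stratified_summary(
    annotated: pd.DataFrame,
    group_cols: Sequence[str],
    mask: MappabilityMask | None = None,
    timing_profile=None,
) -> pd.DataFrame:
    """Mean efficiency/length, origin density and 95% normal CIs per
    stratum defined by *group_cols* of an :func:`annotate_origins`
    table.

    Density (origins per Mb) is reported when the stratum includes a
    timing category and mask+timing profile are supplied; its
    denominator is the mappable Mb assigned to that category.
    """
    rows = []
    for key, sub in annotated.groupby(list(group_cols), dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        n = len(sub)
        eff = sub["efficiency"].to_numpy(dtype=float)
        ln = sub["length"].to_numpy(dtype=float)
        row = dict(zip(group_cols, key))
        row.update(
            n=n,
            mean_efficiency=float(eff.mean()),
            efficiency_ci95=float(1.96 * eff.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            mean_length=float(ln.mean()),
            length_ci95=float(1.96 * ln.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        )
        if (
            mask is not None
            and timing_profile is not None
            and "timing_category" in group_cols
        ):
            cat = row["timing_category"]
            if cat is not None and not (isinstance(cat, float) and np.isnan(cat)):
                mb = stratum_footprint_mb(mask, timing_profile, int(cat))
                row["density_per_mb"] = n / mb if mb > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_efficiency(eff_a: np.ndarray, eff_b: np.ndarray) -> tuple[float, float]:
    """Two-sample t-test (equal variances) on origin efficiencies, as
    used to compare mark-associated vs non-associated strata. Returns
    (t, p)."""
    t, p = stats.ttest_ind(np.asarray(eff_a, float), np.asarray(eff_b, float))
    return float(t), float(p)
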