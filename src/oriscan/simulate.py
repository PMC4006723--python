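"""Synthetic SNS-seq data with the statistical structure the detection
model assumes.

The generator is the study-conditions mirror of the detection model:
read-bearing sites arrive as a Poisson process whose intensity is a
constant background (``lambda_sites`` per bp) multiplied by the fold
enrichment inside planted origins; each site carries a Geometric
(``p_geom``) read multiplicity; reads falling in mappability gaps are
discarded. Alongside reads it produces matched input-DNA controls
(background only), feature tracks placed around the truth origins with
timing-group-dependent overlap probabilities, six Repli-Seq fraction
tracks whose per-bin MRT recovers the planted timing category, and a
FASTA whose only G4 motifs are the planted ones.

Every artifact derives from the config and its mandatory seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .coverage import ReadStartProfile
from .intervals import GenomeLayout, IntervalSet, MappabilityMask
from .timing import N_FRACTIONS, FractionTrack, timing_group

DEFAULT_MARK_PROBS: dict[str, dict[str, float]] = {
    # per-mark probability that a truth origin of the given timing group
    # overlaps a peak of the mark
    "H2AZ": {"early": 0.9, "mid": 0.4, "late": 0.1},
    "H3K9ac": {"early": 0.9, "mid": 0.4, "late": 0.1},
    "H3K4me3": {"early": 0.9, "mid": 0.4, "late": 0.1},
    "H4K20me1": {"early": 0.8, "mid": 0.8, "late": 0.2},
    "H3K27me3": {"early": 0.2, "mid": 0.8, "late": 0.3},
    "H3K9me3": {"early": 0.05, "mid": 0.2, "late": 0.9},
}
DEFAULT_CGI_PROBS = {"early": 0.8, "mid": 0.4, "late": 0.1}


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome (defaults are the
    desk-scale conditions: 1 chromosome x 10 Mb, 200 planted 2 kb
    origins at 10x background, ~1% mappability gaps)."""

    seed: int
    chrom_lengths: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"chr1": 10_000_000}
    )
    lambda_sites: float = 0.01  # read-bearing sites per bp, background
    p_geom: float = 0.6  # per-site multiplicity success probability
    n_origins: int = 200
    origin_width: int = 2000
    origin_folds: tuple[float, ...] = (10.0,)
    n_gaps: int = 5
    gap_fraction: float = 0.01
    timing_region_size: int = 500_000
    timing_bin_size: int = 10_000
    mark_probs: dict = dataclasses.field(default_factory=lambda: DEFAULT_MARK_PROBS)
    cgi_probs: dict = dataclasses.field(default_factory=lambda: DEFAULT_CGI_PROBS)
    mark_background_per_mb: float = 5.0
    n_g4: int = 60
    g4_loop_sizes: tuple[int, ...] = (3, 5, 7)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(f < 1 for f in self.origin_folds):
            raise ValueError("fold enrichments must be >= 1")
        if self.origin_width < 1:
            raise ValueError("origin width must be >= 1")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout.from_dict(self.chrom_lengths)

    # flat key = value config file; values JSON-encoded
    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {json.dumps(getattr(self, f.name))}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {i}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"{path}: line {i}: unknown key {key!r}")
            val = json.loads(raw.strip())
            if isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# deterministic layout of gaps, origins and timing regions
# ---------------------------------------------------------------------------

def plan_gaps(config: SimulationConfig) -> IntervalSet:
    """Mappability gaps: evenly spaced blocks covering ``gap_fraction``
    of each chromosome."""
    rows = []
    for chrom, length in config.chrom_lengths.items():
        if config.n_gaps == 0 or config.gap_fraction <= 0:
            continue
        gap_len = int(config.gap_fraction * length / config.n_gaps)
        if gap_len == 0:
            continue
        for k in range(config.n_gaps):
            center = int((k + 0.5) * length / config.n_gaps)
            rows.append((chrom, center - gap_len // 2, center - gap_len // 2 + gap_len))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if df.empty:
        df = pd.DataFrame({"chrom": [], "start": [], "end": []})
    return IntervalSet(df, label="gaps")


def mappability_mask(config: SimulationConfig) -> MappabilityMask:
    from .intervals import subtract

    whole = MappabilityMask.whole_genome(config.layout)
    space = subtract(whole.mappable, plan_gaps(config))
    rows = [
        (chrom, int(s), int(e))
        for chrom, (ss, ee) in space.items()
        for s, e in zip(ss, ee)
    ]
    return MappabilityMask(
        IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), label="mappable")
    )


def plan_origins(config: SimulationConfig) -> IntervalSet:
    """Truth origins: one per slot on a per-chromosome grid, jittered
    within the slot, avoiding mappability gaps; fold enrichments cycle
    through ``origin_folds``."""
    rng = _rng(config, 0)
    gaps = plan_gaps(config).by_chrom()
    rows = []
    i = 0
    total_bp = sum(config.chrom_lengths.values())
    remaining = config.n_origins
    chrom_items = list(config.chrom_lengths.items())
    for ci, (chrom, length) in enumerate(chrom_items):
        if ci == len(chrom_items) - 1:
            n = remaining
        else:
            n = int(round(config.n_origins * length / total_bp))
            remaining -= n
        if n == 0:
            continue
        slot = length / n
        if slot < 3 * config.origin_width:
            raise ValueError("genome too small for the requested number of origins")
        for k in range(n):
            margin = config.origin_width
            lo = int(k * slot) + margin
            hi = int((k + 1) * slot) - margin - config.origin_width
            for _ in range(20):  # re-draw if the slot position hits a gap
                start = int(rng.integers(lo, hi + 1))
                end = start + config.origin_width
                in_gap = False
                if chrom in gaps:
                    gs, ge = gaps[chrom]
                    j = np.searchsorted(gs, end, side="left")
                    in_gap = j > 0 and ge[j - 1] > start
                if not in_gap:
                    break
            fold = config.origin_folds[i % len(config.origin_folds)]
            rows.append((chrom, start, end, f"truth_{i + 1}", fold))
            i += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "fold"])
    return IntervalSet(df, label="truth_origins")


def plan_timing_regions(config: SimulationConfig) -> IntervalSet:
    """Consecutive fixed-size regions with timing categories cycling
    1..6 along each chromosome."""
    rows = []
    for chrom, length in config.chrom_lengths.items():
        n = -(-length // config.timing_region_size)
        for k in range(n):
            start = k * config.timing_region_size
            end = min(start + config.timing_region_size, length)
            rows.append((chrom, start, end, k % 6 + 1))
    return IntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "category"]),
        label="timing_regions",
    )


def origin_category(origin_mid: int, config: SimulationConfig) -> int:
    return (origin_mid // config.timing_region_size) % 6 + 1


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _drop_in_gaps(chrom: str, pos: np.ndarray, gaps: dict) -> np.ndarray:
    if chrom not in gaps or len(pos) == 0:
        return pos
    gs, ge = gaps[chrom]
    idx = np.searchsorted(gs, pos, side="right")
    inside = (idx > 0) & (pos < ge[np.maximum(idx - 1, 0)])
    return pos[~inside]


def simulate_reads(
    config: SimulationConfig, background_only: bool = False, stream: int = 1
) -> tuple[ReadStartProfile, IntervalSet]:
    """Simulate the SNS read-start profile; returns (profile, truth).

    ``background_only`` produces the matched input-DNA control: the
    same noise process with no planted enrichment (truth returned
    unchanged for bookkeeping).
    """
    rng = _rng(config, stream)
    truth = plan_origins(config)
    gaps = plan_gaps(config).by_chrom()
    reads: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths.items():
        n_bg = rng.poisson(config.lambda_sites * length)
        sites = [rng.integers(0, length, size=n_bg)]
        if not background_only:
            sub = truth.df[truth.df["chrom"] == chrom]
            for start, end, fold in zip(sub["start"], sub["end"], sub["fold"]):
                extra = rng.poisson(config.lambda_sites * (fold - 1) * (end - start))
                sites.append(rng.integers(start, end, size=extra))
        pos = _drop_in_gaps(chrom, np.concatenate(sites), gaps)
        if config.p_geom < 1:
            mult = rng.geometric(config.p_geom, size=len(pos))
        else:
            mult = np.ones(len(pos), dtype=np.int64)
        reads[chrom] = np.repeat(pos, mult)
    return ReadStartProfile.from_positions(reads), truth


def simulate_input_reads(config: SimulationConfig) -> ReadStartProfile:
    """Matched input-DNA control: background-only noise, separate stream."""
    profile, _ = simulate_reads(config, background_only=True, stream=3)
    return profile


# ---------------------------------------------------------------------------
# tracks, fractions and sequence
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticTracks:
    truth_origins: IntervalSet
    timing_regions: IntervalSet
    fraction_tracks: list[FractionTrack]
    planted_categories: dict[str, np.ndarray]  # per timing bin; 0 = missing
    marks: dict[str, IntervalSet]
    cgi: IntervalSet
    sequences: dict[str, str]
    g4_truth: IntervalSet
    mask: MappabilityMask


def _category_weights(cat: int) -> np.ndarray:
    """Fraction-signal mixture whose MRT falls in category *cat*: most
    signal in fraction cat, a little in its neighbours."""
    w = np.zeros(N_FRACTIONS)
    w[cat - 1] = 0.8
    if cat > 1:
        w[cat - 2] += 0.1
    else:
        w[cat - 1] += 0.1
    if cat < N_FRACTIONS:
        w[cat] += 0.1
    else:
        w[cat - 1] += 0.1
    return w


def simulate_fraction_tracks(
    config: SimulationConfig,
) -> tuple[list[FractionTrack], dict[str, np.ndarray]]:
    """Six Repli-Seq fraction tracks. Per bin, the planted category sets
    the signal mixture across fractions (the per-bin amplitude varies
    lognormally, which leaves the MRT untouched); bins inside
    mappability gaps carry zero signal in all fractions (missing)."""
    rng = _rng(config, 4)
    b = config.timing_bin_size
    gaps = plan_gaps(config).by_chrom()
    values = [dict() for _ in range(N_FRACTIONS)]
    planted: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths.items():
        n = -(-length // b)
        cats = (np.arange(n) * b // config.timing_region_size) % 6 + 1
        amp = 100.0 * rng.lognormal(0.0, 0.25, size=n)
        missing = np.zeros(n, dtype=bool)
        if chrom in gaps:
            gs, ge = gaps[chrom]
            for s, e in zip(gs, ge):
                lo, hi = int(s) // b, -(-int(e) // b)
                missing[lo : min(hi, n)] = True
        sig = np.zeros((N_FRACTIONS, n))
        for cat in range(1, 7):
            sel = cats == cat
            sig[:, sel] = _category_weights(cat)[:, None] * amp[sel]
        sig[:, missing] = 0.0
        for i in range(N_FRACTIONS):
            values[i][chrom] = sig[i]
        out_cats = cats.copy()
        out_cats[missing] = 0
        planted[chrom] = out_cats
    tracks = [FractionTrack(i + 1, b, values[i]) for i in range(N_FRACTIONS)]
    return tracks, planted


def _place_feature_intervals(
    config: SimulationConfig,
    probs: Mapping[str, float],
    rng: np.random.Generator,
    width_range: tuple[int, int],
    label: str,
    truth: IntervalSet,
) -> IntervalSet:
    """Intervals overlapping each truth origin with the timing-group
    probability, plus uniform background intervals."""
    rows = []
    for _, o in truth.df.iterrows():
        mid = (int(o["start"]) + int(o["end"])) // 2
        group = timing_group(origin_category(mid, config))
        if rng.random() < probs[group]:
            w = int(rng.integers(width_range[0], width_range[1] + 1))
            jitter = int(rng.integers(-config.origin_width // 4, config.origin_width // 4 + 1))
            start = max(0, mid - w // 2 + jitter)
            rows.append((o["chrom"], start, start + w))
    for chrom, length in config.chrom_lengths.items():
        n_bg = rng.poisson(config.mark_background_per_mb * length / 1e6)
        for _ in range(n_bg):
            w = int(rng.integers(width_range[0], width_range[1] + 1))
            start = int(rng.integers(0, max(1, length - w)))
            rows.append((chrom, start, start + w))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if df.empty:
        df = pd.DataFrame({"chrom": [], "start": [], "end": []})
    return IntervalSet(df, label=label).sorted()


def simulate_marks(config: SimulationConfig) -> tuple[dict[str, IntervalSet], IntervalSet]:
    rng = _rng(config, 5)
    truth = plan_origins(config)
    marks = {
        name: _place_feature_intervals(config, probs, rng, (1000, 3000), name, truth)
        for name, probs in config.mark_probs.items()
    }
    cgi = _place_feature_intervals(config, config.cgi_probs, rng, (500, 2000), "CGI", truth)
    return marks, cgi


def _g4_free_sequence(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random ACGT with every G- and C-run capped at length 2, so the
    sequence contains no G4 motif on either strand."""
    letters = np.frombuffer(b"ACGT", dtype="S1")
    seq = letters[rng.integers(0, 4, size=n)].copy()
    for base, repl in ((b"G", b"A"), (b"C", b"T")):
        run = (seq == base)
        triple = run[2:] & run[1:-1] & run[:-2]
        idx = np.nonzero(triple)[0] + 2  # third position of every run of 3
        seq[idx] = repl
    return seq


def _motif_string(loop: int, strand: str) -> str:
    if strand == "+":
        return "GGG" + ("A" * loop + "GGG") * 3
    return "CCC" + ("T" * loop + "CCC") * 3


def simulate_sequences(config: SimulationConfig) -> tuple[dict[str, str], IntervalSet]:
    """FASTA with planted G4 motifs and G4-free flanks by construction."""
    rng = _rng(config, 6)
    sequences: dict[str, str] = {}
    rows = []
    for chrom, length in config.chrom_lengths.items():
        seq = _g4_free_sequence(length, rng)
        n = config.n_g4
        if n > 0:
            slot = length / n
            for k in range(n):
                loop = config.g4_loop_sizes[k % len(config.g4_loop_sizes)]
                strand = "+" if k % 2 == 0 else "-"
                motif = _motif_string(loop, strand).encode()
                lo = int(k * slot) + 10
                hi = int((k + 1) * slot) - 10 - len(motif)
                pos = int(rng.integers(lo, hi + 1))
                seq[pos : pos + len(motif)] = np.frombuffer(motif, dtype="S1")
                seq[pos - 1] = b"T"
                seq[pos + len(motif)] = b"T"
                rows.append((chrom, pos, pos + len(motif), f"g4_{k + 1}", loop, strand))
        sequences[chrom] = seq.tobytes().decode()
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    return sequences, IntervalSet(df, label="g4_truth")


def simulate_tracks(config: SimulationConfig) -> SyntheticTracks:
    """All non-read artifacts: timing regions and fraction tracks, mark
    and CGI tracks, sequence with planted G4s, and the mappability
    mask."""
    truth = plan_origins(config)
    tracks, planted = simulate_fraction_tracks(config)
    marks, cgi = simulate_marks(config)
    sequences, g4_truth = simulate_sequences(config)
    return SyntheticTracks(
        truth_origins=truth,
        timing_regions=plan_timing_regions(config),
        fraction_tracks=tracks,
        planted_categories=planted,
        marks=marks,
        cgi=cgi,
        sequences=sequences,
        g4_truth=g4_truth,
        mask=mappability_mask(config),
    )


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# synthetic distance matrices for the discriminant module
# ---------------------------------------------------------------------------

GROUP_NEAR_MARKS = {
    "early": ("H2AZ", "H3K9ac", "H3K4me3", "H4K20me1"),
    "mid": ("H4K20me1", "H3K27me3"),
    "late": ("H3K9me3",),
}
# planted effect sizes: a group-characteristic mark sits at contact
# distance (0 bp w.p. 0.7, else ~1 kb), any other mark is genuinely
# distant (20 kb offset + ~80 kb exponential tail); marks are
# group-characteristic w.p. 0.85, swapped w.p. 0.05 (label noise)
P_NEAR, P_NEAR_OTHER = 0.85, 0.05
P_CONTACT = 0.7
NEAR_TAIL_BP = 1000.0
FAR_OFFSET_BP, FAR_TAIL_BP = 20000.0, 80000.0


def simulate_distance_matrix(n_per_group: int = 150, seed: int = 0):
    """Synthetic origins x marks distance matrix with planted proximity
    structure: early origins near open marks (H2AZ, H3K9ac, H3K4me3)
    and H4K20me1, mid origins near H4K20me1 + H3K27me3, late origins
    near H3K9me3; effect sizes as in the module constants above."""
    from .discriminant import DistanceMatrix

    rng = np.random.default_rng(seed)
    mark_names = list(DEFAULT_MARK_PROBS)
    rows = []
    groups = []
    for group in ("early", "mid", "late"):
        near_set = set(GROUP_NEAR_MARKS[group])
        for _ in range(n_per_group):
            row = []
            for m in mark_names:
                p = P_NEAR if m in near_set else P_NEAR_OTHER
                if rng.random() < p:
                    d = 0.0 if rng.random() < P_CONTACT else rng.exponential(NEAR_TAIL_BP)
                else:
                    d = FAR_OFFSET_BP + rng.exponential(FAR_TAIL_BP)
                row.append(d)
            rows.append(row)
            groups.append(group)
    X = pd.DataFrame(rows, columns=mark_names)
    return DistanceMatrix(X=X, groups=pd.Series(groups, name="group"), n_dropped=0)
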