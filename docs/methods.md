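# Methods

## The detection model

Short-nascent-strand (SNS) sequencing marks replication origins as local
accumulations of read starts. Because SNS fragments are size-selected at
roughly 1.5–2 kb before sequencing, no detection can resolve origins
below that scale; generic ChIP-seq peak callers ignore this floor and
tend to fragment one origin into several sub-kb peaks. The scan
detector therefore fixes the resolution a priori: it slides a window of
width u = 2,000 bp along the genome and asks whether the window's read
count is exceptional under a background noise model.

The noise model is a marked point process. Read-bearing *sites* arrive
along the genome as a Poisson process with intensity λ_sites (sites per
bp); each occupied site carries a geometric number of reads
(Geometric(p_geom) on {1, 2, ...}, mean 1/p), capturing amplification
and ligation multiplicity. The count W of a u-bp window under this null
is compound Poisson (Pólya–Aeppli): a Poisson(λ_sites · u) number of
geometric summands.

### Threshold calibration

The detection threshold τ is calibrated genome-wise: τ is the smallest
integer such that the probability that the *richest* window of the
scanned genome reaches τ is at most α (default 0.05). Windows with
count ≥ τ are significant (inclusive ties — the conservative-consistent
reading of "smallest τ with tail ≤ α").

Two threshold modes are provided and must agree within ±1 read:

* **monte_carlo** — simulate the null genome and take the empirical
  (1−α) point of the maximum window count over the same window grid the
  scan uses. This is the reference implementation of the contract.
* **analytic** (default) — exact window-count distribution by the
  Panjer recursion, combined with an entry-rate (clumping)
  approximation of the maximum over the stepped grid: consecutive
  windows share a stretch of length u − step, and a clump of
  exceedances starts at a window whose predecessor stayed below τ;
  with shared count C and fresh-stretch count B (both compound
  Poisson),

      q(τ) = Σ_c P(C = c) · F_B(τ−1−c) · (1 − F_B(τ−1−c)),
      P(max ≥ τ) ≈ 1 − (1 − P(W ≥ τ)) · exp(−(n_windows − 1) · q(τ)).

  Modeling the grid directly (rather than a continuous slide) is what
  brings the approximation within one read of the Monte-Carlo
  calibration at the default step.

### Coverage adaptation

Real coverage is heterogeneous, so a single genome-wide λ would either
flood rich regions with false positives or lose power in poor ones. The
binned coverage process (default 1 kb bins) is segmented into regions
of constant intensity with a penalized Poisson changepoint model:
segment costs are negative Poisson log-likelihoods, the penalty is
BIC-style (`penalty_scale · log n` per segment, default scale 2), and
the optimum is found by pruned penalized DP (PELT); an exact fixed-K DP
is provided and tested against exhaustive enumeration. Two choices
matter:

* **Minimum segment length** (default 50 bins = 50 kb): a 2 kb origin
  inflates its bin so strongly that an unconstrained segmentation would
  carve it out as its own "background", raising the local threshold and
  destroying the detection the scan exists for. The floor keeps
  segmentation at the regional-coverage scale; origins then inflate
  their segment's λ̂ only mildly (a conservative bias of the
  plug-in background, visible as type-I rates slightly below nominal).
* **Low-coverage exclusion**: segments with λ̂ below 10% of the
  genome-wide mean intensity are excluded from scanning (the analog of
  dropping unmappable/extremely poor regions).

The genome-wise α is allocated across analyzed segments proportionally
to their share of the scanned length (Bonferroni in segments), and each
segment's null uses its own λ̂ (converted to site intensity via the
globally estimated p̂, λ_sites = λ̂_reads · p̂). p̂ itself is the
method-of-moments estimate 1/(mean multiplicity per occupied site) over
background segments.

Significant windows overlapping or abutting each other merge into
origins; reads are recounted over the union and the origin's
**efficiency** is reads per bp, the proxy for the fraction of cell
cycles in which the origin fires. No origin can be shorter than u
(except segment clipping), which is the resolution control.

An upper-bound FDR can be estimated against matched input DNA: the
fraction of SNS origins that are also called when the detector runs on
the input track.

## Comparative toolkit

* **Clustering / matched resolution** — `merge_within(set, gap)`
  transitively merges origins whose edge-to-edge distance is strictly
  below the gap (12 kb, 6 kb and 20 kb are the values used when
  matching maps of different native resolution).
* **Overlap and randomization nulls** — overlap requires ≥ 1 bp and
  ignores strand. Expected overlap replaces one origin set by sets of
  random intervals with its exact length multiset, placed uniformly on
  the mappable genome minus that set's own footprint (50 sets by
  default). Feature enrichment uses average-length random intervals
  instead (100,000 intervals × 1,000 replicates by default) and
  reports an add-one empirical p per direction; enrichment/depletion
  is called by the two one-sided tests at α/2 each, uncorrected across
  strata.
* **Replication timing** — MRT of a bin is the signal-weighted mean of
  the six fraction midpoints (weights (i − 0.5)/6), so MRT ∈ [1/12,
  11/12]; zero-signal bins are missing. Categories split [0, 1] into
  six left-closed intervals (the last closed); 1–2 early, 3–4 mid, 5–6
  late. An origin takes the category of its midpoint bin — origins
  (few kb) are far smaller than timing bins, so averaging over the span
  would change nothing but the edge cases.
* **G4 scanning** — Quadparser-style motifs: four runs of G{3,}
  separated by loops of 1..loop_max arbitrary bases (N allowed in
  loops, never in runs), matched leftmost-greedy and non-overlapping
  per strand; the minus strand is scanned on the reverse complement
  and mirrored, which makes the scanner exactly strand-symmetric.
  The greedy backtracking order (runs and loops longest-first) is a
  dialect choice pinned by an exhaustive-enumerator oracle in the
  tests; whether overlapping same-strand matches should be collapsed
  differently is not determinable from the method description.
* **Discriminant analysis** — each origin is described by its bp
  distance (0 = overlap) to the nearest peak of each chromatin mark
  (H2AZ, H4K20me1, H3K27me3, H3K9me3, H3K9ac, H3K4me3) and grouped
  early/mid/late. Multi-class LDA (scikit-learn) yields at most
  n_groups − 1 axes; per-variable Pearson correlations with each axis
  are the interpretive output. Axis signs are fixed so the
  largest-|correlation| variable of each axis correlates negatively —
  a pure reporting convention that makes outputs reproducible.
  Distances are used raw in bp by default; a `log1p` flag is provided
  because nearest-peak distances are heavy-tailed, and LDA on raw
  heavy-tailed distances is statistically inefficient (on the synthetic
  recovery benchmark below, raw-bp LDA reaches ≈ 0.86 nearest-centroid
  accuracy vs ≈ 0.95 with log1p; the recovery checks use log1p).

## Synthetic data: what it emulates and what it does not

The generator mirrors the detection model exactly: background sites
Poisson(λ_sites), fold-enrichment multiplier inside planted origins,
geometric per-site multiplicities, reads discarded in mappability gaps.
Default study conditions (chosen once): one 10 Mb chromosome, λ_sites =
0.01 sites/bp, p_geom = 0.6, 200 planted 2 kb origins at 10× background
(detection-power checks require ≥ 8×), 1% of the genome in five
mappability gaps. Matched input DNA is the same process without
enrichment. Feature tracks place mark/CGI intervals overlapping truth
origins with timing-group-dependent probabilities plus uniform
background intervals; Repli-Seq fractions assign each 500 kb region a
cycling category 1..6 and put ~80% of the (lognormally varying) bin
amplitude in the matching fraction, so the planted category is
recoverable exactly; the FASTA is G4-free by construction (G/C runs
capped at 2) with planted motifs at recorded positions. The
distance-matrix simulator plants the early/mid/late proximity
structure with explicit effect sizes (contact distance with
probability 0.85 for group-characteristic marks, 20 kb offset + 80 kb
exponential tail otherwise).

Because generator and model share their assumptions, passing tests
demonstrate correctness and calibration of the implementation — not
robustness to what real SNS data adds: GC/mappability biases of λ,
non-geometric duplicate structure, fragment-length variation,
cell-population heterogeneity, and origin widths/spacings that are not
constants. Claims that depend on real sequencing data (origin counts
per cell line, cross-method overlap percentages, real FDR estimates,
real mark correlations) are outside what this package can validate.

## Numerical choices and problem sizes

* Scan step 200 bp (windows overlap 10×); finer steps change only
  boundary resolution.
* Panjer support is extended adaptively until the null tail is resolved
  below the per-segment level.
* Monte-Carlo threshold mode uses 2,000 null replicates by default
  (10,000 in the analytic-vs-MC agreement checks).
* Segmentation: bins of 1 kb, penalty scale 2, minimum segment 50
  bins, low-coverage floor 10% of the genome mean; the penalty is
  doubled until the per-chromosome segment cap (50) is met.
* Statistical validation sizes: 500 background genomes of 1 Mb per
  noise setting for type-I control; 100 replicates of the default
  10 Mb genome for power/FDR; 100 replicates of 2 Mb × 40 origins at
  folds 2–32 for quantification; 10⁵ placements for null-overlap
  accuracy; 100 enrichment runs (199 replicates each, null replicate
  size equal to the origin count so null spread matches the observed
  statistic's sampling spread) for the ns-rate check; 3 × 1,000 random
  10 kb sequences for the G4 oracle; 450 rows for LDA recovery. These
  sizes give Monte-Carlo error comfortably below each check's margin
  while keeping the whole validation in minutes on one CPU.

## Known limitations

* The analytic threshold is an approximation; its contract (±1 read of
  the Monte-Carlo calibration) is enforced at the default window/step
  and the tested intensity range, not proven globally.
* The plug-in background (λ̂ estimated from the same data that is
  scanned) makes realized type-I rates run slightly below nominal on
  origin-bearing genomes, since planted signal inflates segment λ̂.
* Enrichment p-values are uncorrected across strata by design; treat
  per-stratum stars accordingly.
* Three reported discriminant axes for three groups (as sometimes seen
  in published outputs) exceed the classical LDA maximum of 2; the
  implementation exposes `n_axes` but never fabricates a third axis.
* The timing-category round trip is exact only because the generator
  places each region's MRT at the category midpoint; real MRT values
  near category boundaries are assigned deterministically
  (left-closed bins) but not robustly.
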