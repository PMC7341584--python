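# Methods

## Coverage model and peak calling

A polyA site sampled by 3'-biased chemistry produces reads whose 3'
ends scatter around the cleavage position; per-base coverage is then
approximately Gaussian (a Normal location kernel convolved with the
read-length boxcar). Peaks are discovered per gene by iterative
fit-and-subtract on coverage tracks:

- **Junction handling.** Junctions come from CIGAR `N` gaps (each
  flanking aligned block must span >= `min_overhang` = 5 bases; the
  overhang guard is plumbing, not a biological filter) or from a
  BED6/BED12 junction file. Junctions with support below
  `max(min_jcutoff = 50, min_jcutoff_prop = 5% of the gene's maximum
  coverage)` are discarded. Retained intronic spans are merged when
  they overlap (the degenerate alternative-splicing case has no
  canonical treatment; merging keeps the partition well defined).
  Reads wholly inside a retained span form one within-junction track
  per span; all remaining reads form the across-junction track with
  retained spans excised and flanks concatenated, plus an index-to-
  genome position map.
- **Fitting.** `y = k·exp(-(x-mu)²/(2 sigma²))` is fitted by
  least squares (`scipy.optimize.curve_fit`) over a 600-bp window
  centred on the apex, initialised at mu = 300 (window midpoint when
  the window is clipped at a track edge), sigma = 100, k = apex
  height. sigma is bounded to [5, 350] bp during optimisation and fits
  converging onto a bound are rejected as degenerate; optimiser
  failure marks the fit unconverged and the window is zeroed so the
  same apex is not revisited.
- **Interval and subtraction.** A converged fit yields the interval
  `centre ± 3 sigma` with `centre = window start + mu` in track
  coordinates; the working track is zeroed over that interval (the
  spirit of "zero the fitted peak"; zeroing exactly the 600-bp window
  would erase neighbouring peaks closer than 300 bp). Both interval
  ends and the fitted centre are mapped back through the position map;
  a peak whose reads splice across a retained junction therefore has a
  genomic envelope spanning the intron while its assigned coverage
  does not.
- **Stopping.** Before each fit, iteration over the whole gene stops
  when residual coverage is both <= `min_cov_prop` (5%) of the gene
  total and <= `min_cov_cutoff` (500); a track stops when the current
  apex is both < `min_peak_cutoff` (200) and <= `min_peak_prop` (5%)
  of the gene's maximum coverage. Both rules demand both thresholds,
  acting as floors on residual signal; within-junction tracks use the
  gene-level totals. A 200-iteration-per-track valve guards
  pathological tracks. A consequence worth knowing: in deep data a
  single dominant peak's residual tail at the ±3 sigma boundary
  (~1.1% of the apex) can exceed the absolute height floor and yield a
  flanking secondary call; this is inherent to hard-interval
  subtraction, not a fitting error.

Only the least-squares backend is provided; a maximum-likelihood
backend would add a second optimiser path for peaks that are, in our
and others' experience, almost always concordant.

## Peak merging

The distance between two peaks of one gene is
`(|Δstart| + |Δend|) / width(scoring peak)`; similarity is
`max(0, 1 - distance)`, read with the sum of coordinate deltas by
default (a max-of-deltas variant is available via `distance_mode`).
Matching requires >= 0.75 in
one orientation and >= 0.5625 (25% relaxation) in the other; note that
with the sum reading the relaxed threshold cannot bind for realizable
coordinate pairs (the deltas sum is orientation-symmetric, so a 0.75
score in one direction forces >= 2/3 in the other) — it matters only
for score pairs arising from other distance readings, and the rule is
implemented and tested at the score level. Matching is greedy,
best-score-first, one-to-one, with coordinate tie-breaks; multi-dataset
merging is iterative in input order with a final coordinate re-sort.

## UMI counting

The molecule key is (cell barcode, UMI, gene); each distinct key
increments every peak of the gene that any of its reads' aligned
blocks overlap by >= 1 base. Spliced gaps do not overlap; strand is
ignored by default (a strict-strand mode exists). Non-whitelisted
barcodes are excluded. The matrix is written as MatrixMarket plus
peaks/barcodes TSV sidecars, CellRanger-triplet style.

## Annotation

Feature types are collected across all transcripts of the peak's gene
(UTR3, UTR5, coding-exon, intron; all overlapped features are kept)
and the primary label follows UTR3 > UTR5 > exon > intron. The 3' bias
of the assay justifies ranking UTR3 above UTR5. UTRs are taken from
explicit GTF features when present and otherwise derived from CDS vs
exon extents. Sequence scanning is strand-aware in transcription
direction: 200 nt (default; configurable) downstream of the peak's 3'
boundary for AATAAA and for any 13-mer with >= 12 A's; the mirrored
upstream window for 13-mers with >= 12 T's. The window length is a
package default chosen because canonical polyA signals sit 10–30 nt
upstream of cleavage while called boundaries are ±3 sigma
approximations of the cleavage position.

## Differential usage

Cells of each population are shuffled (one seeded stream per
population, so results are independent of label order) and dealt
round-robin into n = 6 groups whose counts are summed. n = 6 balances
replicate count against runtime, consistent with how pseudo-bulk DTU
testing is usually tuned. Size factors are median-of-ratios over
all-positive peaks with the shorth (mean of the shortest half) as
location estimator — more stable than the median at low counts — and
are rescaled to geometric mean 1.

Each testable peak (default filters: primary feature UTR3 or exon,
optionally not A-rich, detected in >= 10% of cells of at least one
population, gene with >= 2 surviving peaks) is tested with a two-bin
NB GLM on (peak count, rest-of-gene count) per pseudo-bulk column:
log link, offsets log(size factor), design `sample + bin +
population:bin`. Dispersion is a per-peak Cox–Reid adjusted
profile-likelihood estimate on the full model (floored at 1e-6;
a gene-wise moment estimate is used below 4 total replicates). The
interaction is tested with a 1-df likelihood-ratio statistic referred
to **F(1, residual df)** rather than chi-squared: with 24 observations,
14 parameters and a dispersion estimated from the same data, the
chi-squared reference is anticonservative (measured pooled null
rejection 0.079 at alpha = 0.05 over 2000 simulated null genes), while
the F reference — the quasi-likelihood small-sample rationale — gives
0.048 at alpha = 0.05 and 0.010 at alpha = 0.01 with uniform p-values.
`usage_LFC` is the interaction coefficient / ln 2; a model-free
proportion-ratio diagnostic (`usage_LFC_simple`, pseudo-count 1) is
emitted alongside. BH adjustment runs over tested peaks; defaults for
calling a DU peak are p_adj < 0.01 and |usage_LFC| > 0.5, and a DTU
gene has >= 1 DU peak.

## 3'UTR shortening and relative expression

DU 3'UTR peaks (from a run restricted to UTR3 with A-rich exclusion)
are placed on the longest transcript 3'UTR that overlaps them (tie
rule for overlapping transcript UTRs); all tested peaks on the same
UTR are ordered by strand-aware midpoint distance from the terminating
exon and scored i/(k-1) (single peak: 0). Up- vs downregulated score
distributions are compared with a two-sided Wilcoxon rank-sum test
(normal approximation, tie-corrected); "shortening" is reported when
upregulated peaks are more proximal and p < 0.05.

Relative expression per cluster c: G is the grand mean of the gene's
peaks × cells block, P_i = mean_j(x_ij)/G, and
R_ij = log2(x_ij/(G+v)·P_i + 1) with pseudo-count v = 1. x is expected
on the log-normalised counts-per-ten-thousand scale (a helper is
provided); a cluster with G = 0 returns R = 0 (the division-by-v
alternative would render an unexpressed cluster non-null).

## Synthetic fixtures: what they emulate, and what they do not

Each synthetic gene is a two-exon transcript (600-bp 5' exon, 2-kb
intron, terminal exon with a 3'UTR sized to its peak count). Molecules
pick a polyA site by per-population usage proportions; the cleavage
position is Normal(site, sigma); a 91-nt read (10x v3-like) is placed
ending at the cleavage position in transcription direction, spliced
across the intron when it crosses the junction. Junction evidence
comes from a "bridge" polyA-like site 50 nt before the 5' exon's end
whose reads partially splice — a uniform junction-read band was
rejected at design time because any retained junction's boundary
coverage clump necessarily exceeds the height-stopping thresholds and
would force spurious calls. Intronic decoys model internal priming:
reads are unspliced pre-mRNA fragments and the genome carries an
A-homopolymer downstream. Truth tables record, per site, the cleavage
position, the expected coverage apex (cleavage shifted upstream by
(read length - 1)/2), sigma, usage and read-class share; AATAAA and
A-rich signals are embedded downstream of the *expected called
interval end* (apex + 3·sigma_eff with the read-length boxcar folded
into sigma_eff), where the annotation scan of a called peak will look.

Defaults: the smoke scenario has 6 genes, 2 populations × 300 cells,
~60 UMIs/cell across the fixture's genes (so a few thousand reads per
gene — the depth regime where all thresholds are active), one gene
switching usage 0.8/0.2 → 0.2/0.8 and one intronic decoy. The deep
peak-recovery benchmark uses 20 genes × 2–4 sites, sigma 60–150,
50,000 reads per gene; 2-peak genes draw sigma from [100, 150] and
multi-peak genes use fixed usage patterns with shares in [0.2, 0.4],
keeping the junction filter threshold (5% of the maximum coverage)
below the bridge support — the regime choice is part of the fixture
design and is stated here rather than tuned. DU calibration and power
are simulated directly at the pseudo-bulk level (NB counts, dispersion
0.05, 400 expected UMIs per gene per replicate, 6+6 replicates).

Not emulated: sequencing errors, barcode collisions/correction,
ambient RNA, multimapping, overlapping genes, antisense reads, or
non-Gaussian cleavage heterogeneity. Passing tests therefore certify
the algorithmic contracts (splice-aware decomposition, dedup
semantics, statistical calibration under the stated count model), not
robustness to every artefact of real libraries.

## Numerical and reproducibility notes

- Coordinates are 1-based inclusive internally (GTF convention);
  BED/bedGraph output is 0-based half-open; MatrixMarket is 1-based.
- All simulation randomness flows from one integer seed through
  `numpy.random.default_rng([seed, fixed offset, ...])` sub-streams;
  per-gene and per-population streams make outputs independent of
  iteration order. Pseudo-bulk assignment records its seed.
- Greedy tie-breaks (merging candidates, shorth interval, argmax
  apexes) are leftmost/coordinate-sorted for determinism.
- Known limitations: the AND-form stopping rules let sub-threshold
  coverage bumps between the two floors be fitted in shallow genes
  (visible as small extra "exon" peaks in the smoke fixture); greedy
  one-to-one matching does not resolve the one-peak-contains-two case
  beyond best-score-first; the usage LFC is a model coefficient and is
  not numerically identical to other tools' fold-change transforms.
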