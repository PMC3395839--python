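# Methods

## Measurement model (synthetic data)

The simulator emulates a genome-wide BAC array of 2,464 clones printed in
triplicate, hybridized male-test vs. female-reference. Clones are laid out
deterministically: allocated to 22 autosomes + X (+ Y) proportionally to
built-in approximate chromosome lengths (largest-remainder rounding, at
least one clone per chromosome) and placed at evenly spaced midpoints with
a nominal 150 kb insert. Only relative positions matter for segmentation,
so no specific genome build is implied and real BAC coordinates are not
reproduced.

The noise-free log2 ratio of a clone follows a purity mixture: with tumor
fraction φ_t, tumor copy number c, contaminating-normal copy number g and
reference copy number r,

    mix = φ_t·c + (1 − φ_t)·g,    log2 ratio = log2(max(mix, f) / max(r, f)).

g and r are 2 on autosomes; on X they are 1 for a male and 2 for a female
carrier, which makes −1 the neutral male-vs-female baseline and produces
the dampened dynamic range of contaminated samples (|log2| shrinks
monotonically to 0, or to the sex baseline on X, as φ_t → 0). The floor
f (`floor_copies`, default 0.05) stands in for the array's dynamic-range
floor so a homozygous deletion in a pure sample maps to a deep finite
ratio rather than −∞.

Measured spots add, per clone, a shared offset ~N(0, σ_clone²) (probe-
specific bias, default 0.08) and per-spot noise ~N(0, σ_spot²) (default
0.05); each spot is independently hit with probability 0.01 by an extra
N(0, 1) outlier deviation, sized so that an affected triplicate usually
exceeds the SD > 0.2 QC cutoff. The platform's real noise magnitudes are
not published; these defaults produce clone-mean SDs (~0.06) that make the
±0.2 call thresholds comfortably separable at full purity, which matches
the qualitative behaviour the assay reports. Truth presets (`vcap_like`,
`pc3_like`, `lncap_like`, `patient9_like`, `normal_male_leukocyte`) encode
the well-known landscapes of the named prostate lines — 8p loss/8q gain,
PTEN-region 10q loss, 11q13 focal amplification, and a high-level X gain
over the AR region — at fixed, documented intervals; all are male vs.
female reference with tumor fraction 1 by default.

What the simulator does **not** model: whole-genome-amplification bias and
locus dropout, two-color intensity physics (log2 ratios are generated
directly), GC waves, and real clone coordinates. Passing tests therefore
demonstrate correctness of the analysis pipeline under idealized Gaussian
noise, not performance on real hybridizations.

## Replicate summarization and QC

Per clone: arithmetic mean and sample SD (n−1 denominator; "standard
deviation" is taken in its conventional triplicate-QC sense) of the spot
log2 ratios. Clones with SD strictly greater than 0.2 are flagged as
QC-failed — flagged rather than deleted, so concordance can intersect
QC-passing clones across samples — and all downstream stages skip them.
The SD = 0.2 boundary case is retained. Chromosome Y is dropped before
analysis. QC runs before segmentation (whether the original pipeline
filtered before or after segmentation is not documented; filtering first
keeps the segmentation input well defined).

## Segmentation

Circular binary segmentation on within-window ranks. For a window of m
clone means the procedure:

1. replaces the window by its average ranks mapped through van der Waerden
   normal scores Φ⁻¹(rank/(m+1));
2. finds the circular arc (i, j), 1 ≤ i < j ≤ m (gap m coincides with gap
   0, so each arc/complement split is enumerated exactly once), maximizing
   the pooled two-sample |t| between arc members and non-members, computed
   incrementally from prefix sums (O(m²) per scan); ties break to the
   lexicographically smallest pair;
3. accepts the split if a permutation test on the scored window gives
   p = (1 + #{T* ≥ T_obs}) / (B + 1) ≤ α, with B = 1000 shuffles and
   α = 0.01 by default (the add-one convention keeps p > 0; the loop stops
   early once non-significance is certain, which cannot change the
   decision); both boundaries of an interior arc become breakpoints, and
   the procedure recurses on each piece of width ≥ 2·min_width;
4. afterwards merges adjacent segments whose means (always computed on the
   original, unranked log2 scale) differ by less than `merge_tol`
   (default 0.05).

Splits producing any piece narrower than `min_width` (default 2 clones)
are rejected; a window shorter than 2·min_width is returned as one
segment. Segment means are reported on the original scale.

Design choices made where the method's published description is silent:

- **Rank scores.** Ranks are recomputed within each recursion window (the
  alternative — ranking each chromosome once — was evaluated and is less
  sensitive). Plain linear ranks cap the arc statistic of a short
  high-amplitude arc near the permutation null's upper quantiles; the
  normal-score map, a strictly increasing function of the ranks, restores
  leverage for extremes while keeping every decision a function of the
  data's ranks only. Split boundaries are therefore invariant under any
  strictly increasing transform of the input (a tested property).
- **Statistic.** Pooled two-sample t with m − 2 degrees of freedom. A zero
  pooled variance with distinct group means (a perfectly sharp step, e.g.
  noise-free data) yields T = +∞, which the permutation comparison handles
  naturally.
- **Known power limit.** A short intermediate-level segment (≈4 clones at
  copy-neutral level between two large opposite aberrations, window ≈38
  clones) has an essentially fixed rank pattern whose max-arc statistic
  sits at the null's ~q99: its permutation p is ≈0.015, so at α = 0.01 it
  is detected only ≈30% of the time. The same geometry is recovered 100%
  of the time on the unranked scale (`use_ranks=False`). This is the
  inherent price of rank robustness, not an implementation artifact;
  large aberrations and 6-clone focal amplifications are detected
  reliably (measured 10/10 seeds at σ_spot = σ_clone = 0.05).

## Copy-number calling

Five states by strict thresholds on the segment mean: > 0.6 HIGH_GAIN,
> 0.2 GAIN, < −0.6 HOMOZYGOUS_LOSS, < −0.2 LOSS, else NEUTRAL. Values
exactly at a threshold do not cross it. On chromosome X the baseline
log2(test X copies / reference X copies) (−1 for male vs. female) is
subtracted before thresholding — algebraically identical to shifting all
four thresholds by the baseline, which is how the original software
phrases its automatic X adjustment — so a normal male X reads NEUTRAL and
only deviations from the expected sex ratio are reported. Note that at
tumor fraction 1 a single-copy autosomal loss sits at exactly −1 and is
therefore classified beyond the −0.6 cutoff; the thresholds presuppose
some admixture and are reported as printed, not reinterpreted.

Locus queries (e.g. AR) return the overlapping segment's state; a query
spanning several segments returns the most extreme state (high-level
beats single-level beats neutral, |adjusted mean| breaking gain-vs-loss
ties), matching the single-call-per-sample reporting of locus-level
results.

## Cohort recurrence

Each design clone inherits the state of the segment it belongs to, per
sample; clones excluded by QC in a sample are missing for that sample, and
frequencies are computed over non-missing samples only (how the original
analysis handled per-sample QC gaps is not documented). Gain frequency
counts GAIN and HIGH_GAIN together (likewise losses). Recurrent regions
are maximal runs of consecutive clones with frequency strictly above the
threshold (default 0.5, i.e. present in > 50% of samples — 5 of 9
qualifies, exactly half does not), reported at clone resolution; cytoband
labelling is out of scope.

## Profile concordance

The weighted Pearson correlation is computed on clone-level means of the
shared autosomal, QC-passing-in-both clones. Weights follow the published
formula: with x̃, ỹ the medians over all n shared clones,
w_i = ½·[median_{j∈{i,i+1}}|x_j − x̃| + median_{j∈{i,i+1}}|y_j − ỹ|] for
i = 1..n−1; the median of two numbers is their midpoint. The weighted
covariances use the Σw normalizer (no small-sample correction is
specified) and run over observations 1..n−1, since the published index
leaves clone n without a weight. All-zero weights (two flat profiles) or a
zero weighted variance make r_w undefined: the result is flagged
degenerate rather than silently substituting uniform weights. r_w ∈ [0.8, 1]
is "highly", [0.6, 0.8) "moderately", [0.4, 0.6) "fairly", [0.2, 0.4)
"lowly", [0, 0.2) "un-" correlated; negative values get the distinct label
"anticorrelated" rather than being folded into the lowest bin.

## Numerical and interface conventions

- Clone tables are 1-based inclusive; BED outputs (segments, calls,
  recurrent regions) are 0-based half-open.
- Profile TSVs print 6 decimal places; round-tripping preserves values to
  that precision.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); segmentation derives one independent
  substream per chromosome from (seed, chromosome rank), so results do not
  depend on which other chromosomes are present.
- Simulations in the test suite and acceptance script use the default
  2,464-clone array, ten replicate seeds for the noisy-recovery benchmark,
  200 random windows for the exhaustive-oracle comparison and 100 random
  pairs for the weighted-correlation oracle.

## Known limitations

- No GC-wave correction, multi-sample joint segmentation, allele-specific
  analysis, or integer-copy-number estimation from log2 ratios.
- The rank-CBS power limit for very short intermediate-level segments
  described above.
- The AR locus interval is supplied by the caller (a default region is
  exported); the exact interval used in the original analyses is not
  published.
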