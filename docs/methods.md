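# Methods

This note documents the models and procedures implemented in `isvbalance`,
their assumptions, the defaults that matter, and what the synthetic-data
generators do and do not emulate.

## Vessel sequence statistics (`pattern_stats`)

The substrate is an ordered sequence of binary vessel labels (arterial
`A` / venous `V`, or Notch-reporter `tp1+` / `tp1-`) at 1-based somite
positions on the left and right flanks of each embryo's scored trunk
segment (10 somites by default). Flanks are independent sequences with no
wrap-around.

**Global balance** is the pooled fraction of positive-labelled vessels,
with per-embryo fractions (mean ± s.e.m.) alongside, and tag filters for
mosaic analyses (all / NICD-clamped / wild-type vessels).

**Ipsilateral neighbourhood analysis**: for a set of offsets (default
{−1, +1}; variants {+1} and {−2, −1, +1, +2} for right-neighbour and
radius-2 analyses), a vessel is eligible iff *every* offset position lies
inside its flank. The condition is the number of positive labels among the
offset positions; the table reports, per condition, the eligible count and
the conditional probability of the centre vessel being positive. Boundary
vessels are excluded from eligibility — with two-sided unit offsets a
10-vessel flank contributes 8 eligible vessels, which is what makes the
bookkeeping arithmetic (74 embryos × 2 × 8 = 1184) come out. Conditions
realised by no vessel are reported with an undefined (`NA`) probability,
never as zero. **Contralateral analysis** conditions on the label of the
same-position vessel on the opposing flank; every vessel is eligible.

**Uncertainty** is quantified by a percentile bootstrap that resamples
*embryos* with replacement — the embryo is the independent experimental
unit; vessels within an embryo are correlated by the patterning process,
so vessel-level resampling would understate the variance.

## Polarity and migration (`track_analysis`)

Golgi–nucleus offsets are expressed in the local ISV frame (first
component along the vessel axis, pointing dorsally). The polarity class is
set by the angle θ between the offset and the dorsal direction:
dorsal if θ < 90° − b, ventral if θ > 90° + b, unpolarised otherwise. The
band half-width b defaults to 30°, which partitions directions into three
equal 120° sectors; it is a free parameter because the original scoring
("Golgi parallel to the nucleus") is qualitative. A zero offset is
unpolarised by convention. Classification depends only on the offset in
the local frame, so it is invariant under joint rotations of frame and
offset.

Polarity summaries score one call per cell per timepoint and sum over
timepoints within each (fate, phase) group, matching the manual scoring
workflow in which all timepoint scores are added. This weighs cells with
more timepoints more heavily; `per_cell=True` instead makes a single call
per cell per phase from its mean offset vector.

Upward speed of a cell within a remodelling phase (I: before
secondary-sprout connection, II: during the three-way connection, III:
after resolution) is the net change of nucleus distance-from-aorta divided
by the elapsed time between the first and last in-phase samples, computed
in µm/min and reported ×1440 as µm/day. Positive speeds point away from
the aorta (toward the DLAV); reflecting a trajectory negates its speed.
Group summaries are mean ± s.e.m. over cells. Phase-window lengths around
connection/resolution differ between published polarity (2.5 h) and speed
(1 h) analyses; here the phase intervals are part of the track data, so
any windowing convention can be expressed upstream.

Categorical annotation summaries (`summarize_fraction`) pool
numerator/denominator counts by default (percentage = 100·Σnum/Σden) and
optionally aggregate per embryo first (mean ± s.e.m. of embryo
percentages), the form used for regression-behaviour quantifications.
Percentages can be rounded to the display precision of the corresponding
published figure (one decimal for the perfusion counts, integer for the
polarity and lumenisation counts); raw fractions are always retained.

## Velocimetry and heart rate (`flow_quant`)

Frame-to-frame displacement is estimated by phase correlation: the
cross-power spectrum F(a)·conj(F(b)) is magnitude-normalized and
inverse-transformed; the correlation-map peak sits at minus the
displacement of `b` relative to `a` (modulo the frame size). The map is
smoothed with a Gaussian (σ = 1 px default) before the integer argmax;
optional 3-point parabolic interpolation refines to sub-pixel (off by
default). Offsets are unwrapped to the centred range [−dim/2, dim/2),
assuming the dominant motion is below half the crop — the intended input
is a crop of the dorsal aorta. Normalization makes the estimate invariant
to global intensity scaling. Numerical caveats: a constant frame has an
undefined normalized spectrum and raises; on frames with *even* dimensions
a shift of exactly ±dim/2 is inherently sign-ambiguous (the two values
coincide modulo the frame), so exactness properties are stated for
|shift| ≤ dim/4 and antisymmetry is exact on odd-sized frames.

Speed per frame pair is |displacement| × pixel size / frame interval. The
magnitude trace (not the components) is smoothed with a centred moving
average of span 5; at the trace ends the window shrinks symmetrically
(5 → 3 → 1), keeping output length equal to input and leaving interior
values the plain 5-frame mean.

Kymographs sample intensity along a line at unit steps (nearest pixel;
width-1 default); wider lines average over perpendicular unit offsets, so
a width-w kymograph equals the mean of w width-1 kymographs.

Heart rate: the trace (or the spatial mean of a kymograph) is screened
for periodicity via its autocorrelation — the lag-0 main lobe is skipped
by walking to the first local minimum and the dominant period is the
argmax beyond it; a monotonically decaying autocorrelation raises "no
beats detected". The trace is then lightly smoothed (Gaussian, σ = 5% of
the period) and beats are local maxima above mean + k·SD (k = 1) separated
by at least 40% of the period. Beats are counted over a window (default
8 s) starting at the first detected beat; the window is truncated at the
trace end, which for a periodic signal does not change the count. Rate =
beats / window × 60.

## The dual-mechanism simulator (`balance_model`)

The model formalises, with minimal functional forms, a verbal mechanism:
primary ISVs are pre-specified ~60% arterial by heterogeneous Notch
activity patterned by lateral inhibition, and blood flow subsequently
fine-tunes the cohort to a 50:50 balance by re-specifying the most
plastic arteries as veins.

**Pre-pattern.** Per flank, Notch levels follow a stationary AR(1)
process with coefficient −λ (default λ = 0.4, σ = 0.3, µ = 1): each
vessel's level is pushed away from its predecessor's, producing
neighbour anticorrelation r = −λ — the alternating tp1-reporter pattern.
The first vessel is drawn from the stationary distribution
N(µ, σ²/(1−λ²)), so the marginal level distribution is identical at every
position and every λ; the arterial threshold is its 40th percentile,
making the pre-arterial fraction exactly 0.6 in expectation regardless of
λ. Levels above the 90th percentile (`high_notch_quantile = 0.1`) are
classed "high" (tp1-high analogue); positives above threshold, negatives
below. NICD mosaic overexpression clamps a random fraction of vessels
arterial irrespective of level.

**Resolution.** Each vessel forms a transient three-way connection with
probability 0.775 (the observed lower bound for future aISVs; treated as
the common rate for both fates since nearly all secondary sprouts engage).
With flow on, while the cohort's arterial fraction f exceeds the target
f* = 0.5, the Δ = ⌈(f − f*)·n⌉ lowest-Notch eligible vessels (connected,
unclamped, still arterial) each flip to venous with probability
g·(f − f*) per iteration (gain g = 2). Restricting each iteration's
candidates to the current deficit concentrates flips at the bottom of the
Notch distribution — high-Notch vessels are effectively never recruited
under default conditions, matching the observed insensitivity of tp1-high
vessels to flow — and prevents overshoot below the target. Flips are
one-directional (A→V): whether artery-deficient cohorts could recruit
V→A flips is untested in vivo and disabled here. Iteration stops when the
arterial excess is below `tolerance` (0.005, i.e. half a percent of the
cohort) or after `max_iterations` (500); non-convergence is flagged on
the result, not raised. With flow off (tricaine) no flips occur and final
identities equal the pre-pattern exactly, per vessel.

Compensation acts on the pooled cohort fraction rather than per embryo.
A per-embryo variant (each embryo balancing its own 20 vessels) is the
more literal biology but interacts badly with one-directional flips:
embryos pre-patterned below 50% arterial cannot be pulled up, biasing the
cohort mean below the target. The cohort-level rule reproduces the
population endpoints (50:50 with flow, 60:40 without, scalable mosaic
compensation) with one mechanism; an explicit per-embryo hemodynamic
network is out of scope.

Scenarios wire the simulator into the sequence analyses: `wild_type`,
`tricaine` (flow off), `nicd_mosaic` (clamp 30%), `nicd_mosaic_tricaine`.
Clamping randomises vessel identity with respect to position, so the
mosaic scenario flattens the ipsilateral conditional-probability profile
while flow keeps the global fraction at 0.5 — with the venous burden
shifted onto unclamped vessels.

## Synthetic data (`synthetic_data`)

The generators supply every input modality with known ground truth.

- **Sequences**: a two-state Markov chain per flank whose next-label draw
  mixes an independent Bernoulli(p_artery) with strict alternation
  (weight = `alternation`); the right flank additionally copies (or
  inverts, for negative coupling) the left flank's same-position label
  with probability |`contralateral_coupling`|. Defaults (p = 0.5,
  alternation 0, coupling 0) give the iid null used by the oracle tests;
  the alternation parameter spans the observed ipsilateral patterning.
  With p ≠ 0.5 the alternation mixing pulls the marginal toward 0.5.
- **Tracks**: nucleus distance evolves piecewise linearly at the
  fate/phase mean speed plus iid Gaussian position noise (σ = 0.5 µm);
  default speeds (vISV: +150/+200/+100 µm/day in phases I/II/III; aISV:
  −30/−50/−30) and polarity class probabilities (aISV phase III 60%
  ventral; vISV phase III 52% dorsal; same-signed but weaker biases in
  phase I) are set to the reported phase-III percentages and the
  qualitative early-heterogeneity findings. Phase durations default to
  150/180/150 min within the 32–54 hpf remodelling window. Golgi offsets
  are drawn uniformly within each class's angular sector, 5° clear of the
  default band edges so classification recovers the drawn class exactly.
- **Flow movies**: Gaussian particles (σ = 1.5 px) advected along +x by a
  constant, sinusoidal-pulsatile or callable velocity profile; per-pair
  ground-truth displacement is the exact integral of the profile over the
  frame interval divided by the pixel size. Periodic wrapping (default)
  makes an integer per-frame shift an exact circular translation, the
  construction oracle for phase correlation; an aperiodic mode exists for
  robustness testing. Defaults (64² px, 0.5 µm/px, 10 ms interval,
  150 µm/s) put dorsal-aorta-like speeds at 3 px/frame.
- **Heartbeat traces**: unit-amplitude Gaussian pulse trains (width 10%
  of the period) with the first beat at half a period, so every beat peak
  is an interior sample; additive Gaussian noise.

All randomness flows from one seeded generator per call; per-embryo and
per-track sub-streams are spawned deterministically, so outputs are
bit-identical under a fixed seed.

**What the generators do not emulate**: photorealistic microscopy (no
point-spread function, photobleaching, drift or segmentation error),
3-D geometry, cell division or rearrangement within ISVs, aperiodic
heart-rate variability, and any coupling between the track generator and
the sequence/balance models. Passing the recovery tests therefore shows
that the estimators are correct on data matching their stated assumptions,
not that they are robust to every artefact of real movies.

## Problem sizes and numerical choices

Statistical tests and the acceptance script use cohorts chosen so that
sampling error is well below the tolerances being checked: 10⁴ flanks for
iid conditional-probability flatness (3 binomial SE ≈ 0.02), 1000 embryos
(20 000 vessels) for simulator endpoints (3 SE ≈ 0.01), 100 seeds for the
noisy heart-rate mean, 60 cells per (fate, phase) group for speed
recovery, and exhaustive enumeration of all binary sequences up to length
12 against a brute-force recount. Bootstrap coverage is checked with 100
simulation replicates of 25 embryos at 199 resamples.

Tie-breaking and degenerate inputs: argmax ties in the correlation map
are resolved by first occurrence (measure-zero for noisy images);
ties in the Notch flip order are broken by an RNG jitter; empty
neighbourhood conditions are `NA`; a zero Golgi offset is unpolarised; a
constant frame, a flat trace, an unpaired flank, or an empty selection
raise informative errors.

## Known limitations

- The flip rule and the lateral-inhibition draw are minimal forms chosen
  to reproduce the stated endpoints; the data do not constrain their
  functional shape, and alternatives (e.g. explicit hemodynamic feedback)
  are isolated behind `ModelParams` for substitution.
- Phase-correlation accuracy degrades for non-integer shifts without
  sub-pixel refinement and for motion above a quarter of the crop.
- The heart-rate extractor assumes a single dominant periodicity; traces
  with strong harmonics of comparable power may lock onto the wrong peak
  spacing, though the 40%-of-period minimum distance guards the common
  cases.
- Real scored cohorts can have ragged flank lengths (embryos scored over
  fewer somites); the sequence container supports this, but the
  generators always produce full-length flanks.
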