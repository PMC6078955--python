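# Methods

This note documents the models, conventions and numerical choices behind
`barreltree`, and what the synthetic generators do and do not emulate.

## Coordinate and unit conventions

All morphology is in µm. The tangential (imaging) plane is x–y and depth
is z. Angles are degrees, measured from the soma with 0° toward the
home-barrel center, counter-clockwise positive, in (−180°, 180°]. Time is
counted in imaging *frames*: one frame is the 8-h interval between
consecutive sessions of the default schedule P3_L, P4_E, P4_M, P4_L,
P5_E, P5_M, P5_L, P6_L; the longer final interval (P5_L→P6_L) counts as
one frame, since all downstream statistics are frame-based.

## Morphometry

**Segments and the 5 µm rule.** A dendritic segment is a maximal polyline
between branch points, or between a branch point and a tip. Terminal
processes of arc length ≤ 5 µm are twigs, not segments: they are pruned
iteratively (a branch point whose twigs vanish dissolves, merging its
flanking paths), they do not count toward segment or tip numbers, but
their length still contributes to total tree length. Consequence for the
OBI: the index is a ratio of *segment* lengths, so its numerator and
denominator sum over retained segments; they equal total BD length
exactly only when no twigs exist. The invariant asserted in tests is
inner + outer = total retained segment length.

**Inside/outside boundary.** The boundary is the line through the soma
center (projected to x–y) perpendicular to the unit vector from the soma
to the home-barrel center; "inside" is the half-plane containing the
barrel center. A soma exactly at the barrel center has no defined
direction and raises an error (such neurons are barrel-center cells, for
which the OBI is not meaningful). Segment side is assigned by the
majority of the segment's arc length, with ties going inside; arc length
is 3-D by default with a 2-D side test (`projected=True` switches to
fully 2-D lengths — the choice moves the OBI only at the third decimal
for realistic tortuosity).

**Edge rule.** Somata whose planar distance to the home-barrel boundary
is ≤ 12.5 µm (inclusive) are barrel-edge; inside and farther than
12.5 µm, barrel-center; anything else is outside the field. Depth is
ignored.

**AD groups.** A trajectory of per-session apical-dendrite lengths is
Group 1 (retracting; prospective spiny stellate) if the first-session
length is exactly 0 or the final length falls more than δ below the
running maximum; otherwise Group 2 (continuously extending; star
pyramid). δ defaults to 10 µm to absorb tracing jitter and is
configurable; the classification is invariant to session relabeling.

## Session registration and identity tracking

Rotation-only least squares on matched soma coordinates: with both point
sets centered, θ = atan2(Σ a′×b′, Σ a′·b′). Translation is handled by
centroid subtraction; no scaling or shear is fitted, and slow brain
growth is absorbed by the matching tolerances instead. Neurons are
matched mutual-nearest within 30 µm; tree origins, expressed relative to
the soma center, are matched mutual-nearest within 5 µm of 3-D distance
(origins live on the soma surface, so the relevant notion of "same
position" is three-dimensional). Greedy matching takes the globally
closest pair first, with distance ties broken by the smaller identifier,
making results deterministic.

Identities are chained into a presence matrix (tree × session with
present/absent/unknown cells). By default a track survives one unknown
session (image not acquired) when origins match across the gap; a track
unmatched at an *observed* session is eliminated and never resurrected.
Gap bridging is a documented convention, not an observed fact, and can be
disabled (`bridge_gaps=False`). Lifetimes count present cells, so a
bridged unknown session does not add a frame.

## Survival analysis

One record per tree newly formed inside the analysis window: birth
requires an observed absent cell at the previous session (pre-existing
trees and post-gap first sightings are excluded); lifetime counts present
sessions; trees still present at the final session are right-censored. A
death time masked by an unknown cell is resolved as death at the first
definite absence and flagged interval-censored.

Kaplan–Meier estimation and the log-rank test are delegated to
`lifelines` (product-limit estimator, Greenwood variance, exponential
log(−log) confidence bands; log-rank as (O−E)²/V with 1 df). The test
suite checks both against a from-scratch event-table implementation —
empirical survival products and explicit hypergeometric O/E/V
accumulation — on a thousand random small cohorts, to machine precision.

The one-frame elimination fraction is (#uncensored records with
lifetime ≤ 1)/n over the side's newly formed trees; restricting the birth
window so that every birth has an observed next session makes this an
unbiased estimator of the one-frame elimination probability.

## Calcium-imaging analysis

F0 is the per-pixel mean over quiescent frames — supplied explicitly, or
auto-selected as the lowest-field-mean 20% of usable frames (at least
50). Motion-excluded frames are dropped before every computation.
ΔF/F = (F−F0)/F0. Zone detection smooths each frame with a Gaussian
(σ = 10 px), thresholds strictly at ΔF/F > 1.0, labels 8-connected
components, discards zones below 2500 µm² (a zone of exactly 2500 µm² is
retained) and traces boundaries by marching squares. By default the *raw*
movie is smoothed before ΔF/F is formed; the alternative order (smooth
the ΔF/F image) is exposed via `smooth_raw_first=False` and differs
negligibly for smooth baselines.

ROI analysis uses a centered 5×8 grid of 20 µm-diameter circular ROIs at
50 µm spacing; each trace is the mean ΔF/F over the disk. Rasters
threshold strictly at ΔF/F > 0.5. Correlation matrices are Pearson over
all ROI pairs; zero-variance traces get NaN rows/columns and are excluded
from ordering. The display order is the ascending first-principal-
component score of the (centered) correlation-matrix rows, with the PC
sign fixed by making the first ROI's score non-negative; no manual
rearrangement is applied.

## Statistics

Two-sided throughout. Welch's t uses the Welch–Satterthwaite df; the
Brunner–Munzel test uses the t-approximation; Wilcoxon signed-rank is
exact for n ≤ 25 and normal-approximated above. The variance-ratio F test
puts the larger variance in the numerator, doubles the upper tail, and is
symmetric in its arguments; it accepts raw samples or summary SDs with
group sizes. Hedges' g applies the small-sample correction
J = 1 − 3/(4N−9). The non-parametric effect size is r = |z|/√n; published
analyses in this area sometimes report r values above 1, which that
formula cannot produce, so the quantity reported here should not be
compared numerically against such values. Holm's correction is the
step-down procedure with running-maximum monotonicity enforcement.

## Synthetic data generators

**What they emulate.** The longitudinal generator draws, per neuron, a
class (barrel-edge SS, barrel-center SS, nerve-cut SS, or barrel-edge
star pyramid; default mix 50/26/0/24%), a soma position consistent with
the class (edge classes 6–10 µm inside the boundary, center classes
8–18 µm off-center), initial trees with lengths Normal(65, 36) µm
truncated above 5 µm, and then per 8-h frame: Poisson tree births per
side, one-frame elimination of newborns (defaults 0.31 inner / 0.82
outer for edge SS), a smaller per-frame hazard afterwards (and a still
smaller hazard for trees already present at the first session, which are
treated as established), and linear growth of survivors with
multiplicative noise. Apical dendrites either retract at ~40 µm/frame
from a uniformly drawn onset (Group 1; 3% of Group 1 neurons lack an AD
entirely) or extend at 15 µm/frame (Group 2). Arbors are emitted as
tortuous 3-D polylines with one branch tip per ~26 µm of length (every
segment > 5 µm so the twig rule never bites on generated data), and
origins are fixed on the soma sphere for life.

Two generator conventions exist purely to keep identity tracking
well-posed, mirroring what a human tracer enforces implicitly: newborn
origins keep > 5.5 µm (3-D) clearance from origins vacated within the
last two frames (otherwise a newborn would be indistinguishable from the
dead tree), and ≥ 2 µm from live origins.

Growth slopes (30 µm/frame for edge-SS inner trees, 5 outer; ~20 for
center classes) and the per-length tip rule were set so that the default
cohort's first-to-last-session fold changes center on 3.0× (total BD
length) and 2.7× (tip count), the reported magnitudes of early postnatal
BD growth; the side-specific hazards make inner survival curves dominate
outer ones. Birth rates derive from the reported counts of newly formed
trees (≈16 inner and 22 outer per 8 edge neurons over 6 frames).

The calcium generator produces 15-min, 1-Hz, 256×256 movies at 2 µm/px
over a 2×2 grid of 150 µm barrels with 30 µm septa. Control events light
up exactly one barrel interior (soft-edged plateau, peak ΔF/F ≈ 2);
nerve-cut events have random centers and wobbly elliptical extents of at
least 2.5 barrel diameters. Events rise in one frame and decay
exponentially (τ = 1.5 s); Gaussian noise (SD 2% of baseline) rides on a
flat baseline; the first 60 frames are guaranteed event-free so an F0
always exists.

**What they do not emulate.** Real tracing errors (broken branches,
missed thin processes), optics and PSF, depth attenuation, neuropil
contamination, brain growth between sessions (somata are static),
non-rigid deformation, correlated event timing across barrels, and
inter-animal variability. Passing tests on generated data therefore
demonstrate the correctness and calibration of the *pipeline*, not the
robustness of the measurements to those real-world nuisances.

## Numerical choices and degenerate inputs

- Ties: segments exactly half inside go inside; tree origins exactly on
  the boundary are inner; matching distance ties break on the smaller id.
- Zero BD length → the OBI raises rather than returning NaN; zero
  variance traces/differences likewise raise in the statistics module.
- `fold_change` is a ratio of means (per-neuron ratios are also
  returned); a zero first-session mean is an error.
- All generators accept either an integer seed or a numpy `Generator`;
  identical seed and config give bit-identical output.
- Problem sizes in the test suite (cohorts of 12–200 neurons, movies of
  80–900 frames, 1000-instance oracle sweeps) were chosen as the smallest
  sizes at which the checked quantities are statistically stable.

## Known limitations

- The inside/outside boundary is a straight line through the soma; real
  barrel walls curve, so the OBI of neurons on strongly curved barrel
  edges is approximated.
- Interval-censored lifetimes are resolved conservatively (death at first
  definite absence) instead of being modeled.
- The log-rank comparison assumes independent tree lifetimes; trees of
  one neuron share a cell, so p-values on real data understate
  within-cell correlation.
- PCA ordering of correlation matrices is a visualization aid; block
  recovery is only guaranteed for well-separated synchrony structure.
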