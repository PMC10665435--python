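# Methods

## The measurement model

A kinase translocation reporter makes Erk1/2 activity visible as
redistribution of a fluorescent substrate between nucleus and cytoplasm:
phosphorylation by active Erk1/2 drives nuclear export, so the ratio of
mean reporter intensity in a cytoplasmic region to that in the nucleus
(C/N) rises with kinase activity. The pipeline quantifies C/N per cell
and frame from a two-channel movie (channel 0: nuclear dye; channel 1:
reporter), normalizes each trace to the single frame just prior to
stimulation, and summarizes each cell by the parameters of a piecewise
exponential response model.

Two model variants are fitted, both equal to 1 up to an onset delay
`t_on` (s) and rising toward an equilibrium ratio `R_eq` with rate `k_on`
(1/s). The *monotone* variant holds that plateau; the *recovery* variant
switches at `t_off` (s) to an exponential return toward baseline with
rate `k_off` (1/s). Continuity at `t_off` is structural — the third piece
starts from the middle piece's value `r(t_off)`, which is never a free
parameter. The recovery variant describes cells whose response is
transient (in the motivating biology, senescent "old" fibroblasts whose
nuclear Erk1/2 signalling is not sustained).

Time is measured in seconds with t = 0 at the stimulation event: frame k
(0-based) has time `(k − stimulation_frame) · frame_interval_s`.
Pre-stimulation samples are included in the fit; they constrain r = 1.

## Synthetic data: what it emulates, and what it does not

No raw movies are available for the motivating study, so a generator
(`ktr.simulate`) produces ground-truthed movies with the statistical
structure the analysis assumes:

- **Schedule.** One frame every 15 s for 30 min after stimulation
  (defaults `frame_interval_s = 15`, `duration_s = 1800`, giving 121
  post-stimulation frames), plus `n_prestim_frames = 4` pre-stimulation
  frames. The number of pre-stimulation frames is not specified by the
  motivating acquisition; at least one is required for normalization and
  four gives a visible baseline. At `pixel_size_um = 0.22`, the 5-px
  measurement ring spans ~1.1 µm.
- **Population archetypes.** Cells are drawn from young / mid-old / old
  archetypes; young and mid-old respond with the monotone model, old with
  the recovery model. The per-archetype parameter ranges (uniform draws)
  were chosen once as realistic for serum-stimulated Erk-KTR responses in
  fibroblasts — onset within one to a few minutes, rise times of minutes,
  equilibrium ratios around 2–3.5, old-cell recovery completing inside the
  30-min window — with old cells slower (k_on 0.003–0.010 /s vs
  0.008–0.020 /s for young) and delayed (t_on 60–150 s vs 30–90 s). The
  t_off range (400–800 s) lies strictly above every t_on range.
- **Rendering.** Nuclei are hard (non-anti-aliased) disks of radius 8 px
  so that pixel-count oracles are exact. The reporter channel paints the
  nucleus at a constant gain and a cytoplasmic annulus (width 8 px, wider
  than the 5-px measurement ring so segmentation jitter never reads
  background) at gain × C/N, making the measured ring/nucleus mean ratio
  equal the true C/N before noise; only the ratio is constrained by the
  model, so the constant nuclear gain is a free convention. Pre-stimulation
  C/N is exactly 1 for every cell.
- **Noise and motion.** Additive Gaussian pixel noise (a Poisson-like
  camera model is deliberately out of scope), constant background, per-cell
  isotropic Gaussian random-walk motion plus optional global drift for
  registration tests. Initial positions sit on a jittered grid keeping
  centers at least `2·(nucleus_radius + annulus width) + 1` px apart, and
  steps that would violate that separation are re-drawn (or raise,
  per configuration).

Not emulated: photobleaching, shot noise, defocus blur, nucleus shape
variation, touching or dividing cells, cell death or departure. Passing
tests therefore demonstrate correctness of the computational chain under
the stated noise and motion models — not robustness to crowded fields,
declumping, or illumination drift in real microscopy.

## Segmentation and measurement choices

- Background subtraction is `max(frame − b, 0)` with `b` a constant or a
  frame percentile; registration is integer-pixel translation maximizing
  circular cross-correlation, estimated on the dye channel and applied to
  both channels. Constant frames register at (0, 0) with a warning.
- Nuclei: Otsu threshold (or fixed), hole filling, 8-connected components,
  area filter (default 30 px), labels assigned 1..n in raster order of
  each component's first pixel. Declumping of touching nuclei is not
  implemented; the generator guarantees separation.
- Rings: Euclidean-distance-transform dilation thresholded at the ring
  width (default 5 px) — a disk structuring element, matching the
  physical-width reading; Chebyshev dilation would overshoot diagonally.
  Pixels reachable from several nuclei go to the nearest nucleus, distance
  ties to the lower label, so rings are pairwise disjoint and exclude all
  nuclei.
- C/N is the arithmetic mean of the (background-subtracted) reporter over
  ring pixels divided by the mean over nucleus pixels; the ratio is
  invariant to positive rescaling of the reporter channel, and to constant
  background when subtraction is applied identically to both regions.
  Whether raw or background-subtracted intensities enter the ratio is
  configurable; for uniform background the normalized trace is unaffected.
- Nuclei touching the image border are kept but flagged, and their traces
  are excluded from fitting by default (a truncated ring biases C/N).
  Undefined frames (gap, non-positive nuclear mean) stay undefined — no
  interpolation; the fitter simply omits those time points.
- The normalization reference is the single frame at index
  `stimulation_frame − 1`, not an average of pre-stimulation frames.
  Traces without a defined positive reference value are excluded with an
  explicit reason code.

## Tracking

Link costs are centroid Euclidean distances only (no area or intensity
terms — the minimal faithful reading), gated at `max_link_dist_px = 15`.
The matching is solved as a padded square linear assignment problem:
each detection and each track gets a "stay unmatched" dummy whose cost
exceeds any real link, so the solver returns the minimum-cost matching of
maximum cardinality among non-forbidden pairs. A vetted optimal solver
(`scipy.optimize.linear_sum_assignment`) stands behind the interface;
its optimality on gated instances is enforced by an exhaustive
permutation oracle in the test suite, not assumed. Tracks unmatched for
more than `max_gap` frames (default 0) are closed; bridged interior
frames are recorded as MISSING. Only tracks that span the normalization
reference frame and at least 80 % of frames enter fitting.

## Fitting and variant selection

Bounded nonlinear least squares (trust-region reflective) with a
deterministic multi-start grid: `t_on` on 5 knots over the observed
post-stimulation times, `k_on` starting from {10⁻³, 10⁻², 10⁻¹} 1/s,
`R_eq` from the trace tail mean; the recovery variant adds `k_off` starts
{10⁻³, 10⁻²} 1/s and initializes `t_off` at the trace peak,
parameterized internally as `t_on + Δ` with Δ ≥ 1 s so the constraint
`t_off > t_on` is structural. Bounds: rates in [10⁻⁵, 1] 1/s, `t_on` in
[0, t_max], `R_eq` in [0.1, 10] — generous for a 30-min window. The best
SSE wins; SSE ties break toward the smallest `k_on`. `t_on` is fitted
continuously, not snapped to frame times. Fitting requires at least 8
defined post-stimulation points; traces whose post-stimulation excursion
from 1 stays below `flat_tol = 0.2` (four times the calibrated trace
noise SD, far below any modelled response amplitude) are flagged
unidentifiable and report no parameters.

Variant selection (the motivating study states no rule): *recovery* is
chosen iff the post-peak decline exceeds `decline_frac = 0.25` of the
rise above baseline **and** the recovery fit improves SSE by at least
`sse_improvement = 10 %` over the monotone fit; otherwise *monotone*.
Both thresholds are configuration.

Fitting is equivariant to time units: refitting with times in minutes
(and correspondingly scaled rate bounds/starts) multiplies `k_on` by 60,
asserted in the tests.

## Group statistics

Cell status from doubling time (DT, days) and SA-β-Gal positivity (%):
young = DT ∈ [1, 2] and SA-β-Gal < 1 %; mid-old = DT ∈ [5, 7] and < 5 %;
old = DT > 14 and > 65 %. Band edges are closed exactly as printed;
inputs in none of the bands (e.g. DT ∈ (2, 5)) are unclassified rather
than force-assigned.

Parameters are compared pairwise between groups with a one-tailed
Mann–Whitney U test: U from midrank sums; exact p by full enumeration of
rank arrangements when n₁ + n₂ ≤ 12 with no ties, otherwise the normal
approximation with tie and continuity corrections. The one-tailed
direction must be declared per parameter in configuration — there is no
automatic direction choice. Summaries are mean ± SD; no multiple-testing
correction is applied (p values are per comparison, noted in the report
metadata). A two-tailed Student's t test is provided for normally
distributed samples.

## Validation experiments and problem sizes

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) recompute, from the given seed:

- model-identity residuals (value at onset, one-ulp continuity gap at
  `t_off`, asymptote residuals);
- assignment optimality on 500 random gated cost matrices up to 6×6
  against exhaustive permutation search;
- ring pixel counts for disk radii {8, 10, 15} px at width 5 against the
  continuous annulus area and an independent brute-force enumeration;
- a noiseless stationary 20-cell movie on the full 15-s/30-min schedule
  through the entire segment→track→quantify→fit chain (worst per-cell
  relative error of k_on, t_on, R_eq; track–truth agreement);
- a 100-cell movie with 1 px/frame random-walk motion, whose extracted
  normalized traces receive Gaussian noise of SD 0.05 before refitting
  (median parameter errors, per-archetype variant-selection accuracy).
  Noise is injected at the trace level because that is the scale on which
  the noise condition is stated; a pixel-level noise equivalent would
  depend on mask areas and be only approximate;
- Mann–Whitney exact p against full enumeration over all sample-size
  splits with n₁ + n₂ ≤ 10, and the test's type-I error rate at α = 0.05
  over 1000 replicates of identically distributed groups.

These sizes keep the whole validation under a few minutes on one CPU
while leaving each check statistically meaningful.

## Known limitations

- No declumping or shape-based segmentation: crowded or touching nuclei
  are out of scope.
- Distance-only link costs; no motion model (Kalman) or mitosis-aware
  lineage handling.
- The Gaussian noise model ignores photon statistics; intensity-dependent
  noise would mildly bias C/N at low nuclear counts.
- The recovery-detection rule is heuristic; near-threshold transient
  responses (shallow decline, late `t_off`) can be labelled monotone.
- Exact Mann–Whitney enumeration is limited to small samples; larger
  samples use the asymptotic approximation.
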