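# Methods

This note documents the models, conventions and design choices behind
`dart2`, in the order data flow through the pipeline.

## Tracking statistics

A frame is binarized with a preset brightness level (Otsu estimation is
available but off by default — the assay is run with a fixed,
pre-calibrated threshold).  Pixels outside the configured tube span are
never flagged.  `polarity` states which side of the level flies occupy;
with near-infrared illumination flies are bright on a dark background.

**Normalization.**  With 0-based column offsets `x_n` from the odorant
end, the per-frame center of mass is `Σ x_n / (M (L − 1))`.  A
denominator of `M · L` cannot attain 1.0 (its maximum is `(L−1)/L`) and
maps the homogeneous distribution to `(L−1)/(2L) ≠ 0.5`; dividing by
`L − 1` instead makes the three canonical anchors — 0 (all mass at the
odorant end), 0.5 (homogeneous), 1.0 (all mass at the far end) — hold
exactly.  The two conventions differ by O(1/L), i.e. less than half a
percent for the ~300-pixel tubes the assay uses.

**Orientation.**  `x` is always measured from the odorant end; a
geometry flag (`odorant_end`) records which image side that is, and
flipping it maps CoM → 1 − CoM exactly.

**Avoidance index.**  The tube is bisected; the index is
`(N_odorant − N_solvent) / M` over above-threshold pixels (a proxy for
fly counts — the statistic is not operationalized per fly).  For an odd
tube width the single middle column belongs to neither half but stays in
the denominator, so a mask entirely in the middle column scores 0.  As
printed the formula is positive for *attraction*; avoidance comes out
negative.  The implementation follows the formula verbatim and exposes
`aversion_positive=True` to flip the sign rather than guessing intent.

**Missing frames.**  A frame with no above-threshold pixel yields NaN
for both statistics — flagged missing, excluded from window averages,
never imputed and never silently zero.

## Time series

Captured traces (1 frame/s) are decimated to the 10 s analysis cadence
by keeping every k-th sample starting at t = 0; non-multiple intervals
are rejected rather than resampled.  The summary statistic is the
arithmetic mean of non-missing CoM samples inside an odor-specific
steady-state window, endpoints inclusive (the choice is worth one
sample either way).  Time zero is odor application; the 20 min
acclimation that precedes it is not recorded.  The shipped window table
(minutes): benzaldehyde 20–60, propionic acid 5–25, R-limonene 0–60,
AITC 20–60, citronellal 20–60, isovaleric acid 5–25, lemongrass 20–60.
Unknown odors require an explicit window: the window is part of an
odor's assay definition, not something the package infers.

## The assay simulator

Flies are independent agents on the tube axis `[0, L]`, updated by the
Euler scheme

    x[t+dt] = x[t] + κ_rep · (1 − e^(−t/τ)) · dt + σ √dt · ξ

with reflecting boundaries (flies accumulate at, not through, tube
ends).  Crowding is a pairwise soft-core repulsion: flies closer than
`d_ex` push each other apart by half their overlap (a displacement that
decays linearly to zero at `d_ex`); positions are clipped to the tube
afterwards.  `κ_rep = κ + η`, with `η ~ N(0, drift_jitter)` drawn once
per tube, models tube-to-tube variability (odor loading, handling).

Parameters, defaults and rationale:

| parameter | default | units | why |
|---|---|---|---|
| `n_flies` | 16 | – | middle of the assay's working range |
| `duration_s`, `fps` | 3600, 1 | s, 1/s | the 60 min, 1 frame/s protocol |
| `tube_length_mm` | 150 | mm | physical tube |
| `drift_mm_s` (κ) | 0.25 | mm/s | sets the advection time L/κ ≈ 10 min, so the trace is near steady state by 20 min |
| `onset_tau_s` (τ) | 420 | s | single-exponential aversion ramp; no kinetic law is established, this is the simplest form putting the plateau at ~20 min |
| `diffusion_mm_sqrt_s` (σ) | 4.5 | mm/√s | with κ above gives a stationary mean CoM ≈ 0.755, the observed steady-state aversion to 1% benzaldehyde |
| `crowding_radius_mm` (d_ex) | 3 | mm | fly body scale |
| `drift_jitter_mm_s` | 0.05 | mm/s | calibrated so the variance floor and effect-size plateau sit at 8–16 flies per tube (see calibration below) |

The stationary density of the jitter- and crowding-free walk is
`p(x) ∝ exp(2κx/σ²)`, whose normalized mean is
`e^y/(e^y − 1) − 1/y` with `y = 2κL/σ²`.  `estimate_drift` inverts this
relation (Brent's method) to recover κ from an observed plateau mean,
assuming independent flies and known σ; simulations at n = 16 with 20
replicates recover the generating κ within 25% (the estimate is biased
slightly low because the 20–60 min window is not fully stationary).

**Canonical patterns.**  Seven named position distributions anchor the
CoM scale, uniform on their supports: homogeneous [0, 1], left/right
cluster in the outer tenth, left/right bias in one half, slight
left/right bias in the inner quarter of one half.  Supports are disjoint
from the midpoint by construction, so right-side patterns always score
CoM > 0.5 and left-side < 0.5.

**What the generator emulates, and what it does not.**  It reproduces
the statistical structure the analysis relies on — ramp to a steady
state, replicate variance shrinking with group size toward a tube-level
floor, crowding depressing the response at 32–64 flies, mirror symmetry
under drift reversal — but not odor plume physics, olfactory
transduction, fly orientation, grooming, or inter-fly behavioral
coupling beyond volume exclusion.  Passing tests therefore validate the
*quantification pipeline*, not any claim about real fly behavior.

## Rendering

Flies are drawn as discs (radius `fly_radius_px`) on an 8-bit background
with additive Gaussian noise; a configuration whose fly/background
contrast is below 10 noise SDs is rejected, since no fixed threshold
could then separate them (at the default margin the midpoint threshold
sits > 10 SDs from both levels, so false pixels are practically
impossible).  Two choices matter for fidelity of the roundtrip
(render → threshold → CoM vs. the point-mass CoM of the true positions):

- **Cap clamping.**  Disc centers are clamped one radius inside the tube
  span — a fly's body cannot protrude past the caps.  Without this, a
  fly at the tube end loses part of its disc to the span mask and is
  down-weighted in the pixel-weighted CoM, an error that scales with the
  fly's distance from the group rather than with the disc size.  With
  clamping every fly contributes a full, symmetric disc and the
  per-frame roundtrip error is bounded by one radius (in columns).
- **Row placement.**  Transverse rows carry no signal.  The default
  places them uniformly at random; flies closer than a disc diameter
  can then occlude, merging into one blob whose pixels under-weight the
  pair — just as occluding real flies do.  `row_mode="lanes"` assigns
  flies to disjoint transverse lanes (shuffled per frame), guaranteeing
  non-overlapping discs; the one-radius roundtrip guarantee is stated
  for this mode.

## Group-size calibration

For each group size the simulator runs replicate tubes in an odor arm
(base drift) and a matched control arm (drift 0, same jitter), each
trace is decimated to 10 s and window-averaged, and the sweep reports
the unbiased across-replicate variance of the odor-arm means, Cohen's d
between arms (pooled SD with n−1 weights; the conventional two-sample
effect size, which the drift-free null calibrates to zero), and both
arms' mean CoM.  Across-replicate variance is the primary output; the
within-replicate temporal variance is exposed separately as a
diagnostic.

The drift jitter is the one generator parameter set by calibration
rather than first principles: without a tube-level variance component,
replicate variance falls as 1/n indefinitely and Cohen's d keeps
growing with group size, which contradicts the assay's observed
behavior (variance and effect size both saturating so that 8–16 flies
is the sweet spot).  At 0.05 mm/s the variance floor is reached around
8–16 flies and the effect size plateaus there (d(8)/d_max ≈ 0.75,
d(16)/d_max ≈ 0.84 in a 50-replicate sweep), while crowding pulls the
32- and 64-fly mean CoM below the 16-fly mean.  In tests the "sweet
spot" is operationalized as: variance non-increasing within sampling
error (successive ratio ≤ 1.5 at 50 replicates), the region
{n : variance ≤ 2 × min variance and d ≥ 0.7 × max d} containing both
8 and 16, and the 32/64-fly means below the 16-fly mean.

## Rank-based statistics

All comparisons are rank-based and hence invariant under strictly
monotone transformations of the data.

- **Mann–Whitney U** (two-sided): exact when the smaller sample has ≤ 8
  values and the pooled data are tie-free, else the tie-corrected
  normal approximation with continuity correction.  At the branch
  boundary (n = 8 vs 8) the approximation tracks the exact p-value to
  a worst case of about 0.011, typically a few thousandths.
- **Paired Wilcoxon signed-rank** (two-sided): zero differences are
  dropped; exact for ≤ 15 nonzero differences.  The exact branch is
  computed in-house — by the classical counting recursion for tie-free
  integer ranks, and by full enumeration of the 2^n sign assignments
  over midranks when |differences| tie, where shift-algorithm "exact"
  p-values are wrong.  The reported statistic is min(W+, W−).
- **Kruskal–Wallis + Dunn**: scipy's omnibus, then Dunn's z-tests on
  pooled midranks with the tie-corrected variance factor
  `N(N+1)/12 − Σ(t³−t)/(12(N−1))`, Bonferroni-adjusted over the tested
  pairs (the adjustment is not prescribed; Bonferroni is the
  conservative convention).  A two-group call degenerates to the
  two-group omnibus and orders datasets like Mann–Whitney.

Null-simulation calibration targets a 5% type-I error.  Exact rank
tests are discrete, so the achieved level depends on n: the Monte-Carlo
checks use 12 tubes per group for Mann–Whitney (the assay's typical
replication; achieved level 0.0449) and 15 pairs for Wilcoxon (the
largest exact-branch size; achieved level 0.0479).  At 8 pairs — a
realistic paired-recording count — the exact Wilcoxon can only achieve
0.039, purely through discreteness; that is a property of exact tests
at small n, not of this implementation.

## Evoked responses

All three modalities share the peak-minus-baseline rule: baseline is
the mean signal over a window before the stimulus (5 s for EAG and
patch, 30 s for DCFDA), the amplitude is the largest absolute deflection
from baseline in the response window, reported as a positive magnitude
(EAG deflections are downward; agonist-evoked currents at negative
holding potentials are inward).  Response windows are not prescribed
anywhere, so defaults are: 10 s after the puff for EAG (a 500 ms puff
plus washout), the full 120 s post-record for DCFDA, and the full
post-stimulus record for patch.  EAG amplitudes below 0.05 mV mark the
trace excluded (with a machine-readable reason) rather than dropping it
silently.  For DCFDA the "steady-state peak" is the maximum of a
3-sample (9 s at the 3 s cadence) moving average — honoring both
"steady state" and "peak" — and both ΔF and ΔF/F0 are reported, since
the normalized and un-normalized conventions are both in use; ΔF is
offset-invariant, ΔF/F0 is not.  Percent-of-control is
`100 · test/control`, undefined (rejected) for zero or excluded
controls.  Membrane-resealing exclusion for patch recordings is taken
as an input flag, not detected.

## Numerical and testing choices

- CoM/AI are exact rational arithmetic in floating point; the oracle
  equivalence tests compare against an independent brute-force loop at
  1e−12.
- Determinism: a single master seed drives initial positions, dynamics
  noise and tube jitter through spawned substreams; rendering has its
  own seed.  Identical configurations reproduce trajectories, CSVs and
  TIFFs bit for bit.
- Problem sizes in the shipped tests were chosen to probe each claim at
  the scale where it is informative: the calibration sweep runs the
  full 7 × 2 × 50 tube grid at full 60 min duration (~30 s), the null
  simulations 10⁴ replicates each, oracle sweeps 10²–10³ random
  instances.
- Sampling-error tolerances in stochastic tests (e.g. the 1.5× ratio
  allowed between successive variance estimates at 50 replicates) are
  set from the dispersion of variance ratios at those replicate counts.

## Known limitations

- The simulator's flies interact only through volume exclusion; real
  collective effects (following, aggregation pheromones) are absent, so
  the variance floor is a modeling device, calibrated rather than
  derived.
- The AI uses pixel counts as a proxy for fly counts and inherits any
  body-size differences between flies.
- `estimate_drift` assumes no crowding and known σ; it is a consistency
  check on the generator, not a general inference tool.
- Otsu thresholding is per-frame and can flicker on nearly empty
  frames; the fixed preset threshold is the supported path.
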