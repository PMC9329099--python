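# Methods

This note documents the models and procedures implemented in `consink`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Coordinate and angle conventions

Lengths are in cm, times in seconds, angles in degrees. Allocentric
directions use 0° = +x, counter-clockwise positive, wrapped to [0, 360).
Relative (egocentric) direction is `wrap(HD − bearing(position → point))`
in (−180°, 180°]: 0° facing the point, positive when the point is to the
animal's right. All statistics computed here are equivariant under global
rotation, so the choice of reference axis is immaterial. Direction bins are
half-open (`[−180 + k·w, −180 + (k+1)·w)`, with 180° identified with
−180°); one integer binning formula is shared by the scalar reference
implementation, the vectorised grid search and the permutation kernel, so
the oracle-equivalence tests compare exactly.

## Maze geometry

The maze is the centred hexagonal tessellation of 61 platforms (rings
1+6+12+18+24), hexagon side 11.5 cm, adjacent centres √3·11.5 ≈ 19.9 cm
apart; overall span ≈ 182 cm. The tessellation is the Voronoi diagram of
the platform centres, so point-in-platform lookup is nearest-centre plus
three half-plane tests. Physical 30° maze rotations between trials are not
modelled; all coordinates are in the room frame. Choice scoring uses
Euclidean centre-to-centre distance to the goal ("closer" is not otherwise
defined); equidistant pairs are left unscored.

## Synthetic sessions

The generator emulates the statistical structure the analyses assume, not
rat biomechanics.

* **Task.** Thirteen start platforms are drawn one per angular maze
  subsection. Choice pairs are adjacent to the occupied platform, at least
  one strictly closer to the goal, previously unused platforms preferred
  while that stipulation can be met. The simulated animal picks the closer
  platform with probability `p_correct` (default 0.85, matching
  well-trained performance). Subtrial timing: 4-s wait after the previous
  platforms lower (wait 1), a 2–3-s raise delay, 5.5–7.5 s of scanning
  before the choice; wait 2 is the 4-s window ending 1 s before the torso
  transition. Transitions take 1 s; reward consumption 8 s.
* **Trajectory** (~25 Hz). During dwells the torso drifts slowly
  (0.3–0.6 rad/s) on a circle of 0.35 × apothem around the platform
  centre; the head sits 5 cm ahead of the torso along the heading. The
  heading is a triangle-wave sweep (amplitude 300°, period 3 s, 8° jitter)
  around a per-dwell random base, guaranteeing ≥180° of sweep in any 4-s
  window and full coverage of all 24 relative-direction bins. A variant of
  this model in which the torso pivots with the heading was evaluated and
  rejected: it makes head position and heading nearly redundant, which
  destroys the convergence of raw per-bin vector fields that tuned cells
  must show. An optional biased mode replaces the sweep with an
  Ornstein–Uhlenbeck excursion (σ = 55°) about the bearing to a target
  point; it exists to create the uneven directional sampling that the
  occupancy correction is designed to remove.
* **Spikes.** Per-frame rate λ(t) multiplies a von Mises gain in relative
  direction to the cell's sink (κ_rd), an optional Gaussian place field,
  an optional Gaussian gain in distance-to-sink and an optional von Mises
  gain in allocentric direction, then is normalised so the session mean
  equals `base_rate`. Spikes are drawn by thinning with λ held constant
  within each frame (exact for piecewise-constant rates); an independent
  time-rescaling sampler provides the distributional cross-check. The base
  ConSink phenotype is direction-only; place-only cells default to a 40-cm
  field, and realistic session-mean rates are 1–3 Hz. A per-cell
  `error_gain` multiplies the rate inside error-trial wait windows to
  emulate degraded goalward firing.

What passing tests on these sessions show: that the estimators recover the
parameters of data generated under the analyses' own assumptions, at
realistic data volumes, and that the null calibrations hold when those
assumptions hold. What they do not show: robustness to tracking noise and
dropped frames, theta-phase and within-field rate dynamics, non-Poisson
spiking, overdispersion, or behavioural idiosyncrasies of real rats.

## ConSink detection

The corrected tuning, grid search and significance tests follow the
procedure summarised in the README. Numerical choices:

* Control scaling: each platform's frame histogram is scaled to sum to the
  cell's spike count on that platform, so the summed control has total
  mass equal to the spike count and the corrected distribution of an
  untuned cell is ≈1 in every bin.
* Bins whose control mass is zero are excluded from the MRL/mean (set to
  weight zero), never imputed — division by a vanishing control must not
  manufacture tuning.
* The Rayleigh test is the weighted formulation on the binned corrected
  distribution with the standard bin-width correction (d/2)/sin(d/2),
  α = 0.05; it agrees with pingouin's circular routines to 10⁻⁶ (tested).
* Argmax ties are broken toward the lowest y then x grid index and
  flagged; an argmax on the grid boundary is flagged as an allocentric
  suspect (sinks "at infinity" reduce to allocentric HD tuning, a tested
  limit property).
* The grid is 34 × 29 at exactly 7.0 cm, centred on the tracked bounding
  box (the camera field of view is not otherwise known).
* The head-direction permutation keeps spike positions and permutes spike
  HDs within the cell, preserving both marginals while destroying their
  association; each permutation re-runs the entire grid search and
  contributes its maximal MRL to the null. The inner loop runs in a numba
  kernel that is verified against the pure-numpy path to 10⁻¹² in tests.
* The time-shift control shifts the spike train circularly by
  U(60 s, T − 60 s) and recomputes tuning to the fixed detected sink with
  the shifted pose.
* Burst samples use the circular mean of member-spike relative directions
  per candidate (not the RD of the averaged pose; both readings of the
  procedure are defensible, the former is implemented) and the burst's
  mean spike position; burst merging combines qualifying bursts separated
  by <0.5 s, iterated to a fixpoint (single-pass mode available).
* The downsampling validation keeps each spike with probability
  `occ_min / occ_b` within its platform × 15°-HD bin (equalising
  directional sampling), re-runs an uncorrected search per repeat, and
  averages; it agrees with the correction method within ~1 grid step on
  simulated cells.

Estimator precision: on 30-min sessions at 1–3 Hz the sink is recovered
with a median error of ~4–6 cm; in roughly one cell in ten the argmax
wanders 1–2 grid steps along a nearly flat MRL ridge (the MRL difference
between the chosen and the true-sink candidate is then ~0.002), mostly for
low-rate cells or sinks near the maze edge where all spikes lie on one
side and distance along the bearing is weakly constrained. Preferred
directions are essentially always recovered within a few degrees.

## Population fields and the population sink

Per platform and cell, a unit vector at the cell's mean allocentric spike
heading is scaled by platform mean rate (spikes / occupancy seconds, a
definition the source procedure leaves open) times the cell's MRL and
summed over the cells that fired there; per-platform spike headings are
used raw (no occupancy correction is described for this step). The
population sink maximises the vector-length-weighted MRL of platform
directions re-expressed relative to each candidate.

## LN-Poisson models

100-ms windows; window pose is the time-weighted (circular for angles)
mean of its frames; windows overlapping exclusion intervals are dropped
whole. Variables: RD (18 circular bins), AD (18 circular bins), Ds (20
linear bins spanning [0, max distance]). The penalised Poisson objective
(quadratic second-difference penalty, circular wrap for RD/AD, β = 1 per
variable) is maximised by damped Newton with exact block Hessians;
convergence tolerance 10⁻⁶ on the scaled gradient, with a tiny ridge for
the additive-offset degeneracy of multi-variable models. Cross-validation
uses 50 contiguous sections dealt round-robin into 10 folds. Selection is
forward: the best model of each size by mean cross-validated gain, stepping
up only while the increase over the incumbent is one-sided signed-rank
significant (α = 0.05), and requiring the final model to significantly
beat the mean-rate model — the simplest model that adequately improves
prediction. With cross-validated gains this is conservative for
homogeneous cells (overfitting makes null gains negative in expectation),
which the calibration tests confirm.

## Goal statistics

* **Fantail**: pooled ConSink-cell spikes, 12 × 30° bins *centred* at 0°,
  ±30°, …, 180° (so the central bin straddles the goal direction); per
  platform, bin rates are spike counts over occupancy seconds; platforms
  are averaged with equal weight, excluding (platform, bin) cells with
  less than 1 s of occupancy (sub-second occupancies make single pooled
  spikes read as tens of Hz and dominate the average); divided by the
  number of cells; z-scored.
* **Wait-period firing**: goalward rate restricts spikes and occupancy to
  frames within ±15° of the goal direction (one fantail half-bin; the
  angular cone is not otherwise specified); the preferred-direction rate
  uses ±15° around the cell's preferred RD to its own sink. Population
  comparisons are Wilcoxon signed-rank (two-sided for goalward, one-sided
  correct > error for preferred-direction tuning).
* **Goal shift**: one-sided rank-sum per epoch (distance to own goal vs
  other goal); cells with sinks in both epochs get a two-sided signed-rank
  on movement toward the new goal.
* **Remapping**: 40 × 32 rate maps on the union field of view;
  population-vector correlations per bin across cells and per-cell
  linearised-map correlations, against first-half/second-half
  within-condition baselines.
* **Screening**: spatial information (bits/spike) and coherence
  (correlation of each bin's rate with its neighbours' mean, unsmoothed
  map) must both exceed the 95th percentile of a circular time-shift null
  (≥60 s, 200 shifts by default). On platform-confined trajectories the
  coherence null is itself high (occupancy clumping), making coherence the
  binding constraint — the screen is conservative for broad fields.
* Exclusion windows require theta power below its mean, and population
  rate and ripple power above mean + 2 s.d., simultaneously for ≥50 ms;
  band-power series are consumed precomputed (spectral estimation from raw
  LFP is out of scope). The 500-spike inclusion rule is applied per
  condition after exclusion.

## Problem sizes

Validation suites use 30-min sessions (trimmed to exactly 1800 s where the
condition calls for it) for parameter recovery and calibration, 20 cells
per generator class for model recovery, 50 cells × 200 permutations for
type-I calibration, and 13-trial sessions elsewhere; the acceptance script
uses 8–20 cells per analysis and 100 permutations. These sizes give
standard errors comfortably inside the tested margins for every check
except sink recovery, whose 90% bar sits at the estimator's intrinsic
per-cell recovery rate (~0.88–0.92 with sinks uniform over the maze), so a
20-cell draw can land one cell either side of it.

## Known limitations

* The occupancy correction is platform-granular; directional sampling
  biases *within* a platform that correlate with position are not
  corrected (and are inherited by any method built on it).
* The permutation null is conservative for cells whose firing is locked to
  position, because permutation breaks the position–heading coupling of
  the behaviour as well as the cell's tuning.
* Sinks far outside the maze are weakly localised (all bearings become
  parallel); such cells are flagged by the boundary indicator rather than
  re-classified as allocentric.
* Session file I/O round-trips the generator's ground truth, but no
  importer for third-party tracking/spike formats is provided beyond the
  documented CSV schemas.
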