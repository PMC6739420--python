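# Methods

`collic` analyzes how the intermediate layers of the superior colliculus
drive head orienting. It covers the full desk-side analysis chain for this
kind of experiment: segmentation of 3D head-over-body movements, scoring of
optogenetic stimulation trials, decomposition of prolonged responses into
stepwise saccade-like movements, spike- and light-triggered averages of head
displacement with permutation nulls, topographic motor maps and their
magnification factor, detection of periodic anatomical modules in density
volumes, and pupil tracking. A synthetic-data module generates every input
with known ground truth, so each stage is testable end to end without any
recording.

## Coordinate conventions and sampling

Head-over-body orientation is expressed as yaw (positive = head pointing
right), pitch (positive = up) and roll (positive = clockwise) Euler angles in
degrees, sampled uniformly at 50 Hz (20 ms bins). Angles are treated as
unwrapped continuous signals; head-over-body excursions are far below 360°,
so no modular arithmetic is applied. Times are seconds, distances microns or
millimetres as labelled; nothing converts units implicitly.

## Motion-event segmentation (`kinematics`)

Angular velocity is the first difference of position (deg/bin; divided by
the 20 ms bin for deg/s). A motion event requires at least five consecutive
velocity bins of identical sign, each strictly exceeding 0.5 deg/bin
(25 deg/s) — i.e. a minimum duration of 100 ms. The candidate is then
refined outward: the onset moves backward and the offset forward to the last
contiguous bin sharing the event's direction. Two reading decisions:

* *constant direction* is strict sign equality of per-bin velocity, and a
  zero-velocity bin terminates a run;
* the speed criterion applies to every bin of the candidate core, while the
  refined flanks only need matching direction;
* candidates refined into the same direction run merge, so events are
  disjoint per axis.

Event extent is the summed per-bin velocity over the refined span (equal to
the position change onset→offset) and is signed. An independent brute-force
detector (exhaustive enumeration of qualifying five-bin windows expanded to
maximal constant-sign runs) is kept in the package purely as an oracle for
equivalence testing.

Displacement histograms use 10° bins and are normalized to the modal bin
count (our reading of peak normalization; the acquisition-rate reading of
the same phrase would only rescale the y axis). A Gaussian is least-squares
fitted to the normalized bin heights and its peak/mean/sigma reported.

Sensor validation mirrors bench checks of the inertial system: in the static
case, jitter (mean absolute per-bin shift) and cumulative drift (last minus
first heading); on a rotation table at v deg/s, the expected per-bin step is
v/50 (28 → 0.56°, 40 → 0.8°, 56 → 1.12°, 80 → 1.6°) and the per-degree error
is the mean absolute deviation from it divided by it.

## Optogenetic trial scoring and step decomposition (`optostim`)

A trial is successful on an axis when a motion event starts within 2 s of
light onset. The trial amplitude is the deviation of largest magnitude from
baseline (mean position over the 1 s preceding onset) within that window,
with its sign retained — the signed-extremum reading covers movements
opposing an ongoing drift. Mean displacement is averaged over successful
trials only, and trials lacking 1 s pre / 2 s post context are dropped with
a warning. Overall trial success is the OR across axes.

For step decomposition, trials are baseline-subtracted and scanned for
moments when head speed exceeds 25 deg/s (the same criterion as the event
detector). A step terminates at whichever comes first:

1. a velocity sign inversion (covers the brief contraversive deflections
   seen between steps);
2. a speed local minimum between consecutive speed peaks falling below 50%
   of both flanking peaks (the 50% trough fraction is our quantitative cut;
   no published value exists — it is configurable);
3. the point of maximum displacement attained during the trial.

A step ending while speed is still above threshold seeds the next step at
its own termination, so steps tile each movement epoch without overlap and
step amplitudes telescope to the net displacement. Step amplitude is the
position difference termination minus onset; summaries report steps/trial,
amplitude (also relative to the site's characteristic vector as a ratio),
peak velocity, duration, and the fraction of trials by step count.

## Triggered averages, shuffle nulls and tuning (`tuning`)

The spike-triggered average (STA) aligns displacement to spikes: for every
trigger with full context the angular velocity over the 50 bins (1 s) before
and 100 bins (2 s) after is cumulatively summed into a 151-bin displacement
curve zeroed at the trigger. Each trigger's displacement vector is
max − min of its curve, positive when the minimum precedes the maximum; the
unit's vector is the mean of per-trigger vectors (the per-trigger range
estimator has a small upward noise bias — an inherent property of this
estimator, which is why recovery benchmarks run at low noise). Triggers
whose windows cross the session edges are dropped rather than padded. The
light-triggered average (LTA) substitutes light onsets for spikes.

The null shifts all spike times by a single uniform random draw from
20–150 s, wraps modulo the session length (spike count preserved exactly,
inter-spike structure preserved up to one wrap point), and recomputes the
mean displacement vector; the default is 1000 repetitions. The shift
distribution is continuous uniform — the source procedure names only a
random draw from that range.

A unit is tuned on an axis when a one-sample t test of its per-trigger
vectors against the null mean is significant at 0.05 in *both* light epochs
and the two epoch vectors share a sign. No additional absolute-amplitude
floor is applied (whether one was used originally is unknowable from the
description; the t test plus sign consistency is the documented rule). The
characteristic angle is the mean extent of motion events starting within
2 s after a spike — the 2 s window matches the STA post-window.

Optotagging: a unit is light-activated when its median first-spike latency
after pulse onset is below 5 ms and the fraction of answered pulses exceeds
a configurable floor (default 0.5). The PSTH uses 1 ms bins.

Firing onset relative to movement: the movement-onset-triggered rate (20 ms
bins, −1 to +1 s) is z-scored per bin against wrap-around-shifted spike
trains (the same 20–150 s scheme, reused by analogy since no separate null
is described for this comparison). The onset is the first bin of the
earliest run of at least **three** consecutive bins with z > 1.96. Three
bins rather than two is a deliberate numerical choice: with ~100 tested bins
a two-bin run at z > 1.96 (one-sided p ≈ 0.025) yields an expected
family-wise false-onset rate of ≈ 99 × 0.025² ≈ 6%, right at the edge of the
type-I budget this detector is required to meet; three bins push the
expected rate to ≈ 0.15% at negligible cost in onset-timing sensitivity for
burst-like rate rises (the onset is still reported as the first bin of the
run). Both the z criterion and the run length are configurable.

## Motor maps and magnification (`motormap`)

Nine stimulation sites on a 3 × 3 grid with 500 μm pitch (x = medial→lateral,
y = anterior→posterior) each carry the mean (yaw, pitch, roll) vector over
successful trials; maps may be normalized to site 5. Missing sites are
filled from valid 4-neighbours before smoothing (interpolate → smooth →
gradient; the original order is not documented, and for the affine maps used
in validation the order is immaterial). Smoothing is Gaussian with
σ = 250 μm by default ("250 μm wide" is ambiguous; an FWHM interpretation is
available as an option) with reflective boundaries, which preserves the map
mean exactly for a symmetric kernel. Gradients are central differences in
the interior and one-sided at edges over the 0.5 mm pitch; ∇A is the
gradient *vector* (∂A/∂x, ∂A/∂y) — a scalar sum could not supply the arrow
direction and length the maps display. The magnification factor is

    M = 1 / |det J|,  J = [[∂Y/∂x, ∂Y/∂y], [∂P/∂x, ∂P/∂y]]   (mm²/deg²),

the collicular surface area per unit of (yaw, pitch) motor angle. Sites with
|det J| below tolerance (default 1e-9) are flagged undefined, never reported
as infinity. M is invariant to constant offsets of either map and equals the
closed form exactly on affine maps.

## Periodic-module detection (`periodicity`)

Density volumes (DV, AP, ML axes) are maximum-intensity projected onto the
ML–AP plane and band-pass filtered with a difference of Gaussians. The DoG
scales default to σs = 0.15·L and σl = 0.35·L of the expected lattice
constant (130 μm default). The large scale is deliberately kept well below
the lattice constant: a broader kernel (e.g. 0.6·L) couples adjacent cells
and drags each cell's intensity minimum toward its neighbours, which we
measured to bias recovered mean spacing by ≈ −10 μm on jittered 130 μm
lattices versus ≈ −2 μm at 0.35·L. Both scales are configurable.

Low-density ("off-zone") centroids are regional minima of the filtered image
below an intensity percentile (default 20th; strict inequality, so a flat
background tied at the threshold is excluded). The sub-threshold mask is
partitioned by watershed seeded at those minima — adjacent zones whose
sub-threshold regions touch remain separate — and each basin is reduced to a
centroid weighted by depth below threshold, in microns. Module spacing is
the mean ± SEM of nearest-neighbour centroid distances.

One geometric caveat documented for interpretation: the mean NN distance of
a lattice with per-centre Gaussian jitter is *intrinsically* below the
lattice constant (nearest of ~6 jittered neighbours; ≈ −12 μm at jitter SD
7 μm for L = 130 μm). Recovery benchmarks therefore compare the pipeline
output against the true mean NN spacing of the generated centres, which
equals L only at zero jitter. The spherical-cap cropping used on real
cleared-brain images is replaced by an optional rectangular ROI; it is
geometry-specific preprocessing, not algorithmic content.

## Pupil tracking (`eyetrack`)

Frames are low-pass filtered (Gaussian, default σ = 1 px; benchmarks on
noisy frames use 1.5–2 px — heavier smoothing biases small pupils inward by
roughly σ²/a per semi-axis, so the default stays light), the pupil outline
is the level-crossing contour at a configurable intensity (midpoint of the
frame's range by default, mirroring the manual per-session adjustment such
recordings need), and an ellipse is least-squares fitted to the outline
(frames with fewer than six outline points are flagged undetected). Area is
πab. The angular eye-movement amplitude is α = arcsin(d/r) in degrees, with
d the Euclidean excursion of the pupil centre from rest (median centre over
pre-stimulus baselines) and r the eye radius supplied per session (the eye
treated as a sphere; no default is asserted as biological truth). The sign
of α follows the horizontal direction of the excursion — the original sign
convention is not documented, so this is an implementation choice. Samples
with d > r are flagged invalid. Light-triggered α and pupil-area (dilation)
curves reuse the head-movement triggered-average machinery.

## Synthetic data (`synthetic`)

The generators emulate the statistical structure the analyses assume; all
are pure functions of their arguments including the seed.

* **Head traces**: baseline wander (exact-discretization Ornstein–Uhlenbeck
  process, configurable SD and reversion time, default 2 s, keeping
  excursions bounded as for a real head) plus discrete displacement bouts
  plus white sensor noise, at 50 Hz. The bout position profile is a quintic
  smoothstep — a sigmoid with *compact support*, exactly 0 before onset and
  exactly the amplitude after offset, so noiseless net displacement equals
  the injected amplitude to machine precision (an ordinary logistic leaves
  ≈1% of its amplitude outside any finite window and cannot satisfy that
  contract). A piecewise-linear "ramp" profile (constant velocity) is
  provided for exact-velocity and exact-step-amplitude tests.
* **Stimulation logs**: onsets every `inter_trial` seconds after a 10 s
  quiet lead-in (the default 10 × 250 ms pulses every 10 s reproduces the
  standard session layout).
* **Spike trains**: inhomogeneous Poisson — base rate everywhere, burst rate
  in windows from `lead_time` (default 80 ms) before each direction-matched
  bout onset until bout end; optional optotag responses, one spike per light
  pulse at uniform 1–4 ms latency (inside the 5 ms criterion).
* **Honeycomb volumes**: hexagonal lattice of Gaussian density pits
  (σ = 0.3·L) in a uniform wall, extended along DV; centres jittered by an
  isotropic Gaussian. Wall level 100, pit depth 90, so overlapping pits stay
  positive and no clipping plateaus appear.
* **Pupil frames**: bright background (220), dark ellipse (40) with a ~1 px
  soft edge (so the midpoint level crossing sits on the true outline), plus
  Gaussian intensity noise.
* **Rotation-table traces**: exact linear heading ramps.

What the generators do **not** emulate: vestibular/biomechanical coupling
between axes, neck-plant dynamics, sensor fusion artifacts, spike-sorting
contamination, non-Poisson spiking statistics, anisotropic or curved
anatomy, eyelid occlusion and corneal reflections. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
assumptions, not robustness to every artifact of real recordings.

## Benchmark problem sizes and conditions

The benchmark suite (`collic.benchmarks`, used by `scripts/acceptance.py`
and the acceptance tests) runs on one CPU in about a minute:

* detector/brute-force equivalence on 1000 random 10 s traces (bouts over
  OU wander SD 1° plus white noise SD 0.3°);
* characteristic-vector recovery at 500 spikes per unit, amplitudes 5–40°
  of both signs on all three axes, white noise SD 0.1° and no wander —
  deliberately low-noise to isolate the estimator, since the per-trigger
  min–max vector carries an irreducible upward noise bias (see above);
* null calibration over 500 runs of motion-independent Poisson spiking
  (~3 Hz, 160 s sessions) against 100-repetition wrap-around nulls: by
  exchangeability the expected exceedance rate of the null's 95th
  percentile is 5/101 ≈ 4.95%;
* staircase recovery over 100 noiseless ramp-profile trials (k = 1..5,
  amplitudes 8–25°, bout edges on the 20 ms grid so amplitudes are exact);
* honeycomb recovery over 50 volumes (L ∈ {100, 130, 160} μm crossed with
  jitter SD ∈ {0, 5, 10} μm, 10 μm voxels, 1.92 mm field), each compared to
  the generated lattice's true mean NN spacing within ±7 μm;
* ellipse-fit recovery over 500 frames (semi-axes 8–30 px, noise SD 10% of
  contrast).

## Known limitations

* The event detector's "constant direction" rule is brittle to white noise
  whose per-bin velocity approaches the threshold — real sensor output is
  band-limited, which the OU wander model reflects; raw white noise of ≥1°
  per sample at 50 Hz defeats any sign-constancy criterion.
* The trough criterion (50% of flanking peaks) and the firing-onset run
  length are declared numerical choices, configurable but not derivable
  from the source description.
* Histogram normalization follows the modal-bin reading; the alternative
  acquisition-rate reading would change only the y scale of the fitted
  Gaussian, not its mean or sigma.
* The magnification factor is meaningful only where the (yaw, pitch) map is
  locally invertible; degenerate sites are flagged rather than extrapolated.
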