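# Methods

## Pipeline model and assumptions

A single participant stands ~2 m in front of a fixed depth camera
(defaults follow a Kinect-v2-like sensor: 512×424 px, fx = fy ≈ 365.456,
30 Hz) performing one of eight standing balance tasks drawn from the
Berg, Tinetti and CTSIB batteries (task 1 lasts 120 s, tasks 2–8 60 s).
The scene is assumed static apart from the person, with a block of
person-free frames at the start of every recording.

**Background subtraction.** The background model is the per-pixel median
depth over the leading person-free frames (median, not mean, so a few
outlier returns do not bias the model). A pixel is foreground when it
has a valid (non-zero) return at least `threshold_mm` (default 300 mm)
closer than background; the silhouette is the largest 8-connected
component. 300 mm is far smaller than the person–background gap in any
plausible room (≥ 1 m) yet far larger than sensor noise (≈ 1–10 mm), so
the choice is insensitive over a wide range; it is a config knob. An
optional binary-opening radius exists for speckly sensors and is off by
default to keep the extraction contract minimal.

**Back-projection and the horizontal plane.** Silhouette pixels are
mapped to camera-frame metres via the pinhole model. "Horizontal" means
the camera (x, z) plane — lateral and antero-posterior axes — which is
where standing sway lives when the camera faces the participant. Sway in
y (vertical) is ignored by all three parameters.

**The three balance parameters.**

- *Centroid variability* = `sqrt(var(x) + var(z))` of the per-frame
  centroid, sample variance (n−1). The paper-level definition is a
  standard deviation of a 2D position; the sum-of-variances scalarization
  is the RMS distance from the mean position and is rotation-invariant in
  the horizontal plane.
- *Centroid max speed*: the horizontal centroid is smoothed with a
  centred moving average (default 5 frames ≈ 167 ms) before central
  differencing, because single-pixel mask flicker otherwise dominates the
  maximum; window 1 disables smoothing. The smoothing attenuates a
  0.5 Hz sinusoid by ~1.1% — validation oracles therefore apply the same
  discrete pipeline to ideal samples rather than comparing against the
  continuous derivative.
- *Max body dispersion* = max over frames of λ₁/λ₂ of the 2×2 covariance
  of the cloud's (x, z) coordinates, computed on back-projected metric
  points (not raw pixel columns), so the measure is invariant to distance
  and to rotation about the vertical axis. Degenerate clouds
  (λ₂ ≤ 1e-12 m²) are capped at 1e6 to keep the output bounded and
  sortable. Frames with fewer than 3 silhouette pixels are skipped.

Empty-mask frames become gaps in the centroid trace; interior gaps are
filled by linear interpolation, leading/trailing gaps dropped. The two
trials of a task are combined by an element-wise arithmetic mean — the
trial-combination rule is not dictated by the protocol, and averaging is
the variance-minimizing choice for a symmetric pair (entering trials
separately is a one-line change via `CohortTable.trial_features`).

## Clustering and labeling

Per task and parameter subset, trial-averaged parameters are z-scored
(n−1) and split by K-means with K = 2. Two numerical choices matter:

- For cohorts of ≤ 12 rows the minimum-inertia 2-partition is found
  *exactly* by enumerating all 2^(n−1)−1 splits; Lloyd's algorithm has
  measurable local-optimum rates on tiny inputs regardless of restarts,
  and the enumeration is instant and deterministic. Above that size the
  scikit-learn Lloyd implementation runs (k-means++, best of 10 restarts,
  tol 1e-8, fixed seed), which is the regime of any real cohort.
- Display names: cluster A is the one with the larger `centroid_max_speed`
  centroid (falling back to centroid norm when that parameter is not in
  the subset), so A consistently denotes larger/faster movements. This is
  a naming convention only; risk labels never depend on it.

A model is *relevant* only when the entire young reference group lands in
one cluster; that cluster becomes `lower_risk`. A split reference group
leaves both clusters `undetermined` (and the split counts are reported) —
no majority-based softening, since the premise is that every young
participant has good balance.

## Statistical evaluation

Cluster comparisons use two-sided Wilcoxon rank-sum tests restricted to
elderly participants (including the young would inflate any difference).
The p-value is exact — full enumeration of the rank-sum null — when
n1+n2 ≤ 12 with no ties, and a tie- and continuity-corrected normal
approximation otherwise; the switchover keeps exactness wherever
enumeration is cheap. Two-sided tests are the conservative reading of
"significant differences". No multiple-testing correction is applied
across tasks by default (per-comparison α = 0.05, mirroring the
protocol); a Holm adjustment is available behind a flag.

TUG: trial 1 is familiarization; performance is the mean of trials 2 and
3; `mean ≥ 13.5 s` flags high fall risk (the standard screening cutoff).
Activity volume is Σ MET-level × minutes/week with rest defined as 1 MET.

## Synthetic data: what it emulates, and what it does not

**Rendered level.** Sway is a sinusoid plus Gaussian velocity noise
(smoothed, σ = 2 frames, integrated), chosen over a biomechanical
inverted-pendulum model because it gives closed forms for the sway s.d.
(A/√2) and peak speed (2πfA), against which the whole
render→silhouette→parameter chain is validated. The body is rendered as
an upright silhouette whose half-width varies elliptically with height
and whose depth relief varies with height (chest fullest). Two rendering
choices are deliberate numerical-fidelity choices:

- *Height-varying width*: mask edges on different rows cross pixel
  boundaries at different sway phases, so the discrete centroid tracks
  the continuous trajectory to < 0.1 mm instead of moving in
  pixel-sized steps whose spurious velocity would corrupt the speed
  maximum.
- *Height-varying (not laterally varying) depth relief*: each row's front
  face is laterally flat, so perspective ray sampling is uniform across
  the body and the sampled centroid translates exactly with the body. A
  laterally curved front face biases the sampled centroid by several
  percent of the sway amplitude. The cloud still has genuine depth
  variance, keeping the dispersion ratio finite and informative.

Arm abductions are horizontal bars at shoulder height (they raise the
dispersion ratio, as arm use should); posture breaks widen the
below-centre silhouette, inside the fixed task duration. Depth values are
quantized to integer millimetres; optional Gaussian depth noise is added
before quantization. The renderer exports ground-truth masks and the
exact (pre-quantization) centroid path.

Not emulated: clothing and body-shape variation, flooring/furniture
clutter, multi-path and edge noise of real depth sensors, breathing and
weight-shifting micro-movements, and any physiological link between sway
spectra and fall risk. Passing rendered-pipeline tests therefore
demonstrates geometric and numerical correctness of the measurement
chain, not clinical validity on real recordings.

**Feature level.** Balance parameters are log-normal (positive,
right-skewed, as ratio- and extremum-type statistics are). Baseline
(better-balance) geometric means: 8 mm variability, 0.05 m/s peak speed,
dispersion 8; log-scale σ = 0.2 (moderate inter-individual spread).
At-risk elderly (half of the 40 elderly, by default) are shifted upward
on task 8 only, by 3 trial-level log-SDs on all three parameters.
**Effect sizes are defined at the trial level**: participants' features
average two i.i.d. trial draws, so the participant-level separation the
clustering sees is 3·√2 ≈ 4.24 within-group SDs per parameter. This is
the regime in which the all-44-young-unsplit prerequisite is
reliably met for the three-parameter model (nearest-centroid
misclassification ≈ 1e-4 per participant); single-parameter models sit
near the split boundary, so their relevance is seed-dependent — matching
the qualitative pattern that combined-parameter clustering is the robust
route. Correlates mirror the expected direction: at-risk elderly TUG
12.5 ± 0.9 s vs 10.0 ± 1.1 s (Δ = 2.5 s), activity 400 ± 200 vs
1200 ± 400 MET-min/week, ages 70–85 vs 65–80; young: TUG 8.5 ± 0.8 s,
activity 1500 ± 500, ages 21–29. Trial-to-trial TUG scatter is 0.3 s.
`CohortSpec.null_features()` removes the feature shift;
`CohortSpec.null_correlates()` keeps the feature shift but gives all
elderly one TUG/age/activity distribution — the construction used for
type-I-error calibration, where cluster labels stay determined but the
compared variable is null.

All generators are fully deterministic given their seed.

## Problem sizes used in validation

Rendered validation runs a 60 s, 30 Hz, 512×424 sequence (1800 frames);
unit tests use shorter sequences at quarter resolution. Oracle
comparisons use 1000 random clouds (dispersion), 100 random instances
(clustering), every untied sample-size pair with n1+n2 ≤ 10 (Wilcoxon),
500 null cohorts (type-I error) and 100 generated cohorts (recovery).

## Known limitations

- The background-subtraction scheme is a deliberately simple stand-in for
  production depth-segmentation methods; it assumes a static scene and a
  single person.
- The sway generator is phenomenological; recovery results quantify the
  measurement chain, not physiology.
- Real per-task effect sizes are unknown (no public recordings); the
  generator's defaults reproduce the qualitative single-task relevance
  pattern, not any specific published counts.
- TUG times are inputs; the package does not time the TUG from video.
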