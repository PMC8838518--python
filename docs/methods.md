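# Methods

## Temperature simulation

Each of the 13 heatable regions (head front/back, three torso bands,
upper/lower segments of four limbs) follows a set-point schedule. For a
heat-up from `T_current` to `T_target` the controller adds one fixed
step per update interval (default 30 s) until the target is reached,
then holds. The step width is the gap divided by the smallest step
count that keeps every step at or below `max_heat_rate ·
update_interval / 60`; with the defaults (1 °C/min, 30 s) the step cap
is 0.5 °C. This construction guarantees two properties the rest of the
package relies on: the positive change over any 60 s window never
exceeds `max_heat_rate`, and the target is attained exactly (no
overshoot, no residual). Temperature decreases are applied as a single
jump — the physical plant being emulated cools slowly on its own, so no
software limit is needed. The equal-step rule itself is a design choice:
the requirement is only a sub-1 °C/min heat-up, and equal steps with a
ceiling-division count is the simplest rule that both respects the cap
and lands on the target exactly.

The skin lags the set temperature by a first-order element
`T_skin' = (T_set − T_skin)/τ`, integrated exactly per sampling
interval. τ defaults to 60 s, a plausible thermal time constant for a
heated silicone surface; τ = 0 disables the lag and is used wherever a
test needs exact steady states. An optional constant offset between an
internal temperature probe and the surface (≈2.5 °C in the emulated
hardware, where the probes sit next to the heating elements) is
available but off by default, since the pipeline measures the surface.

## Heart rate and PPG

The set heart rate starts at the target HRT and every 5 s adds an
integer drawn uniformly from [−r_max, +r_max], then is clipped to
HRT ± bound (defaults r_max = 10 bpm, bound = 10 bpm). Uniform steps
with clipping (rather than redrawing) at the boundary is the simplest
rule consistent with a bounded pseudorandom walk; with r_max = 0 the
rate is constant. All stochastic operations take an explicit seed and
use an isolated generator — there is no global random state anywhere in
the package.

The PPG waveform renders one pulse per beat; beat onsets are spaced
60/HRS(t) seconds using the piecewise-constant set rate at the onset.
The default pulse is a raised-cosine systolic peak (center 0.2, half
width 0.2 of the period, amplitude 1) plus a smaller diastolic bump
(amplitude 0.3, center 0.65, half width 0.15). The diastolic bump
exists specifically so the peak detector's rejection of minor local
maxima is exercised by every rendered video, not just by dedicated
tests.

## Scene rendering

A canonical canvas (default 640×360 for the thermal geometry, 320×180
for long video runs; all geometry scales with the canvas) holds the
region masks and a 14-point skeleton. The two thermal cameras see the
left and right ~57.5% of the canvas through projective views with a 15%
overlap, mimicking two tilted sensors covering one mattress; each
160×120 sensor pixel reads the temperature of the nearest canvas point
through the *inverse* of the camera's true affine response (default
K1 = 1.82, K2 = −20.18, the response the calibration experiment should
recover), plus optional Gaussian noise and 0.01 °C quantization (below
the emulated sensor's 0.05 K sensitivity). Background pixels sit at the
incubator ambient of 30 °C. The RGB camera shares the canvas geometry
at 30 fps; only the red channel inside the head region is modulated:
`baseline + depth · ppg(t)`, optionally with per-pixel Gaussian noise.
Keypoints are emitted from ground truth with optional positional
jitter; a point jittered off-canvas loses its confidence and is treated
as missing downstream. The renderer replaces both the physical cameras
and the pretrained pose network, so pipeline results quantify the
*processing* chain, not pose-estimation accuracy.

## Calibration

`fit_calibration` is ordinary least squares of reference on measured
temperature. OLS (not orthogonal regression) because the reference
probe is treated as exact (a ±0.1 °C gold-standard contact probe)
while all error is attributed to the thermal sensor. Error statistics
are restricted to the band whose *reference* temperature lies in
30–40 °C — the clinically relevant range; keying the band on the
reference rather than the measured value is a deliberate choice where
either reading would be defensible. Statistics are computed on raw
(not time-averaged) samples. A constant measured series is rejected as
degenerate. The improvement property (calibrated band MAE < raw band
MAE) holds for any noise below 1 °C because the raw response is a
gross affine distortion.

## Registration and mosaicking

Homographies are estimated from point correspondences by normalized
DLT inside a seeded RANSAC loop (defaults: 2 px reprojection
threshold, 1000 iterations), then refitted on the full consensus set.
Correspondences are an input artifact — in the emulated hardware they
were clicked once for rigidly mounted cameras — so the scenario runner
generates them from the known view geometry (a 4×3 sensor grid with a
5 px margin) rather than providing an interactive tool. Thermal frames
are upscaled 4× by nearest neighbour *before* warping so no
sub-sensor temperatures are invented; bilinear interpolation happens
only at warp time. Warped frames carry NaN outside the source
footprint, keeping "invalid" distinct from "cold"; the mosaic takes
camera 1 in the overlap (deterministic precedence, camera 1 views the
upper body). Pixel convention throughout: 0-based, x right / y down,
half-open rectangles.

## ROI geometry and vitals

The six ROIs are squares with side 0.4 × the neck-to-mid-hip distance:
hands on the wrists, feet on the ankles, chest at the shoulder/hip
centroid, and the forehead offset from the nose by half a side along
the neck→nose axis (away from the body — "above" the nose for an
upright subject). The size fraction and forehead offset are this
package's parameterization; only the set of six ROIs is prescribed by
the emulated setup. A missing keypoint silently removes its ROI; the
cpTD peripheral mean uses whatever hands/feet remain, while a missing
chest makes cpTD unavailable rather than guessed.

Heart-rate extraction: the PPGI signal is the per-frame red mean over
the forehead ROI. Peaks must have prominence ≥ 0.5 × the signal's full
range (rejecting the 0.3-amplitude diastolic bumps with a 2× margin)
and be spaced at least 60/300 s apart. Inter-beat intervals are
filtered *individually* to the plausible 36–300 bpm band before
averaging — a single noise-induced short interval is dropped without
poisoning the estimate — and HR = 60 / mean(valid intervals ending in
the trailing 10 s window); no valid interval yields "undefined", not a
number. The estimator window is 10 s; a separate 30 s settling horizon
excludes transition samples from phase labels and error metrics. These
two horizons are kept distinct deliberately: the first defines the
estimator, the second the reporting convention.

With peak times quantized to the 30 fps frame grid, an N-interval
window at true rate f is off by at most one frame period over the
summed span, bounding the error by `60·f²/(60·fs·N − f)` — about
0.5 bpm at 230 bpm — so rounded steady-state estimates are exact at
the rates used here.

## Pathology classes

Temperature: severe hypothermia < 32 ≤ moderate < 36 ≤ mild < 36.5 ≤
normothermia ≤ 37.5 < hyperthermia < 40 ≤ severe hyperthermia. The
36.5–37.5 °C band is assigned to normothermia with both boundaries
inclusive, because the adjacent bands are defined by strict
inequalities toward it; in particular 37.5 °C exactly is normothermic.
Heart rate: nested bands resolved severest-first (> 220 severe
tachycardia, then > 200; < 80 severe bradycardia, then < 100), so a
severe rate can never be labelled with the mild sibling.
Centralization: |cpTD| > 2 °C, strict. Instantaneous labels carry no
hysteresis; smoothing happens only in `label_phases`, which takes the
majority class over a phase's post-settling samples and flags
too-short phases or tied votes as inconclusive. A phase whose majority
cpTD flag is raised is labelled "Centralization", or "Severe
Centralization" above a median |cpTD| of 5 °C — the midpoint between
the two steady states the shipped scenario produces (4 °C and
≈5.9 °C), so both classify correctly with margin.

## Scenario runner

`run_pathology_experiment` chains everything: simulate → render →
calibrate → register → extract → classify, persisting the vitals and
heart-rate streams as CSV so every reported number is recomputable
from intermediates. The gain-offset correction is applied to the raw
thermal frames *before* registration; ROIs come from the RGB-side
keypoints; temperatures are read from the corrected, transformed
mosaic. Processing is offline batch (a streaming generator preserves
the frame-by-frame contract) rather than a multithreaded real-time
loop. Thermal frames are processed at a configurable interval
(default 10 s) rather than the sensor's native 8.7 Hz: surface
temperatures are inert, and one processed frame per 10 s already gives
every phase dozens of votes.

The shipped scenarios mirror the two validation protocols. The
temperature scenario's exact set points are not prescribed anywhere,
so the package chooses values consistent with the intended conditions:
34 °C (moderate hypothermia), 37, 38.5 (fever), 37, then 37/33
(centralization, cpTD 4 °C) and 37.5/31.6 (severe centralization,
cpTD ≈ 5.9 °C), and back to 37. The cardiac scenario uses 140 bpm
(physiological), 55 bpm (severe bradycardia; the protocol being
reproduced states only "below 60"), 180 bpm (high physiological),
230 bpm (severe tachycardia) and 140 bpm with the ±10 bpm HRV walk.

## What the synthetic data does and does not show

The renderer emulates geometry (two overlapping tilted thermal views,
one RGB view), the sensor's affine distortion, noise and quantization,
pulse-synchronous intensity modulation, and keypoint jitter. It does
not emulate motion, lens distortion, emissivity variation, ambient
reflections, pose-estimation failures, or a breathing/moving subject —
the dominant error sources in real camera-based monitoring. Passing
results therefore validate the processing chain (calibration recovery,
registration accuracy, interval bookkeeping, threshold logic) under
controlled conditions; they say nothing about robustness to motion or
to real sensor artifacts beyond the modelled ones.

## Numerical choices and problem sizes

Homography recovery is asserted to 1e−6 Frobenius distance on
noise-free correspondences; warp round-trips to 0.05 °C on smooth
fields (bilinear interpolation error); calibration recovery to 1e−9 on
noise-free data. Long video runs use a 320×180 canvas — ROI statistics
are means over hundreds of pixels, so canvas resolution affects only
edge effects, and the registration experiments that exercise geometry
use 640×360. The acceptance script's problem sizes (1000-sample
calibration sweep, 1 h heart-rate walk, 60 s single-rate videos, four
120 s phases, one steady centralization scene) are chosen so the whole
script runs in seconds while every estimate is well inside its
asymptotic regime.

## Known limitations

The simulator's plant model is a first-order lag, not silicone
thermodynamics; the thermal hysteresis seen in real sensors is not
modelled, so fitting and validation statistics here differ only by
noise realization. SpO2 (two-wavelength) simulation, respiration and
motion are out of scope. The HRV-phase heart-rate error is inherently
larger than the constant-rate phases (the set rate moves within the
averaging window) and depends strongly on the particular random walk
realization, so it is reported but not bounded by any test.
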