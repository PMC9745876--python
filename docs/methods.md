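# Methods

`stereomantis` implements two minimal stereoscopic mechanisms inspired by
praying-mantis behaviour, together with the binocular geometry and synthetic
stimuli needed to train and probe them.  Neither mechanism solves the stereo
correspondence problem or builds a disparity map; both map retinal input
directly to behaviour.  This note records the models, the assumptions behind
them, the parameters that matter, and the design choices taken where the
design was genuinely open.

## Binocular geometry

The world frame is right-handed: Z points out in front of the animal, Y up,
and positive azimuth is an anticlockwise rotation about Y (leftward).  Head
pose uses Fick coordinates — azimuth-longitude and elevation-latitude, with
the elevation rotation applied first:

    M_W^H = Ry(azimuth) @ Rx(elevation)

The eyes are fixed on the head at `position ± (I/2)·M_W^H·X` (left eye at
+X, interocular distance I = 1 cm by default) and share the head's rotation,
so each eye's visual axis is parallel to the gaze.  A world point projects
to per-eye azimuth/elevation by subtracting the eye's nodal point, rotating
into the head frame, and reading off `atan2(x, z)` and `asin(y/r)` —
elevation is therefore a latitude in [−90°, 90°], and azimuth a longitude
with correct quadrants.  Binocular disparity is `δ = α_R − α_L`; it is
positive inside the binocular overlap and decreases to zero with distance.
The cyclopean azimuth `(α_R + α_L)/2` is the direction behavioural fusion
targets.

Refixating a target postmultiplies the pose's rotation by the Fick matrix of
the target's direction.  The product of two torsion-free Fick matrices can
carry a torsion component, so `HeadPose` stores the full rotation matrix;
the stored azimuth/elevation always describe the gaze column.  This makes
the refixation postcondition (the target re-projects to exactly (0, 0))
hold to machine precision, at the cost of torsion being implicit.

Degenerate inputs (a point at a nodal point or at the head position) raise
`ValueError` rather than returning NaN.

## Synthetic scenes and retinal rendering

Training scenes contain four spheres with azimuth and elevation drawn
independently from N(0°, 45°), distance uniform on [1, 11] cm, and diameter
scaled so each sphere subtends 10° at the origin — equal angular size forces
the network to use disparity, not size, as its distance cue.  The subtense
convention is the exact silhouette angle of a sphere, `2·asin(r/d)` (a 15°
sphere at 8 cm has diameter 2.1 cm).

Retinae are equally spaced lat-long grids (default 51 × 51 over ±70°,
spacing 2.8°), flattened like a Mercator map, which is why off-equator
spheres render elongated in azimuth.  Rendering is binary by unit-centre
inclusion: a unit is active iff its direction lies within a sphere's
angular radius as seen from that eye's nodal point.  Spheres union; there
is no occlusion handling, partial coverage, or photometric structure —
the images stand for the output of an upstream monocular target detector,
not for luminance.

Pixel noise, where used, is additive i.i.d. Gaussian clipped at zero,
default σ = 0.1 of the target amplitude, drawn independently per eye.  The
noise model is a package choice (the underlying behavioural simulations are
described with noisy inputs but no stated distribution); conclusions that
depend on its exact form are avoided — tests assert statistics that are
stable under moderate changes of σ.

The supervised label of a scene is the output-grid unit whose direction is
(great-circle) nearest the headcentric direction of the nearest sphere whose
*centre* falls within the grid extent of at least one eye; scenes with no
visible centre are labelled with the (0°, 0°) "no action" unit.

## The saccade network

A single fully connected affine layer maps the two flattened retinal images
(left first) onto a grid of headcentric direction units; the decision is
winner-take-all, with ties broken to the lowest linear index (row-major over
elevation then azimuth).  The output units are purely linear — softmax and
cross-entropy exist only inside the training loss — so the only nonlinearity
is the readout.  Training is minibatch SGD with momentum 0.9, constant
learning rate 0.05, batch size 128, reshuffling every epoch; weights start
uniform within `±0.01/√fan_in`, biases at zero, so the initial loss is
log(n_classes) to within a percent.  Training, given a seed, is exactly
reproducible.  An optional per-feature zero-centring of the inputs is
implemented (`center_inputs`) but off by default: on the raw binary images
the learned weights show the cleaner disparity template — net excitation
onto a unit at azimuth α_H from left-eye units with α_L < α_H and right-eye
units with α_R > α_H, which is the geometry of near objects.

### Presets and problem sizes

* `full`: 51 × 51 retinae and outputs (5202 inputs, 2601 classes), 100 000
  scenes, 8 epochs.  This is the reference configuration; on one CPU it is
  hours-scale and is exercised only through its architecture constants.
* `scaled_down`: the same protocol and output grid, with the retinal input
  downsampled to 25 × 25 per eye (1250 inputs).  This is the configuration
  the test suite and `scripts/acceptance.py` train.  The output grid is
  kept at the reference 2.8° spacing deliberately: output quantisation
  directly bounds every saccade-direction statistic, whereas the
  behavioural results proved robust to halving the retinal sampling.  With
  the full 100 000-scene / 8-epoch schedule this trains in a few minutes on
  one CPU.
* `tiny`: 15 × 15 → 25 × 25, 3000 scenes, 4 epochs; a smoke-test preset for
  exercising machinery, not behaviour.

Desk-scale training reproduces the headline behaviour — behavioural fusion
(two-target mean saccade azimuth at the cyclopean direction) and the strong
preference for the nearer of two equal-subtense targets — but not every
property of the fully trained reference run.  Known gaps, asserted at full
strength in the acceptance tests and left failing there deliberately:

* the no-action unit's bias is reliably the *largest* bias (blank input
  maps to "stay put"), but exceeds the runner-up by roughly 4× rather than
  the order of magnitude seen after full-scale training;
* the near-preference heat map over 10°-subtense target pairs does not
  reach ≥ 0.9 correct in every distance-ratio ≥ 1.5 cell; very near pairs
  (≤ 3 cm), whose monocular images are widely separated and small, remain
  error-prone at desk scale.

## The strike sensor

A single binocular neuron models the release of predatory strikes.  Each
eye's pathway applies, in order: isotropic Gaussian spatial low-pass
(default σ = 2°, standing for coarse ommatidial sampling), a first-order
temporal high-pass `y_t = a(y_{t−1} + x_t − x_{t−1})` with
`a = τ/(τ + Δt)`, and full-wave rectification — so only temporal change
drives the sensor, regardless of contrast polarity, and static scenes decay
to silence.  The default τ = 250 ms keeps a motion trail comparable to the
preferred target size at typical sweep speeds (40°/s); much shorter
constants reduce the drive to bare edges and make the tuning curves jagged.

The receptive field in each eye is a difference of Gaussians in angular
separation from the RF centre: excitatory centre of scale
`centre_radius/2` (default radius 5°), inhibitory surround of scale
`surround_radius/2` (default 15°), surround weight balancing the centre's
integral so very large stimuli self-cancel.  The centres sit nasally at the
azimuth of a midline point 2.5 cm ahead (±11.3° for I = 1 cm), so both
lines of sight cross at the catch range.  Binocular combination is a
thresholded sum raised to the fifth power,
`max(L + R − θ, 0)^5` — threshold-then-power was chosen because it makes
monocular silence a direct consequence of θ.  The threshold is calibrated
at construction: 1.05 × the peak drive either eye alone receives from the
optimal moving disc (centre-sized, preferred distance), so a stimulus
confined to one eye can never activate the sensor, while a binocular
near-optimal target clears θ by roughly the size of one monocular drive.
Strike emission is Bernoulli per frame with probability
`min(gain · activity, 1)`; the default gain puts the peak per-frame
probability near 0.05.

With these defaults the sensor shows: unimodal size tuning peaking near the
centre diameter (the measured peak sits at ~13° for a 10° centre — spatial
blur plus the motion trail enlarge the effective optimum); a strong
preference for the preferred distance over half or double; suppression of
"ghost pairs" (two distant objects placed on the two eyes' lines of sight so
each eye locally sees the image of a single near target) because the second
image in each eye lands in the other RF's surround; and monotonic
attenuation with non-epipolar vertical disparity, vanishing by ~16°.  One
reference property is *not* reproduced: the half-response vertical offset is
diameter-independent only for targets at or below the centre size; for a
disc twice the centre diameter the response plateaus under small shifts
(coverage of an isotropic window is first-order insensitive to shifting a
disc that fully covers it), so the cutoff roughly doubles from 10° to 20°
discs.  Matching the fitted sensor's behaviour there appears to require its
fitted, published-elsewhere temporal and receptive-field parameterisation,
which this package does not attempt to reproduce.

## Toy correspondence demonstrations

The discrete-ensemble module evaluates linear, squaring ("energy") and
thresholded-linear binocular units on scalar monocular inner products drawn
from a small equiprobable set (default {1, 2, 3}).  Means are exact
enumerations: matched pairs are (v, v); non-matched pairs are unordered
distinct pairs, weighted uniformly (the convention implied by the
three-element sets in the reference arithmetic).  The linear unit's matched
and non-matched means coincide (no correspondence); the energy unit's
matched mean exceeds its non-matched mean for every non-degenerate ensemble
(a Jensen-type inequality — weak correspondence); the thresholded unit at
θ = 4 gives 10/3 vs 3.

The sensor-lattice module enumerates one disparity sensor per (left
location, right location) pair.  A sensor activates when both of its
locations contain object images the local predicate accepts: identity must
match for distinguishable objects, anything pairs with anything for
indistinguishable ones — producing the 1 / 2 / 4 active-sensor counts that
motivate global-correspondence machinery.  The recurrent interactions that
would resolve the 4-sensor ambiguity are represented only by their expected
final activation sets; no update dynamics are defined for them in the
source material, and none are invented here.

## Experiments and reproducibility

`run_two_target_experiment` renders a two-sphere scene (defaults: ±15°
azimuth, 4 cm vs 8 cm, both subtending 15°), adds per-repeat clipped
Gaussian noise, and records 1000 winner-take-all decisions.
`run_preference_map` tabulates the proportion of saccades toward the nearer
target over a distance × distance grid (equal 10° subtense) or a size ×
size grid (fixed 8 cm / 4 cm distances), 200 repeats per cell by default
(a package choice; no repeat count is stated for the reference maps).
`run_strike_sweeps` emits tidy tables for size × distance tuning,
vertical-disparity tuning, and ghost-versus-real comparisons.  Every runner
takes an explicit seed, embeds it in its output table, and is exactly
reproducible from (configuration, seed); summaries are always recomputable
from the raw per-trial rows.  The CLI writes CSV plus a JSON sidecar with
the configuration echo, seed and package version.

`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes
the worked geometry example (−22°/−8°), the 2.1 cm diameter, the toy means
(3 and 10/3), the full-scale input dimensionality (5202), and the
two-target mean saccade azimuth after training the scaled-down preset from
scratch with seed N.

## Known limitations

* The scaled-down network's behaviour carries seed-to-seed idiosyncrasy
  (the reference run itself reports a side bias for very close target
  pairs); statistics over noisy repeats are stable, single noise-free
  decisions for eccentric or very near targets less so.
* The synthetic scenes are bright discs on black: no texture, occlusion,
  background clutter, or monocular-detection noise.  Passing tests show the
  stereoscopic mechanisms work in this reduced world, not that they survive
  real imagery.
* The strike sensor is qualitative by design: its parameters are defaults
  chosen to reproduce orderings (preferred size/distance, ghost
  suppression, monocular silence), not fitted curves; strike counts are
  unitless.
* Angles are stored in degrees throughout; trigonometry is in radians
  internally.  Plotting conventions (azimuth increasing leftward) are left
  to the user.
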