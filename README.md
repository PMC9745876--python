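# stereomantis

Correspondence-free stereopsis: mantis-inspired models of depth-guided
behaviour.

Praying mantises are the only insects in which stereoscopic vision has been
demonstrated, and their stereo behaviour — turning the head toward the
nearer of two prey-like targets, and striking only when prey sits in the
catch range — can be produced by algorithms far simpler than anything in
the primate or machine-stereo tradition.  No correspondence problem is
solved, no disparity map is built, and no disparity is ever explicitly
estimated; retinal input maps directly to behaviour.  This package
implements two such mechanisms at desk scale, for computational
neuroscientists and bio-inspired-robotics researchers who want executable,
testable versions of the models:

* **Saccade network** — a two-layer, fully linear network.  Input units are
  the two retinae (lat-long grids of azimuth-longitude α and
  elevation-latitude κ); output units encode headcentric directions
  (α_H, κ_H), and a head saccade is made toward the maximally active unit
  (winner-take-all).  Trained by softmax cross-entropy on synthetic scenes
  of four spheres (directions ~ N(0°, 45°), distances ~ U(1, 11) cm, all
  subtending 10° at the origin) labelled with the direction of the nearest
  visible object, it learns disparity-dependent weights: excitation onto
  the unit at α_H from left-eye units with α_L < α_H and right-eye units
  with α_R > α_H — the signature of near objects, for which
  α_L < α_H < α_R and disparity δ = α_R − α_L > 0.  The trained network
  exhibits behavioural binocular fusion (saccades to the cyclopean
  direction (α_R + α_L)/2, not to either monocular image) and a strong
  preference for the stereoscopically nearer of two equal-size targets.
* **Strike sensor** — a single binocular neuron with nasally placed
  centre–surround receptive fields whose lines of sight cross ~2.5 cm
  ahead.  Monocular pathways are spatially low-passed, temporally
  high-passed and rectified (motion-sensitive, contrast-sign-blind); the
  binocular stage is a thresholded sum raised to the 5th power.  It fires
  only for binocular, roughly centre-sized targets near the catch range,
  ignores purely monocular stimulation, and responds far less to "ghost
  pairs" — two distant objects that locally forge the retinal images of a
  single near one — because their second images land in the inhibitory
  surrounds.

Supporting modules provide the fixed-eye Fick-coordinate binocular geometry
(head pose, nodal points, retinal projection, refixation), the synthetic
scene generator and lat-long renderer, executable toy demonstrations of
ideal/strong/weak/no local correspondence, and reproducible experiment
runners with a CLI.

## Worked example

Train the scaled-down network and run the classic two-target experiment —
two spheres of equal 15° angular size at ±15° azimuth, the left one at
4 cm and the right at 8 cm, 1000 noisy presentations:

```
$ stereomantis train --preset scaled_down --seed 1 --out results
$ stereomantis saccade-two-target --weights results/saccade_net_scaled_down_seed1.npz \
      --seed 1 --out results
mean saccade azimuth -15.07 deg (s.d. 1.38); proportion toward nearer target 1.000
```

The mean saccade azimuth sits at the *cyclopean* direction of the nearer
sphere (−15°), although that sphere's centre projects to α_L ≈ −22° in the
left eye and α_R ≈ −8° in the right (geometry you can check with
`stereomantis.project_to_retina`): the network behaves as if it fuses the
two monocular images.  And essentially every saccade chooses the nearer
target even though both targets have identical angular size — distance is
being read from disparity alone.

The toy correspondence table (exact enumeration over monocular inner
products {1, 2, 3}):

```
$ stereomantis toy-fig2
unit                 matched   non-matched
linear                 4.000         4.000
energy                18.667        16.667
thresholded_linear     3.333         3.000
```

A linear binocular unit cannot tell matching from non-matching images even
on average; a squaring or thresholding output nonlinearity makes matched
images stronger on average — weak correspondence, the minimum needed for
disparity tuning in random-pattern stimuli.

Strike-sensor sweeps (`stereomantis strike-sweep --seed 1 --out results`)
tabulate size and distance tuning, vertical-disparity attenuation and
ghost-pair suppression; `stereomantis saccade-map` produces the
near-preference heat-map tables.

## Library use

```python
import numpy as np
import stereomantis as sm

net = sm.train_saccade_network(preset="scaled_down", seed=1)
table = sm.run_two_target_experiment(net, n_repeats=1000, seed=1)
print(table["azimuth"].mean())          # ~ -15 (cyclopean fusion)
print(table["chose_near"].mean())       # ~ 1.0 (near preference)

sensor = sm.make_default_sensor()
stim = sm.build_stimulus("moving_disc", distance=2.5, diameter_deg=10.0)
mean_activity, strikes = sm.run_trial(
    stim, sensor, sm.MonocularPreproc(), np.random.default_rng(1)
)
```

`SaccadeNetworkClassifier` is a scikit-learn-style estimator (`fit`,
`predict`, `decision_function`, `get_params`) over flattened dichoptic
image pairs, so it composes with sklearn tooling.

## Layout

```
src/stereomantis/
  geometry.py     Fick rotations, nodal points, projection, refixation
  scenes.py       grids, spheres, rendering, noise, labelling, scene I/O
  network.py      saccade classifier, training presets, weight files
  strike.py       monocular preprocessing, DoG receptive fields, stimuli
  toy.py          discrete-ensemble units and the sensor lattice
  experiments.py  two-target / preference-map / strike-sweep runners
  cli.py          command-line interface over the above
```
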