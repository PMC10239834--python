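# Methods

## Overview

`cortexflow` simulates the development of motion selectivity along the
primate dorsal visual pathway with a three-stage hierarchy:

1. **Front end (V1 analogue)** — a mosaic of neural-field tiles with
   ON-center/OFF-surround lateral connectivity, trained unsupervised with a
   symmetric Hebbian rule on afferent weights and an *asymmetric* Hebbian
   rule on lateral weights. The direction-selective mosaic (DSMN) is a
   16 x 16 grid of 20 x 20-neuron tiles over 5 x 5-pixel windows; the
   velocity-selective mosaic (VSMN) is a 10 x 10 grid of 48 x 48-neuron
   tiles over 8 x 8 windows with an activity self-decay term.
2. **Mid stage (MT analogue)** — either eight independent cell planes
   (CPNW), each trained on one translational direction with a normalized
   Hebbian rule, or a winner-take-all Hebbian network (HBNW) of 8-neuron
   columns in which only the most active neuron of a column learns.
3. **Output stage (MSTd analogue)** — a 4-class perceptron (model 1), a
   2048-256-156-50-4 MLP (model 2), or a CNN over the 480 x 480
   concatenated VSMN response (model 3; one 36-map 10 x 10 stride-10
   convolution, fully connected layers 350/150/150/100, 8-way softmax).

All stimuli are synthetic random-dot sequences (80 x 80 binary frames):
translation in 8 directions, and radial/rotational optic flow defined by
polar increments `m += v cos(theta)`, `phi += v sin(theta)` about the image
center.

## Neural-field dynamics

Per frame, a tile computes an afferent drive
`A = sigma_a(gamma_aff * W x)`, then iterates for a fixed number of
settling steps

```
eta(s) = sigma_s(A + gamma_exc * E eta(s-1) - gamma_inhb * I eta(s-1) - delta * eta(s-1))
```

starting from the previous frame's settled activity (zeros at sequence
start). Weight updates follow every frame:

```
dW  = alpha_aff * x * eta(t)                          (afferent, symmetric)
dE, dI = alpha * max(0, eta(t) - eta(t-1)) * eta(t-1) (lateral, asymmetric)
```

after which each weight vector is renormalized to a fixed total mass.
The asymmetric rule potentiates connections from neurons active on the
previous frame onto neurons whose activity *rises* on the current frame.
Over training this carves motion-order-specific lateral chains into the
sheet; at inference the carried-over activity of the previous frame feeds
these chains, so the settled response depends on the direction (and, for
the VSMN, speed) of stimulus history, not only on the current frame.

### Activation functions and lateral balance

The sheet nonlinearity is a piecewise-linear sigmoid
`sigma(x) = clip((x - lo)/(hi - lo), 0, 1)` with separate windows for the
afferent and settling stages; both windows and the per-neuron inhibitory
weight mass are explicit parameters, because they select the operating
regime of the sheet:

* the **afferent window** (default (0, 0.08) = roughly twice the mean
  initial weight) lets a single dot drive its best-matching neurons to
  O(1) activity at the start of training, which the competitive
  rich-get-richer afferent learning needs to bootstrap;
* the **settling window** upper threshold sits well above the lateral gain
  (DSMN: 12 with gamma_exc = 21.6; VSMN: 35 with gamma_exc = 50), which
  keeps recurrent excitation modulatory: lateral chains bias and amplify
  afferent-driven activity but cannot ignite or freeze activity on their
  own. With narrower windows the sheet locks into stimulus-independent
  attractors (every response identical); with much wider ones activity
  dies. The lower threshold (0.5) gates sub-threshold neurons to exactly
  zero, keeping the code sparse;
* the **inhibitory mass** (DSMN 40, VSMN 75, vs. excitatory mass 1) makes
  total inhibition exceed total excitation, the ON-center/OFF-surround
  balance that the architecture requires. Normalization preserves these
  masses exactly after every update (conservation is asserted to 1e-9 in
  the tests).

The remaining field parameters (gamma, alpha, radii, settling steps,
epochs) use the published operating point for each mosaic (DSMN:
gamma_exc 21.6, gamma_inhb 1, r_exc 2, r_inhb 5, 10 settling steps,
500 epochs; VSMN: gamma_exc 50, gamma_inhb 1.5, r_inhb 4, decay present,
250 epochs). The VSMN decay coefficient is 0.01, the geometric middle of
the reported usable range (0.1 fails to separate speeds, 0.001 is
unstable).

### Local training sets

Each DSMN tile trains on 24 sequences: a 1 x 1 dot crossing the 5 x 5
window in 8 directions from 3 start positions, with wrap-around. The
default starts are the window center and two corners. Each VSMN tile
trains on 16 sequences: a 2 x 2 dot in 8 directions at speeds 1 and 2.
VSMN tiles always share weights (one trained tile copied across the grid);
DSMN tiles share weights in the desk-scale profile and train independently
in the full-scale profile.

## Mid and output stages

CPNW planes update once per sequence presentation with the
normalization-embedded rule `W <- (W + lr * Z * C) / sum`, reading the
end-of-sequence settled tile response Z. Classification takes the plane
with maximal summed activity, mapped through labels recorded on the
training set. HBNW columns update only their winner (and only the
winner's weights are renormalized); presentation order reshuffles every
epoch. The perceptron uses the mistake-driven multi-class update with a
constant bias feature. The MLP trains by full-batch gradient descent on
softmax cross-entropy (lr 0.1); its mid-stage input features are z-scored
on the training split first, because the sigmoid activities of the
winner-take-all columns occupy a narrow band around 0.5 and the raw scale
leaves the network unable to fit even the training set. The CNN trains with minibatch SGD
(lr 0.01, batch 20, momentum 0.9) on zero-centered inputs (training-set
mean image subtracted); the convolution stage is implemented exactly as a
block reshape plus matrix product because kernel size equals stride.

## Stimulus generator

`place_dots` draws one anchor per exclusion-grid cell (64 dots in 10 x 10
cells for models 1-2; 100 two-pixel squares in 8 x 8 cells for model 3),
uniform within the chosen cells. Translation adds `(v cos a, v sin a)`
per frame modulo the frame side; rendering rounds anchors to the nearest
pixel and wraps, so anchor count is conserved in every frame. Flows
update polar coordinates about the image center; a dot contracted through
the center (radius would go negative) re-seeds at the largest in-frame
radius on its ray, mirroring the translational wrap rule and conserving
density. Overlapping dots paint with binary OR. The standard datasets
are: 15 configurations x 8 directions = 120 translational sequences
(first 10 configurations train, last 5 test); 15 x 4 flow types = 60
(40/20) for models 1-2; 15 x 4 x 2 speeds = 120 (80/40) for model 3, plus
a 240-sequence translational probe set (15 x 8 x 2).

What the generator does *not* emulate: real-scene statistics (texture,
occlusion, contrast variation), spiral or combined flows, observer noise.
Passing tests therefore demonstrate that the architecture extracts motion
structure from idealized dot kinematograms, not robustness to natural
video.

## Desk-scale profile and problem sizes

Two profiles ship. `full` uses the complete epoch counts (tiles
500/250, CPNW 1000, HBNW 10000, perceptron 500, MLP 5000, CNN 350) and
independent DSMN tiles. `fast` — used by the test suite and the
acceptance script — shares DSMN tile weights and divides all epoch counts
by five. The acceptance script retrains every stage
from scratch in each replicate (default one replicate per invocation, the
single-CPU scale; `--n-seeds` enables medians over several).

## Numerical choices

* Settling uses a fixed step count (10), not a convergence criterion;
  activity is carried across frames within a sequence and zeroed at
  sequence boundaries.
* Batched mosaic inference runs in float32 with a numba CSR kernel
  (columns = tile x sequence pairs); per-tile training runs in float64.
  The two paths agree to ~1e-5, verified in the tests.
* Ties in winner selection (HBNW columns, preference maps, perceptron
  argmax) resolve to the lowest index.
* Renormalization guards empty rows and all-zero sums; weights are
  clipped away from exact zero denominators at 1e-300.
* Probe classifiers standardize features on the training split before the
  perceptron (zero mean, unit variance), for conditioning only.

## Known limitations

* The published lateral gains could not be used with unit-mass inhibitory
  normalization: total excitation would then always dominate total
  inhibition and the sheet saturates uniformly for any monotone clamp
  nonlinearity. The mass-preserving normalization described above is this
  package's resolution; the printed gain values themselves are retained.
* The cell-plane read-out (maximal summed plane activity over
  l1-normalized templates) assumes every direction class produces equally
  sharp, equally consistent population responses. The self-organized code
  here is noticeably less consistent for oblique directions (whose
  rendered trajectories are staircase-like), so CPNW held-out accuracy
  saturates well below a cosine-normalized read-out of the same responses;
  see the acceptance report for measured values.
* Velocity (speed) information in the VSMN code is weaker than direction
  information; speed-dependent quantities inherit that weakness.
* Results at the desk scale vary noticeably across seeds; the acceptance
  script's medians are over few replicates by design (single-CPU scale),
  so individual quantities carry several percentage points of replicate
  noise.
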