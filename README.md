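# cortexflow

Hierarchical neural-field models of optic-flow processing in the primate
dorsal ("where") visual pathway.

Neurons in macaque area MSTd respond selectively to full-field optic-flow
patterns — expansion, contraction, clockwise and anti-clockwise rotation —
built up from the local direction signals of V1 and the translational
motion signals of MT. `cortexflow` implements three multi-stage network
models of this hierarchy, for computational neuroscientists who want to
study how motion selectivity can *develop* from unsupervised Hebbian
learning rather than be hand-wired:

* **Model 1** — Direction-Selective Mosaic Network (DSMN, a 16 x 16 grid
  of neural-field tiles trained with asymmetric Hebbian learning) → Cell
  Plane Network (8 direction-tuned planes) → 4-class perceptron.
* **Model 2** — DSMN → winner-take-all Hebbian network (16 x 16 columns
  of 8 competing neurons) → MLP (2048-256-156-50-4).
* **Model 3** — Velocity-Selective Mosaic Network (VSMN, 10 x 10 grid of
  48 x 48-neuron tiles encoding direction *and* speed) → CNN over the
  480 x 480 concatenated response (36-map stride-10 convolution, four
  fully connected layers, 8-way softmax for 4 flow types x 2 speeds).

The core dynamical element is a neural field: a sheet of rate neurons
sharing one image window, with short-range excitatory and longer-range
inhibitory lateral weights, settled for a fixed number of steps per frame:

    eta(s) = sigma( A + g_e * E @ eta(s-1) - g_i * I @ eta(s-1) - delta * eta(s-1) )

Afferent weights learn with the symmetric Hebbian rule
`dW = alpha * x * eta(t)`; lateral weights with the *asymmetric* rule
`dW = alpha * max(0, eta(t) - eta(t-1)) * eta_pre(t-1)`, which wires
motion-order-specific chains and is the sole source of direction
selectivity. All stimuli are synthetic random-dot kinematograms generated
by the package (translation by `(v cos a, v sin a)`; flows by polar
increments `m += v cos theta`, `phi += v sin theta`).

The package also ships the representational analyses used to compare model
layers with the cortical hierarchy: Pearson and Euclidean response
similarity matrices (RSMs), cross-speed RSMs, and linear probes on frozen
layer activations.

## Worked example

Train the full model-1 pipeline at desk scale (shared tile weights,
reduced epochs) and report its staged accuracies:

```python
from cortexflow import pipelines

report = pipelines.run_model(1, profile="fast", seed=1)
print(f"mid-stage held-out direction accuracy: {report['cpnw_test_accuracy']:.2f}")
print(f"optic-flow test accuracy:              {report['flow_test_accuracy']:.2f}")
```

```
mid-stage held-out direction accuracy: 0.12
optic-flow test accuracy:              0.55
```

The first number is the fraction of 40 held-out translational sequences
(5 unseen dot configurations x 8 directions) whose maximally responding
cell plane matches the direction label recorded on the training set; the
second is the 4-class optic-flow accuracy of the perceptron reading the
frozen cell planes on 20 held-out flow sequences. Desk-scale replicates
vary substantially with the random initialization of the single shared
tile (this replicate's mid-stage read-out landed in a weak basin; others
reach ~0.4-0.6 — see "Known limitations" in `docs/methods.md`). The same
entry point runs models 2 and 3; `pipelines.run_speed_variant` swaps the
velocity front end into models 1-2 for the two-speed flow task.

A command-line interface wraps the library:

```
cortexflow generate --config cfg.yaml --seed 1 --out stim/   # TIFF + manifest
cortexflow train    --config cfg.yaml --seed 1 --out run/    # staged pipeline
cortexflow rsm      --config cfg.yaml --seed 1 --out rsms/   # conv1/fc4 RSMs
cortexflow report   --results runs/
```

## Layout

```
src/cortexflow/
  stimuli.py       random-dot sequence generator and datasets
  neural_field.py  the field engine (settling, Hebbian rules)
  mosaic.py        DSMN / VSMN tilings and batched inference
  midstage.py      cell-plane and winner-take-all networks
  classifiers.py   perceptron, MLP, CNN
  analysis.py      RSMs, linear probes, selectivity summaries
  pipelines.py     staged end-to-end runs and profiles
  fixtures.py      tiny deterministic fixtures for testing
  io.py            HDF5 / TIFF / CSV serialization
  cli.py           command-line interface
docs/methods.md    model assumptions, parameters, design notes
```
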