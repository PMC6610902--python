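# gliacap

Information-theoretic analysis of noise-induced glioma differentiation
dynamics: simulate stochastic models of cholera-toxin (CT) induced
differentiation and estimate how many bits the GFAP response carries about
the stimulus.

## The problem

Cholera toxin induces glioma cells to differentiate into normal glia-like
cells; the differentiation marker GFAP reports the outcome.  Both the
stochasticity of intracellular reactions (intrinsic noise) and cell-to-cell
variability (extrinsic noise) blur the mapping from stimulus to response.
Treating the pathway as a communication channel — input: one of 16
composite signals (CT dose × noise setting); output: a single cell's GFAP
response — the *channel capacity*

C = max_w I(signal; response),  0 ≤ C ≤ log2 16 = 4 bits,

measures how many distinct stimulus conditions the response can resolve.
`gliacap` is aimed at computational systems biologists who want a tested,
reproducible pipeline for this kind of analysis: SDE ensemble simulation,
response featurization, kNN mutual-information estimation, capacity
maximization, and subpopulation decompositions.

## What's inside

* **Models** (`gliacap.models`) — three Itô SDE variants of a 10-state
  CT→GFAP network (PKA/CREB, PI3K/AKT/pGSK3β, IL6/JAK2/STAT3 branches, an
  ultrasensitive bistable cyclin D1 switch repressing GFAP), integrated by
  Euler–Maruyama with per-cell RNG streams: additive-noise (**AN**),
  chemical-Langevin (**CLE**, intrinsic √propensity noise + extrinsic
  per-cell parameter perturbations), and **CLE-** (cyclin D1 positive
  feedback inhibited).  Parameters ship in a packaged YAML file — a
  synthetic calibration (see `docs/methods.md`).
* **Descriptors & sampling** (`gliacap.descriptors`, `gliacap.sampling`) —
  max response, max fold change, AUC; fold transformation; symmetric /
  balanced / greedy time-point sampling plans, including a scikit-learn
  `TimepointSampler` transformer.
* **Capacity estimator** (`gliacap.capacity`) — kNN conditional-density
  plug-in mutual information maximized over input distributions by a
  safeguarded Blahut–Arimoto fixed point; scikit-learn style
  `ChannelCapacityEstimator(k=5).fit(X, y)` with `capacity_`, `weights_`,
  `mi_uniform_` attributes.
* **Subpopulations** (`gliacap.subpop`) — terminal-threshold filtering and
  per-signal k-means trajectory clustering (`TrajectoryKMeans`) with
  C1/C2/C3 rank labels and per-cluster capacities.
* **Fixtures** (`gliacap.fixtures`) — synthetic channels with known
  information content (exact discrete channels, Gaussian mixtures with
  quadrature/QMC truth, trajectory toys) for validating the estimator.
* **Pipeline & CLI** (`gliacap.pipeline`, `gliacap` console script) —
  replicated experiments, Welch t-test comparisons, heatmaps/trajectory
  fans/bar charts; verbs `simulate`, `describe`, `fixtures`, `capacity`,
  `cluster`, `run`, `compare`.

## Worked example

```python
import numpy as np
from gliacap import (ChannelCapacityEstimator, SimulationConfig,
                     build_signal_grid, load_model_spec, simulate_ensemble,
                     symmetric_plan, assemble_response_dataset)

spec = load_model_spec("CLE")
ensembles = [
    simulate_ensemble(spec, sig, SimulationConfig(n_cells=200, dt=0.05,
                                                  save_stride=2, seed=100 + i))
    for i, sig in enumerate(build_signal_grid("CLE"))
]
plan = symmetric_plan(len(ensembles[0].time_grid), d=6)
ds = assemble_response_dataset(ensembles, plan)

est = ChannelCapacityEstimator(k=5).fit(ds.vectors, ds.labels)
print(f"vector capacity: {est.capacity_:.2f} bits "
      f"(MI at uniform {est.mi_uniform_:.2f})")
```

Output:

```
vector capacity: 2.56 bits (MI at uniform 1.75)
```

So with 200 cells per signal the 6-point GFAP response vector resolves
about 2.6 of the 4 bits needed to identify the 16 (dose, noise) conditions
— the rest is destroyed by intrinsic and extrinsic noise.  The capacity
exceeds the uniform-input mutual information because the optimizing
weights `est.weights_` shift probability away from mutually confusable
signals.

The same analysis from the shell:

```bash
gliacap simulate --model cle --cells 200 --seed 7 --out sim/
gliacap describe --in sim/ --out descriptors.csv
gliacap run --seed 7 --replicates 3 --cells 300 --out study/
```

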