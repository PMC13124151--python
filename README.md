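# gcresponse

Simulation-based inference of the **affinity–fitness response function** of
germinal-center (GC) B cells.

B cells in a germinal center divide, mutate their receptor (BCR) by somatic
hypermutation, and die under affinity-based selection. The relationship
between a cell's antigen-binding affinity and its division rate — the
affinity–fitness response function — cannot be measured directly, because a
cell's fitness is an emergent property of the whole evolving population.
`gcresponse` recovers it from collections of sampled BCR phylogenies by
likelihood-free inference: a cell-based forward simulator, a neural network
trained on encoded simulated trees, and summary-statistic matching.

## The model

Affinity is measured on a log scale relative to the naive (founder)
sequence, `x = -log10(K_D / K_D^naive)`. The intrinsic birth rate of a cell
with affinity `x` is a four-parameter sigmoid

```
lambda(x) = y_c / (1 + exp(-x_c (x - x_h))) + y_h
```

with steepness `x_c` (xscale), midpoint `x_h` (xshift), dynamic range `y_c`
(yscale) and low-affinity floor `y_h` (yshift). Sequences map to affinities
through an additive (no-epistasis) table of single-nucleotide effects, DMS
style; mutation follows a 5-mer-context hypermutation model; death is
constant, with a much higher rate for stop-codon-bearing sequences. A
carrying capacity `N0` is enforced by multiplying every birth rate by

```
m = (sum_i mu_i / sum_i lambda_i) ** (N / N0)
```

so growth is supercritical while the population is small and critical at
capacity. The simulator is an exact stochastic (Gillespie-type) event loop
over birth, death and mutation.

For inference, each sampled per-GC tree is ladderized with deterministic
tiebreakers, scaled to mean unit depth, and flattened into a 4×200 matrix
(CBLV encoding augmented with per-node affinities). A small convolutional
network maps the matrix — plus three assumed "non-sigmoid" parameters
(carrying capacity, initial population, death rate) — to the sigmoid
parameters, trained with the **curve-difference loss**: the area between
true and inferred response curves divided by the area under the true curve
on the affinity domain [-2.5, 3]. Because the network only infers sigmoid
parameters *conditional on* non-sigmoid values, a second step scans a grid
of non-sigmoid combinations, simulates a "data mimic" sample from each
combination's inferred (medoid) parameters, and selects the combination
whose summary statistics best match the data — the "central data mimic".

## Worked example

```python
import numpy as np
import gcresponse as gr

rng = np.random.default_rng(7)
amap, shm = gr.default_fixtures(rng)          # synthetic DMS + 5-mer SHM model

# simulate one germinal center at the central data-mimic settings
tree = gr.run_simulation(gr.CENTRAL_MIMIC_CONFIG, gr.CENTRAL_MIMIC_PARAMS,
                         amap, shm, rng, trace_population=True)
tr = tree.population_trace
late = tr[(tr[:, 0] >= 15) & (tr[:, 0] <= 20), 1]
print(f"sampled tips: {tree.sampled.sum()}, late population: {late.mean():.0f}")

aff = tree.affinity[tree.sampled]
print(f"sampled affinities: mean {aff.mean():.2f}, range "
      f"[{aff.min():.2f}, {aff.max():.2f}]")
```

prints

```
sampled tips: 70, late population: 491
sampled affinities: mean 1.38, range [-0.14, 2.21]
```

— a GC that grew to its carrying capacity of 500 cells by day ~10 and, by
day 20, has evolved from affinity 0 to a population mean around +1.4 (on
the log10-relative scale, i.e. ~25-fold tighter binding than naive), with
the sampled-cell affinities spanning mildly deleterious to strongly
beneficial mutants.

Training and the two-step scan are a few more lines:

```python
ts = gr.generate_training_set(5000, amap, shm, rng)   # ~2 min, desk scale
model = gr.fit_model(ts)                              # Adam + EMA, 35 epochs
```

A command-line interface mirrors the library:
`gcresponse simulate|trees|train|infer|scan --help`.

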