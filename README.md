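# entrace

Per-cell decomposition of endothelial Ca2+ imaging signals into a **slow
sustained component** (plasma-membrane Ca2+ influx, e.g. through TRPV4
channels) and a **fast oscillatory component** (IP3-receptor-mediated
release from the internal store), with downstream classification of cells
that switch to a dominant sustained plateau and population-level
concentration–response summaries.

It is written for labs doing wide-field Ca2+ imaging of en-face artery
preparations (hundreds of endothelial cells per field), and for anyone who
needs a tested, reproducible implementation of envelope-based trace
decomposition with ground-truth validation.

## The method

Each cell's F/F0 trace `y(t)` is modelled multiplicatively, `y = z · r`:

* `z(t)` — the slow component — is the **asymmetric least squares (ALS)**
  smooth of `y`: the minimiser of
  `Σ wᵢ(yᵢ − zᵢ)² + λ Σ (Δ²zᵢ)²` with `wᵢ = p` where `yᵢ > zᵢ` and `1 − p`
  otherwise (`p = 0.002`), iterated to a weight fixed point. The smooth
  hugs the lower envelope of the trace: oscillation transients are
  rejected, the sustained rise is tracked.
* `r(t) = y(t) / z(t)` — the fast component — fluctuates about 1 and
  carries the oscillations; `y = z · r` holds exactly by construction.

Per cell, the **sustained amplitude** is the mean of `z` over the last
30 s minus the pre-stimulus baseline; a cell is **switched** when its
amplitude strictly exceeds the field threshold (mean + 3 × SEM across
cells). Oscillations are prominence-filtered peaks of `r − 1`; their rate
is compared before and after the switch time. Fields aggregate into
mean ± SD dose–response curves per component, max-normalised sensitivity
curves, and Welch t comparisons between groups (n = fields).

A synthetic-field generator produces traces with exactly this two-component
structure (plus noise, bleaching, and a Poisson photon model at the movie
level) together with full ground truth, so every stage — including movie
segmentation and ROI extraction — is testable without any raw data.

## Worked example

```python
from entrace import (GeneratorConfig, simulate_field, decompose_field,
                     classify_cells)

cfg = GeneratorConfig(n_cells=200, concentration_nmol=30.0, seed=1)
field, truth = simulate_field(cfg)
decomposed, als = decompose_field(field)          # ALS slow/fast split
cells, summary = classify_cells(decomposed, field.time_s)

print(summary.threshold, summary.pct_switched)
```

Output (trimmed):

```
cells analysed:          200
field threshold:         1.451 F/F0
mean sustained amp:      1.284 +/- 0.056 (SEM)
fast component (field):  0.335
switched cells:          19.5%  (true fraction 0.20)
osc freq pre/post switch: 1.98 -> 0.21 events/min (n=39 switchers)
```

The field threshold (1.451 F/F0) is the mean sustained amplitude plus
three standard errors; 19.5% of cells exceed it, recovering the generative
switcher fraction of 0.20. Switched cells oscillate ~2 events/min before
the switch and nearly stop afterwards — the signature of the transition
from store release to sustained influx.

The same pipeline runs from the shell:

```bash
entrace simulate --seed 1 --n-cells 50 --outdir out/sim --movie
entrace extract out/sim/movie.tif --frame-rate 5 --outdir out/ext
entrace decompose out/ext/traces.csv --outdir out
entrace classify out/decomposition.csv --outdir out
entrace run --config config.yaml --outdir out/full   # full pipeline + manifest
```

## Layout

```
src/entrace/
  synthetic.py       field generator + movie renderer (ground truth)
  imaging.py         ΔF/F0 projection, segmentation, ROI extraction
  decomposition.py   banded ALS solver, slow/fast separation
  classification.py  sustained amplitude, switch threshold, oscillations
  population.py      dose-response, normalisation, Welch comparisons
  experiments.py     canned end-to-end simulation experiments
  cli.py, config.py, pipeline.py, io.py, traces.py
docs/methods.md      model, parameter choices, limitations
```
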