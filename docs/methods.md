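# Methods

## Problem and model

Agonist stimulation of the endothelium of an intact artery evokes, in each
cell, a Ca2+ signal with two superimposed components: repetitive fast
transients produced by IP3-receptor-mediated release from the internal
store, and a slow sustained F/F0 rise produced by Ca2+ influx through
plasma-membrane TRPV4 channels. The two components have opposite
physiological readouts (oscillatory release drives dilation; a dominant
sustained influx accompanies impaired dilation), so the analysis problem is
to separate them per cell, quantify each, and detect the subpopulation of
cells that "switch" to a dominant sustained plateau.

`entrace` models an F/F0 trace multiplicatively,

    y(t) = z(t) · r(t),

where `z` is the slow sustained component and `r` the fast oscillatory
component fluctuating about 1. The slow component is estimated by an
asymmetric least squares (ALS) smooth: the minimiser of

    Σ w_i (y_i − z_i)² + λ Σ (Δ² z_i)²,   w_i = p if y_i > z_i else 1 − p,

iterated on the weights to a fixed point. With p ≪ 1 the smooth hugs the
lower envelope of the trace, rejecting upward transients while following
the sustained rise; the fast component is then the ratio `r = y / z`, so the
reconstruction identity `y = z · r` holds exactly at every sample, and fast
amplitudes are reported as `r − 1`.

## ALS parameters

* **λ (smoothness)** — default corresponds to λ = 20 on a 1 Hz recording,
  scaled by `frame_rate^(2·order)` so the smoothing bandwidth is fixed in
  seconds (12 500 at the 5 Hz reference rate, second-difference penalty).
  The value sits in the window dictated by timescale separation: stiff
  enough that an oscillation transient (~1 s decay) or a small cluster of
  transients cannot lift the fit by more than a few hundredths of an F/F0
  unit, yet compliant enough to track a sustained rise developing over
  tens of seconds with relative error below 1%.
* **p (asymmetry)** — default 0.002. Smaller p improves transient
  rejection (the fit's effective stiffness on the upper side scales as
  λ/p) but drags the fit below a steep rise; 0.002 balances the two at the
  default timescales.
* **Iteration** — weights start at 1 (symmetric first pass) and iterate to
  a fixed point, capped at 10 rounds. Under measurement noise a few
  near-boundary weights can flip indefinitely; the fit itself is stable
  after a handful of rounds (results are identical for caps 10–50), so a
  capped run is returned with `converged=False` and a logged warning.
* **Edge handling** — the series is reflection-padded by 10 s on both ends
  before smoothing and the fit truncated back. A transient at the very
  last samples otherwise has no following data to pull the asymmetric fit
  back down, and the boundary ride-up roughly doubles the worst-case slow
  recovery error. `edge_pad = 0` recovers natural boundary conditions.
* **Solver** — the normal equations `(W + λ DᵀD) z = W y` are symmetric
  positive definite and banded (bandwidth = difference order), solved with
  a banded Cholesky routine, O(n) per iteration. The test suite and the
  reproduction script verify agreement with an independently assembled
  dense solve to < 1e−8.

## Classification

* **Sustained amplitude** = mean of `z` over the final 30 s minus its mean
  over a 30 s pre-stimulus baseline window. Referencing the baseline
  window (rather than the constant 1) makes the statistic robust to
  imperfect F0 normalisation.
* **Switch threshold** = field mean amplitude + 3 × SEM across cells
  (default). The pure `3 × SEM` rule without the mean offset is available
  as `threshold_mode="sem_only"`; the run manifest records the rule used.
  Cells strictly above threshold are "switched" (ties are not switched, so
  an all-equal field is unambiguous).
* **Oscillation detection** — peaks of `r − 1` after a 0.6 s moving
  average (a crude matched filter: without it, sample noise alone
  generates spurious prominence-crossing peaks at a rate comparable to the
  true event rate), with prominence ≥ 0.1 and separation ≥ 1.5 s.
  Prominence rather than absolute height gives immunity to residual slow
  leakage in the ratio.
* **Switch time** = first crossing of baseline + 50% of the final
  sustained amplitude (the logistic midpoint of the generative model).
  Pre/post oscillation frequencies are event counts divided by the window
  lengths; an undefined post window is reported as absent, never as a
  division by zero.

## Population aggregation

The unit of replication is the field/artery. Per-field slow amplitude is
the mean sustained amplitude over cells; per-field fast amplitude is the
mean over cells of each cell's mean peak prominence, with quiescent cells
contributing 0. Fields are aggregated per concentration into mean ± SD
dose–response curves; sensitivity comparisons divide each component by its
own maximum over concentrations. Group differences use the two-sided Welch
t test (Satterthwaite degrees of freedom) on per-field values, unadjusted
per comparison. Hill fits (bottom fixed at 0) are provided for recovery
checks only, not used by the pipeline.

## Synthetic data generator

The generator emulates a wide-field recording of an en-face endothelial
field: hundreds of cells, each a multiplicative two-component signal
`z · r · bleach · (1 + ε)`. Defaults describe a 360 s recording at
5 frames/s with agonist present from t = 0:

* Slow influx: logistic rise, onset 120 ± 20 s, τ = 25 s, saturating
  amplitude 1.0 F/F0 units × Hill(concentration; EC50 5 nmol/L, h = 2),
  lognormal cell-to-cell amplitude spread (σ = 0.15).
* Oscillations: homogeneous Poisson events (rate 0.04 Hz × Hill(conc;
  EC50 3 nmol/L, h = 1)), bi-exponential transients (0.3 s rise, 1.2 s
  decay) of amplitude 0.3 ± 0.1 (truncated at 0.05), present from t = 0 —
  oscillatory release begins promptly on stimulation while the sustained
  influx develops slowly.
* Switchers: Bernoulli(0.2 by default); amplitude × 3, oscillation rate
  × 0.1 after the switch time (the logistic midpoint).
* Nuisance: multiplicative Gaussian noise (σ = 0.02); optional exponential
  bleaching; Poisson photon noise available at the rendering stage.

The timescales were chosen once, jointly: the analysis can only separate
the components when transient width (~1 s), typical event spacing
(tens of seconds) and the sustained rise time (~100 s) are well separated,
and these values are simultaneously plausible for Cal-520 recordings of
agonist-stimulated endothelium. The two strain presets differ only in
sustained amplitude (0.8 vs 1.4) and switcher fraction (0.15 vs 0.45);
oscillation amplitudes are identical, encoding the biological contrast the
population analysis is designed to detect.

What the generator does **not** emulate: spatial waves and inter-cell
coupling, motion, focus drift, baseline drift other than exponential
bleaching, non-Poisson (bursting) event statistics, and amplitude–frequency
coupling within a cell. Passing recovery tests therefore demonstrates the
analysis is correct for signals with this two-component structure, not that
it is robust to every artefact of real recordings.

## Reference problem sizes

Simulation-based checks use fields of 200 cells (matching the "hundreds of
cells" regime the analysis targets), 6 fields per strain per concentration
for population contrasts, 20 fields for the switched-fraction recovery
sweep, and 10 seeded replicates of the full two-strain experiment. The
concentration series defaults to {1, 3, 10, 30, 100} nmol/L.

## Known limitations

* The ALS smoother's accuracy degrades when oscillation clusters are wide
  relative to the sustained rise time; the quoted recovery tolerances hold
  for the default timescale separation.
* The mean + 3×SEM threshold adapts to the field: in a field consisting
  mostly of switchers the threshold rises with the mean, compressing the
  estimated switched fraction (the recovery slope is measured over true
  fractions 0.1–0.6 for this reason).
* Fast-amplitude estimates are prominence-based and censored below the
  detection threshold, biasing the per-cell mean upward by ~10% at default
  noise; the bias is common to all groups and cancels in contrasts.
* Segmentation is a deterministic threshold/watershed stand-in adequate
  for well-separated cells; it makes no claim of matching any particular
  laboratory's extraction pipeline.
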