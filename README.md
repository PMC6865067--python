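# delaysum

Analysis and modelling toolkit for the *delay-and-summate* account of motion
computation by ON direction-selective (ON DS) retinal ganglion cells: how a
population of glutamatergic inputs with no direction preference of their own
— bipolar-cell boutons and glutamatergic amacrine inputs, spatiotemporally
organised along the cell's motion-preference axis — sums into speed- and
direction-selective excitation.

The package is aimed at retinal and systems-neuroscience modellers. It
provides, as an importable library:

- **Synthetic ground truth** — circuits of glutamatergic units in six
  kinetic groups (G1 fast-transient … G5 slow-sustained, G6 slow
  amacrine-like), with a spatial double gradient (slow→fast and
  sustained→transient from the preferred to the null side of the dendritic
  field), plus the standard visual stimuli (dense noise, static and moving
  spots/bars, four-phase modulating flash) and fluorescence-movie /
  summed-current synthesis with planted ground truth.
- **ROI detection** for two-photon glutamate-imaging movies (Gaussian
  smoothing, 0.7 downsampling, baseline mean + 3 SD responsive mask,
  correlation grouping, 1–10 µm² bouton size filter) and dendritic-field
  geometry (convex-hull centre, positional histograms).
- **Receptive fields** by reverse correlation: the space–time volume
  F(x, y, τ) = ⟨r(t) S(x, y, t−τ)⟩, independent-noise control thresholds,
  the stRF profile along the preference axis, per-column peak/activation
  times, and the tilt slope Δs/Δµm whose inverse predicts the optimal
  stimulus speed.
- **Response metrics** — DSI = (R_pref − R_null)/(R_pref + R_null) in
  amplitude and charge, decay-change index DCI, exponential decay fits,
  frequency/contrast sensitivity from the modulating flash, Gaussian-fit
  speed tuning.
- **Clustering** — sparse PCA (cardinality-constrained) on flash responses,
  Gaussian mixtures with BIC = −2 ln L + k ln n order selection, and
  hierarchical similarity (five kinetic features, or 1 − Pearson distance on
  mean traces under pharmacological-blockade emulation).
- **The model** — each unit is a separable linear filter (2-D Gaussian
  spatial RF × temporal kernel); its linear response is modulated past the
  peak by the double-decay envelope exp(−t/τ₁) − exp(−t/τ₂); unit outputs
  are sorted from the preferred to the null side and summed. Shuffled
  (positions permuted) and sustained (transient kinetics replaced) control
  variants and the RMS error between model and reference DSI curves are
  included.

## The model in brief

For stimulus contrast s(x, y, t) a unit's input is the linear convolution

    i(t) = ∫ s(x, y, t − τ) F(x, y, τ) dτ dx dy,

with F separable into a Gaussian spatial profile and a peak-normalised
temporal kernel whose latency decreases from the preferred to the null side
at 5 ms/µm. After its peak, i(t) is multiplied by the normalised envelope
exp(−t/τ₁) − exp(−t/τ₂). Summing all units, the *peak* of the summed trace
is direction- and speed-selective — maximal when the stimulus speed matches
ΔS/ΔT = 200 µm/s of the delay gradient — while its *time integral* (charge)
is exactly direction-invariant for the linear stage: the signature of
preferred-direction enhancement.

## Worked example

```bash
python examples/speed_tuning_model.py
```

prints (abridged):

```
reference circuit: 193 units
   speed  amp pref  amp null  DSI amp  DSI chg
     100      6.36      4.06    0.221   0.0000
     150      8.36      4.91    0.260   0.0000
     200      8.83      5.43    0.238   0.0000
     250      8.62      5.71    0.203  -0.0000
     300      8.35      5.86    0.176   0.0000
     500      7.04      5.45    0.127  -0.0000
     800      5.26      4.67    0.059   0.0000
    1600      3.05      3.11   -0.011   0.0000

optimal speed (argmax of preferred amplitude): 200 um/s
amplitude DSI at 150 um/s: 0.260
```

The summed input prefers slow preferred-direction motion with an optimum at
200 µm/s — the speed encoded by the circuit's spatial delay gradient — and
an amplitude DSI around 0.26 at 150 µm/s, while the charge DSI stays at
zero. `examples/` contains similar narrative scripts for the two-unit
enhancement pair, ROI detection, kinetic-group clustering and the stRF tilt.

A thin CLI orchestrates end-to-end runs:

```bash
delaysum all --seed 1 --outdir run1     # generate → detect → rf → … → report
```

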