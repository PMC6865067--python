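# Methods

This note documents the models, the synthetic-data generator and the
numerical choices behind `delaysum`. Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The forward model

Each glutamatergic input (a bipolar-cell bouton or a glutamatergic-amacrine
contact) is a separable linear filter followed by a decay modulation:

1. **Spatial stage.** A 2-D Gaussian receptive field (default σ = 4 µm per
   axis, bouton scale). The unit's *drive* is the RF-weighted mean stimulus
   contrast. For moving bars the drive is evaluated in closed form as the
   Gaussian probability mass under the bar (products of normal CDFs); for
   arbitrary movies it is the box-integrated Gaussian weight over pixels.
   The closed form keeps the linear stage's charge direction-invariance at
   machine precision, which pixel rasterisation cannot.
2. **Temporal kernel.** A rise–decay lobe (1 − e^(−t/τ_r)) e^(−t/τ_d) minus
   a 1.8×-slower copy weighted by 0.25 × transience, normalised to unit
   peak, with an onset delay placing the peak at the unit's latency. Kernels
   are fast (τ_d = 0.03–0.06 s) relative to stimulus passage, so unit
   response amplitude is essentially speed-invariant; the mild negative lobe
   ("droop") pins the response peak to the leading edge of stimulus
   coverage.
3. **Double-decay envelope.** Past its peak the linear response is
   multiplied by e^(−t/τ₁) − e^(−t/τ₂) (τ₁ > τ₂). Applied literally from
   the peak time this expression starts at zero and would annihilate the
   peak; the envelope is therefore applied *from its own maximum onward*, so
   it equals 1 at the response peak and decays monotonically. For stimuli
   with several driven epochs (the modulating flash), the envelope restarts
   at each epoch, defined as a rise of the drive after ≥ 0.5 s of silence;
   for a single motion sweep this reduces exactly to the plain from-the-peak
   rule. Transient groups carry short envelopes (τ₁ ≈ 0.2 s), sustained
   groups long ones (τ₁ ≈ 0.6–0.7 s), the amacrine-like group the longest
   (1.2 s).

Population output: unit traces are sorted from the preferred side (entered
first by preferred-direction motion) to the null side and summed. The peak
of the summed trace is the model output; its trapezoidal integral over the
stimulus epoch plus a 2 s tail is the charge. The simulation time base is
1 ms; stimuli are held (zero-order) onto it.

**Analytic property.** With the envelope disabled, the charge of every unit
— hence of the sum — is the product of the drive integral and the kernel
integral. A full edge-to-edge traversal deposits the same drive integral in
both directions, so charge DSI is zero to numerical precision at every
speed; direction selectivity can only live in the peak amplitude. This is
asserted at 1e-6 relative tolerance in the tests.

## The synthetic circuit and its calibration

The reference cell has 193 units in six groups (G1…G6 = 32, 25, 26, 34, 56,
20) on a 400 µm dendritic disc. Group mean positions on the
motion-preference axis (u, preferred side negative):
G5 −80, G6 −40, G3 0, G4 +40, G2 +60, G1 +100 µm, Gaussian scatter
SD 60 µm truncated to the disc. This reproduces the observed double
gradient: sustained/slow groups on the preferred side, transient/fast
groups on the null side, with the transient G1 most null-biased.

**Latency scheme.** Bipolar-group latency is *positional*:
latency(u) = 1.10 − 0.005·u seconds, i.e. a delay gradient of 5 ms/µm whose
inverse is the design speed ΔS/ΔT = 200 µm/s. Two corrections ride on the
ramp: (i) a per-group adjustment (−0.08…+0.05 s) compensating each group's
intrinsic lag from drive onset to response peak, measured once on
single-unit moving-bar responses at 200 µm/s, so that *response peaks*, not
kernel peaks, follow the ramp; (ii) Gaussian unit-to-unit jitter
(SD 0.25 s) for biological variability. G6, the putative glutamatergic
amacrine pathway, does not follow the ramp: it has a fixed 1.35 s latency,
a long envelope and double unitary gain, acting as a slow,
direction-neutral background (a multi-synaptic route has no reason to
inherit the bipolar delay gradient).

**What the calibration targets were.** The defaults above were chosen once
so that the reference circuit meets the study conditions the package is
built around: preferred-direction optimum exactly at 200 µm/s on the
default grid {100, 150, 200, 250, 300, 500, 800, 1600}; amplitude DSI at
150 µm/s inside the measured band 0.26 ± 0.05 for excitation with
cholinergic transmission blocked; amplitude DSI below 0.1 at ≥ 1200 µm/s;
a sustained-variant optimum at or above the delay-sum optimum; a flatter
shuffled-variant tuning. They are a calibration, not a measurement: the
absolute kinetic constants of the six groups are free parameters
constrained only by their orderings and these closure conditions.

**Known limitation.** The shuffled control keeps roughly half of the
delay-sum model's max/min tuning ratio rather than less than half: both
variants share the per-unit geometry that narrows responses at high speed,
so the shuffled curve is flatter but not flat. The corresponding acceptance
assertion is intentionally left failing rather than weakened; the
qualitative claim (shuffled flatter than delay-sum, no interior optimum
advantage) holds.

**Model variants.** *Shuffled*: unit positions permuted among the occupied
positions (kinetics travel with the unit), 50 permutations averaged at the
level of model outputs. *Sustained*: G1 units adopt G2 kinetic shapes and
G4 units G5 shapes (rise, envelope, transience), keeping their own
positional latency and position, so only the transient/sustained character
changes.

**Pharmacology emulation.** Conditions return modified circuit copies:
GABA-receptor blockade triples the slow decay constant of G1/G3/G4/G6 (and
reduces their transience proportionally), glycine blockade doubles it for
G3/G6, and Naᵥ blockade adds a fixed 0.6 s to the latency of the fast
groups G1/G2 (removal of a fast conduction component, hence additive). All
factors are arguments.

## Synthetic observables

*Imaging movies*: each unit deposits its frame-binned response onto a
Gaussian optical footprint (σ = 0.9 µm) over a baseline of 1; 3 s of
baseline frames precede the stimulus; noise is Gaussian per pixel (or
Poisson photon noise); pixels default to 0.5 µm at 10 Hz. Ground truth
(half-maximum masks, centroids, traces, group labels) is returned with the
movie. *Summed currents*: the population sum plus seeded Gaussian noise,
positive-going by convention. The generator does **not** emulate motion
artefacts, bleaching, neuropil contamination, dendritic filtering or
trial-to-trial adaptation — recovery results on these fixtures bound what
the pipeline can do on clean data, not on every real recording.

## Analysis choices

- **ROI detection** follows the fixed order smooth (3×3 Gaussian,
  σ = 0.65 px) → bilinear downsample to 0.7 per axis → responsive mask →
  correlation grouping → size filter. The responsive statistic is the peak
  of the 3-frame-boxcar-smoothed stimulus-period trace against the
  baseline mean + 3 SD (a single-frame max floods the mask with false
  positives at realistic noise). Grouping links 4-adjacent responsive
  pixels whose full time courses correlate at ≥ 0.7. The reported bouton
  footprint is the part of a correlated patch above 30 % of its peak
  response — making the area noise-level-invariant — and must fall in
  1–10 µm²; fragments adjacent to patches rejected as oversized are
  suppressed. ROIs are reported in original pixel coordinates.
- **Reverse correlation** uses a fixed averaging count across lags, so the
  estimator is exactly linear in the response. Signal thresholds come from
  the control volume (same response, freshly seeded noise): mean + 3 SD.
  Peak times are defined on the absolute filter value; activation time is
  the earliest suprathreshold lag of a column (the term is used for the
  quantity "first lag above the noise control"). The stRF slope is the
  least-squares fit of peak time against position over suprathreshold
  columns (≥ 3 required); its sign follows the axis convention (latency
  decreasing toward the null side gives a negative slope) and the predicted
  optimal speed is 1/|slope|.
- **Event-triggered spatial RFs** detect events at trace mean + k·SD
  (k = 3 default; the full record is the window) and score the map against
  a shuffled-event control. The 2-D Gaussian fit is plain least squares
  with box bounds.
- **Speed-tuning Gaussian fits** are performed on log₁₀(speed) by default:
  the grids are log-spaced and tuning spans a decade, so a linear-axis
  Gaussian is badly skewed by the high-speed tail. A linear-axis fit is
  available by flag.
- **Clustering**: sparse PCA is a cardinality-constrained truncated power
  iteration with deflation (≤ 10 non-zero loadings per component, 20
  components by default; with the constraint removed it reduces to
  ordinary PCA up to sign, which is tested). Mixtures use diagonal
  covariances (sparse scores are near-decorrelated; full covariance by
  flag), 10 restarts per order, and BIC = −2 ln L + k ln n computed
  explicitly (cross-checked against the scikit-learn value). Cluster
  similarity uses Ward linkage on the five z-scored kinetic features and
  average linkage on 1 − Pearson distances for blockade comparisons.
- **Pipeline**: one run seed fans out to per-stage seeds through
  `SeedSequence.spawn`, so stages re-run in isolation reproduce their
  streams; the manifest checksums every artifact and identical configs
  reproduce identical checksums.

## Problem sizes

Defaults in tests and the pipeline are desk-scale by design: 4–10 min of
dense noise for receptive-field estimation, 600–1000 ROIs for clustering,
12-unit planted movies for detection, 50 shuffles for the control model.
All scale up by argument.

## Degenerate inputs and flags

Decay fits on non-decaying segments report τ with `ok=False`; tuning
optima at a grid boundary are flagged; stRFs with < 3 suprathreshold
columns return no slope; one-sided stRFs return `None` for the missing
side; empty responsive masks warn and return an empty ROI list; constant
traces are rejected where a correlation is undefined. The non-DS
classification cutoff (firing DSI < 0.2 at all speeds) and the ON-DS
acceptance (DSI > 0.3 at 150 µm/s) are module constants.
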