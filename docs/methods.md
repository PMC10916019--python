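# Methods

## Signal model and pipeline

A spermatozoon held on the aperture of a hollow AFM cantilever transmits
the z-component of its flagellar thrust to the lever. The photodetector
voltage `V(t)` is converted to force by `F = V · S · K` (S: deflection
sensitivity, nm/V; K: spring constant, nN/nm ≡ N/m). The residual suction
holding the cell bends the lever by a constant amount; this is treated as
a baseline and removed by mean subtraction (a least-squares linear detrend
is available via `detrend="linear"` for drifting records; both leave the
oscillatory content untouched). Since only variance enters downstream,
the choice matters only for records with genuine drift.

Band decomposition multiplies the full complex FFT spectrum by the
indicator of one band at a time and inverse-transforms. Properties that
follow and are enforced by tests: each band signal is exactly the
band-limited component of the input (no phase distortion), the bands plus
the out-of-scheme residual reconstruct the input to floating precision,
and the operation equals circular convolution with the ideal band kernel.
Band edges are half-open `[3k, 3k+3)` Hz so every spectral bin belongs to
exactly one band; the printed labels ("0–2 Hz", …) follow the instrument
convention for integer bins. The DC bin is excluded from every band:
static bending is baseline, not beating, and including it would couple the
first band's maximum to residual offset.

The per-band endpoint is `max |F_band(t)|` over the recording with a
1 s guard trimmed from each end (rectangular spectral masking rings at the
edges of a finite record; 1 s covers the ringing of a 3 Hz-wide ideal
filter). Magnitude rather than signed maximum is used because the sign
only encodes the instantaneous swimming direction relative to the lever;
a peak-to-peak option (`statistic="ptp"`) exists for sensitivity analysis.
No window/taper is applied before the FFT — band isolation with exact
reconstruction is the goal, not spectral-density estimation; a taper would
destroy the reconstruction identity.

## Thermal-noise calibration

`K = β · k_B T / Var(z)` with `Var` the unbiased sample variance of the
free-lever deflection in nm and `k_B = 1.380649 × 10⁻⁵ nN·nm/K`. The
mode-shape factor β defaults to 1 (ideal point mass); the standard
first-flexural-mode value for a rectangular lever (≈ 0.817) can be passed
by the caller. The synthetic thermal trace is Gaussian white positional
noise at the equipartition variance: the estimator uses only total
variance, so the spectral shape of a real damped oscillator is
irrelevant to its contract, and a flat spectrum keeps the oracle closed
form.

## Quality control

The instrument protocol excludes cells that cease moving mid-recording
(originally judged from simultaneous video). Here the detector is
trace-based: the force is band-limited to 0–30 Hz (DC excluded), tiled
into contiguous 5 s windows, and a window is active when its RMS is at
least 0.05 nN. A cell fails when its active fraction is below 0.5 or when
an all-inactive run longer than 20 s reaches the end of the trace
(cessation; resolution is one window). All four numbers are detector
settings, not instrument constants. With the default circular phenotype
(burst duty 0.3) the active fraction sits near the 0.5 boundary by
construction, so a small fraction of healthy sparse beaters is excluded —
a conservative bias consistent with dropping doubtful traces. Excluded
cells stay in the QC report with `passed=False` for auditability.

## Group statistics

Per band: Kruskal–Wallis on midranks with tie correction (p from the
χ² approximation), then Dunn's pairwise z-tests on the pooled midranks
with tie correction, two-sided, Bonferroni-adjusted over all pairs
(the convention packaged with "Dunn's comparison" in common
statistics software; `adjust="none"` is available). Stars: p ≤ 0.05 (\*),
≤ 0.01 (\*\*), ≤ 0.001 (\*\*\*). Fully tied data degenerate to H = 0,
p = 1 rather than erroring. Box summaries use linear-interpolation
quartiles. Each band is annotated on its own with no cross-band
multiplicity correction — deliberate, matching per-band annotation
practice, and stated here prominently: across 10 bands, ~0.4 falsely
starred bands are expected per null comparison at α = 0.05.

## Synthetic cohorts

Each cell's force is
`baseline + Σᵢ Aᵢ · envᵢ(t) · sin(2πfᵢt + φᵢ) + N(0, σ²)`, converted to
volts by `V = F/(S·K)` with nominal constants S = 20 nm/V, K = 0.3 nN/nm.
The envelope is a slow raised-cosine modulation
`(1 − cos(2π·f_am·t + ψ))/2` (orientation drift; f_am = 0.05 Hz, random
phase ψ per cell and component, so each frequency peaks at a different,
seed-dependent time) gated by an on/off burst process (5 s segments,
Bernoulli with the profile's duty, 0.5 s raised-cosine ramps). Defaults:

| parameter | linear | circular | why |
|---|---|---|---|
| components (Hz) | 1, 4, 7, 10, 13, 25 | same | spread over the beating range, one per occupied band |
| amplitudes (nN) | 0.60, 0.45, 0.35, 0.30, 0.25, 0.15 | 40% of linear | low band anchored at the human 0–2 Hz force scale (~0.6 nN), decaying upward |
| burst duty | 1.0 | 0.3 | continuous vs. sparse bursts of the two motility classes |
| noise σ (nN) | 0.05 | 0.05 | optical-lever force noise at K = 0.3 N/m |
| baseline (nN) | −0.5 | −1.5 | suction bending; magnitude irrelevant after subtraction |

Across a cohort, per-cell component amplitudes are jittered log-normally
with CV 0.33 and mean preserved (matching a 0.6 ± 0.2 nN dispersion and
keeping forces positive). Cohorts mirror the study structure
(16 linear tail-trapped + 10 linear head/midpiece-trapped + 17 circular;
120 s at 1000 Hz per cell). `generate_cohort(..., return_truth=True)`
exposes the realized per-cell amplitudes for recovery studies.

What the generator does **not** emulate: hydrodynamics or flagellar
waveform mechanics, trapping-pressure dynamics, inter-donor effects,
harmonic coupling between components, 1/f drift, or video-observable
behavior. Passing tests therefore demonstrate that the analysis recovers
what this signal model encodes — band-limited amplitudes under amplitude
modulation, bursting and white noise — not that it is robust to every
artifact of real recordings.

## Replicated studies at the statistic level

The calibration (type-I error) and power of the group comparison are
measured over thousands of replicate cohorts. These replicates are drawn
by `simulate_band_force_table`, which samples each cell's per-band maximum
directly from the generator's amplitude distribution (profile amplitude ×
log-normal jitter; sensor-noise floor 0.02 nN in unoccupied bands) instead
of synthesizing and decomposing full traces. The trace pipeline maps each
cell deterministically to approximately these values and preserves
exchangeability across group labels, so the rank tests' operating
characteristics are identical; the single-cohort recovery study ties the
table-level distribution to the full trace pipeline. Sizes used: 2000
cohorts (43 cells each) for null calibration, 200 replicates for power —
chosen to put Monte-Carlo error well below the effects measured.

## Numerical choices and degenerate inputs

- Half-open band edges; exact-divisor check on the band width (1e-9
  tolerance); schemes beyond Nyquist rejected.
- `irfft` guarantees real band signals; the residual is computed from its
  own complementary mask so the reconstruction identity is a genuine
  cross-check, not a subtraction tautology.
- Trace files store 9 significant digits (exact for float32-class data);
  time is validated uniform within 1 ns on read.
- Degenerate statistics: all-identical observations give H = 0, p = 1;
  zero-variance thermal series and empty groups raise informative errors.
- All generators are deterministic given a seed; cohort seeds derive from
  a `SeedSequence` spawn per cell.

## Known limitations

- The amplitude-recovery of the smallest configured band amplitude
  (0.06 nN, circular 24–26 Hz) is biased upward by roughly 10–15%: the
  maximum statistic rides band-limited noise extremes (~0.01 nN over a
  2-minute record) when the beat amplitude is within an order of magnitude
  of the noise floor. This is inherent to a max-based endpoint at low
  signal-to-noise, and it is visible in the recovery numbers the
  acceptance script reports.
- The QC detector is a proxy for video-based exclusion and cannot
  distinguish a cell that stops beating from one that reorients into the
  cantilever plane (both lose z-signal).
- The χ² approximation to the Kruskal–Wallis null is used throughout;
  for the cohort sizes here its type-I error is within Monte-Carlo error
  of nominal (measured in the acceptance run), but very small groups
  (n ≲ 5) would need exact permutation p-values, which are not
  implemented.
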