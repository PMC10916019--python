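# flagellabeat

Analysis of the forces a single swimming spermatozoon exerts while held on
the hollow cantilever of a fluidic force microscope (FluidFM). A trapped
cell's flagellar beating deflects the cantilever; the recorded photodetector
voltage trace encodes the z-component of the beating thrust. This package
turns such traces — real or simulated — into per-cell, per-frequency-band
maximum beating forces and compares them across motility phenotypes
(linear vs. circular swimmers) and semen-sample groups.

## Method

1. **Calibration.** Voltage to force via `F (nN) = V (V) · S (nm/V) · K
   (nN/nm)`, with deflection sensitivity `S` measured on-instrument and
   spring constant `K` estimated by the thermal-noise method: for a free
   cantilever in thermal equilibrium, equipartition gives
   `K = k_B T / ⟨z²⟩`. The constant suction-induced bending is a baseline
   and is subtracted (mean removal by default).
2. **Band decomposition.** The force trace is FFT-masked into contiguous
   3 Hz bands covering the human flagellar beating range 0–30 Hz
   (0–2 Hz, 3–5 Hz, …, 27–29 Hz) and inverse-transformed, keeping real and
   imaginary parts so each band signal is the exact band-limited component
   of the trace. The DC bin is excluded (it is baseline, not beating).
3. **Per-band statistic.** Because the cell's orientation modulates how
   much thrust reaches the cantilever, the per-band endpoint is the
   maximum absolute force over the recording, `max_t |F_band(t)|`.
4. **QC.** Cells that cease to move mid-recording are excluded, detected
   from the trace by sliding-window RMS activity.
5. **Statistics.** Per band: Kruskal–Wallis omnibus test across groups,
   Dunn's post hoc pairwise comparisons (Bonferroni-adjusted), starred at
   p ≤ 0.05 (\*), ≤ 0.01 (\*\*), ≤ 0.001 (\*\*\*).

A synthetic-trace generator emulates cohorts of both phenotypes
(band-limited oscillatory thrust, orientation-dependent amplitude
modulation, burst-mode beating, suction baseline, sensor noise), since
instrument recordings are not redistributable.

## Worked example

Simulate a 43-cell cohort (26 linear, 17 circular swimmers, 120 s at
1000 Hz each), run the full pipeline, and compare phenotypes:

```sh
flagellabeat simulate --out-dir out --seed 2
flagellabeat compare --table out/band_force.csv --group-by phenotype --out-dir out
```

which prints, per band, the group summaries and test results:

```
    band  group_a group_b  n_a  n_b  median_a_nN  median_b_nN      kw_H         kw_p  dunn_p_adj stars
  0–2 Hz circular  linear   17   26     0.254373     0.486822 24.435006 7.685935e-07 7.685935e-07   ***
  3–5 Hz circular  linear   17   26     0.194783     0.423105 25.177293 5.229429e-07 5.229429e-07   ***
 ...
15–17 Hz circular  linear   17   26     0.014963     0.014755  0.002468 9.603773e-01 9.603773e-01    ns
```

Reading: in the 0–2 Hz band the median maximum beating force of linear
swimmers (0.49 nN) exceeds that of circular swimmers (0.25 nN), and the
Kruskal–Wallis/Dunn comparison stars the difference at p ≤ 0.001; bands
where neither phenotype beats (e.g. 15–17 Hz) sit at the sensor-noise
floor and are not significant. `out/` also contains `band_force.csv` (one
row per QC-passing cell, one column per band), `qc_report.csv` (every
cell, excluded ones flagged), and the simulated `.trace.tsv` files —
plain-text traces with a `# key=value` header that `flagellabeat analyze
--input-dir` accepts back.

Spring-constant calibration from a free-cantilever thermal trace:

```sh
flagellabeat calibrate --thermal-trace thermal.txt --temperature-k 298
k = 0.297927 N/m
```

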