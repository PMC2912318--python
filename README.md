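# gammapen

Approximate-entropy (ApEn) complexity analysis of stimulus-evoked
hippocampal gamma oscillations, as a tested, reusable pipeline:

- **synthetic_lfp** — seeded generator of tetanus-evoked field potentials
  (stimulus artifact, ≥100 ms latency, ~60 Hz gamma burst over 100–300 ms
  post-stimulus, irregular tail, pink background noise) with
  condition-dependent regularity (control / nicotine / washout) and a
  calibration routine that inverts the regularity → ApEn mapping.
- **preprocess** — stimulus-artifact blanking (linear interpolation),
  anti-aliased decimation to 2 kHz, piecewise linear detrending (100 ms
  knots), zero-phase 4th-order Butterworth 30–300 Hz band-pass.
- **gamma_segment** — isolation of the 150–250 ms post-stimulus window,
  Hann periodogram on a 1 Hz grid, dominant-frequency and
  gamma-dominance checks.
- **apen_core** — from-scratch ApEn (m = 2, r = 0.1 × SD by default,
  Chebyshev distance, self-matches included) plus a deliberately naive
  O(N²) brute-force oracle used to validate it.
- **group_stats** — per-condition means ± SEM, paired two-tailed t-tests
  (with Wilcoxon signed-rank companions), end-to-end orchestration.
- **signal_io** — domain types and the plain-text on-disk format
  (CSV trace + flat JSON sidecar).

Shipped per-condition generator parameters (`src/gammapen/params/*.json`)
were produced by `scripts/calibrate_params.py` so that a simulated
14-slice cohort reproduces the target group means
(control ≈ 0.49, nicotine ≈ 0.42, washout ≈ 0.46; nicotine < control at
p < 0.05, paired).

## CLI

```bash
gammapen simulate   --out-dir cohort/ --n 14 --seed 1
gammapen preprocess --in cohort/ --out clean/
gammapen segment    --in clean/ --out segs/
gammapen apen       --in segs/ --m 2 --r-coeff 0.1
gammapen pipeline   --simulate --n 14 --seed 1 --out report.json --csv perslice.csv
# or run on files:  gammapen pipeline --in cohort/ --out report.json
```

`pipeline` prints per-condition means ± SEM and all three pairwise
p-values, and writes a full JSON report (config, per-trace QC, summaries,
comparisons).

## Data format

Each recording is a pair of files: `<name>.csv` with header
`time_ms,voltage_uV` (one sample per row) and `<name>.json` with keys
`fs`, `stim_time_ms`, `condition` (`control` | `nicotine` | `washout`)
and `slice_id`. Analysis windows are half-open `[t0, t1)` in ms relative
to stimulus onset.
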