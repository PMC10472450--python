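# bcgkit

Detection of the **IJK-complex** in single-channel ballistocardiogram
(BCG) signals, with downstream beat-to-beat heart rate, heart-rate
variability (HRV) and waveform-morphology estimation.

The BCG is the whole-body micro-vibration produced by cardiac blood
ejection, recordable without skin contact by pressure sensors in beds,
chairs or scales. Each heartbeat leaves a W-shaped H-I-J-K-L deflection
whose central IJK-complex (negative I trough, dominant positive J peak,
negative K trough) indexes cardiac ejection: the I-J amplitude tracks
stroke volume and the I-K interval the complex width. Most BCG
algorithms only estimate inter-beat intervals; `bcgkit` localizes the
actual I, J and K sample positions, which is what morphology-based
applications (atrial-fibrillation screening, cuffless blood-pressure
timing, heart-failure monitoring) require. The package is aimed at
biomedical-signal researchers working with unobtrusive cardiac sensors.

## Method

Detection fuses two complementary views of the filtered (1–20 Hz) BCG,
processed in 10 s segments with 2 s pads:

1. **STFT band-energy locator.** S(t) = Σ<sub>ω∈[4.5,7] Hz</sub>
   |STFT<sub>x</sub>(t, ω)| is computed at every sample with a Hann
   window whose length w<sub>t</sub> is grown adaptively from 0.3 s in
   0.1 s steps until every candidate peak of S(t) exceeds 3× all other
   local maxima within ±w<sub>t</sub>/2. Peaks of S(t) at least 0.3 s
   apart are robust but temporally blurred beat candidates.
2. **EEMD peak extraction.** Ensemble empirical mode decomposition
   (noise ratio N<sub>std</sub> = 3 %, ensemble size N<sub>E</sub> = 100)
   separates in-band noise from the cardiac mode, which preserves the
   true IJK positions. Peaks of the cardiac IMF are extracted with a
   deliberately low threshold — half the median of the eight largest
   normalized maxima, no distance constraint — trading false peaks for a
   near-zero miss rate.
3. **Regional-search fusion.** Each S(t) candidate is snapped to a
   flanking IMF peak: the unique peak within ±40 ms if one exists; the
   nearer if both qualify; otherwise the candidate has been dragged
   toward a dominant H or L wave and the drift direction is taken from
   the median of the last 9 signed offsets, with a nearest-point
   override when the trend-consistent peak is more than twice as far as
   the other. I and K are the first sufficiently deep minima flanking J
   with a zero crossing in between; positions are refined on the raw
   filtered signal, rhythm outliers interpolated, pad regions trimmed.

Agreement with an ECG reference is summarised by MAE, MAE% = 100·MAE/ȳ,
RMSE, and Bland-Altman bias ± 1.96 SD; HRV indices (mean, SDNN, pNN50,
MSSD, CV, LF/HF/TP band powers) are computed identically for ECG R-R and
BCG J-J series.

Because bed-sensor recordings of this kind are not publicly deposited,
the package ships a synthetic generator (`bcgkit.simulate`) producing
annotated records with the structure the detector must survive:
Gaussian-lobe HIJKLMN complexes (optionally with H/L rivalling J),
RSA-structured inter-beat intervals, residual 0.3 Hz respiration,
broadband noise, motion-artifact bursts, and a paired ECG R-spike train.

## Worked example

```python
from bcgkit import (SimConfig, simulate_record, detect_ijk, RunConfig,
                    preprocess_ecg, detect_r_peaks, paired_heart_rates,
                    agreement, hrv_summary)
from bcgkit.pipeline import evaluate_against_truth, jj_series

record, truth = simulate_record(SimConfig(seed=1))     # 60 s, ~60 bpm
ann, report = detect_ijk(record, RunConfig(rng_seed=1), return_report=True)

m = evaluate_against_truth(ann, truth.annotations.j_indices, record.fs)
print(f"beats detected: {ann.n_beats} (true: {truth.annotations.n_beats})")
print(f"J hit rate (±20 ms): {m['hit_rate_pct']:.1f}%  timing MAE: {m['timing_mae_ms']:.2f} ms")

ecg = preprocess_ecg(record)
r = detect_r_peaks(ecg)
hr_ref, hr_test, matching = paired_heart_rates(r, ann, record.fs)
rep = agreement(hr_ref, hr_test)
print(f"HR MAE vs ECG: {rep.mae:.2f} bpm  RMSE: {rep.rmse:.2f} bpm  "
      f"coverage: {matching.coverage_pct:.1f}%")
s = hrv_summary(jj_series(ann))
print(f"JJ mean {s.mean_s:.3f} s  SDNN {s.sdnn_s*1000:.1f} ms  pNN50 {s.pnn50:.2f}")
```

Output:

```
beats detected: 60 (true: 60)
J hit rate (±20 ms): 100.0%  timing MAE: 0.47 ms
HR MAE vs ECG: 0.14 bpm  RMSE: 0.18 bpm  coverage: 100.0%
JJ mean 0.999 s  SDNN 33.2 ms  pNN50 0.26
```

The detector recovered every simulated beat to sub-millisecond timing;
the heart-rate series agrees with the ECG-derived reference to 0.14 bpm
on this noise level.

The same pipeline is available from the shell:

```bash
bcg simulate --out rec.csv --truth truth.csv --duration 60 --seed 1
bcg run --in rec.csv --out results/      # beats.csv, hrv.json, report.json, run.log
```

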