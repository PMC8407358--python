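# neoburst

Cortical-burst analysis of neonatal EEG for survivors of hypoxic-ischemic
encephalopathy (HIE).

Term infants cooled for HIE are monitored with 9-channel EEG (F3, F4, C3,
C4, Cz, T3, T4, O1, O2 at 250 Hz). Their EEG contains *cortical bursts* —
transient runs of fast 8–30 Hz oscillations reflecting excitatory input to
developing cortex — whose power carries prognostic information: higher
duration-normalised burst power predicts worse cognitive, motor and language
outcome on the Bayley-III scales. `neoburst` implements the full analysis
chain:

1. **EEG I/O and artifact masking** — EDF reading (via MNE), the >500 µV
   amplitude criterion with a 0.5-s pad. Artifact sections are *masked*, not
   cut, so hour-scale analyses keep true timestamps.
2. **Burst detection** — per channel, the 8–30 Hz band-passed signal is
   reduced to an RMS amplitude series over sliding 400-ms windows; maximal
   runs of windows strictly above 1.5×SD of that channel's RMS series
   lasting ≥0.5 s become bursts. Each burst's *normalised power* is the
   8–30 Hz power integrated over the burst divided by its duration (µV²):
   for a burst b on channel c,  P(b) = (1/T_b) ∫_b x_c,8–30(t)² dt.
3. **Time–frequency characterisation** — Morlet maps over a log-spaced
   0.2–40 Hz grid (3–135 cycles), in dB relative to the mean power in the
   11 s preceding burst onset, averaged over bursts.
4. **Sleep-cycle periodicity** — burst power binned onto a regular grid;
   the dominant DFT period below 3.5 h is the sleep-cycle estimate, flagged
   unreliable for recordings with under 4.5 h of clean data; plus the
   per-channel correlation between burst power and the time since the last
   burst (tracé alternant signature).
5. **Outcome statistics** — Pearson and partial Pearson correlations
   (controlling for the 6-point MRI injury score) with percentile-bootstrap
   95% CIs and the conjunction significance rule (p < .05 AND CI excludes
   0); ROC/AUC of burst power against abnormal outcome (composite < 85)
   with a sensitivity-first cutoff; and the Fisher-z sample-size formula
   n = ⌈((z₁₋α/₂ + z_power)/atanh r)² + 3⌉.
6. **Synthetic data** — patient recordings are not redistributable, so a
   generator plants bursts, sleep-cycle modulation, artifacts and
   power→outcome effects with queryable ground truth, making every stage
   testable end to end.

## Worked example

```python
from neoburst import (SimulationConfig, generate_recording, mask_artifacts,
                      detect, summarise_bursts, match_events)

cfg = SimulationConfig(duration=1800.0, burst_amplitude=50.0,
                       background_amplitude=10.0, seed=7)
sim = generate_recording(cfg)                 # 30 min, 9 channels, 250 Hz
rec, masked_s = mask_artifacts(sim.recording) # >500 µV criterion
events = detect(rec)                          # burst table (one row per burst)
print(match_events(events, sim.ground_truth))
print(summarise_bursts(events, rec.clean_duration).head(3))
```

prints

```
{'recall': 0.9993016759776536, 'precision': 1.0, 'n_truth': 1432, 'n_detected': 1431}
  channel  median_duration_s  rate_per_s  median_power_uV2  mean_power_uV2  n_bursts
0      C3               2.00    0.090556        854.777777      844.420027       163
1      C4               1.90    0.081667        844.556127      837.442236       147
2      Cz               1.95    0.088889        848.538892      833.584978       160
```

— the detector recovers 99.9% of planted bursts with no false positives,
and the estimated occurrence rate (~1 burst per 11–12 s) and median duration
(~2 s) match the planted process. The same stages are available from the
shell: `neoburst simulate|preprocess|detect|tfr|cycle|stats|power`, e.g.

```bash
neoburst power --r2 0.26 --power 0.8 --alpha 0.05
# {"r2": 0.26, "power": 0.8, "alpha": 0.05, "n": 28}
```

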