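# sleepspace

State-space analysis of human sleep EEG: each 5-s epoch of a single EEG
channel is projected onto two log-scaled ratios of spectral band powers, so
a whole night becomes a trajectory through a 2-D plane in which the
behavioural states (WAKE, NREM1–3, REM) form clusters. On top of that plane
the package provides

- **probability-based sleep staging** — a pooled-covariance linear
  discriminant (LDA) classifier over the two ratio coordinates, evaluated
  by positive predictive value (PPV) against manual scoring, with a proper
  train/held-out-subject protocol;
- **band optimization** — a genetic algorithm (band-pair regrouping
  crossover, 10 % per-gene mutation) followed by Nelder–Mead refinement
  that tunes the eight band edges to maximize staging PPV;
- **state-space velocity** — `v_i = ‖p_{i+1} − p_i‖₂ / Δt`, a quantitative
  measure of behavioural-state instability, with a slow/fast partition that
  separates consolidated sleep from transitions and fluctuations;
- **interhemispheric laterality** — the score
  `(v_R − v_L) / (v_R + v_L) ∈ [−1, 1]` between homologous electrode pairs,
  analysed in 100-epoch (500 s) bouts by sample autocorrelation (lags
  0–90) with a white-noise confidence band ±z₀.₉₇₅/√n, and an FFT of the
  ACF that extracts slow (~0.5–1.5 min period) oscillations of velocity
  dominance between the hemispheres;
- **synthetic polysomnography** — a seeded generator of stage-templated
  EEG (resonator narrowbands over 1/f background, sticky Markov stage
  sequence) with an optional antiphase jitter modulation that injects a
  lateralized velocity oscillation, so the whole pipeline is testable
  without any recordings.

The default state-space ratios are the optimized bands
`Ratio1 = (8.6–19.3 Hz)/(1.0–10.9 Hz)` and
`Ratio2 = (11.5–20.3 Hz)/(17.9–31.5 Hz)`; spectra come from Hann-windowed
5-s epochs (500 samples at 100 Hz) zero-padded to 512 FFT points.

Audience: sleep researchers and EEG methods developers who want a
quantitative, continuous view of sleep dynamics next to conventional
30-s-epoch scoring.

## Worked example

```python
from sleepspace import *

spec = SyntheticSpec(duration=5400.0, seed=1,
                     oscillation=Oscillation(("C3", "C4"), period_s=48.0, depth=0.5))
hyp = generate_hypnogram(spec)          # 1080 5-s epochs, Markov stage sequence
rec = generate_recording(spec, hyp)     # 6 channels, 100 Hz, microvolts

# staging: project C3 into the state space, fit and apply the LDA classifier
traj = state_trajectory(rec, "C3", DEFAULT_BANDS, smooth_window=10)
model = fit_classifier(traj.points, hyp.labels)
ppv = positive_predictive_value(model.predict(traj.points), hyp.labels)
print(f"overall PPV: {ppv['overall']:.3f}")

# laterality: same bouts analysed in three homologous pairs simultaneously
reports = multiderivation_report(rec, hyp,
                                 pairs=[("F3","F4"), ("C3","C4"), ("O1","O2")],
                                 stage=None)
for pair, reps in reports.items():
    for r in reps[:2]:
        print(f"{pair[0]}/{pair[1]} bout {r.bout}: period {r.period:5.1f} s, "
              f"significant: {r.significant}")
```

prints

```
overall PPV: 0.979
F3/F4 bout (0, 100): period  33.7 s, significant: False
F3/F4 bout (187, 287): period  34.6 s, significant: False
C3/C4 bout (0, 100): period  47.4 s, significant: True
C3/C4 bout (187, 287): period  47.4 s, significant: True
O1/O2 bout (0, 100): period  40.0 s, significant: False
O1/O2 bout (187, 287): period  64.0 s, significant: False
```

The classifier agrees with the generated hypnogram on 97.9 % of epochs, and
the 48-s velocity oscillation injected into C3/C4 is detected in that pair
only (47.4 s is the nearest bin of the ACF spectrum); the uninjected pairs
show no significant periodicity — their "period" is just the location of
the largest noise peak, which is why it wanders from bout to bout.

The same pipeline is available from the shell:

```sh
sleepspace simulate --out-dir sim --duration 5400 --seed 1 --oscillation-pair C3,C4
sleepspace train --recording sim/recording.edf --hypnogram sim/hypnogram.csv --out model.json
sleepspace score --recording sim/recording.edf --model model.json \
    --reference sim/hypnogram.csv --out staging.csv
sleepspace laterality --recording sim/recording.edf --hypnogram sim/hypnogram.csv \
    --pairs "F3,F4;C3,C4;O1,O2" --stage '' --out laterality.json
```

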