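# hdemg

Spatial analysis of high-density surface electromyography (HDEMG) grids,
built for ergonomics and motor-control studies that ask *where* on a muscle
activity happens, not just how much. The motivating use case is trunk-muscle
loading during industrial cart pushing: a participant pushes a loaded cart
with one of six handle designs (hip/shoulder height × horizontal/
semi-pronated/vertical orientation) while monopolar EMG is recorded from an
8 × 4 electrode grid (one corner electrode absent, 31 channels, 8 mm
spacing) over each of three bilateral trunk muscles, together with the hand
force on the cart.

The package implements the full chain from raw grid recording to per-trial
spatial features and study-level summary tables:

* **Preprocessing** — 10–500 Hz zero-phase band-pass; push-initiation
  windowing (the 0.5 s epoch starting when hand force first exceeds 20 N);
  maximum-voluntary-contraction (MVC) references and %MVC normalization.
* **Activation maps** — per-electrode RMS over the window,
  `HM_ij = RMS(sEMG_ij)`.
* **Spatial features** per trial:
  intensity `I = log₁₀((1/N) Σ HM_ij)`;
  differential intensity `DI = log₁₀ RMS(sEMG_ij − sEMG_i+1,j)` aggregated
  over fiber-direction electrode pairs;
  mean RMS in %MVC;
  modified entropy `E = −Σ p_i² log₂ p_i²` with `p_i²` the normalized
  channel power (bits; maximal `log₂ N` for a uniform map);
  coefficient of variation `CoV = 100·SD/mean` (%).
  Entropy and CoV index spatial heterogeneity: clustered activation lowers
  `E` and raises CoV.
* **Study pipeline** — per-trial orchestration with auditable failure
  records, completeness accounting (6 designs × 3 muscle pairs = 18
  recording trials per participant) and grouped mean/SD tables ready for
  external inferential statistics.
* **Synthetic studies** — a generator of grid-EMG trials, force traces, MVC
  trials and whole multi-participant studies with known ground truth
  (Gaussian activation territories, a scalar clustering knob, per-design
  effect tables), used to validate every stage end-to-end.

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

```python
from hdemg import (SimulationConfig, bandpass, build_map, compute_mvc,
                   coefficient_of_variation, detect_initiation,
                   differential_intensity, generate_force_trace,
                   generate_grid_emg, generate_mvc_trials, intensity,
                   mean_rms, modified_entropy, normalize)

config = SimulationConfig(duration=3.0, clustering=0.8, noise_sd=0.05, seed=7)
recording = generate_grid_emg(config)                  # 31-channel grid trial
force = generate_force_trace(config)                   # crosses 20 N at 1.0 s
mvc = compute_mvc(generate_mvc_trials(recording.layout, 8.0, seed=8))

filtered = bandpass(recording)                         # 10-500 Hz, zero phase
window = detect_initiation(force)                      # [t0, t0 + 0.5 s)
raw_map = build_map(filtered, window)
norm_map = normalize(raw_map, mvc)
```

Running this (it is `examples/02_spatial_features.py`) prints:

```
initiation window: samples [1001, 1501)
intensity               I  =  -0.045  (log10 a.u.)
differential intensity  DI =   0.112  (27 fiber-direction pairs)
mean RMS                   =    10.4  %MVC
modified entropy        E  =   4.934  bits (max 4.954)
coefficient of variation   =     8.5  %
```

The window starts one sample after the configured 1.0 s onset (first sample
*strictly* above 20 N). Intensity near 0 reflects channel RMS near 1 in the
simulator's arbitrary units; mean activation is ~10 %MVC because the MVC
amplitude is 8× the task amplitude; entropy sits 0.02 bits below the
31-channel maximum of log₂ 31 ≈ 4.954 because clustering 0.8 concentrates
activation mildly toward the grid center, which also lifts CoV above the
uniform-map value of 0 %.

`examples/04_full_study.py` simulates a two-participant study and recovers
the built-in design effects from the summary table — the hip-height
horizontal handle (HH) comes out lowest in mean %MVC (5.7 vs 10.5–12.7 for
the other five designs), matching the generator's ground truth.

Each script in `examples/` is a short narrative of one capability:
simulation against the analytic amplitude target, single-trial features,
onset detection, a full study, and heat-map rendering.

## Command line

```sh
hdemg simulate --config study.yaml --out study/ --seed 7   # write a synthetic study
hdemg process  --in study/ --out features.csv              # trials -> tidy features
hdemg summarize --in features.csv --by design              # grouped mean/SD table
hdemg features --emg trial.csv --force force.csv --mvc m1.csv --mvc m2.csv --mvc m3.csv
```

Recordings live on disk as plain channel-matrix CSVs with JSON sidecars;
simulated and imported studies are indistinguishable, and identical seeds
reproduce output directories byte for byte.

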