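# Methods

This note documents the models and numerical conventions behind `hdemg`: the
per-trial analysis chain, the spatial features, the synthetic-data generator
used to validate the chain, and the design choices made where the underlying
methodology is genuinely open.

## Recording model and grid conventions

The package analyses monopolar surface-EMG recorded on a 2-D electrode grid
of 8 rows × 4 columns (8 mm inter-electrode distance in both directions)
with the upper-right corner electrode absent, leaving 31 usable sites. The
grid is placed so its columns run parallel to the muscle fibers; adjacent
electrodes within a column are therefore the pairs used to form
single-differential channels. Signals are sampled at 1000 Hz with a hardware
bandwidth of 10–500 Hz. None of these numbers is hard-coded:
`GridLayout` accepts arbitrary dimensions and missing-electrode masks, and
every feature derives its channel count from the mask at run time.

Conventions (asserted in tests, recorded in every file sidecar): 0-based
`(row, col)` indices, row 0 = top of the grid as placed, channels ordered
row-major over valid electrodes and named `r<row>c<col>`.

## Per-trial chain

1. **Band-pass filter** — 4th-order Butterworth, 10–500 Hz, applied
   forward–backward (`sosfiltfilt`) so the output has zero phase lag against
   the force clock. Only the band is methodologically fixed; the realization
   is a choice, and zero phase was chosen precisely because the analysis
   window is defined on the force channel. At 1000 Hz the 500 Hz edge sits
   on Nyquist and is clamped to 0.99 × Nyquist (495 Hz); with the hardware
   anti-aliasing already at 500 Hz this is a formality. Filtering twice
   changes in-band RMS by < 2 % (tested), so accidental re-filtering is
   benign.
2. **Initiation window** — the push-initiation epoch is the 0.5 s interval
   `[t0, t0 + 0.5 s)` where `t0` is the first sample at which the hand force
   strictly exceeds 20 N. The phrase "0.5 s after the force surpassed 20 N"
   admits a second reading (a window *starting* 0.5 s after the crossing);
   that alternative is exposed as `window_offset_s` / `--window-offset`
   rather than guessed at. No debounce is applied by default (synthetic
   traces are clean through the ramp); `min_hold_s` adds a minimum-hold
   requirement for noisy imported data. A trace that never crosses the
   threshold raises `NoInitiationError`; a crossing without room for a full
   window raises `TruncatedWindowError`. Failures are recorded per trial,
   never silently dropped.
3. **Activation map** — `HM[i, j] = RMS(sEMG[i, j])` over the window; masked
   electrodes carry `NaN` and are excluded from every statistic.
4. **MVC normalization** — the MVC reference is, per channel, the maximum
   across the three 5 s maximal-contraction trials of the RMS over a 0.5 s
   sliding window. The sliding-max reduction is standard practice and is
   matched in duration to the task window; the duration is `mvc_window_s`.
   Whether normalization should be per channel or against a single
   grid-level scalar is not methodologically settled; both are implemented
   (`per_channel`, the default, and `global` = mean of the per-channel
   references). A channel identically zero in all MVC trials makes %MVC
   undefined and raises `DegenerateMVCError`.

## Spatial features

With `v_1..v_N` the map values over the `N` valid channels:

* **Intensity** `I = log10(mean(v))` — log of the mean raw-map amplitude.
  Computed on the *raw* (un-normalized) map by default, with
  `intensity_on="normalized"` available; the log₁₀ scale means MVC
  normalization would only shift it per participant.
* **Differential intensity** — single-differential signals are formed for
  every adjacent valid pair along the fiber axis (up to 7 per column × 4
  columns = 28 on a full grid; 27 on the default grid, where the absent
  corner breaks one pair), each pair's RMS is taken over the window, and
  `DI = log10(mean(pair RMS))`. Averaging before the log mirrors the
  structure of `I`; the alternative (mean of per-pair logs) is the
  `mean_of_logs` option. If all differentials cancel exactly (identical
  channels) the log argument is floored at 1e-12 and the result flagged
  `di_floored` rather than returned as −∞.
* **Mean RMS** — arithmetic mean of the MVC-normalized map; a fraction of
  MVC (×100 = %MVC). Requires a normalized map by contract.
* **Modified entropy** `E = −Σ p_i² log2 p_i²` with
  `p_i² = v_i² / Σ_j v_j²` the normalized channel power, `0·log 0 ≡ 0`;
  bits. `E` is bounded by `[0, log2 N]`, maximal for a uniform map
  (`log2 28 ≈ 4.8` on 28 channels, `log2 31 ≈ 4.954` on the default grid)
  and zero when one channel carries everything. Source texts for this
  statistic are inconsistent about `N` (28, 31 and 32 all appear for the
  same hardware; 28 equals the single-differential channel count of a full
  grid, suggesting the statistic is sometimes computed on differential
  maps). This implementation takes no position: entropy is computed on
  whatever map it is given, over that map's valid channels.
* **Coefficient of variation** `CoV = 100 · SD(v) / mean(v)`, percent. The
  SD convention is not standardised in this literature; the sample SD
  (`ddof=1`) is the default here (the common human-movement convention) with
  `ddof=0` available. Reported magnitudes of 40–80 for trunk-muscle maps
  are only consistent with the percentage scale, hence the ×100.

Entropy and CoV are permutation- and scale-invariant; intensity obeys
`I(k·map) = I(map) + log10 k`. These invariants, the bounds and equality
cases, and agreement with independent brute-force summations at 1e-12
relative tolerance are enforced by property tests.

All-zero maps raise `UndefinedFeatureError` for `I`, `E` and `CoV` rather
than returning 0, −∞ or NaN — a silent sentinel would corrupt group means.

## Synthetic-data generator

Real grid-EMG from pushing studies is generally not publicly deposited, so
validation uses a generator whose ground truth is known exactly.

**Source model.** A trial is a set of *territories*: isotropic Gaussian
amplitude profiles `w(e) = gain · exp(−d(e, center)² / (2 spread²))` over
the grid (`d` in electrode units), standing in for spatially clustered
active muscle regions. Each (territory, channel) pair receives an
independent Gaussian carrier, zero-phase filtered into 10–500 Hz, trimmed by
0.25 s at each end to discard filter transients, and normalized to exactly
unit RMS per realization; channel noise of RMS `noise_sd` is added the same
way. Per-channel RMS therefore equals `sqrt(Σ_t w_t(e)² + noise_sd²)`
exactly in expectation and to within sampling error per realization —
`expected_channel_rms` evaluates this closed form so tests can invert the
generator. Carriers are independent per channel (not shared across the
grid): a shared carrier would make all single-differential channels cancel
and degenerate the DI feature.

**Clustering knob.** `clustering ∈ [0, 1]` maps linearly onto the spread of
a single grid-centered territory, `spread = 25 − 24.4 · clustering`
electrode units: 25 makes the farthest electrode's weight > 0.95 of the
center's (effectively uniform), 0.6 concentrates the territory on roughly
one electrode. Increasing clustering monotonically lowers map entropy and
raises CoV (verified end-to-end by rank correlation over seeded trials).

**Force trace.** Piecewise-linear: baseline ≈ 0 N, a 0.5 s ramp whose start
is placed so the force equals the 20 N threshold exactly at `onset_time`,
then a plateau at `force_plateau`. Gaussian measurement noise
(`force_noise_sd`, default 0.5 N) is applied to baseline and plateau but not
to the ramp, keeping the rise through the threshold monotone; onset recovery
is therefore exact to within one sample. Plateaus at or below 20 N never
cross the threshold, exercising the no-initiation path.

**MVC trials.** Three 5 s trials whose per-channel RMS equals the requested
amplitude exactly (unit-RMS carriers scaled); between-participant MVC
variability enters at the study level.

**Study generator.** Each participant records one trial bundle per (handle
design × bilateral muscle pair) — 6 × 3 = 18 bundles, each holding left and
right grid recordings sharing one force trace — plus three MVC trials per
muscle and side. Participant strength is log-normal (SD 0.2 in log units),
trial-to-trial gain jitter log-normal (SD 0.1), and the MVC amplitude is
8 × the base push amplitude, which puts task activation near the 6–13 %MVC
range typical of submaximal trunk-muscle pushing. The per-design effect
table multiplies the base activation (1.0) and base clustering (0.4):

| design | activation | clustering |
|--------|-----------|------------|
| HH     | 0.50      | 0.70       |
| HS     | 1.00      | 1.00       |
| HV     | 0.95      | 1.00       |
| SH     | 0.95      | 1.00       |
| SS     | 1.00      | 1.25       |
| SV     | 1.10      | 1.25       |

(codes: height letter H = hip / S = shoulder, then orientation H =
horizontal / S = semi-pronated / V = vertical). These defaults encode the
qualitative pattern reported for trunk muscles during cart pushing — the
hip-height horizontal handle elicits the lowest mean activation and the
most homogeneous maps, shoulder-height semi-pronated/vertical the most
clustered — and are study conditions, not tuning knobs.

Randomness: each bundle draws from its own stream seeded from
`(study seed, participant index, trial index)` via `SeedSequence`, so any
trial is reproducible in isolation; identical seeds give bit-identical
studies and byte-identical on-disk output.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: motor-unit action-potential shapes, firing
statistics and synchronisation; volume conduction and innervation-zone
geometry; electrode–skin impedance, motion artifacts and ECG contamination;
within-trial nonstationarity (the simulated push is statistically
stationary after onset). The generator validates the *pipeline's*
correctness and sensitivity, not physiological realism; amplitude units are
arbitrary, so simulated intensity values are not on the a.u. scale of any
particular acquisition system.

## Problem sizes in the test suite

Statistical acceptance checks run at desk scale as the package's own
choice of validation size: the clustering-monotonicity sweep uses 6 levels
× 20 seeds × 2 s trials; design-effect recovery uses 100 replicates of a
one-participant study (18 bundles each, 2 s pushes, 5 s MVC trials),
requiring the HH design to have the lowest summarized mean RMS in ≥ 95 % of
replicates. With the default effect table the observed recovery rate is
100/100.

## Known limitations

* Group-level inference (mixed-model ANOVA, post-hoc corrections, normality
  checks) is intentionally out of scope; the pipeline exports a tidy
  per-trial table that any statistics package can consume.
* No vendor binary-format importer; the on-disk format is the documented
  CSV + JSON sidecar pair.
* No artifact rejection, bad-channel interpolation or map interpolation for
  display.
* Simulated amplitudes are in arbitrary units; calibration to a physical
  µV scale is not attempted.
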