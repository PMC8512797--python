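"""Synthetic grid-EMG studies with known ground-truth spatial structure.

Human grid-EMG recordings from pushing studies are rarely deposited, so this
module generates surrogate data on which every pipeline stage can be
exercised and validated: single grid trials, force traces, MVC calibration
trials and complete multi-participant handle-design studies.

Source model
------------
A trial's activity is a set of *source territories* — isotropic Gaussian
amplitude profiles over the grid, standing in for the spatial clustering of
active muscle regions. Each (territory, channel) pair receives an
independent band-limited (10-500 Hz) Gaussian noise carrier normalized to
unit RMS, scaled by the territory's spatial weight at that electrode

    w_t(e) = gain_t * exp(-d(e, center_t)^2 / (2 * spread_t^2))

with ``d`` in electrode units. Independent measurement noise of RMS
``noise_sd`` is added per channel, so the per-channel RMS is exactly the
quadrature sum

    RMS(e) = sqrt(sum_t w_t(e)^2 + noise_sd^2)

(:func:`expected_channel_rms` evaluates this closed form so tests can invert
the generator). The model deliberately stops at the RMS spatial structure
the map features measure; motor-unit action-potential shapes, volume
conduction and motion artifacts are out of scope.

The scalar ``clustering`` knob maps linearly onto the spread of a single
grid-centered territory, from effectively uniform activation (``0``) to a
single tight territory (``1``); see :func:`clustering_to_spread`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from .errors import ConfigurationError
from .grid import GridLayout
from .preprocess import _design_bandpass
from .recording import EMGRecording, ForceTrace

__all__ = [
    "SourceTerritory",
    "SimulationConfig",
    "DesignEffect",
    "StudyDesign",
    "TrialBundle",
    "SyntheticStudy",
    "DEFAULT_EFFECTS",
    "HANDLE_DESIGNS",
    "MUSCLES",
    "SIDES",
    "clustering_to_spread",
    "territory_weights",
    "expected_channel_rms",
    "generate_grid_emg",
    "generate_force_trace",
    "generate_mvc_trials",
    "generate_study",
]

#: Handle-design codes: height letter (H hip, S shoulder) then orientation
#: letter (H horizontal, S semi-pronated, V vertical).
HANDLE_DESIGNS: tuple[str, ...] = ("HH", "HS", "HV", "SH", "SS", "SV")
#: Bilateral trunk muscles recorded: erector spinae, external oblique,
#: rectus abdominis.
MUSCLES: tuple[str, ...] = ("ES", "EO", "RA")
SIDES: tuple[str, ...] = ("left", "right")

# clustering -> territory spread (electrode units), linear interpolation.
# At SPREAD_UNIFORM the weight ratio between grid center and the farthest
# 8x4 electrode is > 0.95 (effectively uniform); SPREAD_TIGHT concentrates
# the territory on roughly one electrode.
SPREAD_UNIFORM: float = 25.0
SPREAD_TIGHT: float = 0.6

# Internal padding discarded at each end of filtered noise so zero-phase
# filter edge transients never reach the emitted samples.
EDGE_TRIM_S: float = 0.25

_FORCE_RISE_S: float = 0.5
_THRESHOLD_N: float = 20.0


@dataclass(frozen=True)
class SourceTerritory:
    """One Gaussian activation territory on the grid.

    ``center`` is a continuous ``(row, col)`` grid coordinate, ``spread`` the
    isotropic spatial SD in electrode units, ``gain`` the dimensionless
    amplitude multiplier.
    """

    center: tuple[float, float]
    spread: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ConfigurationError("territory spread must be positive")
        if self.gain < 0:
            raise ConfigurationError("territory gain must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated trial.

    ``territories=None`` derives a single grid-centered territory from the
    ``clustering`` knob. ``onset_time`` is when the force trace crosses the
    20 N initiation threshold; ``force_plateau`` the steady pushing force.
    """

    duration: float = 3.0
    sampling_rate: float = 1000.0
    band: tuple[float, float] = (10.0, 500.0)
    territories: tuple[SourceTerritory, ...] | None = None
    noise_sd: float = 0.05
    clustering: float = 0.5
    onset_time: float = 1.0
    force_plateau: float = 100.0
    force_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high <= self.sampling_rate / 2):
            raise ConfigurationError(
                f"band {self.band} invalid for fs={self.sampling_rate} Hz"
            )
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.noise_sd < 0 or self.force_noise_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        if not (0.0 <= self.clustering <= 1.0):
            raise ConfigurationError("clustering must lie in [0, 1]")
        if self.territories is not None:
            object.__setattr__(self, "territories", tuple(self.territories))


def clustering_to_spread(clustering: float) -> float:
    """Map the clustering knob in [0, 1] linearly onto territory spread.

    ``spread = SPREAD_UNIFORM + clustering * (SPREAD_TIGHT - SPREAD_UNIFORM)``
    — 0 gives an effectively uniform profile, 1 a single tight territory.
    """
    if not (0.0 <= clustering <= 1.0):
        raise ConfigurationError("clustering must lie in [0, 1]")
    return SPREAD_UNIFORM + clustering * (SPREAD_TIGHT - SPREAD_UNIFORM)


def _resolve_territories(
    config: SimulationConfig, layout: GridLayout, gain: float = 1.0
) -> tuple[SourceTerritory, ...]:
    if config.territories is not None:
        return config.territories
    center = ((layout.n_rows - 1) / 2.0, (layout.n_cols - 1) / 2.0)
    return (SourceTerritory(center, clustering_to_spread(config.clustering), gain),)


def territory_weights(
    territories: Sequence[SourceTerritory], layout: GridLayout
) -> np.ndarray:
    """Spatial weights of each territory at each valid electrode.

    Returns an array of shape ``(n_territories, n_valid)``.
    """
    positions = np.asarray(layout.valid_positions, dtype=float)
    weights = np.empty((len(territories), positions.shape[0]))
    for i, t in enumerate(territories):
        cr, cc = t.center
        if not (0 <= cr <= layout.n_rows - 1 and 0 <= cc <= layout.n_cols - 1):
            raise ConfigurationError(
                f"territory center {t.center} lies outside the grid"
            )
        d2 = (positions[:, 0] - cr) ** 2 + (positions[:, 1] - cc) ** 2
        weights[i] = t.gain * np.exp(-d2 / (2.0 * t.spread**2))
    return weights


def expected_channel_rms(config: SimulationConfig, layout: GridLayout) -> np.ndarray:
    """Closed-form per-channel RMS the generator targets.

    ``sqrt(sum_t w_t(e)^2 + noise_sd^2)`` — the analytic inverse of the
    generator, used by tests to check generated amplitudes.
    """
    w = territory_weights(_resolve_territories(config, layout), layout)
    return np.sqrt(np.sum(w**2, axis=0) + config.noise_sd**2)


def _unit_rms_band_noise(
    n_samples: int,
    n_channels: int,
    sampling_rate: float,
    band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian noise, each channel normalized to exactly unit RMS.

    White noise is zero-phase filtered into the band; ``EDGE_TRIM_S`` of
    padding at each end absorbs the filter transients so the emitted segment
    is stationary.
    """
    pad = round(EDGE_TRIM_S * sampling_rate)
    white = rng.standard_normal((n_samples + 2 * pad, n_channels))
    sos = _design_bandpass(band[0], band[1], sampling_rate, order=4)
    filtered = _signal.sosfiltfilt(sos, white, axis=0)
    segment = filtered[pad : pad + n_samples]
    rms = np.sqrt(np.mean(segment**2, axis=0))
    return segment / rms


def generate_grid_emg(
    config: SimulationConfig,
    layout: GridLayout | None = None,
    *,
    rng: np.random.Generator | None = None,
    meta: Mapping[str, Any] | None = None,
) -> EMGRecording:
    """Generate one grid-EMG trial.

    One channel per valid electrode (masked electrodes are absent); each
    channel is zero-mean band-limited noise whose RMS equals
    :func:`expected_channel_rms` up to sampling error. Deterministic given
    ``config.seed`` (or an explicit ``rng``).
    """
    if layout is None:
        layout = GridLayout()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = round(config.duration * config.sampling_rate)
    territories = _resolve_territories(config, layout)
    weights = territory_weights(territories, layout)
    samples = np.zeros((n, layout.n_valid))
    for w in weights:
        if np.any(w > 0):
            samples += w * _unit_rms_band_noise(
                n, layout.n_valid, config.sampling_rate, config.band, rng
            )
    if config.noise_sd > 0:
        samples += config.noise_sd * _unit_rms_band_noise(
            n, layout.n_valid, config.sampling_rate, config.band, rng
        )
    full_meta: dict[str, Any] = {"kind": "push", "seed": config.seed}
    if meta:
        full_meta.update(meta)
    return EMGRecording(samples, config.sampling_rate, layout, full_meta)


def generate_force_trace(
    config: SimulationConfig, *, rng: np.random.Generator | None = None
) -> ForceTrace:
    """Generate the hand-force trace of a push trial.

    Force sits near 0 N (strictly below the 20 N threshold) before
    ``onset_time``, ramps up linearly so that it equals the threshold exactly
    at ``onset_time``, and plateaus at ``force_plateau``. Measurement noise
    (``force_noise_sd``) is applied to the baseline and plateau but never to
    the ramp, so the rise through the threshold is monotone.
    """
    if config.onset_time + 0.5 > config.duration:
        raise ConfigurationError(
            "onset too close to the end of the trace: need at least 0.5 s "
            f"after onset at {config.onset_time:g} s in a "
            f"{config.duration:g} s trial"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = round(config.duration * fs)
    t = np.arange(n) / fs
    plateau = config.force_plateau
    if plateau > _THRESHOLD_N:
        # ramp start chosen so force == threshold exactly at onset_time
        ramp_start = config.onset_time - _FORCE_RISE_S * _THRESHOLD_N / plateau
        if ramp_start < 0:
            raise ConfigurationError(
                "onset_time too early for the force ramp to start at rest"
            )
    else:
        ramp_start = config.onset_time
    ramp = np.clip((t - ramp_start) / _FORCE_RISE_S, 0.0, 1.0)
    force = plateau * ramp
    if config.force_noise_sd > 0:
        noise = config.force_noise_sd * rng.standard_normal(n)
        on_ramp = (t >= ramp_start) & (t < ramp_start + _FORCE_RISE_S)
        force = force + np.where(on_ramp, 0.0, noise)
    return ForceTrace(force, fs)


def generate_mvc_trials(
    layout: GridLayout,
    true_mvc_amplitude: float | np.ndarray,
    seed: int | np.random.Generator = 0,
    *,
    n_trials: int = 3,
    duration: float = 5.0,
    sampling_rate: float = 1000.0,
    band: tuple[float, float] = (10.0, 500.0),
    meta: Mapping[str, Any] | None = None,
) -> list[EMGRecording]:
    """Generate maximal-voluntary-contraction calibration trials.

    Defaults to three 5 s trials, each channel's RMS equal to
    ``true_mvc_amplitude`` (scalar or per-channel). Different seeds give
    different sample paths with the same RMS.
    """
    amplitude = np.broadcast_to(
        np.asarray(true_mvc_amplitude, dtype=float), (layout.n_valid,)
    )
    if np.any(amplitude <= 0):
        raise ConfigurationError("MVC amplitude must be strictly positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = round(duration * sampling_rate)
    trials = []
    for k in range(n_trials):
        noise = _unit_rms_band_noise(n, layout.n_valid, sampling_rate, band, rng)
        trial_meta: dict[str, Any] = {"kind": "mvc", "mvc_trial": k}
        if meta:
            trial_meta.update(meta)
        trials.append(EMGRecording(amplitude * noise, sampling_rate, layout, trial_meta))
    return trials


@dataclass(frozen=True)
class DesignEffect:
    """Ground-truth multiplicative shifts a handle design applies to the
    base activation amplitude and the base clustering level."""

    activation: float = 1.0
    clustering: float = 1.0


#: Default per-design effects. They encode the qualitative pattern reported
#: for trunk muscles across handle designs: the hip-height horizontal handle
#: (HH) elicits the lowest mean activation and the most homogeneous
#: (least clustered) maps, shoulder-height semi-pronated/vertical handles
#: (SS, SV) the most clustered.
DEFAULT_EFFECTS: dict[str, DesignEffect] = {
    "HH": DesignEffect(activation=0.5, clustering=0.7),
    "HS": DesignEffect(activation=1.0, clustering=1.0),
    "HV": DesignEffect(activation=0.95, clustering=1.0),
    "SH": DesignEffect(activation=0.95, clustering=1.0),
    "SS": DesignEffect(activation=1.0, clustering=1.25),
    "SV": DesignEffect(activation=1.1, clustering=1.25),
}


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a synthetic handle-design study.

    Each participant records each of the six handle designs once per
    bilateral muscle pair: 6 designs x 3 muscle pairs = 18 recording trials.
    ``effect_table`` holds the per-design ground-truth shifts;
    ``mvc_headroom`` is the ratio of MVC amplitude to the base push
    amplitude (8x puts mean task activation near the 6-13 %MVC range typical
    of submaximal trunk-muscle pushing).
    """

    n_participants: int = 20
    designs: tuple[str, ...] = HANDLE_DESIGNS
    muscles: tuple[str, ...] = MUSCLES
    sides: tuple[str, ...] = SIDES
    effect_table: Mapping[str, DesignEffect] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    base_activation: float = 1.0
    base_clustering: float = 0.4
    mvc_headroom: float = 8.0
    participant_sd: float = 0.2
    trial_jitter_sd: float = 0.1
    noise_sd: float = 0.05
    duration: float = 3.0
    onset_time: float = 1.0
    force_plateau: float = 100.0
    mvc_duration: float = 5.0
    sampling_rate: float = 1000.0
    band: tuple[float, float] = (10.0, 500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("need at least one participant")
        if len(self.designs) != 6:
            raise ConfigurationError("a study uses exactly 6 handle designs")
        if len(self.muscles) != 3:
            raise ConfigurationError("a study records exactly 3 bilateral muscles")
        if len(self.sides) != 2:
            raise ConfigurationError("a study records exactly 2 sides")
        missing = [d for d in self.designs if d not in self.effect_table]
        if missing:
            raise ConfigurationError(f"effect_table missing designs: {missing}")

    @property
    def trials_per_participant(self) -> int:
        return len(self.designs) * len(self.muscles)


@dataclass
class TrialBundle:
    """One recording trial: a bilateral muscle pair under one handle design.

    ``recordings`` maps side -> grid recording (both grids of the pair share
    the force trace); ``mvc_trials`` maps side -> that muscle/side's MVC
    calibration trials for this participant.
    """

    participant: str
    sex: str
    muscle: str
    design: str
    recordings: dict[str, EMGRecording]
    force: ForceTrace
    mvc_trials: dict[str, list[EMGRecording]]
    ground_truth: dict[str, Any] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    """A generated study: trial bundles plus shared MVC calibration trials."""

    design: StudyDesign
    layout: GridLayout
    bundles: list[TrialBundle]
    mvc_trials: dict[tuple[str, str, str], list[EMGRecording]]

    @property
    def participants(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for b in self.bundles:
            seen.setdefault(b.participant, None)
        return tuple(seen)


def generate_study(
    design: StudyDesign, layout: GridLayout | None = None
) -> SyntheticStudy:
    """Generate a full multi-participant study.

    Per participant, one bundle per (design, muscle pair) — 18 bundles —
    with the per-design ground-truth effects of ``effect_table`` applied.
    Each bundle draws from its own RNG stream seeded from
    ``(study seed, participant index, trial index)``, so any trial is
    independently reproducible; MVC trials use streams keyed off the
    participant.
    """
    if layout is None:
        layout = GridLayout()
    bundles: list[TrialBundle] = []
    mvc_store: dict[tuple[str, str, str], list[EMGRecording]] = {}
    for p in range(design.n_participants):
        pid = f"P{p + 1:02d}"
        sex = "M" if p % 2 == 0 else "F"
        rng_p = np.random.default_rng(np.random.SeedSequence([design.seed, p]))
        strength = math.exp(design.participant_sd * rng_p.standard_normal())
        # MVC calibration: one set of three trials per muscle and side
        for m_idx, muscle in enumerate(design.muscles):
            for s_idx, side in enumerate(design.sides):
                amp = design.mvc_headroom * strength * math.exp(
                    0.05 * rng_p.standard_normal()
                )
                rng_mvc = np.random.default_rng(
                    np.random.SeedSequence([design.seed, p, 1000 + 10 * m_idx + s_idx])
                )
                mvc_store[(pid, muscle, side)] = generate_mvc_trials(
                    layout,
                    amp,
                    rng_mvc,
                    duration=design.mvc_duration,
                    sampling_rate=design.sampling_rate,
                    band=design.band,
                    meta={
                        "participant": pid,
                        "sex": sex,
                        "muscle": muscle,
                        "side": side,
                    },
                )
        for trial_idx, (code, muscle) in enumerate(
            itertools.product(design.designs, design.muscles)
        ):
            rng_t = np.random.default_rng(
                np.random.SeedSequence([design.seed, p, trial_idx])
            )
            effect = design.effect_table[code]
            clustering = float(np.clip(design.base_clustering * effect.clustering, 0, 1))
            recordings: dict[str, EMGRecording] = {}
            gains: dict[str, float] = {}
            for side in design.sides:
                jitter = math.exp(design.trial_jitter_sd * rng_t.standard_normal())
                gain = design.base_activation * effect.activation * strength * jitter
                config = SimulationConfig(
                    duration=design.duration,
                    sampling_rate=design.sampling_rate,
                    band=design.band,
                    territories=(
                        SourceTerritory(
                            ((layout.n_rows - 1) / 2.0, (layout.n_cols - 1) / 2.0),
                            clustering_to_spread(clustering),
                            gain,
                        ),
                    ),
                    noise_sd=design.noise_sd * strength,
                    clustering=clustering,
                    onset_time=design.onset_time,
                    force_plateau=design.force_plateau,
                )
                recordings[side] = generate_grid_emg(
                    config,
                    layout,
                    rng=rng_t,
                    meta={
                        "participant": pid,
                        "sex": sex,
                        "muscle": muscle,
                        "side": side,
                        "design": code,
                    },
                )
                gains[side] = gain
            force_config = SimulationConfig(
                duration=design.duration,
                sampling_rate=design.sampling_rate,
                onset_time=design.onset_time,
                force_plateau=design.force_plateau,
            )
            force = generate_force_trace(force_config, rng=rng_t)
            bundles.append(
                TrialBundle(
                    participant=pid,
                    sex=sex,
                    muscle=muscle,
                    design=code,
                    recordings=recordings,
                    force=force,
                    mvc_trials={
                        side: mvc_store[(pid, muscle, side)] for side in design.sides
                    },
                    ground_truth={"clustering": clustering, "gain": gains},
                )
            )
    return SyntheticStudy(design, layout, bundles, mvc_store)
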