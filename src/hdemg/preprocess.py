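"""Filtering, push-initiation detection and MVC normalization.

The preprocessing chain for a push trial is: band-pass the grid recording at
10-500 Hz, locate the 0.5 s initiation window that starts when the hand
force first exceeds 20 N, and (for amplitude features) express activation
relative to the participant's maximum voluntary contraction (MVC).
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from scipy import signal

from .errors import (
    ConfigurationError,
    DegenerateMVCError,
    LayoutMismatchError,
    NoInitiationError,
    NormalizationError,
    TruncatedWindowError,
)
from .maps import ActivationMap
from .recording import EMGRecording, ForceTrace, MVCReference, TrialWindow

__all__ = [
    "bandpass",
    "detect_initiation",
    "sliding_rms",
    "compute_mvc",
    "normalize",
]

# Fraction of Nyquist the high band edge is clamped to when it coincides with
# Nyquist (a 500 Hz edge at fs = 1000); the acquisition chain low-passes at
# 500 Hz anyway, so the clamp is a formality.
_NYQUIST_CLAMP = 0.99


def _design_bandpass(low: float, high: float, sampling_rate: float, order: int):
    nyquist = sampling_rate / 2.0
    if not (0 < low < high):
        raise ConfigurationError(f"invalid band ({low}, {high}) Hz")
    if high >= nyquist:
        if low >= _NYQUIST_CLAMP * nyquist:
            raise ConfigurationError(
                f"band ({low}, {high}) Hz cannot fit under the "
                f"{nyquist:g} Hz Nyquist frequency"
            )
        high = _NYQUIST_CLAMP * nyquist
    return signal.butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")


def bandpass(
    recording: EMGRecording,
    low: float = 10.0,
    high: float = 500.0,
    *,
    order: int = 4,
) -> EMGRecording:
    """Zero-phase Butterworth band-pass filter applied to every channel.

    A 4th-order Butterworth is applied forward-backward (``sosfiltfilt``) so
    the output carries no phase lag against the force clock. A high edge at
    or above Nyquist is clamped to 0.99 x Nyquist. Output length equals input
    length; filter settings are appended to the recording's provenance.
    """
    sos = _design_bandpass(low, high, recording.sampling_rate, order)
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=0)
    provenance = list(recording.meta.get("provenance", []))
    provenance.append(
        {"stage": "bandpass", "low_hz": low, "high_hz": high, "order": order, "zero_phase": True}
    )
    return recording.with_samples(filtered, provenance=provenance)


def detect_initiation(
    force: ForceTrace,
    threshold: float = 20.0,
    window_s: float = 0.5,
    *,
    offset_s: float = 0.0,
    min_hold_s: float = 0.0,
) -> TrialWindow:
    """Locate the push-initiation analysis window from the force trace.

    The initiation instant is the first sample where force strictly exceeds
    ``threshold`` newtons; the returned window is the ``window_s``-long
    interval immediately following it, ``[t0, t0 + window_s)``.

    Parameters
    ----------
    threshold
        Force threshold in newtons (default 20 N).
    window_s
        Window duration in seconds (default 0.5 s).
    offset_s
        Delay between the crossing and the window start. The default 0 reads
        the window as the interval immediately after the crossing; a 0.5 s
        offset gives the alternative reading "a window starting 0.5 s after
        the crossing".
    min_hold_s
        Optional debounce: the force must stay above threshold for this long
        for a crossing to count. Default 0 (first strictly-greater sample).

    Raises
    ------
    NoInitiationError
        If the force never exceeds the threshold (for at least
        ``min_hold_s``).
    TruncatedWindowError
        If the crossing sits too close to the end of the trace for a full
        window.
    """
    if window_s <= 0:
        raise ConfigurationError("window duration must be positive")
    above = force.force > threshold
    hold = max(1, round(min_hold_s * force.sampling_rate))
    if hold > 1:
        kernel = np.ones(hold)
        sustained = np.convolve(above.astype(float), kernel, mode="valid") >= hold
        candidates = np.flatnonzero(sustained)
    else:
        candidates = np.flatnonzero(above)
    if candidates.size == 0:
        raise NoInitiationError(
            f"no initiation detected: force never exceeds {threshold:g} N"
            + (f" for {min_hold_s:g} s" if hold > 1 else "")
        )
    start = int(candidates[0]) + round(offset_s * force.sampling_rate)
    end = start + round(window_s * force.sampling_rate)
    if end > force.n_samples:
        raise TruncatedWindowError(
            f"truncated window: crossing at sample {candidates[0]} leaves "
            f"{force.n_samples - start} of {end - start} samples"
        )
    return TrialWindow(start, end)


def sliding_rms(samples: np.ndarray, window_samples: int) -> np.ndarray:
    """RMS over every fully-contained sliding window.

    ``samples`` is ``(n_samples, n_channels)``; returns
    ``(n_samples - window_samples + 1, n_channels)``.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if not (0 < window_samples <= n):
        raise ConfigurationError(
            f"window of {window_samples} samples does not fit in {n} samples"
        )
    # cumulative sum of squares -> O(n) mean over each window
    cs = np.cumsum(samples**2, axis=0)
    cs = np.vstack([np.zeros((1, samples.shape[1])), cs])
    window_means = (cs[window_samples:] - cs[:-window_samples]) / window_samples
    return np.sqrt(np.maximum(window_means, 0.0))


def compute_mvc(
    trials: Sequence[EMGRecording],
    *,
    window_s: float = 0.5,
    muscle: str | None = None,
    side: str | None = None,
) -> MVCReference:
    """Per-channel MVC reference from maximal-contraction trials.

    For each channel the reference is the maximum, across all trials, of the
    RMS over a ``window_s`` sliding window — the standard peak-amplitude
    reduction, matched in duration to the task analysis window.
    """
    if not trials:
        raise ConfigurationError("compute_mvc requires at least one trial")
    layout = trials[0].layout
    per_channel = np.zeros(layout.n_valid)
    for trial in trials:
        if trial.layout != layout:
            raise LayoutMismatchError("MVC trials use different electrode layouts")
        w = round(window_s * trial.sampling_rate)
        windowed = sliding_rms(trial.samples, min(w, trial.n_samples))
        per_channel = np.maximum(per_channel, windowed.max(axis=0))
    if np.any(per_channel <= 0):
        dead = [
            name
            for name, v in zip(layout.channel_names, per_channel)
            if v <= 0
        ]
        raise DegenerateMVCError(
            f"degenerate MVC: channel(s) {', '.join(dead)} are identically zero "
            "across all trials; %MVC would be undefined"
        )
    if muscle is None:
        muscle = trials[0].meta.get("muscle")
    if side is None:
        side = trials[0].meta.get("side")
    return MVCReference(per_channel, layout, muscle=muscle, side=side)


def normalize(
    map: ActivationMap,
    mvc: MVCReference,
    *,
    mode: Literal["per_channel", "global"] = "per_channel",
) -> ActivationMap:
    """Express an activation map as a fraction of MVC.

    ``per_channel`` (default) divides each electrode's value by that
    electrode's own MVC reference; ``global`` divides the whole map by a
    single grid-level scalar (the mean of the per-channel references).
    Reporting %MVC multiplies the result by 100.
    """
    if map.normalized:
        raise NormalizationError("map is already MVC-normalized")
    if map.layout != mvc.layout:
        raise LayoutMismatchError("map and MVC reference use different layouts")
    grid = np.array(map.values, dtype=float)
    if mode == "per_channel":
        for value, (r, c) in zip(mvc.values, mvc.layout.valid_positions):
            grid[r, c] = grid[r, c] / value
    elif mode == "global":
        grid = grid / mvc.grid_scalar
    else:
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    return ActivationMap(grid, map.layout, normalized=True, window=map.window)
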