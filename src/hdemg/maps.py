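"""RMS activation maps and spatial features.

The activation (heat-intensity) map assigns each grid electrode the RMS of
its signal over the analysis window, ``HM[i, j] = RMS(sEMG[i, j])``. Five
scalar features summarise such a map per trial:

* **intensity** — the common logarithm of the mean map value,
  ``I = log10(mean(HM))``, a global log-amplitude measure robust to the
  nonlinear EMG-amplitude/force relationship;
* **differential intensity** — the same log-mean construction applied to the
  RMS amplitudes of single-differential channels (differences of adjacent
  electrodes along the fiber direction), which suppress common-mode activity;
* **mean RMS** — the arithmetic mean of an MVC-normalized map, i.e. mean
  activation as a fraction of the participant's maximum voluntary
  contraction;
* **modified entropy** — the Shannon entropy of normalized channel *power*
  ``p_i^2 = HM_i^2 / sum_j HM_j^2``, ``E = -sum p_i^2 log2 p_i^2`` in bits.
  E is maximal (``log2 N``) when all channels carry the same RMS and zero
  when a single channel carries everything, so low entropy indicates
  spatially clustered activation;
* **coefficient of variation** — ``100 * SD(HM) / mean(HM)`` in percent, a
  complementary heterogeneity index (uniform maps give a small CoV).

Every feature is computed over the map's *valid* channels only; the channel
count N is always derived from the electrode mask, never hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .errors import ConfigurationError, NormalizationError, UndefinedFeatureError
from .grid import GridLayout
from .recording import EMGRecording, TrialWindow

__all__ = [
    "ActivationMap",
    "SpatialFeatures",
    "DifferentialIntensity",
    "build_map",
    "intensity",
    "differential_intensity",
    "modified_entropy",
    "coefficient_of_variation",
    "mean_rms",
    "DI_FLOOR",
]

#: Floor for the differential-intensity log argument when all differential
#: signals cancel exactly (identical channels); flagged, never silent.
DI_FLOOR: float = 1e-12


@dataclass
class ActivationMap:
    """Per-electrode RMS values on the grid.

    ``values`` is the full ``(n_rows, n_cols)`` array with ``NaN`` at masked
    positions; valid positions hold non-negative RMS amplitudes. ``normalized``
    records whether values are fractions of MVC (set by
    :func:`hdemg.preprocess.normalize`); ``window`` is the analysis-epoch
    provenance.
    """

    values: np.ndarray
    layout: GridLayout
    normalized: bool = False
    window: TrialWindow | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.n_rows, self.layout.n_cols):
            raise ConfigurationError(
                f"map shape {self.values.shape} does not match the "
                f"{self.layout.n_rows}x{self.layout.n_cols} layout"
            )
        vals = self.valid_values
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("map has non-finite values at valid electrodes")
        if np.any(vals < 0):
            raise ConfigurationError("map values must be non-negative")

    @classmethod
    def from_channels(
        cls,
        channel_values: np.ndarray,
        layout: GridLayout,
        *,
        normalized: bool = False,
        window: TrialWindow | None = None,
    ) -> "ActivationMap":
        """Build a map from a 1-D channel-ordered value vector."""
        channel_values = np.asarray(channel_values, dtype=float).ravel()
        if channel_values.shape[0] != layout.n_valid:
            raise ConfigurationError(
                f"{channel_values.shape[0]} values for {layout.n_valid} valid electrodes"
            )
        grid = np.full((layout.n_rows, layout.n_cols), np.nan)
        for value, (r, c) in zip(channel_values, layout.valid_positions):
            grid[r, c] = value
        return cls(grid, layout, normalized=normalized, window=window)

    @property
    def mask(self) -> np.ndarray:
        """Boolean valid-electrode indicator, shape ``(n_rows, n_cols)``."""
        mask = np.ones((self.layout.n_rows, self.layout.n_cols), dtype=bool)
        for r, c in self.layout.missing:
            mask[r, c] = False
        return mask

    @property
    def valid_values(self) -> np.ndarray:
        """Values at valid electrodes, 1-D in channel order."""
        return np.array([self.values[r, c] for r, c in self.layout.valid_positions])

    @property
    def n_valid(self) -> int:
        return self.layout.n_valid

    def scaled(self, k: float) -> "ActivationMap":
        if k < 0:
            raise ConfigurationError("scale factor must be non-negative")
        return ActivationMap(
            self.values * k, self.layout, normalized=self.normalized, window=self.window
        )


class DifferentialIntensity(NamedTuple):
    """Differential-intensity value with its quality flag."""

    value: float
    floored: bool
    n_pairs: int


@dataclass(frozen=True)
class SpatialFeatures:
    """The five per-trial spatial features.

    ``intensity`` and ``differential_intensity`` are log10 amplitudes in
    arbitrary units; ``mean_rms`` is a fraction of MVC (multiply by 100 to
    report %MVC); ``entropy`` is in bits; ``cov`` in percent.
    """

    intensity: float
    differential_intensity: float
    mean_rms: float
    entropy: float
    cov: float
    n_channels_used: int
    di_floored: bool = False


def _window_segment(recording: EMGRecording, window: TrialWindow) -> np.ndarray:
    if window.end > recording.n_samples:
        raise ConfigurationError(
            f"window [{window.start}, {window.end}) exceeds the "
            f"{recording.n_samples}-sample recording"
        )
    return recording.samples[window.slice(), :]


def build_map(recording: EMGRecording, window: TrialWindow) -> ActivationMap:
    """Compute the RMS activation map of a recording over an analysis window.

    Each valid electrode's pixel is the root-mean-square of its channel over
    ``[start, end)``; masked electrodes stay absent (NaN).
    """
    segment = _window_segment(recording, window)
    rms = np.sqrt(np.mean(segment**2, axis=0))
    return ActivationMap.from_channels(rms, recording.layout, window=window)


def intensity(map: ActivationMap) -> float:
    """Common logarithm of the mean map value, ``I = log10((1/N) sum HM)``.

    Raises :class:`UndefinedFeatureError` on an all-zero map (log of zero)
    rather than returning a sentinel.
    """
    mean = float(np.mean(map.valid_values))
    if mean <= 0:
        raise UndefinedFeatureError("intensity is undefined for an all-zero map")
    return math.log10(mean)


def differential_intensity(
    recording: EMGRecording,
    window: TrialWindow,
    *,
    aggregate: Literal["log_of_mean", "mean_of_logs"] = "log_of_mean",
    floor: float = DI_FLOOR,
) -> DifferentialIntensity:
    """Differential intensity over single-differential channels.

    Forms the difference signal of every adjacent valid electrode pair along
    the fiber direction (within each column), takes each pair's RMS over the
    window, and returns ``log10`` of the mean pair RMS. The alternative
    ``aggregate="mean_of_logs"`` averages per-pair log10 values instead.

    If the differentials are identically zero (all channels carry the same
    signal) the log argument is floored at ``floor`` and the result flagged.
    """
    pairs = recording.layout.fiber_pairs()
    if not pairs:
        raise ConfigurationError("layout has no adjacent valid electrode pair")
    segment = _window_segment(recording, window)
    idx = recording.layout.channel_index
    pair_rms = np.array(
        [
            np.sqrt(np.mean((segment[:, idx(*a)] - segment[:, idx(*b)]) ** 2))
            for a, b in pairs
        ]
    )
    if aggregate == "log_of_mean":
        mean = float(np.mean(pair_rms))
        floored = mean <= floor
        value = math.log10(max(mean, floor))
    elif aggregate == "mean_of_logs":
        floored = bool(np.any(pair_rms <= floor))
        value = float(np.mean(np.log10(np.maximum(pair_rms, floor))))
    else:
        raise ConfigurationError(f"unknown aggregate mode {aggregate!r}")
    return DifferentialIntensity(value, floored, len(pairs))


def modified_entropy(map: ActivationMap) -> float:
    """Modified entropy of the map's normalized channel power, in bits.

    ``p_i^2 = HM_i^2 / sum_j HM_j^2`` over the valid channels;
    ``E = -sum_i p_i^2 log2 p_i^2`` with the ``0 log 0 = 0`` convention.
    Bounded by ``[0, log2 N_valid]``; raises on an all-zero map.
    """
    values = map.valid_values
    total_power = float(np.sum(values**2))
    if total_power <= 0:
        raise UndefinedFeatureError("entropy is undefined for an all-zero map")
    p = values**2 / total_power
    nonzero = p > 0
    return float(-np.sum(p[nonzero] * np.log2(p[nonzero])))


def coefficient_of_variation(map: ActivationMap, *, ddof: int = 1) -> float:
    """Coefficient of variation of the map values, in percent.

    ``CoV = 100 * SD / mean`` over valid channels. The default SD is the
    sample standard deviation (``ddof=1``); pass ``ddof=0`` for the
    population convention.
    """
    values = map.valid_values
    if values.size - ddof < 1:
        raise UndefinedFeatureError(
            f"CoV needs more than {ddof} valid channel(s), got {values.size}"
        )
    mean = float(np.mean(values))
    if mean <= 0:
        raise UndefinedFeatureError("CoV is undefined for a zero-mean map")
    return 100.0 * float(np.std(values, ddof=ddof)) / mean


def mean_rms(map: ActivationMap) -> float:
    """Mean of an MVC-normalized map — mean activation as a fraction of MVC.

    Requires a normalized map; computing it on raw amplitudes would silently
    report meaningless units, so that is an error.
    """
    if not map.normalized:
        raise NormalizationError("mean_rms requires an MVC-normalized map")
    return float(np.mean(map.valid_values))
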