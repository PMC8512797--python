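"""In-memory containers for multichannel EMG, force traces and derived
references.

All channel-ordered arrays follow the row-major valid-electrode order defined
by :class:`~hdemg.grid.GridLayout`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import ConfigurationError, LayoutMismatchError
from .grid import GridLayout

__all__ = ["EMGRecording", "ForceTrace", "TrialWindow", "MVCReference"]


@dataclass
class EMGRecording:
    """Monopolar multichannel surface-EMG recording on a grid.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)``; one column per valid
        electrode, in the layout's row-major channel order. Masked electrodes
        carry no column.
    sampling_rate
        Sampling frequency in Hz.
    layout
        Electrode geometry the channels map onto.
    meta
        Trial metadata: participant, sex, muscle, side, handle-design code,
        trial kind (``"push"`` or ``"mvc"``), simulation seed if synthetic,
        and a ``"provenance"`` list that each processing stage appends its
        parameters to.
    """

    samples: np.ndarray
    sampling_rate: float
    layout: GridLayout
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigurationError("samples must be a 2-D (n_samples, n_channels) array")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.samples.shape[1] != self.layout.n_valid:
            raise ConfigurationError(
                f"recording has {self.samples.shape[1]} channels but the layout "
                f"defines {self.layout.n_valid} valid electrodes"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, row: int, col: int) -> np.ndarray:
        """Time series of the electrode at ``(row, col)``."""
        return self.samples[:, self.layout.channel_index(row, col)]

    def with_samples(self, samples: np.ndarray, **meta_updates: Any) -> "EMGRecording":
        """Copy of this recording with new sample data and updated metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return EMGRecording(samples, self.sampling_rate, self.layout, meta)


@dataclass
class ForceTrace:
    """Hand-force time series in newtons, on the same clock as its paired
    EMG recording (shared time origin, sample 0 = recording start)."""

    force: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float).ravel()
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.force)):
            raise ConfigurationError("force trace contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.force.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class TrialWindow:
    """Half-open sample-index window ``[start, end)`` of an analysis epoch."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ConfigurationError(
                f"window [{self.start}, {self.end}) is empty or negative"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def duration(self, sampling_rate: float) -> float:
        return self.n_samples / sampling_rate

    def slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass
class MVCReference:
    """Per-channel maximum-voluntary-contraction amplitude reference.

    ``values`` holds one strictly positive RMS reference per valid electrode,
    in channel order; task maps are divided by it to express activation as a
    fraction of MVC.
    """

    values: np.ndarray
    layout: GridLayout
    muscle: str | None = None
    side: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape[0] != self.layout.n_valid:
            raise LayoutMismatchError(
                f"MVC reference has {self.values.shape[0]} entries for a layout "
                f"with {self.layout.n_valid} valid electrodes"
            )
        if not np.all(self.values > 0):
            raise ConfigurationError("MVC reference values must be strictly positive")

    @property
    def grid_scalar(self) -> float:
        """Single grid-level reference (mean of the per-channel references),
        for the scalar normalization mode."""
        return float(np.mean(self.values))
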