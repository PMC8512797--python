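"""Electrode grid geometry.

The recording hardware modelled here is a 2-D adhesive electrode grid with
eight rows and four columns (one electrode absent in the upper-right corner,
31 usable sites) at 8 mm inter-electrode distance in both directions. The
grid is placed so that its *columns* run parallel to the muscle fibers;
consecutive electrodes within a column (adjacent rows) are therefore the
pairs used to form single-differential channels.

Conventions, asserted in tests and recorded in every file sidecar:

* grid indices are 0-based ``(row, col)``; row 0 is the top of the grid as
  placed, column 0 the left edge;
* channels are ordered row-major over the valid electrodes and named
  ``r<row>c<col>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

__all__ = ["GridLayout", "DEFAULT_MISSING"]

#: Upper-right corner electrode absent on the default 8x4 grid.
DEFAULT_MISSING: frozenset[tuple[int, int]] = frozenset({(0, 3)})


@dataclass(frozen=True)
class GridLayout:
    """Geometry of an electrode grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions. The default 8 x 4 grid matches the 32-site adhesive
        arrays used for trunk-muscle recordings.
    missing
        Set of ``(row, col)`` positions with no electrode. The default marks
        the upper-right corner, leaving 31 valid electrodes.
    inter_electrode_distance_mm
        Center-to-center electrode spacing, identical in both directions.
    """

    n_rows: int = 8
    n_cols: int = 4
    missing: frozenset[tuple[int, int]] = DEFAULT_MISSING
    inter_electrode_distance_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if self.inter_electrode_distance_mm <= 0:
            raise ConfigurationError("inter-electrode distance must be positive")
        object.__setattr__(self, "missing", frozenset(tuple(p) for p in self.missing))
        for r, c in self.missing:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ConfigurationError(
                    f"missing electrode ({r}, {c}) lies outside the "
                    f"{self.n_rows}x{self.n_cols} grid"
                )
        if not self.valid_positions:
            raise ConfigurationError("layout has no valid electrode")

    @property
    def valid_positions(self) -> tuple[tuple[int, int], ...]:
        """Valid ``(row, col)`` positions in row-major channel order."""
        return tuple(
            (r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
            if (r, c) not in self.missing
        )

    @property
    def n_valid(self) -> int:
        return self.n_rows * self.n_cols - len(self.missing)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(f"r{r}c{c}" for r, c in self.valid_positions)

    def channel_index(self, row: int, col: int) -> int:
        """Index of electrode ``(row, col)`` in channel order."""
        try:
            return self.valid_positions.index((row, col))
        except ValueError:
            raise KeyError(f"({row}, {col}) is not a valid electrode") from None

    def is_valid(self, row: int, col: int) -> bool:
        return (
            0 <= row < self.n_rows
            and 0 <= col < self.n_cols
            and (row, col) not in self.missing
        )

    def fiber_pairs(self) -> tuple[tuple[tuple[int, int], tuple[int, int]], ...]:
        """Adjacent valid electrode pairs along the fiber direction.

        Columns run parallel to the fibers, so a pair is ``(r, c)`` with
        ``(r+1, c)``; on the full 8x4 grid this yields 7 pairs per column
        (28 total), fewer wherever the absent electrode breaks a pair.
        """
        return tuple(
            ((r, c), (r + 1, c))
            for c in range(self.n_cols)
            for r in range(self.n_rows - 1)
            if self.is_valid(r, c) and self.is_valid(r + 1, c)
        )
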