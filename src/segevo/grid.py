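"""Spatial axis and expression-profile containers.

All patterning in this package lives on a one-dimensional anterior-posterior
(AP) axis, discretized into uniform bins. Position is measured as a fraction
of embryo length, anterior pole at ``x = 0``; the axis is half-open, ``[0, 1)``.
There is no spatial coupling in the model: every bin is an autonomous cell
reading the local maternal gradient levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AxisGrid", "SpatialProfile"]


@dataclass(frozen=True)
class AxisGrid:
    """Uniform discretization of the AP axis.

    Parameters
    ----------
    n_bins
        Number of bins; at least 50 so that up to ~8 pair-rule stripes can be
        resolved. The default of 200 gives a bin width of 0.5% embryo length.
    """

    n_bins: int = 200

    def __post_init__(self) -> None:
        if int(self.n_bins) != self.n_bins or self.n_bins < 50:
            raise ValueError(f"n_bins must be an integer >= 50, got {self.n_bins!r}")

    @property
    def positions(self) -> np.ndarray:
        """Left bin edges, strictly increasing, in ``[0, 1)``."""
        return np.arange(self.n_bins) / float(self.n_bins)

    @property
    def spacing(self) -> float:
        return 1.0 / self.n_bins

    def index_of(self, x: float) -> int:
        """Bin index containing axis position ``x``."""
        if not 0.0 <= x < 1.0:
            raise ValueError(f"position {x} outside [0, 1)")
        return int(x * self.n_bins)


@dataclass
class SpatialProfile:
    """One gene's (or regulatory module's) expression level along the axis.

    Values are non-negative, finite, in arbitrary concentration units, one per
    grid bin.
    """

    gene: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError(f"profile for {self.gene!r} must be 1-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"profile for {self.gene!r} contains non-finite values")
        if np.any(v < 0):
            raise ValueError(f"profile for {self.gene!r} contains negative values")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)

    @property
    def max(self) -> float:
        return float(self.values.max()) if len(self.values) else 0.0

    def normalized(self, floor: float = 0.0) -> np.ndarray:
        """Profile scaled to unit maximum.

        If the maximum is at or below ``floor`` the profile is treated as
        absent and a zero array is returned (avoids amplifying numerical
        residue of an eliminated module into an O(1) shape).
        """
        m = self.max
        if m <= floor or m == 0.0:
            return np.zeros_like(self.values)
        return self.values / m

    def copy(self) -> "SpatialProfile":
        return SpatialProfile(self.gene, self.values.copy())
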