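"""Stimulus-space geometry for continuous-reproduction tasks.

Two one-dimensional response geometries are supported:

* :class:`CircularSpace` — periodic features such as grating orientation
  (period 180 deg).  Internally, orientations are mapped onto the full
  circle by angle doubling, the standard treatment in directional
  statistics for axial data; results are halved back on output.
* :class:`BoundedSpace` — a bounded Euclidean interval, e.g. the intensity
  of a facial expression morph in percent, clamped to [0, 100].

All error arithmetic and histogram binning used elsewhere in the package
is defined here so that every module agrees on wrapping and bin-edge
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "CircularSpace",
    "BoundedSpace",
    "FeatureSpace",
    "signed_error",
    "response_bins",
    "fitting_bin_edges",
    "bin_index",
]


@dataclass(frozen=True)
class CircularSpace:
    """A periodic stimulus dimension.

    Parameters
    ----------
    period:
        Angular extent in degrees over which stimuli repeat.  Grating
        orientation has period 180: a bar at 0 deg is identical to one at
        180 deg.
    """

    period: float = 180.0

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ValueError(f"period must be positive, got {self.period}")

    @property
    def half_period(self) -> float:
        return self.period / 2.0

    # -- value handling -------------------------------------------------
    def wrap(self, values):
        """Wrap values into the canonical interval [0, period).

        Wrapping is idempotent.
        """
        w = np.mod(values, self.period)
        # np.mod of a tiny negative can round up to exactly `period`
        w = np.where(w >= self.period, 0.0, w)
        return w[()] if np.ndim(w) == 0 else w

    def validate(self, values, name: str = "value") -> None:
        arr = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite entries")

    def signed_error(self, target, response):
        """Signed deviation response - target, wrapped into (-period/2, period/2].

        The antipode (exactly period/2 away) maps to +period/2.
        """
        self.validate(target, "target")
        self.validate(response, "response")
        d = np.mod(np.asarray(response, dtype=float) - np.asarray(target, dtype=float), self.period)
        out = np.where(d > self.half_period, d - self.period, d)
        return out[()] if np.ndim(out) == 0 else out

    # -- doubled-angle internal representation --------------------------
    def to_doubled_radians(self, values):
        """Map stimulus values onto the full circle in radians (angle doubling)."""
        return np.asarray(values, dtype=float) * (2.0 * np.pi / self.period)

    def from_doubled_radians(self, phi):
        return np.asarray(phi, dtype=float) * (self.period / (2.0 * np.pi))

    # -- binning --------------------------------------------------------
    def bin_edges(self, n_bins: int) -> np.ndarray:
        """Equal-width bin edges tiling the response space [0, period]."""
        _check_n_bins(n_bins)
        return np.linspace(0.0, self.period, n_bins + 1)

    def error_edges(self, n_bins: int) -> np.ndarray:
        """Equal-width bin edges tiling the signed-error range [-period/2, period/2]."""
        _check_n_bins(n_bins)
        return np.linspace(-self.half_period, self.half_period, n_bins + 1)


@dataclass(frozen=True)
class BoundedSpace:
    """A bounded one-dimensional Euclidean stimulus dimension.

    The default [0, 100] interval corresponds to expression intensity in
    percent, from a neutral face (0%) to the full emotional expression
    (100%).
    """

    lower: float = 0.0
    upper: float = 100.0

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError(f"upper ({self.upper}) must exceed lower ({self.lower})")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def validate(self, values, name: str = "value") -> None:
        arr = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite entries")
        bad = (arr < self.lower) | (arr > self.upper)
        if np.any(bad):
            offender = float(np.asarray(arr)[np.nonzero(np.atleast_1d(bad))[0][0]]) if arr.ndim else float(arr)
            raise ValueError(
                f"{name} outside [{self.lower}, {self.upper}]: {offender!r}"
            )

    def signed_error(self, target, response):
        """Plain difference response - target; both must lie in the interval."""
        self.validate(target, "target")
        self.validate(response, "response")
        out = np.asarray(response, dtype=float) - np.asarray(target, dtype=float)
        return out[()] if np.ndim(out) == 0 else out

    def bin_edges(self, n_bins: int) -> np.ndarray:
        _check_n_bins(n_bins)
        return np.linspace(self.lower, self.upper, n_bins + 1)


FeatureSpace = Union[CircularSpace, BoundedSpace]


def _check_n_bins(n_bins: int) -> None:
    if n_bins < 2:
        raise ValueError(f"n_bins must be at least 2, got {n_bins}")


def signed_error(space: FeatureSpace, target, response):
    """Signed reproduction error in the given space (see the space classes)."""
    return space.signed_error(target, response)


def response_bins(space: FeatureSpace, n_bins: int) -> np.ndarray:
    """Edges of ``n_bins`` equal-width bins tiling the response space once."""
    return space.bin_edges(n_bins)


def fitting_bin_edges(space: FeatureSpace, n_bins: int) -> np.ndarray:
    """Bin edges used as the fitting currency.

    Circular spaces are binned in signed-error coordinates (the error
    distribution is rotation invariant); bounded spaces are binned in
    response coordinates per target.
    """
    if isinstance(space, CircularSpace):
        return space.error_edges(n_bins)
    return space.bin_edges(n_bins)


def bin_index(edges: np.ndarray, values, closed: str = "right") -> np.ndarray:
    """Map values to bin indices for the given ordered edges.

    closed="right": bins are [e_i, e_{i+1}) with the last bin closed above
    (used for response-space binning, so the upper bound maps to the last
    bin).  closed="left": bins are (e_i, e_{i+1}] (used for circular
    signed-error binning, whose range is (-period/2, period/2]).
    """
    vals = np.asarray(values, dtype=float)
    n = len(edges) - 1
    if closed == "right":
        idx = np.searchsorted(edges, vals, side="right") - 1
    elif closed == "left":
        idx = np.searchsorted(edges, vals, side="left") - 1
    else:  # pragma: no cover - programming error
        raise ValueError(f"unknown closed mode {closed!r}")
    return np.clip(idx, 0, n - 1)
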