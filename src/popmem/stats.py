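"""Descriptive statistics of reproduction errors: bias and variability.

Bounded features use ordinary Euclidean statistics (arithmetic mean,
sample SD).  Circular features use directional statistics on doubled
angles: the circular mean direction for bias and Fisher's circular
standard deviation sqrt(-2 ln Rbar) for dispersion, where Rbar is the
mean resultant length.  Results are rescaled back to the original
(period-180) orientation scale by halving; the raw doubled-angle value is
also available since conventions differ between reports.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .spaces import BoundedSpace, CircularSpace, FeatureSpace

__all__ = ["bias", "dispersion", "summarize"]


def _as_errors(errors) -> np.ndarray:
    arr = np.asarray(errors, dtype=float)
    if arr.size == 0:
        raise ValueError("empty error set")
    return arr


def bias(errors, space: FeatureSpace) -> float:
    """Mean signed error.

    Circular: circular mean direction of the doubled-angle errors, halved
    back to the stimulus scale (result in (-period/2, period/2]).
    """
    arr = _as_errors(errors)
    if isinstance(space, CircularSpace):
        phi = space.to_doubled_radians(arr)
        mean_dir = np.arctan2(np.sin(phi).mean(), np.cos(phi).mean())
        out = float(space.from_doubled_radians(mean_dir))
        if out <= -space.half_period:
            out += space.period
        return out
    return float(arr.mean())


def dispersion(errors, space: FeatureSpace, scale: str = "stimulus") -> float:
    """Standard deviation of signed errors.

    Bounded: sample SD (n-1 denominator; 0.0 for a single observation).
    Circular: Fisher's circular SD sqrt(-2 ln Rbar) computed on doubled
    angles.  ``scale`` selects the units for circular spaces:
    "stimulus" (default) rescales the doubled-angle radian value back to
    the orientation scale in degrees; "doubled_radians" returns it raw.
    A zero resultant (Rbar = 0) yields infinity, not an exception.
    """
    arr = _as_errors(errors)
    if isinstance(space, BoundedSpace):
        if arr.size == 1:
            return 0.0
        return float(arr.std(ddof=1))
    if scale not in ("stimulus", "doubled_radians"):
        raise ValueError(f"unknown scale {scale!r}")
    phi = space.to_doubled_radians(arr)
    rbar = float(np.hypot(np.sin(phi).mean(), np.cos(phi).mean()))
    if rbar < 1e-12:  # exactly balanced sample: no preferred direction
        return float("inf")
    sd = np.sqrt(-2.0 * np.log(min(rbar, 1.0)))
    if scale == "doubled_radians":
        return float(sd)
    return float(space.from_doubled_radians(sd))


def summarize(
    trials: pd.DataFrame,
    grouping: Sequence[str],
    space: FeatureSpace,
) -> pd.DataFrame:
    """Bias, dispersion and trial count per group of reproduction trials.

    ``trials`` must carry ``target`` and ``response`` columns; rows with
    a ``probed`` column are filtered to probed items first.  An empty
    grouping list yields a single grand-summary row.  Circular spaces
    additionally report the dispersion in doubled-angle radians
    (``sd_doubled_rad``), since both conventions appear in the
    literature.
    """
    grouping = list(grouping)
    if "probed" in trials.columns:
        trials = trials[trials["probed"].astype(bool)]
    for col in ["target", "response", *grouping]:
        if col not in trials.columns:
            raise KeyError(f"unknown column {col!r} in trial table")
    if len(trials) == 0:
        raise ValueError("no probed trials to summarize")
    work = trials.copy()
    work["_error"] = space.signed_error(
        work["target"].to_numpy(dtype=float), work["response"].to_numpy(dtype=float)
    )

    def _row(err: np.ndarray) -> dict:
        out = {
            "n": int(err.size),
            "bias": bias(err, space),
            "sd": dispersion(err, space),
        }
        if isinstance(space, CircularSpace):
            out["sd_doubled_rad"] = dispersion(err, space, scale="doubled_radians")
        return out

    if not grouping:
        return pd.DataFrame([_row(work["_error"].to_numpy())])
    rows = []
    for key, sub in work.groupby(grouping, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(grouping, key)) | _row(sub["_error"].to_numpy()))
    return pd.DataFrame(rows)
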