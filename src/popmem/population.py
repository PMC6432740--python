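"""Neural population encoding and decoding of a single memorized feature.

The model: a memorized stimulus value theta is encoded in the spike counts
of M feature-selective neurons with preferred values tiling the space.
Neuron i fires with a Poisson count of mean

    f_i(theta) = (gamma / N) * g_i(theta) / sum_j g_j(theta)

where g_i is a bell-shaped tuning kernel (von-Mises-shaped on the doubled
circle for circular spaces, Gaussian for bounded spaces), gamma is the
gain constant — the expected total spike count of the population — and N
is the number of items concurrently in memory.  The divisive
normalization makes the summed expected count exactly gamma/N for every
stimulus value, so total population activity is conserved across set
sizes: memory load is carried entirely by the per-item share gamma/N.

Decoding reconstructs the stimulus from a spike pattern either by
maximum likelihood over a dense stimulus grid, or by drawing one sample
from the Bayesian posterior (likelihood times a prior over the grid).
Posterior sampling is the natural read-out for bounded spaces, where the
decoded value must stay inside the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .spaces import BoundedSpace, CircularSpace, FeatureSpace

__all__ = [
    "PopulationParams",
    "PriorDistribution",
    "preferred_values",
    "tuning_kernel",
    "expected_rates",
    "sample_spikes",
    "decoding_grid",
    "log_likelihood_grid",
    "decode_ml",
    "posterior_probabilities",
    "decode_posterior_sample",
    "simulate_responses",
]

#: Default decoding-grid step: 1 degree for orientation (pre-doubling),
#: 0.5% for expression intensity.
DEFAULT_GRID_STEP_CIRCULAR = 1.0
DEFAULT_GRID_STEP_BOUNDED = 0.5

#: Default population size.
DEFAULT_N_NEURONS = 1000


@dataclass(frozen=True)
class PopulationParams:
    """The model's two free parameters plus the population layout.

    Parameters
    ----------
    gain:
        gamma — expected total spike count of the population across all
        memorized items (dimensionless count, > 0).
    tuning_width:
        omega — dispersion of each neuron's tuning kernel.  For circular
        spaces this is the width of the von-Mises-shaped kernel in
        doubled-angle radians (concentration kappa = 1/omega**2); for
        bounded spaces it is the Gaussian standard deviation in stimulus
        units (% intensity).
    n_neurons:
        Population size M (default 1000).
    """

    gain: float
    tuning_width: float
    n_neurons: int = DEFAULT_N_NEURONS

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if not self.tuning_width > 0:
            raise ValueError(f"tuning_width must be positive, got {self.tuning_width}")
        if self.n_neurons < 2:
            raise ValueError(f"n_neurons must be at least 2, got {self.n_neurons}")

    def preferred_values(self, space: FeatureSpace) -> np.ndarray:
        return preferred_values(space, self.n_neurons)


def preferred_values(space: FeatureSpace, m: int) -> np.ndarray:
    """M preferred stimulus values evenly spaced over the space.

    Circular: evenly around the circle, endpoint excluded (0 and the
    period coincide).  Bounded: evenly over [lower, upper] inclusive.
    """
    if isinstance(space, CircularSpace):
        return np.arange(m) * (space.period / m)
    return np.linspace(space.lower, space.upper, m)


def tuning_kernel(space: FeatureSpace, tuning_width: float, stimulus, centers):
    """Unnormalized tuning kernel g evaluated at ``stimulus`` for each center.

    Broadcasts: ``stimulus`` and ``centers`` follow numpy broadcasting
    rules; typical use is ``stimulus[..., None]`` against a 1-D center
    array.
    """
    w2 = float(tuning_width) ** 2
    if isinstance(space, CircularSpace):
        phi = space.to_doubled_radians(stimulus)
        phic = space.to_doubled_radians(centers)
        return np.exp((np.cos(phi - phic) - 1.0) / w2)
    d = np.asarray(stimulus, dtype=float) - np.asarray(centers, dtype=float)
    return np.exp(-(d * d) / (2.0 * w2))


def expected_rates(
    params: PopulationParams,
    space: FeatureSpace,
    stimulus,
    set_size: int,
) -> np.ndarray:
    """Mean spike count per neuron for one memorized item among ``set_size``.

    Divisive normalization guarantees the rates sum to gain/set_size for
    every stimulus value, including near the edges of a bounded space.
    """
    if set_size < 1:
        raise ValueError(f"set_size must be at least 1, got {set_size}")
    space.validate(stimulus, "stimulus")
    centers = params.preferred_values(space)
    g = tuning_kernel(space, params.tuning_width, np.asarray(stimulus, dtype=float)[..., None], centers)
    total = g.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise FloatingPointError("tuning kernel sum underflowed to zero")
    return (params.gain / set_size) * g / total


def sample_spikes(rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson spike counts, one per neuron."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    return rng.poisson(rates)


def decoding_grid(space: FeatureSpace, step: Optional[float] = None) -> np.ndarray:
    """Dense grid of candidate stimulus values used for decoding."""
    if isinstance(space, CircularSpace):
        step = DEFAULT_GRID_STEP_CIRCULAR if step is None else step
        return np.arange(0.0, space.period, step)
    step = DEFAULT_GRID_STEP_BOUNDED if step is None else step
    n = int(round(space.width / step))
    return np.linspace(space.lower, space.upper, n + 1)


def log_likelihood_grid(
    spikes: np.ndarray,
    params: PopulationParams,
    space: FeatureSpace,
    set_size: int,
    grid: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Poisson log-likelihood of the spike pattern at each grid value.

    Entry for candidate theta is sum_i [n_i log f_i(theta) - f_i(theta)],
    i.e. the Poisson log-likelihood up to the theta-independent factorial
    terms.  A rate that underflows to zero while the neuron spiked gives
    -inf, not an exception.
    """
    spikes = np.asarray(spikes)
    if spikes.ndim != 1 or len(spikes) != params.n_neurons:
        raise ValueError("spike pattern length must equal n_neurons")
    if np.any(spikes < 0):
        raise ValueError("spike counts must be non-negative")
    if grid is None:
        grid = decoding_grid(space)
    rates = expected_rates(params, space, grid, set_size)  # (G, M)
    with np.errstate(divide="ignore"):
        log_rates = np.log(rates)
    active = spikes > 0
    ll = -rates.sum(axis=1)
    if np.any(active):
        contrib = spikes[active] * log_rates[:, active]
        # n_i > 0 with f_i == 0 contributes -inf; suppress the 0 * -inf
        # warning for inactive neurons by never touching them.
        ll = ll + contrib.sum(axis=1)
    return ll


def decode_ml(
    spikes: np.ndarray,
    params: PopulationParams,
    space: FeatureSpace,
    set_size: int,
    grid: Optional[np.ndarray] = None,
) -> float:
    """Maximum-likelihood decoded stimulus value.

    Returns the grid point of maximal log-likelihood.  Ties — including
    numerical ties within an absolute tolerance of 1e-9, such as the
    exactly flat surface left by a zero-spike pattern — are broken by
    the lowest grid index.
    """
    if grid is None:
        grid = decoding_grid(space)
    ll = log_likelihood_grid(spikes, params, space, set_size, grid)
    return float(grid[int(np.argmax(ll >= ll.max() - 1e-9))])


@dataclass(frozen=True)
class PriorDistribution:
    """A discrete prior over the decoding grid.

    ``weights`` are non-negative and are normalized to sum to one.
    """

    grid: np.ndarray
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if grid.shape != w.shape:
            raise ValueError("grid and weights must have the same shape")
        if np.any(w < 0):
            raise ValueError("prior weights must be non-negative")
        total = w.sum()
        if not total > 0:
            raise ValueError("prior weights must not all be zero")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "weights", w / total)

    @classmethod
    def uniform(cls, space: FeatureSpace, grid: Optional[np.ndarray] = None) -> "PriorDistribution":
        """Uniform prior over the decoding grid (the model's default)."""
        if grid is None:
            grid = decoding_grid(space)
        return cls(grid=grid, weights=np.ones_like(grid))

    @classmethod
    def point_mass(cls, space: FeatureSpace, value: float, grid: Optional[np.ndarray] = None) -> "PriorDistribution":
        if grid is None:
            grid = decoding_grid(space)
        w = np.zeros_like(grid)
        w[int(np.argmin(np.abs(grid - value)))] = 1.0
        return cls(grid=grid, weights=w)


def posterior_probabilities(
    spikes: np.ndarray,
    params: PopulationParams,
    space: FeatureSpace,
    set_size: int,
    prior: PriorDistribution,
) -> np.ndarray:
    """Normalized posterior over the prior's grid (log-sum-exp stable)."""
    ll = log_likelihood_grid(spikes, params, space, set_size, prior.grid)
    with np.errstate(divide="ignore"):
        logw = np.log(prior.weights)
    logpost = ll + logw
    peak = np.max(logpost)
    if not np.isfinite(peak):
        raise ValueError("posterior has no support: all mass is zero")
    p = np.exp(logpost - peak)
    return p / p.sum()


def decode_posterior_sample(
    spikes: np.ndarray,
    params: PopulationParams,
    space: FeatureSpace,
    set_size: int,
    prior: PriorDistribution,
    rng: np.random.Generator,
) -> float:
    """One draw from the posterior over stimulus values.

    With zero spikes the likelihood is flat (normalization fixes the
    expected total count independent of theta), so the draw follows the
    prior exactly.
    """
    p = posterior_probabilities(spikes, params, space, set_size, prior)
    return float(prior.grid[rng.choice(len(p), p=p)])


def simulate_responses(
    params: PopulationParams,
    space: FeatureSpace,
    target: float,
    set_size: int,
    decoder: str,
    n: int,
    rng: np.random.Generator,
    prior: Optional[PriorDistribution] = None,
    grid: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Simulate ``n`` full encode-decode cycles at one target value.

    decoder is "ml" or "posterior_sampling".  Uses a vectorized sampler
    (total count + categorical neuron assignment, exactly equivalent to
    per-neuron Poisson draws) so large n is cheap.
    """
    from . import _engine  # local import to avoid a cycle

    if n < 1:
        raise ValueError("n must be at least 1")
    if grid is None:
        grid = decoding_grid(space)
    log_prior = _engine.log_prior_weights(space, grid, prior)
    totals = np.full(n, params.gain / set_size)
    return _engine.simulate_batch(
        space,
        params.tuning_width,
        totals,
        np.full(n, float(target)),
        decoder,
        grid,
        log_prior,
        rng,
        params.n_neurons,
    )
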