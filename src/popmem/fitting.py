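"""Model fitting: predicted error distributions, grid search, AIC comparison.

The fitting currency is a binned Monte-Carlo estimate of the model's
response distribution.  For every candidate parameter pair (gain gamma,
tuning width omega) on a log-spaced grid, simulated encode-decode cycles
produce a histogram of predicted responses (bounded spaces: per target,
over the response interval; circular spaces: of signed errors, which are
rotation invariant).  The log-likelihood of the observed trials is the
summed log probability of the bins their responses fall in, and the grid
maximizer is the fit.  Model variants (maximum-likelihood vs
posterior-sampling read-out) are compared with the Akaike Information
Criterion; both have k = 2 free parameters, so AIC differences reduce to
likelihood differences.

Two evaluation engines are available:

* ``"stratified"`` (default) — stratifies the Monte-Carlo prediction by
  the total spike count T.  Decode outcomes conditional on T do not
  depend on the gain or the set size (those enter only through the
  Poisson distribution of T), so one table of count-conditional
  histograms per tuning width serves the entire gain grid and every set
  size, with the Poisson mixing done exactly.  This is a
  variance-reduced, much faster estimator of the same quantity.
* ``"direct"`` — literally evaluates :func:`trial_log_likelihood` (plain
  forward simulation) at every grid point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _engine
from .population import (
    PopulationParams,
    PriorDistribution,
    decoding_grid,
    simulate_responses,
)
from .spaces import (
    BoundedSpace,
    CircularSpace,
    FeatureSpace,
    bin_index,
    fitting_bin_edges,
)

__all__ = [
    "ErrorDistribution",
    "FitResult",
    "DecoderComparison",
    "TASKS",
    "task_space",
    "task_defaults",
    "default_grids",
    "predict_distribution",
    "trial_log_likelihood",
    "grid_search_fit",
    "fit_grouped",
    "aic",
    "compare_decoders",
]


def _orientation_ml_width_grid() -> np.ndarray:
    # Tuning of the ML-decoding variant is grid-searched in concentration
    # units, 60 log-spaced kappa in [1, 100]; exposed in width units
    # omega = 1/sqrt(kappa), ascending.
    return np.sort(1.0 / np.sqrt(np.logspace(0.0, 2.0, 60)))


#: Per-task default configuration: stimulus space, decoder, simulated
#: responses per target, histogram bins, and the parameter grids.
TASKS: Dict[str, dict] = {
    "orientation_ml": dict(
        space=CircularSpace(180.0),
        decoder="ml",
        n_sim=10_000,
        n_bins=40,
        gain_grid=np.logspace(0.0, 2.0, 60),
        width_grid=_orientation_ml_width_grid(),
    ),
    "orientation_sampling": dict(
        space=CircularSpace(180.0),
        decoder="posterior_sampling",
        n_sim=10_000,
        n_bins=40,
        gain_grid=np.logspace(-1.0, 3.0, 50),
        width_grid=np.logspace(-1.0, 0.0, 20),
    ),
    "expression_sampling": dict(
        space=BoundedSpace(0.0, 100.0),
        decoder="posterior_sampling",
        n_sim=100_000,
        n_bins=20,
        gain_grid=np.logspace(-1.0, 3.0, 50),
        width_grid=np.logspace(-2.0, 1.0, 50),
    ),
}


def _task(task: str) -> dict:
    try:
        return TASKS[task]
    except KeyError:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}") from None


def task_space(task: str) -> FeatureSpace:
    return _task(task)["space"]


def task_defaults(task: str) -> dict:
    """Full default configuration for a named task (copy)."""
    return dict(_task(task))


def default_grids(task: str) -> Tuple[np.ndarray, np.ndarray]:
    """(gain grid, tuning-width grid) for a named task."""
    cfg = _task(task)
    return cfg["gain_grid"].copy(), cfg["width_grid"].copy()


@dataclass(frozen=True)
class ErrorDistribution:
    """Binned probability estimate of model responses for one condition.

    For circular spaces the bins cover signed errors in
    (-period/2, period/2]; for bounded spaces they cover the response
    interval.  Probabilities are floored by add-one smoothing (no bin
    below 1/(n_sim + n_bins)) and sum to one.
    """

    space: FeatureSpace
    target: float
    set_size: int
    bin_edges: np.ndarray = field(repr=False)
    probabilities: np.ndarray = field(repr=False)
    decoder: str = "ml"
    n_sim: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def bin_of(self, targets, responses) -> np.ndarray:
        """Bin indices of observed responses (errors for circular spaces)."""
        if isinstance(self.space, CircularSpace):
            errors = self.space.signed_error(targets, responses)
            return bin_index(self.bin_edges, errors, closed="left")
        self.space.validate(responses, "response")
        return bin_index(self.bin_edges, responses, closed="right")

    def log_prob(self, targets, responses) -> np.ndarray:
        return np.log(self.probabilities[self.bin_of(targets, responses)])


def predict_distribution(
    params: PopulationParams,
    space: FeatureSpace,
    target: float,
    set_size: int,
    decoder: str,
    n_sim: int,
    n_bins: int,
    rng: np.random.Generator,
    prior: Optional[PriorDistribution] = None,
    grid: Optional[np.ndarray] = None,
    marginalize_targets: bool = False,
    n_floor: Optional[int] = None,
) -> ErrorDistribution:
    """Monte-Carlo predicted response distribution at one target value.

    Runs ``n_sim`` full encode-decode cycles and bins the outcomes
    (signed errors for circular spaces, responses for bounded spaces).
    ``marginalize_targets`` (circular only) returns the error marginal
    over continuously, uniformly distributed targets instead of the
    on-grid distribution at the literal target — the form needed to
    score orientation data, whose targets never sit on the decoding
    grid.  ``n_floor`` sets the pseudo-count floor 1/(n_floor + n_bins)
    (default: ``n_sim``).
    """
    if grid is None:
        grid = decoding_grid(space)
    n_floor = n_sim if n_floor is None else int(n_floor)
    edges = fitting_bin_edges(space, n_bins)
    if isinstance(space, CircularSpace):
        if marginalize_targets:
            log_prior = _engine.log_prior_weights(space, grid, prior)
            x = _engine.canonical_circular_error_samples(
                space, params.tuning_width, params.gain / set_size, decoder,
                grid, log_prior, rng, params.n_neurons, n_sim,
            )
        else:
            responses = simulate_responses(
                params, space, target, set_size, decoder, n_sim, rng,
                prior=prior, grid=grid,
            )
            x = space.signed_error(target, responses)
        bins = bin_index(edges, x, closed="left")
    else:
        responses = simulate_responses(
            params, space, target, set_size, decoder, n_sim, rng, prior=prior, grid=grid
        )
        bins = bin_index(edges, responses, closed="right")
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    probs = (n_floor * (counts / n_sim) + 1.0) / (n_floor + n_bins)
    return ErrorDistribution(
        space=space,
        target=float(target),
        set_size=int(set_size),
        bin_edges=edges,
        probabilities=probs,
        decoder=decoder,
        n_sim=n_sim,
    )


# ---------------------------------------------------------------------------
# Trial likelihood


def _require_columns(trials: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")


def _condition_keys(trials: pd.DataFrame, space: FeatureSpace):
    """Unique prediction conditions and a per-trial key array.

    Circular: the error distribution does not depend on the target, so
    conditions collapse to the set size and predictions are computed at a
    canonical target (period/2).  Bounded: one condition per unique
    (target, set size) pair.
    """
    if isinstance(space, CircularSpace):
        keys = [(space.half_period, int(n)) for n in sorted(trials["set_size"].unique())]
        trial_keys = [
            (space.half_period, int(n)) for n in trials["set_size"].to_numpy()
        ]
    else:
        pairs = sorted(
            {(float(t), int(n)) for t, n in zip(trials["target"], trials["set_size"])}
        )
        keys = pairs
        trial_keys = [
            (float(t), int(n)) for t, n in zip(trials["target"], trials["set_size"])
        ]
    return keys, trial_keys


def trial_log_likelihood(
    trials: pd.DataFrame,
    params: PopulationParams,
    space: FeatureSpace,
    decoder: str,
    n_sim: int,
    n_bins: int,
    seed: int,
    prior: Optional[PriorDistribution] = None,
    grid: Optional[np.ndarray] = None,
    n_floor: Optional[int] = None,
) -> float:
    """Summed log probability of the observed trials under the model.

    One predicted distribution is computed per unique condition (see
    :func:`_condition_keys`); each condition draws its Monte-Carlo stream
    from a child seed derived deterministically from ``seed`` and the
    condition's index in sorted order, so duplicated trials and cached
    vs uncached evaluation give identical results.  Circular predictions
    are dithered (targets in orientation data are continuous).
    """
    _require_columns(trials, ["target", "response", "set_size"])
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    space.validate(trials["response"].to_numpy(), "response")
    space.validate(trials["target"].to_numpy(), "target")
    keys, trial_keys = _condition_keys(trials, space)
    marginalize = isinstance(space, CircularSpace)
    dists = {}
    for k_idx, (target, set_size) in enumerate(keys):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k_idx,)))
        dists[(target, set_size)] = predict_distribution(
            params, space, target, set_size, decoder, n_sim, n_bins, rng,
            prior=prior, grid=grid, marginalize_targets=marginalize, n_floor=n_floor,
        )
    total = 0.0
    tvals = trials["target"].to_numpy(dtype=float)
    rvals = trials["response"].to_numpy(dtype=float)
    for i, key in enumerate(trial_keys):
        total += float(dists[key].log_prob(tvals[i], rvals[i]))
    return total


# ---------------------------------------------------------------------------
# Grid search


@dataclass(frozen=True)
class FitResult:
    """Outcome of a grid-search maximum-likelihood fit (k = 2 parameters)."""

    best_gain: float
    best_width: float
    log_likelihood: float
    aic: float
    gain_grid: np.ndarray = field(repr=False)
    width_grid: np.ndarray = field(repr=False)
    grid_loglik: np.ndarray = field(repr=False)
    decoder: str = "ml"
    n_trials: int = 0

    def grid_frame(self) -> pd.DataFrame:
        """Long-format dump of the evaluated likelihood surface."""
        gg, ww = np.meshgrid(self.gain_grid, self.width_grid, indexing="ij")
        return pd.DataFrame(
            {
                "gain": gg.ravel(),
                "width": ww.ravel(),
                "log_likelihood": self.grid_loglik.ravel(),
            }
        )


def aic(log_likelihood: float, n_params: int = 2) -> float:
    """Akaike Information Criterion, 2 k - 2 ln L."""
    if n_params < 0:
        raise ValueError("n_params must be non-negative")
    return 2.0 * n_params - 2.0 * log_likelihood


def _observed_cells(trials: pd.DataFrame, space: FeatureSpace, n_bins: int):
    """Observed bin counts per prediction condition.

    Returns a list of (table_target, set_size, counts) where table_target
    is the target the predicted distribution is computed at (canonical
    for circular spaces).
    """
    edges = fitting_bin_edges(space, n_bins)
    cells = []
    if isinstance(space, CircularSpace):
        errors = space.signed_error(
            trials["target"].to_numpy(dtype=float), trials["response"].to_numpy(dtype=float)
        )
        bins = bin_index(edges, errors, closed="left")
        for n in sorted(trials["set_size"].unique()):
            sel = trials["set_size"].to_numpy() == n
            counts = np.bincount(bins[sel], minlength=n_bins).astype(float)
            cells.append((space.half_period, int(n), counts))
    else:
        bins = bin_index(edges, trials["response"].to_numpy(dtype=float), closed="right")
        tvals = trials["target"].to_numpy(dtype=float)
        nvals = trials["set_size"].to_numpy()
        for target, set_size in sorted({(float(t), int(n)) for t, n in zip(tvals, nvals)}):
            sel = (tvals == target) & (nvals == set_size)
            counts = np.bincount(bins[sel], minlength=n_bins).astype(float)
            cells.append((target, set_size, counts))
    return cells


def _fit_stratified(
    trials, space, decoder, gain_grid, width_grid, n_sim, n_bins, seed,
    n_neurons, grid, log_prior, n_floor, n_chains,
):
    cells = _observed_cells(trials, space, n_bins)
    table_targets = sorted({t for t, _, _ in cells})
    set_sizes = sorted({n for _, n, _ in cells})
    edges = fitting_bin_edges(space, n_bins)
    dither = isinstance(space, CircularSpace)
    t_cap = _engine.spike_count_cap(float(np.max(gain_grid)) / min(set_sizes))
    if n_chains is None:
        if isinstance(space, CircularSpace):
            # the analytic circular read-outs make chains nearly free
            n_chains = max(2048, n_sim)
        else:
            n_chains = max(128, math.ceil(n_sim / 8))
    # Poisson count weights depend only on (gain, set size): precompute.
    weights = {
        n: np.vstack([_engine.poisson_count_weights(g / n, t_cap) for g in gain_grid])
        for n in set_sizes
    }
    grid_ll = np.zeros((len(gain_grid), len(width_grid)))
    for j, omega in enumerate(width_grid):
        tables = {}
        for ti, target in enumerate(table_targets):
            # One stream per target, restarted for every width: common
            # random numbers across the width grid keep the likelihood
            # surface smooth, so the argmax does not wander on table noise.
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(ti,)))
            tables[target] = _engine.conditional_histograms(
                space, float(omega), float(target), decoder, grid, log_prior,
                edges, t_cap, n_chains, rng, n_neurons, dither=dither,
            )
        for target, set_size, counts in cells:
            probs = weights[set_size] @ tables[target]  # (n_gain, n_bins)
            probs = (n_floor * probs + 1.0) / (n_floor + n_bins)
            grid_ll[:, j] += np.log(probs) @ counts
    return grid_ll


def _fit_direct(
    trials, space, decoder, gain_grid, width_grid, n_sim, n_bins, seed,
    n_neurons, grid, prior, n_floor,
):
    grid_ll = np.empty((len(gain_grid), len(width_grid)))
    for i, gain in enumerate(gain_grid):
        for j, omega in enumerate(width_grid):
            child = int(
                np.random.SeedSequence(seed, spawn_key=(i, j)).generate_state(1)[0]
            )
            params = PopulationParams(float(gain), float(omega), n_neurons)
            grid_ll[i, j] = trial_log_likelihood(
                trials, params, space, decoder, n_sim, n_bins, child,
                prior=prior, grid=grid, n_floor=n_floor,
            )
    return grid_ll


def grid_search_fit(
    trials: pd.DataFrame,
    task: Optional[str] = None,
    *,
    space: Optional[FeatureSpace] = None,
    decoder: Optional[str] = None,
    gain_grid: Optional[np.ndarray] = None,
    width_grid: Optional[np.ndarray] = None,
    n_sim: Optional[int] = None,
    n_bins: Optional[int] = None,
    seed: int = 0,
    engine: str = "stratified",
    n_neurons: int = 1000,
    grid_step: Optional[float] = None,
    prior: Optional[PriorDistribution] = None,
    n_floor: Optional[int] = None,
    n_chains: Optional[int] = None,
) -> FitResult:
    """Grid-search maximum-likelihood fit of (gain, tuning width).

    All set sizes present in the data are fit jointly: divisive
    normalization alone carries the memory-load effect, so a single
    parameter pair must explain every set size.  ``task`` fills any
    unspecified setting from :data:`TASKS`; explicit keyword arguments
    override it.  Ties in the likelihood surface resolve to the lowest
    gain index, then the lowest width index.

    ``n_floor`` sets the pseudo-count floor 1/(n_floor + n_bins) of the
    predicted distributions.  It defaults to the task's nominal
    simulation count, not to a reduced ``n_sim``: the floor is a model
    regularization, and tying it to a cheap Monte-Carlo budget would
    visibly fatten predicted tails.  ``n_chains`` overrides the
    stratified engine's Monte-Carlo chain count (default n_sim / 8, at
    least 128).
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    cfg = _task(task) if task is not None else {}
    space = space if space is not None else cfg.get("space")
    if space is None:
        raise ValueError("either task or space must be given")
    decoder = decoder if decoder is not None else cfg.get("decoder", "ml")
    _engine.check_decoder(decoder)
    gain_grid = np.asarray(gain_grid if gain_grid is not None else cfg["gain_grid"], dtype=float)
    width_grid = np.asarray(width_grid if width_grid is not None else cfg["width_grid"], dtype=float)
    n_sim = int(n_sim if n_sim is not None else cfg.get("n_sim", 10_000))
    n_bins = int(n_bins if n_bins is not None else cfg.get("n_bins", 40))
    if n_floor is None:
        n_floor = int(cfg.get("n_sim", n_sim))
    _require_columns(trials, ["target", "response", "set_size"])
    space.validate(trials["response"].to_numpy(), "response")
    space.validate(trials["target"].to_numpy(), "target")

    dec_grid = decoding_grid(space, grid_step)
    log_prior = _engine.log_prior_weights(space, dec_grid, prior)
    if engine == "stratified":
        grid_ll = _fit_stratified(
            trials, space, decoder, gain_grid, width_grid, n_sim, n_bins,
            seed, n_neurons, dec_grid, log_prior, n_floor, n_chains,
        )
    elif engine == "direct":
        grid_ll = _fit_direct(
            trials, space, decoder, gain_grid, width_grid, n_sim, n_bins,
            seed, n_neurons, dec_grid, prior, n_floor,
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    i, j = np.unravel_index(int(np.argmax(grid_ll)), grid_ll.shape)
    best_ll = float(grid_ll[i, j])
    return FitResult(
        best_gain=float(gain_grid[i]),
        best_width=float(width_grid[j]),
        log_likelihood=best_ll,
        aic=aic(best_ll, 2),
        gain_grid=gain_grid,
        width_grid=width_grid,
        grid_loglik=grid_ll,
        decoder=decoder,
        n_trials=len(trials),
    )


def fit_grouped(
    trials: pd.DataFrame,
    task: str,
    groupby: Sequence[str] = ("participant", "emotion"),
    seed: int = 0,
    **kwargs,
) -> Tuple[pd.DataFrame, Dict[tuple, FitResult]]:
    """Fit each group of trials separately (default: participant x emotion).

    Returns a tidy table (one row per group: parameters, log-likelihood,
    AIC, trial count) and the full per-group FitResults.
    """
    groupby = list(groupby)
    _require_columns(trials, groupby)
    rows = []
    fits: Dict[tuple, FitResult] = {}
    grouped = trials.groupby(groupby, sort=True, observed=True)
    for g_idx, (key, sub) in enumerate(grouped):
        key = key if isinstance(key, tuple) else (key,)
        child = int(np.random.SeedSequence(seed, spawn_key=(g_idx,)).generate_state(1)[0])
        fit = grid_search_fit(sub, task, seed=child, **kwargs)
        fits[key] = fit
        rows.append(
            dict(zip(groupby, key))
            | {
                "gain": fit.best_gain,
                "width": fit.best_width,
                "log_likelihood": fit.log_likelihood,
                "aic": fit.aic,
                "n_trials": fit.n_trials,
                "decoder": fit.decoder,
            }
        )
    return pd.DataFrame(rows), fits


@dataclass(frozen=True)
class DecoderComparison:
    """Paired fits of the ML and posterior-sampling read-outs.

    ``delta_aic`` = AIC(ml) - AIC(sampling); negative values favour the
    maximum-likelihood read-out.
    """

    fit_ml: FitResult
    fit_sampling: FitResult
    delta_aic: float


def compare_decoders(
    trials: pd.DataFrame,
    seed: int = 0,
    n_sim: Optional[int] = None,
    **kwargs,
) -> DecoderComparison:
    """Fit both decoder variants to the same orientation trials.

    Only defined for circular (orientation) data — the ML read-out is not
    used on bounded spaces, where decoding must respect the interval.
    """
    if not isinstance(task_space("orientation_ml"), CircularSpace):  # pragma: no cover
        raise RuntimeError("task registry is inconsistent")
    _require_columns(trials, ["target", "response", "set_size"])
    if np.any(trials["target"].to_numpy(dtype=float) > 180.0) or np.any(
        trials["target"].to_numpy(dtype=float) < 0.0
    ):
        raise ValueError("compare_decoders expects orientation data in [0, 180)")
    s_ml = int(np.random.SeedSequence(seed, spawn_key=(0,)).generate_state(1)[0])
    s_ps = int(np.random.SeedSequence(seed, spawn_key=(1,)).generate_state(1)[0])
    fit_ml = grid_search_fit(trials, "orientation_ml", seed=s_ml, n_sim=n_sim, **kwargs)
    fit_ps = grid_search_fit(trials, "orientation_sampling", seed=s_ps, n_sim=n_sim, **kwargs)
    return DecoderComparison(
        fit_ml=fit_ml,
        fit_sampling=fit_ps,
        delta_aic=fit_ml.aic - fit_ps.aic,
    )
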