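"""Vectorized simulation internals shared by the forward model and the fitter.

The Poisson population likelihood admits low-dimensional sufficient
statistics of a spike pattern, which this module exploits:

* circular space: with von-Mises-shaped kernels on the doubled circle and
  divisive normalization, the log-likelihood over candidate values phi is
  (A cos phi + B sin phi) / omega**2 + const, where A and B are the summed
  cosines/sines of the preferred values of the neurons that spiked
  (counted with multiplicity).
* bounded space: with Gaussian kernels, the log-likelihood over grid
  values theta is -(T theta**2 - 2 W theta)/(2 omega**2) - T log S(theta)
  + const, where T is the total spike count, W the sum of spiking
  neurons' preferred values and S(theta) the kernel sum at theta.

Spike patterns are sampled by the exact two-stage decomposition of
independent Poisson counts: a Poisson total T with mean gamma/N, then T
neuron labels drawn categorically with probabilities proportional to the
tuning kernel at the target.  Both give large batches of encode-decode
cycles at a cost proportional to the number of spikes rather than the
number of neurons.

Nothing here is public API; the routines are exercised against the
generic :mod:`popmem.population` implementations in the test suite.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import stats as sstats

from .population import PriorDistribution, preferred_values, tuning_kernel
from .spaces import BoundedSpace, CircularSpace, FeatureSpace, bin_index

DECODERS = ("ml", "posterior_sampling")


def check_decoder(decoder: str) -> str:
    if decoder not in DECODERS:
        raise ValueError(f"unknown decoder {decoder!r}; expected one of {DECODERS}")
    return decoder


def log_prior_weights(
    space: FeatureSpace, grid: np.ndarray, prior: Optional[PriorDistribution]
) -> np.ndarray:
    """Log prior weights aligned with the decoding grid (uniform if None)."""
    if prior is None:
        prior = PriorDistribution.uniform(space, grid)
    if prior.grid.shape != grid.shape or not np.allclose(prior.grid, grid):
        raise ValueError("prior is defined on a different grid than the decoder")
    with np.errstate(divide="ignore"):
        return np.log(prior.weights)


def tuning_probs(space: FeatureSpace, omega: float, target: float, centers: np.ndarray) -> np.ndarray:
    g = tuning_kernel(space, omega, float(target), centers)
    total = g.sum()
    if not total > 0:
        raise FloatingPointError("tuning kernel sum underflowed to zero")
    return g / total


def _sample_labels(pcum: np.ndarray, size, rng: np.random.Generator) -> np.ndarray:
    idx = np.searchsorted(pcum, rng.random(size))
    return np.minimum(idx, len(pcum) - 1)


def _grid_features(space: FeatureSpace, omega: float, grid: np.ndarray, m: int):
    """Per-grid-point quantities entering the sufficient-statistic scores."""
    if isinstance(space, CircularSpace):
        phi = space.to_doubled_radians(grid)
        return np.cos(phi), np.sin(phi)
    centers = preferred_values(space, m)
    s = tuning_kernel(space, omega, grid[:, None], centers).sum(axis=1)
    return grid, np.log(s)


def _scores(space, omega, stats, grid_feat):
    """Log-likelihood over the grid, up to theta-independent terms.

    stats: circular -> (A, B); bounded -> (T, W).  Leading dimensions of
    the stats arrays are preserved; a grid axis is appended.
    """
    w2 = omega * omega
    if isinstance(space, CircularSpace):
        A, B = stats
        cosg, sing = grid_feat
        return (np.multiply.outer(A, cosg) + np.multiply.outer(B, sing)) / w2
    T, W = stats
    g, logS = grid_feat
    return (
        -(np.multiply.outer(T, g * g) - 2.0 * np.multiply.outer(W, g)) / (2.0 * w2)
        - np.multiply.outer(T, logS)
    )


def _softmax_sample_rows(scores: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row from softmax(scores) along the last axis."""
    s = scores - scores.max(axis=-1, keepdims=True)
    p = np.exp(s)
    cdf = np.cumsum(p, axis=-1)
    u = rng.random(cdf.shape[:-1] + (1,)) * cdf[..., -1:]
    idx = (cdf < u).sum(axis=-1)
    return np.minimum(idx, scores.shape[-1] - 1)


#: Upper bound on score-matrix elements held in memory at once; decode
#: batches larger than this are processed in row chunks.
CHUNK_ELEMENTS = 4_000_000


def _decode_indices(space, omega, stats, grid_feat, decoder, log_prior, rng):
    lead_shape = stats[0].shape
    n_grid = grid_feat[0].shape[-1]
    flat = tuple(s.reshape(-1) for s in stats)
    n_rows = flat[0].shape[0]
    rows_per_chunk = max(1, CHUNK_ELEMENTS // n_grid)
    out = np.empty(n_rows, dtype=np.intp)
    for start in range(0, n_rows, rows_per_chunk):
        sl = slice(start, start + rows_per_chunk)
        scores = _scores(space, omega, tuple(s[sl] for s in flat), grid_feat)
        if decoder == "ml":
            out[sl] = np.argmax(scores, axis=-1)
        else:
            out[sl] = _softmax_sample_rows(scores + log_prior, rng)
    return out.reshape(lead_shape)


def simulate_batch(
    space: FeatureSpace,
    omega: float,
    totals_mean: np.ndarray,
    targets: np.ndarray,
    decoder: str,
    grid: np.ndarray,
    log_prior: np.ndarray,
    rng: np.random.Generator,
    m: int,
) -> np.ndarray:
    """Simulate one encode-decode cycle per trial; returns decoded responses.

    totals_mean[k] is the per-item expected total spike count gamma/N_eff
    for trial k; targets[k] the memorized value.  Trials are grouped by
    unique target so the categorical spike sampler is shared.
    """
    check_decoder(decoder)
    targets = np.asarray(targets, dtype=float)
    totals_mean = np.asarray(totals_mean, dtype=float)
    n = len(targets)
    centers = preferred_values(space, m)
    if isinstance(space, CircularSpace):
        cvals = space.to_doubled_radians(centers)
    grid_feat = _grid_features(space, omega, grid, m)
    responses = np.empty(n)
    for tval in np.unique(targets):
        sel = np.flatnonzero(targets == tval)
        p = tuning_probs(space, omega, tval, centers)
        pcum = np.cumsum(p)
        T = rng.poisson(totals_mean[sel])
        labels = _sample_labels(pcum, int(T.sum()), rng)
        owner = np.repeat(np.arange(len(sel)), T)
        k = len(sel)
        if isinstance(space, CircularSpace):
            A = np.bincount(owner, weights=np.cos(cvals[labels]), minlength=k)
            B = np.bincount(owner, weights=np.sin(cvals[labels]), minlength=k)
            stats = (A, B)
        else:
            W = np.bincount(owner, weights=centers[labels], minlength=k)
            stats = (T.astype(float), W)
        idx = _decode_indices(space, omega, stats, grid_feat, decoder, log_prior, rng)
        responses[sel] = grid[idx]
    return responses


def conditional_histograms(
    space: FeatureSpace,
    omega: float,
    target: float,
    decoder: str,
    grid: np.ndarray,
    log_prior: np.ndarray,
    edges: np.ndarray,
    t_max: int,
    n_chains: int,
    rng: np.random.Generator,
    m: int,
    dither: bool = False,
) -> np.ndarray:
    """Monte-Carlo decode-outcome histograms conditional on the spike count.

    Returns H of shape (t_max + 1, n_bins): row T is the binned
    distribution of decoded outcomes given exactly T spikes (circular:
    signed error relative to the target; bounded: the response itself).
    Rows are estimated from ``n_chains`` coupled chains — the first T
    labels of one i.i.d. label sequence form an exact T-spike sample, so
    one sequence serves every row.

    ``dither`` (circular spaces) adds a uniform one-grid-step jitter to
    the decoded errors before binning.  This is dithered quantization:
    for data whose targets are continuous, decoding happens on a grid
    whose offset relative to the target is uniformly distributed, and
    jittering the canonical-target outcomes reproduces that marginal
    exactly for the ML read-out (the discrete argmax is the continuous
    resultant direction rounded to the grid) and to the same order for
    posterior sampling.

    For circular ML decoding the T = 0 row is the exact marginal over a
    uniformly distributed target: with a flat likelihood the decoder's
    lowest-index tie-break returns a fixed grid point, whose signed error
    is uniform when targets are uniform, so the row is uniform over bins.
    """
    check_decoder(decoder)
    n_bins = len(edges) - 1
    centers = preferred_values(space, m)
    p = tuning_probs(space, omega, target, centers)
    pcum = np.cumsum(p)
    labels = _sample_labels(pcum, (n_chains, t_max), rng)
    zeros = np.zeros((n_chains, 1))
    flat_prior = bool(np.ptp(log_prior) < 1e-12)
    if isinstance(space, CircularSpace):
        cvals = space.to_doubled_radians(centers)
        A = np.concatenate([zeros, np.cumsum(np.cos(cvals[labels]), axis=1)], axis=1)
        B = np.concatenate([zeros, np.cumsum(np.sin(cvals[labels]), axis=1)], axis=1)
        if flat_prior:
            # Analytic circular read-outs: the grid argmax of the score
            # A cos(phi) + B sin(phi) is the resultant direction rounded
            # to the grid, and under a uniform prior the posterior is
            # von Mises with concentration R/omega^2.  Sampling those
            # continuous laws directly (plus the dither below, which
            # absorbs grid quantization) is exact and avoids the score
            # matrix entirely.
            mu = np.arctan2(B, A)
            if decoder == "ml":
                vals_d = mu
            else:
                kappa = np.hypot(A, B) / (omega * omega)
                vals_d = rng.vonmises(mu, kappa)
            values = space.wrap(space.from_doubled_radians(vals_d))
        else:
            grid_feat = _grid_features(space, omega, grid, m)
            idx = _decode_indices(space, omega, (A, B), grid_feat, decoder, log_prior, rng)
            values = grid[idx]
        if dither:
            step = grid[1] - grid[0]
            values = values + rng.uniform(-0.5 * step, 0.5 * step, size=values.shape)
        x = space.signed_error(target, values)
        bins = bin_index(edges, x, closed="left")
    else:
        T = np.broadcast_to(np.arange(t_max + 1, dtype=float), (n_chains, t_max + 1))
        W = np.concatenate([zeros, np.cumsum(centers[labels], axis=1)], axis=1)
        grid_feat = _grid_features(space, omega, grid, m)
        idx = _decode_indices(space, omega, (T, W), grid_feat, decoder, log_prior, rng)
        bins = bin_index(edges, grid[idx], closed="right")
    t_ids = np.broadcast_to(np.arange(t_max + 1), bins.shape)
    flat = t_ids.ravel() * n_bins + bins.ravel()
    H = np.bincount(flat, minlength=(t_max + 1) * n_bins).astype(float)
    H = H.reshape(t_max + 1, n_bins) / n_chains
    if isinstance(space, CircularSpace) and decoder == "ml":
        H[0, :] = 1.0 / n_bins
    return H


def canonical_circular_error_samples(
    space: CircularSpace,
    omega: float,
    mean_total: float,
    decoder: str,
    grid: np.ndarray,
    log_prior: np.ndarray,
    rng: np.random.Generator,
    m: int,
    n: int,
) -> np.ndarray:
    """Signed-error samples marginalized over uniformly distributed targets.

    Circular error distributions are rotation invariant, so they are
    simulated once at a canonical target; the uniform one-grid-step
    jitter reproduces the decoding-grid offset of a continuous target,
    and zero-spike ML decodes (a fixed tie-break point) are replaced by
    the exact uniform error they induce when targets are uniform.
    """
    check_decoder(decoder)
    target = space.half_period
    centers = preferred_values(space, m)
    p = tuning_probs(space, omega, target, centers)
    pcum = np.cumsum(p)
    T = rng.poisson(mean_total, size=n)
    labels = _sample_labels(pcum, int(T.sum()), rng)
    owner = np.repeat(np.arange(n), T)
    cv = space.to_doubled_radians(centers)
    A = np.bincount(owner, weights=np.cos(cv[labels]), minlength=n)
    B = np.bincount(owner, weights=np.sin(cv[labels]), minlength=n)
    if np.ptp(log_prior) < 1e-12:
        mu = np.arctan2(B, A)
        if decoder == "ml":
            vals_d = mu
        else:
            vals_d = rng.vonmises(mu, np.hypot(A, B) / (omega * omega))
        values = space.wrap(space.from_doubled_radians(vals_d))
    else:
        grid_feat = _grid_features(space, omega, grid, m)
        idx = _decode_indices(space, omega, (A, B), grid_feat, decoder, log_prior, rng)
        values = grid[idx]
    step = grid[1] - grid[0]
    values = values + rng.uniform(-0.5 * step, 0.5 * step, size=n)
    errors = np.asarray(space.signed_error(target, values))
    if decoder == "ml":
        zero = T == 0
        if zero.any():
            errors[zero] = rng.uniform(
                -space.half_period, space.half_period, size=int(zero.sum())
            )
    return errors


def poisson_count_weights(mean_total: float, t_max: int) -> np.ndarray:
    """Poisson(mean) pmf over counts 0..t_max with the tail lumped onto t_max."""
    t = np.arange(t_max + 1)
    w = sstats.poisson.pmf(t, mean_total)
    w[t_max] += sstats.poisson.sf(t_max, mean_total)
    return w


def mixture_probabilities(
    H: np.ndarray, mean_total: float, n_floor: int, n_bins: int
) -> np.ndarray:
    """Predicted bin probabilities for one (gain, set-size) cell.

    Mixes the count-conditional histograms with Poisson weights, then
    applies the add-one pseudo-count floor (no bin below
    1/(n_floor + n_bins)), so no observed response has zero likelihood.
    """
    w = poisson_count_weights(mean_total, H.shape[0] - 1)
    probs = w @ H
    return (n_floor * probs + 1.0) / (n_floor + n_bins)


def spike_count_cap(max_mean_total: float) -> int:
    """Upper truncation of the Poisson count used by the stratified fitter."""
    return int(np.ceil(max_mean_total + 6.0 * np.sqrt(max_mean_total) + 10.0))
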