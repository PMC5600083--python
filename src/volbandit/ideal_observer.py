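"""Sequential Bayesian estimation of a drifting reward probability.

The observer maintains a joint discretized posterior over three quantities:

* ``r`` — the current probability that option A is rewarded,
* ``v`` — the log-volatility controlling how fast ``r`` drifts, and
* ``k`` — a static hyper-parameter controlling how fast ``v`` itself drifts.

One filtering step propagates ``v`` through a Gaussian random walk with
standard deviation ``exp(k)``, propagates ``r`` through a beta-family kernel
with mean ``r`` and concentration ``exp(-v)`` (higher ``v`` = wider kernel),
multiplies by the Bernoulli likelihood ``r**y * (1-r)**(1-y)`` of the latest
outcome and renormalizes. ``k`` is never propagated; it is marginalized at
readout. The per-trial expectation ``E[r]`` is the regressor handed to the
choice models downstream.

Grid resolutions and prior ranges are package defaults, chosen so that
doubling every resolution moves the ``E[r]`` trajectory by well under 0.01
(see the test suite); they are all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .schedule import Schedule

__all__ = [
    "PosteriorGrid",
    "ObserverTrajectory",
    "init_posterior",
    "update_posterior",
    "run_observer",
    "expected_value",
    "GRID_BOUNDS",
]

# (low, high) bounds for each latent dimension; v and k live on log scales.
GRID_BOUNDS = {
    "r": (0.01, 0.99),
    "v": (-11.0, -2.0),
    "k": (-4.5, 0.5),
}

DEFAULT_GRID_SIZES = (40, 15, 15)

_MASS_TOL = 1e-10


class FilterNumericsError(RuntimeError):
    """Posterior mass underflowed to zero during an update."""


@dataclass
class PosteriorGrid:
    """Discretized joint belief over (r, v, k).

    ``weights`` has shape ``(len(r_grid), len(v_grid), len(k_grid))``, is
    non-negative and sums to one.
    """

    r_grid: np.ndarray
    v_grid: np.ndarray
    k_grid: np.ndarray
    weights: np.ndarray

    @property
    def e_r(self) -> float:
        """Posterior mean reward probability for option A."""
        return float(np.einsum("rvk,r->", self.weights, self.r_grid))

    @property
    def e_v(self) -> float:
        """Posterior mean log-volatility."""
        return float(np.einsum("rvk,v->", self.weights, self.v_grid))

    @property
    def r_marginal(self) -> np.ndarray:
        return self.weights.sum(axis=(1, 2))

    @property
    def v_marginal(self) -> np.ndarray:
        return self.weights.sum(axis=(0, 2))

    def total_mass(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class ObserverTrajectory:
    """Per-trial posterior summaries from a full filtering run."""

    e_r: np.ndarray
    e_v: np.ndarray

    def __len__(self) -> int:
        return len(self.e_r)


def _grids(sizes, bounds=None):
    n_r, n_v, n_k = sizes
    bounds = bounds or GRID_BOUNDS
    r = np.linspace(*bounds["r"], n_r)
    v = np.linspace(*bounds["v"], n_v)
    k = np.linspace(*bounds["k"], n_k)
    return r, v, k


@lru_cache(maxsize=8)
def _transition_ops(r_key: tuple, v_key: tuple, k_key: tuple):
    """Row-normalized transition matrices for the v-walk and the r-kernel.

    Returns ``(T_v, T_r)`` with ``T_v[k, v, v']`` the probability of moving
    from v to v' given k, and ``T_r[v', r, r']`` the probability of moving
    from r to r' given the *new* volatility v'.
    """
    r = np.asarray(r_key)
    v = np.asarray(v_key)
    k = np.asarray(k_key)

    # Transition mass is integrated over destination cells (CDF differences)
    # rather than sampled point-wise; this keeps coarse grids consistent with
    # their refinements.
    def _edges(g):
        mid = 0.5 * (g[:-1] + g[1:])
        return np.concatenate(([-np.inf], mid, [np.inf]))

    v_edges = _edges(v)
    r_edges = np.clip(_edges(r), 0.0, 1.0)

    # v random walk: Gaussian with sd exp(k), cell-integrated on the v grid.
    sd = np.exp(k)[:, None, None]
    cdf = stats.norm.cdf((v_edges[None, None, :] - v[None, :, None]) / sd)
    t_v = np.diff(cdf, axis=2)
    t_v /= t_v.sum(axis=2, keepdims=True)

    # r kernel: beta with mean r and concentration exp(-v'), cell-integrated
    # on the r grid.
    nu = np.exp(-v)  # concentration per v level
    a = r[None, :, None] * nu[:, None, None]
    b = (1.0 - r[None, :, None]) * nu[:, None, None]
    cdf = stats.beta.cdf(r_edges[None, None, :], a, b)
    t_r = np.diff(cdf, axis=2)
    t_r /= t_r.sum(axis=2, keepdims=True)
    return t_v, t_r


def init_posterior(grid_sizes=DEFAULT_GRID_SIZES, bounds=None) -> PosteriorGrid:
    """Uniform joint prior over the grid; E[r] = 0.5 by symmetry."""
    if any(int(n) < 2 for n in grid_sizes):
        raise ValueError(f"every grid size must be >= 2, got {grid_sizes}")
    r, v, k = _grids(tuple(int(n) for n in grid_sizes), bounds)
    w = np.full((len(r), len(v), len(k)), 1.0 / (len(r) * len(v) * len(k)))
    return PosteriorGrid(r, v, k, w)


def update_posterior(post: PosteriorGrid, outcome: int) -> PosteriorGrid:
    """One filtering step on the outcome indicator (1 = option A rewarded)."""
    y = int(outcome)
    if y not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    t_v, t_r = _transition_ops(
        tuple(post.r_grid), tuple(post.v_grid), tuple(post.k_grid)
    )
    # v' | v, k  — batched over k: (r,v,k) x (k,v,v') -> (r,v',k)
    w = np.einsum("rvk,kvu->ruk", post.weights, t_v)
    # r' | r, v' — batched over v': (r,v',k) x (v',r,r') -> (r',v',k)
    w = np.einsum("rvk,vrs->svk", w, t_r)
    # Bernoulli likelihood in r'
    lik = post.r_grid if y == 1 else 1.0 - post.r_grid
    w *= lik[:, None, None]
    total = w.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise FilterNumericsError(
            f"posterior mass underflow (total={total!r}); grid sizes "
            f"{post.weights.shape}, r range [{post.r_grid[0]}, {post.r_grid[-1]}]"
        )
    w /= total
    return PosteriorGrid(post.r_grid, post.v_grid, post.k_grid, w)


def run_observer(
    schedule: Schedule, grid_sizes=DEFAULT_GRID_SIZES, bounds=None
) -> ObserverTrajectory:
    """Filter the full outcome sequence of a schedule.

    Uses only the sequence of rewarded options — never choices or
    magnitudes. ``e_r[t]`` is the posterior mean *after* observing trial
    ``t+1``'s outcome.
    """
    if schedule.n_trials == 0:
        raise ValueError("cannot run the observer on an empty schedule")
    post = init_posterior(grid_sizes, bounds)
    outcomes = schedule.rewarded_a.astype(int)
    e_r = np.empty(len(outcomes))
    e_v = np.empty(len(outcomes))
    for t, y in enumerate(outcomes):
        post = update_posterior(post, y)
        assert abs(post.total_mass() - 1.0) < _MASS_TOL
        e_r[t] = post.e_r
        e_v[t] = post.e_v
    return ObserverTrajectory(e_r=e_r, e_v=e_v)


def expected_value(prob: float, magnitude: float) -> float:
    """Expected value of an option: reward probability times reward size."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"prob must be in [0, 1], got {prob}")
    if not 0.0 <= magnitude <= 100.0:
        raise ValueError(f"magnitude must be in [0, 100], got {magnitude}")
    return prob * magnitude
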