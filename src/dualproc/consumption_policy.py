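"""Optimal consumption under controlled processing.

A controlled act must split the currently available pool of resources (the
resource just encountered, if any, plus the store ``S``) between immediate
consumption and storage.  Because the utility of consumption saturates with
the energy level ``E``, the right split depends on ``E``, on ``S``, and on
how likely resources are to arrive in the future.

We pose the problem as a discounted Markov decision process on a
discretized ``(E, S)`` state space.  Each step of the chain is: drain;
stochastic acquisition of one resource of size ``rho`` with probability
``p_acquire``; choice of a consumption amount ``x`` from a finite menu of
fractions of the available pool; storage of the remainder.  The per-step
reward is the post-step energy level, so the solved policy maximizes the
expected discounted stream of ``E`` — the quantity that defines fitness.
The solver is plain value iteration with either bilinear interpolation of
the value function at off-grid successor states (default) or
nearest-neighbour projection (which turns the problem into an exact finite
MDP, used by the brute-force cross-checks).

Agents do not know ``p_acquire``; they track an experience-based estimate
``p_hat`` by exponential moving average and use the policy solved for the
nearest level on a fixed grid of availability levels (a
:class:`PolicySet`).  Competition is therefore felt through experience:
resources lost to other agents simply never enter ``p_hat``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .energy_model import EnvironmentParams

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "PolicyGrid",
    "PolicySet",
    "AvailabilityEstimate",
    "PolicyConvergenceError",
    "solve_policy",
    "solve_policy_set",
    "optimal_consumption",
    "update_availability",
    "default_availability_levels",
    "policy_to_csv",
    "policy_from_csv",
]


class PolicyConvergenceError(RuntimeError):
    """Value iteration failed to reach the requested tolerance."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"value iteration residual {residual:.3g} after {max_iter} iterations"
        )


@dataclass(frozen=True)
class GridSpec:
    """Discretization of the consumption problem.

    ``n_E`` energy bins over ``[0, E_max]``, ``n_S`` store bins over
    ``[0, S_cap]``, and ``n_x`` candidate consumption levels given as
    evenly spaced fractions of the available pool.
    """

    n_E: int = 33
    n_S: int = 33
    S_cap: float = 50.0
    n_x: int = 11

    def __post_init__(self) -> None:
        if self.n_E < 2 or self.n_S < 2 or self.n_x < 2:
            raise ValueError("grid counts must all be >= 2")
        if not self.S_cap > 0:
            raise ValueError("S_cap must be positive")

    def energy_grid(self, params: EnvironmentParams) -> np.ndarray:
        return np.linspace(0.0, params.E_max, self.n_E)

    def store_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.S_cap, self.n_S)

    def fractions(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_x)


@dataclass
class PolicyGrid:
    """Solved consumption policy for one availability level.

    ``frac[iE, iS, a]`` is the optimal fraction of the available pool to
    consume in state ``(E_grid[iE], S_grid[iS])`` when a resource was
    acquired this step (``a = 1``) or not (``a = 0``).  ``values`` holds the
    converged state values.
    """

    p_acquire: float
    gamma: float
    grid: GridSpec
    params: EnvironmentParams
    frac: np.ndarray  # (n_E, n_S, 2)
    values: np.ndarray  # (n_E, n_S)
    residual: float
    n_iter: int
    _warned_clamp: bool = field(default=False, repr=False)


@dataclass(frozen=True)
class AvailabilityEstimate:
    """Experience-based estimate of the per-step acquisition probability."""

    p_hat: float
    lam: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hat <= 1.0:
            raise ValueError(f"p_hat must be in [0, 1], got {self.p_hat}")
        if not 0.0 < self.lam < 1.0:
            raise ValueError(f"lambda must be in (0, 1), got {self.lam}")


def update_availability(est: AvailabilityEstimate, acquired: bool) -> AvailabilityEstimate:
    """Exponential-moving-average update toward this step's outcome."""
    target = 1.0 if acquired else 0.0
    return replace(est, p_hat=(1.0 - est.lam) * est.p_hat + est.lam * target)


def default_availability_levels(n: int = 21, p_min: float = 1e-3) -> np.ndarray:
    """Grid of acquisition-probability levels at which policies are solved.

    Zero plus a geometric ladder from ``p_min`` to 1.  The geometric spacing
    concentrates resolution at the small probabilities that scarce
    environments produce, where the optimal policy changes fastest.
    """
    if n < 2:
        raise ValueError("need at least two availability levels")
    return np.concatenate([[0.0], np.geomspace(p_min, 1.0, n - 1)])


# ---------------------------------------------------------------------------
# MDP machinery


def _build_transitions(
    p_params: EnvironmentParams, grid: GridSpec, projection: str
):
    """Rewards and successor-projection matrix for every (state, acq, action).

    Rows are ordered ``((iE * n_S + iS) * 2 + acq) * n_x + ix``.  The sparse
    matrix ``P`` maps a value vector over states to the interpolated value
    at each row's successor state.
    """
    E_grid = grid.energy_grid(p_params)
    S_grid = grid.store_grid()
    fracs = grid.fractions()

    E = E_grid[:, None, None, None]
    S = S_grid[None, :, None, None]
    acq = np.array([0.0, 1.0])[None, None, :, None]
    fr = fracs[None, None, None, :]

    E_d = np.maximum(0.0, E - p_params.drain)
    pool = S + acq * p_params.rho
    x = fr * pool
    E_next = p_params.E_max - (p_params.E_max - E_d) * np.exp(
        -p_params.u * x / p_params.E_max
    )
    S_next = np.minimum(grid.S_cap, pool - x)
    E_next, S_next = np.broadcast_arrays(E_next, S_next)
    reward = E_next

    dE = E_grid[1] - E_grid[0]
    dS = S_grid[1] - S_grid[0]
    pos_E = (E_next / dE).ravel()
    pos_S = (S_next / dS).ravel()
    n_rows = pos_E.size
    n_states = grid.n_E * grid.n_S

    if projection == "interp":
        i0 = np.clip(np.floor(pos_E).astype(np.int64), 0, grid.n_E - 2)
        j0 = np.clip(np.floor(pos_S).astype(np.int64), 0, grid.n_S - 2)
        wE = np.clip(pos_E - i0, 0.0, 1.0)
        wS = np.clip(pos_S - j0, 0.0, 1.0)
        rows = np.repeat(np.arange(n_rows), 4)
        cols = np.stack(
            [
                i0 * grid.n_S + j0,
                i0 * grid.n_S + j0 + 1,
                (i0 + 1) * grid.n_S + j0,
                (i0 + 1) * grid.n_S + j0 + 1,
            ],
            axis=1,
        ).ravel()
        data = np.stack(
            [
                (1 - wE) * (1 - wS),
                (1 - wE) * wS,
                wE * (1 - wS),
                wE * wS,
            ],
            axis=1,
        ).ravel()
    elif projection == "nearest":
        i = np.clip(np.rint(pos_E).astype(np.int64), 0, grid.n_E - 1)
        j = np.clip(np.rint(pos_S).astype(np.int64), 0, grid.n_S - 1)
        rows = np.arange(n_rows)
        cols = i * grid.n_S + j
        data = np.ones(n_rows)
    else:
        raise ValueError(f"unknown projection {projection!r}")

    P = sparse.csr_matrix((data, (rows, cols)), shape=(n_rows, n_states))
    return reward.reshape(n_states, 2, grid.n_x), P


_TIE_TOL = 1e-9


def _greedy(Q: np.ndarray) -> np.ndarray:
    """Index of the smallest consumption fraction attaining the max value."""
    qmax = Q.max(axis=-1, keepdims=True)
    scale = np.maximum(1.0, np.abs(qmax))
    return np.argmax(Q >= qmax - _TIE_TOL * scale, axis=-1)


def solve_policy(
    p_acquire: float,
    params: EnvironmentParams,
    grid: GridSpec | None = None,
    gamma: float = 0.997,
    tol: float = 1e-3,
    max_iter: int = 20_000,
    horizon: int | None = None,
    projection: str = "interp",
) -> PolicyGrid:
    """Solve the consumption MDP for one acquisition probability.

    With ``horizon=None`` (default) runs infinite-horizon value iteration
    until the sup-norm value change drops below ``tol``; with an integer
    ``horizon`` performs exactly that many backward-induction sweeps from a
    terminal value of zero (no convergence requirement), which is the
    finite-horizon problem the enumeration oracles check.
    """
    if not 0.0 <= p_acquire <= 1.0:
        raise ValueError(f"p_acquire must be in [0, 1], got {p_acquire}")
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    grid = grid or GridSpec()

    reward, P = _build_transitions(params, grid, projection)
    n_states = grid.n_E * grid.n_S
    v = np.zeros(n_states)
    p = p_acquire
    residual = np.inf
    n_sweeps = horizon if horizon is not None else max_iter
    it = 0
    for it in range(1, n_sweeps + 1):
        Q = reward + gamma * (P @ v).reshape(n_states, 2, grid.n_x)
        Qmax = Q.max(axis=2)
        v_new = (1.0 - p) * Qmax[:, 0] + p * Qmax[:, 1]
        residual = float(np.max(np.abs(v_new - v)))
        v = v_new
        if horizon is None and residual < tol:
            break
    else:
        if horizon is None:
            raise PolicyConvergenceError(residual, max_iter)

    Q = reward + gamma * (P @ v).reshape(n_states, 2, grid.n_x)
    ix = _greedy(Q)  # (n_states, 2)
    frac = grid.fractions()[ix].reshape(grid.n_E, grid.n_S, 2)
    return PolicyGrid(
        p_acquire=p_acquire,
        gamma=gamma,
        grid=grid,
        params=params,
        frac=frac,
        values=v.reshape(grid.n_E, grid.n_S),
        residual=residual,
        n_iter=it,
    )


@dataclass
class PolicySet:
    """Policies solved on a fixed ladder of availability levels.

    Lifetime simulations hold one of these and route each controlled act to
    the policy whose availability level is nearest the agent's current
    estimate ``p_hat``.
    """

    p_levels: np.ndarray
    policies: list[PolicyGrid]

    def __post_init__(self) -> None:
        self.p_levels = np.asarray(self.p_levels, dtype=float)
        if len(self.policies) != self.p_levels.size:
            raise ValueError("one policy per availability level required")
        # midpoints between consecutive levels, for nearest-level routing
        self._edges = 0.5 * (self.p_levels[1:] + self.p_levels[:-1])
        self.frac_stack = np.stack([pol.frac for pol in self.policies])

    @property
    def grid(self) -> GridSpec:
        return self.policies[0].grid

    @property
    def params(self) -> EnvironmentParams:
        return self.policies[0].params

    def index_for(self, p_hat):
        """Index of the availability level nearest each ``p_hat``."""
        return np.searchsorted(self._edges, p_hat)

    def policy_for(self, p_hat: float) -> PolicyGrid:
        return self.policies[int(self.index_for(p_hat))]


def solve_policy_set(
    params: EnvironmentParams,
    grid: GridSpec | None = None,
    p_levels: np.ndarray | None = None,
    gamma: float = 0.997,
    tol: float = 1e-3,
    max_iter: int = 20_000,
) -> PolicySet:
    """Solve the consumption MDP at every availability level."""
    grid = grid or GridSpec()
    if p_levels is None:
        p_levels = default_availability_levels()
    policies = [
        solve_policy(float(p), params, grid, gamma=gamma, tol=tol, max_iter=max_iter)
        for p in p_levels
    ]
    return PolicySet(p_levels=np.asarray(p_levels, dtype=float), policies=policies)


def optimal_consumption(
    policy: PolicyGrid, E: float, S: float, acquired: float
) -> float:
    """Consumption amount prescribed by a solved policy at ``(E, S)``.

    ``acquired`` is the size of the resource acquired this step (0 if none).
    The policy cell is the nearest grid node; the stored fraction is applied
    to the actual pool ``S + acquired``, so the returned amount always
    satisfies ``0 <= x <= S + acquired``.  States beyond the grid are
    clamped (with a one-time warning per policy).
    """
    if acquired < 0 or S < 0:
        raise ValueError("store and acquired amount must be non-negative")
    grid, params = policy.grid, policy.params
    if (E > params.E_max or S > grid.S_cap) and not policy._warned_clamp:
        logger.warning(
            "state (E=%.3g, S=%.3g) outside policy grid (E_max=%.3g, S_cap=%.3g); clamping",
            E, S, params.E_max, grid.S_cap,
        )
        policy._warned_clamp = True
    dE = params.E_max / (grid.n_E - 1)
    dS = grid.S_cap / (grid.n_S - 1)
    iE = int(np.clip(round(E / dE), 0, grid.n_E - 1))
    iS = int(np.clip(round(S / dS), 0, grid.n_S - 1))
    a = 1 if acquired > 0 else 0
    pool = S + acquired
    return float(min(policy.frac[iE, iS, a] * pool, pool))


# ---------------------------------------------------------------------------
# serialization


def policy_to_csv(policy: PolicyGrid, path, meta_path=None) -> None:
    """Write a policy as flat CSV plus a JSON sidecar of solver metadata."""
    grid, params = policy.grid, policy.params
    E_grid = grid.energy_grid(params)
    S_grid = grid.store_grid()
    rows = []
    for iE in range(grid.n_E):
        for iS in range(grid.n_S):
            for a in (0, 1):
                pool = S_grid[iS] + (params.rho if a else 0.0)
                rows.append(
                    {
                        "E_bin": iE,
                        "S_bin": iS,
                        "acquired_flag": a,
                        "frac": policy.frac[iE, iS, a],
                        "x": policy.frac[iE, iS, a] * pool,
                        "value": policy.values[iE, iS],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
    meta_path = meta_path or str(path) + ".json"
    meta = {
        "p_acquire": policy.p_acquire,
        "gamma": policy.gamma,
        "residual": policy.residual,
        "n_iter": policy.n_iter,
        "grid": {"n_E": grid.n_E, "n_S": grid.n_S, "S_cap": grid.S_cap, "n_x": grid.n_x},
        "params": {
            "R": params.R,
            "drain": params.drain,
            "rho": params.rho,
            "E_max": params.E_max,
            "u": params.u,
        },
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def policy_from_csv(path, meta_path=None) -> PolicyGrid:
    """Read a policy written by :func:`policy_to_csv`."""
    meta_path = meta_path or str(path) + ".json"
    with open(meta_path) as fh:
        meta = json.load(fh)
    grid = GridSpec(**meta["grid"])
    params = EnvironmentParams(**meta["params"])
    df = pd.read_csv(path)
    frac = np.zeros((grid.n_E, grid.n_S, 2))
    frac[df["E_bin"], df["S_bin"], df["acquired_flag"]] = df["frac"]
    values = np.zeros((grid.n_E, grid.n_S))
    values[df["E_bin"], df["S_bin"]] = df["value"]
    return PolicyGrid(
        p_acquire=meta["p_acquire"],
        gamma=meta["gamma"],
        grid=grid,
        params=params,
        frac=frac,
        values=values,
        residual=meta["residual"],
        n_iter=meta["n_iter"],
    )
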