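"""Lifetime simulation of dual-process agents and the fitness surface.

An agent with control propensity ``C`` acts in a controlled manner with
probability ``C`` on each timestep and automatically otherwise.  Automatic
acts fully consume any encountered resource and cannot touch the store;
controlled acts consult the solved consumption policy to split the
available pool (resource encountered plus store) between consumption and
storage, guided by an experience-based estimate of resource availability.

Competition is folded into two per-mode access probabilities: ``p_auto``
(chance of acquiring a resource on an automatic step) and ``p_ctrl`` (same
for a controlled step), computed from the richness ``R``, the population
size ``N``, and the population's mix of modes.  In a contested encounter an
automatic actor beats a controlled one with probability ``w_auto`` (1 by
default); same-mode contests are split randomly.  Fitness is the mean
energy level over a lifetime, precomputed on a grid over
``(C, p_auto, p_ctrl)`` so the evolutionary layer can look it up instead of
re-simulating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .consumption_policy import PolicySet
from .energy_model import EnvironmentParams, consumption_to_reach

__all__ = [
    "CompetitionModel",
    "AccessProbabilities",
    "AutomaticPolicy",
    "FitnessTable",
    "TargetFitnessTable",
    "access_probabilities",
    "simulate_lifetimes_batch",
    "simulate_lifetime",
    "simulate_lifetime_evolvable_auto",
    "build_fitness_table",
    "build_target_fitness_table",
    "lookup_fitness",
    "default_c_levels",
    "default_p_levels",
    "table_to_csv",
    "table_from_csv",
]


@dataclass(frozen=True)
class CompetitionModel:
    """How often encounters are contested and who wins mixed contests.

    A contest requires a competitor to encounter the same resource at the
    same time, so the contest probability grows with both the population
    size and the richness: ``p_contest = min(1, kappa * (N - 1) * R)`` by
    default, or the gentler saturating form
    ``1 - (1 - kappa * R)**(N - 1)`` with ``saturating=True`` (one
    independent chance per potential competitor).  ``w_auto`` is the
    probability that the automatic actor wins a mixed contest; any value
    above 0.5 preserves the automatic speed advantage.
    """

    kappa: float = 0.2
    w_auto: float = 1.0
    saturating: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if not 0.5 < self.w_auto <= 1.0:
            raise ValueError(f"w_auto must be in (0.5, 1], got {self.w_auto}")

    def contest_probability(self, N: int, R: float) -> float:
        if N < 1:
            raise ValueError(f"population size must be >= 1, got {N}")
        if self.saturating:
            return 1.0 - (1.0 - self.kappa * R) ** (N - 1)
        return min(1.0, self.kappa * (N - 1) * R)


@dataclass(frozen=True)
class AccessProbabilities:
    """Per-step resource-acquisition probabilities by processing mode."""

    p_auto: float
    p_ctrl: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_ctrl <= self.p_auto <= 1.0:
            raise ValueError(
                f"require 0 <= p_ctrl <= p_auto <= 1, got ({self.p_auto}, {self.p_ctrl})"
            )


@dataclass(frozen=True)
class AutomaticPolicy:
    """Automatic consumption rule (evolvable-target variant).

    In the default model an automatic act consumes the whole encountered
    resource and ignores the store.  The variant gives automatic acts a
    heritable target energy level ``target_E``: consume from everything at
    hand (resource plus store) exactly enough to reach the target, store
    the rest.
    """

    mode: str = "full_consume"  # or "target_level"
    target_E: float = np.inf

    def __post_init__(self) -> None:
        if self.mode not in ("full_consume", "target_level"):
            raise ValueError(f"unknown automatic policy mode {self.mode!r}")


def access_probabilities(
    R: float, N: int, mean_auto_share: float, comp: CompetitionModel
) -> AccessProbabilities:
    """Mode-specific acquisition probabilities under competition.

    An encountered resource is contested with probability ``p_contest``
    (increasing in ``N``).  The opponent acts automatically with probability
    ``mean_auto_share`` (the population mean of ``1 - C``).  An automatic
    focal actor wins automatic-vs-automatic contests half the time and
    mixed contests with probability ``w_auto``; a controlled focal actor
    wins controlled-vs-controlled contests half the time and mixed ones
    with probability ``1 - w_auto``.
    """
    if N < 1:
        raise ValueError(f"population size must be >= 1, got {N}")
    if not 0.0 <= R <= 1.0:
        raise ValueError(f"R must be in [0, 1], got {R}")
    if not 0.0 <= mean_auto_share <= 1.0:
        raise ValueError(f"mean_auto_share must be in [0, 1], got {mean_auto_share}")
    pc = comp.contest_probability(N, R)
    m = mean_auto_share
    w = comp.w_auto
    p_auto = R * ((1.0 - pc) + pc * (m * 0.5 + (1.0 - m) * w))
    p_ctrl = R * ((1.0 - pc) + pc * ((1.0 - m) * 0.5 + m * (1.0 - w)))
    return AccessProbabilities(p_auto=p_auto, p_ctrl=p_ctrl)


# ---------------------------------------------------------------------------
# lifetime simulation


def simulate_lifetimes_batch(
    C,
    p_auto,
    p_ctrl,
    params: EnvironmentParams,
    policies: PolicySet,
    steps: int,
    rng: np.random.Generator,
    target_E=None,
    lam: float = 0.01,
    p_hat_init=None,
    E0: float = 0.0,
    S0: float = 0.0,
    record: bool = False,
):
    """Simulate many independent lifetimes in lockstep.

    ``C``, ``p_auto``, ``p_ctrl`` broadcast to a common length ``n``; one
    lifetime of ``steps`` timesteps is simulated per entry.  Returns
    ``(mean_E, var_E)`` arrays of length ``n`` (per-lifetime time mean and
    variance of the energy level) or, with ``record=True``, additionally
    the full ``(steps, n)`` energy trace.

    ``target_E`` switches automatic acts to the evolvable target-level rule
    (an array of per-agent targets); ``None`` gives the default
    full-consumption rule with no store access.  ``p_hat_init`` seeds the
    availability estimate; by default it starts at each agent's true
    expected acquisition probability ``C * p_ctrl + (1 - C) * p_auto``.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    C, p_auto, p_ctrl = np.broadcast_arrays(
        np.atleast_1d(np.asarray(C, dtype=float)),
        np.atleast_1d(np.asarray(p_auto, dtype=float)),
        np.atleast_1d(np.asarray(p_ctrl, dtype=float)),
    )
    n = C.shape[0]
    grid = policies.grid
    E_max, drain, rho = params.E_max, params.drain, params.rho
    dE_bin = E_max / (grid.n_E - 1)
    dS_bin = grid.S_cap / (grid.n_S - 1)
    FR = policies.frac_stack
    edges = policies._edges

    E = np.full(n, float(E0))
    S = np.full(n, float(S0))
    if p_hat_init is None:
        p_hat = C * p_ctrl + (1.0 - C) * p_auto
    else:
        p_hat = np.broadcast_to(np.asarray(p_hat_init, dtype=float), (n,)).copy()
    if target_E is not None:
        target_E = np.broadcast_to(np.asarray(target_E, dtype=float), (n,)).copy()

    sum_E = np.zeros(n)
    sum_E2 = np.zeros(n)
    trace = np.empty((steps, n)) if record else None

    for t in range(steps):
        ctrl = rng.random(n) < C
        E = np.maximum(0.0, E - drain)
        acq = rng.random(n) < np.where(ctrl, p_ctrl, p_auto)

        auto = ~ctrl
        if target_E is None:
            m = auto & acq
            if m.any():
                E[m] = E_max - (E_max - E[m]) * np.exp(-params.u * rho / E_max)
        else:
            if auto.any():
                pool = S[auto] + np.where(acq[auto], rho, 0.0)
                need = consumption_to_reach(E[auto], np.minimum(target_E[auto], E_max), params)
                x = np.minimum(pool, need)
                E[auto] = E_max - (E_max - E[auto]) * np.exp(-params.u * x / E_max)
                S[auto] = pool - x

        if ctrl.any():
            pi = np.searchsorted(edges, p_hat[ctrl])
            iE = np.clip(np.rint(E[ctrl] / dE_bin).astype(np.int64), 0, grid.n_E - 1)
            iS = np.clip(
                np.rint(np.minimum(S[ctrl], grid.S_cap) / dS_bin).astype(np.int64),
                0,
                grid.n_S - 1,
            )
            fr = FR[pi, iE, iS, acq[ctrl].astype(np.int64)]
            pool = S[ctrl] + np.where(acq[ctrl], rho, 0.0)
            x = fr * pool
            E[ctrl] = E_max - (E_max - E[ctrl]) * np.exp(-params.u * x / E_max)
            S[ctrl] = pool - x

        p_hat = (1.0 - lam) * p_hat + lam * acq
        sum_E += E
        sum_E2 += E * E
        if record:
            trace[t] = E

    mean_E = sum_E / steps
    var_E = sum_E2 / steps - mean_E**2
    if record:
        return mean_E, np.maximum(var_E, 0.0), trace
    return mean_E, np.maximum(var_E, 0.0)


def simulate_lifetime(
    C: float,
    access: AccessProbabilities,
    params: EnvironmentParams,
    policies: PolicySet,
    steps: int,
    rng_seed,
    **kwargs,
) -> float:
    """Mean energy level of one agent over one lifetime."""
    rng = np.random.default_rng(rng_seed)
    mean_E, _ = simulate_lifetimes_batch(
        [C], access.p_auto, access.p_ctrl, params, policies, steps, rng, **kwargs
    )
    return float(mean_E[0])


def simulate_lifetime_evolvable_auto(
    C: float,
    auto_policy: AutomaticPolicy,
    access: AccessProbabilities,
    params: EnvironmentParams,
    policies: PolicySet,
    steps: int,
    rng_seed,
    **kwargs,
) -> float:
    """Mean energy over a lifetime with the evolvable automatic target rule."""
    if auto_policy.mode == "full_consume":
        return simulate_lifetime(C, access, params, policies, steps, rng_seed, **kwargs)
    rng = np.random.default_rng(rng_seed)
    mean_E, _ = simulate_lifetimes_batch(
        [C],
        access.p_auto,
        access.p_ctrl,
        params,
        policies,
        steps,
        rng,
        target_E=[auto_policy.target_E],
        **kwargs,
    )
    return float(mean_E[0])


# ---------------------------------------------------------------------------
# fitness table


def default_c_levels(n: int = 11) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def default_p_levels() -> np.ndarray:
    """Access-probability axis for the fitness table.

    Denser at small probabilities, where mean energy changes fastest, while
    still spanning the whole unit interval so any query is in range.
    """
    return np.array([0.0, 0.002, 0.005, 0.01, 0.02, 0.04, 0.07, 0.125, 0.25, 0.5, 1.0])


@dataclass
class FitnessTable:
    """Precomputed mean-energy surface over ``(C, p_auto, p_ctrl)``."""

    c_levels: np.ndarray
    p_auto_levels: np.ndarray
    p_ctrl_levels: np.ndarray
    values: np.ndarray  # (n_C, n_pa, n_pc)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.c_levels = np.asarray(self.c_levels, dtype=float)
        self.p_auto_levels = np.asarray(self.p_auto_levels, dtype=float)
        self.p_ctrl_levels = np.asarray(self.p_ctrl_levels, dtype=float)
        expected = (self.c_levels.size, self.p_auto_levels.size, self.p_ctrl_levels.size)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != grid {expected}")
        self._interp = RegularGridInterpolator(
            (self.c_levels, self.p_auto_levels, self.p_ctrl_levels),
            self.values,
            method="linear",
            bounds_error=True,
        )

    def lookup(self, C, p_auto, p_ctrl):
        return lookup_fitness(self, C, p_auto, p_ctrl)


def lookup_fitness(table: FitnessTable, C, p_auto, p_ctrl):
    """Trilinear interpolation of the fitness surface; exact at grid nodes."""
    pts = np.stack(
        np.broadcast_arrays(
            np.asarray(C, dtype=float),
            np.asarray(p_auto, dtype=float),
            np.asarray(p_ctrl, dtype=float),
        ),
        axis=-1,
    )
    if np.any(pts < 0.0) or np.any(pts > 1.0):
        raise ValueError("fitness query outside the unit cube")
    out = table._interp(pts)
    if pts.ndim == 1:
        return float(out[0] if out.ndim else out)
    return out


def build_fitness_table(
    params: EnvironmentParams,
    policies: PolicySet,
    c_levels=None,
    p_levels=None,
    n_sims: int = 30_000,
    steps: int = 1_000,
    seed=0,
    lam: float = 0.01,
) -> FitnessTable:
    """Monte-Carlo estimate of mean lifetime energy on a full product grid.

    The total simulation budget ``n_sims`` is split evenly across grid
    cells (at least one replicate per cell); each replicate is an
    independent lifetime of ``steps`` timesteps.  The grid is the full
    product of the three axes so interpolation is defined everywhere,
    including the physically unreachable corner ``p_ctrl > p_auto``.
    """
    c_levels = default_c_levels() if c_levels is None else np.asarray(c_levels, float)
    p_levels = default_p_levels() if p_levels is None else np.asarray(p_levels, float)
    if c_levels.size == 0 or p_levels.size == 0:
        raise ValueError("fitness-table axes must be non-empty")
    n_cells = c_levels.size * p_levels.size**2
    reps = max(1, int(round(n_sims / n_cells)))

    Cg, Pa, Pc = np.meshgrid(c_levels, p_levels, p_levels, indexing="ij")
    C_flat = np.repeat(Cg.ravel(), reps)
    pa_flat = np.repeat(Pa.ravel(), reps)
    pc_flat = np.repeat(Pc.ravel(), reps)

    rng = np.random.default_rng(seed)
    mean_E, _ = simulate_lifetimes_batch(
        C_flat, pa_flat, pc_flat, params, policies, steps, rng, lam=lam
    )
    values = mean_E.reshape(n_cells, reps).mean(axis=1)
    values = values.reshape(c_levels.size, p_levels.size, p_levels.size)

    meta = {
        "n_sims": int(reps * n_cells),
        "reps_per_cell": reps,
        "steps": int(steps),
        "seed": int(seed) if np.isscalar(seed) else str(seed),
        "lam": lam,
        "params": {
            "R": params.R,
            "drain": params.drain,
            "rho": params.rho,
            "E_max": params.E_max,
            "u": params.u,
        },
    }
    return FitnessTable(
        c_levels=c_levels,
        p_auto_levels=p_levels,
        p_ctrl_levels=p_levels,
        values=values,
        meta=meta,
    )


@dataclass
class TargetFitnessTable:
    """Fitness surface with an extra axis for the automatic target level.

    Used by the model variant in which automatic acts consume toward a
    heritable target energy level instead of always consuming everything.
    """

    target_levels: np.ndarray
    c_levels: np.ndarray
    p_auto_levels: np.ndarray
    p_ctrl_levels: np.ndarray
    values: np.ndarray  # (n_T, n_C, n_pa, n_pc)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.target_levels = np.asarray(self.target_levels, dtype=float)
        self.c_levels = np.asarray(self.c_levels, dtype=float)
        self.p_auto_levels = np.asarray(self.p_auto_levels, dtype=float)
        self.p_ctrl_levels = np.asarray(self.p_ctrl_levels, dtype=float)
        self._interp = RegularGridInterpolator(
            (self.target_levels, self.c_levels, self.p_auto_levels, self.p_ctrl_levels),
            self.values,
            method="linear",
            bounds_error=True,
        )

    def lookup(self, target, C, p_auto, p_ctrl):
        pts = np.stack(
            np.broadcast_arrays(
                np.asarray(target, dtype=float),
                np.asarray(C, dtype=float),
                np.asarray(p_auto, dtype=float),
                np.asarray(p_ctrl, dtype=float),
            ),
            axis=-1,
        )
        out = self._interp(pts)
        return float(out[0] if out.ndim else out) if pts.ndim == 1 else out


def build_target_fitness_table(
    params: EnvironmentParams,
    policies: PolicySet,
    target_levels=None,
    c_levels=None,
    p_levels=None,
    n_sims: int = 30_000,
    steps: int = 1_000,
    seed=0,
    lam: float = 0.01,
) -> TargetFitnessTable:
    """Monte-Carlo fitness surface for the evolvable automatic-target variant."""
    target_levels = (
        np.linspace(0.0, params.E_max, 6)
        if target_levels is None
        else np.asarray(target_levels, float)
    )
    c_levels = default_c_levels() if c_levels is None else np.asarray(c_levels, float)
    p_levels = default_p_levels() if p_levels is None else np.asarray(p_levels, float)
    if target_levels.size == 0 or c_levels.size == 0 or p_levels.size == 0:
        raise ValueError("fitness-table axes must be non-empty")
    n_cells = target_levels.size * c_levels.size * p_levels.size**2
    reps = max(1, int(round(n_sims / n_cells)))

    Tg, Cg, Pa, Pc = np.meshgrid(
        target_levels, c_levels, p_levels, p_levels, indexing="ij"
    )
    rng = np.random.default_rng(seed)
    mean_E, _ = simulate_lifetimes_batch(
        np.repeat(Cg.ravel(), reps),
        np.repeat(Pa.ravel(), reps),
        np.repeat(Pc.ravel(), reps),
        params,
        policies,
        steps,
        rng,
        target_E=np.repeat(Tg.ravel(), reps),
        lam=lam,
    )
    values = mean_E.reshape(n_cells, reps).mean(axis=1)
    values = values.reshape(
        target_levels.size, c_levels.size, p_levels.size, p_levels.size
    )
    meta = {
        "n_sims": int(reps * n_cells),
        "reps_per_cell": reps,
        "steps": int(steps),
        "variant": "evolvable_automatic_target",
    }
    return TargetFitnessTable(
        target_levels=target_levels,
        c_levels=c_levels,
        p_auto_levels=p_levels,
        p_ctrl_levels=p_levels,
        values=values,
        meta=meta,
    )


def table_to_csv(table: FitnessTable, path, meta_path=None) -> None:
    """Write the fitness surface as flat CSV plus a JSON metadata sidecar."""
    Cg, Pa, Pc = np.meshgrid(
        table.c_levels, table.p_auto_levels, table.p_ctrl_levels, indexing="ij"
    )
    pd.DataFrame(
        {
            "C": Cg.ravel(),
            "p_auto": Pa.ravel(),
            "p_ctrl": Pc.ravel(),
            "mean_E": table.values.ravel(),
        }
    ).to_csv(path, index=False)
    meta_path = meta_path or str(path) + ".json"
    with open(meta_path, "w") as fh:
        json.dump(table.meta, fh, indent=2)


def table_from_csv(path, meta_path=None) -> FitnessTable:
    """Read a fitness surface written by :func:`table_to_csv`."""
    df = pd.read_csv(path)
    c_levels = np.unique(df["C"])
    pa_levels = np.unique(df["p_auto"])
    pc_levels = np.unique(df["p_ctrl"])
    values = (
        df.sort_values(["C", "p_auto", "p_ctrl"])["mean_E"]
        .to_numpy()
        .reshape(c_levels.size, pa_levels.size, pc_levels.size)
    )
    meta_path = meta_path or str(path) + ".json"
    try:
        with open(meta_path) as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {}
    return FitnessTable(
        c_levels=c_levels,
        p_auto_levels=pa_levels,
        p_ctrl_levels=pc_levels,
        values=values,
        meta=meta,
    )
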