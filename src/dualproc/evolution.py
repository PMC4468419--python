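"""Wright-Fisher evolution of the control propensity.

Each generation the population of ``N`` agents is reconstituted by sampling
parents with replacement in proportion to fitness, where an agent's fitness
is its expected mean lifetime energy looked up in the precomputed fitness
table at ``(C_i, p_auto, p_ctrl)``.  The access probabilities are recomputed
every generation from the current ``(R, N, mean(1 - C))``, which is what
makes selection frequency-dependent: as control spreads, the composition of
contests changes and with it every agent's expected access to resources.

Offspring mutate with probability ``rate`` by adding or subtracting
``step`` (sign equiprobable), clamped to ``[0, 1]``.  The optional second
heritable trait — the automatic policy's target energy level — mutates in
the same manner on its own scale ``[0, E_max]`` with step ``step * E_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent_simulation import (
    CompetitionModel,
    FitnessTable,
    access_probabilities,
    lookup_fitness,
)

__all__ = [
    "Population",
    "MutationParams",
    "Trajectory",
    "population_fitnesses",
    "wright_fisher_step",
    "run_fixed_scenario",
]


@dataclass(frozen=True)
class MutationParams:
    """Per-offspring mutation probability and trait increment."""

    rate: float = 0.05
    step: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {self.rate}")
        if not self.step > 0:
            raise ValueError(f"step must be positive, got {self.step}")


@dataclass
class Population:
    """Heritable traits plus the current demographic/environmental state."""

    traits: np.ndarray  # control propensities C, shape (N,)
    R: float
    generation: int = 0
    target_levels: np.ndarray | None = None  # optional evolvable automatic targets

    def __post_init__(self) -> None:
        self.traits = np.asarray(self.traits, dtype=float)
        if self.traits.ndim != 1 or self.traits.size < 1:
            raise ValueError("traits must be a non-empty 1-D array")
        if np.any(self.traits < 0.0) or np.any(self.traits > 1.0):
            raise ValueError("all C values must lie in [0, 1]")
        if self.target_levels is not None:
            self.target_levels = np.asarray(self.target_levels, dtype=float)
            if self.target_levels.shape != self.traits.shape:
                raise ValueError("target_levels must align with traits")

    @property
    def N(self) -> int:
        return self.traits.size


@dataclass
class Trajectory:
    """Per-generation record of an evolutionary run."""

    generation: np.ndarray
    mean_C: np.ndarray
    q10_C: np.ndarray
    q90_C: np.ndarray
    mean_E: np.ndarray
    N: np.ndarray
    R: np.ndarray
    extinct: bool = False
    mean_target: np.ndarray | None = None

    def __len__(self) -> int:
        return self.generation.size

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "generation": self.generation,
            "mean_C": self.mean_C,
            "q10_C": self.q10_C,
            "q90_C": self.q90_C,
            "mean_E": self.mean_E,
            "N": self.N,
            "R": self.R,
        }
        if self.mean_target is not None:
            cols["mean_target"] = self.mean_target
        return pd.DataFrame(cols)


class _TrajectoryBuilder:
    def __init__(self, track_target: bool):
        self.rows: list[tuple] = []
        self.track_target = track_target

    def record(self, g, traits, fitnesses, N, R, targets=None):
        q10, q90 = np.quantile(traits, [0.1, 0.9])
        row = (
            g,
            float(traits.mean()),
            float(q10),
            float(q90),
            float(np.mean(fitnesses)),
            int(N),
            float(R),
        )
        if self.track_target:
            row = row + (float(np.mean(targets)),)
        self.rows.append(row)

    def build(self, extinct: bool) -> Trajectory:
        arr = np.asarray(self.rows, dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 8 if self.track_target else 7)
        return Trajectory(
            generation=arr[:, 0].astype(int),
            mean_C=arr[:, 1],
            q10_C=arr[:, 2],
            q90_C=arr[:, 3],
            mean_E=arr[:, 4],
            N=arr[:, 5].astype(int),
            R=arr[:, 6],
            extinct=extinct,
            mean_target=arr[:, 7] if self.track_target else None,
        )


def population_fitnesses(
    pop: Population, table, comp: CompetitionModel
) -> np.ndarray:
    """Fitness (expected mean lifetime energy) of every agent.

    Access probabilities are computed once from the population composition
    and shared; each agent then differs only through its own traits.
    ``table`` is a :class:`~dualproc.agent_simulation.FitnessTable` or, when
    the population carries evolvable automatic targets, a
    :class:`~dualproc.agent_simulation.TargetFitnessTable`.
    """
    access = access_probabilities(pop.R, pop.N, float(np.mean(1.0 - pop.traits)), comp)
    if pop.target_levels is not None:
        return np.asarray(
            table.lookup(pop.target_levels, pop.traits, access.p_auto, access.p_ctrl)
        )
    return np.asarray(lookup_fitness(table, pop.traits, access.p_auto, access.p_ctrl))


def _sample_offspring(
    traits: np.ndarray,
    fitnesses: np.ndarray,
    n_offspring: int,
    mut: MutationParams,
    rng: np.random.Generator,
    targets: np.ndarray | None = None,
    target_max: float = 100.0,
):
    """Draw mutated offspring by fitness-proportional sampling with replacement."""
    total = float(np.sum(fitnesses))
    if total > 0.0:
        parents = rng.choice(traits.size, size=n_offspring, p=fitnesses / total)
    else:
        # a starving (mean E = 0) population still reproduces: pure drift
        parents = rng.integers(0, traits.size, size=n_offspring)
    child = traits[parents].copy()
    mutate = rng.random(n_offspring) < mut.rate
    signs = rng.integers(0, 2, size=n_offspring) * 2 - 1
    child[mutate] += mut.step * signs[mutate]
    np.clip(child, 0.0, 1.0, out=child)
    child_t = None
    if targets is not None:
        child_t = targets[parents].copy()
        mutate_t = rng.random(n_offspring) < mut.rate
        signs_t = rng.integers(0, 2, size=n_offspring) * 2 - 1
        child_t[mutate_t] += mut.step * target_max * signs_t[mutate_t]
        np.clip(child_t, 0.0, target_max, out=child_t)
    return child, child_t


def wright_fisher_step(
    pop: Population,
    fitnesses: np.ndarray,
    mut: MutationParams,
    rng: np.random.Generator,
    target_max: float = 100.0,
) -> Population:
    """One generation of fitness-proportional reproduction with mutation.

    Population size is conserved.  If total fitness is zero, parents are
    drawn uniformly (pure drift) rather than raising: a fixed-size
    population with mean energy zero is starving, not extinct.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    if fitnesses.shape != pop.traits.shape:
        raise ValueError("fitnesses must align with traits")
    if np.any(fitnesses < 0.0):
        raise ValueError("fitnesses must be non-negative")
    child, child_t = _sample_offspring(
        pop.traits, fitnesses, pop.N, mut, rng, pop.target_levels, target_max
    )
    return Population(
        traits=child,
        R=pop.R,
        generation=pop.generation + 1,
        target_levels=child_t,
    )


def run_scenario(
    N0: int,
    R0: float,
    generations: int,
    table,
    comp: CompetitionModel,
    mut: MutationParams,
    seed,
    update_N=None,
    update_R=None,
    init_C: float = 0.0,
    init_target: float | None = None,
    target_max: float = 100.0,
) -> Trajectory:
    """Generic evolutionary driver shared by the fixed and feedback scenarios.

    ``update_N(N, mean_E) -> N'`` and ``update_R(R, mean_E, mean_C) -> R'``
    are optional per-generation hooks; when ``update_N`` shrinks the
    population, individuals are removed uniformly at random, and when it
    grows, the extra individuals are additional fitness-proportional
    offspring of the previous generation.  The run ends early (trajectory
    to date, flagged extinct) if ``N`` reaches zero.
    """
    if N0 < 1:
        raise ValueError("initial population size must be >= 1")
    rng = np.random.default_rng(seed)
    traits = np.full(N0, float(init_C))
    targets = None if init_target is None else np.full(N0, float(init_target))
    R = float(R0)
    builder = _TrajectoryBuilder(track_target=targets is not None)
    extinct = False

    for g in range(generations):
        pop = Population(traits=traits, R=R, generation=g, target_levels=targets)
        fitnesses = population_fitnesses(pop, table, comp)
        mean_E = float(np.mean(fitnesses))
        mean_C = float(np.mean(traits))
        builder.record(g, traits, fitnesses, pop.N, R, targets)

        n_next = pop.N
        if update_N is not None:
            n_next = int(update_N(pop.N, mean_E))
            if n_next <= 0:
                extinct = True
                break
        n_draw = max(n_next, pop.N)
        child, child_t = _sample_offspring(
            traits, fitnesses, n_draw, mut, rng, targets, target_max
        )
        if n_next < pop.N:
            keep = rng.permutation(n_draw)[:n_next]
            child = child[keep]
            child_t = None if child_t is None else child_t[keep]
        elif n_next > pop.N:
            pass  # extra offspring already drawn from the same parent pool
        traits, targets = child, child_t

        if update_R is not None:
            R = float(update_R(R, mean_E, mean_C))

    return builder.build(extinct)


def run_fixed_scenario(
    N: int,
    R: float,
    generations: int,
    table,
    comp: CompetitionModel | None = None,
    mut: MutationParams | None = None,
    seed=0,
    init_C: float = 0.0,
    init_target: float | None = None,
    target_max: float = 100.0,
) -> Trajectory:
    """Evolve a fixed-size population in a fixed environment.

    Starts from a homogeneous population (``C = init_C``, default 0) and
    returns one record per generation; two runs with the same seed yield
    identical trajectories.
    """
    return run_scenario(
        N,
        R,
        generations,
        table,
        comp or CompetitionModel(),
        mut or MutationParams(),
        seed,
        init_C=init_C,
        init_target=init_target,
        target_max=target_max,
    )
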