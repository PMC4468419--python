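"""Eco-evolutionary feedback loops and trajectory diagnostics.

Two scenarios couple the evolving population back to its demography or its
environment:

* **Variable population size** — richness ``R`` is fixed; the population
  grows by ``delta_N`` individuals whenever mean energy exceeds
  ``T_N + epsilon``, shrinks by ``delta_N`` when it falls below
  ``T_N - epsilon``, and is otherwise stable.  Reaching ``N = 0`` is
  extinction and ends the run.  Because competition intensifies with
  ``N``, the fitness surplus generated by controlled processing enlarges
  the population and thereby erodes the advantage of control — the
  boom-bust pattern.

* **Variable richness** — ``N`` is fixed; ``R`` rises by ``delta_R`` when
  the product ``mean_E * mean_C`` exceeds ``T_R + epsilon`` (deliberation
  plus surplus energy producing innovation), falls when the product drops
  below ``T_R - epsilon``, and never falls below the baseline ``R_0``.
  Enrichment removes the scarcity that favored control, automatic
  processing free-rides on the richer environment, and the system can
  settle into a sustained limit cycle of ``mean_C`` and ``R``.

``detect_limit_cycle`` quantifies such oscillations from a trajectory by
peak/trough analysis of the smoothed ``mean_C`` series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .agent_simulation import CompetitionModel
from .evolution import MutationParams, Trajectory, run_scenario

__all__ = [
    "FeedbackConfig",
    "CycleStats",
    "update_population_size",
    "update_richness",
    "run_variable_N",
    "run_variable_R",
    "detect_limit_cycle",
]


@dataclass(frozen=True)
class FeedbackConfig:
    """Thresholds and increments for the two feedback loops.

    ``T_N`` acts on mean energy (population growth); ``T_R`` acts on the
    product of mean energy and mean control (enrichment).  ``epsilon`` is
    the dead-band half-width within which nothing changes, keeping
    near-threshold populations stable instead of oscillating one increment
    up and down.
    """

    T_N: float = 12.0
    T_R: float = 6.0
    epsilon: float = 0.24
    delta_N: int = 1
    delta_R: float = 2e-4
    N_0: int = 30
    R_0: float = 0.005

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if not (isinstance(self.delta_N, (int, np.integer)) and self.delta_N >= 1):
            raise ValueError(f"delta_N must be an integer >= 1, got {self.delta_N}")
        if not self.delta_R > 0:
            raise ValueError(f"delta_R must be positive, got {self.delta_R}")
        if self.N_0 < 1:
            raise ValueError(f"N_0 must be >= 1, got {self.N_0}")
        if not 0.0 < self.R_0 <= 1.0:
            raise ValueError(f"R_0 must be in (0, 1], got {self.R_0}")


@dataclass(frozen=True)
class CycleStats:
    """Summary of oscillations in a trajectory's mean control level."""

    is_cycling: bool
    amplitude: float
    period: float
    n_cycles: int


def update_population_size(N: int, mean_E: float, cfg: FeedbackConfig) -> int:
    """Dead-band growth rule for the population size.

    Grow by ``delta_N`` above ``T_N + epsilon``, shrink below
    ``T_N - epsilon`` (floored at zero, which flags extinction), hold
    inside the band.
    """
    if N < 0:
        raise ValueError("N must be >= 0")
    if mean_E > cfg.T_N + cfg.epsilon:
        return N + cfg.delta_N
    if mean_E < cfg.T_N - cfg.epsilon:
        return max(0, N - cfg.delta_N)
    return N


def update_richness(R: float, mean_E: float, mean_C: float, cfg: FeedbackConfig) -> float:
    """Dead-band enrichment rule for environmental richness.

    Driven by ``mean_E * mean_C``; capped at 1 above and floored at the
    baseline ``R_0`` below.
    """
    product = mean_E * mean_C
    if product > cfg.T_R + cfg.epsilon:
        return min(1.0, R + cfg.delta_R)
    if product < cfg.T_R - cfg.epsilon:
        return max(cfg.R_0, R - cfg.delta_R)
    return R


def run_variable_N(
    cfg: FeedbackConfig,
    R: float,
    generations: int,
    table,
    comp: CompetitionModel | None = None,
    mut: MutationParams | None = None,
    seed=0,
    init_C: float = 0.0,
    init_target: float | None = None,
) -> Trajectory:
    """Evolve with fitness-driven population size at fixed richness."""
    return run_scenario(
        cfg.N_0,
        R,
        generations,
        table,
        comp or CompetitionModel(),
        mut or MutationParams(),
        seed,
        update_N=lambda N, mean_E: update_population_size(N, mean_E, cfg),
        init_C=init_C,
        init_target=init_target,
    )


def run_variable_R(
    cfg: FeedbackConfig,
    N: int,
    generations: int,
    table,
    comp: CompetitionModel | None = None,
    mut: MutationParams | None = None,
    seed=0,
    init_C: float = 0.0,
    init_target: float | None = None,
) -> Trajectory:
    """Evolve with control-driven environmental richness at fixed size."""
    return run_scenario(
        N,
        cfg.R_0,
        generations,
        table,
        comp or CompetitionModel(),
        mut or MutationParams(),
        seed,
        update_R=lambda R, mean_E, mean_C: update_richness(R, mean_E, mean_C, cfg),
        init_C=init_C,
        init_target=init_target,
    )


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    if window <= 1:
        return x
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def detect_limit_cycle(
    traj: Trajectory,
    burn_in: float = 0.2,
    min_amplitude: float = 0.2,
    min_cycles: int = 3,
    smooth_window: int | None = None,
) -> CycleStats:
    """Detect sustained oscillations in a trajectory's mean control level.

    After discarding the initial ``burn_in`` fraction, the ``mean_C``
    series is smoothed with a centered moving average (window 2% of the
    remaining length by default) and its alternating peaks and troughs are
    located.  The trajectory is classified as cycling when at least
    ``min_cycles`` peak/trough alternations with peak-to-trough amplitude
    at least ``min_amplitude`` are present.  Reported ``period`` is the
    mean spacing between successive peaks and ``amplitude`` the mean
    peak-to-trough swing.
    """
    start = int(burn_in * len(traj))
    x = np.asarray(traj.mean_C[start:], dtype=float)
    if x.size < 4 or np.ptp(x) == 0.0:
        return CycleStats(is_cycling=False, amplitude=0.0, period=float("nan"), n_cycles=0)

    window = smooth_window if smooth_window is not None else max(1, int(0.02 * x.size))
    sm = _smooth(x, window)
    prominence = min_amplitude / 2.0
    peaks, _ = find_peaks(sm, prominence=prominence)
    troughs, _ = find_peaks(-sm, prominence=prominence)

    # merge into one alternating sequence of extrema
    events = sorted(
        [(int(i), 1) for i in peaks] + [(int(i), -1) for i in troughs]
    )
    cleaned: list[tuple[int, int]] = []
    for idx, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            # keep the more extreme of two same-kind neighbours
            prev = cleaned[-1][0]
            better = idx if kind * sm[idx] > kind * sm[prev] else prev
            cleaned[-1] = (better, kind)
        else:
            cleaned.append((idx, kind))

    swings = [
        abs(sm[cleaned[k + 1][0]] - sm[cleaned[k][0]])
        for k in range(len(cleaned) - 1)
    ]
    qualifying = [s for s in swings if s >= min_amplitude]
    n_cycles = len(qualifying)
    amplitude = float(np.mean(qualifying)) if qualifying else 0.0

    peak_idx = [i for i, kind in cleaned if kind == 1]
    if len(peak_idx) >= 2:
        period = float(np.mean(np.diff(peak_idx)))
    elif len(cleaned) >= 2:
        period = 2.0 * float(np.mean(np.diff([i for i, _ in cleaned])))
    else:
        period = float("nan")

    is_cycling = n_cycles >= min_cycles
    return CycleStats(
        is_cycling=is_cycling,
        amplitude=amplitude,
        period=period,
        n_cycles=n_cycles,
    )
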