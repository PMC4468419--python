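"""Single-timestep energy bookkeeping for resource-consuming agents.

Each agent carries an energy level ``E`` that is drained by a constant
subsistence cost every timestep and replenished by consuming resources.
Consumption is subject to satiety: the marginal energetic gain of one unit
of resource is ``u * (1 - E / E_max)``, so consumption is most valuable when
the agent is close to starvation and worthless at the ceiling ``E_max``.
Integrating that marginal-gain rate gives the closed form used throughout::

    E' = E_max - (E_max - E) * exp(-u * x / E_max)

which is monotone increasing and concave in the amount consumed ``x`` and
never exceeds ``E_max``.  Unconsumed resources sit in a store ``S`` (no
interest, no decay) that only controlled behaviour can access.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnvironmentParams",
    "EnergyState",
    "apply_drain",
    "consume",
    "marginal_gain",
    "consumption_to_reach",
]


@dataclass(frozen=True)
class EnvironmentParams:
    """Environment and physiology constants.

    Parameters
    ----------
    R : float
        Per-timestep probability of encountering a resource ("richness"),
        in ``[0, 1]``.
    drain : float
        Energy subtracted every timestep (subsistence cost), ``> 0``.
    rho : float
        Size of one encountered resource, in the same units as energy
        consumed, ``> 0``.
    E_max : float
        Satiety ceiling on the energy level, ``> 0``.
    u : float
        Utility rate constant: marginal energy per unit consumed at
        ``E = 0``.  Larger ``u`` makes the satiety curve bend harder, which
        raises the value of spreading consumption over time.
    """

    R: float = 0.005
    drain: float = 1.0
    rho: float = 10.0
    E_max: float = 100.0
    u: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.R <= 1.0:
            raise ValueError(f"R must be in [0, 1], got {self.R}")
        for name in ("drain", "rho", "E_max", "u"):
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class EnergyState:
    """Energy ``E`` and stored resource ``S`` of one agent at one instant."""

    E: float
    S: float = 0.0

    def __post_init__(self) -> None:
        if self.E < 0.0:
            raise ValueError(f"E must be >= 0, got {self.E}")
        if self.S < 0.0:
            raise ValueError(f"S must be >= 0, got {self.S}")


def apply_drain(state: EnergyState, params: EnvironmentParams) -> EnergyState:
    """Subtract the per-step subsistence drain, flooring energy at zero."""
    return EnergyState(E=max(0.0, state.E - params.drain), S=state.S)


def consume(E, x, params: EnvironmentParams):
    """Energy level after consuming ``x`` units of resource at energy ``E``.

    Closed form of the saturating marginal-gain ODE
    ``dE/dx = u * (1 - E / E_max)``.  Accepts scalars or numpy arrays and
    broadcasts.  ``x`` must be non-negative; a negative ``x`` indicates a
    caller bug and raises.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0.0):
        raise ValueError("consumption amount x must be non-negative")
    E_arr = np.asarray(E, dtype=float)
    out = params.E_max - (params.E_max - E_arr) * np.exp(-params.u * x_arr / params.E_max)
    if np.isscalar(E) and np.isscalar(x):
        return float(out)
    return out


def marginal_gain(E, params: EnvironmentParams):
    """Instantaneous energy gain per unit consumed, ``u * (1 - E/E_max)``."""
    E_arr = np.asarray(E, dtype=float)
    if np.any(E_arr < 0.0) or np.any(E_arr > params.E_max):
        raise ValueError("E must lie in [0, E_max]")
    out = params.u * (1.0 - E_arr / params.E_max)
    return float(out) if np.isscalar(E) else out


def consumption_to_reach(E, target, params: EnvironmentParams):
    """Amount that must be consumed to lift energy from ``E`` to ``target``.

    Inverse of :func:`consume`:
    ``x = (E_max / u) * ln((E_max - E) / (E_max - target))``.
    Returns 0 where ``target <= E`` and ``inf`` where ``target >= E_max``
    (the ceiling is approached only asymptotically).
    """
    E_arr = np.asarray(E, dtype=float)
    t_arr = np.asarray(target, dtype=float)
    with np.errstate(divide="ignore"):
        x = (params.E_max / params.u) * (
            np.log(params.E_max - E_arr) - np.log(np.maximum(params.E_max - t_arr, 0.0))
        )
    out = np.where(t_arr <= E_arr, 0.0, x)
    if np.isscalar(E) and np.isscalar(target):
        return float(out)
    return out
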