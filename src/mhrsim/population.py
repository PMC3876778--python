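"""The multi-hit-repair population chain.

Vital cells N are knocked one level down a chain of damaged populations
L₁ … L_kmax at the hit rate αR (one hit per transition); repair moves cells
one level back up at rate c_r·P(Γ,Λ), and elimination removes damaged cells
irreversibly at rate c_e.  The chain is truncated at ``k_max``: a further hit
on L_kmax leaks the cell into an *overflow* ledger and counts it dead.
Eliminated and overflowed cells are book-kept so that

    N + Σ L_k + eliminated + overflow = N(0)

holds exactly along any trajectory.

State vector layout (length k_max + 7)::

    [N, L1, ..., Lk_max, Gamma, Upsilon, Lambda, eliminated, overflow, dose]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import (
    RadiationParams,
    RepairProbabilityModel,
    ThermalParams,
    arrhenius_k1,
    celsius_to_kelvin,
)

__all__ = ["SystemState", "make_rhs", "mhr_rates", "survival_from_state", "LOG10_E"]

#: log10(e) — conversion between natural-log and log10 survival.
LOG10_E = math.log10(math.e)

BODY_TEMPERATURE_K = celsius_to_kelvin(37.0)


@dataclass
class SystemState:
    """Full state of the coupled population + damage-kinetics system."""

    N: float
    L: np.ndarray
    Gamma: float
    Upsilon: float
    Lambda: float
    eliminated: float
    overflow: float
    dose_delivered: float

    @classmethod
    def initial(cls, k_max: int = 6, N0: float = 1.0) -> "SystemState":
        """Untreated initial condition: all cells vital, no damage."""
        return cls(
            N=N0,
            L=np.zeros(k_max),
            Gamma=0.0,
            Upsilon=1.0,
            Lambda=0.0,
            eliminated=0.0,
            overflow=0.0,
            dose_delivered=0.0,
        )

    @property
    def k_max(self) -> int:
        return len(self.L)

    @property
    def total(self) -> float:
        """Conserved cell budget N + ΣL + eliminated + overflow."""
        return self.N + float(self.L.sum()) + self.eliminated + self.overflow

    def to_vector(self) -> np.ndarray:
        k = self.k_max
        y = np.empty(k + 7)
        y[0] = self.N
        y[1 : 1 + k] = self.L
        y[k + 1] = self.Gamma
        y[k + 2] = self.Upsilon
        y[k + 3] = self.Lambda
        y[k + 4] = self.eliminated
        y[k + 5] = self.overflow
        y[k + 6] = self.dose_delivered
        return y

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "SystemState":
        k = len(y) - 7
        return cls(
            N=float(y[0]),
            L=np.array(y[1 : 1 + k]),
            Gamma=float(y[k + 1]),
            Upsilon=float(y[k + 2]),
            Lambda=float(y[k + 3]),
            eliminated=float(y[k + 4]),
            overflow=float(y[k + 5]),
            dose_delivered=float(y[k + 6]),
        )


def make_rhs(
    rad: RadiationParams,
    therm: ThermalParams | None = None,
    pmodel: RepairProbabilityModel | None = None,
):
    """Build the packed-vector right-hand side f(y, R, k1) of the MHR system.

    The returned callable takes the state vector ``y``, the dose rate ``R``
    (Gy/h) and the thermal damage rate ``k1`` (per hour, precomputed from the
    segment temperature) and returns dy/dt.  Closing over the parameters
    keeps the inner loop of the fixed-step integrator cheap.
    """
    if pmodel is None:
        pmodel = RepairProbabilityModel(
            mu_gamma=rad.mu_gamma,
            mu_lambda=therm.mu_lambda if therm is not None else 0.0,
        )
    k = rad.k_max
    alpha, c_r, c_e, gamma = rad.alpha, rad.c_r, rad.c_e, rad.gamma
    k2 = therm.k2 if therm is not None else 0.0
    prob = pmodel  # callable P(Gamma, Lambda)

    def rhs(y: np.ndarray, R: float, k1: float) -> np.ndarray:
        N = y[0]
        L = y[1 : 1 + k]
        Gamma = y[k + 1]
        Upsilon = y[k + 2]
        Lambda = y[k + 3]
        crP = c_r * prob(max(Gamma, 0.0), min(max(Lambda, 0.0), 1.0))
        aR = alpha * R
        d = np.empty_like(y)
        d[0] = -aR * N + crP * L[0]
        dL = d[1 : 1 + k]
        np.multiply(L, -(aR + crP + c_e), out=dL)
        dL[0] += aR * N
        dL[1:] += aR * L[:-1]       # hits cascading down the chain
        dL[:-1] += crP * L[1:]      # repair moving one level up
        d[k + 1] = R - gamma * Gamma
        dU = -k1 * Upsilon + k2 * Lambda
        d[k + 2] = dU
        d[k + 3] = -dU
        d[k + 4] = c_e * L.sum()    # eliminated ledger
        d[k + 5] = aR * L[-1]       # overflow past the cutoff
        d[k + 6] = R                # delivered dose
        return d

    return rhs


def mhr_rates(
    state: SystemState,
    R: float,
    T: float = BODY_TEMPERATURE_K,
    rad: RadiationParams | None = None,
    therm: ThermalParams | None = None,
    pmodel: RepairProbabilityModel | None = None,
) -> SystemState:
    """Time derivatives of every state component, as a :class:`SystemState`.

    Convenience wrapper around :func:`make_rhs` for single evaluations;
    the integrator uses the closure directly.
    """
    if rad is None:
        raise ValueError("rad parameters are required")
    if R < 0:
        raise ValueError(f"dose rate must be >= 0, got {R}")
    y = state.to_vector()
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state component in {y}")
    k1 = arrhenius_k1(T, therm) if therm is not None else 0.0
    dy = make_rhs(rad, therm, pmodel)(y, R, k1)
    return SystemState.from_vector(dy)


def survival_from_state(state: SystemState, mode: str = "current", **relax_kwargs):
    """log₁₀ surviving fraction S = N/N₀ (N₀ = 1 by construction).

    ``mode="current"`` reads the instantaneous value; ``mode="asymptotic"``
    integrates onward with the beam off until all damaged populations have
    resolved to repaired or eliminated (see
    :func:`mhrsim.simulate.relax_to_asymptote`, which accepts the parameters
    through ``relax_kwargs``).
    """
    if mode == "current":
        return math.log10(state.N)
    if mode == "asymptotic":
        from .simulate import relax_to_asymptote

        final = relax_to_asymptote(state, **relax_kwargs)
        return math.log10(final.N)
    raise ValueError(f"mode must be 'current' or 'asymptotic', got {mode!r}")
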