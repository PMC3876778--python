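"""Exposure protocols and fixed-step RK4 integration of the coupled system.

A :class:`Protocol` is a contiguous sequence of piecewise-constant segments,
each carrying a dose rate (Gy/h) and a temperature (K).  The integrator is a
classical 4th-order Runge-Kutta scheme with a step size chosen per segment:
``dt`` during beam-on (reduced automatically for very high dose rates, where
the beam-on window is only seconds long) and ``dt_off`` during beam-off.
Steps are clipped so segment boundaries are hit exactly.  After the protocol
ends, the system relaxes beam-off until every damaged population has resolved
to repaired or eliminated — the *asymptotic* survival read-out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    RadiationParams,
    RepairProbabilityModel,
    ThermalParams,
    arrhenius_k1,
    celsius_to_kelvin,
)
from .population import SystemState, make_rhs

__all__ = [
    "Segment",
    "Protocol",
    "Trajectory",
    "rk4_step",
    "run",
    "relax_to_asymptote",
    "asymptotic_survival",
]

BODY_TEMPERATURE_K = celsius_to_kelvin(37.0)

# Integrator defaults.  DT_ON spans the coarse end of the working step-size
# range; above HIGH_RATE_THRESHOLD the beam-on window for a typical fraction
# is a few seconds, so the step drops to DT_HIGH.
DT_ON = 1e-3           # h, beam-on
DT_HIGH = 5e-5         # h, beam-on at very high dose rate
DT_OFF = 1e-3          # h, beam-off
HIGH_RATE_THRESHOLD = 300.0   # Gy/h

# Asymptote criteria: damaged populations resolved and N stationary.
SUM_L_TOL = 1e-9       # fraction of N0
DNDT_TOL = 1e-9        # fraction of N0 per hour
DEFAULT_HORIZON = 200.0  # h
_RELAX_CHUNK = 0.25      # h between convergence checks

_NEG_TOL = 1e-10       # negative-compartment tolerance before step halving
_MAX_HALVINGS = 30


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant exposure interval."""

    t_start: float
    t_end: float
    dose_rate: float = 0.0
    temperature: float = BODY_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"segment must have t_end > t_start, got {self}")
        if self.dose_rate < 0:
            raise ValueError(f"dose rate must be >= 0, got {self.dose_rate}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def dose(self) -> float:
        return self.dose_rate * self.duration


@dataclass(frozen=True)
class Protocol:
    """Contiguous, non-overlapping exposure timeline starting at t = 0."""

    segments: tuple[Segment, ...]

    def __init__(self, segments) -> None:
        segments = tuple(segments)
        for prev, nxt in zip(segments, segments[1:]):
            if abs(prev.t_end - nxt.t_start) > 1e-12:
                raise ValueError(
                    f"segments must be contiguous: {prev.t_end} != {nxt.t_start}"
                )
        if segments and segments[0].t_start < 0:
            raise ValueError("protocol must start at t >= 0")
        object.__setattr__(self, "segments", segments)

    @property
    def total_dose(self) -> float:
        return sum(s.dose for s in self.segments)

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end if self.segments else 0.0

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


def rk4_step(rhs, y: np.ndarray, dt: float, R: float, k1: float) -> np.ndarray:
    """One classical RK4 update of the packed state vector.

    If the update drives any population compartment negative beyond a small
    tolerance the step is retried at half size (recursively, bounded); this
    guards the stiff beam-off transient without an implicit solver.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_pop = len(y) - 6  # N and the L-chain
    h = dt
    for _ in range(_MAX_HALVINGS):
        k1v = rhs(y, R, k1)
        k2v = rhs(y + 0.5 * h * k1v, R, k1)
        k3v = rhs(y + 0.5 * h * k2v, R, k1)
        k4v = rhs(y + h * k3v, R, k1)
        y_new = y + (h / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        if not np.all(np.isfinite(y_new)):
            raise FloatingPointError("non-finite state after RK4 step")
        if y_new[:n_pop].min() >= -_NEG_TOL:
            if h == dt:
                return y_new
            # substep succeeded; finish the remainder at the same size
            y = y_new
            remaining = dt - h
            while remaining > 1e-15:
                step = min(h, remaining)
                y = rk4_step(rhs, y, step, R, k1)
                remaining -= step
            return y
        h *= 0.5
    raise RuntimeError(
        "RK4 step kept producing negative populations after "
        f"{_MAX_HALVINGS} halvings (dt={dt})"
    )


@dataclass
class Trajectory:
    """Recorded time course of the full system state plus derived read-outs."""

    times: np.ndarray
    states: np.ndarray  # shape (n_points, k_max + 7)
    rad: RadiationParams
    pmodel: RepairProbabilityModel

    @property
    def k_max(self) -> int:
        return self.states.shape[1] - 7

    @property
    def N(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def L(self) -> np.ndarray:
        return self.states[:, 1 : 1 + self.k_max]

    @property
    def Gamma(self) -> np.ndarray:
        return self.states[:, self.k_max + 1]

    @property
    def Upsilon(self) -> np.ndarray:
        return self.states[:, self.k_max + 2]

    @property
    def Lambda(self) -> np.ndarray:
        return self.states[:, self.k_max + 3]

    @property
    def eliminated(self) -> np.ndarray:
        return self.states[:, self.k_max + 4]

    @property
    def overflow(self) -> np.ndarray:
        return self.states[:, self.k_max + 5]

    @property
    def dose(self) -> np.ndarray:
        return self.states[:, self.k_max + 6]

    @property
    def log10S(self) -> np.ndarray:
        return np.log10(self.N)

    @property
    def P(self) -> np.ndarray:
        return np.array(
            [self.pmodel(g, lam) for g, lam in zip(self.Gamma, self.Lambda)]
        )

    def final_state(self) -> SystemState:
        return SystemState.from_vector(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_h": self.times, "N": self.N}
        for i in range(self.k_max):
            cols[f"L{i + 1}"] = self.L[:, i]
        cols.update(
            Gamma_Gy=self.Gamma,
            Upsilon=self.Upsilon,
            Lambda=self.Lambda,
            eliminated=self.eliminated,
            overflow=self.overflow,
            dose_Gy=self.dose,
            log10S=self.log10S,
            P=self.P,
        )
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _segment_dt(R: float, dt: float, dt_off: float) -> float:
    if R <= 0:
        return dt_off
    if R > HIGH_RATE_THRESHOLD:
        return min(dt, DT_HIGH)
    return dt


def _integrate_segment(rhs, y, t0, t1, R, k1, dt_nominal, recorder, record_every):
    """March y from t0 to t1 with steps clipped to land on t1 exactly."""
    length = t1 - t0
    n_steps = max(1, math.ceil(length / dt_nominal - 1e-12))
    h = length / n_steps
    t = t0
    for i in range(n_steps):
        y = rk4_step(rhs, y, h, R, k1)
        t = t1 if i == n_steps - 1 else t0 + (i + 1) * h
        if recorder is not None and ((i + 1) % record_every == 0 or i == n_steps - 1):
            recorder[0].append(t)
            recorder[1].append(y.copy())
    return y, t


def run(
    protocol: Protocol,
    rad: RadiationParams,
    therm: ThermalParams | None = None,
    pmodel: RepairProbabilityModel | None = None,
    *,
    dt: float = DT_ON,
    dt_off: float = DT_OFF,
    relax: bool = True,
    horizon: float = DEFAULT_HORIZON,
    record_every: int = 1,
    initial: SystemState | None = None,
) -> Trajectory:
    """Integrate the full MHR system through a protocol.

    Parameters
    ----------
    protocol
        The exposure timeline.
    rad, therm, pmodel
        Model parameters; ``therm=None`` disables the thermal subsystem
        (k₁ = k₂ = 0, Λ stays at its initial value) and ``pmodel=None``
        selects the exponential repair probability with the sensitivities
        taken from ``rad``/``therm``.
    dt, dt_off
        Beam-on / beam-off step sizes (hours).  Beam-on steps drop to
        5·10⁻⁵ h automatically above 300 Gy/h.
    relax, horizon
        If ``relax``, continue beam-off after the last segment until the
        asymptote criteria are met (ΣL < 10⁻⁹ and |dN/dt| < 10⁻⁹ h⁻¹ per
        unit N₀), failing loudly after ``horizon`` hours.
    record_every
        Record every n-th step (segment boundaries are always recorded).
    """
    if pmodel is None:
        pmodel = RepairProbabilityModel(
            mu_gamma=rad.mu_gamma,
            mu_lambda=therm.mu_lambda if therm is not None else 0.0,
        )
    rhs = make_rhs(rad, therm, pmodel)
    state = initial if initial is not None else SystemState.initial(rad.k_max)
    y = state.to_vector()
    t = protocol.segments[0].t_start if len(protocol) else 0.0
    recorder = ([t], [y.copy()])

    for seg in protocol:
        k1 = arrhenius_k1(seg.temperature, therm) if therm is not None else 0.0
        dt_seg = _segment_dt(seg.dose_rate, dt, dt_off)
        y, t = _integrate_segment(
            rhs, y, seg.t_start, seg.t_end, seg.dose_rate, k1,
            dt_seg, recorder, record_every,
        )

    if relax:
        y, t = _relax(rhs, y, t, therm, dt_off, horizon, recorder, record_every)

    times = np.array(recorder[0])
    states = np.vstack(recorder[1])
    return Trajectory(times=times, states=states, rad=rad, pmodel=pmodel)


def _relax(rhs, y, t, therm, dt_off, horizon, recorder, record_every):
    """Beam-off integration until the asymptote criteria hold."""
    k1 = arrhenius_k1(BODY_TEMPERATURE_K, therm) if therm is not None else 0.0
    n_pop = len(y) - 6
    t_stop = t + horizon
    while True:
        sum_L = y[1:n_pop].sum()
        dNdt = abs(rhs(y, 0.0, k1)[0])
        if sum_L < SUM_L_TOL and dNdt < DNDT_TOL:
            return y, t
        if t >= t_stop:
            raise RuntimeError(
                f"asymptotic survival not converged within horizon={horizon} h "
                f"(sum L = {sum_L:.3g}, |dN/dt| = {dNdt:.3g})"
            )
        t1 = min(t + _RELAX_CHUNK, t_stop)
        y, t = _integrate_segment(
            rhs, y, t, t1, 0.0, k1, dt_off, recorder, record_every
        )


def relax_to_asymptote(
    state: SystemState,
    rad: RadiationParams,
    therm: ThermalParams | None = None,
    pmodel: RepairProbabilityModel | None = None,
    *,
    dt_off: float = DT_OFF,
    horizon: float = DEFAULT_HORIZON,
) -> SystemState:
    """Integrate beam-off from ``state`` until damaged populations resolve."""
    if pmodel is None:
        pmodel = RepairProbabilityModel(
            mu_gamma=rad.mu_gamma,
            mu_lambda=therm.mu_lambda if therm is not None else 0.0,
        )
    rhs = make_rhs(rad, therm, pmodel)
    y, _ = _relax(rhs, state.to_vector(), 0.0, therm, dt_off, horizon, None, 1)
    return SystemState.from_vector(y)


def asymptotic_survival(
    protocol: Protocol,
    rad: RadiationParams,
    therm: ThermalParams | None = None,
    pmodel: RepairProbabilityModel | None = None,
    *,
    dt: float = DT_ON,
    dt_off: float = DT_OFF,
    horizon: float = DEFAULT_HORIZON,
) -> float:
    """Asymptotic log₁₀ survival for a protocol (fast path, no recording)."""
    if pmodel is None:
        pmodel = RepairProbabilityModel(
            mu_gamma=rad.mu_gamma,
            mu_lambda=therm.mu_lambda if therm is not None else 0.0,
        )
    rhs = make_rhs(rad, therm, pmodel)
    y = SystemState.initial(rad.k_max).to_vector()
    t = 0.0
    for seg in protocol:
        k1 = arrhenius_k1(seg.temperature, therm) if therm is not None else 0.0
        dt_seg = _segment_dt(seg.dose_rate, dt, dt_off)
        y, t = _integrate_segment(
            rhs, y, seg.t_start, seg.t_end, seg.dose_rate, k1, dt_seg, None, 1
        )
    y, _ = _relax(rhs, y, t, therm, dt_off, horizon, None, 1)
    return math.log10(y[0])
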