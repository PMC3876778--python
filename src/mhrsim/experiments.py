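"""In-silico radiobiology experiments built on the MHR simulator.

Protocol builders for fractionated radiotherapy and combined
hyperthermia-radiotherapy (HT-RT), the chain-cutoff analysis, dose-rate
scans, and the linear-quadratic (LQ) reference survival law.

Two published parameter presets are provided for convenience:
``NONAPOPTOTIC_FIBROBLAST`` (p53-deficient murine fibroblasts, an efficient-
repair cell line) and ``T98G`` (radioresistant glioblastoma, used for the
high-dose-rate scans).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import RadiationParams, RepairProbabilityModel, ThermalParams, celsius_to_kelvin
from .population import LOG10_E
from .simulate import (
    BODY_TEMPERATURE_K,
    DT_OFF,
    DT_ON,
    Protocol,
    Segment,
    asymptotic_survival,
    run,
)

__all__ = [
    "LQParams",
    "CutoffReport",
    "NONAPOPTOTIC_FIBROBLAST",
    "T98G",
    "fractionation_protocol",
    "ht_rt_protocol",
    "cutoff_scan",
    "fit_exponential_decay",
    "dose_rate_scan",
    "lq_log_survival",
]

#: Repair-competent (nonapoptotic) murine fibroblast parameter set.
NONAPOPTOTIC_FIBROBLAST = RadiationParams(
    alpha=1.1, c_r=100.0, c_e=10.0, mu_gamma=0.5, gamma=1.45, k_max=6
)

#: T98G glioblastoma parameter set (high-dose-rate experiments).
T98G = RadiationParams(
    alpha=0.27, c_r=90.0, c_e=19.0, mu_gamma=0.8, gamma=1.45, k_max=6
)


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic survival law, ln S = −(αD + βD²)."""

    alpha_lq: float
    beta_lq: float

    def __post_init__(self) -> None:
        if self.alpha_lq < 0 or self.beta_lq < 0:
            raise ValueError("LQ coefficients must be >= 0")


def lq_log_survival(lq: LQParams, D) -> float | np.ndarray:
    """Natural-log survival of the LQ reference model at dose D (Gy).

    Multiply by ``log10(e)`` to obtain the log₁₀ convention used in
    survival plots.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be >= 0")
    out = -(lq.alpha_lq * D + lq.beta_lq * D * D)
    return float(out) if out.ndim == 0 else out


def fractionation_protocol(
    n: int,
    d: float,
    R: float,
    gap: float = 24.0,
    temperature: float = BODY_TEMPERATURE_K,
) -> Protocol:
    """n fractions of d Gy delivered at R Gy/h, separated by ``gap`` hours.

    Beam-on duration per fraction is d/R; total dose is exactly n·d.
    """
    if n < 1:
        raise ValueError("need at least one fraction")
    if d <= 0:
        raise ValueError("dose per fraction must be > 0")
    if R <= 0:
        raise ValueError("dose rate must be > 0")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    beam_on = d / R
    segments = []
    t = 0.0
    for i in range(n):
        segments.append(Segment(t, t + beam_on, R, temperature))
        t += beam_on
        # gaps shorter than the integrator step resolution are dropped
        if gap > 1e-9 and i < n - 1:
            segments.append(Segment(t, t + gap, 0.0, temperature))
            t += gap
    return Protocol(segments)


def ht_rt_protocol(
    dose: float,
    R: float,
    T_heat: float,
    heat_duration: float,
    time_gap: float,
    T_baseline: float = BODY_TEMPERATURE_K,
) -> Protocol:
    """Combined hyperthermia-radiotherapy timeline for a signed time gap.

    The gap is measured between the midpoints of the heating interval and
    the (short) irradiation interval; negative gaps mean irradiation before
    heating.  Overlapping windows are merged into segments carrying both the
    dose rate and the elevated temperature.
    """
    if heat_duration <= 0:
        raise ValueError("heat_duration must be > 0")
    if dose <= 0 or R <= 0:
        raise ValueError("dose and dose rate must be > 0")
    irr_duration = dose / R
    heat = (-heat_duration / 2.0, heat_duration / 2.0)       # centred at 0
    irr = (time_gap - irr_duration / 2.0, time_gap + irr_duration / 2.0)
    shift = -min(heat[0], irr[0])
    heat = (heat[0] + shift, heat[1] + shift)
    irr = (irr[0] + shift, irr[1] + shift)
    edges = sorted({heat[0], heat[1], irr[0], irr[1]})
    segments = []
    for a, b in zip(edges, edges[1:]):
        mid = 0.5 * (a + b)
        in_heat = heat[0] <= mid <= heat[1]
        in_irr = irr[0] <= mid <= irr[1]
        if not in_heat and not in_irr:
            segments.append(Segment(a, b, 0.0, T_baseline))
        else:
            segments.append(
                Segment(a, b, R if in_irr else 0.0, T_heat if in_heat else T_baseline)
            )
    return Protocol(segments)


@dataclass
class CutoffReport:
    """Effect of truncating the damage chain at different k_max.

    ``log10S[i, j]`` is the survival with cutoff ``k_values[i]`` after
    cumulative dose ``cumulative_doses[j]`` (read at full recovery between
    fractions).  Ratios and deltas are taken against the reference cutoff
    (k_max = 6 by default): ratio = log S(k)/log S(ref), delta =
    log S(ref) − log S(k).
    """

    k_values: np.ndarray
    k_ref: int
    cumulative_doses: np.ndarray
    log10S: np.ndarray
    ratio: np.ndarray
    delta: np.ndarray
    ratio_mean: np.ndarray
    ratio_std: np.ndarray

    def fit_delta(self, subset=None, dose_index: int = -1) -> tuple[float, float]:
        """Exponential fit delta ≈ a·e^(−b·k) at one cumulative-dose level."""
        deltas = self.delta[:, dose_index]
        points = [
            (int(k), float(d))
            for k, d in zip(self.k_values, deltas)
            if k != self.k_ref and d > 0
        ]
        return fit_exponential_decay(points, subset=subset)


def cutoff_scan(
    rad: RadiationParams,
    n_fractions: int,
    dose_per_fraction: float,
    dose_rate: float,
    gap: float = 24.0,
    k_list=(1, 2, 3, 4, 5, 6),
    k_ref: int = 6,
    *,
    dt: float = DT_ON,
    dt_off: float = DT_OFF,
) -> CutoffReport:
    """Run the identical fractionation scheme at each chain cutoff k_max.

    Every fraction is followed by a recovery interval of ``gap`` hours (long
    enough for Γ and all damaged populations to decay), so the survival read
    at the end of each interval is asymptotic for that cumulative dose.
    """
    if k_ref not in k_list:
        k_list = tuple(k_list) + (k_ref,)
    beam_on = dose_per_fraction / dose_rate
    segments = []
    t = 0.0
    for _ in range(n_fractions):
        segments.append(Segment(t, t + beam_on, dose_rate))
        t += beam_on
        segments.append(Segment(t, t + gap, 0.0))
        t += gap
    protocol = Protocol(segments)

    doses = dose_per_fraction * np.arange(1, n_fractions + 1)
    k_values = np.array(sorted(set(int(k) for k in k_list)))
    log10S = np.empty((len(k_values), n_fractions))
    for i, k in enumerate(k_values):
        rad_k = RadiationParams(
            alpha=rad.alpha, c_r=rad.c_r, c_e=rad.c_e,
            mu_gamma=rad.mu_gamma, gamma=rad.gamma, k_max=int(k),
        )
        traj = run(
            protocol, rad_k, dt=dt, dt_off=dt_off,
            relax=False, record_every=10**9,
        )
        # recorded points: t=0 then the end of every segment; survival at
        # the end of each recovery interval is the asymptotic value for
        # that cumulative dose
        gap_end = traj.log10S[2::2]
        log10S[i] = gap_end

    ref_row = log10S[k_values.tolist().index(k_ref)]
    ratio = log10S / ref_row
    delta = ref_row - log10S
    return CutoffReport(
        k_values=k_values,
        k_ref=k_ref,
        cumulative_doses=doses,
        log10S=log10S,
        ratio=ratio,
        delta=delta,
        ratio_mean=ratio.mean(axis=1),
        ratio_std=ratio.std(axis=1),
    )


def fit_exponential_decay(points, subset=None) -> tuple[float, float]:
    """Fit delta = a·e^(−b·k) to (k, delta) pairs.

    Two points give the exact solution; more points are fitted by least
    squares on ln(delta) versus k.  ``subset`` restricts the fit to the
    listed k values (e.g. ``{1, 2}`` for the exact two-point variant).
    """
    pts = [(k, d) for k, d in points if subset is None or k in subset]
    if len(pts) < 2:
        raise ValueError("need at least two (k, delta) points")
    if any(d <= 0 for _, d in pts):
        raise ValueError("all delta values must be > 0")
    ks = np.array([k for k, _ in pts], dtype=float)
    logd = np.log([d for _, d in pts])
    if len(pts) == 2:
        b = (logd[0] - logd[1]) / (ks[1] - ks[0])
        a = math.exp(logd[0] + b * ks[0])
    else:
        slope, intercept = np.polyfit(ks, logd, 1)
        b = -slope
        a = math.exp(intercept)
    return a, b


def dose_rate_scan(
    rad: RadiationParams,
    dose: float,
    R_list,
    *,
    dt: float = DT_ON,
    dt_off: float = DT_OFF,
) -> pd.DataFrame:
    """Asymptotic log₁₀ survival of a single uninterrupted exposure per rate."""
    if dose <= 0:
        raise ValueError("dose must be > 0")
    rows = []
    for R in R_list:
        protocol = fractionation_protocol(1, dose, R)
        logS = asymptotic_survival(protocol, rad, dt=dt, dt_off=dt_off)
        rows.append({"dose_rate_Gy_h": float(R), "log10S": logS})
    return pd.DataFrame(rows)
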