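"""State-variable kinetics for radiation- and heat-induced protein damage.

The multi-hit-repair (MHR) model tracks two kinds of protein-related damage
as variables of state:

* ``Gamma`` (Γ, in Gy) — a *biological dose equivalent* accumulating with the
  dose rate R and decaying by first-order repair,  dΓ/dt = R − γΓ.  It is
  calibrated so that the decay integral ∫γΓ dt equals the delivered physical
  dose once the system has relaxed.
* ``Upsilon``/``Lambda`` (Υ, Λ) — fractions of functional and heat-damaged
  repair proteins, Υ + Λ = 1, exchanging by first-order kinetics with a
  thermal damage rate k₁(T) following an Arrhenius law and a repair rate k₂.

Both feed a repair probability P(Γ, Λ) ∈ (0, 1] that multiplies the repair
rate constant of the cell-population chain (see :mod:`mhrsim.population`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "CELSIUS_OFFSET",
    "ANCHOR_TEMPERATURE_K",
    "RadiationParams",
    "ThermalParams",
    "RepairProbabilityModel",
    "celsius_to_kelvin",
    "gamma_rate",
    "analytic_gamma",
    "gamma_calibration_integral",
    "arrhenius_k1",
    "thermal_rates",
    "repair_probability",
]

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Offset used throughout for Celsius -> Kelvin conversion.
CELSIUS_OFFSET = 273.16

#: Reference temperature (38 degC) at which the thermal damage rate k1 is
#: anchored to a * 1e-3 / h.
ANCHOR_TEMPERATURE_K = 38.0 + CELSIUS_OFFSET


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert degC to K using the model's +273.16 convention."""
    return t_celsius + CELSIUS_OFFSET


@dataclass(frozen=True)
class RadiationParams:
    """Radiation-response constants of the hit-chain model.

    Parameters
    ----------
    alpha : float
        Radiosensitivity, per Gy.  Governs the hit rate alpha*R moving cells
        one step down the damage chain.
    c_r : float
        Repair rate constant, per hour.  Effective repair rate is c_r * P.
    c_e : float
        Elimination rate constant, per hour (apoptosis-like irreversible
        removal of damaged cells).
    mu_gamma : float
        Sensitivity of the repair probability to Gamma, per Gy.
    gamma : float
        First-order decay constant of Gamma, per hour.
    k_max : int
        Damage-chain cutoff: cells hit beyond ``k_max`` leak into the
        overflow ledger and are counted dead.
    """

    alpha: float
    c_r: float
    c_e: float
    mu_gamma: float
    gamma: float
    k_max: int = 6

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.c_r < 0:
            raise ValueError(f"c_r must be >= 0, got {self.c_r}")
        if self.c_e < 0:
            raise ValueError(f"c_e must be >= 0, got {self.c_e}")
        if self.mu_gamma < 0:
            raise ValueError(f"mu_gamma must be >= 0, got {self.mu_gamma}")
        if not (isinstance(self.k_max, (int, np.integer)) and self.k_max >= 1):
            raise ValueError(f"k_max must be an integer >= 1, got {self.k_max}")


@dataclass(frozen=True)
class ThermalParams:
    """Constants of the thermal protein damage/repair kinetics.

    ``a`` anchors the Arrhenius damage rate at 38 degC: k1(38 degC) =
    a * 1e-3 / h.  ``E_a`` (J/mol) sets the temperature sensitivity, ``k2``
    (per hour) the chaperone-mediated repair of heat-damaged protein, and
    ``mu_lambda`` the sensitivity of the repair probability to Lambda.
    """

    a: float = 0.56
    E_a: float = 1.528e6
    k2: float = 2.76
    mu_lambda: float = 29.19

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if not self.E_a > 0:
            raise ValueError(f"E_a must be > 0, got {self.E_a}")
        if self.k2 < 0:
            raise ValueError(f"k2 must be >= 0, got {self.k2}")
        if self.mu_lambda < 0:
            raise ValueError(f"mu_lambda must be >= 0, got {self.mu_lambda}")


@dataclass(frozen=True)
class RepairProbabilityModel:
    """Functional form of the repair probability P(Gamma, Lambda).

    Variants
    --------
    ``exponential`` (default)
        P = exp(-(mu_gamma*Gamma + mu_lambda*Lambda)) — repair probability
        decreases monotonically with both damage variables.
    ``gaussian``
        P = exp(-xi*(Gamma - gamma_c)^2) * exp(-mu_lambda*Lambda) — induced
        repair peaking at a characteristic dose ``gamma_c`` (models low-dose
        hypersensitivity).
    ``sigmoidal``
        P = logistic in Gamma, normalised so P(0) = 1, times
        exp(-mu_lambda*Lambda); ``midpoint`` (Gy) and ``steepness`` (per Gy)
        set the transition.
    """

    variant: str = "exponential"
    mu_gamma: float = 0.5
    mu_lambda: float = 0.0
    xi: float = 0.0
    gamma_c: float = 0.0
    midpoint: float = 2.0
    steepness: float = 1.0

    _VARIANTS = ("exponential", "gaussian", "sigmoidal")

    def __post_init__(self) -> None:
        if self.variant not in self._VARIANTS:
            raise ValueError(
                f"variant must be one of {self._VARIANTS}, got {self.variant!r}"
            )
        for name in ("mu_gamma", "mu_lambda", "xi", "steepness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def __call__(self, Gamma: float, Lambda: float = 0.0) -> float:
        return repair_probability(Gamma, Lambda, self)


def gamma_rate(Gamma: float, R: float, params: RadiationParams) -> float:
    """Time derivative of the biological dose equivalent, dΓ/dt = R − γΓ.

    Parameters are the current dose equivalent ``Gamma`` (Gy), the dose rate
    ``R`` (Gy/h) and the radiation parameter set (only ``gamma`` is used).
    """
    if Gamma < 0:
        raise ValueError(f"Gamma must be >= 0, got {Gamma}")
    if R < 0:
        raise ValueError(f"dose rate must be >= 0, got {R}")
    return R - params.gamma * Gamma


def analytic_gamma(R: float, gamma: float, t) -> float | np.ndarray:
    """Closed-form Γ(t) = (R/γ)(1 − e^{−γt}) for constant dose rate, Γ(0)=0.

    Serves as the integrator oracle on constant-rate segments.  The γ → 0
    limit degenerates to R·t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if gamma == 0.0:
        out = R * t
    else:
        out = (R / gamma) * -np.expm1(-gamma * t)
    return float(out) if out.ndim == 0 else out


def gamma_calibration_integral(
    times: np.ndarray,
    Gamma: np.ndarray,
    gamma: float,
    *,
    tol: float = 1e-6,
) -> float:
    """Accumulated dose equivalent ∫γΓ dt over a recorded trajectory.

    By the calibration condition this integral equals the total delivered
    dose once Γ has decayed to (numerically) zero.  A :class:`RuntimeWarning`
    is emitted when the trajectory ends with Γ above ``tol`` — the integral
    has then not converged to D_tot and is short by exactly Γ(end).
    """
    times = np.asarray(times, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    if times.shape != Gamma.shape:
        raise ValueError("times and Gamma must have the same shape")
    if Gamma[-1] > tol:
        import warnings

        warnings.warn(
            f"Gamma at trajectory end is {Gamma[-1]:.3g} > tol={tol:.3g}; "
            "the calibration integral has not converged to the delivered dose",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(np.trapezoid(gamma * Gamma, times))


def arrhenius_k1(T: float, params: ThermalParams) -> float:
    """Thermal protein-damage rate k₁(T), per hour.

    Anchored so that k₁ at 38 degC equals ``a * 1e-3`` per hour, with
    Arrhenius temperature dependence

        k₁(T) = a·10⁻³ h⁻¹ · exp[(E_a/R_gas)(1/311.16 K − 1/T)].

    ``T`` is in kelvin.
    """
    if not T > 0:
        raise ValueError(f"temperature must be > 0 K, got {T}")
    exponent = (params.E_a / GAS_CONSTANT) * (1.0 / ANCHOR_TEMPERATURE_K - 1.0 / T)
    return params.a * 1e-3 * math.exp(exponent)


def thermal_rates(
    Upsilon: float, Lambda: float, T: float, params: ThermalParams
) -> tuple[float, float]:
    """Rates (dΥ/dt, dΛ/dt) of the functional/damaged protein fractions.

    First-order exchange dΥ/dt = −k₁Υ + k₂Λ, dΛ/dt = k₁Υ − k₂Λ; the two
    rates sum to zero exactly, so Υ + Λ is conserved.
    """
    k1 = arrhenius_k1(T, params)
    dU = -k1 * Upsilon + params.k2 * Lambda
    return dU, -dU


def repair_probability(
    Gamma: float, Lambda: float, model: RepairProbabilityModel
) -> float:
    """Evaluate the repair probability P(Γ, Λ) ∈ (0, 1] for the given model."""
    if Gamma < 0:
        raise ValueError(f"Gamma must be >= 0, got {Gamma}")
    if not 0.0 <= Lambda <= 1.0 + 1e-9:
        raise ValueError(f"Lambda must be in [0, 1], got {Lambda}")
    p_lambda = math.exp(-model.mu_lambda * Lambda)
    if model.variant == "exponential":
        return math.exp(-model.mu_gamma * Gamma) * p_lambda
    if model.variant == "gaussian":
        return math.exp(-model.xi * (Gamma - model.gamma_c) ** 2) * p_lambda
    # sigmoidal: logistic in Gamma, normalised to P(0) = 1
    s, g0 = model.steepness, model.midpoint
    norm = 1.0 + math.exp(-s * g0)
    return norm / (1.0 + math.exp(s * (Gamma - g0))) * p_lambda
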