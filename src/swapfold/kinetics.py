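"""Domain-swapping dissociation kinetics and barrier thermodynamics.

A dimer D dissociates into two monomers M with 2M <-> D governed by
``d[D]/dt = k_on [M]^2 - k_off [D]``. Experimentally the dimer fraction
(in monomer units, f_D = 2[D]/P_t) relaxes to its equilibrium value and is
fitted as a single exponential; the fitted decay constant is reported as
k_off, the equilibrium fraction yields K_d = 2 P_t (1-f_eq)^2 / f_eq, and
k_on follows from K_d = k_off / k_on. Rates are converted to activation
free energies with the Eyring relation ΔG‡ = -RT ln(k h / k_B T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .io import (
    DegenerateDataError,
    FitError,
    R_KCAL,
    T_DEFAULT,
    ValidationError,
    kbt_over_h,
)

__all__ = [
    "KineticTrace",
    "KineticFit",
    "DimerEnergetics",
    "fit_exponential_decay",
    "kd_from_dimer_fraction",
    "equilibrium_dimer_fraction",
    "delta_g_dissociation",
    "kon_from_koff_kd",
    "eyring_free_energy",
    "dimer_energetics",
    "relaxation_rate",
]


@dataclass
class KineticTrace:
    """Time course of the dimer fraction at one condition.

    times in minutes; f_d dimensionless (monomer units); p_total in M.
    """

    times: np.ndarray
    f_d: np.ndarray
    ph: float = 7.8
    temperature: float = T_DEFAULT
    p_total: float = 5e-6

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f_d = np.asarray(self.f_d, dtype=float)
        if self.times.shape != self.f_d.shape:
            raise ValidationError("times and f_d must have equal length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be non-negative and increasing")
        if np.any(self.f_d < 0) or np.any(self.f_d > 1):
            raise ValidationError("dimer fraction must lie in [0, 1]")


@dataclass
class KineticFit:
    """Single-exponential fit f_D(t) = f_eq + A exp(-k_obs t)."""

    k_obs: float  # min^-1; reported as k_off
    f_eq: float
    amplitude: float
    sigmas: dict[str, float] = field(default_factory=dict)
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.k_obs <= 0:
            raise ValidationError("k_obs must be positive")
        if not 0.0 <= self.f_eq <= 1.0:
            raise ValidationError("f_eq must lie in [0, 1]")


@dataclass
class DimerEnergetics:
    """Equilibrium and barrier thermodynamics of the monomer-dimer system."""

    k_d: float  # M
    dg_d: float  # kcal/mol
    k_on: float  # M^-1 min^-1
    dg_on: float  # kcal/mol, association barrier
    dg_off: float  # kcal/mol, dissociation barrier
    c_standard: float = 1.0  # M, standard state for the bimolecular barrier

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValidationError("K_d must be positive")


def _exp_model(t: np.ndarray, f_eq: float, amp: float, k: float) -> np.ndarray:
    return f_eq + amp * np.exp(-k * t)


def fit_exponential_decay(trace: KineticTrace) -> KineticFit:
    """Fit a single exponential relaxation to a dissociation trace.

    Initialization: f_eq from the final point, amplitude from the first,
    and k_obs from a log-linear regression of |f_D - f_D(last)| over the
    first half of the trace; on failure, up to 5 perturbed restarts.
    """
    t, y = trace.times, trace.f_d
    if t.size < 5:
        raise ValidationError("need at least 5 time points")
    span = float(np.ptp(y))
    if span == 0.0:
        raise DegenerateDataError("constant trace: no relaxation to fit")

    f_eq0 = float(y[-1])
    amp0 = float(y[0] - f_eq0)
    if amp0 == 0.0:
        amp0 = span * np.sign(y[0] - np.median(y)) or span
    # log-linear k_obs estimate on the first half
    half = max(5, t.size // 2)
    dev = (y[:half] - f_eq0) / amp0
    mask = dev > 0.05
    if mask.sum() >= 2:
        slope = np.polyfit(t[:half][mask], np.log(dev[mask]), 1)[0]
        k0 = max(-float(slope), 1e-6)
    else:
        k0 = 1.0 / max(float(t[-1]), 1.0)

    rng = np.random.default_rng(0)
    last_exc: Exception | None = None
    best_resid: np.ndarray | None = None
    for attempt in range(6):
        if attempt == 0:
            p0 = (f_eq0, amp0, k0)
        else:
            p0 = (
                np.clip(f_eq0 + 0.1 * span * rng.standard_normal(), 0, 1),
                amp0 * np.exp(0.5 * rng.standard_normal()),
                k0 * np.exp(rng.standard_normal()),
            )
        try:
            popt, pcov = curve_fit(
                _exp_model, t, y, p0=p0,
                bounds=([-0.5, -2.0, 1e-9], [1.5, 2.0, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            last_exc = exc
            continue
        resid = y - _exp_model(t, *popt)
        best_resid = resid
        sig = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        return KineticFit(
            k_obs=float(popt[2]),
            f_eq=float(np.clip(popt[0], 0, 1)),
            amplitude=float(popt[1]),
            sigmas={"f_eq": float(sig[0]), "amplitude": float(sig[1]),
                    "k_obs": float(sig[2])},
            rss=float(resid @ resid),
        )
    raise FitError(f"exponential fit failed after restarts: {last_exc}",
                   residuals=best_resid)


def kd_from_dimer_fraction(f_eq: float, p_total: float) -> float:
    """K_d = 2 P_t (1 - f_eq)^2 / f_eq, with f_eq in monomer units.

    Follows from K_d = [M]^2/[D] with [M] = P_t (1 - f_eq) and
    [D] = P_t f_eq / 2.
    """
    if p_total <= 0:
        raise ValidationError("P_t must be positive")
    if not 0.0 < f_eq < 1.0:
        raise ValidationError("K_d undefined at f_eq = 0 or 1")
    return 2.0 * p_total * (1.0 - f_eq) ** 2 / f_eq


def equilibrium_dimer_fraction(k_d: float, p_total: float) -> float:
    """Inverse of :func:`kd_from_dimer_fraction`: the physical root of
    2 P_t f^2 - (4 P_t + K_d) f + 2 P_t = 0."""
    if k_d <= 0 or p_total <= 0:
        raise ValidationError("K_d and P_t must be positive")
    b = 4.0 * p_total + k_d
    disc = b * b - 16.0 * p_total * p_total
    # smaller root is the one in (0, 1); use the stable quotient form
    return (4.0 * p_total) / (b + np.sqrt(disc))


def delta_g_dissociation(k_d: float, temperature: float = T_DEFAULT) -> float:
    """ΔG_d = -RT ln K_d with K_d in M (1 M standard state)."""
    if k_d <= 0:
        raise ValidationError("K_d must be positive")
    return -R_KCAL * temperature * np.log(k_d)


def kon_from_koff_kd(k_off: float, k_d: float) -> float:
    """k_on = k_off / K_d."""
    if k_off <= 0 or k_d <= 0:
        raise ValidationError("k_off and K_d must be positive")
    return k_off / k_d


def eyring_free_energy(k: float, temperature: float = T_DEFAULT,
                       molecularity: int = 1, c_standard: float = 1.0,
                       time_unit: str = "min") -> float:
    """Activation free energy ΔG‡ = -RT ln(k h / k_B T) in kcal/mol.

    ``k`` is given per ``time_unit`` ('min' or 's'); bimolecular rates
    (molecularity 2, M^-1 time^-1) are made pseudo-first-order by
    multiplying with the standard-state concentration ``c_standard`` (M).
    """
    if k <= 0:
        raise ValidationError("rate must be positive")
    if time_unit == "min":
        k_s = k / 60.0
    elif time_unit == "s":
        k_s = float(k)
    else:
        raise ValidationError(f"unknown time unit {time_unit!r}")
    if molecularity == 2:
        k_s *= c_standard
    elif molecularity != 1:
        raise ValidationError("molecularity must be 1 or 2")
    return -R_KCAL * temperature * np.log(k_s / kbt_over_h(temperature))


def dimer_energetics(k_off: float, f_eq: float, p_total: float,
                     temperature: float = T_DEFAULT,
                     c_standard: float = 1.0) -> DimerEnergetics:
    """Assemble K_d, ΔG_d, k_on and both Eyring barriers from a fitted
    dissociation rate and equilibrium dimer fraction."""
    k_d = kd_from_dimer_fraction(f_eq, p_total)
    k_on = kon_from_koff_kd(k_off, k_d)
    return DimerEnergetics(
        k_d=k_d,
        dg_d=delta_g_dissociation(k_d, temperature),
        k_on=k_on,
        dg_on=eyring_free_energy(k_on, temperature, molecularity=2,
                                 c_standard=c_standard),
        dg_off=eyring_free_energy(k_off, temperature),
        c_standard=c_standard,
    )


def relaxation_rate(k_off: float, k_on: float, p_total: float) -> float:
    """True small-perturbation relaxation constant of 2M <-> D.

    Linearizing d[D]/dt = k_on [M]^2 - k_off [D] about equilibrium gives
    k_relax = k_off + 4 k_on [M]_eq; serves as the oracle for the bias of
    the single-exponential estimator.
    """
    k_d = k_off / k_on
    f_eq = equilibrium_dimer_fraction(k_d, p_total)
    m_eq = p_total * (1.0 - f_eq)
    return k_off + 4.0 * k_on * m_eq
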