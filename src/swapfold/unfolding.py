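"""Equilibrium chemical denaturation: population models and LEM fitting.

Three unfolding schemes are supported, all with linear free-energy
extrapolation ΔG(den) = ΔG - m·[den]:

* ``two_state_IU`` — monomeric I <-> U (the wild-type fluorescence data).
* ``three_state_dimer`` — N2 <-> 2I <-> 2U with a concentration-explicit
  first step, K1 = [I]^2/[N2] in M; this coupling is what shifts the first
  transition midpoint when total protein concentration changes.
* ``three_state_monomer`` — N <-> I <-> U (anisotropy data).

Signals are modelled as population-weighted linear baselines, one
(intercept, slope) pair per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq, least_squares

from .io import FitError, R_KCAL, T_DEFAULT, ValidationError

Scheme = Literal["two_state_IU", "three_state_dimer", "three_state_monomer"]

SCHEMES: tuple[str, ...] = (
    "two_state_IU", "three_state_dimer", "three_state_monomer"
)

__all__ = [
    "SCHEMES",
    "UnfoldingCurve",
    "TransitionParams",
    "SpeciesPopulations",
    "UnfoldingFit",
    "populations_two_state",
    "populations_three_state_dimer",
    "populations_three_state_monomer",
    "populations",
    "fit_unfolding",
    "midpoint",
]


@dataclass
class UnfoldingCurve:
    """Signal versus denaturant at fixed pH and protein concentration."""

    denaturant: np.ndarray  # M
    signal: np.ndarray  # arbitrary units
    ph: float = 7.8
    p_total: float = 15e-6  # M, monomer units
    observable: str = "fluorescence"

    def __post_init__(self) -> None:
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.denaturant.shape != self.signal.shape:
            raise ValidationError("denaturant and signal must have equal length")
        if np.any(np.diff(self.denaturant) <= 0) or np.any(self.denaturant < 0):
            raise ValidationError("denaturant grid must be non-negative, increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signals must be finite")


@dataclass
class TransitionParams:
    """One LEM transition: ΔG at zero denaturant (kcal/mol) and m-value
    (kcal/mol/M)."""

    dg: float
    m: float

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValidationError("m-value must be positive")

    def k_eq(self, den: np.ndarray | float, temperature: float = T_DEFAULT):
        return np.exp(-(self.dg - self.m * np.asarray(den, dtype=float))
                      / (R_KCAL * temperature))


@dataclass
class SpeciesPopulations:
    """Species fractions, in monomer units, at one denaturant value."""

    fractions: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < -1e-12):
            raise ValidationError("negative population")
        if abs(self.fractions.sum() - 1.0) > 1e-10:
            raise ValidationError("populations must sum to 1")

    def __getitem__(self, label: str) -> float:
        return float(self.fractions[self.labels.index(label)])


def populations_two_state(params: TransitionParams, den: float,
                          temperature: float = T_DEFAULT) -> SpeciesPopulations:
    """I <-> U with K = exp(-(ΔG - m den)/RT); f_U = K/(1+K)."""
    k = float(params.k_eq(den, temperature))
    f_u = k / (1.0 + k)
    return SpeciesPopulations(np.array([1.0 - f_u, f_u]), ("I", "U"))


def populations_three_state_dimer(params1: TransitionParams,
                                  params2: TransitionParams,
                                  den: float, p_total: float,
                                  temperature: float = T_DEFAULT
                                  ) -> SpeciesPopulations:
    """N2 <-> 2I <-> 2U. K1 = [I]^2/[N2] (M), K2 = [U]/[I].

    Mass balance 2[N2] + [I] + [U] = P_t with [N2] = [I]^2/K1 and
    [U] = K2 [I] gives the quadratic 2[I]^2/K1 + (1+K2)[I] - P_t = 0,
    whose positive root is taken; fractions are monomer-unit.
    """
    if p_total <= 0:
        raise ValidationError("P_t must be positive")
    k1 = float(params1.k_eq(den, temperature))
    k2 = float(params2.k_eq(den, temperature))
    b = 1.0 + k2
    # stable positive root of (2/K1) x^2 + b x - P_t = 0
    conc_i = 2.0 * p_total / (b + np.sqrt(b * b + 8.0 * p_total / k1))
    assert conc_i > 0
    conc_n2 = conc_i * conc_i / k1
    conc_u = k2 * conc_i
    fr = np.array([2.0 * conc_n2, conc_i, conc_u]) / p_total
    fr /= fr.sum()  # remove last-digit rounding
    return SpeciesPopulations(fr, ("N2", "I", "U"))


def populations_three_state_monomer(params1: TransitionParams,
                                    params2: TransitionParams,
                                    den: float,
                                    temperature: float = T_DEFAULT
                                    ) -> SpeciesPopulations:
    """N <-> I <-> U with f_N : f_I : f_U = 1 : K1 : K1 K2."""
    k1 = float(params1.k_eq(den, temperature))
    k2 = float(params2.k_eq(den, temperature))
    w = np.array([1.0, k1, k1 * k2])
    return SpeciesPopulations(w / w.sum(), ("N", "I", "U"))


def populations(scheme: str, transitions: list[TransitionParams], den: float,
                p_total: float | None = None,
                temperature: float = T_DEFAULT) -> SpeciesPopulations:
    """Dispatch to the population model for ``scheme``."""
    if scheme == "two_state_IU":
        return populations_two_state(transitions[0], den, temperature)
    if scheme == "three_state_dimer":
        if p_total is None:
            raise ValidationError("three_state_dimer requires P_t")
        return populations_three_state_dimer(transitions[0], transitions[1],
                                             den, p_total, temperature)
    if scheme == "three_state_monomer":
        return populations_three_state_monomer(transitions[0], transitions[1],
                                               den, temperature)
    raise ValidationError(f"unknown scheme {scheme!r}")


def n_species(scheme: str) -> int:
    return 2 if scheme == "two_state_IU" else 3


def population_matrix(scheme: str, transitions: list[TransitionParams],
                      den: np.ndarray, p_total: float | None = None,
                      temperature: float = T_DEFAULT) -> np.ndarray:
    """Species fractions for a whole denaturant grid, shape
    (n_den, n_species); vectorized equivalent of :func:`populations`."""
    den = np.atleast_1d(np.asarray(den, dtype=float))
    if scheme == "two_state_IU":
        k = transitions[0].k_eq(den, temperature)
        f_u = k / (1.0 + k)
        return np.column_stack([1.0 - f_u, f_u])
    if scheme == "three_state_monomer":
        k1 = transitions[0].k_eq(den, temperature)
        k2 = transitions[1].k_eq(den, temperature)
        w = np.column_stack([np.ones_like(k1), k1, k1 * k2])
        return w / w.sum(axis=1, keepdims=True)
    if scheme == "three_state_dimer":
        if p_total is None:
            raise ValidationError("three_state_dimer requires P_t")
        k1 = transitions[0].k_eq(den, temperature)
        k2 = transitions[1].k_eq(den, temperature)
        b = 1.0 + k2
        conc_i = 2.0 * p_total / (b + np.sqrt(b * b + 8.0 * p_total / k1))
        fr = np.column_stack([2.0 * conc_i * conc_i / k1, conc_i,
                              k2 * conc_i]) / p_total
        return fr / fr.sum(axis=1, keepdims=True)
    raise ValidationError(f"unknown scheme {scheme!r}")


def signal_model(scheme: str, transitions: list[TransitionParams],
                 baselines: np.ndarray, den: np.ndarray,
                 p_total: float | None = None,
                 temperature: float = T_DEFAULT) -> np.ndarray:
    """Population-weighted linear baselines: Σ_s f_s (a_s + b_s den)."""
    den = np.asarray(den, dtype=float)
    baselines = np.asarray(baselines, dtype=float).reshape(n_species(scheme), 2)
    fr = population_matrix(scheme, transitions, den, p_total, temperature)
    lines = baselines[None, :, 0] + baselines[None, :, 1] * den[:, None]
    return np.einsum("ds,ds->d", fr, lines)


@dataclass
class UnfoldingFit:
    """Fitted LEM parameters for one unfolding curve."""

    scheme: str
    transitions: list[TransitionParams]
    baselines: np.ndarray  # (n_species, 2)
    sigmas: dict[str, float] = field(default_factory=dict)
    midpoints: list[float] = field(default_factory=list)
    rss: float = float("nan")
    p_total: float | None = None
    temperature: float = T_DEFAULT

    def predict(self, den: np.ndarray) -> np.ndarray:
        return signal_model(self.scheme, self.transitions, self.baselines,
                            den, self.p_total, self.temperature)


def _initial_guesses(curve: UnfoldingCurve, scheme: str) -> tuple[np.ndarray, np.ndarray]:
    """Midpoints from extrema of the smoothed derivative; baselines from
    the grid ends; m from the apparent transition width."""
    den, sig = curve.denaturant, curve.signal
    n = den.size
    k = max(3, n // 8)
    kern = np.ones(k) / k
    smooth = np.convolve(sig, kern, mode="same")
    deriv = np.gradient(smooth, den)
    mag = np.abs(deriv)
    if scheme == "two_state_IU":
        cm = [float(den[np.argmax(mag)])]
    else:
        # two transitions: strongest derivative peak in each half of the grid
        mid = n // 2
        i1 = int(np.argmax(mag[:mid]))
        i2 = mid + int(np.argmax(mag[mid:]))
        cm = sorted([float(den[i1]), float(den[i2])])
    width = max((den[-1] - den[0]) / 4.0, 0.5)
    m0 = max(4.0 * R_KCAL * T_DEFAULT / width, 0.5)
    a_n, b_n = float(smooth[0]), 0.0
    a_u, b_u = float(smooth[-1]), 0.0
    if scheme == "two_state_IU":
        theta = [m0 * cm[0], m0]
        base = [a_n, b_n, a_u, b_u]
    else:
        dg1 = m0 * cm[0]
        if scheme == "three_state_dimer":
            dg1 += -R_KCAL * T_DEFAULT * np.log(curve.p_total)
        theta = [dg1, m0, m0 * cm[1], m0]
        base = [a_n, b_n, 0.5 * (a_n + a_u), 0.0, a_u, b_u]
    return np.array(theta), np.array(base)


def fit_unfolding(curve: UnfoldingCurve, scheme: str,
                  temperature: float = T_DEFAULT,
                  sigma: np.ndarray | None = None,
                  max_restarts: int = 6) -> UnfoldingFit:
    """Weighted least-squares fit of an unfolding curve.

    Parameters are (ΔG, m) per transition plus a linear baseline per
    species. Uncertainties come from the Jacobian-based covariance at the
    optimum. Raises on too few points (< 1.5 per parameter) and warns
    below 3 per parameter.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    n_trans = 1 if scheme == "two_state_IU" else 2
    n_par = 2 * n_trans + 2 * n_species(scheme)
    n_pts = curve.denaturant.size
    if n_pts < 8:
        raise ValidationError("need at least 8 denaturant points")
    if n_pts < 1.5 * n_par:
        raise ValidationError(
            f"{n_pts} points cannot constrain {n_par} parameters")
    if n_pts < 3 * n_par:
        import warnings
        warnings.warn(f"only {n_pts} points for {n_par} parameters",
                      stacklevel=2)
    weights = 1.0 / sigma if sigma is not None else np.ones(n_pts)
    theta0, base0 = _initial_guesses(curve, scheme)
    span = float(np.ptp(curve.signal)) or 1.0

    def unpack(x):
        trans = [TransitionParams(x[2 * i], x[2 * i + 1]) for i in range(n_trans)]
        return trans, x[2 * n_trans:]

    def resid(x):
        trans, base = unpack(x)
        pred = signal_model(scheme, trans, base, curve.denaturant,
                            curve.p_total, temperature)
        return (pred - curve.signal) * weights

    lo = ([-20.0, 1e-3] * n_trans) + [-np.inf] * (2 * n_species(scheme))
    hi = ([40.0, 20.0] * n_trans) + [np.inf] * (2 * n_species(scheme))
    rng = np.random.default_rng(0)
    best = None
    x0 = np.concatenate([theta0, base0])
    for attempt in range(max_restarts):
        if attempt > 0:
            x0 = np.concatenate([
                theta0 * np.exp(0.3 * rng.standard_normal(theta0.size)),
                base0 + 0.2 * span * rng.standard_normal(base0.size),
            ])
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost <= 2.0 * (0.02 * span) ** 2 * n_pts:
            break
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("unfolding fit failed to converge")

    trans, base = unpack(best.x)
    dof = max(n_pts - n_par, 1)
    s2 = 2.0 * best.cost / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        perr = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        perr = np.full(n_par, np.nan)
    names = []
    for i in range(n_trans):
        suffix = str(i + 1) if n_trans > 1 else ""
        names += [f"dg{suffix}", f"m{suffix}"]
    sigmas = {nm: float(perr[i]) for i, nm in enumerate(names)}
    mids = [midpoint(trans, scheme, i, curve.p_total, temperature)
            for i in range(n_trans)]
    resid0 = resid(best.x)
    return UnfoldingFit(scheme=scheme, transitions=trans,
                        baselines=np.asarray(base).reshape(-1, 2),
                        sigmas=sigmas, midpoints=mids,
                        rss=float(resid0 @ resid0), p_total=curve.p_total,
                        temperature=temperature)


def midpoint(transitions: list[TransitionParams], scheme: str,
             index: int = 0, p_total: float | None = None,
             temperature: float = T_DEFAULT) -> float:
    """Denaturant concentration at a transition midpoint.

    Monomeric transitions: C_m = ΔG/m. The dimer-coupled first transition
    has no closed form; C_m is root-found where the monomer-unit fractions
    of N2 and I cross (this is what makes C_m depend on P_t).
    """
    tr = transitions[index]
    if tr.m <= 1e-12:
        raise ValidationError("m-value too small for a midpoint")
    if not (scheme == "three_state_dimer" and index == 0):
        cm = tr.dg / tr.m
    else:
        if p_total is None:
            raise ValidationError("dimer midpoint requires P_t")

        def gap(den):
            pops = populations_three_state_dimer(transitions[0], transitions[1],
                                                 den, p_total, temperature)
            return pops["N2"] - pops["I"]

        lo_v, hi_v = gap(0.0), gap(10.0)
        if lo_v * hi_v > 0:
            cm = 0.0 if lo_v < 0 else 10.0
        else:
            cm = brentq(gap, 0.0, 10.0, xtol=1e-10)
    if not 0.0 <= cm <= 10.0:
        import warnings
        warnings.warn(f"midpoint {cm:.2f} M outside [0, 10] M (extrapolated)",
                      stacklevel=2)
    return float(cm)
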