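"""Proton linkage: pH dependence of free energies via titratable residues.

The pH dependence of a free-energy difference between two states A and B
is written in terms of the proton-binding polynomials of the titratable
residues, each residue i carrying state-specific pKa values:

    ΔΔG(pH) = s · (−RT Σ_i ln [ (1 + 10^(pKa_i^A − pH)) (1 + 10^(pKa_i^B − pH_ref))
                               / (1 + 10^(pKa_i^B − pH)) (1 + 10^(pKa_i^A − pH_ref)) ])

with pH_ref the reference condition (default 5.0) at which ΔΔG vanishes
by construction. An explicit sign s ∈ {+1, −1} is carried on the model:
with the A/B assignment used for the unfolding series, the bare expression
has the opposite sign to the observed stabilization at basic pH, so the
fit selects s by best residual and reports the assignment used.

The sequential protocol fits a single-residue model to a mutant series in
which only one histidine titrates, then holds that residue fixed while a
second residue is fitted on the wild-type series.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .io import FitError, R_KCAL, T_DEFAULT, ValidationError

__all__ = [
    "TitratableResidue",
    "LinkageModel",
    "PhStabilitySeries",
    "linkage_delta_g",
    "fit_pka",
    "sequential_pka_protocol",
    "barrier_series_from_rates",
]


@dataclass(frozen=True)
class TitratableResidue:
    """One titratable residue with pKa values in states A and B."""

    label: str
    pka_a: float
    pka_b: float
    fixed_a: bool = False
    fixed_b: bool = False

    def __post_init__(self) -> None:
        for v in (self.pka_a, self.pka_b):
            if not 0.0 <= v <= 14.0:
                raise ValidationError(f"pKa {v} outside [0, 14]")


@dataclass
class LinkageModel:
    """Set of titratable residues plus the reference free energy.

    ``sign`` multiplies the printed linkage sum; ``dg_ref`` is the series
    value at ``ph_ref`` (pinned, not fitted).
    """

    residues: list[TitratableResidue]
    ph_ref: float = 5.0
    dg_ref: float = 0.0
    temperature: float = T_DEFAULT
    sign: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph_ref <= 14.0:
            raise ValidationError("pH_ref outside [0, 14]")
        if self.sign not in (-1, 1):
            raise ValidationError("sign must be +1 or -1")

    def delta_g(self, ph: np.ndarray | float) -> np.ndarray | float:
        """Total free energy ΔG(pH) = ΔG_ref + s·ΔΔG(pH)."""
        return self.dg_ref + linkage_delta_g(self, ph)


@dataclass
class PhStabilitySeries:
    """Free energies (kcal/mol) as a function of pH."""

    ph: np.ndarray
    dg: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.dg = np.asarray(self.dg, dtype=float)
        if self.ph.shape != self.dg.shape:
            raise ValidationError("pH and ΔG must have equal length")
        if self.ph.size == 0:
            raise ValidationError("empty pH series")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)


def _log_binding_term(pka_a: float, pka_b: float, ph: np.ndarray,
                      ph_ref: float) -> np.ndarray:
    """ln of the per-residue binding-polynomial ratio, evaluated stably
    via log1p/log10 identities."""
    ln10 = np.log(10.0)

    def lp(pka, x):  # ln(1 + 10^(pka - x))
        return np.logaddexp(0.0, ln10 * (pka - x))

    return (lp(pka_a, ph) + lp(pka_b, ph_ref)
            - lp(pka_b, ph) - lp(pka_a, ph_ref))


def linkage_delta_g(model: LinkageModel, ph: np.ndarray | float):
    """ΔΔG(pH) relative to pH_ref (kcal/mol), including the model sign."""
    ph_arr = np.asarray(ph, dtype=float)
    rt = R_KCAL * model.temperature
    total = np.zeros_like(ph_arr, dtype=float)
    for res in model.residues:
        total += _log_binding_term(res.pka_a, res.pka_b, ph_arr, model.ph_ref)
    out = model.sign * (-rt) * total
    return float(out) if np.isscalar(ph) else out


def _pin_dg_ref(series: PhStabilitySeries, ph_ref: float) -> float:
    """Series value at pH_ref (interpolated if not a grid point)."""
    i = np.argmin(np.abs(series.ph - ph_ref))
    if abs(series.ph[i] - ph_ref) < 1e-9:
        return float(series.dg[i])
    if not series.ph.min() <= ph_ref <= series.ph.max():
        raise ValidationError("pH_ref outside the series range")
    return float(np.interp(ph_ref, series.ph, series.dg))


def fit_pka(series: PhStabilitySeries, model: LinkageModel,
            fit_sign: bool = True, fit_dg_ref: bool | str = "auto",
            n_bootstrap: int = 200, seed: int = 0) -> LinkageModel:
    """Nonlinear least squares over the free pKa values of ``model``.

    Free pKa values are bounded to [2, 12] and multi-started from a 3x3
    grid of initial values; if ``fit_sign`` the sign s is chosen by best
    residual and the result is canonicalized to s = −1 (exactly
    equivalent by the A↔B antisymmetry), so that state A is the
    first-listed state of each pair.

    ΔG_ref: the measured point at pH_ref is as noisy as any other, so by
    default ("auto") the reference free energy is fitted as an offset
    whenever at least 3 points remain beyond the free pKa values, and is
    otherwise pinned to the series value at pH_ref.

    Parameter uncertainties are estimated by a seeded residual bootstrap
    and stored on the returned model as ``.sigmas``.
    """
    free: list[tuple[int, str]] = []
    for i, res in enumerate(model.residues):
        if not res.fixed_a:
            free.append((i, "a"))
        if not res.fixed_b:
            free.append((i, "b"))
    if not free:
        raise ValidationError("no free parameters")
    if len(free) > series.ph.size - 1:
        raise ValidationError(
            f"{len(free)} free pKa values cannot be determined from "
            f"{series.ph.size} points")
    if fit_dg_ref == "auto":
        fit_dg_ref = series.ph.size - len(free) >= 3
    dg_ref0 = _pin_dg_ref(series, model.ph_ref)
    weights = (1.0 / series.sigma) if series.sigma is not None else np.ones_like(series.dg)

    def build(x: np.ndarray, sign: int) -> LinkageModel:
        residues = list(model.residues)
        for val, (i, which) in zip(x, free):
            kw = {"pka_a": val} if which == "a" else {"pka_b": val}
            residues[i] = replace(residues[i], **kw)
        dg_ref = float(x[-1]) if fit_dg_ref else dg_ref0
        return replace(model, residues=residues, dg_ref=dg_ref, sign=sign)

    def resid(x: np.ndarray, sign: int, dg: np.ndarray) -> np.ndarray:
        return (np.asarray(build(x, sign).delta_g(series.ph)) - dg) * weights

    signs = (1, -1) if fit_sign else (model.sign,)
    grid = [4.0, 6.5, 9.0]
    starts = [np.array(c) for c in itertools.product(grid, repeat=len(free))]
    lo = [2.0] * len(free)
    hi = [12.0] * len(free)
    if fit_dg_ref:
        span = float(np.ptp(series.dg)) + 1.0
        lo += [dg_ref0 - 10.0 * span]
        hi += [dg_ref0 + 10.0 * span]
        starts = [np.concatenate([x0, [dg_ref0]]) for x0 in starts]

    def solve(dg: np.ndarray) -> tuple[np.ndarray, int, float]:
        best = None
        for sign in signs:
            for x0 in starts:
                try:
                    sol = least_squares(resid, x0, args=(sign, dg),
                                        bounds=(lo, hi), max_nfev=2000)
                except Exception:
                    continue
                if best is None or sol.cost < best[2]:
                    best = (sol.x, sign, sol.cost)
        if best is None:
            raise FitError("pKa fit failed for all starts")
        return best

    x_hat, sign_hat, cost = solve(series.dg)
    fitted = build(x_hat, sign_hat)
    all_free = all(not r.fixed_a and not r.fixed_b for r in model.residues)
    swapped = fit_sign and all_free and fitted.sign == 1
    if swapped:
        # canonical representation: swap A<->B on every residue, s = -1
        fitted = replace(
            fitted,
            residues=[replace(r, pka_a=r.pka_b, pka_b=r.pka_a)
                      for r in fitted.residues],
            sign=-1,
        )

    # residual bootstrap for uncertainties
    rng = np.random.default_rng(seed)
    base = np.asarray(fitted.delta_g(series.ph))
    res0 = series.dg - base
    # column permutation that applies the A<->B mirror to a sample vector
    mirror = np.arange(len(free) + (1 if fit_dg_ref else 0))
    if all_free:
        pos = {fk: k for k, fk in enumerate(free)}
        for i, _ in enumerate(model.residues):
            mirror[pos[(i, "a")]], mirror[pos[(i, "b")]] = (
                pos[(i, "b")], pos[(i, "a")])
    canon_sign = fitted.sign
    samples = []
    for _ in range(n_bootstrap):
        dg_star = base + rng.choice(res0, size=res0.size, replace=True)
        try:
            x_star, sign_star, _ = solve(dg_star)
        except FitError:
            continue
        if fit_sign and all_free and sign_star != canon_sign:
            x_star = x_star[mirror]
        samples.append(x_star)
    n_x = len(free) + (1 if fit_dg_ref else 0)
    sig = (np.std(np.array(samples), axis=0, ddof=1)
           if len(samples) > 2 else np.full(n_x, np.nan))
    flip = {"a": "b", "b": "a"} if swapped else {"a": "a", "b": "b"}
    sigmas = {
        f"{model.residues[i].label}.pka_{flip[which]}": float(s)
        for (i, which), s in zip(free, sig)
    }
    if fit_dg_ref:
        sigmas["dg_ref"] = float(sig[-1])
    fitted.sigmas = sigmas  # type: ignore[attr-defined]
    fitted.rss = float(2.0 * cost)  # type: ignore[attr-defined]
    return fitted


def sequential_pka_protocol(mutant_series: PhStabilitySeries,
                            wt_series: PhStabilitySeries,
                            shared_label: str = "H54",
                            second_label: str = "H59",
                            ph_ref: float = 5.0,
                            temperature: float = T_DEFAULT,
                            n_bootstrap: int = 200,
                            seed: int = 0) -> LinkageModel:
    """Two-stage fit: single residue on the mutant, then the second
    residue on the wild type with the first held fixed.

    Stage 1 fits the shared residue (the one still present in the mutant)
    to the mutant series. Stage 2 carries that residue, fixed, into a
    two-residue model and fits the second residue on the wild-type
    series. Both stages share pH_ref and temperature; stage provenance is
    attached to the returned model.
    """
    stage1 = fit_pka(
        mutant_series,
        LinkageModel([TitratableResidue(shared_label, 6.0, 6.0)],
                     ph_ref=ph_ref, temperature=temperature),
        n_bootstrap=n_bootstrap, seed=seed,
    )
    shared = replace(stage1.residues[0], fixed_a=True, fixed_b=True)
    stage2 = fit_pka(
        wt_series,
        LinkageModel([shared, TitratableResidue(second_label, 6.0, 6.0)],
                     ph_ref=ph_ref, temperature=temperature,
                     sign=stage1.sign),
        fit_sign=False,
        n_bootstrap=n_bootstrap, seed=seed + 1,
    )
    stage2.provenance = {  # type: ignore[attr-defined]
        "stage1": {
            "series": mutant_series.label,
            "residue": shared_label,
            "pka_a": stage1.residues[0].pka_a,
            "pka_b": stage1.residues[0].pka_b,
            "sign": stage1.sign,
        },
        "stage2": {"series": wt_series.label, "residue": second_label},
    }
    return stage2


def barrier_series_from_rates(ph: np.ndarray, rates: np.ndarray,
                              ph_ref: float = 5.0,
                              temperature: float = T_DEFAULT,
                              label: str = "ddG_barrier") -> PhStabilitySeries:
    """ΔΔG‡(pH) = −RT ln(k(pH)/k(pH_ref)) from a set of rate constants.

    Working with rate ratios makes the barrier series independent of the
    standard state and of the time unit of the rates.
    """
    ph = np.asarray(ph, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValidationError("rates must be positive")
    i = np.argmin(np.abs(ph - ph_ref))
    if abs(ph[i] - ph_ref) > 1e-9:
        raise ValidationError("pH_ref must be one of the pH values")
    ddg = -R_KCAL * temperature * np.log(rates / rates[i])
    return PhStabilitySeries(ph=ph, dg=ddg, label=label)
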