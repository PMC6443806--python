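"""Charged C-alpha structure-based (Go-type) folding model.

Each residue is one bead at its C-alpha position. The native structure
defines harmonic bonds and angles, cosine dihedrals, and a native-contact
list: residue pairs separated by at least 4 in sequence whose heavy atoms
approach within 6 A in the native state. Native contacts attract through
a 12-10 potential eps_C [5 (sigma/r)^12 - 6 (sigma/r)^10] with sigma the
native C-alpha distance; all other pairs repel as eps_NC (sigma_NC/r)^12.
Charged beads (Asp/Glu -1, Lys/Arg +1, and optionally a protonated
histidine +1) additionally interact through a screened Debye-Hueckel
potential k_elec B(lambda_D) q_i q_j exp(-r/lambda_D) / (eps r).

Units are reduced: energies in eps_C (mapped to 1 kcal/mol for the
electrostatic prefactor), k_B = 1, bead mass = 1, distances in A.
Dynamics are Langevin (BAOAB splitting; velocity Verlet when friction is
zero). Multi-temperature runs are combined by WHAM into free-energy
profiles F(Q) over the fraction of native contacts Q, from which the
folding temperature and transition-state contact statistics follow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .io import StructureModel, ValidationError

__all__ = [
    "CaTopology",
    "SimRun",
    "FreeEnergyProfile",
    "ContactStats",
    "build_ca_topology",
    "assign_charges",
    "potential_energy",
    "forces",
    "run_langevin",
    "fraction_native_contacts",
    "wham_free_energy",
    "ts_contact_probability",
    "compare_contact_probability",
]

#: Coulomb constant in kcal A mol^-1 e^-2; the eps_C = 1 kcal/mol mapping
#: carries it unchanged into reduced units.
K_ELEC_KCAL = 332.0

CHARGE_BY_RESIDUE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}


class IntegrationError(RuntimeError):
    """Energy divergence during dynamics; carries the step index."""

    def __init__(self, message: str, step: int):
        super().__init__(message)
        self.step = step


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


@dataclass
class CaTopology:
    """Parameters of the coarse-grained model for one chain."""

    coords0: np.ndarray  # (n, 3) native C-alpha coordinates, A
    sequence: str
    contacts: np.ndarray  # (nc, 2) int, residue indices (0-based)
    contact_sigma: np.ndarray  # (nc,) native C-alpha distances, A
    charges: np.ndarray | None = None  # (n,) in e
    k_bond: float = 200.0  # eps / A^2
    k_angle: float = 40.0  # eps / rad^2
    k_dihedral: float = 1.0  # eps
    eps_c: float = 1.0
    eps_nc: float = 1.0
    sigma_nc: float = 4.0  # A
    lambda_d: float = 13.6  # A (0.05 M monovalent salt)
    dielectric: float = 80.0
    b_factor: float = 1.0
    k_elec: float = K_ELEC_KCAL
    min_seq_sep: int = 4

    def __post_init__(self) -> None:
        self.coords0 = np.asarray(self.coords0, dtype=float)
        self.contacts = np.asarray(self.contacts, dtype=np.int64).reshape(-1, 2)
        self.contact_sigma = np.asarray(self.contact_sigma, dtype=float)
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.size != self.n_beads:
                raise ValidationError("charge vector length mismatch")
        if len(self.sequence) != self.n_beads:
            raise ValidationError("sequence length mismatch")
        if np.any(np.diff(np.sort(self.contacts, axis=1), axis=1)
                  < self.min_seq_sep):
            raise ValidationError(
                f"contact pairs must satisfy j - i >= {self.min_seq_sep}")

    @property
    def n_beads(self) -> int:
        return self.coords0.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.contacts.shape[0]

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "coords0": self.coords0.tolist(),
            "sequence": self.sequence,
            "contacts": self.contacts.tolist(),
            "contact_sigma": self.contact_sigma.tolist(),
            "charges": None if self.charges is None else self.charges.tolist(),
        }
        for k in ("k_bond", "k_angle", "k_dihedral", "eps_c", "eps_nc",
                  "sigma_nc", "lambda_d", "dielectric", "b_factor", "k_elec",
                  "min_seq_sep"):
            d[k] = getattr(self, k)
        blob = json.dumps(d)
        if path is not None:
            Path(path).write_text(blob)
        return blob

    @classmethod
    def from_json(cls, source: str | Path) -> "CaTopology":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        d = json.loads(text)
        charges = d.pop("charges")
        return cls(
            coords0=np.array(d.pop("coords0")),
            sequence=d.pop("sequence"),
            contacts=np.array(d.pop("contacts")),
            contact_sigma=np.array(d.pop("contact_sigma")),
            charges=None if charges is None else np.array(charges),
            **d,
        )


def build_ca_topology(structure: StructureModel, cutoff: float = 6.0,
                      min_seq_sep: int = 4,
                      contact_list: np.ndarray | None = None,
                      **params) -> CaTopology:
    """Build the coarse-grained topology from an all-heavy-atom structure.

    A contact (i, j) is included iff j - i >= ``min_seq_sep`` and any
    heavy-atom pair of the two residues is closer than ``cutoff``;
    sigma_ij is the native C-alpha distance. A user-supplied
    ``contact_list`` (pairs of 0-based residue indices) overrides the
    cutoff definition.
    """
    if structure.n_models != 1:
        raise ValidationError("topology requires a single-model structure")
    ca_idx = structure.ca_indices()
    if ca_idx.size < 2:
        raise ValidationError("structure must contain C-alpha atoms")
    coords = structure.coords[0]
    ca = coords[ca_idx]
    n_res = ca_idx.size
    # map atoms to residue ordinal
    res_of_atom = np.empty(structure.n_atoms, dtype=int)
    ordinal = -1
    last = None
    for k, a in enumerate(structure.atoms):
        key = (a.chain_id, a.res_seq)
        if key != last:
            ordinal += 1
            last = key
        res_of_atom[k] = ordinal
    heavy = np.array([i for i, a in enumerate(structure.atoms)
                      if a.element != "H"], dtype=int)

    if contact_list is not None:
        pairs = np.asarray(contact_list, dtype=np.int64).reshape(-1, 2)
    else:
        d = np.linalg.norm(coords[heavy][:, None, :] - coords[heavy][None, :, :],
                           axis=-1)
        close = d < cutoff
        res_h = res_of_atom[heavy]
        found = set()
        ii, jj = np.nonzero(close)
        for a_i, a_j in zip(res_h[ii], res_h[jj]):
            if a_j - a_i >= min_seq_sep:
                found.add((int(a_i), int(a_j)))
        pairs = np.array(sorted(found), dtype=np.int64).reshape(-1, 2)
    sigma = np.linalg.norm(ca[pairs[:, 0]] - ca[pairs[:, 1]], axis=1) \
        if pairs.size else np.empty(0)
    seq = "".join(structure.sequence.values())
    return CaTopology(coords0=ca, sequence=seq, contacts=pairs,
                      contact_sigma=sigma, min_seq_sep=min_seq_sep, **params)


def assign_charges(sequence: str, h59_protonated: bool = False,
                   h59_index: int | None = None) -> np.ndarray:
    """Charge per bead: Asp/Glu -1, Lys/Arg +1, all else 0; the histidine
    at ``h59_index`` (0-based) gets +1 iff ``h59_protonated``."""
    q = np.array([CHARGE_BY_RESIDUE.get(c.upper(), 0.0) for c in sequence])
    if h59_index is not None:
        if not 0 <= h59_index < len(sequence):
            raise ValidationError("histidine index out of range")
        if sequence[h59_index].upper() != "H":
            raise ValidationError(
                f"residue {h59_index} is {sequence[h59_index]!r}, not histidine")
        if h59_protonated:
            q[h59_index] = 1.0
    elif h59_protonated:
        raise ValidationError("h59_protonated requires h59_index")
    return q


# ---------------------------------------------------------------------------
# Packed arrays and numba kernels
# ---------------------------------------------------------------------------


def _pack(top: CaTopology) -> tuple:
    """Precompute integer/float arrays for the jitted kernels."""
    x0 = top.coords0
    n = top.n_beads
    bi = np.arange(n - 1, dtype=np.int64)
    bj = bi + 1
    br0 = np.linalg.norm(x0[bj] - x0[bi], axis=1)

    ai = np.arange(n - 2, dtype=np.int64)
    u = x0[ai] - x0[ai + 1]
    w = x0[ai + 2] - x0[ai + 1]
    cos = np.sum(u * w, axis=1) / (np.linalg.norm(u, axis=1)
                                   * np.linalg.norm(w, axis=1))
    ath0 = np.arccos(np.clip(cos, -1, 1))

    di = np.arange(max(n - 3, 0), dtype=np.int64)
    dphi0 = np.array([_dihedral_angle(x0[k], x0[k + 1], x0[k + 2], x0[k + 3])
                      for k in di]) if n >= 4 else np.empty(0)

    in_contact = set(map(tuple, top.contacts))
    nn = [(i, j) for i in range(n) for j in range(i + top.min_seq_sep, n)
          if (i, j) not in in_contact]
    nn_arr = np.array(nn, dtype=np.int64).reshape(-1, 2)

    q = top.charges if top.charges is not None else np.zeros(n)
    charged = np.nonzero(q)[0]
    qp = [(i, j, q[i] * q[j]) for ii, i in enumerate(charged)
          for j in charged[ii + 1:] if j - i >= top.min_seq_sep]
    qi = np.array([p[0] for p in qp], dtype=np.int64)
    qj = np.array([p[1] for p in qp], dtype=np.int64)
    qprod = np.array([p[2] for p in qp], dtype=float)
    pref = top.k_elec * top.b_factor / top.dielectric / top.eps_c

    return (bi, bj, br0, top.k_bond,
            ai, ath0, top.k_angle,
            di, dphi0, top.k_dihedral,
            top.contacts[:, 0].copy(), top.contacts[:, 1].copy(),
            top.contact_sigma.copy(), top.eps_c,
            nn_arr[:, 0].copy(), nn_arr[:, 1].copy(),
            top.sigma_nc, top.eps_nc,
            qi, qj, qprod, pref, top.lambda_d)


def _dihedral_angle(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m1 @ n2, n1 @ n2))


@njit(cache=True)
def _energy_forces(x, f,
                   bi, bj, br0, kb,
                   ai, ath0, kth,
                   di, dphi0, kphi,
                   ci, cj, csig, eps_c,
                   ni, nj, sig_nc, eps_nc,
                   qi, qj, qprod, qpref, lam):
    """Total potential energy and forces (both in reduced units).

    Returns the 6-term breakdown (bond, angle, dihedral, contact,
    non-native, electrostatic); ``f`` is overwritten.
    """
    n = x.shape[0]
    for k in range(n):
        for d in range(3):
            f[k, d] = 0.0
    e_bond = 0.0
    for b in range(bi.shape[0]):
        i, j = bi[b], bj[b]
        dx = x[j] - x[i]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        dr = r - br0[b]
        e_bond += 0.5 * kb * dr * dr
        c = kb * dr / r
        for d in range(3):
            f[i, d] += c * dx[d]
            f[j, d] -= c * dx[d]

    e_angle = 0.0
    for a in range(ai.shape[0]):
        i = ai[a]
        j = i + 1
        k = i + 2
        u = x[i] - x[j]
        w = x[k] - x[j]
        nu = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
        nw = np.sqrt(w[0] ** 2 + w[1] ** 2 + w[2] ** 2)
        cosang = (u[0] * w[0] + u[1] * w[1] + u[2] * w[2]) / (nu * nw)
        if cosang > 1.0:
            cosang = 1.0
        if cosang < -1.0:
            cosang = -1.0
        theta = np.arccos(cosang)
        sin = np.sqrt(1.0 - cosang * cosang)
        if sin < 1e-8:
            sin = 1e-8
        dth = theta - ath0[a]
        e_angle += 0.5 * kth * dth * dth
        coef = -kth * dth
        for d in range(3):
            dth_di = (cosang * u[d] / nu - w[d] / nw) / (nu * sin)
            dth_dk = (cosang * w[d] / nw - u[d] / nu) / (nw * sin)
            f[i, d] += coef * dth_di
            f[k, d] += coef * dth_dk
            f[j, d] -= coef * (dth_di + dth_dk)

    e_dih = 0.0
    for t in range(di.shape[0]):
        i = di[t]
        b1 = x[i + 1] - x[i]
        b2 = x[i + 2] - x[i + 1]
        b3 = x[i + 3] - x[i + 2]
        n1 = np.empty(3)
        n2 = np.empty(3)
        n1[0] = b1[1] * b2[2] - b1[2] * b2[1]
        n1[1] = b1[2] * b2[0] - b1[0] * b2[2]
        n1[2] = b1[0] * b2[1] - b1[1] * b2[0]
        n2[0] = b2[1] * b3[2] - b2[2] * b3[1]
        n2[1] = b2[2] * b3[0] - b2[0] * b3[2]
        n2[2] = b2[0] * b3[1] - b2[1] * b3[0]
        nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        m1 = np.empty(3)
        m1[0] = (n1[1] * b2[2] - n1[2] * b2[1]) / nb2
        m1[1] = (n1[2] * b2[0] - n1[0] * b2[2]) / nb2
        m1[2] = (n1[0] * b2[1] - n1[1] * b2[0]) / nb2
        sy = m1[0] * n2[0] + m1[1] * n2[1] + m1[2] * n2[2]
        sx = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        phi = np.arctan2(sy, sx)
        dphi = phi - dphi0[t]
        e_dih += kphi * ((1.0 - np.cos(dphi)) + 0.5 * (1.0 - np.cos(3.0 * dphi)))
        dv = kphi * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        tcoef = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (nb2 * nb2)
        scoef = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (nb2 * nb2)
        for d in range(3):
            fi = -dv * nb2 / n1sq * n1[d]
            fl = dv * nb2 / n2sq * n2[d]
            f[i, d] += fi
            f[i + 3, d] += fl
            f[i + 1, d] += -(1.0 + tcoef) * fi + scoef * fl
            f[i + 2, d] += tcoef * fi - (1.0 + scoef) * fl

    e_con = 0.0
    for c in range(ci.shape[0]):
        i, j = ci[c], cj[c]
        dx = x[j] - x[i]
        r2 = dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2
        r = np.sqrt(r2)
        s_r = csig[c] / r
        s10 = s_r ** 10
        s12 = s_r ** 12
        e_con += eps_c * (5.0 * s12 - 6.0 * s10)
        # dV/dr = eps_c * (-60 s12 + 60 s10)/r ; force = -dV/dr * dx/r
        coef = eps_c * 60.0 * (s12 - s10) / r2
        for d in range(3):
            f[i, d] -= coef * dx[d]
            f[j, d] += coef * dx[d]

    e_nc = 0.0
    for c in range(ni.shape[0]):
        i, j = ni[c], nj[c]
        dx = x[j] - x[i]
        r2 = dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2
        if r2 > 16.0 * sig_nc * sig_nc:
            continue
        s12 = (sig_nc * sig_nc / r2) ** 6
        e_nc += eps_nc * s12
        coef = 12.0 * eps_nc * s12 / r2
        for d in range(3):
            f[i, d] -= coef * dx[d]
            f[j, d] += coef * dx[d]

    e_dh = 0.0
    for c in range(qi.shape[0]):
        i, j = qi[c], qj[c]
        dx = x[j] - x[i]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        ex = np.exp(-r / lam)
        e = qpref * qprod[c] * ex / r
        e_dh += e
        coef = e * (1.0 / r + 1.0 / lam) / r
        for d in range(3):
            f[i, d] -= coef * dx[d]
            f[j, d] += coef * dx[d]

    return e_bond, e_angle, e_dih, e_con, e_nc, e_dh


@njit(cache=True)
def _q_of(x, ci, cj, csig, ratio):
    formed = 0
    for c in range(ci.shape[0]):
        dx = x[cj[c]] - x[ci[c]]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        if r <= ratio * csig[c]:
            formed += 1
    return formed / ci.shape[0]


@njit(cache=True)
def _langevin(x0, v0, n_steps, dt, friction, temperature, seed, save_every,
              bi, bj, br0, kb, ai, ath0, kth, di, dphi0, kphi,
              ci, cj, csig, eps_c, ni, nj, sig_nc, eps_nc,
              qi, qj, qprod, qpref, lam, ratio):
    """BAOAB Langevin integrator; velocity Verlet when friction == 0.

    Records potential energy, Q, instantaneous kinetic temperature and
    coordinates every ``save_every`` steps (including step 0).
    """
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    v = v0.copy()
    f = np.zeros((n, 3))
    _energy_forces(x, f, bi, bj, br0, kb, ai, ath0, kth, di, dphi0, kphi,
                   ci, cj, csig, eps_c, ni, nj, sig_nc, eps_nc,
                   qi, qj, qprod, qpref, lam)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(max(temperature * (1.0 - c1 * c1), 0.0))
    n_save = n_steps // save_every + 1
    e_out = np.empty(n_save)
    q_out = np.empty(n_save)
    t_out = np.empty(n_save)
    x_out = np.empty((n_save, n, 3))
    step_out = np.empty(n_save, dtype=np.int64)
    isave = 0
    diverged = -1
    for step in range(n_steps + 1):
        if step % save_every == 0:
            terms = _energy_forces(x, f, bi, bj, br0, kb, ai, ath0, kth,
                                   di, dphi0, kphi, ci, cj, csig, eps_c,
                                   ni, nj, sig_nc, eps_nc,
                                   qi, qj, qprod, qpref, lam)
            epot = terms[0] + terms[1] + terms[2] + terms[3] + terms[4] + terms[5]
            if np.abs(epot) > 1e6 or np.isnan(epot):
                diverged = step
                break
            e_out[isave] = epot
            q_out[isave] = _q_of(x, ci, cj, csig, ratio)
            ke = 0.0
            for k in range(n):
                ke += v[k, 0] ** 2 + v[k, 1] ** 2 + v[k, 2] ** 2
            t_out[isave] = ke / (3.0 * n)
            x_out[isave] = x
            step_out[isave] = step
            isave += 1
        if step == n_steps:
            break
        # B
        v += 0.5 * dt * f
        # A
        x += 0.5 * dt * v
        # O
        if friction > 0.0:
            for k in range(n):
                for d in range(3):
                    v[k, d] = c1 * v[k, d] + c2 * np.random.standard_normal()
        # A
        x += 0.5 * dt * v
        # B
        _energy_forces(x, f, bi, bj, br0, kb, ai, ath0, kth, di, dphi0, kphi,
                       ci, cj, csig, eps_c, ni, nj, sig_nc, eps_nc,
                       qi, qj, qprod, qpref, lam)
        v += 0.5 * dt * f
    return (e_out[:isave], q_out[:isave], t_out[:isave], x_out[:isave],
            step_out[:isave], diverged)


# ---------------------------------------------------------------------------
# Public energy / dynamics API
# ---------------------------------------------------------------------------

_TERM_NAMES = ("bond", "angle", "dihedral", "contact", "non_native",
               "electrostatic")


def potential_energy(coords: np.ndarray, top: CaTopology
                     ) -> tuple[float, dict[str, float]]:
    """Total reduced potential energy with a per-term breakdown."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("non-finite coordinates")
    _check_overlap(coords)
    f = np.zeros_like(coords)
    terms = _energy_forces(coords, f, *_pack(top))
    breakdown = dict(zip(_TERM_NAMES, map(float, terms)))
    return float(sum(terms)), breakdown


def forces(coords: np.ndarray, top: CaTopology) -> np.ndarray:
    """Analytic forces, -dV/dx, in reduced units."""
    coords = np.asarray(coords, dtype=float)
    _check_overlap(coords)
    f = np.zeros_like(coords)
    _energy_forces(coords, f, *_pack(top))
    return f


def _check_overlap(coords: np.ndarray) -> None:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 0.01:
        raise ValidationError("overlapping beads (r < 0.01 A)")


@dataclass
class SimRun:
    """Recorded observables of one constant-temperature trajectory."""

    steps: np.ndarray
    energies: np.ndarray  # potential, reduced units
    q: np.ndarray
    kinetic_temps: np.ndarray
    coords: np.ndarray  # (n_frames, n_beads, 3)
    temperature: float
    dt: float
    friction: float
    seed: int
    n_steps: int

    def frames_after_equilibration(self, fraction: float = 0.2) -> np.ndarray:
        return np.nonzero(self.steps >= fraction * self.n_steps)[0]

    def write_table(self, path) -> None:
        """Columnar text format: step, temperature, potential energy, Q."""
        import pandas as pd
        pd.DataFrame({
            "step": self.steps,
            "temperature": np.full(self.steps.size, self.temperature),
            "energy": self.energies,
            "q": self.q,
        }).to_csv(path, index=False)


def run_langevin(top: CaTopology, temperature: float, n_steps: int,
                 dt: float = 0.0005, friction: float = 1.0, seed: int = 0,
                 save_every: int = 200, coords0: np.ndarray | None = None
                 ) -> SimRun:
    """Langevin dynamics at a fixed reduced temperature.

    Velocities are initialized from the Maxwell-Boltzmann distribution at
    ``temperature``; with ``friction`` = 0 the thermostat is off and the
    integrator reduces to velocity Verlet (microcanonical). Runs are
    bitwise deterministic for a given seed.
    """
    if dt > 0.001:
        raise ValidationError("time step too large (dt <= 0.001)")
    if top.n_contacts == 0:
        raise ValidationError("topology has no native contacts")
    x0 = np.array(top.coords0 if coords0 is None else coords0, dtype=float)
    rng = np.random.default_rng(seed)
    v0 = np.sqrt(max(temperature, 0.0)) * rng.standard_normal(x0.shape)
    packed = _pack(top)
    out = _langevin(x0, v0, n_steps, dt, friction, temperature,
                    int(seed) % (2 ** 31), save_every, *packed, 1.2)
    e, q, t_inst, frames, steps, diverged = out
    if diverged >= 0:
        raise IntegrationError(
            f"potential energy diverged at step {diverged}", int(diverged))
    return SimRun(steps=steps, energies=e, q=q, kinetic_temps=t_inst,
                  coords=frames, temperature=temperature, dt=dt,
                  friction=friction, seed=seed, n_steps=n_steps)


def fraction_native_contacts(coords: np.ndarray, top: CaTopology,
                             ratio: float = 1.2) -> float:
    """Q: fraction of native contacts with r_ij <= ratio * sigma_ij."""
    if top.n_contacts == 0:
        raise ValidationError("topology has no native contacts")
    coords = np.asarray(coords, dtype=float)
    return float(_q_of(coords, top.contacts[:, 0].copy(),
                       top.contacts[:, 1].copy(),
                       top.contact_sigma.copy(), ratio))


# ---------------------------------------------------------------------------
# WHAM and contact statistics
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergyProfile:
    """F(Q) in units of k_B T at each query temperature."""

    q_centers: np.ndarray
    free_energy: dict[float, np.ndarray]
    occupied: np.ndarray  # bool mask of Q bins with any counts
    t_f: float
    q_barrier: float
    q_folded: float
    q_unfolded: float


def _histograms(runs, equilibration, n_e_bins):
    e_all, q_all = [], []
    for run in runs:
        idx = run.frames_after_equilibration(equilibration)
        e_all.append(run.energies[idx])
        q_all.append(run.q[idx])
    e_lo = min(e.min() for e in e_all)
    e_hi = max(e.max() for e in e_all) + 1e-9
    e_edges = np.linspace(e_lo, e_hi, n_e_bins + 1)
    return e_all, q_all, e_edges


def wham_free_energy(runs: list[SimRun], query_temps=None,
                     n_e_bins: int = 80, n_q_bins: int | None = None,
                     equilibration: float = 0.2, tol: float = 1e-6,
                     max_iter: int = 100000,
                     q_split: float | None = None) -> FreeEnergyProfile:
    """Combine multi-temperature runs into free-energy profiles F(Q).

    Standard self-consistent WHAM on (E, Q) histograms; because the bias
    between temperatures depends only on E, the density of states
    factorizes over E bins. Iteration stops when every per-run free-energy
    shift changes by less than ``tol``. The folding temperature T_F is
    where the basin populations (integrated over Q below/above the
    barrier top) are equal; for weakly cooperative systems whose barrier
    top is poorly defined, ``q_split`` fixes the folded/unfolded divide
    at a given Q instead.
    """
    if len(runs) == 0:
        raise ValidationError("no runs")
    temps = np.array([r.temperature for r in runs])
    e_all, q_all, e_edges = _histograms(runs, equilibration, n_e_bins)
    # energy-overlap check between temperature-adjacent runs
    order = np.argsort(temps)
    for a, b in zip(order[:-1], order[1:]):
        if len(runs) > 1 and (e_all[a].max() < e_all[b].min()
                              or e_all[b].max() < e_all[a].min()):
            raise ValidationError(
                f"energy histograms of runs at T={temps[a]:g} and "
                f"T={temps[b]:g} do not overlap")
    e_centers = 0.5 * (e_edges[:-1] + e_edges[1:])
    if n_q_bins is None:
        n_q_bins = 26
    q_edges = np.linspace(0.0, 1.0 + 1e-9, n_q_bins + 1)
    q_centers = 0.5 * (q_edges[:-1] + q_edges[1:])

    counts = np.zeros((len(runs), n_e_bins, n_q_bins))
    for k, (e, q) in enumerate(zip(e_all, q_all)):
        counts[k], _, _ = np.histogram2d(e, q, bins=[e_edges, q_edges])
    c_lm = counts.sum(axis=0)  # (E, Q)
    c_l = c_lm.sum(axis=1)  # (E,)
    n_k = counts.sum(axis=(1, 2))  # frames per run

    # iterate f_k = -ln sum_l omega_l(E) exp(-E_l / T_k)
    beta = 1.0 / temps
    f_k = np.zeros(len(runs))
    log_cl = np.where(c_l > 0, np.log(np.maximum(c_l, 1)), -np.inf)
    for _ in range(max_iter):
        # log denominator per E bin: ln sum_k N_k exp(f_k - beta_k E_l)
        log_den = logsumexp(
            np.log(n_k)[:, None] + f_k[:, None] - beta[:, None] * e_centers[None, :],
            axis=0)
        log_omega_l = log_cl - log_den  # ln density of states per E bin
        new_f = -logsumexp(log_omega_l[None, :] - beta[:, None] * e_centers[None, :],
                           axis=1)
        new_f -= new_f[0]
        if np.max(np.abs(new_f - f_k)) < tol:
            f_k = new_f
            break
        f_k = new_f
    # per-(E,Q) density of states: omega_lm = c_lm / den_l
    log_den = logsumexp(
        np.log(n_k)[:, None] + f_k[:, None] - beta[:, None] * e_centers[None, :],
        axis=0)
    with np.errstate(divide="ignore"):
        log_omega_lm = np.where(c_lm > 0, np.log(np.maximum(c_lm, 1e-300)),
                                -np.inf) - log_den[:, None]
    occupied = np.isfinite(log_omega_lm).any(axis=0)

    def profile_at(t: float) -> np.ndarray:
        logp = logsumexp(log_omega_lm - e_centers[:, None] / t, axis=0)
        fq = -(logp - logp.max())
        return fq

    def basin_split(fq: np.ndarray) -> tuple[float, float, float]:
        occ = np.nonzero(occupied)[0]
        fo = fq[occ]
        i_unf = occ[np.argmin(fo[:max(1, len(occ) // 2)])]
        i_fold = occ[len(occ) // 2 + np.argmin(fo[len(occ) // 2:])] \
            if len(occ) > 1 else occ[0]
        if i_fold <= i_unf:
            i_barrier = (i_unf + i_fold) // 2
        else:
            seg = fq[i_unf:i_fold + 1]
            i_barrier = i_unf + int(np.flatnonzero(seg == seg.max())[-1])
        return (float(q_centers[i_barrier]), float(q_centers[i_fold]),
                float(q_centers[i_unf]))

    def log_pop_ratio(t: float) -> float:
        logp = logsumexp(log_omega_lm - e_centers[:, None] / t, axis=0)
        if q_split is None:
            fq = -(logp - logp.max())
            qb, _, _ = basin_split(fq)
        else:
            qb = q_split
        hi = q_centers > qb
        lo = ~hi
        return (logsumexp(logp[hi & occupied])
                - logsumexp(logp[lo & occupied]))

    t_lo, t_hi = float(temps.min()), float(temps.max())
    if len(runs) == 1:
        t_f = float(temps[0])
    else:
        g_lo, g_hi = log_pop_ratio(t_lo), log_pop_ratio(t_hi)
        if g_lo * g_hi < 0:
            from scipy.optimize import brentq
            t_f = float(brentq(log_pop_ratio, t_lo, t_hi, xtol=1e-6))
        else:
            grid = np.linspace(t_lo, t_hi, 101)
            t_f = float(grid[np.argmin([abs(log_pop_ratio(t)) for t in grid])])

    query = list(query_temps) if query_temps is not None else sorted(set(temps))
    free = {float(t): profile_at(float(t)) for t in query}
    fq_tf = profile_at(t_f)
    qb, qf, qu = basin_split(fq_tf)
    return FreeEnergyProfile(q_centers=q_centers, free_energy=free,
                             occupied=occupied, t_f=t_f, q_barrier=qb,
                             q_folded=qf, q_unfolded=qu)


@dataclass
class ContactStats:
    """Per-contact formation probabilities within one ensemble."""

    contacts: np.ndarray  # (nc, 2)
    probability: np.ndarray  # (nc,)
    ensemble: str
    n_frames: int

    def __post_init__(self) -> None:
        if np.any(self.probability < 0) or np.any(self.probability > 1):
            raise ValidationError("probabilities must lie in [0, 1]")


def ts_contact_probability(run: SimRun, top: CaTopology,
                           profile: FreeEnergyProfile,
                           ensemble: str = "ts", window: float = 0.025,
                           ratio: float = 1.2, min_frames: int = 100,
                           equilibration: float = 0.2) -> ContactStats:
    """P(i,j): per-contact formation probability in a chosen ensemble of
    frames of a run at (or near) T_F.

    'ts' selects frames with Q within ±``window`` of the barrier top;
    'native' and 'unfolded' select frames on the corresponding side of
    the barrier.
    """
    idx = run.frames_after_equilibration(equilibration)
    q = run.q[idx]
    if ensemble == "ts":
        sel = np.abs(q - profile.q_barrier) <= window
    elif ensemble == "native":
        sel = q > profile.q_barrier
    elif ensemble == "unfolded":
        sel = q < profile.q_barrier
    else:
        raise ValidationError(f"unknown ensemble {ensemble!r}")
    frames = run.coords[idx][sel]
    if frames.shape[0] < min_frames:
        raise ValidationError(
            f"only {frames.shape[0]} frames in the {ensemble} ensemble "
            f"(need {min_frames})")
    diff = frames[:, top.contacts[:, 0], :] - frames[:, top.contacts[:, 1], :]
    r = np.linalg.norm(diff, axis=-1)  # (n_frames, nc)
    formed = r <= ratio * top.contact_sigma[None, :]
    return ContactStats(contacts=top.contacts.copy(),
                        probability=formed.mean(axis=0),
                        ensemble=ensemble, n_frames=frames.shape[0])


def compare_contact_probability(stats_a: ContactStats, stats_b: ContactStats,
                                threshold: float = 0.10
                                ) -> list[tuple[int, int, float]]:
    """Contacts with |P_a - P_b| > threshold, as (i, j, ΔP) sorted by
    decreasing |ΔP| (ΔP = a - b)."""
    if stats_a.contacts.shape != stats_b.contacts.shape or \
            np.any(stats_a.contacts != stats_b.contacts):
        raise ValidationError("contact lists differ between the two ensembles")
    dp = stats_a.probability - stats_b.probability
    hits = [(int(i), int(j), float(d))
            for (i, j), d in zip(stats_a.contacts, dp)
            if threshold <= 0 or abs(d) > threshold]
    return sorted(hits, key=lambda t: -abs(t[2]))
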