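"""Seed-deterministic generators for every analysis stage.

Each generator produces data with exactly the statistical structure the
corresponding fit assumes, so that estimators can be validated by
parameter recovery without any external downloads: relaxation of the
dimer fraction to a K_d-determined equilibrium (exact ODE integration or
the pure-exponential idealization), multi-state denaturation signals with
linear baselines, pH series built from the proton-linkage binding
polynomial, ideal-geometry toy structures, and multi-model trajectories
with a prescribed hydrogen-bond occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .io import AtomRecord, StructureModel, ValidationError
from .kinetics import KineticTrace, equilibrium_dimer_fraction, relaxation_rate
from .linkage import LinkageModel, PhStabilitySeries
from .unfolding import SCHEMES, TransitionParams, UnfoldingCurve, signal_model

__all__ = [
    "KineticSimSpec",
    "UnfoldingSimSpec",
    "simulate_dissociation",
    "simulate_unfolding_curve",
    "simulate_ph_series",
    "make_toy_structure",
    "toy_charged_hairpin",
    "make_hbond_trajectory",
]


# ---------------------------------------------------------------------------
# Dissociation kinetics
# ---------------------------------------------------------------------------


@dataclass
class KineticSimSpec:
    """Conditions of one dissociation experiment.

    Rates follow 2M <-> D with d[D]/dt = k_on [M]^2 - k_off [D];
    concentrations in M, time in minutes; the dimer fraction is reported
    in monomer units f_D = 2[D]/P_t, matching chromatographic area
    fractions. Defaults reproduce the standard experiment: 5 uM of
    protein incubated from a purely dimeric start.
    """

    k_on: float = 9.0e3  # M^-1 min^-1
    k_off: float = 33.2e-3  # min^-1
    p_total: float = 5e-6  # M
    f_d0: float = 1.0
    times: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 120.0, 25))
    noise_sd: float = 0.0
    seed: int = 0
    ph: float = 6.0
    temperature: float = 310.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValidationError("rates must be positive")
        if self.p_total <= 0:
            raise ValidationError("P_t must be positive")
        if not 0.0 <= self.f_d0 <= 1.0:
            raise ValidationError("initial dimer fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on


def simulate_dissociation(spec: KineticSimSpec,
                          mode: str = "ode") -> KineticTrace:
    """Simulate a dissociation trace.

    ``mode='ode'`` integrates the exact bimolecular rate equation with a
    stiff-capable adaptive scheme (rtol 1e-9) so the trace can serve as an
    oracle for estimator bias; ``mode='exponential'`` evaluates the
    idealized single-exponential relaxation
    f_D(t) = f_eq + (f_D(0) - f_eq) exp(-k_obs t) for exact-recovery
    tests. Gaussian noise of sd ``noise_sd`` is added to the fraction and
    truncated to [0, 1]; noiseless when sd = 0.
    """
    t = spec.times
    f_eq = equilibrium_dimer_fraction(spec.k_d, spec.p_total)
    if mode == "exponential":
        k_obs = relaxation_rate(spec.k_off, spec.k_on, spec.p_total)
        f = f_eq + (spec.f_d0 - f_eq) * np.exp(-k_obs * t)
    elif mode == "ode":
        d0 = spec.f_d0 * spec.p_total / 2.0

        def rhs(_t, y):
            m = spec.p_total - 2.0 * y[0]
            return [spec.k_on * m * m - spec.k_off * y[0]]

        t_span = (float(t[0]), float(t[-1]) if t[-1] > t[0] else float(t[0]) + 1e-9)
        sol = solve_ivp(rhs, t_span, [d0], t_eval=t, method="LSODA",
                        rtol=1e-9, atol=1e-12 * spec.p_total)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        f = 2.0 * sol.y[0] / spec.p_total
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + spec.noise_sd * rng.standard_normal(f.shape)
    f = np.clip(f, 0.0, 1.0)
    return KineticTrace(times=t, f_d=f, ph=spec.ph,
                        temperature=spec.temperature, p_total=spec.p_total)


# ---------------------------------------------------------------------------
# Unfolding curves
# ---------------------------------------------------------------------------


@dataclass
class UnfoldingSimSpec:
    """Conditions of one equilibrium denaturation experiment.

    ``transitions`` holds one (two-state) or two (three-state) LEM
    parameter sets; ``baselines`` one (intercept, slope) pair per species
    in scheme order. The denaturant grid spans the experimental 0-6 M
    range by default.
    """

    scheme: str = "two_state_IU"
    transitions: list[TransitionParams] = field(
        default_factory=lambda: [TransitionParams(8.9, 2.3)])
    baselines: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, -0.02], [0.2, 0.01]]))
    p_total: float = 15e-6
    denaturant: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 6.0, 25))
    noise_sd: float = 0.0
    seed: int = 0
    ph: float = 7.8
    temperature: float = 310.0

    def __post_init__(self) -> None:
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.baselines = np.asarray(self.baselines, dtype=float)
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if np.any(self.denaturant < 0) or np.any(np.diff(self.denaturant) <= 0):
            raise ValidationError("denaturant grid must be non-negative, increasing")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")


def simulate_unfolding_curve(spec: UnfoldingSimSpec) -> UnfoldingCurve:
    """Species populations -> signal = Σ f_s (a_s + b_s den) + noise."""
    sig = signal_model(spec.scheme, spec.transitions, spec.baselines,
                       spec.denaturant, spec.p_total, spec.temperature)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sig = sig + spec.noise_sd * rng.standard_normal(sig.shape)
    return UnfoldingCurve(denaturant=spec.denaturant, signal=sig,
                          ph=spec.ph, p_total=spec.p_total)


# ---------------------------------------------------------------------------
# pH series
# ---------------------------------------------------------------------------


def simulate_ph_series(model: LinkageModel, ph_grid: np.ndarray,
                       noise_sd: float = 0.0, seed: int = 0,
                       label: str = "synthetic") -> PhStabilitySeries:
    """ΔG(pH) = ΔG_ref + s·ΔΔG(pH) + Gaussian noise."""
    ph_grid = np.asarray(ph_grid, dtype=float)
    if ph_grid.size == 0:
        raise ValidationError("empty pH grid")
    if not ph_grid.min() <= model.ph_ref <= ph_grid.max():
        raise ValidationError("pH_ref outside the grid range")
    dg = np.asarray(model.delta_g(ph_grid), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dg = dg + noise_sd * rng.standard_normal(dg.shape)
    return PhStabilitySeries(ph=ph_grid, dg=dg, label=label)


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _helix_ca(n: int) -> np.ndarray:
    """Ideal alpha-helix C-alpha trace: 2.3 A radius, 1.5 A rise,
    100 degrees per residue."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _hairpin_ca(n: int) -> np.ndarray:
    """Two antiparallel strands 4.8 A apart joined by a turn; residues
    zigzag out of the strand plane (pleat amplitude 0.6 A) as real
    beta-strands do, which also keeps every bond angle away from the
    degenerate straight-chain geometry."""
    half = n // 2
    coords = np.zeros((n, 3))
    for i in range(n):
        pleat = 0.6 * (-1.0) ** i
        if i < half:
            coords[i] = (0.0, 3.5 * i, pleat)
        else:
            coords[i] = (4.8, 3.5 * (n - 1 - i) + 1.75 * (n % 2), pleat)
    return coords


def make_toy_structure(n_res: int, motif: str = "helix",
                       sequence: str | None = None) -> StructureModel:
    """Deterministic ideal-geometry toy structure with backbone atoms.

    Generates N, CA, C, O per residue around an ideal C-alpha trace; the
    resulting structure has at least 5 native contacts under the
    6 A / |i-j| >= 4 rule. ``sequence`` defaults to polyalanine.
    """
    if n_res < 8:
        raise ValidationError("need at least 8 residues")
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValidationError("sequence length must equal n_res")
    if motif == "helix":
        ca = _helix_ca(n_res)
    elif motif == "hairpin":
        ca = _hairpin_ca(n_res)
    else:
        raise ValidationError(f"unknown motif {motif!r}")

    # backbone N and C by interpolation along the chain; O placed so that
    # it points toward the next helical turn (the i -> i+4 H-bond partner)
    atoms: list[AtomRecord] = []
    xyz: list[np.ndarray] = []
    n_pos = np.empty((n_res, 3))
    c_pos = np.empty((n_res, 3))
    for i in range(n_res):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - (ca[i + 1] - ca[i])
        next_ca = ca[i + 1] if i < n_res - 1 else ca[i] + (ca[i] - ca[i - 1])
        n_pos[i] = ca[i] + 0.35 * (prev_ca - ca[i])
        c_pos[i] = ca[i] + 0.35 * (next_ca - ca[i])
    for i in range(n_res):
        if motif == "helix" and i + 4 < n_res:
            direction = n_pos[i + 4] - c_pos[i]
        else:
            radial = np.array([ca[i, 0], ca[i, 1], 0.0])
            norm = np.linalg.norm(radial)
            direction = radial / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        direction = direction / np.linalg.norm(direction)
        o_pos = c_pos[i] + 1.23 * direction
        res_name = _THREE[sequence[i].upper()]
        for name, elem, pos in (("N", "N", n_pos[i]), ("CA", "C", ca[i]),
                                ("C", "C", c_pos[i]), ("O", "O", o_pos)):
            atoms.append(AtomRecord(name=name, element=elem, res_name=res_name,
                                    res_seq=i + 1, chain_id="A"))
            xyz.append(pos)
    return StructureModel(atoms=atoms, coords=np.array(xyz)[None, :, :],
                          sequence={"A": sequence.upper()})


def toy_charged_hairpin(n_res: int = 18) -> tuple[StructureModel, int]:
    """Toy beta-hairpin with a titratable histidine facing a basic patch.

    The histidine sits on the first strand with lysine/arginine residues
    directly across on the second strand (all native-contact partners),
    plus an acidic pair at the turn. Protonating the histidine then adds
    screened-Coulomb repulsion inside native contacts, emulating the
    destabilization of the folded state by a protonated histidine packed
    against positive charge. Returns (structure, histidine index,
    0-based).
    """
    if n_res < 16:
        raise ValidationError("need at least 16 residues for the motif")
    half = n_res // 2
    h = half // 2
    partner = n_res - 1 - h  # directly across the strand pair
    seq = ["A"] * n_res
    seq[half - 1], seq[half] = "D", "E"  # turn
    seq[h] = "H"
    for k in (partner - 1, partner, partner + 1):
        seq[k] = "K" if (k - partner) % 2 == 0 else "R"
    return make_toy_structure(n_res, "hairpin", "".join(seq)), h


# ---------------------------------------------------------------------------
# Hydrogen-bond trajectories
# ---------------------------------------------------------------------------


def make_hbond_trajectory(occupancy: float, n_frames: int,
                          seed: int = 0) -> StructureModel:
    """Multi-model structure whose donor-H...acceptor triad satisfies the
    3.0 A / 20 degree criterion in exactly round(occupancy * n_frames)
    frames (donor-acceptor 2.9 A, 5 degrees) and violates it in the rest
    (4.5 A).

    The donor is the side-chain NE2 of residue 1 (with hydrogen HE2); the
    acceptor is the backbone O of residue 2. Qualifying frames are chosen
    by a seeded shuffle.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValidationError("occupancy must lie in [0, 1]")
    if n_frames < 1:
        raise ValidationError("need at least one frame")
    n_qual = int(round(occupancy * n_frames))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_frames)
    qualifying = np.zeros(n_frames, dtype=bool)
    qualifying[order[:n_qual]] = True

    atoms = [
        AtomRecord("CA", "C", "HIS", 1, "A"),
        AtomRecord("NE2", "N", "HIS", 1, "A"),
        AtomRecord("HE2", "H", "HIS", 1, "A"),
        AtomRecord("CA", "C", "ASN", 2, "A"),
        AtomRecord("C", "C", "ASN", 2, "A"),
        AtomRecord("O", "O", "ASN", 2, "A"),
    ]
    frames = np.empty((n_frames, len(atoms), 3))
    angle = np.deg2rad(5.0)
    h_dir = np.array([np.cos(angle), np.sin(angle), 0.0])
    for k in range(n_frames):
        d_a = 2.9 if qualifying[k] else 4.5
        donor = np.array([0.0, 0.0, 0.0])
        acceptor = np.array([d_a, 0.0, 0.0])
        frames[k] = [
            donor + (-1.5, 0.0, 0.0),     # donor-side CA
            donor,                         # NE2 (donor)
            donor + 1.0 * h_dir,           # HE2, 5 deg off the D->A axis
            acceptor + (1.2, 1.2, 0.0),    # acceptor-side CA
            acceptor + (1.2, 0.0, 0.0),    # C
            acceptor,                      # O (acceptor)
        ]
    return StructureModel(atoms=atoms, coords=frames)
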