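"""Geometric hydrogen-bond detection and trajectory occupancy.

A hydrogen bond is scored on a donor (N/O with an attached hydrogen) and
an acceptor (N/O): donor-acceptor distance at most 3.0 A and an angle at
most 20 degrees. The default angle convention is the one used by common
trajectory-analysis tools: the angle between the D->H and D->A vectors.
An alternative convention, the deviation of the D-H...A angle from
linearity (180 deg minus the angle at H), is selectable. Hydrogens are
associated with donor heavy atoms by distance (< 1.2 A), since
multi-model PDB files carry no bond records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import StructureModel, ValidationError

__all__ = [
    "HBondCriterion",
    "HBondOccupancy",
    "detect_hbonds",
    "hbond_occupancy",
    "select_atom",
]

_DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}
_H_BOND_MAX = 1.2  # A, H-to-heavy-atom distance that marks a covalent pair


@dataclass(frozen=True)
class HBondCriterion:
    """Distance/angle cutoffs. ``angle_convention`` is 'donor' (angle
    between D->H and D->A) or 'linearity' (deviation of D-H...A from
    180 degrees)."""

    distance_cutoff: float = 3.0  # A, donor-acceptor
    angle_cutoff: float = 20.0  # degrees
    angle_convention: str = "donor"

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValidationError("cutoffs must be positive")
        if self.angle_convention not in ("donor", "linearity"):
            raise ValidationError(
                f"unknown angle convention {self.angle_convention!r}")


@dataclass
class HBondOccupancy:
    donor: int
    hydrogen: int
    acceptor: int
    occupancy: float
    n_frames: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError("occupancy must lie in [0, 1]")


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _qualifies(coords: np.ndarray, donor: int, hydrogen: int, acceptor: int,
               criterion: HBondCriterion) -> bool:
    d, h, a = coords[donor], coords[hydrogen], coords[acceptor]
    if np.linalg.norm(a - d) > criterion.distance_cutoff:
        return False
    if criterion.angle_convention == "donor":
        ang = _angle_deg(h - d, a - d)
    else:
        ang = 180.0 - _angle_deg(d - h, a - h)
    return ang <= criterion.angle_cutoff


def _donor_hydrogens(structure: StructureModel,
                     frame: int = 0) -> list[tuple[int, int]]:
    """(donor, hydrogen) pairs: N/O heavy atoms with an H within 1.2 A."""
    coords = structure.coords[frame]
    heavy = [i for i, a in enumerate(structure.atoms)
             if a.element in _DONOR_ACCEPTOR_ELEMENTS]
    hydro = [i for i, a in enumerate(structure.atoms) if a.element == "H"]
    pairs = []
    for ih in hydro:
        dists = [float(np.linalg.norm(coords[ih] - coords[i])) for i in heavy]
        if not dists:
            continue
        j = int(np.argmin(dists))
        if dists[j] < _H_BOND_MAX:
            pairs.append((heavy[j], ih))
    return pairs


def detect_hbonds(structure: StructureModel, frame: int = 0,
                  criterion: HBondCriterion = HBondCriterion()
                  ) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triads satisfying the criterion in
    one frame. Raises if the frame carries no hydrogens."""
    if not any(a.element == "H" for a in structure.atoms):
        raise ValidationError(
            "no hydrogens present; add hydrogens or use a heavy-atom-only "
            "criterion")
    coords = structure.coords[frame]
    donors = _donor_hydrogens(structure, frame)
    acceptors = [i for i, a in enumerate(structure.atoms)
                 if a.element in _DONOR_ACCEPTOR_ELEMENTS]
    out = []
    for d, h in donors:
        for acc in acceptors:
            if acc == d:
                continue
            if _qualifies(coords, d, h, acc, criterion):
                out.append((d, h, acc))
    return out


def select_atom(structure: StructureModel, selection: str) -> int:
    """Resolve a 'resnum:atomname' selection to an atom index."""
    try:
        res_s, name = selection.split(":")
        res = int(res_s)
    except ValueError as exc:
        raise ValidationError(
            f"selection {selection!r} is not 'resnum:atomname'") from exc
    return structure.atom_index(res, name)


def hbond_occupancy(traj: StructureModel, donor: int | str,
                    acceptor: int | str,
                    criterion: HBondCriterion = HBondCriterion()
                    ) -> HBondOccupancy:
    """Fraction of frames in which the donor-acceptor pair is hydrogen
    bonded. Donor and acceptor may be indices or 'resnum:atomname'."""
    d = select_atom(traj, donor) if isinstance(donor, str) else int(donor)
    a = select_atom(traj, acceptor) if isinstance(acceptor, str) else int(acceptor)
    pairs = dict(_donor_hydrogens(traj, 0))
    if d not in pairs:
        raise ValidationError(
            f"atom {d} is not a donor (no hydrogen within {_H_BOND_MAX} A)")
    h = pairs[d]
    count = sum(
        _qualifies(traj.coords[k], d, h, a, criterion)
        for k in range(traj.n_models)
    )
    return HBondOccupancy(donor=d, hydrogen=h, acceptor=a,
                          occupancy=count / traj.n_models,
                          n_frames=traj.n_models)
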