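"""Structure and table I/O, configuration, and result records.

This module owns the boundary formats of the pipeline: PDB files (input
structures and multi-model trajectories, via gemmi), delimited numeric
tables (kinetic traces, unfolding curves, pH series), plain-text key-value
configuration files, and JSON result records that carry parameter
estimates with their uncertainties and enough provenance to re-run a
deterministic stage bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("swapfold")

# ---------------------------------------------------------------------------
# Physical constants (kcal-based) and defaults
# ---------------------------------------------------------------------------

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.987e-3
#: Default temperature (K): the experiments are performed at 37 degC.
T_DEFAULT: float = 310.0
#: Boltzmann constant (J K^-1) and Planck constant (J s), SI.
KB_SI: float = 1.380649e-23
H_SI: float = 6.62607015e-34


def kbt_over_h(temperature: float = T_DEFAULT) -> float:
    """Eyring prefactor k_B*T/h in s^-1 at the given temperature."""
    return KB_SI * temperature / H_SI


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class FormatError(ValueError):
    """Malformed input file (PDB or table)."""


class ValidationError(ValueError):
    """Input object violates a documented invariant."""


class DegenerateDataError(ValueError):
    """Data carries no information for the requested fit."""


class FitError(RuntimeError):
    """A nonlinear fit failed to converge; carries the best residuals seen."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


# ---------------------------------------------------------------------------
# StructureModel
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the (shared) topology of a structure."""

    name: str
    element: str
    res_name: str
    res_seq: int  # residue number, 1-based as in the PDB file
    chain_id: str


@dataclass
class StructureModel:
    """A protein structure with one or more coordinate models.

    All models share one atom table (``atoms``); ``coords`` has shape
    (n_models, n_atoms, 3) in Angstrom. ``sequence`` maps chain id to a
    one-letter residue string.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    sequence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None, :, :]
        if self.coords.shape[1] != len(self.atoms) or self.coords.shape[2] != 3:
            raise ValidationError(
                f"coordinate array {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        # residue numbers strictly increasing within each chain
        last: dict[str, int] = {}
        for a in self.atoms:
            prev = last.get(a.chain_id)
            if prev is not None and a.res_seq < prev:
                raise ValidationError(
                    f"residue numbers not increasing in chain {a.chain_id}: "
                    f"{a.res_seq} after {prev}"
                )
            last[a.chain_id] = a.res_seq
        if not self.sequence:
            self.sequence = _sequence_from_atoms(self.atoms)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def models(self) -> list[np.ndarray]:
        """List of (n_atoms, 3) coordinate frames."""
        return [self.coords[i] for i in range(self.n_models)]

    def model(self, i: int = 0) -> np.ndarray:
        return self.coords[i]

    def atom_index(self, res_seq: int, atom_name: str, chain_id: str | None = None) -> int:
        """Index of the atom named ``atom_name`` in residue ``res_seq``."""
        for i, a in enumerate(self.atoms):
            if a.res_seq == res_seq and a.name == atom_name and (
                chain_id is None or a.chain_id == chain_id
            ):
                return i
        raise KeyError(f"no atom {res_seq}:{atom_name}")

    def ca_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.name == "CA"], dtype=int
        )

    def residue_numbers(self) -> np.ndarray:
        """Residue number of each residue, in order of first appearance."""
        seen: list[int] = []
        for a in self.atoms:
            if not seen or a.res_seq != seen[-1]:
                seen.append(a.res_seq)
        return np.array(seen, dtype=int)


def _sequence_from_atoms(atoms: Sequence[AtomRecord]) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    last: dict[str, int] = {}
    for a in atoms:
        if a.chain_id not in last or a.res_seq != last[a.chain_id]:
            info = gemmi.find_tabulated_residue(a.res_name)
            one = info.one_letter_code.upper() if info else "X"
            if not one.isalpha():
                one = "X"
            seqs.setdefault(a.chain_id, []).append(one)
            last[a.chain_id] = a.res_seq
    return {c: "".join(s) for c, s in seqs.items()}


def read_pdb(path: str | Path, include_hetatm: bool = False) -> StructureModel:
    """Read a (possibly multi-model) PDB file into a StructureModel.

    HETATM records and waters are excluded by default; alternate locations
    are resolved by keeping the highest-occupancy conformer (first
    encountered on ties). All models must have the same atoms in the same
    order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    atoms_ref: list[AtomRecord] | None = None
    frames: list[np.ndarray] = []
    for imod, model in enumerate(st):
        atoms: list[AtomRecord] = []
        xyz: list[tuple[float, float, float]] = []
        for chain in model:
            for res in chain:
                if res.name in _WATER_NAMES:
                    continue
                if res.het_flag == "H" and not include_hetatm:
                    continue
                # altloc resolution: group by atom name, keep best occupancy
                by_name: dict[str, gemmi.Atom] = {}
                for atom in res:
                    prev = by_name.get(atom.name)
                    if prev is None or atom.occ > prev.occ:
                        by_name[atom.name] = atom
                for atom in res:  # preserve file order
                    kept = by_name.get(atom.name)
                    if kept is None or kept is not atom:
                        continue
                    del by_name[atom.name]
                    atoms.append(
                        AtomRecord(
                            name=atom.name,
                            element=atom.element.name,
                            res_name=res.name,
                            res_seq=res.seqid.num,
                            chain_id=chain.name,
                        )
                    )
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        if atoms_ref is None:
            atoms_ref = atoms
        elif [
            (a.name, a.res_seq, a.chain_id) for a in atoms
        ] != [(a.name, a.res_seq, a.chain_id) for a in atoms_ref]:
            raise FormatError(
                f"model {imod + 1} has a different atom set than model 1"
            )
        frames.append(np.array(xyz, dtype=float))
    if atoms_ref is None or len(atoms_ref) == 0:
        raise FormatError(f"no ATOM records in {path}")
    return StructureModel(atoms=atoms_ref, coords=np.stack(frames))


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a (multi-model) PDB file."""
    st = gemmi.Structure()
    for imod in range(structure.n_models):
        model = gemmi.Model(imod + 1)
        # build bottom-up: gemmi's add_* methods copy their argument, so
        # residues and chains must be complete before insertion
        chain_order: list[str] = []
        per_chain: dict[str, list[gemmi.Residue]] = {}
        res_cur: gemmi.Residue | None = None
        res_key: tuple[str, int] | None = None
        for a, pos in zip(structure.atoms, structure.coords[imod]):
            if a.chain_id not in per_chain:
                per_chain[a.chain_id] = []
                chain_order.append(a.chain_id)
                res_key = None
            if res_key != (a.chain_id, a.res_seq):
                res_cur = gemmi.Residue()
                res_cur.name = a.res_name
                res_cur.seqid = gemmi.SeqId(a.res_seq, " ")
                res_cur.het_flag = "A"
                per_chain[a.chain_id].append(res_cur)
                res_key = (a.chain_id, a.res_seq)
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            res_cur.add_atom(atom)
        for cid in chain_order:
            chain = gemmi.Chain(cid)
            for res in per_chain[cid]:
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------


def write_table(records: pd.DataFrame | Mapping[str, Sequence], path: str | Path,
                delimiter: str = ",") -> None:
    """Write a rectangular table; numeric columns round-trip losslessly."""
    df = pd.DataFrame(records)
    df.to_csv(path, sep=delimiter, index=False)


def read_table(path: str | Path, delimiter: str = ",",
               numeric_columns: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a delimited table written by :func:`write_table`.

    Raises FormatError (with the offending line, as reported by the pandas
    tokenizer) on ragged rows, and on non-numeric cells in columns named in
    ``numeric_columns``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if numeric_columns:
        for col in numeric_columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}: column {col!r} not numeric: {exc}") from exc
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def parse_config_text(text: str) -> dict[str, object]:
    """Parse 'key = value' lines; '#' starts a comment; values are coerced
    to int/float/bool when possible."""
    out: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"config line {lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = _coerce(val)
    return out


def load_config(path: str | Path) -> dict[str, object]:
    return parse_config_text(Path(path).read_text())


def _coerce(val: str) -> object:
    low = val.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val


def config_hash(config: Mapping[str, object]) -> str:
    blob = json.dumps({k: config[k] for k in sorted(config)}, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------


@dataclass
class ResultRecord:
    """Outcome of one analysis stage.

    ``params`` maps parameter name to a dict with either
    ``{"value": x, "sigma": s}`` or ``{"value": x, "fixed": True}``; every
    estimate must carry a finite uncertainty or the explicit fixed marker.
    """

    analysis: str
    params: dict[str, dict]
    gof: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in self.params.items():
            if p.get("fixed"):
                continue
            sigma = p.get("sigma")
            if sigma is None or not np.isfinite(sigma):
                raise ValidationError(
                    f"parameter {name!r} lacks a finite uncertainty and is "
                    "not marked fixed"
                )

    def to_json(self, path: str | Path | None = None) -> str:
        blob = json.dumps(
            {
                "analysis": self.analysis,
                "params": self.params,
                "gof": self.gof,
                "provenance": self.provenance,
            },
            indent=2,
            default=float,
        )
        if path is not None:
            Path(path).write_text(blob)
        return blob

    @classmethod
    def from_json(cls, source: str | Path) -> "ResultRecord":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        d = json.loads(text)
        return cls(d["analysis"], d["params"], d.get("gof", {}), d.get("provenance", {}))
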