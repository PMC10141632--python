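"""Structure/trajectory containers, selections, parameter assignment and PDB/PQR I/O.

The in-memory model is struct-of-arrays: an :class:`AtomTable` holds per-atom
identity and physical parameters shared by every frame of a trajectory;
:class:`StructureFrame` and :class:`Trajectory` attach one or many coordinate
sets to it.  Multi-model PDB files (MODEL/ENDMDL) are read and written through
biotite; frame times travel in ``REMARK 250`` lines.  PQR uses the
whitespace-delimited pdb2pqr dialect.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bstruc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomTable",
    "StructureFrame",
    "Trajectory",
    "Selection",
    "ParameterTable",
    "ParameterEntry",
    "DEFAULT_PARAMETERS",
    "read_trajectory",
    "write_trajectory",
    "read_pqr",
    "write_pqr",
    "resolve_selection",
    "assign_parameters",
    "parse_residue_interval",
]

_TIME_REMARK = 250
_TIME_TAG = "FRAME TIME NS"


class StructureError(ValueError):
    """Raised for malformed structures, selections or parameter tables."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AtomTable:
    """Per-atom identity and physical parameters (positions live elsewhere).

    Parameters that have not been assigned are NaN; ``has_charges`` etc.
    report assignment status.  All fields are numpy arrays of equal length.
    """

    serial: np.ndarray
    name: np.ndarray
    residue_name: np.ndarray
    chain: np.ndarray
    residue_number: np.ndarray
    mass: np.ndarray
    charge: np.ndarray = None  # type: ignore[assignment]
    radius: np.ndarray = None  # type: ignore[assignment]
    lj_epsilon: np.ndarray = None  # type: ignore[assignment]
    lj_rmin_half: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.serial)
        for attr in ("charge", "radius", "lj_epsilon", "lj_rmin_half"):
            if getattr(self, attr) is None:
                setattr(self, attr, np.full(n, np.nan))
        for attr in ("name", "residue_name", "chain", "residue_number",
                     "mass", "charge", "radius", "lj_epsilon", "lj_rmin_half"):
            if len(getattr(self, attr)) != n:
                raise StructureError(f"atom field '{attr}' length mismatch")
        if np.any(self.mass <= 0):
            raise StructureError("all atomic masses must be positive")

    def __len__(self) -> int:
        return len(self.serial)

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def has_charges(self) -> bool:
        return not np.any(np.isnan(self.charge))

    @property
    def has_radii(self) -> bool:
        return not np.any(np.isnan(self.radius))

    @property
    def has_lj(self) -> bool:
        return not (np.any(np.isnan(self.lj_epsilon))
                    or np.any(np.isnan(self.lj_rmin_half)))

    def atom_label(self, i: int) -> str:
        """Human-readable identity, e.g. ``LYS:A:830:NZ``."""
        return (f"{self.residue_name[i]}:{self.chain[i]}:"
                f"{self.residue_number[i]}:{self.name[i]}")

    def residue_label(self, i: int) -> str:
        return f"{self.residue_name[i]}:{self.chain[i]}:{self.residue_number[i]}"

    def subset(self, indices: np.ndarray) -> "AtomTable":
        idx = np.asarray(indices, dtype=int)
        return AtomTable(
            serial=self.serial[idx].copy(),
            name=self.name[idx].copy(),
            residue_name=self.residue_name[idx].copy(),
            chain=self.chain[idx].copy(),
            residue_number=self.residue_number[idx].copy(),
            mass=self.mass[idx].copy(),
            charge=self.charge[idx].copy(),
            radius=self.radius[idx].copy(),
            lj_epsilon=self.lj_epsilon[idx].copy(),
            lj_rmin_half=self.lj_rmin_half[idx].copy(),
        )

    def copy(self) -> "AtomTable":
        return self.subset(np.arange(self.n_atoms))


@dataclass
class StructureFrame:
    """One coordinate snapshot over an :class:`AtomTable`."""

    atoms: AtomTable
    coords: np.ndarray
    time_ns: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.atoms.n_atoms, 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.atoms.n_atoms} atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.atoms.n_atoms

    def subset(self, indices: np.ndarray) -> "StructureFrame":
        idx = np.asarray(indices, dtype=int)
        return StructureFrame(self.atoms.subset(idx), self.coords[idx].copy(),
                              self.time_ns)

    def copy(self) -> "StructureFrame":
        return StructureFrame(self.atoms.copy(), self.coords.copy(), self.time_ns)


@dataclass
class Trajectory:
    """Ordered frames sharing one atom table; times in ns, strictly increasing."""

    atoms: AtomTable
    coords: np.ndarray          # (n_frames, n_atoms, 3)
    times: np.ndarray           # (n_frames,) ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.atoms.n_atoms:
            raise StructureError("trajectory coordinate array has wrong shape")
        if len(self.times) != self.coords.shape[0]:
            raise StructureError("times/frames length mismatch")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atoms.n_atoms

    def frame(self, i: int) -> StructureFrame:
        return StructureFrame(self.atoms, self.coords[i], float(self.times[i]))

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_INTERVAL_RE = re.compile(r"^([A-Za-z]?)(\d+)$")


def parse_residue_interval(text: str) -> tuple[str | None, int, str | None, int]:
    """Parse ``"T815-P906"`` / ``"815-906"`` into (letter, start, letter, end).

    Single residues (``"830"``) yield start == end.  The optional one-letter
    residue-type prefixes are returned for validation against the structure.
    """
    parts = text.split("-")
    if len(parts) == 1:
        parts = [parts[0], parts[0]]
    if len(parts) != 2:
        raise StructureError(f"cannot parse residue interval {text!r}")
    out: list[tuple[str | None, int]] = []
    for p in parts:
        m = _INTERVAL_RE.match(p.strip())
        if not m:
            raise StructureError(f"cannot parse residue token {p!r}")
        letter = m.group(1).upper() or None
        out.append((letter, int(m.group(2))))
    (la, a), (lb, b) = out
    if a > b:
        raise StructureError(f"interval {text!r} has start > end")
    return la, a, lb, b


#: Minimal 3-letter -> 1-letter map for residue-prefix validation.
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "PTR": "Y",
}


@dataclass
class Selection:
    """Named subset: chain and/or closed residue-number intervals and/or names.

    ``intervals`` entries are ``(start, end)`` in author numbering, closed on
    both ends, optionally carrying residue-letter prefixes (``"T815-P906"``)
    which are validated when the structure carries standard residue names.
    """

    name: str
    chain: str | None = None
    intervals: Sequence[str | tuple[int, int]] = field(default_factory=list)
    residue_names: Sequence[str] | None = None
    atom_names: Sequence[str] | None = None


def resolve_selection(obj: Trajectory | StructureFrame, sel: Selection,
                      strict: bool = False) -> np.ndarray:
    """Resolve a :class:`Selection` to a sorted array of atom indices.

    Residue-letter prefixes in intervals are checked against the residue type
    at that number when the structure uses standard amino-acid names; a
    mismatch raises under ``strict`` and is ignored otherwise (synthetic
    structures carry non-standard names).
    """
    atoms = obj.atoms
    mask = np.ones(atoms.n_atoms, dtype=bool)
    if sel.chain is not None:
        mask &= atoms.chain == sel.chain
    if sel.residue_names is not None:
        mask &= np.isin(atoms.residue_name, list(sel.residue_names))
    if sel.atom_names is not None:
        mask &= np.isin(atoms.name, list(sel.atom_names))
    if sel.intervals:
        in_any = np.zeros(atoms.n_atoms, dtype=bool)
        for iv in sel.intervals:
            if isinstance(iv, str):
                la, a, lb, b = parse_residue_interval(iv)
            else:
                a, b = iv
                la = lb = None
            for letter, number in ((la, a), (lb, b)):
                if letter is None:
                    continue
                here = mask & (atoms.residue_number == number)
                names = set(atoms.residue_name[here])
                known = {n for n in names if n in _THREE_TO_ONE}
                if known and all(_THREE_TO_ONE[n] != letter for n in known):
                    msg = (f"selection {sel.name!r}: residue {number} is "
                           f"{sorted(known)}, not '{letter}'")
                    if strict:
                        raise StructureError(msg)
            in_any |= (atoms.residue_number >= a) & (atoms.residue_number <= b)
        mask &= in_any
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise StructureError(f"selection {sel.name!r} matches no atoms")
    return idx


# ---------------------------------------------------------------------------
# parameter table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterEntry:
    """Charge (e), radius (Å), mass (amu) and LJ parameters for one atom type."""

    charge: float
    radius: float
    mass: float
    lj_epsilon: float
    lj_rmin_half: float


class ParameterTable:
    """(residue_name, atom_name) -> :class:`ParameterEntry` lookup.

    Lookups must be total over the atoms a structure presents, or assignment
    fails listing every unmatched atom.  ``with_entry`` returns an amended
    copy, which is how alternative charge states (e.g. a −1 vs −2 phosphate
    on phosphotyrosine) are expressed explicitly rather than defaulted.
    """

    def __init__(self, entries: dict[tuple[str, str], ParameterEntry]):
        self._entries = dict(entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def get(self, residue_name: str, atom_name: str) -> ParameterEntry | None:
        return self._entries.get((residue_name, atom_name))

    def with_entry(self, residue_name: str, atom_name: str,
                   entry: ParameterEntry) -> "ParameterTable":
        new = dict(self._entries)
        new[(residue_name, atom_name)] = entry
        return ParameterTable(new)

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterTable":
        entries = {}
        for res, atoms in data.items():
            for name, vals in atoms.items():
                entries[(res, name)] = ParameterEntry(
                    charge=float(vals["charge"]), radius=float(vals["radius"]),
                    mass=float(vals["mass"]),
                    lj_epsilon=float(vals.get("lj_epsilon", 0.0)),
                    lj_rmin_half=float(vals.get("lj_rmin_half", 1.0)))
        return cls(entries)


# CHARMM-like values for the synthetic residue set used by the fixture
# generators, plus the ions/fragments the analyses touch.  Charges are the
# idealized unit charges the oracles assume, not a force-field fit.
_DEFAULT_DATA = {
    # rigid pseudo-domain bead (carbon-like)
    "DOM": {"C1": dict(charge=0.0, radius=1.7, mass=12.011,
                       lj_epsilon=0.07, lj_rmin_half=2.0),
            "C2": dict(charge=0.0, radius=1.7, mass=12.011,
                       lj_epsilon=0.07, lj_rmin_half=2.0),
            "C3": dict(charge=0.0, radius=1.7, mass=12.011,
                       lj_epsilon=0.07, lj_rmin_half=2.0),
            "C4": dict(charge=0.0, radius=1.7, mass=12.011,
                       lj_epsilon=0.07, lj_rmin_half=2.0)},
    # hydrogen-bond donor (amide-like) and acceptor (hydroxyl-like)
    "GLN": {"NE2": dict(charge=-0.62, radius=1.55, mass=14.007,
                        lj_epsilon=0.20, lj_rmin_half=1.85),
            "HE21": dict(charge=0.31, radius=1.0, mass=1.008,
                         lj_epsilon=0.046, lj_rmin_half=0.2245)},
    "SER": {"OG": dict(charge=-0.65, radius=1.52, mass=15.999,
                       lj_epsilon=0.1521, lj_rmin_half=1.77)},
    # salt-bridge partners: ammonium nitrogen / carboxylate oxygen
    "LYS": {"NZ": dict(charge=1.0, radius=1.55, mass=14.007,
                       lj_epsilon=0.20, lj_rmin_half=1.85)},
    "GLU": {"OE1": dict(charge=-1.0, radius=1.52, mass=15.999,
                        lj_epsilon=0.12, lj_rmin_half=1.70),
            "OE2": dict(charge=-1.0, radius=1.52, mass=15.999,
                        lj_epsilon=0.12, lj_rmin_half=1.70)},
    # bare point charge / Born sphere probes
    "CHG": {"Q1": dict(charge=1.0, radius=1.5, mass=22.99,
                       lj_epsilon=0.0, lj_rmin_half=1.5),
            "Q2": dict(charge=-1.0, radius=1.5, mass=35.45,
                       lj_epsilon=0.0, lj_rmin_half=1.5)},
    "BRN": {"Q": dict(charge=1.0, radius=2.0, mass=22.99,
                      lj_epsilon=0.0, lj_rmin_half=2.0)},
    # monovalent ions
    "POT": {"K": dict(charge=1.0, radius=1.76, mass=39.098,
                      lj_epsilon=0.087, lj_rmin_half=1.76)},
    "CLA": {"CL": dict(charge=-1.0, radius=2.27, mass=35.45,
                       lj_epsilon=0.15, lj_rmin_half=2.27)},
    # phosphotyrosine phosphate: the protonation state is a modelling choice
    # (−1 vs −2); both entries are provided and must be picked explicitly.
    "PTR": {"P": dict(charge=1.5, radius=1.9, mass=30.974,
                      lj_epsilon=0.585, lj_rmin_half=2.15),
            "O1P": dict(charge=-0.9, radius=1.7, mass=15.999,
                        lj_epsilon=0.12, lj_rmin_half=1.70),
            "O2P": dict(charge=-0.9, radius=1.7, mass=15.999,
                        lj_epsilon=0.12, lj_rmin_half=1.70),
            "O3P": dict(charge=-0.9, radius=1.7, mass=15.999,
                        lj_epsilon=0.12, lj_rmin_half=1.70)},
}

DEFAULT_PARAMETERS = ParameterTable.from_dict(_DEFAULT_DATA)


def assign_parameters(frame: StructureFrame,
                      table: ParameterTable = DEFAULT_PARAMETERS
                      ) -> StructureFrame:
    """Populate charge/radius/mass/LJ fields from the table (copy returned).

    Every atom must be present in the table; otherwise a
    :class:`StructureError` lists all unmatched atoms.
    """
    atoms = frame.atoms
    missing = [atoms.atom_label(i) for i in range(atoms.n_atoms)
               if table.get(atoms.residue_name[i], atoms.name[i]) is None]
    if missing:
        raise StructureError(
            "parameter table has no entry for: " + ", ".join(missing))
    new = atoms.copy()
    for i in range(atoms.n_atoms):
        e = table.get(atoms.residue_name[i], atoms.name[i])
        assert e is not None
        new.charge[i] = e.charge
        new.radius[i] = e.radius
        new.mass[i] = e.mass
        new.lj_epsilon[i] = e.lj_epsilon
        new.lj_rmin_half[i] = e.lj_rmin_half
    return StructureFrame(new, frame.coords.copy(), frame.time_ns)


def total_charge(frame: StructureFrame) -> float:
    if not frame.atoms.has_charges:
        raise StructureError("charges not assigned")
    return float(np.sum(frame.atoms.charge))


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _to_atom_array(frame_atoms: AtomTable, coords: np.ndarray) -> bstruc.AtomArray:
    n = frame_atoms.n_atoms
    arr = bstruc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = frame_atoms.chain.astype("U4")
    arr.res_id = frame_atoms.residue_number.astype(int)
    arr.res_name = frame_atoms.residue_name.astype("U5")
    arr.atom_name = frame_atoms.name.astype("U6")
    arr.element = np.array([_guess_element(nm) for nm in frame_atoms.name])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in ("CL", "NA", "MG", "ZN", "BR", "FE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB with frame times in ``REMARK 250`` lines."""
    stack = bstruc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord = traj.coords.astype(np.float32)
    one = _to_atom_array(traj.atoms, traj.coords[0])
    for cat in ("chain_id", "res_id", "res_name", "atom_name", "element",
                "hetero"):
        stack.set_annotation(cat, one.get_annotation(cat))
    pdb = PDBFile()
    pdb.set_structure(stack)
    remarks = [
        f"REMARK {_TIME_REMARK} {_TIME_TAG} MODEL {i + 1} {t:.6f}"
        for i, t in enumerate(traj.times)
    ]
    pdb.lines = remarks + pdb.lines
    pdb.write(str(path))


def _check_model_atom_counts(lines: list[str]) -> None:
    counts: list[tuple[int, int]] = []
    current = 0
    model_no = 0
    in_model = False
    for ln in lines:
        rec = ln[:6].strip()
        if rec == "MODEL":
            in_model = True
            model_no = int(ln[6:].split()[0]) if ln[6:].split() else model_no + 1
            current = 0
        elif rec == "ENDMDL":
            counts.append((model_no, current))
            in_model = False
        elif rec in ("ATOM", "HETATM") and in_model:
            current += 1
    if counts:
        ref_model, ref = counts[0]
        for model_no, c in counts[1:]:
            if c != ref:
                raise StructureError(
                    f"model {model_no} has {c} atoms; model {ref_model} "
                    f"has {ref}")


def read_trajectory(path: str | Path, frame_interval_ns: float = 1.0,
                    masses: dict[str, float] | None = None) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory`.

    Frame times come from ``REMARK 250`` lines written by
    :func:`write_trajectory`; absent those, frame ``i`` (1-based) gets time
    ``i * frame_interval_ns``.  A file without MODEL records is a one-frame
    trajectory.  Masses default to the element mass; charges/radii stay
    unassigned until :func:`assign_parameters` or a PQR supplies them.
    """
    pdb = PDBFile.read(str(path))
    _check_model_atom_counts(pdb.lines)
    stack = pdb.get_structure(model=None)
    n_frames = stack.stack_depth()
    times = np.array([])
    for ln in pdb.lines:
        if ln.startswith(f"REMARK {_TIME_REMARK}") and _TIME_TAG in ln:
            parts = ln.split()
            times = np.append(times, float(parts[-1]))
    if len(times) != n_frames:
        times = frame_interval_ns * np.arange(1, n_frames + 1)
    element_masses = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                      "P": 30.974, "S": 32.06, "K": 39.098, "Cl": 35.45,
                      "Na": 22.99, "X": 12.0}
    if masses:
        element_masses.update(masses)
    mass = np.array([element_masses.get(e, 12.0) for e in stack.element])
    atoms = AtomTable(
        serial=np.arange(1, stack.array_length() + 1),
        name=np.array(stack.atom_name, dtype="U6"),
        residue_name=np.array(stack.res_name, dtype="U5"),
        chain=np.array(stack.chain_id, dtype="U4"),
        residue_number=np.array(stack.res_id, dtype=int),
        mass=mass,
    )
    return Trajectory(atoms, np.asarray(stack.coord, dtype=float), times)


# ---------------------------------------------------------------------------
# PQR I/O (pdb2pqr whitespace dialect)
# ---------------------------------------------------------------------------

def write_pqr(frame: StructureFrame, path: str | Path) -> None:
    """Write a whitespace-delimited PQR file (charge and radius per atom)."""
    atoms = frame.atoms
    unassigned = [atoms.atom_label(i) for i in range(atoms.n_atoms)
                  if np.isnan(atoms.charge[i]) or np.isnan(atoms.radius[i])]
    if unassigned:
        raise StructureError(
            "cannot write PQR; unassigned charge/radius for: "
            + ", ".join(unassigned))
    with open(path, "w") as fh:
        fh.write("REMARK   1 PQR written by cleftforce\n")
        for i in range(atoms.n_atoms):
            x, y, z = frame.coords[i]
            fh.write(
                f"ATOM {atoms.serial[i]:>6d} {atoms.name[i]:<4s} "
                f"{atoms.residue_name[i]:<4s} {atoms.chain[i]:<1s} "
                f"{atoms.residue_number[i]:>5d} "
                f"{x:10.3f} {y:10.3f} {z:10.3f} "
                f"{atoms.charge[i]:8.4f} {atoms.radius[i]:7.4f}\n")
        fh.write("END\n")


def read_pqr(path: str | Path,
             masses: dict[tuple[str, str], float] | None = None
             ) -> StructureFrame:
    """Read a whitespace-delimited PQR file (with or without a chain field)."""
    serials, names, resnames, chains, resnums = [], [], [], [], []
    coords, charges, radii = [], [], []
    with open(path) as fh:
        for ln in fh:
            if not ln.startswith(("ATOM", "HETATM")):
                continue
            parts = ln.split()
            if len(parts) == 11:       # with chain id
                (_, serial, name, resname, chain, resnum,
                 x, y, z, q, r) = parts
            elif len(parts) == 10:     # pdb2pqr default: no chain
                _, serial, name, resname, resnum, x, y, z, q, r = parts
                chain = "A"
            else:
                raise StructureError(f"unparseable PQR line: {ln.rstrip()!r}")
            serials.append(int(serial))
            names.append(name)
            resnames.append(resname)
            chains.append(chain)
            resnums.append(int(resnum))
            coords.append([float(x), float(y), float(z)])
            charges.append(float(q))
            radii.append(float(r))
    if not serials:
        raise StructureError(f"no ATOM records in {path}")
    default_mass = 12.0
    mass = np.array([
        (masses or {}).get((rn, nm), default_mass)
        for rn, nm in zip(resnames, names)])
    atoms = AtomTable(
        serial=np.array(serials), name=np.array(names, dtype="U6"),
        residue_name=np.array(resnames, dtype="U5"),
        chain=np.array(chains, dtype="U4"),
        residue_number=np.array(resnums), mass=mass,
        charge=np.array(charges), radius=np.array(radii))
    return StructureFrame(atoms, np.array(coords))
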