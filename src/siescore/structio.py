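"""Structures, selections, and trajectories.

Atomic systems are held as flat ordered atom lists (PDB order) with
per-atom partial charges, Lennard-Jones parameters and solvation radii,
plus a receptor/ligand partition used by every binding operation.
Coordinates are Angstrom throughout; residue indices are the
author-assigned PDB residue numbers and are never renumbered.

PDB reading goes through Bio.PDB (alternate locations resolved to the
highest-occupancy conformer, ties to the first encountered); writing is
fixed-width PDB so that write -> read round-trips are exact to format
precision (1e-3 A). Charges and radii come from PQR files or a bundled
parameter table -- force-field atom typing is upstream, not done here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser

from ._parameters import ELEMENT_LJ, ELEMENT_MASSES, element_of

__all__ = [
    "AtomRecord",
    "Selection",
    "MolecularSystem",
    "Trajectory",
    "read_pdb",
    "write_pdb",
    "read_pqr",
    "assign_parameters",
    "select",
    "read_trajectory",
    "write_trajectory",
]


@dataclass
class AtomRecord:
    """One atom: identity, coordinates and energy parameters.

    ``charge`` (e), ``lj_epsilon`` (kcal/mol), ``lj_rmin_half`` (A) and
    ``radius`` (A) default to a zero sentinel until assigned.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    coordinates: np.ndarray
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0
    radius: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial}: negative LJ epsilon")


@dataclass(frozen=True)
class Selection:
    """Ordered, duplicate-free atom index set with a human label."""

    atom_indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValueError(f"selection {self.label!r} contains duplicate indices")

    def __len__(self) -> int:
        return len(self.atom_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.atom_indices, dtype=int)


class MolecularSystem:
    """An ordered atom list with an optional receptor/ligand partition.

    Atom order is stable and shared with any associated
    :class:`Trajectory`. Per-atom quantities are exposed as numpy arrays
    (``coordinates``, ``charges`` ...), rebuilt only when coordinates
    are replaced wholesale via :meth:`set_coordinates`.
    """

    def __init__(self, atoms: Sequence[AtomRecord], model_id: int = 1):
        if not atoms:
            raise ValueError("a MolecularSystem needs at least one atom")
        self.atoms: list[AtomRecord] = list(atoms)
        self.model_id = model_id
        self.receptor: Selection | None = None
        self.ligand: Selection | None = None
        keys = {(a.chain_id, a.residue_index, a.name) for a in self.atoms}
        if len(keys) != len(self.atoms):
            raise ValueError("(chain, residue_index, atom name) not unique within the model")
        self._rebuild_arrays()

    # -- array views -----------------------------------------------------
    def _rebuild_arrays(self) -> None:
        a = self.atoms
        self.coordinates = np.array([x.coordinates for x in a], dtype=float)
        self.charges = np.array([x.charge for x in a], dtype=float)
        self.lj_epsilon = np.array([x.lj_epsilon for x in a], dtype=float)
        self.lj_rmin_half = np.array([x.lj_rmin_half for x in a], dtype=float)
        self.radii = np.array([x.radius for x in a], dtype=float)
        self.names = np.array([x.name for x in a])
        self.elements = np.array([x.element for x in a])
        self.residue_names = np.array([x.residue_name for x in a])
        self.residue_indices = np.array([x.residue_index for x in a], dtype=int)
        self.chain_ids = np.array([x.chain_id for x in a])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def masses(self) -> np.ndarray:
        """Standard atomic masses by element; unknown element is an error."""
        try:
            return np.array([ELEMENT_MASSES[e] for e in self.elements])
        except KeyError as exc:
            raise KeyError(f"no standard mass for element {exc.args[0]!r}") from None

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape {(self.n_atoms, 3)}, got {coords.shape}")
        self.coordinates = coords.copy()
        for atom, xyz in zip(self.atoms, self.coordinates):
            atom.coordinates = xyz

    def copy(self) -> "MolecularSystem":
        new = MolecularSystem(
            [AtomRecord(a.serial, a.name, a.element, a.residue_name, a.residue_index,
                        a.chain_id, a.coordinates.copy(), a.charge, a.lj_epsilon,
                        a.lj_rmin_half, a.radius) for a in self.atoms],
            model_id=self.model_id,
        )
        new.receptor, new.ligand = self.receptor, self.ligand
        return new

    # -- partition -------------------------------------------------------
    def set_partition(self, receptor: Selection, ligand: Selection) -> None:
        """Declare the receptor/ligand split used by binding operations."""
        ri, li = set(receptor.atom_indices), set(ligand.atom_indices)
        if not ri or not li:
            raise ValueError("receptor and ligand selections must be non-empty")
        if ri & li:
            raise ValueError("receptor and ligand selections overlap")
        bad = (ri | li) - set(range(self.n_atoms))
        if bad:
            raise IndexError(f"partition indices out of range: {sorted(bad)[:5]}")
        self.receptor, self.ligand = receptor, ligand

    def partition_by_chains(self, receptor_chain: str, ligand_chain: str) -> None:
        self.set_partition(
            select(self, f"chain {receptor_chain}"),
            select(self, f"chain {ligand_chain}"),
        )

    def require_partition(self) -> tuple[Selection, Selection]:
        if self.receptor is None or self.ligand is None:
            raise ValueError("receptor/ligand partition is not set")
        return self.receptor, self.ligand

    # -- subsetting ------------------------------------------------------
    def subset(self, selection: Selection, model_id: int | None = None) -> "MolecularSystem":
        """New system containing only the selected atoms (order preserved)."""
        atoms = [self.atoms[i] for i in selection.atom_indices]
        return MolecularSystem(
            [AtomRecord(a.serial, a.name, a.element, a.residue_name, a.residue_index,
                        a.chain_id, a.coordinates.copy(), a.charge, a.lj_epsilon,
                        a.lj_rmin_half, a.radius) for a in atoms],
            model_id=self.model_id if model_id is None else model_id,
        )

    def residue_groups(self, selection: Selection | None = None) -> list[tuple[str, np.ndarray]]:
        """(label, atom indices) per residue, in first-appearance order.

        Labels follow the ``Phe23`` / ``G4`` convention: title-cased
        3-letter codes for protein residues, bare base letter for
        nucleotides, each suffixed with the residue number.
        """
        idx = np.arange(self.n_atoms) if selection is None else selection.indices
        groups: dict[tuple[str, int], list[int]] = {}
        for i in idx:
            key = (self.chain_ids[i], int(self.residue_indices[i]))
            groups.setdefault(key, []).append(int(i))
        out = []
        for (chain, resid), members in groups.items():
            resname = self.residue_names[members[0]]
            label = (resname.title() if len(resname) == 3 else resname) + str(resid)
            out.append((label, np.asarray(members, dtype=int)))
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames (A) consistent with one MolecularSystem."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must have shape (n_frames >= 1, n_atoms, 3)")
        if not self.frame_labels:
            self.frame_labels = list(range(self.frames.shape[0]))
        if len(self.frame_labels) != self.frames.shape[0]:
            raise ValueError("frame_labels length must equal the number of frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: Path) -> None:
    """Check ATOM/HETATM records are parseable, reporting line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(f"{path}:{lineno}: truncated ATOM/HETATM record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[6:11])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed ATOM/HETATM record") from None


def read_pdb(path: str | Path, model: int | str = 1):
    """Read a PDB file into one or more :class:`MolecularSystem`.

    ``model`` selects a MODEL number (file numbering, default 1 -- the
    conventional working model for NMR ensembles) or ``"all"`` to return
    every model as a list. Charges/LJ/radii are left as zero sentinels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(path))
    systems = []
    for bio_model in structure:
        model_num = bio_model.serial_num if bio_model.serial_num else bio_model.id + 1
        atoms = []
        for chain in bio_model:
            for residue in chain:
                for atom in residue:  # DisorderedAtom yields highest occupancy
                    elem = atom.element or element_of(atom.get_name())
                    atoms.append(AtomRecord(
                        serial=atom.serial_number,
                        name=atom.get_name(),
                        element=elem.upper(),
                        residue_name=residue.get_resname().strip(),
                        residue_index=residue.id[1],
                        chain_id=chain.id,
                        coordinates=np.asarray(atom.coord, dtype=float),
                    ))
        systems.append(MolecularSystem(atoms, model_id=model_num))
    if model == "all":
        return systems
    for system in systems:
        if system.model_id == model:
            return system
    raise ValueError(f"model {model} not found in {path} "
                     f"(available: {[s.model_id for s in systems]})")


def _format_atom_line(a: AtomRecord, coords: np.ndarray) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    resname = f"{a.residue_name:>3s}"[:4]
    return (f"ATOM  {a.serial:5d} {name:<4s} {resname:<4s}{a.chain_id:1s}"
            f"{a.residue_index:4d}    {coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}")


def write_pdb(system: MolecularSystem | Sequence[MolecularSystem], path: str | Path) -> None:
    """Write one system, or a list of systems as a multi-MODEL file."""
    systems = [system] if isinstance(system, MolecularSystem) else list(system)
    lines = []
    multi = len(systems) > 1
    for k, sys_ in enumerate(systems, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        for a, xyz in zip(sys_.atoms, sys_.coordinates):
            lines.append(_format_atom_line(a, xyz))
        lines.append("ENDMDL" if multi else "TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PQR / parameter assignment
# ---------------------------------------------------------------------------

def read_pqr(path: str | Path) -> list[dict]:
    """Parse a whitespace-delimited PQR file.

    Returns one dict per atom with serial, name, residue_name,
    residue_index, coordinates, charge and radius. A chain column is
    detected by token count (10 fields without chain, 11 with).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            tok = line.split()
            if len(tok) not in (10, 11):
                raise ValueError(f"{path}:{lineno}: expected 10 or 11 fields, got {len(tok)}")
            has_chain = len(tok) == 11
            try:
                records.append({
                    "serial": int(tok[1]),
                    "name": tok[2],
                    "residue_name": tok[3],
                    "chain_id": tok[4] if has_chain else "",
                    "residue_index": int(tok[5 if has_chain else 4]),
                    "coordinates": np.array([float(t) for t in tok[6 if has_chain else 5:][:3]]),
                    "charge": float(tok[-2]),
                    "radius": float(tok[-1]),
                })
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed PQR record") from None
    return records


def assign_parameters(
    system: MolecularSystem,
    source: str | Path | Mapping[tuple[str, str], tuple[float, float]],
    lj_table: Mapping[str, tuple[float, float]] | None = None,
    strict: bool = True,
) -> MolecularSystem:
    """Populate charges, radii and LJ parameters from a PQR file or table.

    Atoms are matched by serial when the source is a PQR with matching
    serials, otherwise by (residue_name, atom name). ``strict`` makes an
    unmatched atom an error (named); otherwise it is zero-filled with a
    warning. LJ well depth / rmin-half come from ``lj_table`` keyed by
    element (default: the bundled per-element table). Coordinates are
    never modified. Returns a new system.
    """
    new = system.copy()
    lj = ELEMENT_LJ if lj_table is None else lj_table

    by_serial: dict[int, tuple[float, float]] = {}
    by_key: dict[tuple[str, str], tuple[float, float]] = {}
    if isinstance(source, (str, Path)):
        for rec in read_pqr(source):
            by_serial[rec["serial"]] = (rec["charge"], rec["radius"])
            by_key[(rec["residue_name"], rec["name"])] = (rec["charge"], rec["radius"])
    else:
        by_key = {k: tuple(v) for k, v in source.items()}

    unmatched = []
    for atom in new.atoms:
        got = by_serial.get(atom.serial) or by_key.get((atom.residue_name, atom.name))
        if got is None:
            unmatched.append(atom)
            continue
        atom.charge, atom.radius = got
        eps, rmin = lj.get(atom.element, (None, None))
        if eps is None:
            unmatched.append(atom)
            continue
        atom.lj_epsilon, atom.lj_rmin_half = eps, rmin

    if unmatched:
        desc = ", ".join(f"{a.residue_name}{a.residue_index}:{a.name}" for a in unmatched[:8])
        if strict:
            raise KeyError(f"{len(unmatched)} atom(s) unmatched by parameter source: {desc}")
        warnings.warn(f"zero-filled {len(unmatched)} unmatched atom(s): {desc}", stacklevel=2)
    new._rebuild_arrays()
    return new


def write_pqr(system: MolecularSystem, path: str | Path) -> None:
    """Write a whitespace-delimited PQR file (with chain column)."""
    lines = []
    for a, xyz in zip(system.atoms, system.coordinates):
        lines.append(f"ATOM {a.serial:6d} {a.name:<4s} {a.residue_name:<4s} "
                     f"{a.chain_id:1s} {a.residue_index:4d} "
                     f"{xyz[0]:10.4f} {xyz[1]:10.4f} {xyz[2]:10.4f} "
                     f"{a.charge:9.4f} {a.radius:7.4f}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selection expressions
# ---------------------------------------------------------------------------

_KEYWORDS = ("chain", "resid", "resname", "name")


def _primary_mask(system: MolecularSystem, keyword: str, value: str) -> np.ndarray:
    if keyword == "chain":
        return system.chain_ids == value
    if keyword == "resname":
        return system.residue_names == value
    if keyword == "name":
        return system.names == value
    if keyword == "resid":
        if ":" in value:
            lo, hi = value.split(":")
            return (system.residue_indices >= int(lo)) & (system.residue_indices <= int(hi))
        return system.residue_indices == int(value)
    raise AssertionError(keyword)


def select(system: MolecularSystem, expression: str, label: str | None = None,
           allow_empty: bool = True) -> Selection:
    """Evaluate a selection expression.

    Grammar: ``chain <id>``, ``resid <n>`` or ``resid <lo>:<hi>``,
    ``resname <code>``, ``name <atom>``, combined with ``and`` / ``or``
    and prefix ``not`` (precedence: not > and > or; no parentheses).
    ``all`` matches every atom. Empty results are allowed but warned.
    """
    tokens = expression.split()
    if not tokens:
        raise ValueError("empty selection expression")

    pos = 0

    def parse_unary() -> np.ndarray:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"selection syntax error: unexpected end in {expression!r}")
        tok = tokens[pos]
        if tok == "not":
            pos += 1
            return ~parse_unary()
        if tok == "all":
            pos += 1
            return np.ones(system.n_atoms, dtype=bool)
        if tok in _KEYWORDS:
            if pos + 1 >= len(tokens):
                raise ValueError(f"selection syntax error: {tok!r} needs a value")
            value = tokens[pos + 1]
            pos += 2
            try:
                return _primary_mask(system, tok, value)
            except ValueError:
                raise ValueError(f"selection syntax error: bad value {value!r} for {tok!r}") from None
        raise ValueError(f"selection syntax error: unexpected token {tok!r} in {expression!r}")

    def parse_and() -> np.ndarray:
        nonlocal pos
        mask = parse_unary()
        while pos < len(tokens) and tokens[pos] == "and":
            pos += 1
            mask = mask & parse_unary()
        return mask

    def parse_or() -> np.ndarray:
        nonlocal pos
        mask = parse_and()
        while pos < len(tokens) and tokens[pos] == "or":
            pos += 1
            mask = mask | parse_and()
        return mask

    mask = parse_or()
    if pos != len(tokens):
        raise ValueError(f"selection syntax error: trailing tokens {tokens[pos:]!r}")
    indices = tuple(int(i) for i in np.flatnonzero(mask))
    if not indices:
        if not allow_empty:
            raise ValueError(f"selection {expression!r} matched no atoms")
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return Selection(indices, label if label is not None else expression)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, system: MolecularSystem) -> Trajectory:
    """Read frames from a multi-model PDB or a .npz archive.

    Every frame must carry exactly ``system.n_atoms`` atoms; coordinates
    are returned in file order, unmodified.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            frames = data["coordinates"]
            labels = list(data["frame_labels"]) if "frame_labels" in data else []
        if frames.shape[1] != system.n_atoms:
            raise ValueError(f"atom-count mismatch: expected {system.n_atoms}, "
                             f"found {frames.shape[1]}")
        return Trajectory(frames, labels)

    models = read_pdb(path, model="all")
    for k, m in enumerate(models):
        if m.n_atoms != system.n_atoms:
            raise ValueError(f"atom-count mismatch in frame {k}: expected "
                             f"{system.n_atoms}, found {m.n_atoms}")
    return Trajectory(np.stack([m.coordinates for m in models]),
                      [m.model_id for m in models])


def write_trajectory(traj: Trajectory, system: MolecularSystem, path: str | Path) -> None:
    """Write frames as a multi-model PDB (or .npz if so suffixed)."""
    path = Path(path)
    if traj.n_atoms != system.n_atoms:
        raise ValueError("trajectory and system atom counts differ")
    if path.suffix == ".npz":
        np.savez_compressed(path, coordinates=traj.frames,
                            frame_labels=np.asarray(traj.frame_labels))
        return
    models = []
    for k in range(traj.n_frames):
        frame_sys = system.copy()
        frame_sys.set_coordinates(traj.frames[k])
        frame_sys.model_id = k + 1
        models.append(frame_sys)
    write_pdb(models, path)
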