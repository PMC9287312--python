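"""Geometric protein-RNA interaction fingerprints.

Per-frame detection of hydrogen bonds, pi-pi stacking and electrostatic
(charged-group) contacts across the receptor/ligand interface, and
their aggregation into percentage-occurrence maps over a snapshot
window. Detection criteria are configurable; the defaults are in the
range used by common pharmacophore/visualisation tools: H-bond
H...acceptor <= 3.0 A with donor-H...acceptor angle >= 120 deg; ring
centroid distance <= 5.5 A with parallel (<= 30 deg) or T-shaped
(60-90 deg) plane angles; charged-group minimum atom distance <= 5.6 A.

Donor/acceptor typing is element-plus-connectivity: any N or O with a
covalently attached hydrogen donates; any N or O accepts. Covalent
attachment is inferred once from the system's reference coordinates so
that the topology is identical for every frame of a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._parameters import COVALENT_RADII
from .structio import MolecularSystem, Selection, Trajectory

__all__ = [
    "InteractionRecord",
    "OccurrenceMap",
    "infer_hydrogen_attachments",
    "detect_hbonds",
    "detect_pipi",
    "detect_electrostatic",
    "occurrence_map",
]

# aromatic ring heavy-atom names per residue type
RING_DEFINITIONS: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TYR": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
    "HIS": [("CG", "ND1", "CE1", "NE2", "CD2")],
    "A": [("N1", "C2", "N3", "C4", "C5", "C6"), ("N9", "C8", "N7", "C5", "C4")],
    "G": [("N1", "C2", "N3", "C4", "C5", "C6"), ("N9", "C8", "N7", "C5", "C4")],
    "U": [("N1", "C2", "N3", "C4", "C5", "C6")],
    "C": [("N1", "C2", "N3", "C4", "C5", "C6")],
}

# charged groups: (residue types, atom names, sign)
CHARGED_GROUPS: list[tuple[tuple[str, ...], tuple[str, ...], int]] = [
    (("A", "G", "U", "C"), ("P", "OP1", "OP2"), -1),       # phosphate
    (("ARG",), ("CZ", "NE", "NH1", "NH2"), +1),            # guanidinium
    (("LYS",), ("NZ",), +1),                               # ammonium
    (("ASP",), ("CG", "OD1", "OD2"), -1),                  # carboxylate
    (("GLU",), ("CD", "OE1", "OE2"), -1),
]

# symmetric atom permutations collapsed for occurrence identity
_SYMMETRIC_SETS = [
    ({"NH1", "NH2"}, "NH*"), ({"HH11", "HH12", "HH21", "HH22"}, "HH*"),
    ({"OP1", "OP2"}, "OP*"), ({"OD1", "OD2"}, "OD*"), ({"OE1", "OE2"}, "OE*"),
    ({"HZ1", "HZ2", "HZ3"}, "HZ*"), ({"H61", "H62"}, "H6*"),
    ({"H21", "H22"}, "H2*"), ({"H41", "H42"}, "H4*"),
]


def canonical_atom_name(name: str) -> str:
    for names, collapsed in _SYMMETRIC_SETS:
        if name in names:
            return collapsed
    return name


@dataclass(frozen=True)
class InteractionRecord:
    """One detected interaction in one frame."""

    kind: str                 # HBD | HBA | pi-pi | electrostatic
    protein_partner: str      # e.g. "Phe23"
    rna_partner: str          # e.g. "G4"
    atoms: tuple[str, ...]    # participating atom names (raw)
    distance: float           # A
    angle: float | None = None  # deg, where applicable

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("interaction distance must be positive")
        if self.angle is not None and not (0.0 <= self.angle <= 180.0):
            raise ValueError("angle must lie in [0, 180] degrees")

    def identity(self) -> tuple:
        """Aggregation key; symmetric atom permutations collapse."""
        return (self.kind, self.protein_partner, self.rna_partner,
                frozenset(canonical_atom_name(a) for a in self.atoms))


@dataclass
class OccurrenceMap:
    """Interaction identities with percentage occurrence over a window."""

    records: list             # (identity, occurrence percent, frame count)
    window_size: int
    examples: dict = field(default_factory=dict)  # identity -> representative record

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for identity, pct, count in self.records:
            kind, prot, rna, atoms = identity
            rows.append({"protein_residue": prot, "nucleotide": rna, "kind": kind,
                         "atoms": "+".join(sorted(atoms)), "occurrence_pct": pct,
                         "frames": count})
        return pd.DataFrame(rows).sort_values(
            ["occurrence_pct", "protein_residue", "nucleotide"],
            ascending=[False, True, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# typing helpers
# ---------------------------------------------------------------------------

def _residue_labels(system: MolecularSystem) -> list[str]:
    labels = [""] * system.n_atoms
    for label, members in system.residue_groups():
        for i in members:
            labels[int(i)] = label
    return labels


def infer_hydrogen_attachments(system: MolecularSystem,
                               tolerance: float = 1.25) -> dict[int, int]:
    """Map each hydrogen to its covalently bonded heavy atom.

    A hydrogen is attached to the nearest heavy atom within
    ``tolerance * (r_cov(H) + r_cov(X))`` of the system's reference
    coordinates. Raises if any hydrogen has no plausible partner.
    """
    coords = system.coordinates
    h_idx = np.flatnonzero(system.elements == "H")
    heavy_idx = np.flatnonzero(system.elements != "H")
    attachments: dict[int, int] = {}
    for h in h_idx:
        d = np.linalg.norm(coords[heavy_idx] - coords[h], axis=1)
        cutoffs = np.array([tolerance * (COVALENT_RADII["H"]
                                         + COVALENT_RADII.get(system.elements[j], 0.8))
                            for j in heavy_idx])
        candidates = np.flatnonzero(d <= cutoffs)
        if candidates.size == 0:
            a = system.atoms[int(h)]
            raise ValueError(f"hydrogen {a.residue_name}{a.residue_index}:{a.name} "
                             "has no bonded heavy atom; is the structure protonated "
                             "and intact?")
        attachments[int(h)] = int(heavy_idx[candidates[np.argmin(d[candidates])]])
    return attachments


def _partition_mask(system: MolecularSystem) -> np.ndarray:
    """+1 for receptor atoms, -1 for ligand atoms, 0 otherwise."""
    receptor, ligand = system.require_partition()
    side = np.zeros(system.n_atoms, dtype=int)
    side[receptor.indices] = 1
    side[ligand.indices] = -1
    return side


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_hbonds(system: MolecularSystem, coords: np.ndarray | None = None,
                  dist_max: float = 3.0, angle_min: float = 120.0,
                  attachments: dict[int, int] | None = None) -> list[InteractionRecord]:
    """Intermolecular donor-H...acceptor contacts.

    Records every cross-interface triple with H...A <= ``dist_max`` and
    D-H...A angle >= ``angle_min``. The kind is labelled from the RNA's
    perspective: HBD when the RNA donates, HBA when it accepts.
    """
    coords = system.coordinates if coords is None else np.asarray(coords, dtype=float)
    if attachments is None:
        attachments = infer_hydrogen_attachments(system)
    side = _partition_mask(system)
    labels = _residue_labels(system)
    acceptors = [i for i in range(system.n_atoms)
                 if system.elements[i] in ("N", "O") and side[i] != 0]
    records = []
    for h, donor in attachments.items():
        if side[h] == 0 or system.elements[donor] not in ("N", "O"):
            continue
        for acc in acceptors:
            if side[acc] == side[h] or acc == donor:
                continue
            d_ha = float(np.linalg.norm(coords[acc] - coords[h]))
            if d_ha > dist_max or d_ha <= 0:
                continue
            v1 = coords[donor] - coords[h]
            v2 = coords[acc] - coords[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < angle_min:
                continue
            rna_donates = side[h] == -1
            prot_i = acc if rna_donates else donor
            rna_i = donor if rna_donates else acc
            records.append(InteractionRecord(
                kind="HBD" if rna_donates else "HBA",
                protein_partner=labels[prot_i], rna_partner=labels[rna_i],
                atoms=(system.names[donor], system.names[h], system.names[acc]),
                distance=d_ha, angle=angle))
    return records


def _rings(system: MolecularSystem) -> list[tuple[str, int, list[int]]]:
    """(residue label, side, atom indices) for every complete ring."""
    side = _partition_mask(system)
    labels = _residue_labels(system)
    out = []
    for label, members in system.residue_groups():
        resname = system.residue_names[members[0]]
        for ring_names in RING_DEFINITIONS.get(resname, []):
            by_name = {system.names[i]: int(i) for i in members}
            if all(n in by_name for n in ring_names):
                idx = [by_name[n] for n in ring_names]
                out.append((labels[idx[0]], int(side[idx[0]]), idx))
    return out


def _ring_normal(xyz: np.ndarray) -> np.ndarray:
    centered = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def detect_pipi(system: MolecularSystem, coords: np.ndarray | None = None,
                centroid_max: float = 5.5, parallel_max: float = 30.0,
                tshape_range: tuple[float, float] = (60.0, 90.0)) -> list[InteractionRecord]:
    """Cross-interface aromatic stacking.

    A protein ring and an RNA base ring are recorded when their centroid
    distance is <= ``centroid_max`` and the acute angle between their
    planes falls in the parallel class (<= ``parallel_max``) or the
    T-shaped class (``tshape_range``); intermediate tilts are not
    recorded.
    """
    coords = system.coordinates if coords is None else np.asarray(coords, dtype=float)
    rings = _rings(system)
    records = []
    for la, sa, ia in rings:
        if sa != 1:
            continue
        for lb, sb, ib in rings:
            if sb != -1:
                continue
            ca, cb = coords[ia].mean(axis=0), coords[ib].mean(axis=0)
            d = float(np.linalg.norm(ca - cb))
            if d > centroid_max:
                continue
            na, nb = _ring_normal(coords[ia]), _ring_normal(coords[ib])
            cosang = abs(float(np.dot(na, nb)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            if angle <= parallel_max:
                klass = "parallel"
            elif tshape_range[0] <= angle <= tshape_range[1]:
                klass = "t-shaped"
            else:
                continue
            records.append(InteractionRecord(
                kind="pi-pi", protein_partner=la, rna_partner=lb,
                atoms=tuple(sorted(system.names[i] for i in ia + ib)) + (klass,),
                distance=d, angle=angle))
    return records


def _charged_groups(system: MolecularSystem) -> list[tuple[str, int, int, list[int]]]:
    """(residue label, side, sign, atom indices) for complete charged groups."""
    side = _partition_mask(system)
    labels = _residue_labels(system)
    out = []
    for label, members in system.residue_groups():
        resname = system.residue_names[members[0]]
        by_name = {system.names[i]: int(i) for i in members}
        for resnames, atom_names, sign in CHARGED_GROUPS:
            if resname in resnames and all(n in by_name for n in atom_names):
                idx = [by_name[n] for n in atom_names]
                out.append((labels[idx[0]], int(side[idx[0]]), sign, idx))
    return out


def detect_electrostatic(system: MolecularSystem, coords: np.ndarray | None = None,
                         dist_max: float = 5.6) -> list[InteractionRecord]:
    """Opposite-charge group pairs across the interface.

    Groups (phosphates, guanidinium/ammonium, carboxylates) of opposite
    formal sign are recorded when their minimum heavy-atom distance is
    <= ``dist_max``; like-charge pairs never are.
    """
    coords = system.coordinates if coords is None else np.asarray(coords, dtype=float)
    groups = _charged_groups(system)
    records = []
    for la, sa, qa, ia in groups:
        if sa != 1:
            continue
        for lb, sb, qb, ib in groups:
            if sb != -1 or qa * qb >= 0:
                continue
            d = np.linalg.norm(coords[ia][:, None, :] - coords[ib][None, :, :], axis=2)
            dmin = float(d.min())
            if dmin <= dist_max:
                records.append(InteractionRecord(
                    kind="electrostatic", protein_partner=la, rna_partner=lb,
                    atoms=tuple(sorted(system.names[i] for i in ia + ib)),
                    distance=dmin))
    return records


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def occurrence_map(traj: Trajectory, system: MolecularSystem, window=None,
                   hbond_kwargs: dict | None = None,
                   pipi_kwargs: dict | None = None,
                   electrostatic_kwargs: dict | None = None) -> OccurrenceMap:
    """Percentage occurrence of every interaction identity over a window.

    An identity is (kind, protein residue, nucleotide, canonicalised
    atom set); its occurrence is 100 x (frames containing it) / (window
    size). The window is a frame index list, ``"last:N"``, or all frames.
    """
    from .sie import _resolve_window  # shared window grammar
    idx = _resolve_window(traj, window)
    attachments = infer_hydrogen_attachments(system)
    counts: dict[tuple, int] = {}
    examples: dict[tuple, InteractionRecord] = {}
    for k in idx:
        frame = traj.frames[k]
        seen = set()
        recs = (detect_hbonds(system, frame, attachments=attachments,
                              **(hbond_kwargs or {}))
                + detect_pipi(system, frame, **(pipi_kwargs or {}))
                + detect_electrostatic(system, frame, **(electrostatic_kwargs or {})))
        for rec in recs:
            ident = rec.identity()
            if ident in seen:
                continue
            seen.add(ident)
            counts[ident] = counts.get(ident, 0) + 1
            examples.setdefault(ident, rec)
    n = len(idx)
    records = sorted(((ident, 100.0 * c / n, c) for ident, c in counts.items()),
                     key=lambda x: (-x[1], str(x[0])))
    return OccurrenceMap(records=records, window_size=n, examples=examples)
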