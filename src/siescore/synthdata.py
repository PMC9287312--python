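"""Synthetic protein-RNA complexes and pseudo-trajectories.

Generates a desk-scale stand-in for an RRM-type protein bound to a
short single-stranded RNA: a pseudo-peptide "receptor" whose side
chains are placed to realise each interaction class the pipeline
detects (an aromatic ring stacked on a base, guanidinium/ammonium
groups salting to phosphates, hydroxyl donors and carboxylate acceptors
hydrogen-bonded to base edges), and an extended 3-5 nucleotide ligand
in a reduced atom representation (phosphate + sugar trace + planar base
rings with polar hydrogens). Charges follow a simplified model --
each phosphate-bearing nucleotide carries net -1 e, charged side chains
+/-1 e, everything else neutral, with per-residue renormalisation making
the nets exact -- and radii/LJ parameters come from the bundled
per-element table. Pseudo-dynamics are i.i.d. Gaussian coordinate
perturbations of the reference pose: they emulate the magnitude of
thermal fluctuation in an equilibrated trajectory, not its correlation
structure.

Geometry conventions: the RNA runs along +x (one nucleotide every
8.5 A), bases lie in the global xy plane pointing +y, the receptor
approaches from above (+y) and from both +z/-z "lanes". All stochastic
draws derive from the spec's master seed through numpy's SeedSequence
spawning ([seed, stream] keys).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._parameters import (ELEMENT_LJ, ELEMENT_RADII, element_of,
                          residue_charge_table, residue_net_charge)
from .structio import AtomRecord, MolecularSystem, Selection, Trajectory, select

__all__ = [
    "SyntheticSpec",
    "make_toy_complex",
    "make_pseudo_trajectory",
    "mutate_nucleotide",
    "nucleotide_selections",
    "base_template",
]

NT_SPACING = 8.5          # A between nucleotide origins
PURINES = ("A", "G")
PYRIMIDINES = ("U", "C")
# backbone atoms of the reduced nucleotide (kept fixed by mutations)
BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "H5T", "C5'", "C4'", "C3'", "O3'", "C1'")
# receptor residue types the builder knows how to place
_BUILDER_TYPES = ("GLY", "ALA", "PHE", "SER", "ASP", "GLU", "LYS", "ARG")
_DEFAULT_PATTERN = ("PHE", "ARG", "SER", "LYS", "ASP",
                    "PHE", "SER", "ALA", "ARG", "GLY")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic complex / pseudo-trajectory.

    Defaults give a pentamer ligand against a 10-residue receptor with
    per-coordinate noise of 0.25 A over 200 frames: per-atom RMSF
    sigma*sqrt(3) ~ 0.43 A, at the low end of heavy-atom fluctuations in
    an equilibrated binding site. The noise is kept below the
    crystallographic-contact scale deliberately -- i.i.d. displacements
    lack the collective correlations that keep contacts apart in real
    dynamics, so larger sigmas produce unphysically close approaches far
    more often than an equally mobile real trajectory would. The window
    length matches one snapshot per 100 ps over a 20 ns production tail.
    """

    n_residues: int = 10
    n_nucleotides: int = 5
    rna_sequence: str = "GUAGU"
    noise_sigma: float = 0.25
    n_frames: int = 200
    seed: int = 1234
    charge_model: str = "phosphate"   # "phosphate" (net -1/linkage) or "zero-net"
    receptor_sequence: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if not (3 <= self.n_nucleotides <= 5):
            raise ValueError("n_nucleotides must be between 3 and 5")
        if len(self.rna_sequence) != self.n_nucleotides:
            raise ValueError("rna_sequence length must equal n_nucleotides")
        bad = set(self.rna_sequence) - set("ACGU")
        if bad:
            raise ValueError(f"invalid RNA letters: {sorted(bad)}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_residues < 1 or self.n_residues > 2 * self.n_nucleotides:
            raise ValueError("builder supports 1 .. 2*n_nucleotides receptor residues")
        if self.charge_model not in ("phosphate", "zero-net"):
            raise ValueError("charge_model must be 'phosphate' or 'zero-net'")
        if self.receptor_sequence is not None:
            unknown = set(self.receptor_sequence) - set(_BUILDER_TYPES)
            if unknown:
                raise ValueError(f"builder cannot place residue types {sorted(unknown)}")
            if len(self.receptor_sequence) != self.n_residues:
                raise ValueError("receptor_sequence length must equal n_residues")


# ---------------------------------------------------------------------------
# base templates (local frame: glycosidic N at origin, ring in xy plane,
# base extending +y / -x; the glycosidic bond direction N->C1' is -y)
# ---------------------------------------------------------------------------

def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _amino_hydrogens(n_pos: np.ndarray, host: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = (n_pos - host) / np.linalg.norm(n_pos - host)
    return n_pos + _rot_z(60.0) @ u, n_pos + _rot_z(-60.0) @ u


def base_template(base: str) -> dict[str, np.ndarray]:
    """Idealised planar geometry of one base, in the local frame."""
    t: dict[str, np.ndarray] = {}
    if base in PYRIMIDINES:
        center = np.array([0.0, 1.39, 0.0])
        names = ("N1", "C2", "N3", "C4", "C5", "C6")
        for k, name in enumerate(names):
            ang = np.radians(-90.0 + 60.0 * k)
            t[name] = center + 1.39 * np.array([np.cos(ang), np.sin(ang), 0.0])
        out = lambda a, d: t[a] + d * (t[a] - center) / np.linalg.norm(t[a] - center)
        t["O2"] = out("C2", 1.23)
        if base == "U":
            t["O4"] = out("C4", 1.23)
            t["H3"] = out("N3", 1.01)
        else:  # C
            t["N4"] = out("C4", 1.35)
            t["H41"], t["H42"] = _amino_hydrogens(t["N4"], t["C4"])
        # mirror so pyrimidines extend -x like the purines do
        t = {k: v * np.array([-1.0, 1.0, 1.0]) for k, v in t.items()}
        return t

    # purine: fused 5-ring (N9 C8 N7 C5 C4) + 6-ring (C4 C5 C6 N1 C2 N3)
    r5 = 1.38 / (2.0 * np.sin(np.radians(36.0)))
    c5 = np.array([0.0, r5, 0.0])
    for k, name in enumerate(("N9", "C8", "N7", "C5", "C4")):
        ang = np.radians(-90.0 + 72.0 * k)
        t[name] = c5 + r5 * np.array([np.cos(ang), np.sin(ang), 0.0])
    edge_mid = 0.5 * (t["C4"] + t["C5"])
    edge = (t["C5"] - t["C4"]) / np.linalg.norm(t["C5"] - t["C4"])
    perp = np.array([-edge[1], edge[0], 0.0])
    if np.dot(perp, c5 - edge_mid) > 0:      # hexagon sits on the far side
        perp = -perp
    side = float(np.linalg.norm(t["C5"] - t["C4"]))
    c6 = edge_mid + (side * np.sqrt(3.0) / 2.0) * perp
    ang4 = np.arctan2(*(t["C4"] - c6)[[1, 0]])
    for k, name in enumerate(("N3", "C2", "N1", "C6")):
        ang = ang4 - np.radians(60.0 * (k + 1))
        t[name] = c6 + side * np.array([np.cos(ang), np.sin(ang), 0.0])
    out6 = lambda a, d: t[a] + d * (t[a] - c6) / np.linalg.norm(t[a] - c6)
    if base == "A":
        t["N6"] = out6("C6", 1.35)
        t["H61"], t["H62"] = _amino_hydrogens(t["N6"], t["C6"])
    else:  # G
        t["O6"] = out6("C6", 1.23)
        t["H1"] = out6("N1", 1.01)
        t["N2"] = out6("C2", 1.35)
        t["H21"], t["H22"] = _amino_hydrogens(t["N2"], t["C2"])
    return t


def glycosidic_atom(base: str) -> str:
    return "N9" if base in PURINES else "N1"


def _base_frame(n_pos: np.ndarray, c1_pos: np.ndarray,
                ring_a: np.ndarray, ring_b: np.ndarray) -> np.ndarray:
    """Rotation whose columns map template axes into the global frame.

    Template -y is the glycosidic bond direction (N -> C1'); template +z
    is the base normal, whose sign is fixed by two declared ring atoms
    (C8/C4 from N9 for purines, C6/C2 from N1 for pyrimidines).
    """
    ey = -(c1_pos - n_pos)
    ey = ey / np.linalg.norm(ey)
    ez = np.cross(ring_a - n_pos, ring_b - n_pos)
    ez -= ey * np.dot(ez, ey)
    ez = ez / np.linalg.norm(ez)
    ex = np.cross(ey, ez)
    return np.column_stack([ex, ey, ez])


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _rna_atoms(spec: SyntheticSpec) -> list[tuple[str, str, int, np.ndarray]]:
    """(name, resname, resid, xyz) for the ligand chain."""
    atoms = []
    for k, base in enumerate(spec.rna_sequence):
        o = np.array([NT_SPACING * k, 0.0, 0.0])
        resid = k + 1
        if k == 0:
            # 5'-hydroxyl terminus instead of a phosphate
            backbone = [("O5'", o + (1.35, 0.75, 0.0)),
                        ("H5T", o + (0.75, 1.50, 0.0))]
        else:
            backbone = [("P", o + (0.0, 0.0, 0.0)),
                        ("OP1", o + (-0.25, -1.0, 1.25)),
                        ("OP2", o + (-0.25, -1.0, -1.25)),
                        ("O5'", o + (1.35, 0.75, 0.0))]
        backbone += [("C5'", o + (2.75, 1.05, 0.0)),
                     ("C4'", o + (4.15, 1.35, 0.0)),
                     ("C3'", o + (5.55, 0.75, 0.0)),
                     ("O3'", o + (6.95, 0.45, 0.0)),
                     ("C1'", o + (4.85, 2.65, 0.0))]
        n_pos = o + (4.85, 4.05, 0.0)
        template = base_template(base)
        frame = np.eye(3)   # construction places bases in the canonical frame
        base_atoms = [(name, n_pos + frame @ xyz) for name, xyz in template.items()]
        for name, xyz in backbone + base_atoms:
            atoms.append((name, base, resid, np.asarray(xyz, dtype=float)))
    return atoms


def _ring_centroid(base: str, n_pos: np.ndarray) -> np.ndarray:
    t = base_template(base)
    names = ("N1", "C2", "N3", "C4", "C5", "C6")
    return n_pos + np.mean([t[n] for n in names], axis=0)


_SER_TARGET = {"G": "O6", "U": "O4", "C": "O2", "A": "N1"}
_ACID_TARGET = {"G": ("H1", "N1"), "U": ("H3", "N3"),
                "A": ("H61", "N6"), "C": ("H41", "N4")}


def _receptor_atoms(spec: SyntheticSpec,
                    rna: list[tuple[str, str, int, np.ndarray]]):
    """Place receptor residues against the already-built RNA."""
    seq = (list(spec.receptor_sequence) if spec.receptor_sequence is not None
           else [_DEFAULT_PATTERN[i % len(_DEFAULT_PATTERN)]
                 for i in range(spec.n_residues)])
    rna_pos = {(resid, name): xyz for name, _, resid, xyz in rna}
    rna_base = {resid: base for _, base, resid, _ in rna}

    atoms = []
    for i, restype in enumerate(seq):
        resid = i + 1
        t = i % spec.n_nucleotides          # target nucleotide (0-based)
        lane = (i // spec.n_nucleotides) % 2
        s = 1.0 if lane == 0 else -1.0      # approach side in z
        nt_id = t + 1
        base = rna_base[nt_id]
        n_pos = rna_pos[(nt_id, glycosidic_atom(base))]
        placed: list[tuple[str, np.ndarray]] = []

        def chain_up(top: np.ndarray, with_cb: bool = True) -> None:
            """Backbone (and CB) stacked above a side-chain top atom."""
            cb = top + np.array([0.0, 1.30, 1.10 * s])
            ca = cb + np.array([0.0, 1.52, 0.0])
            if with_cb:
                placed.append(("CB", cb))
            placed.extend([
                ("CA", ca),
                ("N", ca + np.array([-1.21, 0.75, 0.0])),
                ("H", ca + np.array([-1.74, 1.60, 0.0])),
                ("C", ca + np.array([1.25, 0.60, 0.0])),
                ("O", ca + np.array([1.25, 1.83, 0.0])),
            ])

        if restype in ("GLY", "ALA"):
            anchor = np.array([NT_SPACING * t + 4.85 + (1.8 if lane else -1.8),
                               12.0, 1.2 * s])
            if restype == "ALA":
                placed.append(("CB", anchor + np.array([0.0, -1.52, 0.0])))
            placed.extend([
                ("CA", anchor),
                ("N", anchor + np.array([-1.21, 0.75, 0.0])),
                ("H", anchor + np.array([-1.74, 1.60, 0.0])),
                ("C", anchor + np.array([1.25, 0.60, 0.0])),
                ("O", anchor + np.array([1.25, 1.83, 0.0])),
            ])
        elif restype == "PHE":
            # ring stacked parallel over the base six-ring, 3.4 A along z
            rc = _ring_centroid(base, n_pos) + np.array([0.0, 0.0, 3.4 * s])
            ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
            for k, name in enumerate(ring_names):
                ang = np.radians(90.0 + 60.0 * k)
                placed.append((name, rc + 1.39 * np.array([np.cos(ang), np.sin(ang), 0.0])))
            cg = placed[0][1]
            chain_up(cg)
        elif restype in ("ARG", "LYS"):
            # charged amine donating to a phosphate oxygen (nt1 has no
            # phosphate: fall back to O3' of the sugar trace)
            target_name = ("OP1" if s > 0 else "OP2") if (nt_id, "P") in rna_pos else "O3'"
            o_pos = rna_pos[(nt_id, target_name)]
            if restype == "ARG":
                nh1 = o_pos + np.array([0.0, 0.0, 3.3 * s])
                cz = nh1 + np.array([0.0, 0.80, 1.05 * s])
                ne = cz + np.array([-1.25, 0.45, 0.0])
                nh2 = cz + np.array([1.25, 0.45, 0.0])
                placed.extend([
                    ("NH1", nh1),
                    ("HH11", nh1 + np.array([0.0, 0.0, -1.0 * s])),
                    ("HH12", nh1 + np.array([0.85, -0.50, 0.0])),
                    ("CZ", cz), ("NE", ne), ("HE", ne + np.array([-0.60, 0.80, 0.0])),
                    ("NH2", nh2),
                    ("HH21", nh2 + np.array([0.60, 0.80, 0.0])),
                    ("HH22", nh2 + np.array([0.85, -0.55, 0.0])),
                ])
                chain_up(cz + np.array([0.0, 0.70, 0.9 * s]))
            else:
                nz = o_pos + np.array([0.0, 0.0, 3.2 * s])
                ce = nz + np.array([0.0, 1.40, 0.55 * s])
                placed.extend([
                    ("NZ", nz),
                    ("HZ1", nz + np.array([0.0, 0.0, -1.0 * s])),
                    ("HZ2", nz + np.array([0.80, 0.60, 0.0])),
                    ("HZ3", nz + np.array([-0.80, 0.60, 0.0])),
                    ("CE", ce),
                ])
                chain_up(ce)
        elif restype == "SER":
            # hydroxyl donating to a base acceptor along the outward direction
            target = rna_pos[(nt_id, _SER_TARGET[base])]
            centroid = _ring_centroid(base, n_pos)
            u = (target - centroid) / np.linalg.norm(target - centroid)
            og = target + 3.05 * u
            placed.extend([("OG", og), ("HG", target + 2.09 * u)])
            chain_up(og)
        elif restype in ("ASP", "GLU"):
            # carboxylate oxygen accepting a base N-H
            h_name, n_name = _ACID_TARGET[base]
            h = rna_pos[(nt_id, h_name)]
            n = rna_pos[(nt_id, n_name)]
            u = (h - n) / np.linalg.norm(h - n)
            w = np.cross(u, np.array([0.0, 0.0, 1.0]))
            w = w / np.linalg.norm(w)
            o1 = h + 2.10 * u
            carb = o1 + 1.25 * u
            o2 = carb + 1.25 * w
            if restype == "ASP":
                placed.extend([("OD1", o1), ("CG", carb), ("OD2", o2)])
                chain_up(carb)
            else:
                placed.extend([("OE1", o1), ("CD", carb), ("OE2", o2),
                               ("CG", carb + np.array([0.0, 1.30, 0.65 * s]))])
                chain_up(carb + np.array([0.0, 1.30, 0.65 * s]), with_cb=True)
        for name, xyz in placed:
            atoms.append((name, restype, resid, np.asarray(xyz, dtype=float)))
    return atoms


def _assign_toy_parameters(records: list[AtomRecord], charge_model: str) -> None:
    """Bundled charges (renormalised per residue to exact nets), LJ, radii."""
    by_residue: dict[tuple[str, int], list[AtomRecord]] = {}
    for a in records:
        by_residue.setdefault((a.chain_id, a.residue_index), []).append(a)
    for group in by_residue.values():
        resname = group[0].residue_name
        table = residue_charge_table(resname)
        names = {a.name for a in group}
        has_phosphate = "P" in names
        target = residue_net_charge(resname, has_phosphate)
        if charge_model == "zero-net":
            target = 0.0
        for a in group:
            a.charge = table.get(a.name, 0.0)
            a.radius = ELEMENT_RADII[a.element]
            a.lj_epsilon, a.lj_rmin_half = ELEMENT_LJ[a.element]
        excess = (target - sum(a.charge for a in group)) / len(group)
        for a in group:
            a.charge += excess


def _check_clashes(system: MolecularSystem, floor: float = 2.0) -> list[tuple]:
    """Inter-residue atom pairs closer than the floor (bonded O3'-P exempt)."""
    coords = system.coordinates
    reskey = [(c, int(r)) for c, r in zip(system.chain_ids, system.residue_indices)]
    clashes = []
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    ii, jj = np.nonzero(d < floor)
    for i, j in zip(ii, jj):
        if i >= j or reskey[i] == reskey[j]:
            continue
        a, b = system.atoms[i], system.atoms[j]
        linked = (a.chain_id == b.chain_id
                  and abs(a.residue_index - b.residue_index) == 1
                  and {a.name, b.name} == {"O3'", "P"})
        if linked:
            continue
        clashes.append((f"{a.residue_name}{a.residue_index}:{a.name}",
                        f"{b.residue_name}{b.residue_index}:{b.name}",
                        float(d[i, j])))
    return clashes


def make_toy_complex(spec: SyntheticSpec) -> MolecularSystem:
    """Build the parameterised complex (receptor chain A, RNA chain B).

    Deterministic for a given spec; the receptor/ligand partition is set
    and all charges/LJ/radii are assigned. Raises if the construction
    produces inter-residue contacts below 2.0 A.
    """
    rna = _rna_atoms(spec)
    receptor = _receptor_atoms(spec, rna)
    records = []
    serial = 1
    for name, resname, resid, xyz in receptor:
        records.append(AtomRecord(serial, name, element_of(name), resname, resid,
                                  "A", xyz))
        serial += 1
    for name, resname, resid, xyz in rna:
        records.append(AtomRecord(serial, name, element_of(name), resname, resid,
                                  "B", xyz))
        serial += 1
    _assign_toy_parameters(records, spec.charge_model)
    system = MolecularSystem(records)
    system.partition_by_chains("A", "B")
    clashes = _check_clashes(system)
    if clashes:
        raise AssertionError(f"toy construction produced steric overlaps: {clashes[:5]}")
    return system


def nucleotide_selections(system: MolecularSystem) -> list[Selection]:
    """Ligand nucleotides as Selections labelled nt1..ntN (5'->3')."""
    _, ligand = system.require_partition()
    return [Selection(tuple(int(i) for i in members), f"nt{k + 1}")
            for k, (_, members) in enumerate(system.residue_groups(ligand))]


def make_pseudo_trajectory(system: MolecularSystem, spec: SyntheticSpec) -> Trajectory:
    """Gaussian-perturbed snapshot ensemble around the reference pose.

    Frame 0 is the unperturbed reference; frames 1..n-1 add i.i.d.
    N(0, noise_sigma^2) to every coordinate. Reproducible from the
    spec's master seed (stream key [seed, 1]).
    """
    if spec.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng([spec.seed, 1])
    ref = system.coordinates
    frames = np.empty((spec.n_frames, system.n_atoms, 3))
    frames[0] = ref
    if spec.n_frames > 1:
        frames[1:] = ref[None] + rng.normal(
            0.0, spec.noise_sigma, size=(spec.n_frames - 1, system.n_atoms, 3))
    return Trajectory(frames, list(range(spec.n_frames)))


def mutate_nucleotide(system: MolecularSystem, position: str, new_base: str,
                      templates=None) -> MolecularSystem:
    """Thread a different base onto one nucleotide of the ligand.

    ``position`` is an ordinal label (``"nt3"``) or residue label
    (``"A3"``). Sugar-phosphate atoms are untouched; the base is
    replaced by the template for ``new_base`` superposed on the
    glycosidic frame (glycosidic N kept exactly in place, N->C1'
    direction and ring-plane normal preserved), and charges are
    reassigned for the new residue type. A ``clash_report`` attribute
    lists any new contacts below 2.0 A (with a warning).
    """
    if new_base not in "ACGU" or len(new_base) != 1:
        raise ValueError(f"unknown base {new_base!r}")
    _, ligand = system.require_partition()
    groups = system.residue_groups(ligand)
    target = None
    for k, (label, members) in enumerate(groups):
        if position in (f"nt{k + 1}", label):
            target = (k, label, members)
            break
    if target is None:
        raise KeyError(f"nucleotide {position!r} not found; available: "
                       f"{[f'nt{k + 1}' for k in range(len(groups))]} / "
                       f"{[l for l, _ in groups]}")
    _, _, members = target
    members = [int(i) for i in members]
    old_base = system.atoms[members[0]].residue_name
    resid = system.atoms[members[0]].residue_index
    chain = system.atoms[members[0]].chain_id

    by_name = {system.atoms[i].name: i for i in members}
    gly = glycosidic_atom(old_base)
    ring_a_name, ring_b_name = (("C8", "C4") if old_base in PURINES else ("C6", "C2"))
    try:
        n_pos = system.coordinates[by_name[gly]]
        c1_pos = system.coordinates[by_name["C1'"]]
        frame = _base_frame(n_pos, c1_pos,
                            system.coordinates[by_name[ring_a_name]],
                            system.coordinates[by_name[ring_b_name]])
    except KeyError as exc:
        raise ValueError(f"cannot build glycosidic frame: atom {exc.args[0]} "
                         "missing from the target nucleotide") from None

    template = (templates or {}).get(new_base) or base_template(new_base)
    new_base_atoms = [(name, n_pos + frame @ xyz) for name, xyz in template.items()]

    # rebuild the atom list: backbone kept verbatim, base atoms replaced in place
    base_idx = [i for i in members if system.atoms[i].name not in BACKBONE_ATOMS]
    insert_at = min(base_idx)
    new_records: list[AtomRecord] = []
    for i, a in enumerate(system.atoms):
        if i == insert_at:
            for name, xyz in new_base_atoms:
                new_records.append(AtomRecord(0, name, element_of(name), new_base,
                                              resid, chain, np.asarray(xyz)))
        if i in base_idx:
            continue
        resname = new_base if i in members else a.residue_name
        new_records.append(AtomRecord(0, a.name, a.element, resname, a.residue_index,
                                      a.chain_id, a.coordinates.copy(), a.charge,
                                      a.lj_epsilon, a.lj_rmin_half, a.radius))
    for serial, a in enumerate(new_records, start=1):
        a.serial = serial

    # reassign parameters for the mutated residue only
    mutated = [a for a in new_records if a.chain_id == chain and a.residue_index == resid]
    table = residue_charge_table(new_base)
    names = {a.name for a in mutated}
    net = residue_net_charge(new_base, has_phosphate="P" in names)
    for a in mutated:
        a.charge = table.get(a.name, 0.0)
        a.radius = ELEMENT_RADII[a.element]
        a.lj_epsilon, a.lj_rmin_half = ELEMENT_LJ[a.element]
    excess = (net - sum(a.charge for a in mutated)) / len(mutated)
    for a in mutated:
        a.charge += excess

    out = MolecularSystem(new_records, model_id=system.model_id)
    out.partition_by_chains(system.atoms[system.receptor.atom_indices[0]].chain_id,
                            chain)
    out.clash_report = [c for c in _check_clashes(out)
                        if f"{new_base}{resid}" in (c[0].split(":")[0], c[1].split(":")[0])]
    if out.clash_report:
        warnings.warn(f"mutation {position}->{new_base} introduced "
                      f"{len(out.clash_report)} close contact(s)", stacklevel=2)
    return out
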