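"""Structural trajectory statistics.

Least-squares rigid superposition (Kabsch, via scipy's quaternion
solver), RMSD/RMSF series, radius of gyration, centre-of-mass distance
series, and the box-plot style percentile summaries used for
per-nucleotide distance distributions. All lengths in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import MolecularSystem, Selection, Trajectory

__all__ = [
    "SuperpositionResult",
    "DistanceStats",
    "superpose",
    "apply_transform",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "com_distance_series",
    "percentile_summary",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference."""

    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # 3-vector, applied after rotation
    rmsd: float               # post-fit RMSD over the fitted atoms


@dataclass
class DistanceStats:
    """Five-number-plus-mean summary of a distance series (A)."""

    label: str
    p5: float
    p25: float
    mean: float
    p75: float
    p95: float
    min: float
    max: float
    outliers: list = field(default_factory=list)


def _weights(n: int, weights) -> np.ndarray:
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum, one per atom")
    return w


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights=None) -> SuperpositionResult:
    """Optimal least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t such that
    ``R @ x + t`` best matches the reference, with the post-fit (weighted)
    RMSD. Uniform weights by default; pass masses for a mass-weighted fit.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    w = _weights(n, weights)
    mob_c = np.average(mobile, axis=0, weights=w)
    ref_c = np.average(reference, axis=0, weights=w)
    a = mobile - mob_c
    b = reference - ref_c
    if np.linalg.matrix_rank(np.vstack([a, b])) < 2:
        raise ValueError("degenerate (collinear) configuration")
    # scipy returns the proper rotation minimising the weighted residual
    rot, _ = Rotation.align_vectors(b, a, weights=w)
    r_mat = rot.as_matrix()
    fitted = a @ r_mat.T
    rmsd = float(np.sqrt(np.average(np.sum((fitted - b) ** 2, axis=1), weights=w)))
    translation = ref_c - r_mat @ mob_c
    return SuperpositionResult(rotation=r_mat, translation=translation, rmsd=rmsd)


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords) @ result.rotation.T + result.translation


def _sel_indices(selection: Selection) -> np.ndarray:
    if len(selection) == 0:
        raise ValueError(f"empty selection {selection.label!r}")
    return selection.indices


def rmsd_series(traj: Trajectory, reference: np.ndarray, selection: Selection,
                fit_selection: Selection | None = None) -> np.ndarray:
    """Per-frame RMSD over ``selection`` after fitting on ``fit_selection``.

    Each frame is superposed onto the reference over the fit selection
    (defaults to the analysis selection) before the RMSD is measured.
    """
    reference = np.asarray(reference, dtype=float)
    sel = _sel_indices(selection)
    fit = sel if fit_selection is None else _sel_indices(fit_selection)
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        frame = traj.frames[k]
        res = superpose(frame[fit], reference[fit])
        moved = apply_transform(frame[sel], res)
        out[k] = np.sqrt(np.mean(np.sum((moved - reference[sel]) ** 2, axis=1)))
    return out


def rmsf(traj: Trajectory, selection: Selection, fit: bool = True,
         by_residue: bool = False, system: MolecularSystem | None = None):
    """Root-mean-square fluctuation about the mean structure.

    With ``fit=True`` every frame is first superposed (over the
    selection) onto frame 0 to remove global rigid motion. Per-residue
    values (``by_residue=True``, requires ``system``) are the mean of
    the residue's per-atom RMSFs.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = _sel_indices(selection)
    coords = traj.frames[:, sel, :].copy()
    if fit:
        ref = coords[0]
        for k in range(traj.n_frames):
            coords[k] = apply_transform(coords[k], superpose(coords[k], ref))
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    if not by_residue:
        return per_atom
    if system is None:
        raise ValueError("per-residue RMSF needs the owning system")
    local = {int(g): i for i, g in enumerate(sel)}
    rows = []
    for label, members in system.residue_groups(Selection(tuple(int(i) for i in sel))):
        vals = per_atom[[local[int(m)] for m in members]]
        rows.append((label, float(vals.mean())))
    return rows


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray,
                       selection: Selection | None = None) -> float:
    """Mass-weighted radius of gyration about the centre of mass."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if selection is not None:
        idx = _sel_indices(selection)
        coords, masses = coords[idx], masses[idx]
    if coords.size == 0:
        raise ValueError("empty selection")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    com = np.average(coords, axis=0, weights=masses)
    return float(np.sqrt(np.average(np.sum((coords - com) ** 2, axis=1), weights=masses)))


def com_distance_series(traj: Trajectory, sel_a: Selection, sel_b: Selection,
                        masses: np.ndarray) -> np.ndarray:
    """Per-frame distance between the mass-weighted centroids of two selections."""
    ia, ib = _sel_indices(sel_a), _sel_indices(sel_b)
    masses = np.asarray(masses, dtype=float)
    com_a = np.average(traj.frames[:, ia, :], axis=1, weights=masses[ia])
    com_b = np.average(traj.frames[:, ib, :], axis=1, weights=masses[ib])
    return np.linalg.norm(com_a - com_b, axis=1)


_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def aligned_backbone_rmsd(system_a: MolecularSystem, system_b: MolecularSystem,
                          atom_names: tuple[str, ...] = ("CA",)) -> SuperpositionResult:
    """Superpose two protein domains over sequence-aligned backbone atoms.

    Protein residues (standard amino acids) are extracted from each
    system, their one-letter sequences globally aligned, and the chosen
    backbone atoms of every aligned residue pair are superposed. This is
    the usual route to an inter-domain RMSD for homologous folds; the
    value depends on the residue subset the alignment selects, so the
    fitted atom count is reported alongside.
    """
    from Bio import Align

    def backbone(system):
        seq, xyz = [], []
        for label, members in system.residue_groups():
            resname = system.residue_names[members[0]]
            if resname not in _AA3TO1:
                continue
            by_name = {system.names[i]: i for i in members}
            if all(n in by_name for n in atom_names):
                seq.append(_AA3TO1[resname])
                xyz.append([system.coordinates[by_name[n]] for n in atom_names])
        return "".join(seq), np.asarray(xyz)

    seq_a, xyz_a = backbone(system_a)
    seq_b, xyz_b = backbone(system_b)
    if not seq_a or not seq_b:
        raise ValueError("no complete protein backbone residues found")
    aligner = Align.PairwiseAligner(scoring="blastp")
    aligner.mode = "global"
    alignment = aligner.align(seq_a, seq_b)[0]
    ia, ib = [], []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        ia.extend(range(a0, a1))
        ib.extend(range(b0, b1))
    mob = xyz_a[ia].reshape(-1, 3)
    ref = xyz_b[ib].reshape(-1, 3)
    result = superpose(mob, ref)
    result.n_fitted = len(ia)
    return result


def percentile_summary(values, label: str = "") -> DistanceStats:
    """Box-plot summary: 5/25/75/95th percentiles, mean, extrema, outliers.

    Percentiles use linear interpolation between closest ranks (numpy
    default). Outliers are the values falling outside the 5th-95th
    percentile whiskers, mirroring the plotting convention where
    whiskers span p5-p95 and more extreme points are drawn individually.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    p5, p25, p75, p95 = np.percentile(v, [5, 25, 75, 95])
    return DistanceStats(
        label=label,
        p5=float(p5), p25=float(p25), mean=float(v.mean()),
        p75=float(p75), p95=float(p95),
        min=float(v.min()), max=float(v.max()),
        outliers=[float(x) for x in v[(v < p5) | (v > p95)]],
    )
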