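"""Shared setup for the analysis drivers.

The study design: one reference complex with the canonical pentamer
GUAGU, plus three variants obtained by threading alternative bases onto
the central trinucleotide (GUUGU, GGAGU, GAUGU). Each complex gets five
replica pseudo-trajectories; all statistics and energies are taken over
the pooled replica windows. Trajectories are regenerated from seeds in
every driver rather than stored -- they are cheap and exactly
reproducible.
"""

from __future__ import annotations

import warnings
from pathlib import Path

from siescore.structio import MolecularSystem, Trajectory
from siescore.synthdata import (SyntheticSpec, make_pseudo_trajectory,
                                make_toy_complex, mutate_nucleotide)

RESULTS = Path(__file__).resolve().parents[1] / "results"

BASE_SEED = 20240
N_REPLICAS = 5
N_FRAMES = 200          # one window per replica, pooled to 1000 snapshots

# central-trinucleotide edits that generate each variant from GUAGU
PENTAMERS: dict[str, list[tuple[str, str]]] = {
    "GUAGU": [],
    "GUUGU": [("nt3", "U")],
    "GGAGU": [("nt2", "G")],
    "GAUGU": [("nt2", "A"), ("nt3", "U")],
}


def build_complex(pentamer: str) -> MolecularSystem:
    system = make_toy_complex(SyntheticSpec(seed=BASE_SEED))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # threading clashes are reported in 01
        for position, base in PENTAMERS[pentamer]:
            system = mutate_nucleotide(system, position, base)
    return system


def replica_trajectories(system: MolecularSystem, n_frames: int = N_FRAMES,
                         n_replicas: int = N_REPLICAS) -> list[Trajectory]:
    """Replica r uses master seed BASE_SEED + r (declared splitting rule)."""
    return [make_pseudo_trajectory(system, SyntheticSpec(seed=BASE_SEED + r,
                                                         n_frames=n_frames))
            for r in range(n_replicas)]
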