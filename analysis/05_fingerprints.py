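"""Protein-RNA interaction occurrence maps.

Detects hydrogen bonds (RNA-donor HBD / RNA-acceptor HBA), pi-pi
stacking and electrostatic contacts in every frame of the pooled
replicas and reports each interaction identity's percentage occurrence.
Writes results/fingerprints/occurrence_<pentamer>.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import PENTAMERS, RESULTS, build_complex, replica_trajectories

from siescore.fingerprints import occurrence_map


def main() -> None:
    outdir = RESULTS / "fingerprints"
    outdir.mkdir(parents=True, exist_ok=True)
    for pentamer in PENTAMERS:
        system = build_complex(pentamer)
        trajs = replica_trajectories(system)
        frames = []
        for r, traj in enumerate(trajs):
            omap = occurrence_map(traj, system)
            df = omap.to_frame()
            df.insert(0, "replica", r)
            frames.append(df)
        per_replica = pd.concat(frames)
        pooled = (per_replica.groupby(["protein_residue", "nucleotide", "kind", "atoms"])
                  .agg(occurrence_pct=("occurrence_pct", "mean"),
                       frames=("frames", "sum")).reset_index()
                  .sort_values("occurrence_pct", ascending=False))
        pooled.to_csv(outdir / f"occurrence_{pentamer}.csv", index=False)
        top = pooled.head(5)
        print(f"{pentamer}: top contacts "
              + "; ".join(f"{r.protein_residue}-{r.nucleotide} {r.kind} "
                          f"{r.occurrence_pct:.0f}%" for r in top.itertuples()))
    print(f"\nwrote occurrence maps under {outdir}/")


if __name__ == "__main__":
    main()
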