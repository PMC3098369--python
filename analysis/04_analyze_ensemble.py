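#!/usr/bin/env python
"""Ensemble geometry: torsion statistics, RMSD spread and hydrogen bonds.

Circular mean/std of each glycosidic torsion over the kept conformers, the
all-atom RMSD of every conformer to the lowest-energy one, and geometric
hydrogen bonds (H...A <= 2.5 A, D-H...A >= 120 deg) in the rank-1 model.

Reads:  results/ensemble.pdb
Writes: results/torsion_statistics.csv, results/rmsd.csv,
        results/hydrogen_bonds.csv
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from chondronmr.ensemble import hydrogen_bonds, superpose_rmsd, torsion_statistics
from chondronmr.pdbio import read_multimodel_pdb

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    models = read_multimodel_pdb(os.path.join(OUT, "ensemble.pdb"))
    stats = torsion_statistics(models)
    stats.table.to_csv(os.path.join(OUT, "torsion_statistics.csv"), index=False)
    print("glycosidic torsion statistics (circular mean (std), deg):")
    for _, row in stats.table.iterrows():
        print(f"  {row.linkage:>6} {row.type} {row.angle}: "
              f"{row.mean_deg:7.1f} ({row.std_deg:.1f})")

    rmsds = pd.DataFrame(
        [
            dict(rank=i + 2, rmsd_A=superpose_rmsd(models[0], m))
            for i, m in enumerate(models[1:])
        ]
    )
    rmsds.to_csv(os.path.join(OUT, "rmsd.csv"), index=False)
    if len(rmsds):
        print(f"all-atom RMSD to rank 1: "
              f"{rmsds.rmsd_A.min():.2f}-{rmsds.rmsd_A.max():.2f} A")

    # geometric hydrogen bonds in the lowest-energy conformer; the atoms named
    # here are the ones to watch: GlcA HO2 -> GalNAc carbonyl O7 across
    # beta(1->3), GalNAc HN -> GlcA carboxylate across beta(1->4)
    hbs = hydrogen_bonds(models[0])
    pd.DataFrame(
        [
            dict(donor=h.donor, hydrogen=h.hydrogen, acceptor=h.acceptor,
                 distance_A=h.distance_h_a, angle_deg=h.angle_d_h_a)
            for h in hbs
        ]
    ).to_csv(os.path.join(OUT, "hydrogen_bonds.csv"), index=False)
    print(f"{len(hbs)} hydrogen bond(s) in the rank-1 conformer:")
    for h in hbs:
        print(f"  {h.hydrogen} -> {h.acceptor}  {h.distance_h_a:.2f} A, "
              f"{h.angle_d_h_a:.0f} deg")


if __name__ == "__main__":
    main()
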