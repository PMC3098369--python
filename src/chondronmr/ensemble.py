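"""Ensemble geometry analytics: superposition RMSD, circular torsion
statistics, hydrogen-bond detection and literature torsion comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import circmean, circstd

from .errors import InputError, StructuralError
from .geometry import angle, wrap_angle
from .glycan import OligosaccharideModel, measure_glycosidic_torsions


def default_atom_selection(model) -> np.ndarray:
    """Heavy atoms plus polar hydrogens (those bonded to N or O)."""
    elements = model.elements
    polar_parent = set()
    for i, j in model.bonds:
        if elements[i] == "H" and elements[j] in ("N", "O"):
            polar_parent.add(i)
        if elements[j] == "H" and elements[i] in ("N", "O"):
            polar_parent.add(j)
    return np.array(
        [e != "H" or i in polar_parent for i, e in enumerate(elements)]
    )


def superpose_rmsd(model_a, model_b, atom_selection=None) -> float:
    """All-atom RMSD (A) after optimal rigid-body superposition.

    `atom_selection` may be a boolean mask / index array over atoms or the
    string "all"; the default is heavy atoms + polar hydrogens.
    """
    if atom_selection is None:
        sel_a = default_atom_selection(model_a)
        sel_b = default_atom_selection(model_b)
    elif isinstance(atom_selection, str) and atom_selection == "all":
        sel_a = sel_b = slice(None)
    else:
        sel_a = sel_b = atom_selection
    xa = np.asarray(model_a.coords if hasattr(model_a, "coords") else model_a)[sel_a]
    xb = np.asarray(model_b.coords if hasattr(model_b, "coords") else model_b)[sel_b]
    if xa.shape != xb.shape:
        raise StructuralError(
            f"atom count mismatch after selection: {xa.shape[0]} vs {xb.shape[0]}"
        )
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    _, rssd = Rotation.align_vectors(xa, xb)
    return float(rssd / np.sqrt(xa.shape[0]))


@dataclass
class TorsionStatistics:
    table: pd.DataFrame  # linkage, type, angle, mean_deg, std_deg

    def mean(self, linkage: str, which: str) -> float:
        row = self.table[(self.table.linkage == linkage) & (self.table.angle == which)]
        return float(row.mean_deg.iloc[0])


def circular_mean_std(values_deg) -> tuple:
    """(mean, std) in degrees via unit-vector averaging; std = sqrt(-2 ln R)."""
    v = np.asarray(values_deg, dtype=float)
    mean = wrap_angle(float(np.degrees(circmean(np.radians(v)))))
    std = float(np.degrees(circstd(np.radians(v))))
    return mean, std


def torsion_statistics(models) -> TorsionStatistics:
    """Per-linkage circular mean/std of phi and psi over an ensemble.

    `models` is an iterable of OligosaccharideModel (or of Conformer objects
    with a `.model` attribute) sharing one topology.
    """
    models = [getattr(m, "model", m) for m in models]
    if not models:
        raise InputError("empty ensemble")
    per_linkage = {}
    for m in models:
        for lk, phi, psi in measure_glycosidic_torsions(m):
            key = (
                f"{m.labels[lk.donor_residue_index - 1]}-"
                f"{m.labels[lk.acceptor_residue_index - 1]}"
            )
            per_linkage.setdefault((key, lk.type), []).append((phi, psi))
    rows = []
    for (key, ltype), vals in per_linkage.items():
        arr = np.asarray(vals)
        for col, name in ((0, "phi"), (1, "psi")):
            mean, std = circular_mean_std(arr[:, col])
            rows.append(dict(linkage=key, type=ltype, angle=name,
                             mean_deg=mean, std_deg=std))
    return TorsionStatistics(table=pd.DataFrame(rows))


@dataclass
class HydrogenBond:
    donor: str  # qualified heavy-atom id
    hydrogen: str
    acceptor: str
    distance_h_a: float  # A
    angle_d_h_a: float  # degrees


def hydrogen_bonds(model: OligosaccharideModel, max_h_a: float = 2.5,
                   min_angle: float = 120.0):
    """Geometric hydrogen bonds: H...acceptor <= max_h_a A and
    donor-H...acceptor angle >= min_angle, sorted by distance.

    Donors are O-H/N-H hydrogens; acceptors are any N/O not bonded to the
    hydrogen.  The default criteria are conventional geometric cutoffs.
    """
    elements = model.elements
    adj = {}
    for i, j in model.bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)

    def qualify(i):
        return f"{model.labels[model.atom_res[i]]}:{model.atom_names[i]}"

    donors = []  # (heavy, H)
    acceptors = []
    for i, e in enumerate(elements):
        if e == "H":
            parents = [p for p in adj.get(i, []) if elements[p] in ("N", "O")]
            if parents:
                donors.append((parents[0], i))
        elif e in ("N", "O"):
            acceptors.append(i)

    out = []
    for d, h in donors:
        for a in acceptors:
            if a == d or a in adj.get(h, []):
                continue
            dist = float(np.linalg.norm(model.coords[h] - model.coords[a]))
            if dist > max_h_a:
                continue
            ang = angle(model.coords[d], model.coords[h], model.coords[a])
            if ang < min_angle:
                continue
            out.append(
                HydrogenBond(donor=qualify(d), hydrogen=qualify(h),
                             acceptor=qualify(a), distance_h_a=dist,
                             angle_d_h_a=ang)
            )
    out.sort(key=lambda hb: hb.distance_h_a)
    return out


def circular_abs_difference(a_deg: float, b_deg: float) -> float:
    """|a - b| on the circle, in [0, 180] degrees."""
    return abs(wrap_angle(a_deg - b_deg))


def compare_structures(torsions_ref: dict, torsions_other: dict) -> pd.DataFrame:
    """ABS-delta table between two keyed torsion sets (circular difference).

    Keys present on only one side raise InputError naming them.
    """
    missing = set(torsions_ref) ^ set(torsions_other)
    if missing:
        raise InputError(f"torsion keys do not match: {sorted(missing)}")
    rows = [
        dict(angle=k, ref_deg=torsions_ref[k], other_deg=torsions_other[k],
             abs_delta_deg=circular_abs_difference(torsions_other[k], torsions_ref[k]))
        for k in torsions_ref
    ]
    return pd.DataFrame(rows)
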