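"""Back-calculation of vicinal 3J couplings from model dihedrals.

Two Karplus-type relations are used as structure quality control:

* the generalized H-C-C-H equation with substituent-electronegativity
  corrections,
      J(theta) = P1 cos^2 t + P2 cos t + P3
                 + sum_i dchi_i [P4 + P5 cos^2(xi_i t + P6 |dchi_i|)],
  where dchi_i is the Huggins electronegativity difference of substituent i
  relative to hydrogen and xi_i = +/-1 encodes its orientation (the sign of
  its torsion offset from the coupled proton on the same carbon);
* a plain three-coefficient form A cos^2 t + B cos t + C for the acetamido
  HN-N-C2-H2 coupling.

Coefficients live in an editable YAML registry shipped with the package;
they are configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, StructuralError
from .geometry import dihedral, wrap_angle


@dataclass
class KarplusParameterSet:
    name: str
    P1: float
    P2: float
    P3: float = 0.0
    P4: float = 0.0
    P5: float = 0.0
    P6: float = 0.0  # degrees


@dataclass
class KarplusRegistry:
    hcch_sets: dict  # name -> KarplusParameterSet
    default_hcch: str
    electronegativities: dict  # element -> dchi vs hydrogen
    amide: Optional[dict] = None  # {"A":..., "B":..., "C":...}

    def hcch(self, name: Optional[str] = None) -> KarplusParameterSet:
        return self.hcch_sets[name or self.default_hcch]


def load_registry(path=None) -> KarplusRegistry:
    """Load Karplus coefficients from YAML (package default when path=None)."""
    if path is None:
        text = resources.files("chondronmr.data").joinpath("karplus.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    sets = {
        name: KarplusParameterSet(name=name, **coeffs)
        for name, coeffs in raw.get("hcch_sets", {}).items()
    }
    return KarplusRegistry(
        hcch_sets=sets,
        default_hcch=raw.get("default_hcch_set", next(iter(sets), None)),
        electronegativities=raw.get("electronegativities", {}),
        amide=raw.get("amide"),
    )


def karplus_jhh(theta_deg: float, params: KarplusParameterSet,
                substituents=()) -> float:
    """Generalized vicinal H-C-C-H coupling (Hz) at dihedral theta.

    `substituents` is a sequence of (dchi, xi) with xi in {+1, -1}.  With an
    empty sequence the expression reduces to the plain three-term Karplus
    curve, which is symmetric under theta -> -theta.
    """
    t = np.radians(theta_deg)
    j = params.P1 * np.cos(t) ** 2 + params.P2 * np.cos(t) + params.P3
    for dchi, xi in substituents:
        if abs(xi) != 1:
            raise ConfigurationError("substituent orientation xi must be +1 or -1")
        j += dchi * (
            params.P4
            + params.P5 * np.cos(xi * t + np.radians(params.P6 * abs(dchi))) ** 2
        )
    return float(j)


def karplus_jnh(theta_deg: float, coefficients: Optional[dict] = None,
                registry: Optional[KarplusRegistry] = None) -> float:
    """Amide 3J(HN,H2) coupling (Hz) from the H2-C2-N-HN dihedral."""
    if coefficients is None:
        registry = registry or load_registry()
        coefficients = registry.amide
    if not coefficients or any(k not in coefficients for k in "ABC"):
        raise ConfigurationError(
            "amide Karplus coefficients are not configured (need A, B, C)"
        )
    t = np.radians(theta_deg)
    return float(
        coefficients["A"] * np.cos(t) ** 2
        + coefficients["B"] * np.cos(t)
        + coefficients["C"]
    )


@dataclass
class CouplingPrediction:
    residue: str
    pair: str  # "1,2" ... "4,5" or "HN,H2"
    dihedral_deg: float
    j_calc: float
    j_obs: Optional[float] = None


def _adjacency(model):
    adj = {}
    for i, j in model.bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    return adj


def _fragment_substituents(model, adj, ca, cb, ha, hb, registry):
    """(dchi, xi) list for the Ha-Ca-Cb-Hb fragment, orientation from geometry.

    For a substituent S on Ca, xi is the sign of the (wrapped) offset between
    the S-Ca-Cb-Hb torsion and the proton torsion theta (S sits at roughly
    theta +/- 120 deg); symmetrically for substituents on Cb.
    """
    coords = model.coords
    theta = dihedral(coords[ha], coords[ca], coords[cb], coords[hb])
    subs = []
    for center, far_h, swap in ((ca, hb, False), (cb, ha, True)):
        other = cb if center == ca else ca
        for s in adj[center]:
            if s in (other, ha, hb):
                continue
            el = model.elements[s]
            if el == "H":
                continue
            dchi = registry.electronegativities.get(el)
            if dchi is None:
                continue
            if not swap:
                tor = dihedral(coords[s], coords[ca], coords[cb], coords[hb])
            else:
                tor = dihedral(coords[ha], coords[ca], coords[cb], coords[s])
            xi = 1 if wrap_angle(tor - theta) > 0 else -1
            subs.append((dchi, xi))
    return theta, subs


def back_calculate_ring_couplings(model, registry: Optional[KarplusRegistry] = None,
                                  set_name: Optional[str] = None):
    """Predicted 3J for the H1-H2 ... H4-H5 ring proton pairs of every residue.

    Substituent electronegativity corrections are derived from the model's own
    bonded topology and geometry.  Raises StructuralError when a required ring
    hydrogen is missing from the templates.
    """
    registry = registry or load_registry()
    params = registry.hcch(set_name)
    adj = _adjacency(model)
    out = []
    for ri in range(1, model.n_residues + 1):
        label = model.labels[ri - 1]
        for a, b in ((1, 2), (2, 3), (3, 4), (4, 5)):
            try:
                ha = model.atom_index(label, f"H{a}")
                hb = model.atom_index(label, f"H{b}")
                ca = model.atom_index(label, f"C{a}")
                cb = model.atom_index(label, f"C{b}")
            except StructuralError as exc:
                raise StructuralError(
                    f"cannot back-calculate J{a},{b} for {label}: {exc}"
                ) from exc
            theta, subs = _fragment_substituents(model, adj, ca, cb, ha, hb, registry)
            j = karplus_jhh(theta, params, subs)
            out.append(CouplingPrediction(residue=label, pair=f"{a},{b}",
                                          dihedral_deg=theta, j_calc=j))
    return out


def acetamido_couplings(model, registry: Optional[KarplusRegistry] = None):
    """3J(HN,H2) predictions for every GalNAc from the H2-C2-N-HN dihedral."""
    registry = registry or load_registry()
    out = []
    for ri in range(1, model.n_residues + 1):
        if model.kinds[ri - 1] != "GalNAc":
            continue
        label = model.labels[ri - 1]
        pts = [
            model.position(label, n) for n in ("H2", "C2", "N2", "HN")
        ]
        theta = dihedral(*pts)
        out.append(
            CouplingPrediction(
                residue=label, pair="HN,H2", dihedral_deg=theta,
                j_calc=karplus_jnh(theta, registry=registry),
            )
        )
    return out


def compare_couplings(predictions, observations) -> tuple:
    """Per-pair deltas and RMS between calculated and observed couplings.

    `observations` maps (residue, pair) -> Hz (missing keys are reported as
    n/d, not fatal).  Returns (DataFrame, rms over matched rows).
    """
    rows = []
    deltas = []
    for p in predictions:
        obs = observations.get((p.residue, p.pair))
        delta = None if obs is None else p.j_calc - obs
        if delta is not None:
            deltas.append(delta)
        rows.append(
            dict(residue=p.residue, pair=p.pair, dihedral_deg=p.dihedral_deg,
                 j_calc_Hz=p.j_calc, j_obs_Hz=obs,
                 delta_Hz=delta if delta is not None else np.nan,
                 status="ok" if delta is not None else "n/d")
        )
    unmatched = [
        k for k in observations if k not in {(p.residue, p.pair) for p in predictions}
    ]
    df = pd.DataFrame(rows)
    rms = float(np.sqrt(np.mean(np.square(deltas)))) if deltas else np.nan
    df.attrs["unmatched_observations"] = unmatched
    return df, rms
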