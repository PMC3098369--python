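"""Multi-model PDB input/output for conformer ensembles.

The deposited format for NMR carbohydrate ensembles is a MODEL/ENDMDL
delimited PDB file; gemmi handles the record formatting.  Residue names in
deposited glycan files are inconsistent across depositions, so reading goes
through an overridable name-mapping table (GlcA/GalNAc aliases).
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .errors import ParseError, StructuralError
from .glycan import GlycosidicLinkage, OligosaccharideModel

#: PDB chemical-component aliases for the two chondroitin residues
RESIDUE_NAME_MAP = {
    "BDP": "GlcA", "GCU": "GlcA", "GCV": "GlcA", "UYB": "GlcA", "GLR": "GlcA",
    "NGA": "GalNAc", "A2G": "GalNAc", "NG6": "GalNAc", "YYQ": "GalNAc",
}
WRITE_NAMES = {"GlcA": "BDP", "GalNAc": "NGA"}


def _validate_model_blocks(path):
    """MODEL/ENDMDL records must pair up; report the offending model index."""
    open_index = None
    n_models = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if open_index is not None:
                    raise ParseError(
                        f"line {lineno}: MODEL {n_models + 1} opened before "
                        f"MODEL {open_index} was closed"
                    )
                n_models += 1
                open_index = n_models
            elif rec == "ENDMDL":
                if open_index is None:
                    raise ParseError(f"line {lineno}: ENDMDL without MODEL")
                open_index = None
    if open_index is not None:
        raise ParseError(f"truncated MODEL block: model {open_index} has no ENDMDL")


def _normalize_atom_name(name: str) -> str:
    # deposited glycan hydrogens/oxygens: O1A -> O6A style kept, primes dropped
    return name.replace("'", "").strip()


def _infer_bonds(coords, elements):
    """Distance-based covalent bond inference (PDB files carry no topology).

    Heavy-heavy pairs under 1.75 A and X-H pairs under 1.25 A are bonded;
    generous enough for idealised and deposited glycan geometry alike.
    """
    coords = np.asarray(coords)
    n = len(coords)
    heavy = np.array([e != "H" for e in elements])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            cut = 1.75 if heavy[i] and heavy[j] else (
                1.25 if heavy[i] != heavy[j] else 0.0
            )
            if 0.0 < d[i, j] < cut:
                bonds.append((i, j))
    return bonds


def read_multimodel_pdb(path, name_map: dict = None):
    """Parse a (multi-)model PDB file into OligosaccharideModel objects.

    Residues are mapped to GlcA/GalNAc via `name_map` (defaults to the
    packaged alias table) and relabelled N1/U2/... from the reducing end in
    file order.  Atom names are preserved (primes stripped).
    """
    name_map = {**RESIDUE_NAME_MAP, **(name_map or {})}
    _validate_model_blocks(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")

    models = []
    for gm in st:
        residues = [r for chain in gm for r in chain]
        if not residues:
            raise ParseError(f"{path}: model {gm.name} contains no residues")
        kinds = []
        for r in residues:
            kind = name_map.get(r.name.strip().upper())
            if kind is None:
                raise ParseError(
                    f"{path}: unknown residue name {r.name!r}; extend the "
                    "name mapping to read this file"
                )
            kinds.append(kind)
        labels = [
            ("N" if k == "GalNAc" else "U") + str(i + 1)
            for i, k in enumerate(kinds)
        ]
        atom_names, atom_res, coords = [], [], []
        res_slices = []
        for i, r in enumerate(residues):
            lo = len(atom_names)
            for a in r:
                atom_names.append(_normalize_atom_name(a.name))
                atom_res.append(i)
                coords.append([a.pos.x, a.pos.y, a.pos.z])
            res_slices.append((lo, len(atom_names)))
        linkages = []
        for i in range(1, len(residues)):
            ltype = "beta1-3" if kinds[i] == "GlcA" else "beta1-4"
            linkages.append(GlycosidicLinkage(ltype, i + 1, i, np.nan, np.nan))
        coords = np.asarray(coords, dtype=float)
        elements = [
            "H" if n.startswith("H") else n[0] for n in atom_names
        ]
        model = OligosaccharideModel(
            labels=labels, kinds=kinds, atom_names=atom_names,
            atom_res=atom_res, coords=coords,
            bonds=_infer_bonds(coords, elements), linkages=linkages,
            res_slices=res_slices,
        )
        _alias_glycosidic_oxygens(model)
        models.append(model)
    return models


def _alias_glycosidic_oxygens(model):
    """Deposited files often put the glycosidic oxygen on the acceptor (O3/O4)
    rather than the donor (O1); alias it so torsion quadruples resolve."""
    for lk in model.linkages:
        donor = model.labels[lk.donor_residue_index - 1]
        acceptor = model.labels[lk.acceptor_residue_index - 1]
        site = "O3" if lk.type == "beta1-3" else "O4"
        try:
            model.atom_index(donor, "O1")
            continue  # already present
        except StructuralError:
            pass
        try:
            idx = model.atom_index(acceptor, site)
        except StructuralError:
            continue
        model._index[(donor, "O1")] = idx


def write_multimodel_pdb(ensemble, path, seed=None):
    """Write an energy-ranked ensemble as a multi-model PDB.

    `ensemble` is a ConformerEnsemble or list of Conformer/OligosaccharideModel.
    REMARK 3 lines record per-model energy, max restraint violation and the
    generating seed.
    """
    members = list(ensemble)
    if not members:
        raise ParseError("refusing to write an empty ensemble")

    st = gemmi.Structure()
    st.name = "chondronmr ensemble"
    remarks = ["REMARK   3  CHONDRONMR TORSION-SPACE RESTRAINED ANNEALING ENSEMBLE"]
    if seed is not None:
        remarks.append(f"REMARK   3  SEED {seed}")
    for rank, member in enumerate(members, start=1):
        model = getattr(member, "model", member)
        energy = getattr(member, "energy", None)
        viol = getattr(member, "max_violation", None)
        if energy is not None:
            remarks.append(
                f"REMARK   3  MODEL {rank} ENERGY {energy:.4f} "
                f"MAXVIOL {0.0 if viol is None else viol:.4f}"
            )
        gm = gemmi.Model(rank)
        chain = gemmi.Chain("A")
        for i, (label, kind) in enumerate(zip(model.labels, model.kinds)):
            res = gemmi.Residue()
            res.name = WRITE_NAMES[kind]
            res.seqid = gemmi.SeqId(i + 1, " ")
            lo, hi = model.res_slices[i]
            for j in range(lo, hi):
                atom = gemmi.Atom()
                atom.name = model.atom_names[j]
                atom.element = gemmi.Element(model.elements[j])
                x, y, z = model.coords[j]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
        st.add_model(gm)
    st.raw_remarks = remarks
    st.setup_entities()
    st.write_pdb(str(path))


def write_energy_table(ensemble, path):
    """TSV of per-conformer rank, energy and max restraint violation."""
    rows = [
        dict(rank=i + 1, energy_kcal_mol=c.energy, max_violation_A=c.max_violation,
             seed_index=getattr(c, "seed_index", i))
        for i, c in enumerate(ensemble)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
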