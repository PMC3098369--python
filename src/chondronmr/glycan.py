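"""Residue templates and chain assembly for chondroitin oligosaccharides.

Chondroitin is the alternating copolymer [-4)GlcA-beta(1->3)GalNAc-beta(1-]
with residue 1 at the reducing end (a GalNAc, alpha/beta anomeric mixture in
solution). Residues are held as rigid 4C1 chairs; the chain conformation is
parameterised entirely by the glycosidic torsions

    beta(1->3):  phi = O5(U)-C1(U)-O1(U)-C3(N),  psi = C1(U)-O1(U)-C3(N)-C4(N)
    beta(1->4):  phi = O5(N)-C1(N)-O1(N)-C4(U),  psi = C1(N)-O1(N)-C4(U)-C5(U)

plus named exocyclic rotations (hydroxymethyl omega, acetamido H2-C2-N-HN).
Residue labels follow the reducing-end-first convention: N1, U2, N3, U4, ...

Template geometry is idealised (uniform ring bond 1.50 A, chair ring torsions
alternating +/-60 deg, tetrahedral substituent slots); it reproduces the
stereochemistry that distinguishes GalNAc (axial O4) from GlcA (all-equatorial
glucuronate) without attempting force-field accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import StructuralError, UnknownResidueKindError
from .geometry import angle, dihedral, frame_map, place_atom

RING_ATOMS = ("O5", "C1", "C2", "C3", "C4", "C5")

# idealised bond lengths, Angstrom
BOND = {
    "ring": 1.50,
    "C-C": 1.52,
    "C-O": 1.43,
    "C1-O1": 1.41,
    "O1-Cx": 1.43,  # glycosidic O to aglycone carbon
    "C-N": 1.47,
    "N-C(=O)": 1.34,
    "C=O": 1.23,
    "C-H": 1.09,
    "O-H": 0.96,
    "N-H": 1.01,
}
GLYCOSIDIC_ANGLE = 117.0  # C1-O1-Cx, degrees
CHAIR_TORSION = 60.0  # target magnitude of ring torsions
CLASH_CUTOFF = 1.5  # A, non-bonded heavy-atom clash threshold


def _element_of(name: str) -> str:
    if name.startswith("H"):
        return "H"
    return name[0]


def _chair_ring(bond: float = BOND["ring"], tau: float = CHAIR_TORSION) -> np.ndarray:
    """Six ring positions of an ideal chair with torsions alternating +/-tau."""

    def pts(h):
        # the z-phase fixes the ring chirality to the D-series 4C1 chair
        # (verified against the trans-glycosidic proton-proton distances and
        # the gauche/trans ring-proton dihedral pattern of chondroitin)
        ang = np.radians(60.0 * np.arange(6))
        return np.column_stack(
            [np.cos(ang), np.sin(ang), -h * (-1.0) ** np.arange(6)]
        )

    def tor_mag(h):
        p = pts(h)
        return abs(dihedral(p[0], p[1], p[2], p[3]))

    h = brentq(lambda x: tor_mag(x) - tau, 0.05, 1.0, xtol=1e-14)
    p = pts(h)
    scale = bond / np.linalg.norm(p[1] - p[0])
    return p * scale


@dataclass
class ResidueTemplate:
    """Rigid idealised residue: named atoms, bonds, and rotatable decorations."""

    kind: str  # "GlcA" | "GalNAc"
    names: list
    coords: np.ndarray  # (n, 3)
    bonds: list  # (i, j) index pairs
    ring_signs: list = field(default_factory=list)  # expected sign of each ring torsion
    rotatable: dict = field(default_factory=dict)  # name -> (chain names, moved names)
    anomer: str = "beta"

    @property
    def index(self):
        return {n: i for i, n in enumerate(self.names)}

    @property
    def elements(self):
        return [_element_of(n) for n in self.names]

    def position(self, name: str) -> np.ndarray:
        try:
            return self.coords[self.index[name]]
        except KeyError:
            raise StructuralError(f"atom {name!r} not present in {self.kind} template")

    def ring_torsions(self) -> np.ndarray:
        return ring_pucker_torsions(self)

    def drop(self, names) -> "ResidueTemplate":
        """Copy of the template without the given atoms (linkage-site pruning)."""
        keep = [i for i, n in enumerate(self.names) if n not in set(names)]
        remap = {old: new for new, old in enumerate(keep)}
        return ResidueTemplate(
            kind=self.kind,
            names=[self.names[i] for i in keep],
            coords=self.coords[keep].copy(),
            bonds=[
                (remap[i], remap[j])
                for i, j in self.bonds
                if i in remap and j in remap
            ],
            ring_signs=list(self.ring_signs),
            rotatable={
                k: (chain, [m for m in moved if m not in set(names)])
                for k, (chain, moved) in self.rotatable.items()
            },
            anomer=self.anomer,
        )


def _substituent_dirs(ring: np.ndarray, k: int):
    """(axial, equatorial) unit directions at ring atom k of a chair."""
    p = ring[k]
    a = ring[(k - 1) % 6] - p
    b = ring[(k + 1) % 6] - p
    a /= np.linalg.norm(a)
    b /= np.linalg.norm(b)
    s = a + b
    s /= np.linalg.norm(s)
    t = np.cross(a, b)
    t /= np.linalg.norm(t)
    half = np.radians(54.735)  # half the tetrahedral angle between the two slots
    d1 = -s * np.cos(half) + t * np.sin(half)
    d2 = -s * np.cos(half) - t * np.sin(half)
    centroid = ring.mean(axis=0)
    normal = np.zeros(3)
    for i in range(6):
        normal += np.cross(ring[i] - centroid, ring[(i + 1) % 6] - centroid)
    normal /= np.linalg.norm(normal)
    if abs(np.dot(d1, normal)) >= abs(np.dot(d2, normal)):
        return d1, d2
    return d2, d1


def build_residue_template(kind: str, anomer: str = "beta") -> ResidueTemplate:
    """Construct an idealised 4C1-chair residue template.

    GlcA: beta-D-glucopyranuronate — all substituents equatorial, carboxylate
    at C5.  GalNAc: 2-acetamido-2-deoxy-beta-D-galactopyranose — axial O4
    (the galacto epimer), N-acetyl at C2, hydroxymethyl at C5.  `anomer`
    selects the reducing-end C1 configuration (only meaningful for residue 1).
    """
    if kind not in ("GlcA", "GalNAc"):
        raise UnknownResidueKindError(f"unsupported residue kind: {kind!r}")
    if anomer not in ("alpha", "beta"):
        raise UnknownResidueKindError(f"unknown anomer: {anomer!r}")

    ring = _chair_ring()
    names = list(RING_ATOMS)
    coords = [ring[i] for i in range(6)]
    bonds = [(i, (i + 1) % 6) for i in range(6)]

    def add(name, parent, pos):
        names.append(name)
        coords.append(np.asarray(pos, dtype=float))
        bonds.append((names.index(parent), len(names) - 1))
        return pos

    def pos(name):
        return coords[names.index(name)]

    def sub(ring_idx, which):
        ax, eq = _substituent_dirs(ring, ring_idx)
        return ax if which == "axial" else eq

    # C1: anomeric O1 (beta = equatorial) + H1
    o1_dir, h1_dir = ("equatorial", "axial") if anomer == "beta" else ("axial", "equatorial")
    add("O1", "C1", ring[1] + sub(1, o1_dir) * BOND["C1-O1"])
    add("H1", "C1", ring[1] + sub(1, h1_dir) * BOND["C-H"])
    add("HO1", "O1", place_atom(pos("C2"), pos("C1"), pos("O1"), BOND["O-H"], 107.0, 180.0))

    rotatable = {}
    if kind == "GlcA":
        add("O2", "C2", ring[2] + sub(2, "equatorial") * BOND["C-O"])
        add("H2", "C2", ring[2] + sub(2, "axial") * BOND["C-H"])
        add("HO2", "O2", place_atom(pos("C1"), pos("C2"), pos("O2"), BOND["O-H"], 107.0, 180.0))
        add("O3", "C3", ring[3] + sub(3, "equatorial") * BOND["C-O"])
        add("H3", "C3", ring[3] + sub(3, "axial") * BOND["C-H"])
        add("HO3", "O3", place_atom(pos("C2"), pos("C3"), pos("O3"), BOND["O-H"], 107.0, 180.0))
        add("O4", "C4", ring[4] + sub(4, "equatorial") * BOND["C-O"])
        add("H4", "C4", ring[4] + sub(4, "axial") * BOND["C-H"])
        add("HO4", "O4", place_atom(pos("C3"), pos("C4"), pos("O4"), BOND["O-H"], 107.0, 180.0))
        # carboxylate at C5
        add("C6", "C5", ring[5] + sub(5, "equatorial") * BOND["C-C"])
        add("H5", "C5", ring[5] + sub(5, "axial") * BOND["C-H"])
        add("O6A", "C6", place_atom(pos("O5"), pos("C5"), pos("C6"), BOND["C=O"], 117.0, -90.0))
        add("O6B", "C6", place_atom(pos("O5"), pos("C5"), pos("C6"), BOND["C=O"], 117.0, 90.0))
    else:  # GalNAc
        add("N2", "C2", ring[2] + sub(2, "equatorial") * BOND["C-N"])
        add("H2", "C2", ring[2] + sub(2, "axial") * BOND["C-H"])
        # planar trans acetamido: HN anti to H2 about C2-N2, carbonyl O anti to HN
        add("HN", "N2", place_atom(pos("H2"), pos("C2"), pos("N2"), BOND["N-H"], 118.0, 180.0))
        add("C7", "N2", place_atom(pos("H2"), pos("C2"), pos("N2"), BOND["N-C(=O)"], 123.0, 0.0))
        add("O7", "C7", place_atom(pos("C2"), pos("N2"), pos("C7"), BOND["C=O"], 122.0, 0.0))
        add("C8", "C7", place_atom(pos("C2"), pos("N2"), pos("C7"), BOND["C-C"], 116.0, 180.0))
        add("O3", "C3", ring[3] + sub(3, "equatorial") * BOND["C-O"])
        add("H3", "C3", ring[3] + sub(3, "axial") * BOND["C-H"])
        add("HO3", "O3", place_atom(pos("C2"), pos("C3"), pos("O3"), BOND["O-H"], 107.0, 180.0))
        # galacto: axial O4, equatorial H4
        add("O4", "C4", ring[4] + sub(4, "axial") * BOND["C-O"])
        add("H4", "C4", ring[4] + sub(4, "equatorial") * BOND["C-H"])
        add("HO4", "O4", place_atom(pos("C3"), pos("C4"), pos("O4"), BOND["O-H"], 107.0, 180.0))
        # hydroxymethyl at C5, omega = O5-C5-C6-O6, default trans
        add("C6", "C5", ring[5] + sub(5, "equatorial") * BOND["C-C"])
        add("H5", "C5", ring[5] + sub(5, "axial") * BOND["C-H"])
        add("O6", "C6", place_atom(pos("O5"), pos("C5"), pos("C6"), BOND["C-O"], 109.5, 180.0))
        add("H6R", "C6", place_atom(pos("O5"), pos("C5"), pos("C6"), BOND["C-H"], 109.5, 60.0))
        add("H6S", "C6", place_atom(pos("O5"), pos("C5"), pos("C6"), BOND["C-H"], 109.5, -60.0))
        add("HO6", "O6", place_atom(pos("C5"), pos("C6"), pos("O6"), BOND["O-H"], 107.0, 180.0))
        rotatable["acetamido"] = (("H2", "C2", "N2", "HN"), ["HN", "C7", "O7", "C8"])
        rotatable["omega"] = (("O5", "C5", "C6", "O6"), ["O6", "H6R", "H6S", "HO6"])

    coords = np.asarray(coords, dtype=float)
    tmpl = ResidueTemplate(
        kind=kind,
        names=names,
        coords=coords,
        bonds=bonds,
        rotatable=rotatable,
        anomer=anomer,
    )
    tmpl.ring_signs = [int(np.sign(t)) for t in ring_pucker_torsions(tmpl)]
    return tmpl


def ring_pucker_torsions(residue) -> np.ndarray:
    """The six ring torsions (consecutive ring-atom quadruples), in degrees.

    Accepts anything exposing `.position(name)` for the six ring atoms.
    A 4C1 chair gives values alternating near +60/-60.
    """
    try:
        pts = [residue.position(n) for n in RING_ATOMS]
    except StructuralError as exc:
        raise StructuralError(f"broken ring: {exc}") from exc
    return np.array(
        [
            dihedral(pts[i], pts[(i + 1) % 6], pts[(i + 2) % 6], pts[(i + 3) % 6])
            for i in range(6)
        ]
    )


measure_torsion = dihedral  # the public torsion measurement is the dihedral itself


@dataclass
class GlycosidicLinkage:
    """One glycosidic bond, donor C1 -> acceptor ring carbon."""

    type: str  # "beta1-3" | "beta1-4"
    donor_residue_index: int  # 1-based
    acceptor_residue_index: int
    phi: float
    psi: float


class PlacedResidue:
    """View of one residue inside an assembled model."""

    def __init__(self, model, res_idx):
        self._model = model
        self.i = res_idx

    @property
    def label(self):
        return self._model.labels[self.i]

    @property
    def kind(self):
        return self._model.kinds[self.i]

    def position(self, name):
        return self._model.position(self.label, name)

    def atom_names(self):
        lo, hi = self._model.res_slices[self.i]
        return self._model.atom_names[lo:hi]


class OligosaccharideModel:
    """An assembled chondroitin chain: atoms, coordinates, linkages, bonds."""

    def __init__(self, labels, kinds, atom_names, atom_res, coords, bonds, linkages,
                 res_slices, anomer="beta"):
        self.labels = labels  # e.g. ["N1", "U2", ...]
        self.kinds = kinds
        self.atom_names = atom_names  # per-atom name
        self.atom_res = np.asarray(atom_res)  # per-atom residue index (0-based)
        self.coords = np.asarray(coords, dtype=float)
        self.bonds = bonds  # global (i, j) pairs
        self.linkages = linkages  # list[GlycosidicLinkage]
        self.res_slices = res_slices  # residue -> (lo, hi) atom index range
        self.anomer = anomer
        self._index = {
            (labels[r], n): i
            for i, (r, n) in enumerate(zip(self.atom_res, atom_names))
        }
        self.clashes = []

    # -- lookups ----------------------------------------------------------
    @property
    def n_residues(self):
        return len(self.labels)

    @property
    def elements(self):
        return [_element_of(n) for n in self.atom_names]

    def atom_index(self, residue, name) -> int:
        label = residue if isinstance(residue, str) else self.labels[residue - 1]
        try:
            return self._index[(label, name)]
        except KeyError:
            raise StructuralError(f"no atom {name!r} in residue {label!r}")

    def position(self, residue, name=None) -> np.ndarray:
        if name is None:  # qualified "U2:H1" form
            residue, name = residue.split(":")
        return self.coords[self.atom_index(residue, name)]

    def residue(self, i) -> PlacedResidue:
        """1-based residue accessor (residue 1 = reducing end)."""
        return PlacedResidue(self, i - 1)

    def distance(self, id_a: str, id_b: str) -> float:
        return float(np.linalg.norm(self.position(id_a) - self.position(id_b)))

    def copy_with_coords(self, coords) -> "OligosaccharideModel":
        m = OligosaccharideModel(
            self.labels, self.kinds, self.atom_names, self.atom_res,
            np.asarray(coords, float), self.bonds, list(self.linkages),
            self.res_slices, self.anomer,
        )
        return m


def linkage_quadruples(model: OligosaccharideModel, linkage: GlycosidicLinkage):
    """(phi_atoms, psi_atoms) as (residue-label, atom-name) quadruples."""
    d = model.labels[linkage.donor_residue_index - 1]
    a = model.labels[linkage.acceptor_residue_index - 1]
    if linkage.type == "beta1-3":
        phi = ((d, "O5"), (d, "C1"), (d, "O1"), (a, "C3"))
        psi = ((d, "C1"), (d, "O1"), (a, "C3"), (a, "C4"))
    else:
        phi = ((d, "O5"), (d, "C1"), (d, "O1"), (a, "C4"))
        psi = ((d, "C1"), (d, "O1"), (a, "C4"), (a, "C5"))
    return phi, psi


def measure_glycosidic_torsions(model: OligosaccharideModel):
    """[(linkage, phi, psi)] measured from coordinates via the IUPAC quadruples."""
    out = []
    for lk in model.linkages:
        phi_q, psi_q = linkage_quadruples(model, lk)
        phi = dihedral(*(model.position(r, n) for r, n in phi_q))
        psi = dihedral(*(model.position(r, n) for r, n in psi_q))
        out.append((lk, phi, psi))
    return out


class ChainBuilder:
    """Fast torsion-parameterised coordinate generator for one chain topology.

    The topology (length, anomer) is fixed at construction; `coords()` maps a
    glycosidic torsion list (and optional exocyclic torsions) to Cartesian
    coordinates, and `model()` wraps them in an OligosaccharideModel.
    """

    def __init__(self, length: int, anomer: str = "beta"):
        if length < 2:
            raise StructuralError("chain needs at least 2 residues")
        if length % 2:
            raise StructuralError(
                f"odd length {length}: chondroitin CN_n oligomers have even length"
            )
        self.length = length
        self.anomer = anomer

        base_n_red = build_residue_template("GalNAc", anomer=anomer)
        base_n = build_residue_template("GalNAc")
        base_u = build_residue_template("GlcA")

        self.templates = []
        self.link_types = []  # linkage i joins residue i+2 (donor) to i+1 (acceptor)
        for i in range(1, length + 1):
            kind = "GalNAc" if i % 2 else "GlcA"
            tmpl = base_n_red if i == 1 else (base_n if i % 2 else base_u)
            drop = []
            if i > 1:  # donor: O1 becomes the glycosidic oxygen
                drop.append("HO1")
            if i < length:  # acceptor of linkage i
                drop += ["O3", "HO3"] if kind == "GalNAc" else ["O4", "HO4"]
            t = tmpl.drop(drop)
            # remember the pruned hydroxyl position: it is where the incoming
            # glycosidic oxygen sits
            site = "O3" if kind == "GalNAc" else "O4"
            t.link_site = tmpl.position(site).copy() if i < length else None
            self.templates.append(t)
            if i < length:
                self.link_types.append("beta1-3" if kind == "GalNAc" else "beta1-4")

        # donor anchors / internal geometry (identical for all donors of a kind)
        self._donor_geo = []
        for i, t in enumerate(self.templates):
            if i == 0:
                self._donor_geo.append(None)
                continue
            ix = t.index
            o1, c1, o5 = t.coords[ix["O1"]], t.coords[ix["C1"]], t.coords[ix["O5"]]
            self._donor_geo.append(
                dict(
                    d_c1o1=float(np.linalg.norm(c1 - o1)),
                    d_o5c1=float(np.linalg.norm(o5 - c1)),
                    ang_o5c1o1=angle(o5, c1, o1),
                    idx=(ix["O1"], ix["C1"], ix["O5"]),
                )
            )

        # global atom bookkeeping
        self.labels = [
            ("N" if i % 2 else "U") + str(i) for i in range(1, length + 1)
        ]
        self.kinds = ["GalNAc" if i % 2 else "GlcA" for i in range(1, length + 1)]
        self.atom_names = []
        self.atom_res = []
        self.res_slices = []
        bonds = []
        offset = 0
        for r, t in enumerate(self.templates):
            n = len(t.names)
            self.res_slices.append((offset, offset + n))
            self.atom_names += t.names
            self.atom_res += [r] * n
            bonds += [(i + offset, j + offset) for i, j in t.bonds]
            offset += n
        # glycosidic bonds: donor O1 - acceptor C3/C4
        for li, lt in enumerate(self.link_types):
            acc, don = li, li + 1
            acc_c = "C3" if lt == "beta1-3" else "C4"
            bonds.append(
                (
                    self.res_slices[don][0] + self.templates[don].index["O1"],
                    self.res_slices[acc][0] + self.templates[acc].index[acc_c],
                )
            )
        self.bonds = bonds
        self.n_atoms = offset

        # exocyclic torsion labels, in a stable order
        self.exo_labels = []
        for r, t in enumerate(self.templates):
            for name in t.rotatable:
                self.exo_labels.append((r, name))

        # precompute rotatable machinery per template instance
        self._rot = []
        for r, t in enumerate(self.templates):
            rots = {}
            for name, (chain, moved) in t.rotatable.items():
                ix = t.index
                default = dihedral(*(t.coords[ix[c]] for c in chain))
                rots[name] = dict(
                    axis=(ix[chain[1]], ix[chain[2]]),
                    moved=[ix[m] for m in moved],
                    default=default,
                )
            self._rot.append(rots)

    # ------------------------------------------------------------------
    def _local_coords(self, r, exo):
        t = self.templates[r]
        c = t.coords
        if exo:
            rots = self._rot[r]
            for name, target in exo:
                if name not in rots:
                    continue
                info = rots[name]
                delta = target - info["default"]
                if abs(delta) < 1e-12:
                    continue
                c = c.copy() if c is t.coords else c
                i, j = info["axis"]
                # inline Rodrigues rotation (hot path in annealing)
                origin = c[i]
                axis = c[j] - origin
                axis = axis / np.linalg.norm(axis)
                th = np.radians(delta)
                p = c[info["moved"]] - origin
                c[info["moved"]] = (
                    p * np.cos(th)
                    + np.cross(axis, p) * np.sin(th)
                    + np.outer(p @ axis, axis) * (1.0 - np.cos(th))
                    + origin
                )
        return c

    def coords(self, torsions, exo_torsions=None) -> np.ndarray:
        """Cartesian coordinates for glycosidic torsions [(phi, psi), ...].

        `exo_torsions` maps (residue0-based, name) -> degrees for the named
        exocyclic torsions; unset ones stay at their template defaults.
        """
        if len(torsions) != self.length - 1:
            raise StructuralError(
                f"need {self.length - 1} torsion pairs, got {len(torsions)}"
            )
        exo_torsions = exo_torsions or {}
        per_res_exo = [[] for _ in range(self.length)]
        for (r, name), val in exo_torsions.items():
            per_res_exo[r].append((name, val))
        locals_list = [
            self._local_coords(r, per_res_exo[r]) for r in range(self.length)
        ]
        return self.coords_from_locals(torsions, locals_list)

    def coords_from_locals(self, torsions, locals_list) -> np.ndarray:
        """Chain placement given per-residue local coordinate arrays.

        Exposed so callers that perturb one torsion at a time (the annealer)
        can cache the exocyclic-rotated residue frames between evaluations.
        """
        out = np.empty((self.n_atoms, 3))
        acc_rot = [np.eye(3)] + [None] * (self.length - 1)
        acc_t = [np.zeros(3)] + [None] * (self.length - 1)

        lo, hi = self.res_slices[0]
        out[lo:hi] = locals_list[0]

        for li, (phi, psi) in enumerate(torsions):
            acc, don = li, li + 1
            lt = self.link_types[li]
            t_acc = self.templates[acc]
            alo, _ = self.res_slices[acc]
            aix = t_acc.index
            if lt == "beta1-3":
                c_link = out[alo + aix["C3"]]
                c_next = out[alo + aix["C4"]]
            else:
                c_link = out[alo + aix["C4"]]
                c_next = out[alo + aix["C5"]]
            # glycosidic O sits on the acceptor's pruned hydroxyl direction;
            # transform its stored local position with the acceptor's placement
            o1w = acc_rot[acc] @ t_acc.link_site + acc_t[acc]
            geo = self._donor_geo[don]
            c1w = place_atom(c_next, c_link, o1w, geo["d_c1o1"], GLYCOSIDIC_ANGLE, psi)
            o5w = place_atom(c_link, o1w, c1w, geo["d_o5c1"], geo["ang_o5c1o1"], phi)
            t_don = self.templates[don]
            src = t_don.coords[list(geo["idx"])]
            rot, tr = frame_map(src, np.array([o1w, c1w, o5w]))
            dlo, dhi = self.res_slices[don]
            out[dlo:dhi] = locals_list[don] @ rot.T + tr
            acc_rot[don] = rot
            acc_t[don] = tr
        return out

    def model(self, torsions, exo_torsions=None, check_clashes=True) -> OligosaccharideModel:
        coords = self.coords(torsions, exo_torsions)
        linkages = [
            GlycosidicLinkage(self.link_types[i], i + 2, i + 1, float(p), float(s))
            for i, (p, s) in enumerate(torsions)
        ]
        m = OligosaccharideModel(
            self.labels, self.kinds, self.atom_names, self.atom_res, coords,
            self.bonds, linkages, self.res_slices, self.anomer,
        )
        if check_clashes:
            m.clashes = find_clashes(m)
            if m.clashes:
                warnings.warn(
                    f"{len(m.clashes)} non-bonded heavy-atom pair(s) closer than "
                    f"{CLASH_CUTOFF} A after placement", stacklevel=2,
                )
        return m


def bonded_within(model_or_builder, max_bonds: int) -> np.ndarray:
    """Boolean matrix: graph distance over the bond network <= max_bonds."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import shortest_path

    n = model_or_builder.n_atoms if hasattr(model_or_builder, "n_atoms") \
        else len(model_or_builder.atom_names)
    bonds = model_or_builder.bonds
    ij = np.asarray(bonds)
    g = coo_matrix(
        (np.ones(len(ij)), (ij[:, 0], ij[:, 1])), shape=(n, n)
    )
    d = shortest_path(g, method="D", directed=False, unweighted=True)
    return d <= max_bonds


def find_clashes(model: OligosaccharideModel, cutoff: float = CLASH_CUTOFF):
    """Non-bonded heavy-atom pairs closer than `cutoff` Angstrom."""
    heavy = np.array([e != "H" for e in model.elements])
    near = bonded_within(model, 1)
    idx = np.where(heavy)[0]
    sub = model.coords[idx]
    d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
    out = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            if d[a, b] < cutoff and not near[i, j]:
                out.append((i, j, float(d[a, b])))
    return out


def assemble_chain(length: int, torsions, anomer: str = "beta",
                   check_clashes: bool = True) -> OligosaccharideModel:
    """Assemble a CN_length chain (GalNAc at the reducing end) with the given
    per-linkage (phi, psi) torsions, reducing end first."""
    return ChainBuilder(length, anomer).model(torsions, check_clashes=check_clashes)
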