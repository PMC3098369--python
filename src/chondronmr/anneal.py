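"""Restrained simulated annealing of glycan torsions.

The conformational search runs in torsion space: pyranose rings are rigid
4C1 chairs (their geometry never leaves the allowed pucker window, which is
what the ring restraints enforce), and the state vector holds the glycosidic
(phi, psi) pairs plus the named exocyclic torsions (hydroxymethyl omega and
acetamido rotation of each GalNAc).  A Metropolis Monte-Carlo walk under a
heat (1 K -> 500 K) / hold / cool (-> 0 K) schedule samples this space
against a potential of three non-negative terms:

* flat-bottom NOE distance restraints, k = 10 kcal/mol/A^2 outside bounds;
* flat-bottom ring-torsion restraints, zero within +/-(60 +/- 20) deg and
  k = 100 kcal/mol/rad^2 outside (identically zero here by construction,
  but evaluated so arbitrary coordinates can be scored);
* a soft-sphere steric term, k_s (c - d)^2 for heavy-atom pairs more than
  three bonds apart closer than c = 3.0 A.

Each annealing round ends with a derivative-free quench (Powell) standing in
for gradient minimisation.  Repeating rounds from independent seeds and
keeping the lowest-energy fraction yields the reported conformer ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .errors import StructuralError
from .geometry import wrap_angle
from .glycan import (
    ChainBuilder,
    OligosaccharideModel,
    ring_pucker_torsions,
    bonded_within,
)

GAS_CONSTANT = 0.0019872  # kcal/mol/K

RING_WINDOW_CENTER = 60.0  # deg
RING_WINDOW_HALFWIDTH = 20.0  # deg


@dataclass
class EnergyModel:
    restraint_k: float = 10.0  # kcal/mol/A^2
    ring_k: float = 100.0  # kcal/mol/rad^2
    steric_k: float = 5.0  # kcal/mol/A^2
    steric_cutoff: float = 3.0  # A

    def __post_init__(self):
        if min(self.restraint_k, self.ring_k, self.steric_k, self.steric_cutoff) <= 0:
            raise ValueError("all energy-model constants must be positive")


@dataclass
class AnnealingSchedule:
    """Linear heat/hold/cool temperature profile with per-step MC moves."""

    t_start: float = 1.0
    t_max: float = 500.0
    t_end: float = 0.0
    heat_steps: int = 80
    hold_steps: int = 80
    cool_steps: int = 120
    moves_per_step: int = 6
    sigma_hot: float = 30.0  # proposal sd (deg) at t_max
    sigma_cold: float = 2.0  # proposal sd near 0 K

    def temperatures(self) -> np.ndarray:
        heat = np.linspace(self.t_start, self.t_max, self.heat_steps, endpoint=False) \
            if self.heat_steps else np.empty(0)
        hold = np.full(self.hold_steps, self.t_max)
        cool = np.linspace(self.t_max, self.t_end, self.cool_steps) \
            if self.cool_steps else np.empty(0)
        return np.concatenate([heat, hold, cool])

    def sigma(self, temperature: float) -> float:
        frac = min(max(temperature / self.t_max, 0.0), 1.0)
        return self.sigma_cold + (self.sigma_hot - self.sigma_cold) * frac


@dataclass
class Conformer:
    model: OligosaccharideModel
    energy: float
    max_violation: float
    seed_index: int = 0
    torsions: Optional[np.ndarray] = None
    exo: Optional[dict] = None


@dataclass
class ConformerEnsemble:
    models: list  # of Conformer, ascending energy
    n_generated: int
    kept_fraction: float

    def __iter__(self):
        return iter(self.models)

    def __len__(self):
        return len(self.models)

    @property
    def energies(self):
        return np.array([c.energy for c in self.models])


# ---------------------------------------------------------------------------
# energy terms on plain models (API) and on precompiled index arrays (engine)


def _resolve_pairs(model_or_builder, restraints):
    if hasattr(model_or_builder, "atom_index"):
        lookup = model_or_builder.atom_index
    else:
        b = model_or_builder
        amap = {}
        for i, (r, n) in enumerate(zip(b.atom_res, b.atom_names)):
            amap[(b.labels[r], n)] = i

        def lookup(label, name):
            try:
                return amap[(label, name)]
            except KeyError:
                raise StructuralError(f"no atom {name!r} in residue {label!r}")

    ia, ib = [], []
    for r in restraints:
        la, na = r.atom_a.split(":")
        lb, nb = r.atom_b.split(":")
        ia.append(lookup(la, na))
        ib.append(lookup(lb, nb))
    lower = np.array([r.lower for r in restraints], dtype=float)
    upper = np.array([r.upper for r in restraints], dtype=float)
    ks = np.array([r.force_constant for r in restraints], dtype=float)
    return np.array(ia), np.array(ib), lower, upper, ks


def _restraint_energy_arrays(coords, ia, ib, lower, upper, ks):
    d = np.linalg.norm(coords[ia] - coords[ib], axis=1)
    over = np.maximum(d - upper, 0.0)
    under = np.maximum(lower - d, 0.0)
    viol = np.maximum(over, under)
    return float(np.sum(ks * viol * viol)), float(viol.max(initial=0.0))


def restraint_energy(model: OligosaccharideModel, restraints):
    """(energy kcal/mol, max violation A) of flat-bottom distance restraints."""
    if not restraints:
        return 0.0, 0.0
    arrays = _resolve_pairs(model, restraints)
    return _restraint_energy_arrays(model.coords, *arrays)


def ring_restraint_energy(model: OligosaccharideModel, k: float = 100.0) -> float:
    """Flat-bottom pucker energy: zero while every ring torsion stays within
    its +/-(60 +/- 20) deg window (sign per the 4C1 alternation), quadratic
    with force constant k (kcal/mol/rad^2) outside."""
    total = 0.0
    lo = RING_WINDOW_CENTER - RING_WINDOW_HALFWIDTH
    hi = RING_WINDOW_CENTER + RING_WINDOW_HALFWIDTH
    for i in range(1, model.n_residues + 1):
        res = model.residue(i)
        tors = ring_pucker_torsions(res)
        signs = [1, -1, 1, -1, 1, -1]  # D-series 4C1 pattern starting O5-C1-C2-C3
        for t, s in zip(tors, signs):
            v = s * t
            dev = max(lo - v, 0.0) + max(v - hi, 0.0)
            total += k * np.radians(dev) ** 2
    return float(total)


def steric_pairs(model_or_builder):
    """Heavy-atom index pairs more than three bonds apart."""
    if hasattr(model_or_builder, "n_atoms"):
        names = model_or_builder.atom_names
    else:
        names = model_or_builder.atom_names
    heavy = np.array([not n.startswith("H") for n in names])
    near = bonded_within(model_or_builder, 3)
    idx = np.where(heavy)[0]
    pi, pj = [], []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            if not near[i, j]:
                pi.append(i)
                pj.append(j)
    return np.array(pi), np.array(pj)


def _steric_energy_arrays(coords, pi, pj, k, cutoff):
    d = np.linalg.norm(coords[pi] - coords[pj], axis=1)
    pen = np.maximum(cutoff - d, 0.0)
    return float(k * np.sum(pen * pen))


def steric_energy(model: OligosaccharideModel, energy_model: EnergyModel = None) -> float:
    em = energy_model or EnergyModel()
    pi, pj = steric_pairs(model)
    return _steric_energy_arrays(model.coords, pi, pj, em.steric_k, em.steric_cutoff)


def total_energy(model: OligosaccharideModel, restraints,
                 energy_model: EnergyModel = None) -> float:
    """Restraint + ring-pucker + soft-sphere steric energy (kcal/mol)."""
    em = energy_model or EnergyModel()
    e_rest, _ = restraint_energy(model, restraints)
    return e_rest + ring_restraint_energy(model, em.ring_k) + steric_energy(model, em)


# ---------------------------------------------------------------------------
# the annealing engine


class AnnealingEngine:
    """Precompiled energy evaluation for one chain topology + restraint set."""

    def __init__(self, builder: ChainBuilder, restraints,
                 energy_model: EnergyModel = None):
        self.builder = builder
        self.restraints = list(restraints)
        self.em = energy_model or EnergyModel()
        self.ia, self.ib, self.lower, self.upper, self.ks = _resolve_pairs(
            builder, self.restraints
        )
        self.pi, self.pj = steric_pairs(builder)
        self.n_glyco = 2 * (builder.length - 1)
        self.exo_labels = list(builder.exo_labels)
        self.ndof = self.n_glyco + len(self.exo_labels)
        # default exocyclic torsions (template geometry)
        self.exo_defaults = np.array(
            [builder._rot[r][name]["default"] for r, name in self.exo_labels]
        )

    def default_state(self, start_torsions=None) -> np.ndarray:
        if start_torsions is None:
            start_torsions = []
            for lt in self.builder.link_types:
                start_torsions.append((-60.0, 120.0 if lt == "beta1-3" else -120.0))
        x = np.concatenate(
            [np.asarray(start_torsions, dtype=float).ravel(), self.exo_defaults]
        )
        return x

    def split(self, x):
        pairs = x[: self.n_glyco].reshape(-1, 2)
        exo = {lab: x[self.n_glyco + i] for i, lab in enumerate(self.exo_labels)}
        return pairs, exo

    def coords(self, x, locals_list=None):
        pairs, exo = self.split(x)
        if locals_list is None:
            return self.builder.coords(pairs, exo)
        return self.builder.coords_from_locals(pairs, locals_list)

    def _locals(self, x):
        pairs, exo = self.split(x)
        per_res = [[] for _ in range(self.builder.length)]
        for (r, name), val in exo.items():
            per_res[r].append((name, val))
        return [self.builder._local_coords(r, per_res[r]) for r in range(self.builder.length)]

    def energy_of_coords(self, coords):
        e_r, viol = _restraint_energy_arrays(
            coords, self.ia, self.ib, self.lower, self.upper, self.ks
        )
        e_s = _steric_energy_arrays(coords, self.pi, self.pj, self.em.steric_k,
                                    self.em.steric_cutoff)
        return e_r + e_s, viol

    def energy(self, x):
        locals_list = self._locals(x)
        return self.energy_of_coords(self.coords(x, locals_list))


def anneal_once(engine: AnnealingEngine, schedule: AnnealingSchedule = None,
                seed: int = 0, start_torsions=None) -> Conformer:
    """One restrained simulated-annealing round; deterministic for fixed seed.

    Returns the quenched end-of-cooling conformer with its energy and the
    maximum restraint violation.
    """
    schedule = schedule or AnnealingSchedule()
    rng = np.random.default_rng(seed)
    x = engine.default_state(start_torsions)
    locals_list = engine._locals(x)
    e, _ = engine.energy_of_coords(engine.coords(x, locals_list))

    n_exo_start = engine.n_glyco
    for temperature in schedule.temperatures():
        sigma = schedule.sigma(temperature)
        kt = GAS_CONSTANT * temperature
        for _ in range(schedule.moves_per_step):
            i = int(rng.integers(engine.ndof))
            step = rng.normal(0.0, sigma)
            old = x[i]
            x[i] = wrap_angle(old + step)
            if i >= n_exo_start:
                r, name = engine.exo_labels[i - n_exo_start]
                old_local = locals_list[r]
                locals_list[r] = engine._builder_local(r, x)
            e_new, _ = engine.energy_of_coords(engine.coords(x, locals_list))
            de = e_new - e
            if de <= 0 or (kt > 0 and rng.random() < np.exp(-de / kt)):
                e = e_new
            else:
                x[i] = old
                if i >= n_exo_start:
                    locals_list[r] = old_local

    # final quench: derivative-free minimisation of the same potential
    res = minimize(
        lambda v: engine.energy(v)[0], x, method="Powell",
        options=dict(maxfev=2000, xtol=1e-4, ftol=1e-8),
    )
    x = np.array([wrap_angle(v) for v in res.x])
    e, viol = engine.energy(x)
    pairs, exo = engine.split(x)
    model = engine.builder.model(pairs, exo, check_clashes=False)
    return Conformer(model=model, energy=e, max_violation=viol,
                     torsions=pairs.copy(), exo=dict(exo))


# helper used inside the MC loop (kept off the engine hot path for clarity)
def _builder_local(self, r, x):
    per = [
        (name, x[self.n_glyco + i])
        for i, (rr, name) in enumerate(self.exo_labels)
        if rr == r
    ]
    return self.builder._local_coords(r, per)


AnnealingEngine._builder_local = _builder_local


def generate_ensemble(engine: AnnealingEngine, n_rounds: int = 250,
                      keep_fraction: float = 0.10,
                      schedule: AnnealingSchedule = None, seed: int = 0,
                      start_torsions=None) -> ConformerEnsemble:
    """Run `n_rounds` independent annealing rounds (seeds seed+i) and keep the
    lowest-energy fraction, sorted ascending; energy ties break on seed index."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    conformers = []
    for i in range(n_rounds):
        c = anneal_once(engine, schedule, seed=seed + i, start_torsions=start_torsions)
        c.seed_index = i
        conformers.append(c)
    conformers.sort(key=lambda c: (c.energy, c.seed_index))
    n_keep = int(round(keep_fraction * n_rounds))
    return ConformerEnsemble(models=conformers[:n_keep], n_generated=n_rounds,
                             kept_fraction=keep_fraction)
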