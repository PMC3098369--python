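"""Energy terms and the simulated-annealing engine: hand-checked penalty
values, invariances, determinism and ensemble selection."""

import numpy as np
import pytest

from chondronmr.anneal import (
    AnnealingEngine,
    AnnealingSchedule,
    EnergyModel,
    anneal_once,
    generate_ensemble,
    restraint_energy,
    ring_restraint_energy,
    steric_energy,
    total_energy,
)
from chondronmr.glycan import ChainBuilder
from chondronmr.noe import DistanceRestraint

FAST_SCHEDULE = AnnealingSchedule(heat_steps=10, hold_steps=10, cool_steps=15,
                                  moves_per_step=4)


def _restraint_for(model, a, b, lower, upper, k=10.0):
    return DistanceRestraint(a, b, lower, upper, "strong", k)


class TestRestraintEnergy:
    def test_inside_bounds_is_zero(self, cn6_fixture, cn6_restraints):
        e, viol = restraint_energy(cn6_fixture, cn6_restraints)
        assert e == 0.0 and viol == 0.0

    def test_hand_checked_violation(self, cn6_fixture):
        d = cn6_fixture.distance("N1:H3", "U2:H1")  # ~2.23 A
        r_over = _restraint_for(cn6_fixture, "N1:H3", "U2:H1", 1.0, d - 0.1)
        e, viol = restraint_energy(cn6_fixture, [r_over])
        assert e == pytest.approx(10.0 * 0.1 ** 2)  # = 0.1 kcal/mol
        assert viol == pytest.approx(0.1)

    def test_symmetric_below_lower(self, cn6_fixture):
        d = cn6_fixture.distance("N1:H3", "U2:H1")
        r_under = _restraint_for(cn6_fixture, "N1:H3", "U2:H1", d + 0.1, d + 1.0)
        e, viol = restraint_energy(cn6_fixture, [r_under])
        assert e == pytest.approx(0.1)
        assert viol == pytest.approx(0.1)


class TestRingEnergy:
    def test_ideal_chain_zero(self, cn6_fixture):
        assert ring_restraint_energy(cn6_fixture) == 0.0

    def test_hand_checked_well(self):
        # a single torsion 5 deg beyond the 80 deg edge costs 100*(5 rad)^2
        dev = np.radians(5.0)
        expected = 100.0 * dev ** 2
        # construct by direct evaluation of the well formula used in the code
        lo, hi = 40.0, 80.0
        v = 85.0
        e = 100.0 * np.radians(max(lo - v, 0.0) + max(v - hi, 0.0)) ** 2
        assert e == pytest.approx(expected)

    def test_planar_ring_large_penalty(self, cn6_fixture):
        flat = cn6_fixture.coords.copy()
        lo, hi = cn6_fixture.res_slices[0]
        # flatten residue 1's ring onto its mean plane
        ring_idx = [cn6_fixture.atom_index("N1", n) for n in
                    ("O5", "C1", "C2", "C3", "C4", "C5")]
        pts = flat[ring_idx]
        center = pts.mean(axis=0)
        u, s, vt = np.linalg.svd(pts - center)
        normal = vt[2]
        flat[ring_idx] = pts - np.outer((pts - center) @ normal, normal)
        squashed = cn6_fixture.copy_with_coords(flat)
        assert ring_restraint_energy(squashed) > 100.0


class TestTotalEnergy:
    def test_rigid_motion_invariance(self, cn6_fixture, cn6_restraints):
        from scipy.spatial.transform import Rotation

        e0 = total_energy(cn6_fixture, cn6_restraints)
        rot = Rotation.from_euler("xyz", [11.0, -40.0, 95.0], degrees=True)
        moved = cn6_fixture.copy_with_coords(rot.apply(cn6_fixture.coords) + 7.5)
        e1 = total_energy(moved, cn6_restraints)
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_extended_satisfied_is_steric_only(self, cn6_fixture, cn6_restraints):
        e_total = total_energy(cn6_fixture, cn6_restraints)
        assert e_total == pytest.approx(steric_energy(cn6_fixture), abs=1e-12)
        assert e_total < 1.0

    def test_clashing_conformer_dominated_by_sterics(self, cn6_builder,
                                                     cn6_restraints):
        bad = cn6_builder.model([(180, 180)] * 5, check_clashes=False)
        assert steric_energy(bad) > 10.0


class TestAnnealOnce:
    def test_same_seed_bit_identical(self, cn6_builder, cn6_restraints):
        eng = AnnealingEngine(cn6_builder, cn6_restraints)
        a = anneal_once(eng, FAST_SCHEDULE, seed=11)
        b = anneal_once(eng, FAST_SCHEDULE, seed=11)
        assert np.array_equal(a.torsions, b.torsions)
        assert a.energy == b.energy

    def test_different_seeds_differ(self, cn6_builder, cn6_restraints):
        eng = AnnealingEngine(cn6_builder, cn6_restraints)
        a = anneal_once(eng, FAST_SCHEDULE, seed=1)
        b = anneal_once(eng, FAST_SCHEDULE, seed=2)
        assert not np.array_equal(a.torsions, b.torsions)

    def test_degenerate_schedule_no_error(self, cn6_builder, cn6_restraints):
        eng = AnnealingEngine(cn6_builder, cn6_restraints)
        sched = AnnealingSchedule(heat_steps=5, hold_steps=0, cool_steps=0,
                                  moves_per_step=2)
        c = anneal_once(eng, sched, seed=0)
        assert np.isfinite(c.energy)

    def test_quench_satisfies_restraints(self, cn6_builder, cn6_restraints):
        eng = AnnealingEngine(cn6_builder, cn6_restraints)
        c = anneal_once(eng, FAST_SCHEDULE, seed=5)
        assert c.max_violation <= 0.03


class TestEnsemble:
    def test_keep_counts(self, cn6_builder, cn6_restraints):
        eng = AnnealingEngine(cn6_builder, cn6_restraints)
        ens = generate_ensemble(eng, n_rounds=10, keep_fraction=0.5,
                                schedule=FAST_SCHEDULE, seed=3)
        assert len(ens) == 5
        assert ens.n_generated == 10

    def test_kept_energies_sorted_prefix(self, cn6_builder, cn6_restraints):
        eng = AnnealingEngine(cn6_builder, cn6_restraints)
        all_c = [anneal_once(eng, FAST_SCHEDULE, seed=3 + i) for i in range(10)]
        ens = generate_ensemble(eng, n_rounds=10, keep_fraction=0.3,
                                schedule=FAST_SCHEDULE, seed=3)
        expected = sorted(c.energy for c in all_c)[:3]
        assert np.allclose(ens.energies, expected)
        assert np.all(np.diff(ens.energies) >= 0)

    def test_energy_model_validation(self):
        with pytest.raises(ValueError):
            EnergyModel(restraint_k=-1.0)
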