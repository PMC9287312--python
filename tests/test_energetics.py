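"""Coulomb/LJ/GB/surface terms against independent oracles."""

import numpy as np
import pytest

from siescore.energetics import (COULOMB_CONSTANT, GBParameters, born_radii,
                                 canonical_orientation, coulomb_interaction,
                                 delta_msa, delta_reaction_field, lj_interaction,
                                 reaction_field, surface_area)
from siescore.structio import AtomRecord, MolecularSystem, Selection
from tests.conftest import make_random_groups, random_rigid_motion

GB = GBParameters()


def pair_system(q1, q2, r, eps=0.2, rmin_half=1.7, radius=1.6):
    atoms = [AtomRecord(1, "X1", "C", "GRP", 1, "A", (0.0, 0.0, 0.0), q1,
                        eps, rmin_half, radius),
             AtomRecord(2, "X2", "C", "GRP", 2, "B", (r, 0.0, 0.0), q2,
                        eps, rmin_half, radius)]
    system = MolecularSystem(atoms)
    system.set_partition(Selection((0,), "A"), Selection((1,), "B"))
    return system


def test_coulomb_hand_value_and_zero_charge():
    system = pair_system(+1.0, -1.0, 3.320636)
    params = GBParameters(interior_dielectric=1.0)
    got = coulomb_interaction(system, system.receptor, system.ligand, params)
    assert got == pytest.approx(-100.0, abs=1e-9)

    zero = pair_system(0.0, -1.0, 3.0)
    assert coulomb_interaction(zero, zero.receptor, zero.ligand, GB) == 0.0


def test_coulomb_and_lj_match_brute_force_on_random_systems():
    rng = np.random.default_rng(11)
    for _ in range(50):
        system, sel_a, sel_b = make_random_groups(rng)
        xyz, q = system.coordinates, system.charges
        eps, rmh = system.lj_epsilon, system.lj_rmin_half
        ec_ref = evdw_ref = 0.0
        for i in sel_a.indices:
            for j in sel_b.indices:
                r = np.linalg.norm(xyz[i] - xyz[j])
                ec_ref += COULOMB_CONSTANT / GB.interior_dielectric * q[i] * q[j] / r
                e = np.sqrt(eps[i] * eps[j])
                s6 = ((rmh[i] + rmh[j]) / r) ** 6
                evdw_ref += e * (s6 * s6 - 2 * s6)
        assert coulomb_interaction(system, sel_a, sel_b, GB) == \
               pytest.approx(ec_ref, abs=1e-9)
        assert lj_interaction(system, sel_a, sel_b) == pytest.approx(evdw_ref, abs=1e-9)


def test_pair_terms_symmetric_and_additive():
    rng = np.random.default_rng(12)
    system, sel_a, sel_b = make_random_groups(rng)
    assert coulomb_interaction(system, sel_a, sel_b, GB) == \
        pytest.approx(coulomb_interaction(system, sel_b, sel_a, GB), abs=1e-12)
    assert lj_interaction(system, sel_a, sel_b) == \
        pytest.approx(lj_interaction(system, sel_b, sel_a), abs=1e-12)
    # exact pairwise additivity over a partition of B
    half1 = Selection(tuple(sel_b.atom_indices[:5]))
    half2 = Selection(tuple(sel_b.atom_indices[5:]))
    assert coulomb_interaction(system, sel_a, sel_b, GB) == pytest.approx(
        coulomb_interaction(system, sel_a, half1, GB)
        + coulomb_interaction(system, sel_a, half2, GB), abs=1e-9)
    assert lj_interaction(system, sel_a, sel_b) == pytest.approx(
        lj_interaction(system, sel_a, half1) + lj_interaction(system, sel_a, half2),
        abs=1e-9)


def test_lj_minimum_identity_and_zero_epsilon():
    eps1, eps2, rmh1, rmh2 = 0.21, 0.09, 1.8, 1.5
    atoms = [AtomRecord(1, "X1", "C", "G", 1, "A", (0, 0, 0), 0, eps1, rmh1, 1.6),
             AtomRecord(2, "X2", "C", "G", 2, "B", (rmh1 + rmh2, 0, 0), 0, eps2, rmh2, 1.6)]
    system = MolecularSystem(atoms)
    a, b = Selection((0,)), Selection((1,))
    assert lj_interaction(system, a, b) == pytest.approx(-np.sqrt(eps1 * eps2), abs=1e-12)
    atoms[0].lj_epsilon = 0.0
    system = MolecularSystem(atoms)
    assert lj_interaction(system, a, b) == 0.0


def test_overlapping_selections_and_contact_floor_rejected():
    system = pair_system(1.0, -1.0, 0.05)
    with pytest.raises(ValueError, match="close contact"):
        coulomb_interaction(system, system.receptor, system.ligand, GB)
    rng = np.random.default_rng(13)
    sys2, sel_a, sel_b = make_random_groups(rng)
    overlap = Selection(tuple(sel_a.atom_indices[:3]) + tuple(sel_b.atom_indices))
    with pytest.raises(ValueError, match="overlap"):
        coulomb_interaction(sys2, sel_a, overlap, GB)


def test_single_ion_matches_born_closed_form():
    rng = np.random.default_rng(14)
    tau = 1.0 / GB.interior_dielectric - 1.0 / GB.solvent_dielectric
    for _ in range(20):
        q = rng.uniform(-2, 2)
        a = rng.uniform(1.0, 3.0)
        ion = MolecularSystem([AtomRecord(1, "X", "O", "ION", 1, "A", (0, 0, 0),
                                          charge=q, radius=a)])
        expected = -0.5 * COULOMB_CONSTANT * tau * q * q / a
        assert reaction_field(ion, params=GB) == pytest.approx(expected, rel=1e-12)


def test_two_ion_gb_matches_declared_pair_function():
    """Scalar re-derivation of HCT radii + Still pair formula."""
    q1, q2, rho1, rho2, r = 0.7, -1.1, 1.6, 2.1, 3.5
    system = pair_system(q1, q2, r, radius=rho1)
    system.atoms[1].radius = rho2
    system._rebuild_arrays()

    def hct_inverse_radius(rho_i, rho_j, r):
        upper = r + rho_j
        lower = max(abs(r - rho_j), rho_i)
        integral = 0.5 * (1 / lower - 1 / upper
                          + 0.25 * (r - rho_j ** 2 / r) * (1 / upper ** 2 - 1 / lower ** 2)
                          + 0.5 / r * np.log(lower / upper))
        return 1 / rho_i - integral

    a1 = 1.0 / hct_inverse_radius(rho1, rho2, r)
    a2 = 1.0 / hct_inverse_radius(rho2, rho1, r)
    np.testing.assert_allclose(born_radii(system.coordinates, system.radii),
                               [a1, a2], rtol=1e-12)
    tau = 1.0 / GB.interior_dielectric - 1.0 / GB.solvent_dielectric
    f12 = np.sqrt(r * r + a1 * a2 * np.exp(-r * r / (4 * a1 * a2)))
    expected = -0.5 * COULOMB_CONSTANT * tau * (
        q1 * q1 / a1 + q2 * q2 / a2 + 2 * q1 * q2 / f12)
    both = Selection((0, 1))
    assert reaction_field(system, both, GB) == pytest.approx(expected, abs=1e-9)


def test_delta_reaction_field_composition_and_zero_charge():
    atoms = [AtomRecord(1, "R1", "C", "REC", 1, "A", (0.0, 0.0, 0.0), 0.4, 0.1, 1.7, 1.7),
             AtomRecord(2, "R2", "O", "REC", 1, "A", (1.5, 0.0, 0.0), -0.6, 0.2, 1.6, 1.5),
             AtomRecord(3, "R3", "N", "REC", 1, "A", (0.0, 1.5, 0.0), 0.2, 0.17, 1.8, 1.55),
             AtomRecord(4, "L1", "P", "LIG", 2, "B", (4.0, 0.0, 0.0), 1.1, 0.2, 2.1, 1.85),
             AtomRecord(5, "L2", "O", "LIG", 2, "B", (5.2, 0.8, 0.0), -0.8, 0.2, 1.66, 1.5)]
    system = MolecularSystem(atoms)
    rec, lig = Selection((0, 1, 2), "rec"), Selection((3, 4), "lig")
    system.set_partition(rec, lig)
    both = Selection((0, 1, 2, 3, 4))
    expected = (reaction_field(system, both, GB) - reaction_field(system, rec, GB)
                - reaction_field(system, lig, GB))
    assert delta_reaction_field(system, GB) == pytest.approx(expected, abs=1e-12)

    for a in atoms:
        a.charge = 0.0
    zero = MolecularSystem(atoms)
    zero.set_partition(rec, lig)
    assert delta_reaction_field(zero, GB) == 0.0


def test_binding_deltas_vanish_at_large_separation(neutral_system):
    """Net-neutral partners 500 A apart: dG_R and dMSA go to zero."""
    far = neutral_system.copy()
    coords = far.coordinates.copy()
    coords[far.ligand.indices] += np.array([500.0, 0.0, 0.0])
    far.set_coordinates(coords)
    assert abs(delta_reaction_field(far, GB)) <= 1e-3
    assert abs(delta_msa(far)) <= 1e-2  # single-precision area accumulation


def test_sasa_isolated_sphere_and_additivity_limit():
    one = MolecularSystem([AtomRecord(1, "X", "O", "ION", 1, "A", (0, 0, 0),
                                      radius=1.6)])
    expected = 4.0 * np.pi * (1.6 + 1.4) ** 2
    assert surface_area(one, probe_radius=1.4) == pytest.approx(expected, rel=1e-4)

    two = pair_system(0.0, 0.0, 50.0, radius=1.6)
    both = Selection((0, 1))
    assert surface_area(two, both) == pytest.approx(2 * expected, rel=1e-4)
    with pytest.raises(ValueError, match="radius"):
        surface_area(MolecularSystem([AtomRecord(1, "X", "O", "I", 1, "A", (0, 0, 0))]))


def high_density_sasa_oracle(xyz, radii, probe, n_points=4000):
    """Independent golden-spiral Shrake-Rupley, per atom."""
    k = np.arange(n_points)
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    pts = np.stack([np.sqrt(1 - z * z) * np.cos(theta),
                    np.sqrt(1 - z * z) * np.sin(theta), z], axis=1)
    ext = np.asarray(radii) + probe
    areas = np.empty(len(radii))
    for i in range(len(radii)):
        surf = xyz[i] + ext[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(radii)):
            if j == i:
                continue
            exposed &= np.linalg.norm(surf - xyz[j], axis=1) >= ext[j]
        areas[i] = 4 * np.pi * ext[i] ** 2 * exposed.mean()
    return areas


def test_buried_atom_has_zero_area():
    """Centre atom caged by 14 neighbours: area 0, matching a dense oracle."""
    directions = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    directions += [(x / np.sqrt(3), y / np.sqrt(3), z / np.sqrt(3))
                   for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)]
    atoms = [AtomRecord(1, "X0", "C", "CAG", 1, "A", (0, 0, 0), radius=1.5)]
    for k, d in enumerate(directions):
        atoms.append(AtomRecord(k + 2, f"X{k + 1}", "C", "CAG", 2, "A",
                                2.3 * np.asarray(d), radius=2.0))
    system = MolecularSystem(atoms)
    per_atom = surface_area(system, per_atom=True)
    oracle = high_density_sasa_oracle(system.coordinates, system.radii, 1.4)
    assert per_atom[0] == 0.0
    assert oracle[0] == 0.0
    np.testing.assert_allclose(per_atom, oracle, atol=2.0)  # sampling tolerance


def test_sasa_matches_independent_oracle_on_random_cluster():
    rng = np.random.default_rng(15)
    atoms = [AtomRecord(i + 1, f"X{i}", "C", "CLU", i + 1, "A",
                        rng.uniform(-4, 4, 3), radius=rng.uniform(1.2, 2.0))
             for i in range(12)]
    system = MolecularSystem(atoms)
    got = surface_area(system, per_atom=True)
    oracle = high_density_sasa_oracle(system.coordinates, system.radii, 1.4)
    # both are sampling estimates of the same smooth areas
    np.testing.assert_allclose(got.sum(), oracle.sum(), rtol=0.02)


def test_delta_msa_negative_for_contacting_pose(complex_system):
    assert delta_msa(complex_system) < 0.0
    # three-call composition in the shared (complex) frame is exact
    rec, lig = complex_system.require_partition()
    both = Selection(tuple(rec.atom_indices) + tuple(lig.atom_indices))
    canon = canonical_orientation(complex_system.coordinates)
    expected = (surface_area(complex_system, both, coords=canon, canonicalize=False)
                - surface_area(complex_system, rec, coords=canon, canonicalize=False)
                - surface_area(complex_system, lig, coords=canon, canonicalize=False))
    assert delta_msa(complex_system) == pytest.approx(expected, abs=1e-9)


def test_all_energy_terms_rigid_motion_invariant(complex_system):
    rng = np.random.default_rng(16)
    rec, lig = complex_system.require_partition()
    base = (coulomb_interaction(complex_system, rec, lig, GB),
            lj_interaction(complex_system, rec, lig),
            delta_reaction_field(complex_system, GB),
            delta_msa(complex_system))
    for _ in range(3):
        move = random_rigid_motion(rng)
        coords = move(complex_system.coordinates)
        moved = (coulomb_interaction(complex_system, rec, lig, GB, coords),
                 lj_interaction(complex_system, rec, lig, coords),
                 delta_reaction_field(complex_system, GB, coords),
                 delta_msa(complex_system, coords=coords))
        np.testing.assert_allclose(moved, base, atol=1e-8)
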