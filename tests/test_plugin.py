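import numpy as np
import pytest

from plugmd.fixtures import water_box
from plugmd.integrators import integrate_nve, maxwell_boltzmann_velocities
from plugmd.plugin import (CompositeForceField, PluggedModel, RegionSpec,
                           TypeMapError, add_particles_to_region,
                           apply_region_exclusions, create_full_system_force,
                           select_adaptive_region, set_unit_transform)
from plugmd.potentials import (FlexibleWaterPotential, HarmonicWellPotential,
                               SurrogateNNPotential)
from plugmd.system import minimum_image


def jittered(system, seed, scale=0.01):
    rng = np.random.default_rng(seed)
    system.positions += rng.normal(0, scale, system.positions.shape)
    return system


class TestUnitTransform:
    def test_identity_transform_is_passthrough(self):
        system = jittered(water_box(8, box_edge=1.2, seed=1), 2)
        inner = FlexibleWaterPotential.for_system(system, cutoff=0.45)
        plugged = PluggedModel(inner)
        e0, f0 = inner.evaluate(system.positions, system.box)
        e1, f1 = plugged.evaluate(system.positions, system.box)
        assert e1 == pytest.approx(e0, rel=1e-14)
        np.testing.assert_allclose(f1, f0, rtol=1e-14)

    def test_angstrom_kcal_inner_model_equivalence(self):
        """A harmonic model expressed in Angstrom/kcal, driven through the
        unit transform, must match the same physics expressed natively in
        nm/kJ."""
        k_native = 400.0  # kJ/(mol nm^2)
        native = HarmonicWellPotential(k_native)
        # E_kcal(x_A) = 0.5 * k_in * x_A^2 with k_in in kcal/(mol A^2)
        inner = HarmonicWellPotential(k_native / 4.184 / 100.0)
        plugged = PluggedModel(inner, coord_coefficient=10.0,
                               force_coefficient=4.184,
                               energy_coefficient=4.184)
        pos = np.array([[0.12, -0.03, 0.57]])
        e0, f0 = native.evaluate(pos)
        e1, f1 = plugged.evaluate(pos)
        assert e1 == pytest.approx(e0, rel=1e-12)
        np.testing.assert_allclose(f1, f0, rtol=1e-12)

    def test_unit_transform_preserves_nve_trajectory(self):
        k_native = 400.0
        results = []
        for model in (HarmonicWellPotential(k_native),
                      PluggedModel(HarmonicWellPotential(
                          k_native / 4.184 / 100.0), coord_coefficient=10.0,
                          force_coefficient=4.184, energy_coefficient=4.184)):
            pos = np.array([[0.1, 0.0, 0.0]])
            from plugmd.system import ParticleSystem
            system = ParticleSystem(pos, np.zeros((1, 3)), [18.0], ["Ar"],
                                    [0], ["TOY"])
            integrate_nve(system, model, 0.001, 500, save_every=10**9)
            results.append(system.positions.copy())
        np.testing.assert_allclose(results[1], results[0], rtol=1e-10,
                                   atol=1e-14)

    def test_lambda_commutes_with_energy_coefficient(self):
        inner = HarmonicWellPotential(100.0)
        plugged = PluggedModel(inner, lambda_scale=0.5,
                               energy_coefficient=2.0, force_coefficient=2.0)
        pos = np.array([[0.2, 0.1, 0.0]])
        assert plugged.evaluate(pos)[0] == pytest.approx(
            inner.evaluate(pos)[0], rel=1e-14)

    def test_rejects_non_positive_coefficients(self):
        model = PluggedModel(HarmonicWellPotential(1.0))
        with pytest.raises(ValueError):
            set_unit_transform(model, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            set_unit_transform(model, 1.0, -2.0, 1.0)

    def test_lambda_linearity_exact(self):
        system = jittered(water_box(8, box_edge=1.2, seed=3), 4)
        inner = SurrogateNNPotential(system.element_types, cutoff=0.45)
        at_one = PluggedModel(inner, lambda_scale=1.0)
        e1, f1 = at_one.evaluate(system.positions, system.box)
        for lam in (0.0, 0.25, 0.8):
            m = PluggedModel(inner, lambda_scale=lam)
            e, f = m.evaluate(system.positions, system.box)
            assert e == lam * e1
            np.testing.assert_array_equal(f, lam * f1)


class TestRegions:
    def test_full_system_force_matches_direct_evaluation(self):
        system = jittered(water_box(8, box_edge=1.2, seed=5), 6)
        model = FlexibleWaterPotential.for_system(system, cutoff=0.45)
        term = create_full_system_force(model, system)
        e0, f0 = model.evaluate(system.positions, system.box)
        e1, f1 = term.evaluate(system.positions, system.box)
        assert e1 == e0
        np.testing.assert_array_equal(f1, f0)

    def test_particle_count_mismatch_rejected(self):
        small = water_box(4, box_edge=1.2, seed=1)
        big = water_box(8, box_edge=1.4, seed=1)
        model = FlexibleWaterPotential.for_system(small, cutoff=0.45)
        with pytest.raises(TypeMapError):
            create_full_system_force(model, big)

    def test_region_scope_containment(self):
        """A one-water ML region exerts exactly zero force on the other
        particles."""
        system = jittered(water_box(27, density=0.95, seed=7), 8)
        region = [0, 1, 2]
        inner = SurrogateNNPotential(["O", "H", "H"], cutoff=0.3)
        term = add_particles_to_region(inner, region, system)
        _, forces = term.evaluate(system.positions, system.box)
        outside = np.setdiff1d(np.arange(system.n_particles), region)
        assert np.all(forces[outside] == 0.0)
        assert np.abs(forces[region]).max() > 0.0

    def test_select_all_equals_full_system(self):
        system = jittered(water_box(8, box_edge=1.2, seed=9), 10)
        model = SurrogateNNPotential(system.element_types, cutoff=0.45)
        term = add_particles_to_region(model, range(system.n_particles),
                                       system)
        e0, f0 = model.evaluate(system.positions, system.box)
        e1, f1 = term.evaluate(system.positions, system.box)
        assert e1 == e0
        np.testing.assert_array_equal(f1, f0)

    def test_scatter_preserves_total_force(self):
        system = jittered(water_box(27, density=0.95, seed=11), 12)
        region = list(range(9))
        inner = SurrogateNNPotential(system.element_types[:9], cutoff=0.3)
        term = add_particles_to_region(inner, region, system)
        _, f_full = term.evaluate(system.positions, system.box)
        _, f_inner = inner.evaluate(system.positions[region], system.box)
        np.testing.assert_allclose(f_full.sum(axis=0), f_inner.sum(axis=0),
                                   atol=1e-12)

    def test_out_of_range_region_index(self):
        system = water_box(4, box_edge=1.2, seed=1)
        with pytest.raises(IndexError):
            add_particles_to_region(HarmonicWellPotential(1.0), [100], system)


class TestAdaptiveSelection:
    def test_line_of_atoms_distance_cut(self):
        pos = np.array([[x, 0, 0] for x in (0.0, 0.2, 0.3, 0.5, 0.9)])
        sel = select_adaptive_region(pos, np.full(3, 10.0), [0], 0.35,
                                     extend_residues=False)
        assert sel.tolist() == [0, 1, 2]

    def test_radius_covering_box_selects_everything(self):
        system = water_box(8, box_edge=1.2, seed=13)
        sel = select_adaptive_region(system.positions, system.box, [0],
                                     radius=float(np.linalg.norm(system.box)),
                                     extend_residues=False)
        assert sel.tolist() == list(range(system.n_particles))

    def test_residue_closure_completes_water(self):
        system = water_box(8, box_edge=1.4, seed=14)
        # center on one hydrogen with a radius too small to reach anything
        sel = select_adaptive_region(system.positions, system.box, [4],
                                     radius=1e-6, extend_residues=True,
                                     residue_index=system.residue_index)
        assert sel.tolist() == [3, 4, 5]

    def test_monotone_in_radius(self, rng):
        system = water_box(27, density=0.95, seed=15)
        prev = None
        for radius in (0.1, 0.2, 0.35, 0.5):
            sel = set(select_adaptive_region(
                system.positions, system.box, [0, 40], radius,
                extend_residues=True,
                residue_index=system.residue_index).tolist())
            if prev is not None:
                assert prev <= sel
            prev = sel

    def test_empty_centers_rejected(self):
        with pytest.raises(ValueError):
            select_adaptive_region(np.zeros((3, 3)), None, [], 0.35)

    def test_region_spec_validation(self):
        with pytest.raises(ValueError):
            RegionSpec(mode="bogus")
        with pytest.raises(ValueError):
            RegionSpec(mode="adaptive", radius=-1.0)
        with pytest.raises(ValueError):
            RegionSpec(fixed_particles=(1, 1))


class TestExclusions:
    def test_drop_intra_removes_one_waters_bonded_terms(self):
        system = jittered(water_box(8, box_edge=1.2, seed=16), 17, 0.02)
        model = FlexibleWaterPotential.for_system(system, cutoff=0.45)
        ff = CompositeForceField([create_full_system_force(model, system)])
        region = [0, 1, 2]
        excl = apply_region_exclusions(ff, region, "drop_intra")
        e_keep = ff.evaluate(system.positions, system.box)[0]
        e_drop = excl.evaluate(system.positions, system.box)[0]
        intra = model.subset(region).evaluate(system.positions[region],
                                              system.box)[0]
        assert intra != 0.0
        # additivity: dropped + intra = kept
        assert e_drop + intra == pytest.approx(e_keep, rel=1e-12)

    def test_empty_region_is_identity(self):
        system = water_box(4, box_edge=1.2, seed=18)
        model = FlexibleWaterPotential.for_system(system, cutoff=0.45)
        ff = CompositeForceField([create_full_system_force(model, system)])
        assert apply_region_exclusions(ff, [], "drop_intra") is ff

    def test_keep_all_is_identity(self):
        system = water_box(4, box_edge=1.2, seed=18)
        model = FlexibleWaterPotential.for_system(system, cutoff=0.45)
        ff = CompositeForceField([create_full_system_force(model, system)])
        assert apply_region_exclusions(ff, [0, 1, 2], "keep_all") is ff
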