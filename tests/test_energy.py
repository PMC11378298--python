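"""Classical backend: closed forms, symmetries and conservation laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pocketedda.energy import (BackendConfig, COULOMB_K, fragment_energy,
                               gb_cross, pair_interaction_energy,
                               total_energy_and_gradient)
from pocketedda.errors import GeometryError, ParameterError
from pocketedda.records import AtomRecord, Fragment, Topology, merge_fragments

from conftest import point_ion, random_fragment


class TestClosedForms:
    def test_single_neutral_atom_all_zero(self, config):
        f = Fragment("X", [AtomRecord("C", "C1", (0, 0, 0), lj_epsilon=0.1,
                                      lj_sigma=3.4, born_radius=1.7)])
        e = fragment_energy(f, config)
        assert e.total == 0.0

    def test_born_self_term(self, config):
        # q = +1, a = 2 Å, ε_out = 78.5: −½·k·(1 − 1/78.5)/2
        f = point_ion("ION", (0, 0, 0), 1.0)
        expect = -0.5 * COULOMB_K * (1 - 1 / 78.5) / 2.0
        assert fragment_energy(f, config).desolvation == pytest.approx(
            expect, rel=1e-12)
        assert expect == pytest.approx(-81.96, abs=0.005)

    def test_coulomb_pair_plus_100(self, gas_config):
        a = point_ion("A", (0, 0, 0), 1.0)
        b = point_ion("B", (3.320637, 0, 0), 1.0)
        e = pair_interaction_energy(a, b, gas_config)
        assert e.electrostatic == pytest.approx(100.0, abs=1e-10)
        assert e.total == pytest.approx(100.0, abs=1e-10)

    def test_coulomb_pair_minus_100(self, gas_config):
        a = point_ion("A", (0, 0, 0), 1.0)
        b = point_ion("B", (3.320637, 0, 0), -1.0)
        assert pair_interaction_energy(a, b, gas_config).total == \
            pytest.approx(-100.0, abs=1e-10)

    def test_lj_zero_at_sigma_minimum_at_r6(self, gas_config):
        eps, sigma = 0.21, 3.0

        def lj(r):
            a = Fragment("A", [AtomRecord("C", "C", (0, 0, 0), charge=0.0,
                                          lj_epsilon=eps, lj_sigma=sigma,
                                          born_radius=1.7)])
            b = Fragment("B", [AtomRecord("C", "C", (r, 0, 0), charge=0.0,
                                          lj_epsilon=eps, lj_sigma=sigma,
                                          born_radius=1.7)])
            return pair_interaction_energy(a, b, gas_config).total

        assert lj(sigma) == pytest.approx(0.0, abs=1e-12)
        r_min = 2 ** (1 / 6) * sigma
        assert lj(r_min) == pytest.approx(-eps, rel=1e-12)
        # numerically a minimum: neighbors are higher
        assert lj(r_min * 0.99) > lj(r_min) < lj(r_min * 1.01)

    def test_distant_fragments_negligible(self, gas_config):
        a = point_ion("A", (0, 0, 0), 0.0, lj=(0.1, 3.4))
        b = point_ion("B", (1000.0, 0, 0), 0.0, lj=(0.1, 3.4))
        assert abs(pair_interaction_energy(a, b, gas_config).total) < 1e-6

    def test_toy_bond_energy(self, gas_config):
        atoms = [AtomRecord("C", "C1", (0, 0, 0), lj_epsilon=0,
                            lj_sigma=3.4, born_radius=1.7),
                 AtomRecord("C", "C2", (1.6, 0, 0), lj_epsilon=0,
                            lj_sigma=3.4, born_radius=1.7)]
        f = Fragment("L", atoms, topology=Topology(bonds=[(0, 1, 300.0,
                                                           1.5)]))
        assert fragment_energy(f, gas_config).bonded == pytest.approx(
            0.5 * 300.0 * 0.1 ** 2, rel=1e-12)


class TestContracts:
    def test_overlapping_atoms_geometry_error(self, gas_config):
        a = point_ion("A", (0, 0, 0), 1.0)
        b = point_ion("B", (0.05, 0, 0), -1.0)
        with pytest.raises(GeometryError):
            pair_interaction_energy(a, b, gas_config)

    def test_missing_parameter_names_atom(self, gas_config):
        f = Fragment("A", [AtomRecord("C", "Cbad", (0, 0, 0))])
        with pytest.raises(ParameterError, match="Cbad"):
            fragment_energy(f, gas_config)

    def test_components_sum_to_total(self, config):
        rng = np.random.default_rng(3)
        a = random_fragment(rng, "A", 4, (0, 0, 0))
        b = random_fragment(rng, "B", 4, (4.0, 0, 0))
        e = pair_interaction_energy(a, b, config)
        e.check(tol=1e-9)


class TestSymmetries:
    @pytest.mark.parametrize("seed", range(5))
    def test_pair_symmetry(self, config, seed):
        rng = np.random.default_rng(seed)
        a = random_fragment(rng, "A", 3, (0, 0, 0))
        b = random_fragment(rng, "B", 4, (4.5, 0.5, -0.5))
        eab = pair_interaction_energy(a, b, config)
        eba = pair_interaction_energy(b, a, config)
        for f in eab.FIELDS + ("total",):
            assert getattr(eab, f) == pytest.approx(getattr(eba, f),
                                                    abs=1e-12)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, seed):
        """Translating+rotating both fragments together leaves every
        classical energy unchanged."""
        config = BackendConfig()
        rng = np.random.default_rng(seed)
        a = random_fragment(rng, "A", 3, (0, 0, 0))
        b = random_fragment(rng, "B", 3, (4.5, 0, 0))
        e0 = pair_interaction_energy(a, b, config)
        # random rotation (QR) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(size=3) * 10
        for frag in (a, b):
            for at in frag.atoms:
                at.coords = q @ at.coords + t
        e1 = pair_interaction_energy(a, b, config)
        assert abs(e1.total - e0.total) < 1e-9

    def test_hbond_reattribution_conserves_total(self):
        """The gas-phase sum elec+disp+rep+hbond does not depend on the
        geometric gates."""
        rng = np.random.default_rng(11)
        donor = Fragment("D", [
            AtomRecord("O", "O", (0, 0, 0), charge=-0.8, lj_epsilon=0.21,
                       lj_sigma=2.96, born_radius=1.52),
            AtomRecord("H", "H", (0.96, 0, 0), charge=0.4,
                       lj_epsilon=0.0157, lj_sigma=2.65, born_radius=1.2)])
        acceptor = Fragment("A", [
            AtomRecord("N", "N", (2.8, 0, 0), charge=-0.6, lj_epsilon=0.17,
                       lj_sigma=3.25, born_radius=1.55)])
        open_gate = BackendConfig()
        closed_gate = BackendConfig(hbond_distance=1e-6)
        e1 = pair_interaction_energy(donor, acceptor, open_gate)
        e2 = pair_interaction_energy(donor, acceptor, closed_gate)
        assert e1.hbond != 0.0 and e2.hbond == 0.0
        gas1 = e1.electrostatic + e1.dispersion + e1.repulsion + e1.hbond
        gas2 = e2.electrostatic + e2.dispersion + e2.repulsion + e2.hbond
        assert gas1 == pytest.approx(gas2, abs=1e-12)
        assert e1.total == pytest.approx(e2.total, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_pairwise_additivity(self, config, seed):
        """E_int(L, R1∪R2) = E_int(L,R1) + E_int(L,R2): residue–residue
        terms cancel in the supermolecule formula."""
        rng = np.random.default_rng(100 + seed)
        lig = random_fragment(rng, "L", 4, (0, 0, 0))
        r1 = random_fragment(rng, "R1", 3, (4.5, 0, 0))
        r2 = random_fragment(rng, "R2", 3, (-4.5, 1.0, 0))
        lumped = pair_interaction_energy(lig, merge_fragments(r1, r2),
                                         config)
        split = (pair_interaction_energy(lig, r1, config)
                 + pair_interaction_energy(lig, r2, config))
        assert lumped.total == pytest.approx(split.total, abs=1e-8)
        for f in lumped.FIELDS:
            assert getattr(lumped, f) == pytest.approx(
                getattr(split, f), abs=1e-8)

    def test_supermolecule_equals_cross_sums(self, config):
        """E(L∪R) − E(L) − E(R) from fragment energies reproduces the
        direct pair interaction (no topologies: all-pair convention)."""
        rng = np.random.default_rng(42)
        # heavy-atom-only fragments so no hbond gating complicates
        a = Fragment("A", [
            AtomRecord("C", f"C{i}", rng.uniform(-1, 1, 3),
                       charge=float(c), lj_epsilon=0.09, lj_sigma=3.4,
                       born_radius=1.7)
            for i, c in enumerate([0.3, -0.3])])
        b = Fragment("B", [
            AtomRecord("O", f"O{i}", rng.uniform(-1, 1, 3) + 4.0,
                       charge=float(c), lj_epsilon=0.21, lj_sigma=2.96,
                       born_radius=1.52)
            for i, c in enumerate([-0.5, 0.5])])
        direct = pair_interaction_energy(a, b, config)
        union = fragment_energy(merge_fragments(a, b), config)
        diff = (union.total - fragment_energy(a, config).total
                - fragment_energy(b, config).total)
        assert direct.total == pytest.approx(diff, abs=1e-9)

    def test_gb_cross_matches_supermolecule(self, config):
        rng = np.random.default_rng(5)
        a = random_fragment(rng, "A", 3, (0, 0, 0))
        b = random_fragment(rng, "B", 3, (4.0, 0, 0))
        from pocketedda.energy import gb_polarization
        expect = (gb_polarization(merge_fragments(a, b), config)
                  - gb_polarization(a, config)
                  - gb_polarization(b, config))
        assert gb_cross(a, b, config) == pytest.approx(expect, abs=1e-10)


class TestGradient:
    @pytest.mark.parametrize("seed", range(3))
    def test_analytic_gradient_matches_finite_differences(self, seed):
        config = BackendConfig()
        rng = np.random.default_rng(200 + seed)
        # resample until atoms are well separated: finite differences
        # lose precision on near-clash geometries
        for _ in range(100):
            frag = random_fragment(rng, "F", 5, (0, 0, 0), spread=2.0)
            c = frag.coords
            d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() > 1.2:
                break
        frag.topology = Topology(bonds=[(0, 1, 120.0, 1.4)])
        e0, g = total_energy_and_gradient(frag, config)
        h = 1e-6
        for i in (0, 2, 4):
            for k in range(3):
                orig = frag.atoms[i].coords[k]
                frag.atoms[i].coords[k] = orig + h
                ep, _ = total_energy_and_gradient(frag, config)
                frag.atoms[i].coords[k] = orig - h
                em, _ = total_energy_and_gradient(frag, config)
                frag.atoms[i].coords[k] = orig
                assert g[i, k] == pytest.approx((ep - em) / (2 * h),
                                                abs=2e-4)

    def test_energy_consistent_with_fragment_energy(self, config):
        rng = np.random.default_rng(9)
        frag = random_fragment(rng, "F", 4, (0, 0, 0), spread=2.0)
        e, _ = total_energy_and_gradient(frag, config)
        assert e == pytest.approx(fragment_energy(frag, config).total,
                                  abs=1e-9)
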