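import numpy as np
import pytest

from adaptivecomposite.data_model import AssemblyError, ScaleParams, SystemRecord
from adaptivecomposite.energy_model import (
    atomization_energy,
    delta_terms,
    dhf_affine_coefficients,
    heat_of_formation_298,
    scaled_energy,
)
from adaptivecomposite.units import hartree_to_kcal
from tests.conftest import random_record

UNIT = ScaleParams(1, 1, 1, 1)


class TestDeltaTerms:
    def test_hand_subtraction(self):
        rec = SystemRecord(id="x", kind="molecule", composition={"H": 2},
                           e_ref=-1.0, e_qcisd_t=-1.2, e_mp2_dz=-1.1, e_mp2_tz=-1.15)
        assert delta_terms(rec) == pytest.approx((-0.2, -0.05))

    def test_zero_increment_when_energies_match(self):
        rec = SystemRecord(id="x", kind="molecule", composition={"H": 2},
                           e_ref=-1.0, e_qcisd_t=-1.0, e_mp2_dz=-1.1, e_mp2_tz=-1.1)
        assert delta_terms(rec) == (0.0, 0.0)

    def test_same_rule_for_atoms(self):
        rec = SystemRecord(id="x", kind="atom", composition={"C": 1},
                           e_ref=-37.0, e_qcisd_t=-37.2, e_mp2_dz=-37.1, e_mp2_tz=-37.15)
        assert delta_terms(rec) == pytest.approx((-0.2, -0.05))


class TestScaledEnergy:
    def test_unit_factors_reduce_to_unscaled_composite(self):
        rng = np.random.default_rng(0)
        for i in range(20):
            rec = random_record(rng, rec_id=f"m{i}")
            expected = rec.e_qcisd_t + (rec.e_mp2_tz - rec.e_mp2_dz) + rec.zpe
            assert scaled_energy(rec, UNIT).total_scaled == pytest.approx(expected, rel=1e-14)

    def test_zero_increments_leave_reference_plus_thermal(self):
        rec = SystemRecord(id="x", kind="molecule", composition={"H": 2},
                           e_ref=-1.0, e_qcisd_t=-1.0, e_mp2_dz=-1.1, e_mp2_tz=-1.1, zpe=0.02)
        for params in (UNIT, ScaleParams(2.5, 0.1, -3.0, 7.0)):
            assert scaled_energy(rec, params).total_scaled == pytest.approx(-0.98)

    def test_published_group1_factors_match_spreadsheet_arithmetic(self):
        params = ScaleParams(0.962702, 0.970629, 1.391322, 1.399096)
        rec = SystemRecord(id="x", kind="molecule", composition={"C": 1, "H": 4},
                           e_ref=-40.0, e_qcisd_t=-40.3, e_mp2_dz=-40.2, e_mp2_tz=-40.31,
                           zpe=0.044)
        # -40.0 + 0.962702*(-0.3) + 1.391322*(-0.11...) + 0.044 by hand
        expected = -40.0 + 0.962702 * (-0.3) + 1.391322 * (-0.10999999999999943) + 0.044
        assert scaled_energy(rec, params).total_scaled == pytest.approx(expected, rel=1e-12)
        atom = SystemRecord(id="a", kind="atom", composition={"C": 1},
                            e_ref=-37.0, e_qcisd_t=-37.15, e_mp2_dz=-37.1, e_mp2_tz=-37.14,
                            e_so=-1e-4, multiplicity=3)
        expected_atom = -37.0 + 0.970629 * (-0.15) + 1.399096 * (-0.040000000000000036) - 1e-4
        assert scaled_energy(atom, params).total_scaled == pytest.approx(expected_atom, rel=1e-12)


class TestAtomization:
    def test_self_atomization_is_zero(self):
        atom = SystemRecord(id="a", kind="atom", composition={"H": 1},
                            e_ref=-0.5, e_qcisd_t=-0.52, e_mp2_dz=-0.51, e_mp2_tz=-0.52,
                            multiplicity=2)
        pseudo = SystemRecord(id="m", kind="molecule", composition={"H": 1},
                              e_ref=-0.5, e_qcisd_t=-0.52, e_mp2_dz=-0.51, e_mp2_tz=-0.52)
        # same energies, zpe=0: molecular (a, c) vs atomic (b, d) must agree
        assert atomization_energy(pseudo, [atom], UNIT) == pytest.approx(0.0, abs=1e-10)

    def test_diatomic_hand_value(self):
        atom = SystemRecord(id="a", kind="atom", composition={"H": 1},
                            e_ref=-0.5, e_qcisd_t=-0.5, e_mp2_dz=-0.5, e_mp2_tz=-0.5,
                            multiplicity=2)
        mol = SystemRecord(id="m", kind="molecule", composition={"H": 2},
                           e_ref=-1.1, e_qcisd_t=-1.1, e_mp2_dz=-1.1, e_mp2_tz=-1.1)
        assert atomization_energy(mol, [atom], UNIT) == pytest.approx(62.7509474, abs=1e-7)

    def test_monotone_in_molecular_correlation_factor(self, diatomic):
        mol, atoms = diatomic  # de_corr < 0
        values = [atomization_energy(mol, atoms, ScaleParams(a, 1, 1, 1))
                  for a in (0.9, 1.0, 1.1)]
        assert values[0] < values[1] < values[2]

    def test_missing_atom_reported(self, diatomic):
        mol, _ = diatomic
        with pytest.raises(AssemblyError, match="H"):
            atomization_energy(mol, [], UNIT)

    def test_atom_order_irrelevant(self, small_dataset, atom_refs):
        molecules, atoms, _ = small_dataset
        mol = molecules[0]
        fwd = heat_of_formation_298(mol, atoms, UNIT, atom_refs)
        rev = heat_of_formation_298(mol, atoms[::-1], UNIT, atom_refs)
        assert fwd == rev


class TestHeatOfFormation:
    def test_lone_atom_molecule_recovers_reference_value(self, atom_refs):
        # pseudo-molecule identical to the free atom, with h_thermal equal to
        # the elemental correction: everything cancels except dhf_atom_0K
        hth = atom_refs.h_thermal_element["H"]
        atom = SystemRecord(id="a", kind="atom", composition={"H": 1},
                            e_ref=-0.5, e_qcisd_t=-0.52, e_mp2_dz=-0.51, e_mp2_tz=-0.52,
                            multiplicity=2)
        pseudo = SystemRecord(id="m", kind="molecule", composition={"H": 1},
                              e_ref=-0.5, e_qcisd_t=-0.52, e_mp2_dz=-0.51, e_mp2_tz=-0.52,
                              h_thermal=hth / 627.509474)
        got = heat_of_formation_298(pseudo, [atom], UNIT, atom_refs)
        assert got == pytest.approx(atom_refs.dhf_atom_0K["H"], abs=1e-8)

    def test_diatomic_spreadsheet_oracle(self, diatomic, atom_refs):
        mol, atoms = diatomic
        params = ScaleParams(0.9, 1.1, 1.2, 1.3)
        # independent spreadsheet-style arithmetic
        e_at = -0.5 + 1.1 * (-0.02) + 1.3 * (-0.008) + 0.0
        e_mol = -1.1 + 0.9 * (-0.04) + 1.2 * (-0.018) + 0.01
        sigma_d0 = hartree_to_kcal(2 * e_at - e_mol)
        expected = (2 * atom_refs.dhf_atom_0K["H"] - sigma_d0
                    + hartree_to_kcal(0.004) - 2 * atom_refs.h_thermal_element["H"])
        got = heat_of_formation_298(mol, atoms, params, atom_refs)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_affine_gradient_matches_finite_differences(self, atom_refs):
        rng = np.random.default_rng(3)
        atoms = [random_record(rng, "atom", f"a{i}") for i in range(3)]
        # force distinct elements
        for rec, el in zip(atoms, ("C", "H", "O")):
            rec.composition = {el: 1}
        mol = random_record(rng, "molecule", "m")
        mol.composition = {"C": 2, "H": 4, "O": 1}
        g, h0 = dhf_affine_coefficients(mol, atoms, atom_refs)
        # dHf is affine in theta, so central differences carry no truncation
        # error and a generous step keeps hartree-scale round-off negligible
        eps = 1e-3
        base = np.ones(4)
        for j in range(4):
            up, dn = base.copy(), base.copy()
            up[j] += eps
            dn[j] -= eps
            fd = (heat_of_formation_298(mol, atoms, ScaleParams.from_array(up), atom_refs)
                  - heat_of_formation_298(mol, atoms, ScaleParams.from_array(dn), atom_refs)
                  ) / (2 * eps)
            assert fd == pytest.approx(g[j], rel=1e-8, abs=1e-8)
        # intercept consistency: dhf(theta) = h0 + g . theta
        theta = np.array([1.3, 0.7, 1.9, 0.2])
        assert heat_of_formation_298(mol, atoms, ScaleParams.from_array(theta), atom_refs) \
            == pytest.approx(h0 + g @ theta, rel=1e-12)
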