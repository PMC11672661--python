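import numpy as np
import pytest

from adaptivecomposite.data_model import ScaleParams
from adaptivecomposite.energy_model import heat_of_formation_298
from adaptivecomposite.system_fit import (
    UnfittableSystemError,
    _design,
    build_parameter_matrix,
    fit_group_params,
    fit_system_params,
    ridge_closed_form,
)

START = np.ones(4)


def closed_form_oracle(members, ref, ridge):
    """Independent ridge least squares via the normal equations / pinv."""
    G, h = _design(members, ref)
    r1 = G @ START + h
    if ridge > 0:
        A = np.vstack([G, np.sqrt(ridge) * np.eye(4)])
        b = np.concatenate([-r1, np.zeros(4)])
    else:
        A, b = G, -r1
    return START + np.linalg.pinv(A) @ b


class TestSystemFit:
    def test_exact_system_returns_unit_factors(self, small_dataset, atom_refs):
        molecules, atoms, _ = small_dataset
        mol = molecules[0]
        exact = heat_of_formation_298(mol, atoms, ScaleParams(), atom_refs)
        res = fit_system_params(mol, atoms, exact, atom_refs)
        assert res.params.as_array() == pytest.approx(START, abs=1e-9)
        assert res.residual == pytest.approx(0.0, abs=1e-9)

    def test_exact_fit_reachable_without_ridge(self, small_dataset, atom_refs):
        molecules, atoms, _ = small_dataset
        for mol in molecules[:10]:
            res = fit_system_params(mol, atoms, mol.dhf_exp, atom_refs, ridge=0.0)
            assert abs(res.residual) < 1e-8

    def test_huge_ridge_pins_unit_factors(self, small_dataset, atom_refs):
        molecules, atoms, _ = small_dataset
        res = fit_system_params(molecules[0], atoms, molecules[0].dhf_exp,
                                atom_refs, ridge=1e12)
        assert res.params.as_array() == pytest.approx(START, abs=1e-4)

    def test_quasi_newton_matches_closed_form(self, small_dataset, atom_refs):
        molecules, atoms, _ = small_dataset
        for mol in molecules[:20]:
            res = fit_system_params(mol, atoms, mol.dhf_exp, atom_refs)
            oracle = closed_form_oracle([(mol, atoms, mol.dhf_exp)], atom_refs, 1e-8)
            assert res.params.as_array() == pytest.approx(oracle, abs=1e-6)

    def test_unfittable_system_detected(self, atom_refs):
        from adaptivecomposite.data_model import SystemRecord
        atom = SystemRecord(id="a", kind="atom", composition={"H": 1},
                            e_ref=-0.5, e_qcisd_t=-0.5, e_mp2_dz=-0.5, e_mp2_tz=-0.5,
                            multiplicity=2)
        mol = SystemRecord(id="m", kind="molecule", composition={"H": 2},
                           e_ref=-1.1, e_qcisd_t=-1.1, e_mp2_dz=-1.1, e_mp2_tz=-1.1)
        with pytest.raises(UnfittableSystemError):
            fit_system_params(mol, [atom], 50.0, atom_refs, ridge=0.0)


class TestGroupFit:
    def test_single_member_group_equals_system_fit(self, small_dataset, atom_refs):
        molecules, atoms, _ = small_dataset
        mol = molecules[3]
        single = fit_system_params(mol, atoms, mol.dhf_exp, atom_refs, ridge=1e-8)
        group = fit_group_params([(mol, atoms, mol.dhf_exp)], atom_refs, ridge=1e-8)
        assert group.params.as_array() == pytest.approx(single.params.as_array(), abs=1e-9)

    def test_duplicated_members_leave_optimum_unchanged(self, small_dataset, atom_refs):
        molecules, atoms, _ = small_dataset
        members = [(m, atoms, m.dhf_exp) for m in molecules[:8]]
        once = fit_group_params(members, atom_refs)
        twice = fit_group_params(members + members, atom_refs)
        assert twice.params.as_array() == pytest.approx(once.params.as_array(), abs=1e-8)

    def test_noiseless_members_recover_planted_factors(self, atom_refs):
        from adaptivecomposite.synthetic import GeneratorConfig, generate_dataset
        planted = (ScaleParams(0.96, 1.01, 1.39, 1.32),) * 1
        config = GeneratorConfig(n_systems=25, k_groups=1, planted=planted,
                                 noise_sigma=0.0, seed=11)
        molecules, atoms, truth = generate_dataset(config, ref=atom_refs)
        fit = fit_group_params([(m, atoms, m.dhf_exp) for m in molecules], atom_refs)
        assert fit.params.as_array() == pytest.approx(planted[0].as_array(), abs=1e-6)
        assert fit.mae < 1e-5

    def test_group_optimum_beats_unit_start(self, small_dataset, atom_refs):
        molecules, atoms, _ = small_dataset
        members = [(m, atoms, m.dhf_exp) for m in molecules]
        fit = fit_group_params(members, atom_refs)
        G, h = _design(members, atom_refs)
        at_start = float(np.sum((G @ START + h) ** 2))
        assert fit.objective <= at_start + 1e-12

    def test_partition_refinement_inequality(self, small_dataset, atom_refs):
        molecules, atoms, truth = small_dataset
        members = [(m, atoms, m.dhf_exp) for m in molecules]
        union = fit_group_params(members, atom_refs, ridge=0.0).objective
        split = sum(
            fit_group_params([members[i] for i in np.flatnonzero(truth.labels == g)],
                             atom_refs, ridge=0.0).objective
            for g in range(2)
        )
        assert split <= union + 1e-9

    def test_rank_deficient_design_flagged(self, atom_refs):
        from adaptivecomposite.data_model import SystemRecord
        atom = SystemRecord(id="a", kind="atom", composition={"H": 1},
                            e_ref=-0.5, e_qcisd_t=-0.52, e_mp2_dz=-0.51, e_mp2_tz=-0.525,
                            multiplicity=2)
        mol = SystemRecord(id="m", kind="molecule", composition={"H": 2},
                           e_ref=-1.1, e_qcisd_t=-1.15, e_mp2_dz=-1.12, e_mp2_tz=-1.16)
        fit = fit_group_params([(mol, [atom], -20.0)], atom_refs, ridge=0.0)
        assert fit.rank_deficient
        # minimum-norm-about-unit solution agrees with the pinv oracle
        oracle = closed_form_oracle([(mol, [atom], -20.0)], atom_refs, 0.0)
        assert fit.params.as_array() == pytest.approx(oracle, abs=1e-6)


class TestParameterMatrix:
    def test_shape_and_row_order(self, small_dataset, atom_refs):
        molecules, atoms, _ = small_dataset
        systems = [(m, atoms, m.dhf_exp) for m in molecules[:5]]
        M = build_parameter_matrix(systems, atom_refs)
        assert M.shape == (5, 4)
        first = fit_system_params(*systems[0][:2], systems[0][2], atom_refs)
        assert M[0] == pytest.approx(first.params.as_array(), abs=1e-12)

    def test_noiseless_two_group_rows_cluster_tightly(self, atom_refs):
        from adaptivecomposite.synthetic import GeneratorConfig, generate_dataset
        config = GeneratorConfig(n_systems=40, k_groups=2, noise_sigma=0.0, seed=5)
        molecules, atoms, truth = generate_dataset(config, ref=atom_refs)
        M = build_parameter_matrix([(m, atoms, m.dhf_exp) for m in molecules], atom_refs)
        for g in range(2):
            rows = M[truth.labels == g]
            spread = np.linalg.norm(rows - rows.mean(axis=0), axis=1)
            centre_gap = np.linalg.norm(M[truth.labels == 0].mean(axis=0)
                                        - M[truth.labels == 1].mean(axis=0))
            assert spread.mean() < centre_gap
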