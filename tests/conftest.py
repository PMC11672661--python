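import numpy as np
import pytest

from adaptivecomposite.data_model import ScaleParams, SystemRecord, load_atom_references
from adaptivecomposite.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def atom_refs():
    return load_atom_references()


@pytest.fixture(scope="session")
def small_dataset(atom_refs):
    """A modest two-group synthetic dataset shared across tests."""
    config = GeneratorConfig(n_systems=60, k_groups=2, noise_sigma=0.3, seed=42)
    molecules, atoms, truth = generate_dataset(config, ref=atom_refs)
    return molecules, atoms, truth


@pytest.fixture()
def diatomic():
    """A hand-built diatomic with round numbers for arithmetic oracles."""
    h = SystemRecord(
        id="atom-H", kind="atom", composition={"H": 1},
        e_ref=-0.5, e_qcisd_t=-0.52, e_mp2_dz=-0.515, e_mp2_tz=-0.523,
        e_so=0.0, multiplicity=2,
    )
    h2 = SystemRecord(
        id="H2", kind="molecule", composition={"H": 2},
        e_ref=-1.1, e_qcisd_t=-1.14, e_mp2_dz=-1.13, e_mp2_tz=-1.148,
        zpe=0.01, h_thermal=0.004,
    )
    return h2, [h]


def random_record(rng, kind="molecule", rec_id="r"):
    e_ref = -float(rng.uniform(1, 500))
    de_corr = -float(rng.uniform(0.05, 1.0))
    de_basis = -float(rng.uniform(0.02, 0.5))
    if kind == "atom":
        el = rng.choice(["H", "C", "N", "O", "F", "Cl"])
        return SystemRecord(
            id=rec_id, kind="atom", composition={str(el): 1},
            e_ref=e_ref, e_qcisd_t=e_ref + de_corr,
            e_mp2_dz=e_ref + 0.9 * de_corr,
            e_mp2_tz=e_ref + 0.9 * de_corr + de_basis,
            e_so=-1e-4, multiplicity=2,
        )
    return SystemRecord(
        id=rec_id, kind="molecule",
        composition={"C": int(rng.integers(1, 5)), "H": int(rng.integers(1, 9))},
        e_ref=e_ref, e_qcisd_t=e_ref + de_corr,
        e_mp2_dz=e_ref + 0.9 * de_corr,
        e_mp2_tz=e_ref + 0.9 * de_corr + de_basis,
        zpe=float(rng.uniform(0.001, 0.1)),
        h_thermal=float(rng.uniform(0.001, 0.01)),
    )
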