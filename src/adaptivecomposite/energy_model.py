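"""Scaled composite energies and heats of formation.

The internal energy of a system is the HF/aug-cc-pVDZ reference energy plus
two scaled increments — the correlation increment

    de_corr  = E[QCISD(T)/aug-cc-pVDZ] - E[HF/aug-cc-pVDZ]

and the basis-set increment

    de_basis = E[MP2/aug-cc-pVTZ] - E[MP2/aug-cc-pVDZ]

— plus the zero-point energy (molecules) or the spin-orbit correction
(atoms)::

    E(molecule) = e_ref + a*de_corr + c*de_basis + zpe
    E(atom)     = e_ref + b*de_corr + d*de_basis + e_so

Atomization energies are the usual sum-of-atoms minus molecule difference,
and the 298 K heat of formation adds the experimental atomic enthalpies of
formation and the thermal corrections, which enter only at this final stage:

    dHf(0 K)   = sum_el n_el * dHf_atom(0 K) - sigma_D0
    dHf(298 K) = dHf(0 K) + [H(298)-H(0)](molecule) - sum_el n_el * [H(298)-H(0)](element)

Because the scale factors enter linearly, dHf(298 K) is affine in
(a, b, c, d); :func:`dhf_affine_coefficients` exposes the gradient and
intercept, which the fitting module relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import (
    AssemblyError,
    AtomReferenceTable,
    ScaleParams,
    SystemRecord,
)
from .units import hartree_to_kcal

__all__ = [
    "EnergyBreakdown",
    "delta_terms",
    "scaled_energy",
    "atomization_energy",
    "heat_of_formation_298",
    "dhf_affine_coefficients",
    "atoms_for",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """The pieces of one scaled-energy evaluation (all hartree)."""

    e_ref: float
    de_corr: float
    de_basis: float
    corr_factor: float
    basis_factor: float
    thermal_term: float  # ZPE for molecules, E_SO for atoms

    @property
    def total_scaled(self) -> float:
        return (self.e_ref + self.corr_factor * self.de_corr
                + self.basis_factor * self.de_basis + self.thermal_term)


def delta_terms(record: SystemRecord) -> tuple[float, float]:
    """The correlation and basis-set increments (hartree), kind-independent."""
    return (record.e_qcisd_t - record.e_ref, record.e_mp2_tz - record.e_mp2_dz)


def scaled_energy(record: SystemRecord, params: ScaleParams) -> EnergyBreakdown:
    """Scaled composite energy; molecules use (a, c), atoms use (b, d)."""
    de_corr, de_basis = delta_terms(record)
    if record.kind == "molecule":
        cf, bf, thermal = params.a, params.c, record.zpe
    else:
        cf, bf, thermal = params.b, params.d, record.e_so
    return EnergyBreakdown(
        e_ref=record.e_ref, de_corr=de_corr, de_basis=de_basis,
        corr_factor=cf, basis_factor=bf, thermal_term=thermal,
    )


def atoms_for(molecule: SystemRecord,
              atoms: Sequence[SystemRecord]) -> dict[str, SystemRecord]:
    """Map each element of the molecule to its atom record, or raise."""
    table: dict[str, SystemRecord] = {}
    for rec in atoms:
        if rec.kind == "atom":
            table.setdefault(rec.element, rec)
    missing = sorted(el for el, n in molecule.composition.items()
                     if n > 0 and el not in table)
    if missing:
        raise AssemblyError(f"{molecule.id}: no atom record for element(s) {missing}")
    return table


def atomization_energy(molecule: SystemRecord, atoms: Sequence[SystemRecord],
                       params: ScaleParams) -> float:
    """Atomization energy sigma_D0 in kcal/mol under one shared parameter set.

    The same :class:`ScaleParams` supplies (a, c) for the molecule and
    (b, d) for every constituent atom.
    """
    table = atoms_for(molecule, atoms)
    e_mol = scaled_energy(molecule, params).total_scaled
    e_atoms = sum(
        n * scaled_energy(table[el], params).total_scaled
        for el, n in molecule.composition.items() if n > 0
    )
    return hartree_to_kcal(e_atoms - e_mol)


def heat_of_formation_298(molecule: SystemRecord, atoms: Sequence[SystemRecord],
                          params: ScaleParams, ref: AtomReferenceTable) -> float:
    """Heat of formation at 298.15 K in kcal/mol."""
    ref.require(el for el, n in molecule.composition.items() if n > 0)
    sigma_d0 = atomization_energy(molecule, atoms, params)
    dhf0 = sum(n * ref.dhf_atom_0K[el]
               for el, n in molecule.composition.items() if n > 0) - sigma_d0
    thermal = hartree_to_kcal(molecule.h_thermal) - sum(
        n * ref.h_thermal_element[el]
        for el, n in molecule.composition.items() if n > 0
    )
    return dhf0 + thermal


def dhf_affine_coefficients(
    molecule: SystemRecord, atoms: Sequence[SystemRecord], ref: AtomReferenceTable,
) -> tuple[np.ndarray, float]:
    """Gradient ``g`` and intercept ``h0`` with dHf(theta) = h0 + g . theta.

    All in kcal/mol:

        g = (kcal(de_corr_mol), -kcal(sum n*de_corr_atom),
             kcal(de_basis_mol), -kcal(sum n*de_basis_atom))

    Raising a molecular factor on a negative increment lowers the molecular
    energy, raises the atomization energy and so lowers dHf; the atomic
    factors act with the opposite sign.
    """
    table = atoms_for(molecule, atoms)
    dc_mol, db_mol = delta_terms(molecule)
    dc_at = sum(n * delta_terms(table[el])[0]
                for el, n in molecule.composition.items() if n > 0)
    db_at = sum(n * delta_terms(table[el])[1]
                for el, n in molecule.composition.items() if n > 0)
    g = np.array([hartree_to_kcal(dc_mol), -hartree_to_kcal(dc_at),
                  hartree_to_kcal(db_mol), -hartree_to_kcal(db_at)])
    at_zero = heat_of_formation_298(molecule, atoms, ScaleParams(0.0, 0.0, 0.0, 0.0), ref)
    return g, at_zero
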