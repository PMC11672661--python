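"""Unit conventions.

Electronic energies, zero-point energies and thermal enthalpy increments are
carried in hartree; enthalpies of formation and all fitting residuals are in
kcal/mol.  The single conversion constant lives here.
"""

from __future__ import annotations

#: kcal/mol per hartree (CODATA-consistent value, fixed project-wide).
HARTREE_TO_KCAL: float = 627.509474


def hartree_to_kcal(x: float) -> float:
    """Convert an energy from hartree to kcal/mol."""
    return x * HARTREE_TO_KCAL


def kcal_to_hartree(x: float) -> float:
    """Convert an energy from kcal/mol to hartree."""
    return x / HARTREE_TO_KCAL
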