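# Experimental atomic reference data used to convert atomization energies
# into enthalpies of formation.  Editable configuration, not fitted.
#
# dhf_atom_0K:        enthalpy of formation of the gaseous atom at 0 K (kcal/mol),
#                     JANAF / CODATA values as conventionally used by composite
#                     thermochemistry recipes.
# h_thermal_element:  H(298.15 K) - H(0 K) of the element in its standard state,
#                     per atom (kcal/mol).
H:  {dhf_atom_0K: 51.63,  h_thermal_element: 1.01}
Li: {dhf_atom_0K: 37.69,  h_thermal_element: 1.10}
Be: {dhf_atom_0K: 76.48,  h_thermal_element: 0.46}
B:  {dhf_atom_0K: 136.20, h_thermal_element: 0.29}
C:  {dhf_atom_0K: 169.98, h_thermal_element: 0.25}
N:  {dhf_atom_0K: 112.53, h_thermal_element: 1.04}
O:  {dhf_atom_0K: 58.99,  h_thermal_element: 1.04}
F:  {dhf_atom_0K: 18.47,  h_thermal_element: 1.05}
Na: {dhf_atom_0K: 25.69,  h_thermal_element: 1.54}
Mg: {dhf_atom_0K: 34.87,  h_thermal_element: 1.19}
Al: {dhf_atom_0K: 78.23,  h_thermal_element: 1.08}
Si: {dhf_atom_0K: 106.60, h_thermal_element: 0.76}
P:  {dhf_atom_0K: 75.42,  h_thermal_element: 1.28}
S:  {dhf_atom_0K: 65.66,  h_thermal_element: 1.05}
Cl: {dhf_atom_0K: 28.59,  h_thermal_element: 1.10}
Br: {dhf_atom_0K: 28.18,  h_thermal_element: 2.93}
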