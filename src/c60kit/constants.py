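"""Physical constants in the unit system used throughout the toolkit.

Energies are kcal/mol, lengths Angstrom (geometry/simulation) or cm
(ultracentrifugation), masses Da (= g/mol), temperatures K.
"""

#: Gas constant, kcal mol^-1 K^-1 (CODATA R converted from J).
R_KCAL = 1.987204258640832e-3

#: Gas constant, erg mol^-1 K^-1 (CGS; used for sedimentation exponents).
R_ERG = 8.31446261815324e7

#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23

#: Volume per molecule at the 1 M standard state, in Angstrom^3.
#: 1 M = N_A molecules per litre = N_A * 1e-27 molecules per A^3.
STANDARD_STATE_VOLUME_A3 = 1e27 / AVOGADRO

#: Conventional constant in the solvent-content formula
#: solvent fraction = 1 - C / V_M  (inverse of the 0.813 Da/A^3 protein
#: density convention, i.e. partial specific volume ~0.74 mL/g).
MATTHEWS_SOLVENT_CONSTANT = 1.23
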