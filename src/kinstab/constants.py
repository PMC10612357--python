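"""Physical constants and shared defaults.

All free energies and m values are carried in kcal units, so the gas
constant is expressed in kcal·mol⁻¹·K⁻¹ throughout.
"""

#: Gas constant, kcal·mol⁻¹·K⁻¹.
R_KCAL = 1.987e-3

#: Default temperature for equilibrium-unfolding fits, K (spectra at 10 °C).
UNFOLDING_T_K = 283.15

#: Default mean residue molecular mass (g/mol) for mean residue ellipticity.
MEAN_RESIDUE_MASS = 110.0

#: nM -> µM conversion for enzyme concentrations.
NM_TO_UM = 1e-3


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15
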