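"""Physical constants and field-standard reference values used across the package.

Every constant that enters a model is collected here so that a fit's provenance
(`FitResult.fixed`) can point at a single registry.
"""

#: Gas constant, cal mol^-1 K^-1.
R_CAL: float = 1.98720425864

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H: float = 2.6752218744e8

#: Mean residue ellipticity at 222 nm of a fully formed alpha-helix,
#: deg cm^2 dmol^-1 (per-residue reference value).
THETA222_FULL_HELIX: float = -39500.0

#: Hydrodynamic radius of dioxane, the internal size standard in PFG-NMR, in A.
DIOXANE_RH_A: float = 2.12

#: Random-coil hydrodynamic scale law Rh = A * MW**B with Rh in nm and MW in Da.
SCALE_LAW_COEF_NM: float = 0.027
SCALE_LAW_COEF_SD: float = 0.01
SCALE_LAW_EXP: float = 0.50
SCALE_LAW_EXP_SD: float = 0.01

#: Default maximum gradient-coil strength, T/m, used to convert percent-of-max
#: gradient grids to absolute units.
DEFAULT_MAX_GRADIENT_T_PER_M: float = 0.55

#: Default temperatures: CD equilibria measured at 5 C, NMR at 10 C.
T_CD_K: float = 278.15
T_NMR_K: float = 283.15

#: 15N scaling factor in the amide chemical-shift-perturbation Euclidean norm.
CSP_N15_SCALE: float = 0.14

#: Random-coil secondary-shift band: |d(obs) - d(coil)| <= 0.1 ppm.
RANDOM_COIL_SHIFT_BAND_PPM: float = 0.1

CELSIUS_OFFSET: float = 273.15
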