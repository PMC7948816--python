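"""Helix content from CD: direct ellipticity reading and a two-state TFE
titration extrapolated back to water."""

from pepbiophys import cd, synth

# direct estimate: mean residue ellipticity at 222 nm against the -39,500
# full-helix reference
for label, theta in (("wild-type", -2669.8), ("Arg192His", -1829.7)):
    h = cd.helicity_from_theta222(theta)
    print(f"{label}: [theta]222 = {theta:9.1f} -> {h.percent:.1f}% helix")

# cosolvent route: fit a synthetic TFE titration (m = 86.5 cal/mol/%,
# midpoint 16% v/v) and extrapolate the equilibrium to 0% TFE
curve, truth = synth.gen_tfe_titration(86.5, 16.0, 0.0, -39500.0)
fit = cd.fit_tfe_titration(curve)
print(f"\nTFE fit: midpoint = {fit.params['midpoint']:.1f}% v/v, "
      f"m = {fit.params['m_value']:.1f} cal/mol/%")
print(f"aqueous equilibrium constant K = {fit.params['k_water']:.4f}")
print(f"helical population in water   = {100 * fit.params['f_helix_water']:.2f}%")
# K ~ 0.08 means fewer than 1 in 12 molecules are helical in water: a
# nascent, not a stable, helix. TFE only amplifies what is already there.
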