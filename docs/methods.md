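# Methods

This note documents the models implemented in `pepbiophys`, the choices made
where the problem left the design open, and what the synthetic-data tests do
and do not demonstrate.

## Sequence and mass accounting

Peptides are held as single-letter strings with a numbering offset so that
residue-level results are reported in the parent-protein coordinates
(Glu184…Ser210 for the troponin-I C-terminal 27-mer). Masses are **average**
(isotope-abundance-weighted) residue masses from a versioned JSON table,
plus one water for free, unmodified termini; this convention reproduces the
conventional peptide molecular weights (3180.55 Da wild-type, 3161.50 Da
Arg192His) to 0.01 Da, which is why no acetyl/amide terminal correction and
no monoisotopic option are offered. No PTMs, isotope patterns or charge
calculations are in scope.

## CD helix quantification

*Direct reading.* Percent helix = 100·[Θ]²²²/(−39 500), where −39 500
deg cm² dmol⁻¹ is the mean-residue ellipticity of a fully formed helix. The
value is clamped to [0, 100] but the raw ratio is also returned. No
chain-length correction is applied to the reference: for peptides this
short any such correction is model-dependent, and the uncorrected form is
the convention the direct estimates are quoted in. Spectral deconvolution
(CDSSTR/CONTIN-style) is out of scope.

*TFE titration.* The disordered ↔ helical equilibrium is modelled as
two-state with a linear free-energy dependence on cosolvent,
ΔG(x) = m·([TFE]½ − x), so K(x) = exp(m·(x − [TFE]½)/RT), K = 1 at the
midpoint, and the aqueous population is f = K_water/(1+K_water) with
K_water = exp(−m·[TFE]½/RT). The m-value is carried in cal mol⁻¹ %⁻¹; at
the wild-type conditions ([TFE]½ = 16 % v/v, 278.15 K) K_water = 0.0818
corresponds to m ≈ 86.5 cal mol⁻¹ %⁻¹. Units of m are treated as metadata:
the quantities the package stands behind are K_water and f, which are
dimensionless and self-consistent. Uncertainty on K_water and f is
propagated by the delta method from the joint (m, midpoint) covariance. A
fitted midpoint outside the titrated range is returned flagged rather than
silently extrapolated; the two-state sanity check (isodichroic point) is
left to the user as a diagnostic, not a hard gate.

*Thermal melts.* Two-state van 't Hoff transition,
K(T) = exp((ΔH_vH/R)(1/T_m − 1/T)), between linear folded and unfolded
baselines. The logistic (overflow-safe) form is used throughout, so the
infinitely cooperative limit degrades gracefully to a step. Baselines are
seeded from the terminal thirds of the scan; T_m is reported in both K and
°C. Flat scans and edge-pinned midpoints are flagged non-converged.

## Diffusion and hydrodynamics

The gradient decay is the Stejskal–Tanner exponential
I/I₀ = exp(−D γ²δ²G²(Δ−δ/3−τ/2)) for a bipolar-gradient experiment
(γ_H = 2.6752218744×10⁸ rad s⁻¹ T⁻¹). Gradients are in T/m; percent-of-max
grids are converted with a configurable coil maximum (default 0.55 T/m,
the conventional ~55 G/cm probe ceiling, since published protocols state
percentages only). The fit is nonlinear least squares seeded by the
ln(I) vs G² regression; with the experimental timings (δ = 2.25 ms,
Δ = 200 ms, τ = 100 µs) the decay spans many decades, so noisy tail points
may reach zero or below — they are retained in the nonlinear fit and only
excluded from the logarithmic seed.

R_h follows from the Stokes–Einstein inverse proportionality against a
co-dissolved internal standard (dioxane, R_h = 2.12 Å); the standard's
diffusion coefficient is a required input, as it is sample-specific. The
random-coil expectation is R_h = (0.027 ± 0.01)·MW^(0.50 ± 0.01) nm with the
coefficient uncertainties propagated; the nm → Å conversion is hard-coded
because 0.027 with MW in Da yields nm. Measured-vs-predicted classification
uses a 2-combined-SD consistency band by default (the conventional
criterion; nothing sharper is defensible given the scale-law error bars).
Multi-component DOSY and convection correction are out of scope.

## Binding

*Fluorescence.* With receptor held at 10 µM (tropomyosin in **protomer**
units — dimer units would halve the apparent stoichiometry) and K_d of the
same order, free-ligand approximations fail; the exact 1:1 mass-balance
solution is used:
F = F₀ + (ΔF_max/2[R]_T)·[([R]_T+[L]_T+K_d) − √(([R]_T+[L]_T+K_d)² − 4[R]_T[L]_T)].
The fit runs trust-region least squares with five log-spaced K_d starts
(the K_d likelihood is occasionally flat), bounds 10⁻³–10⁴ µM. Estimates
pinned at a bound, with standard error exceeding the estimate, or in the
stoichiometric regime ([R]_T/K_d ≳ 900, where the titration carries no K_d
information) are flagged in `FitResult.message`. Note that at c = [R]/K_d
of only ~1 (10 µM receptor, K_d ~ 8–15 µM) a single 12-point titration
determines K_d with a wide standard error — the recovery tests check CI
coverage, not pinpoint accuracy, at realistic noise.

*ITC.* Per-injection heats from the single-set-of-sites model with the
standard perfusion (displaced-volume) bookkeeping: each injection of volume
v dilutes the cell contents by (1 − v/V₀) and adds titrant at (v/V₀) of the
syringe concentration; the heat of injection i is
q_i = V₀·ΔH·([B]_i − [B]_{i−1}(1 − v/V₀)), which makes the cumulative heat
exactly ΔH times the moles of complex formed in-cell plus displaced. The
simple stoichiometric-limit identity (total heat = n·[M]₀·V₀·ΔH) holds only
up to displacement losses of a few percent, which is why conservation is
tested against the exact identity. Dilution-control heats are subtracted
point-wise when supplied. A flat isotherm (ΔH ≈ 0) is declared
unidentifiable rather than fitted — physically, binding that releases no
heat is invisible to calorimetry however tight it is — and Wiseman c-values
outside [1, 1000] trigger a low-confidence warning on K_d.

## NMR observables

Random-coil Hα reference shifts (model-peptide tabulations) ship as a
versioned JSON file with additive nearest-neighbour corrections (following
proline/aromatic); users may substitute their own table, and the defaults
are deliberately small since the published correction sets differ. A
residue is called non-random-coil when |Δδ| = |δ_obs − (δ_coil + corr)|
exceeds 0.1 ppm, the commonly accepted band. CSP uses the Euclidean norm
with the fixed (configurable) 0.14 ¹⁵N scaling. Relaxation series are fitted
with the two-parameter exponential I(t) = I₀e^(−tR); hetNOE = I_sat/I_nonsat
with the background-noise propagation
σ = |NOE|·√((σ_n/I_sat)² + (σ_n/I_nonsat)²). Free/bound comparisons rank
residues by |ΔR₂| (the dominant binding reporter for a peptide exchanging
with a large partner) and report unmatched residues explicitly.

NOE contacts are classified strong/medium/weak by user thresholds defaulting
to the tertiles of the intensity distribution (published summaries bin "by
bar height" without numbers). The *nascent helix* call — ≥ 3 consecutive
sequential NN(i, i+1) contacts — is an operationalisation of the
conventional qualitative definition and is documented as such; any
(i, i+3)/(i, i+4) contact upgrades the region to *helix-like*. Peak picking,
assignment, structure calculation and model-free analysis are out of scope.

## Contractility

Force–pCa data are fitted with the Hill equation on the concentration scale
([Ca] = 10^(−pCa)), in the overflow-safe logistic form
F = F_max·logistic(n·(pCa50 − pCa)·ln 10); pCa50 is a fitted parameter
directly, which is equivalent to fitting Ca50 and transforming. pCa50 and
n_H are invariant to force rescaling. Condition comparisons pair replicates
by identifier, compute per-pair differences in pCa50, F_max and n_H, and
apply the paired Student t-test implemented from its closed form (checked
against an independent implementation in the tests); a negative mean
ΔpCa50 is a right shift, i.e. calcium desensitisation. Repeated-measures
ANOVA, cross-bridge kinetics and sarcomere-length mechanics are not
modelled.

## Synthetic data: what it shows and what it does not

Each generator evaluates the same closed-form model family the fit assumes
and adds i.i.d. Gaussian noise from a seeded generator (identical seeds give
byte-identical files). Defaults encode the study conditions: CD equilibria
at 278.15 K, NMR at 283.15 K, fluorescence titrations of 10 µM receptor
over 0–15 µM ligand in 12 points, ITC with 28 × 10 µl injections of 609 µM
titrant into a 1.4 ml cell at 30 µM, 16 gradient steps spanning 2–95 % of
0.55 T/m, relaxation delays of 10–550 ms, and the seven-point pCa grid
6.5–4.5. Passing recovery tests therefore demonstrates that the estimators
are correct and well-conditioned *under the assumed model*: they say nothing
about baseline drift, non-Gaussian noise, inner-filter effects, convection,
aggregation or exchange broadening in real data. Problem sizes in the test
suite (100-seed replicate batches, 10⁴-point oracle grids) were chosen as
the smallest that make the medians and biases they check statistically
stable.

## Numerical choices

All fits use `scipy.optimize.least_squares` (trust-region reflective) behind
a shared wrapper that extracts standard errors from the Jacobian
(cov = (JᵀJ)⁻¹·RSS/dof) and returns a uniform `FitResult` with parameters,
errors, RSS, convergence flag, fixed constants and model identifier.
Rank-deficient problems simply omit standard errors. Logistic forms replace
raw exponentials wherever a cooperativity parameter can overflow. Physical
constants (R = 1.98720425864 cal mol⁻¹ K⁻¹, γ_H, the −39 500 reference, the
dioxane radius, scale-law coefficients) live in a single registry module.

## Known limitations

- The two-state TFE analysis inherits the usual caveats of linear
  extrapolation over a ~16 % v/v range; m and midpoint are strongly
  correlated, and K_water uncertainty grows accordingly (propagated, not
  hidden).
- The quadratic binding model is strictly 1:1; weak secondary sites would
  bias K_d upward undetected.
- The ITC model assumes instantaneous mixing and the (1 − v/V₀) perfusion
  convention; alternative overfill conventions differ at the sub-percent
  level for 10 µl injections into 1.4 ml.
- NOE classing and the nascent-helix window rule are deliberately simple,
  order-invariant bookkeeping — not a substitute for structure calculation.
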