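# Methods

This note documents the models, numerical choices and limitations of
`marrowdose`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Compartment model of the spongiosa

Marrow-bearing skeletal sites are treated as spongiosa: a mixture of
trabecular bone, red marrow (RM) and yellow marrow (YM), with tumor as an
optional fourth compartment.  Constituent densities are fixed at
ρ_RM = 1.03, ρ_YM = 0.98, ρ_bone = 1.92 and ρ_tumor = 1.00 g/mL.  The two
dimensionless fields are the bone volume fraction (BVF, fraction of
spongiosa volume that is trabecular bone) and the cellularity fraction
(CF, fraction of the marrow volume that is RM).  Voxel density links them:

    rho_marrow(CF) = CF·rho_RM + (1−CF)·rho_YM
    rho_voxel      = BVF·rho_bone + (1−BVF)·rho_marrow(CF)

Given a CF (tabulated per skeletal site, or inverted per voxel) the BVF
follows from the CT-derived density.  With a sulfur-colloid-derived RM mass
m_RM the pair (BVF, CF) has the closed-form joint solution implemented in
`invert_cf_bvf`; the forward/inverse identity holds to machine precision
and is property-tested.  Out-of-model densities (cortical bone, air) are
clamped to the EAF-table domain — BVF ∈ [0, 0.98], CF ∈ [10⁻³, 0.99] — and
every clamp is counted and reported.

The HU→density calibration is bilinear with a water anchor (0 HU →
1.0 g/mL), slope 0.001 g/mL/HU below a 100 HU breakpoint and
0.0005 g/mL/HU above it, continuous at the breakpoint.  Real calibrations
are instrument-specific; both segments and the breakpoint are config
values (`data/materials.yaml`), as are the per-site reference
cellularities and the age→CF curve used for the reference region (both
approximate adult reference values).

The sulfur-colloid scaling is interpreted as mass per unit activity:
SF = m_RM,ref / (sc_conc_ref · v_ref), m_RM,i = sc_i · v_voxel · SF.  A
literal concentration-times-(mass/concentration) reading is
volume-inconsistent at the voxel level; the adopted form makes a uniform
reference region reproduce m_RM,ref = (1−BVF_ref)·CF_ref·v_ref·ρ_RM
exactly, which is the property the scaling exists to provide.  The
reference-region statistic is the median by default (mean available).
The PET tumor threshold is strict (SUV > 3); a voxel at exactly the
threshold is excluded.

## Time-activity kinetics

Voxel TACs are fitted with a monoexponential A₀e^(−λt) and a 3-parameter
biexponential A(e^(−λ₁t) − e^(−λ₂t)) (λ₂ > λ₁ enforced by construction to
remove the swap degeneracy), both by bounded least squares with decay
constants in [10⁻⁹, 1] s⁻¹.  Starts come from a terminal log-linear fit;
three seeded restarts are tried when the first fit does not reach the
noise floor.  TIA is the analytic integral of the winning model (A₀/λ or
A(1/λ₁ − 1/λ₂)).

Model selection uses the least-squares Akaike criterion
AIC = n·ln(RSS/n) + 2k with the small-sample correction (AICc,
denominator guarded as max(n−k−1, ½)) applied by default.  The choice is
deliberate: voxel fits have n = 3–5 samples, where the uncorrected AIC
systematically over-selects the 3-parameter model (at four timepoints it
chooses the biexponential on roughly half of mono-truth voxels at 5%
noise), while AICc keeps both model classes identifiable; the uncorrected
form remains available as a config switch.  Two further numerical
guards: the RSS entering the criterion is floored at n·(10⁻⁸·max
activity)² so that noise-free data degrade gracefully to a
parameter-count comparison, and a model is eligible only when n ≥ k+1
(with exactly three timepoints only the monoexponential competes).
All-zero voxels short-circuit to TIA 0 with a degenerate flag.  Flooring
the effective decay rate at the ¹⁷⁷Lu physical λ is available but off by
default.

The aorta blood curve is a 4-parameter biexponential
A₁e^(−λ₁t) + A₂e^(−λ₂t) requiring ≥ 4 samples, integrated as
A₁/λ₁ + A₂/λ₂.

## Electron transport and EAF tables

The transport engine (shared by the micro- and macro-scale calculations)
is an intentionally simple condensed-history model: continuous
slowing-down energy loss from a packaged approximate water
stopping-power table (per-material mass-stopping ratios 0.95 bone / 1.01
YM / 1.00 RM, tumor), 5%-of-energy steps capped at the local cell size,
isotropic direction resampling per step, a 1 keV cutoff deposited
locally, and an open escaping boundary.  Every history conserves energy
exactly by construction.  The contract of the tables is their structure,
conservation, limits and monotonicity — not sub-percent agreement with a
production electron-transport code.

Micro geometries are 50 µm subvoxel lattices.  Bone is placed by
thresholding a Gaussian random field (smoothing σ = 2 subvoxels) at the
quantile realizing the requested BVF, giving trabecular-like connected
structures (i.i.d. placement is a config alternative); tumor, when
present, takes a random half of the non-bone subvoxels; RM/YM are
assigned with exact counts at the requested CF.  Realized fractions are
within 1% of the request or the builder raises.  The lattice side is at
least twice the CSDA range of the node energy, within [48, 160] subvoxels
(2.4–8 mm).  The 8 mm cap is the scale of a real spongiosa block; above
roughly 1.1 MeV part of the tabulated escape therefore represents
electrons leaving a finite spongiosa region rather than unbounded
in-medium transport, which is the physically relevant situation for
cm-scale skeletal sites.

Tables carry three source classes — initial emission (born in RM, or in
tumor for the 4-compartment model, matching the assumption that
spongiosa activity originates in active marrow and, where tumor is
present, in tumor), boundary crossing (entering through a lattice face),
and secondary (uniform start) — on a grid of log-spaced energies
(10 keV–2.5 MeV) × BVF (3–35%) × CF (1–99%).  The desk-scale default is
5 × 4 × 8 nodes at 2000 histories per node per class (minutes on one
CPU); the full-resolution 12 × 11 × 37 grid is a long-running documented
mode.  Per-node standard errors (10 batches) are stored; queries
interpolate trilinearly in (log E, BVF, CF) and renormalize so
compartments + escape sum to one.

## Dose engines

The closed-form engines implement the MIRD formulas exactly as stated in
the README; the blood-based engine applies no phantom/patient mass ratio
(its formula is structurally different from the spongiosa MIRD formula;
a mass-scaled variant exists behind a flag for sensitivity analysis).
RMBLR defaults to the hematocrit form 0.19/(1−HCT); the RMBLR = 1
convention is a per-patient override.

The macro Monte Carlo samples decay voxels proportional to TIA and
electron energies from the packaged ¹⁷⁷Lu beta spectrum (three branches,
allowed shape with a simple Fermi factor; discrete conversion/Auger
electrons are supported but empty by default, and all energy-bookkeeping
oracles use the mean emission energy computed from this same object).
Electrons random-walk over the CT density map with steps capped at half
the voxel size.  On introduction into a spongiosa voxel — by birth
(initial-emission class) or entry (boundary-crossing class) — the
electron's current energy is apportioned through the EAF table at that
voxel's (BVF, CF); the escape fraction continues across the voxel and may
be re-apportioned downstream.  RM dose per region is RM-deposited energy
over the region RM mass (site-CF masses for MC, SC-derived masses for
MC_SC+PET).  Monte Carlo standard errors come from 10 independent
batches.  The two principal photon lines can be transported with a
first-interaction attenuation kernel (deposit E·μ_en/μ at the sampled
first interaction; scatter treated as escape); this is on in the
pipeline default and off in the electron-only oracle tests.  Global
bookkeeping (emitted = deposited + escaped) is exact.

The partial-volume TIA correction works per skeletal region: the
blood-expected marrow TIA is Σ [Ã]_RM·m_RM,i over non-tumor marrow
voxels.  Imaged excess is treated as spill-out and moved into the
region's tumor voxels proportional to their TIA (uniformly if the tumor
TIA is zero; discarded with a warning in a tumor-free region), conserving
the region total; an imaged deficit is treated as spill-in contamination
of the blood-pool estimate and marrow voxels are scaled up to the
blood-derived value (the region total rises by exactly the deficit).
Marrow voxels are rescaled uniformly; a voxel-wise scheme would need
information the images do not provide.

## Statistics

Relative change is 100·(followup − baseline)/baseline with non-positive
baselines excluded and logged.  Spearman correlation uses mid-ranks; P
values are exhaustively permutation-exact for n ≤ 9 and t-approximate
above.  The Bonferroni adjustment divides the base α (0.05) by the number
of markers tested (five → 0.01).  Lin's CCC uses population (1/n)
moments, 2s_xy/(s_x² + s_y² + (x̄ − ȳ)²).

## Synthetic phantoms

Phantoms are declarative: box/sphere/cylinder sites with per-site CF,
BVF and TAC parameters, an aorta cylinder carrying the blood curve, a
reference marrow sub-region, and spherical lesions with SUV and target
TIA concentration (optionally displacing marrow).  Density is synthesized
by the forward compartment composition and mapped to HU through the
inverse of the same calibration the pipeline applies, so the noise-free
forward/backward identity is exact; truth BVF/CF/RM-mass/TIA maps are
stored in pipeline units (g, MBq·s) to make oracle comparisons unit-free.
Default marrow kinetics are low-amplitude and consistent with the blood
curve scaled by the RM-to-blood ratio — the tracer has no specific marrow
uptake — while lesions carry order-of-magnitude higher concentrations.
Imaging degradation applies PSF blur before Poisson counting noise
(resolution loss precedes counting statistics); all stochastic outputs
are seeded and bit-reproducible.

What the phantoms do **not** emulate: reconstruction physics
(attenuation, scatter, collimator response), anatomically realistic
skeletons, registration error between modalities (all volumes are
generated pre-registered), or intra-marrow biological heterogeneity
beyond the site-level CF.  Passing tests therefore demonstrate
correctness of the dosimetry arithmetic, transport bookkeeping and
statistical machinery under known kinetics and geometry — not clinical
accuracy on reconstructed patient images.

## Problem sizes used in validation

The validation suite runs desk-scale problems chosen to exercise every
code path at meaningful statistical power: 32×32×48 phantoms of 4 mm
voxels, desk-grid EAF tables (5×4×8 nodes × 2000 histories × 3 source
classes), macro MC runs of 3·10⁵–10⁶ histories, 500-voxel TAC-selection
ensembles, and exhaustive permutation tests at n = 6.  The uniform-medium
equilibrium oracle holds the central-voxel dose to within 3% at 10⁶
histories; method-nesting comparisons resolve at ≤ 3 combined standard
errors.

## Known limitations

- The electron transport has no explicit delta rays, multiple-scattering
  angular model, or bremsstrahlung; stopping powers are approximate.
  EAF values are therefore structurally, not spectroscopically, accurate.
- The photon kernel ignores scattered-photon dose beyond the first
  interaction.
- Deposition within a condensed-history step is attributed to the cell
  where the step starts; at 50 µm (micro) and half-voxel (macro) step
  caps this is a sub-cell-scale approximation.
- The SC scaling assumes a tumor-free, physiologically normal reference
  region; widespread metastatic involvement violates it, as it does
  clinically.
- CF tables and the age curve are population references, not
  patient-specific measurements.
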