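# Methods

## The decay model

`rtdecay` describes the loss of diffraction power of a macromolecular
crystal at room temperature as a function of absorbed dose *D* (MGy).  The
expected intensity of a reflection at resolution *s* = sinθ/λ (Å⁻¹) in a
narrow data wedge is modelled as

    E[I_h] = scale(D) · g(s_h) · exp(−2 B(D) s_h²),

where *g* is an empirical radial intensity curve common to protein
crystals, *scale* is a resolution-independent multiplier and *B* is the
overall isotropic Debye–Waller factor (the convention is
`exp(−2 B s²)` on intensity, with `s = 1/(2d)`).  The dose dependence is
carried by two parameters:

    B(D)     = B0 + β·D            β in Å²/MGy
    scale(D) = C · exp(−γ²·D²)     γ in MGy⁻¹

The linear *B* growth is the classical global-damage signature; the
Gaussian scale decay is the simplest one-parameter curve whose linear decay
rate −d(scale)/dD increases with dose (it satisfies the second-order
kinetic form d(scale)/dD = −2γ²·D·scale).  The Gaussian form is an
empirical parameterization, trusted over the range where the fitted series
actually samples it (normalized scale ≳ 0.6); fits that extrapolate beyond
that range carry a validity flag.  γ is reported in MGy⁻¹ throughout.

Integrating the expectation over reciprocal space gives the total scattered
intensity

    I_Σ(D) ∝ exp(−γ²D²) · ∫ g(s) · exp(−2(B0+βD)s²) · s² ds,

and the half-dose D½ solves 2·I_Σ(D½) = I_Σ(0).  Two systematic effects
make raw D½ values incomparable between experiments: truncating the
integral at the experimental d_min discards exactly the fast-fading
high-angle signal (inflating D½), and crystals with large B0 have little
high-angle signal to lose in the first place (also inflating D½).  The
**normalized half-dose D½\*** removes both: it is D½ recomputed with a
standard B0 = 20 Å² and the integral carried to convergence.  Only
intensity *ratios* are ever used, so the proportionality constant of I_Σ
needs no value.

## Per-wedge scaling

Scaling does not use equivalent-reflection agreement (which presumes
intensities identical across doses — the very thing being measured).
Instead, each wedge is fitted independently under the acentric Wilson
assumption: intensities are exponentially distributed about their
expectation, giving the log-likelihood Σ_h [−ln J_h − I_h/J_h] over
records with I_h > 0 (non-positive background-subtracted intensities are
excluded and counted).  Centric reflections are not treated specially and
symmetry-equivalent observations are not merged — the likelihood treats
every observation independently.

The scale profiles out in closed form (k̂ = mean(I/u), u = g·exp(−2Bs²)),
leaving a one-dimensional score equation in *B* whose right-hand side is an
r-weighted mean of s² with dr/dB = 2s²r, hence strictly increasing: the
maximizer is the unique root and is found by bracketed `brentq` from a
Wilson-plot starting value.  This replaces a two-parameter gradient ascent
with an exact reduction; the two-parameter gradient is still evaluated at
the solution (relative norm < 1e−8 declares convergence), and the observed
information matrix in (ln scale, B) supplies standard errors.  *B* is
unconstrained in sign; a negative estimate is flagged, not clipped.
Per-wedge fits are mutually independent, and the fitted scale is exactly
equivariant under rescaling of the intensities.

## Decay fitting

`fit_b_linear` is a weighted least-squares line in (D, B); a negative
unconstrained slope is clipped to β = 0 with a warning.  `fit_scale_gaussian`
linearizes the Gaussian exactly: ln(scale) is regressed on D², which is
convex and reproducible, with γ² constrained ≥ 0.  `fit_decay` composes the
two on a scaling trace using inverse-variance weights from the per-wedge
observed information (uniform weights when unavailable).  Both fits are
exactly invariant to point ordering and to uniform weight rescaling.
Per-structure summaries use plain means and sample standard deviations.

The ~10% low-dose deviations sometimes seen in real series (attributed to a
mosaicity jump after the first exposures) are *not* modelled; they would
appear as a residual diagnostic, not a model term.

## The radial curve and its calibration

The beamline tabulation of g is not redistributable, so the package ships
parametric families and pins the missing shape information by calibration:

* **flat** — g constant.  Admits closed forms
  (ratio = exp(−γ²D²)·(B0/(B0+βD))^{3/2} for s from 0), used as the
  analytic oracle for the quadrature and root finder.
* **effective_gaussian** — a narrow Gaussian shell in s centred at s_eff
  (fixed width 0.004 Å⁻¹; single parameter s_eff²).  Concentrating g·s² at
  one effective resolution makes the intensity ratio after a B increase ΔB
  equal to exp(−2·ΔB·s_eff²).  This is the minimal family for half-dose
  prediction and the packaged default.
* **gaussian_mixture** — Gaussians in s; the generic protein-like instance
  (components at s = 0.05 and 0.16 Å⁻¹) is the forward-simulation default.
* **tabulated** — piecewise-linear (s, g) knots.

Calibration minimizes the sum of squared relative residuals between
predicted and supplied normalized half-doses over (β, γ, D½\*) rows, using
a fixed coarse grid plus a bounded local refine (reproducible by
construction; the refine never increases the objective).  Calibrated on the
eight designated calibration structures of the packaged survey table, the
effective-Gaussian family lands at s_eff² ≈ 0.0213 Å⁻² with all residuals
below 4%, and predicts the six held-out structures within 4% (the
acceptance bound is 10%).

The curve domain defaults to s ∈ [1/24, 0.5] Å⁻¹ (12 Å to 1 Å).  The
low-resolution integration edge is immaterial: moving it from 12 Å to 20 Å
changes any normalized half-dose by well under 1% (tested), so the
ambiguity between reading "1/12 Å" as a d- or s-value has no consequence.

## Half-dose numerics

The intensity integral uses a 4096-point trapezoid per block; in converged
mode the upper limit is extended block-by-block until the last block
contributes < 1e−9 of the running total (the exponential factor guarantees
rapid convergence for B > 0).  Quadrature is validated against the
flat-curve closed form to 1e−6 over a 10×10 (β, γ) grid.  The half-dose is
found by `brentq` on the strictly decreasing ratio with a bracket found by
doubling from [0, 1] MGy; the achieved |ratio − ½| is verified < 1e−6.
`direct_summation_ratio` implements the classical estimate (per-wedge sums
of all recorded intensities, first downward crossing of ½ located by
piecewise-linear interpolation) and flags series that never cross.

The truncation bias is directional for every packaged parameter set
(truncated D½ ≥ converged D½) and grows as B0 falls: for thaumatin-like
parameters (β = 20, γ = 1.3, d_min = 2.5 Å) the generic curve gives a
discrepancy of ~20% at B0 = 12 Å², ~10% at B0 = 20 Å² and ~2% at
B0 = 40 Å².  The package's >15% demonstration therefore uses B0 = 12 Å², a
strongly diffracting crystal within the B = 10–20 Å² band the generic
model illustrates; the *direction* of the B0 effect on D½ itself
(larger B0 → larger D½) is tested separately.

## Synthetic data: what it emulates and what it does not

The generator draws, per wedge, Miller indices uniformly from the
reciprocal-lattice points of the actual unit cell inside the resolution
annulus [d_min, 12 Å], and intensities from the exponential distribution
with the model mean — i.e. exactly the statistical structure the analysis
assumes.  An optional additive Gaussian term (sd = 5% of the expectation,
floored) emulates counting error.  A fixed seed makes a series
bit-reproducible; dose-rate metadata is carried but never influences
intensities, so the generator is dose-rate independent by construction.

Dose schedules emulate the burn protocol: 11 wedges at equally spaced
accumulated doses (attributed to wedge centres), a data-exposure dose per
cycle capped at ΔB ≤ 1 Å² (per-cycle dose = ΔB_max/β), and interleaved
burn exposures making up the remainder.  The default total-dose budget
mirrors sensitivity-adapted protocol design: it targets the larger of a
scale decay to ≈0.65 and a total B increase of ≈28 Å², capped at
γ·D_total ≤ 1.05 and ΔB_total ≤ 45 Å², so that both decay channels remain
measurable up to the last wedge without extinguishing the high-resolution
signal.  Under these conditions (2000 reflections/wedge — a desk-scale
choice, the real per-wedge counts being unstated) the pipeline recovers β
with ≤ 12% and γ with ≤ 7% median relative error across all fifteen
packaged parameter sets, comfortably inside the 15%/20% reproducibility the
survey methodology claims for itself.

Passing these tests shows the pipeline is a consistent estimator of its own
forward model at realistic counts, and that the survey-level conclusions
(solvent trend, dose-rate null) follow from the model plus the published
parameter table.  It does **not** validate the model against real
diffraction images: mosaicity evolution, spot-profile adjustment noise,
absorption, anisotropy of B, and detector effects are all outside the
generator.  Rotation geometry is not traced — reflections are sampled
uniformly in the annulus — because the narrow-wedge assumption makes the
analysis geometry-agnostic.

## Survey analyses

Aggregation reports plain means and sample SDs per structure (SD only for
n ≥ 2).  The solvent trend uses Spearman rank correlation (the claim is a
monotone trend, not a linear law) plus strict-ordering checks within
declared same-protein form groups (lysozyme, insulin, trypsin).  The
approximate proportionality D½\* ∝ (1/solvent − 1) serves only as the
outlier reference: the proportionality constant is the median per-structure
ratio, and a structure deviating by more than 3× in either direction is
flagged (and excluded from the correlation by default — configurable).  On
the packaged table this flags exactly the high-solvent nitrite reductase
TvNiR, whose anomalous radiation hardness is treated as an outlier, not
modelled.  Dose-rate independence is an OLS slope of D½\* on log10(rate)
with a 95% interval; ≥ 4 records spanning ≥ 1 decade are required.  No
multiple-testing control is applied: these are single pre-specified tests.

## Known limitations

* The effective-Gaussian default curve is calibrated for half-dose
  prediction; it is intentionally *not* a realistic diffraction profile and
  must not be used to simulate data (use `generic_protein_curve`).
* The measurement-error-convolved Wilson likelihood is not implemented;
  recorded sigmas are carried through I/O but do not enter the likelihood.
* Anisotropic B tensors and wide rotation ranges are out of scope (narrow
  wedges only), as are absorbed-dose computation, spot integration and
  time-dependent ("dark progression") decay terms.
* The classical direct-summation half-dose is provided for comparison but
  inherits the truncation and B0 biases described above by construction.
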