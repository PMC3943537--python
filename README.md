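# rtdecay

Room-temperature global radiation damage analysis for macromolecular
crystallography: per-wedge Wilson-likelihood scaling of diffraction
intensities, a two-parameter decay model, and the normalized half-dose
radiation-sensitivity metric.

## The problem

At room temperature a protein crystal loses diffraction power one to two
orders of magnitude faster than at 100 K, and the loss has two distinct
channels.  For a data wedge at accumulated dose *D* (MGy), the expected
reflection intensity is

    E[I_h] = scale(D) · g(s_h) · exp(−2 B(D) s_h²),      s = sinθ/λ,

with a linearly growing overall Debye–Waller factor and a Gaussian-decaying
scale factor:

    B(D) = B0 + β·D        (β in Å²/MGy)
    scale(D) = C·exp(−γ²D²)   (γ in MGy⁻¹)

Integrating over reciprocal space gives the total-intensity decay
I_Σ(D)/I_Σ(0), and the dose at which it halves is the half-dose D½.  Raw
D½ values depend on the experimental resolution cutoff and on how well the
crystal diffracted to begin with; the **normalized half-dose D½\***
(computed with a standard B0 = 20 Å² and the intensity integral carried to
convergence) removes both effects and is the package's headline
sensitivity metric.  Survey-level tools aggregate per-structure statistics,
test the monotone increase of sensitivity with crystal solvent content,
and test independence of the dose rate.

The package is aimed at beamline scientists and methods developers who
need dose-tolerance estimates for planning room-temperature (including
*in situ*) data collections, and at anyone reanalysing burn-protocol wedge
series.  Everything runs on synthetic data generated from the model itself
plus a packaged table of published per-structure parameters — no downloads.

## Worked example

Simulate an 11-wedge burn-protocol series (β = 15 Å²/MGy, γ = 1 MGy⁻¹),
scale it wedge by wedge, fit the decay model, and compute D½\*:

```sh
rtdecay simulate --beta 15 --gamma 1 --seed 3 --out demo/series
rtdecay scale demo/series --out demo/trace.tsv
rtdecay fit demo/trace.tsv --acronym DEMO --out demo/params.tsv
cat demo/params.tsv
```

```
acronym	beta_A2_per_MGy	se_beta	gamma_per_MGy	se_gamma	B0_A2	C
DEMO	13.8452667049159	0.7333934653720134	1.055338127337808	0.02771199702256081	20.62135021685855	1.0488052160179373
```

The fitted slope of the B-factor line is 13.8 ± 0.7 Å²/MGy against a true
β of 15, and the scale-decay parameter is 1.06 ± 0.03 MGy⁻¹ against a true
γ of 1 — both within the 15%/20% reproducibility the measurement protocol
is designed to deliver.  The corresponding normalized half-dose:

```sh
rtdecay halfdose --beta 15 --gamma 1
```

```
d_half_norm_MGy
0.572422
```

i.e. a crystal with these parameters loses half its total diffraction
intensity after ≈ 0.57 MGy — compare ~10–20 MGy for the same metric at
cryo-temperature.

The same pipeline is available as a library:

```python
import rtdecay as rt

curve = rt.default_curve()              # calibrated radial intensity shape
print(rt.normalized_half_dose(32, 3.6, curve))   # cubic insulin: 0.1846 MGy
```

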