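# Methods

## Scope and quantities

All lengths are in cm, areas in cm², volumes in mL, doses (fluences) in
mJ/cm², solid angles in millisteradians. A vessel is an opaque-walled
cylinder described by its growth-area diameter `2a`, wall height `h` and
working medium volume `v`; derived are the growth area `S = πa²`, the
aspect ratio `r = h/2a` and the medium depth `l = v/S`. The bundled
registry carries four standard formats (96-, 24-, 12-well, 3.5 cm dish)
spanning `S` from 0.31 to 8.87 cm² and `r` from 0.35 to 1.77.

`D` always denotes the *set* dose — the open-field fluence at which the
chamber's feedback detector halts exposure. Every adjusted axis (σ, ρ,
D′) is emitted alongside `D`, never in place of it.

## Dose–response model

Responses against dose are modelled with the four-parameter logistic

    y = d + (a − d) / (1 + (x/c)^b)

with lower plateau `a` (the zero-dose response for b > 0), upper plateau
`d`, slope factor `b` and midpoint `c`; on a dose axis `c` is the
half-effect dose `D_1/2`. Fitting uses `scipy.optimize.curve_fit`
(trust-region reflective, ftol = xtol = 1e-10, ≤10,000 evaluations) on
per-dose means by default, matching the mean ± SD presentation of
replicate assays; replicate-level fitting is an option. Initialisation
is deterministic: plateaus from the extreme means, midpoint at the
geometric mean of the positive doses, slope 1. The midpoint is
constrained positive; the slope is free in sign so decreasing-viability
curves fit without re-parameterisation. Dose 0 stays in the fit (the
model is defined there by its limit); no log-dose transform is applied.
R² is computed on the fitted points.

Cytokine-release data decline again at cytotoxic doses, so the
descending tail is trimmed before fitting. Two rules: drop exactly the
top dose group, or (default) drop the maximal trailing run of groups
whose mean lies below the running maximum of the preceding means. Either
rule errors out rather than fit fewer than four dose groups.

## Empirical indices

Across a panel of vessels at equal biological effect, two regressions
hold on the four-vessel reference panel:

* log₁₀(D_1/2) on log₁₀(S): slope −0.687 → power law, index
  `σ = k₁·D·S^0.687`, units mJ·cm^(−1.374) at k₁ = 1;
* log₁₀(D_1/2) on r: slope 0.699 → base 10^0.699 ≈ 5.0, index
  `ρ = k₂·D/5.0^r`, units mJ/cm².

Both are plain unweighted OLS (`scipy.stats.linregress`), matching the
small panels they are fitted on. Two usage modes are deliberate: the
rounded published constants (exponent 0.687, base 5.0) as defaults for
compatibility with the printed worked examples, and re-calibration on
the user's own panel for scientific use. The standardization constants
default to k₁ = k₂ = 1; `k1_for_reference` / `k2_for_reference` anchor
an index to a reference vessel so that its index equals its set dose
(dish-anchored: k₁ = 1/8.87^0.687 ≈ 0.223, k₂ = 5^0.351 ≈ 1.759). Note
σ diverges as S → ∞, so the power law is only trusted on
0.31 ≤ S ≤ 8.87 cm²; outside that range the package warns (extrapolation)
rather than errors. Cross-vessel conversion equates the index:
`D_target = D·(S_src/S_tgt)^0.687` or `D·5^(r_tgt − r_src)`; the k
constants cancel.

Reproducing the published log–log regression from the tabulated inputs
gives slope −0.6857 against the printed −0.6869 (~0.2% drift): the
tabulated `D_1/2` and `S` values are rounded to 1–3 significant figures.
The semi-log regression reproduces to all printed digits. Two σ-adjusted
EC50s are printed in two places in the source material with different
values (52.84/99.41 vs 50.67/95.07); the package reproduces the former,
which follow from the printed formula and inputs, and treats the latter
as unexplained.

## Medium optics

Decadic convention: `T = 10^(−A)`, `A = ε·c·l`, with `c` the
concentration *relative* to undiluted medium, so ε (cm⁻¹ at c = 1) is
not molar. The packaged default ε = 0.1695 /cm is the measured value for
keratinocyte growth medium (HuMedia-KG2) at 302 nm. Absorptivity
estimation from a serial-dilution series uses the closed-form
through-origin slope Σxy/Σx² (the blank must transmit fully), with the
uncentered R² appropriate to a no-intercept fit. The published pairing
of ε = 0.1695 with %T = 89.0 implies an effective path near 0.30 cm
(close to the wells' medium depths) but the intended path length is not
stated, so the package never hard-wires that pairing: transmittance is
always computed from an explicit (ε, path) pair. Single-wavelength
treatment only; no spectral integration over the UVB band.

## Effective-dose model D′

The central modelling choice is the radiance field: **uniform
(isotropic) over the upper hemisphere**. Two observations support it —
the biological response is unchanged by the vessel's distance from the
lamps (rejecting a point-source model; the package still provides the
point-source solid angle `Ω = S/((H−δ)²+a²)` as a diagnostic), and the
chamber's reflective inner walls fill the sky with direct plus reflected
light. Under that field, with cosine weighting and a 1/π normalisation,
an unshielded absorber-free horizontal surface receives exactly the set
dose `D` — the normalisation that matches what the instrument's detector
calibrates.

A point at radial position `x` on the well bottom sees the sky truncated
at zenith `θmax(x,φ) = arctan(t(x,φ)/h)` where
`t = −x·cosφ + sqrt(a² − x²sin²φ)` is the horizontal rim clearance
along azimuth φ. Each surviving ray is attenuated by `10^(−εl/cosθ)`
along its slant path through the medium. The local dose fraction is

    f(x) = (1/π) ∫₀^{2π} dφ ∫₀^{θmax} cosθ sinθ 10^(−εl/cosθ) dθ

and `D′ = D·(2/a²)∫₀^a f(x)·x dx`.

Assumptions, stated as model limitations: walls perfectly opaque (a
covered-dish control suggests real plastic leaks some light), flat
liquid surface, refraction at the air/medium interface ignored,
adherent cells only (the cell plane is the well bottom). Shielding is
referenced to the cell plane (wall stands `h` above the cells) by
default; the rim-above-liquid alternative (`h − l`) is exposed as
`shield_reference="surface"`.

### Numerics

Gauss–Legendre quadrature throughout: 64 azimuthal nodes on [0, π]
(mirror symmetry doubles), 64 zenith nodes on [0, θmax] per azimuth
(closed form `sin²θmax/2` when ε = 0), 64 radial nodes on [0, a]. The
integrands are smooth, and the result is stable to ~1e-12 across orders
16–256 for all bundled vessels; a refinement check against half-order
quadrature guards each call (relative tolerance 1e-6, configurable) and
raises with diagnostics on failure.

The independent Monte-Carlo route samples points uniformly on the disk
(`x = a√u`), directions cosine-weighted on the hemisphere
(`sin²θ = u`), and scores the rim-clearance indicator times the slant
Beer–Lambert factor; the sample mean estimates `f` with a reported
standard error. The seed is a mandatory explicit parameter
(`numpy.random.default_rng`); no global state. Quadrature and Monte
Carlo agree within sampling error for every bundled vessel, and the
transmitted fractions (0.061, 0.125, 0.208, 0.448 at ε = 0.1695 for the
96-, 24-, 12-well and dish respectively) order inversely to the
measured per-vessel half-effect doses, as the mechanism predicts. D′ is
not expected to equal σ- or ρ-adjusted doses numerically — only ρ and
D′ even share units — and the package makes no claim about the absolute
scale of D′ beyond the normalisation stated above.

## Synthetic data

Generators are pure functions of (spec, seed). The dose–response
generator draws Gaussian replicate noise (additive by default,
proportional as an option — replicate SDs in this kind of assay are
reported without a noise model, so homoscedastic is the neutral choice)
around a known 4PL truth on the instrument's dose grid (0–500 mJ/cm²),
3 replicates, noise SD defaulting to 5% of the upper plateau; the
high-dose decline is a multiplicative drop above a threshold dose — it
exists to exercise tail trimming, not to model death kinetics. The
vessel-panel generator produces `D_1/2` tables from a known power-law,
exponential or effective-dose rule with optional lognormal scatter; the
dilution generator produces serial-halving Beer–Lambert series. Passing
tests on these generators demonstrates estimator correctness under the
stated noise model, not robustness to the heteroscedastic,
assay-specific noise of real plates.

Under the default conditions (truth from the dish worked example:
plateaus 2.0/298.9, slope 2.4, midpoint 18.5; 7-dose grid, 3 replicates,
5% noise) the fitted midpoint's median relative error over 200 seeds is
≈3.6%, within 10% for ≈92% of seeds.

## Known limitations

* The σ/ρ defaults inherit the uncertainty of a four-point calibration;
  re-calibrate for other cell types, endpoints or media.
* D′ ignores wall reflectance/transmission, refraction and meniscus
  curvature, and does not apply to suspension culture.
* Solid angles are a point-source diagnostic only; stacking
  calculations need the per-dish stack height supplied as δ.
* No uncertainty propagation from 4PL fits into the calibrations; the
  regressions are unweighted point-estimate fits.
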