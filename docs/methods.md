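# Methods

## The measurement this package models

A giant unilamellar vesicle (GUV) imaged at its equator by a polarized
confocal FLIM microscope appears as a bright ring.  The excitation laser is
linearly polarized along the lab Y axis; emission is collected along the
optical (X) axis through two orthogonal analyzers, parallel (Y) and
perpendicular (Z) to the excitation polarization.  Membrane-bound
chromophores are assumed to sit at a fixed polar angle ν to the local
membrane normal with a uniform azimuth about it (the normal is a symmetry
axis), and to be rotationally immobile on the fluorescence time scale.

Under these assumptions the probability of exciting a chromophore at ring
position ψ (measured from the Y axis in the image plane) is the second
moment

    w(ψ; ν) = cos²ν · cos²ψ + ½ sin²ν · sin²ψ,

whose values at the two sector axes are the absorption factors
A_Y = cos²ν (fragment perpendicular to Y) and A_Z = ½(1 − cos²ν)
(fragment perpendicular to Z); the ½ is the azimuth average of sin².  They
satisfy A_Y + 2 A_Z = 1 identically.  Fluorescence is proportional to
absorbed quanta times the quantum yield, the latter taken proportional to
the amplitude-averaged lifetime ⟨τ⟩ = Σaᵢτᵢ/Σaᵢ of the local decay, so the
ratio of the total fluorescence pooled from the two symmetric membrane
fragments perpendicular to Z and to Y is

    R = F_Z / F_Y = (⟨τ⟩_Z / ⟨τ⟩_Y) · (1 − cos²ν) / (2 cos²ν),

inverted as cos²ν = T / (2R + T) with T = ⟨τ⟩_Z/⟨τ⟩_Y.  R = 1 at equal
lifetimes corresponds to the magic angle ν = 54.74°, the signature of
orientational disorder.  Total fluorescence per pixel is reconstructed as
F = F∥ + 2G·F⊥, where G corrects the unequal detection efficiency of the
two analyzers.  The inversion assumes collinear absorption and emission
dipoles; the offset β is obtained from the fundamental anisotropy via
r₀ = (3cos²β − 1)/5 (r₀ = 0.397 ⇒ β ≈ 4°, i.e. near-collinear), and the
simulator can depolarize emission by a cone of half-angle β for realism.

ν is reported in [0°, 90°]: the cone symmetry makes ν and 180° − ν
indistinguishable.  Uncertainty on ν is first-order propagation of the
Poisson variance of F_Z and F_Y; the uncertainty of T is neglected, being
far below counting noise at the photon budgets used.

## Decay decomposition

TCSPC histograms are modelled as Σᵢ aᵢ·exp(−t/τᵢ) plus a constant
background, integrated over each bin, and fitted by maximizing the Poisson
log-likelihood.  Two estimators:

- **Library-constrained** (`fit_decay_fixed`): lifetimes pinned to the
  amphotericin B organization forms — tetramer 0.35 ns, parallel dimer
  1.8 ns, monomer 3.0 ns, antiparallel dimer 6.8 ns — with only the
  non-negative amplitudes and background free.  The likelihood is concave
  in the amplitudes; it is maximized by monotone multiplicative
  (EM/Richardson–Lucy) updates, which respect the non-negativity boundary
  that matters for sub-percent fractions.  Amplitude fractions (percent of
  Σaᵢ) are the reported organization-form abundances; amplitude rather than
  intensity weighting is the default because the tables this mirrors report
  relative amplitudes (intensity weighting is available via
  `intensity_averaged_lifetime`).  The monomer is excluded from the default
  table subset but selectable.
- **Free** (`fit_decay_free`): lifetimes and amplitudes jointly optimized
  (log-parametrized L-BFGS-B with analytic gradients), 5 seeded restarts,
  ties broken by reduced χ².  Fitted components are mapped onto the library
  within a 0.1 ns tolerance.

Poisson ML rather than unweighted least squares is essential: the 0.2%
tetramer amplitude of a sterol-free membrane is invisible to Gaussian
weighting at 10⁶ photons.  Fits are tail fits from the histogram peak
onward with no IRF deconvolution; the simulator's optional Gaussian IRF
(σ configurable, 0 by default) must stay small against the 0.35 ns
component or be disabled.  Reduced χ² uses Pearson residuals restricted to
bins with expected counts ≥ 10 (near-empty tail bins have per-bin variance
2 + 1/m and would dominate the statistic), dof = bins − parameters.

Anisotropy decays r(t) = r₀·exp(−t/θ) are fitted per bin from two polarized
histograms by weighted least squares, weights from first-order propagation
of the channel Poisson variances.  A correlation time beyond 10× the record
is flagged `rotation_resolved=False` (immobilized fluorophore) rather than
rejected.

## Image pipeline

Ring detection: background = image median, robust σ from the MAD; the
center is the intensity centroid refined once on the annulus, the radius
the argmax of the azimuthally averaged radial profile with parabolic
sub-pixel refinement.  Detection demands a radial peak above background +
5σ and a circle (including the integration annulus) fully inside the
raster.  Sector masks are annulus pixels (|d − r| ≤ half-width) within
±aperture/2 of each half-axis; apertures ≥ 90° resolve overlaps by
nearest-axis assignment, so 360° degenerates to a quadrant partition.
Defaults: aperture 20° (±10° about each axis, the full-aperture reading of
the instrument geometry; the alternative reading is just a different value
of the exposed parameter), ring half-width 2× the lateral PSF radius in
pixels.

Background correction uses the median of pixels outside 1.5× the ring
radius (the source experiment does not specify background handling; this
is a declared default, exposed as a parameter).  Sector lifetimes are
fitted on the pooled photons of both symmetric fragments and both
polarization channels; library-constrained fits are the default (right for
amphotericin-B-style data), free single-component fits suit dye-like data.

The dominant systematic of the method is membrane curvature: a sector of
finite aperture averages w(ψ) around the axis, biasing R away from the
point ratio.  The bias is +0.4° at ν = 38° with a 20° aperture and shrinks
with the aperture; `cone_aperture_scan` exposes it, and the analytic
`aperture_averaged_weight` reproduces it in closed form.

## The simulator and what it does (not) emulate

One photon-level generator serves every stage, so TCSPC and polarization
tests share Poisson-correct statistics.  Ring pixels are weighted by
w(ψ; ν) times the relative quantum yield ⟨τ⟩ of the local population;
expected intensity is blurred by a Gaussian PSF before Poisson draws;
arrival times are exponential mixtures (optionally jittered by a Gaussian
IRF); a uniform background is added; everything is deterministic,
bit-for-bit, under the mandatory seed.

Channel split.  The expected channel intensities at each ring position are
λ∥ = T(1 + 2r)/3 and λ⊥ = T(1 − r)/(3G), where T follows the excitation
weight and r is the exact photoselected emission anisotropy at that ring
position (computed from the dipole second moments ⟨(μ·Ŷ)²(μ_em·p̂)²⟩ by
azimuthal quadrature; the β-cone average uses its exact closed form
cos²β(μ·p̂)² + ½sin²β(1 − (μ·p̂)²)).  This convention makes the isotropic
reconstruction F∥ + 2G·F⊥ reproduce the total-intensity law by
construction.  It is a deliberate modelling choice: for strictly in-plane
detection along X the F∥ + 2GF⊥ reconstruction is exact only where the
photoselected ensemble is cylindrically symmetric about Y (true at the Y
sectors, approximate elsewhere), and a simulator enforcing raw
single-direction dipole radiation would bias the sector method by several
degrees.  The analysis assumes the reconstruction; the simulator grants it
and models G as a detection-efficiency asymmetry (thinning) of the
perpendicular channel — exactly how the correction is applied downstream.
Consequences: anisotropy images and sector ratios are mutually consistent,
the isotropic ensemble shows r = 0.4 everywhere, and high-NA
depolarization, out-of-plane detection components and rotational diffusion
during the excited state are all outside the model.

Defaults are the study conditions: vesicle diameter 17 µm, pixel 0.1 µm,
lateral PSF σ 0.14 µm, G = 1.044, β = 0, decay cube of 250 × 0.1 ns bins,
standalone histograms 4096 bins over 25 ns, photon budget expressed as
10⁶ expected counts in the dimmer pooled sector pair ("per-sector budget"),
background 1 count/pixel (unspecified at source; chosen as a realistic
confocal floor and declared here).  The X-direction confinement of the
focal volume (1.468 µm) is treated as already applied by the pinhole; any
residual out-of-plane membrane signal is omitted, a documented
approximation.  Membrane undulations, photobleaching/blinking and a full
3-D PSF are not simulated — recovery results certify the estimators under
the stated noise model, not instrument artifacts beyond it.

The effective confocal volume helper uses the Gaussian effective volume
V = π^{3/2}·y₀²·x₀ (0.080 fL at y₀ = 140 nm, x₀ = 734 nm); the geometric
ellipsoid (4/3)π·y₀²·x₀ is available as an option and gives 0.060 fL for
the same radii.

## Numerical choices

- Azimuthal quadrature: uniform midpoint grids doubled from 64 nodes until
  successive refinements agree to 10⁻⁶ relative (the integrands are
  low-degree trigonometric polynomials, so convergence is immediate);
  non-convergence raises an error carrying the achieved tolerance.
- EM amplitude updates iterate to a 10⁻¹¹ relative change (≤ 5·10⁴
  iterations); fraction uncertainties come from the observed Fisher
  information by the delta method.
- Free fits: multi-start initial lifetimes log-spaced/log-uniform inside
  the record, bounds keep τ within [bin/4, 10 × record].
- Degenerate inputs raise rather than return junk: empty masks, blank
  images, all-zero histograms, ν = 90° in the forward ratio (unbounded),
  non-physical ratios or r₀ in the inversions.
- ν = 90° reported limits: recovered angles saturate below 90° because the
  aperture average keeps F_Y finite; the mask-integrated forward model is
  the reference for such cases.

## Problem sizes used in the shipped checks

Recovery checks run at the stated study conditions — 10⁶ photons per
pooled sector with 10 generator seeds per orientation truth, and 10⁶
photons with 20 seeds per decay column — which keeps the complete suite in
the minutes range on a single core.  Unit tests use smaller budgets
(5·10⁴–3·10⁵) with correspondingly derived tolerances.

## Known limitations

- The per-image uncertainty σ_ν is counting-statistics only; vesicle-to-
  vesicle spread (the S.D. reported over repeated experiments) is larger.
- The sector method assumes one effective orientation; for mixtures of
  oriented populations it returns the amplitude-weighted mean cos²ν, which
  the lifetime weighting makes exact in expectation (tested), but it cannot
  separate the populations.
- Tail fitting without IRF deconvolution biases the 0.35 ns component when
  a broad IRF is simulated; keep σ_IRF ≪ 0.35 ns or disable it.
- Single-vesicle fields only: no multi-vesicle detection, z-stacks, drift
  correction or aggregate classification.
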