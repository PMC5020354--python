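# guvflim

Polarized confocal FLIM analysis of single giant unilamellar vesicles
(GUVs): recover the mean orientation of membrane-bound transition dipoles
from the photoselection pattern of a vesicle equatorial image, and
quantify the molecular organization forms of amphotericin B from
multi-exponential TCSPC decays.  A photon-level forward simulator
generates ground-truthed inputs so every stage is verifiable without
instrument data.

## Who this is for

Membrane biophysicists doing linear-dichroism-style orientation analysis
on single-bilayer systems with a polarized two-channel FLIM confocal:
the package turns a pair of analyzer rasters (plus optional per-pixel
photon-arrival histograms) into an orientation angle ν with uncertainty
and an organization-form table, and provides the simulator needed to
validate the whole chain.

## The model in brief

With excitation polarized along Y and a chromophore at polar angle ν to
the local membrane normal (uniform azimuth, rotationally immobile), the
excitation probability around the ring is
`w(ψ) = cos²ν cos²ψ + ½ sin²ν sin²ψ`.  Pooling the symmetric membrane
fragments perpendicular to the Z and Y axes and weighting by the
amplitude-averaged lifetime ⟨τ⟩ of each fragment (a quantum-yield proxy):

    R = F_Z / F_Y = (⟨τ⟩_Z / ⟨τ⟩_Y) · (1 − cos²ν) / (2 cos²ν)
    cos²ν = T / (2R + T),    T = ⟨τ⟩_Z / ⟨τ⟩_Y

R = 1 with equal lifetimes is the magic angle (54.74°), the signature of
orientational disorder.  Per-pixel totals use F = F∥ + 2G·F⊥ with the
instrumental G factor; decays are decomposed by Poisson maximum likelihood
against the amphotericin B lifetime library (tetramer 0.35 ns, parallel
dimer 1.8 ns, monomer 3.0 ns, antiparallel dimer 6.8 ns).  Details and
assumptions: `docs/methods.md`.

## Worked example

```python
import guvflim as gf

# simulate one vesicle: dipoles at 38 deg, one 1.8 ns component,
# 1e6 photons in the dimmer pooled sector pair
cfg = gf.SimulationConfig(seed=1, nu_deg=38.0, components=((1.8, 1.0),))
stack, truth = gf.simulate_guv_stack(cfg)

report = gf.estimate_orientation(stack, aperture_deg=20.0)
r = report.result
print(f"nu = {r.nu_deg:.2f} +/- {r.sigma_nu_deg:.2f} deg "
      f"(R = {r.ratio_R:.4f}, T = {r.lifetime_ratio_T:.4f})")
```

prints

```
nu = 38.41 +/- 0.02 deg (R = 0.3142, T = 0.9995)
```

The recovered 38.4° sits ~0.4° above the 38.0° truth: a 20° sector cone
averages the photoselection law over the curved membrane, a small
systematic that `gf.cone_aperture_scan` quantifies (it shrinks with the
aperture).  The quoted ±0.02° is counting statistics only.  The same stack
yields the organization table:

```python
org = gf.organization_report(stack)
print(org.fractions_pct)
# {'tetramer': 0.06, 'parallel_dimer': 99.94, 'antiparallel_dimer': 0.0}
```

The same workflow is scriptable from the shell:

```bash
guvflim simulate -c sim.yaml -o out/          # sim.yaml: seed + parameters
guvflim analyze -i out/stack.tif --h5 out/stack.h5 -o analysis/
guvflim scan-aperture -i out/stack.tif --h5 out/stack.h5 -o scan.csv --apertures 10,20,30,40
```

`analyze` writes orientation and organization reports (JSON + CSV),
anisotropy and fast-lifetime maps (32-bit TIFF), and a provenance block
(config hash, seed, version).  Exit codes: 0 ok, 2 invalid config,
3 no vesicle, 4 fit failure.

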