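"""Ground-truthed forward simulator for single-GUV polarized FLIM data.

One photon-level generator feeds every stage of the analysis: the vesicle
equatorial ring with photoselection-weighted excitation, the polarized
channel split, TCSPC arrival times from exponential mixtures, Poisson
counting noise, Gaussian PSF blur and a uniform background.  Defaults are
the study conditions of the single-bilayer experiment this package models:
a 17 um vesicle at 0.1 um pixels, 140 nm lateral PSF radius, G = 1.044,
sector photon budgets of 1e6 and the amphotericin B lifetime library.

Channel-split convention: the expected per-pixel intensities are
``lambda_par = T (1 + 2 r) / 3`` and ``lambda_perp = T (1 - r) / (3 G)``,
where ``T`` follows the ring excitation weight (times the relative quantum
yield of the local mixture) and ``r`` is the exact photoselected emission
anisotropy at that ring position.  This makes the isotropic reconstruction
``F_par + 2 G F_perp`` reproduce the total-intensity law by construction —
the same assumption the analysis itself relies on — and simulates G as a
detection-efficiency asymmetry of the perpendicular channel.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import decay as dc
from . import photoselection as ps
from .pipeline import PolarizedFLIMStack, VesicleGeometry, build_sector_masks, write_stack

__all__ = [
    "Population",
    "SimulationConfig",
    "GroundTruth",
    "simulate_guv_stack",
    "simulate_decay_histogram",
    "simulate_anisotropy_traces",
    "effective_confocal_volume",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass(frozen=True)
class Population:
    """One oriented chromophore population on the membrane.

    ``nu_deg=None`` marks an orientationally disordered (isotropic)
    population.  ``components`` are (lifetime_ns, amplitude) pairs of the
    population's decay; amplitudes are relative and need not be normalized.
    """

    nu_deg: float | None
    components: tuple[tuple[float, float], ...] = ((1.8, 1.0),)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.nu_deg is not None and not (0.0 <= self.nu_deg <= 90.0):
            raise ValueError("population nu must lie in [0, 90] deg or be None")
        if self.weight <= 0:
            raise ValueError("population weight must be positive")
        if not self.components or any(t <= 0 or a < 0 for t, a in self.components):
            raise ValueError("components must be (tau > 0, amplitude >= 0) pairs")
        if sum(a for _, a in self.components) <= 0:
            raise ValueError("at least one component amplitude must be positive")

    @property
    def tau_amp_ns(self) -> float:
        amps = np.array([a for _, a in self.components])
        taus = np.array([t for t, _ in self.components])
        return float((amps * taus).sum() / amps.sum())

    @property
    def photon_shares(self) -> np.ndarray:
        """Probability that an emitted photon stems from each component (~ a tau)."""
        w = np.array([a * t for t, a in self.components])
        return w / w.sum()


@dataclass
class SimulationConfig:
    """Generator parameters and, with the seed, the complete ground truth.

    Either ``photons_total`` (expected detected-equivalent photons in the
    whole ring) or ``sector_photon_budget`` (expected total fluorescence of
    the dimmer pooled sector pair at ``budget_aperture_deg``) fixes the
    brightness; the sector budget is the default study condition.
    """

    seed: int
    nu_deg: float | None = None
    components: tuple[tuple[float, float], ...] = ((1.8, 1.0),)
    populations: tuple[Population, ...] | None = None
    vesicle_diameter_um: float = 17.0
    pixel_size_um: float = 0.1
    photons_total: float | None = None
    sector_photon_budget: float = 1.0e6
    budget_aperture_deg: float = 20.0
    background_rate: float = 1.0
    psf_sigma_um: float = 0.14
    irf_sigma_ns: float = 0.0
    G: float = 1.044
    beta_deg: float = 0.0
    bin_width_ns: float = 0.1
    n_bins: int = 250
    isotropic: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        if self.populations is None:
            nu = None if self.isotropic else self.nu_deg
            if nu is None and not self.isotropic:
                raise ValueError("provide nu_deg, isotropic=True, or explicit populations")
            self.populations = (Population(nu, tuple(self.components)),)
        else:
            self.populations = tuple(
                p if isinstance(p, Population) else Population(**p) for p in self.populations
            )
        for name in (
            "vesicle_diameter_um",
            "pixel_size_um",
            "bin_width_ns",
            "G",
            "sector_photon_budget",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_rate < 0 or self.psf_sigma_um < 0 or self.irf_sigma_ns < 0:
            raise ValueError("rates and widths must be non-negative")
        if self.beta_deg < 0:
            raise ValueError("beta must be non-negative")
        if self.n_bins < 2:
            raise ValueError("need at least 2 time bins")

    @property
    def radius_px(self) -> float:
        return 0.5 * self.vesicle_diameter_um / self.pixel_size_um

    @property
    def ring_halfwidth_px(self) -> float:
        return max(2.0, 2.0 * self.psf_sigma_um / self.pixel_size_um)

    @property
    def image_shape(self) -> tuple[int, int]:
        half = int(math.ceil(1.5 * self.radius_px)) + 3
        n = 2 * half + 1
        return (n, n)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["populations"] = [dataclasses.asdict(p) for p in self.populations]
        return d


@dataclass
class GroundTruth:
    """The generator record against which recovery is scored."""

    config: dict
    seed: int
    nu_true_deg: list
    nu_effective_deg: float | None
    expected_ratio_R: float
    expected_tau_Z_ns: float
    expected_tau_Y_ns: float
    expected_fractions_pct: dict
    photons_total: float
    geometry: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)


def write_ground_truth(gt: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(gt.to_json())


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _deposit_bilinear(img: np.ndarray, rows: np.ndarray, cols: np.ndarray, w: np.ndarray) -> None:
    """Scatter weights onto the pixel grid with bilinear interpolation."""
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    for dr, dcol, ww in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        np.add.at(img, (r0 + dr, c0 + dcol), w * ww)


def _population_maps(config: SimulationConfig, pop: Population):
    """Expected parallel/perpendicular intensity maps (unnormalized) for one
    population: ring deposit of the photoselection law, then PSF blur."""
    shape = config.image_shape
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    radius = config.radius_px
    n_arc = max(3600, int(8.0 * 2.0 * math.pi * radius))
    psi = (np.arange(n_arc) + 0.5) * (360.0 / n_arc)

    orient = None if pop.nu_deg is None else ps.OrientationAngle(pop.nu_deg)
    if orient is None:
        w = np.full(n_arc, 1.0 / 3.0)  # <mu_y^2> over the sphere
    else:
        w = ps.ring_excitation_weight(orient, psi)
    f_par, f_perp = ps.polarized_emission_fractions(orient, psi, beta_deg=config.beta_deg)
    r = ps.emission_anisotropy(f_par, f_perp)

    intensity = pop.weight * pop.tau_amp_ns * w
    lam_par = intensity * (1.0 + 2.0 * r) / 3.0
    lam_perp = intensity * (1.0 - r) / (3.0 * config.G)

    psi_rad = np.radians(psi)
    rows = center[0] - radius * np.sin(psi_rad)  # +Z is up => smaller row index
    cols = center[1] + radius * np.cos(psi_rad)
    arc_norm = 2.0 * math.pi * radius / n_arc  # arc length per sample, px
    map_par = np.zeros(shape)
    map_perp = np.zeros(shape)
    _deposit_bilinear(map_par, rows, cols, lam_par * arc_norm)
    _deposit_bilinear(map_perp, rows, cols, lam_perp * arc_norm)
    sigma_px = config.psf_sigma_um / config.pixel_size_um
    if sigma_px > 0:
        map_par = ndimage.gaussian_filter(map_par, sigma_px, mode="constant")
        map_perp = ndimage.gaussian_filter(map_perp, sigma_px, mode="constant")
    return map_par, map_perp, center


def _draw_arrival_times(rng, pop: Population, n: int, irf_sigma_ns: float) -> np.ndarray:
    taus = np.array([t for t, _ in pop.components])
    if len(taus) == 1:
        t = rng.exponential(taus[0], size=n)
    else:
        comp = np.searchsorted(np.cumsum(pop.photon_shares), rng.random(n), side="right")
        t = rng.exponential(taus[np.minimum(comp, len(taus) - 1)])
    if irf_sigma_ns > 0:
        t = t + rng.normal(0.0, irf_sigma_ns, size=n)
    return t


def _fill_cube(cube, rng, counts_map, pop, config):
    """Draw arrival times for every photon of a Poisson counts map and
    accumulate them into the [rows, cols, bins] cube."""
    flat = counts_map.ravel()
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return
    reps = flat[nz]
    pix = np.repeat(nz, reps)
    t = _draw_arrival_times(rng, pop, pix.size, config.irf_sigma_ns)
    b = np.floor(t / config.bin_width_ns).astype(np.int64)
    ok = (b >= 0) & (b < config.n_bins)
    idx = pix[ok] * config.n_bins + b[ok]
    cube.ravel()[:] += np.bincount(idx, minlength=cube.size).astype(cube.dtype)


def simulate_guv_stack(config: SimulationConfig) -> tuple[PolarizedFLIMStack, GroundTruth]:
    """Simulate one polarized FLIM stack of a GUV equatorial section.

    Deterministic under the configured seed (bit-for-bit).  Returns the
    stack together with the :class:`GroundTruth` record holding the expected
    sector ratio, sector lifetimes and organization fractions implied by the
    configuration.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.image_shape

    pop_maps = [_population_maps(config, p) for p in config.populations]
    center = pop_maps[0][2]
    total_maps = [mp + 2.0 * config.G * ms for mp, ms, _ in pop_maps]
    grand_total = np.sum([m.sum() for m in total_maps])
    if grand_total <= 0:
        raise ValueError("degenerate configuration: no expected signal")

    geom = VesicleGeometry(
        center_px=center,
        radius_px=config.radius_px,
        ring_halfwidth_px=config.ring_halfwidth_px,
    )
    masks = build_sector_masks(geom, config.budget_aperture_deg, shape)
    mz, my = masks.pair("Z"), masks.pair("Y")
    tz = float(np.sum([m[mz].sum() for m in total_maps]))
    ty = float(np.sum([m[my].sum() for m in total_maps]))

    if config.photons_total is not None:
        scale = config.photons_total / grand_total
    else:
        dimmer = min(tz, ty)
        if dimmer <= 0:
            raise ValueError("sector budget normalization impossible: a sector is dark")
        scale = config.sector_photon_budget / dimmer
    if scale * grand_total < 1:
        import warnings

        warnings.warn("photon budget rounds to an empty stack", stacklevel=2)

    raster_par = np.zeros(shape, dtype=np.int64)
    raster_perp = np.zeros(shape, dtype=np.int64)
    cube_par = np.zeros(shape + (config.n_bins,), dtype=np.uint32)
    cube_perp = np.zeros(shape + (config.n_bins,), dtype=np.uint32)

    for (map_par, map_perp, _), pop in zip(pop_maps, config.populations):
        counts_par = rng.poisson(scale * map_par)
        counts_perp = rng.poisson(scale * map_perp)
        raster_par += counts_par
        raster_perp += counts_perp
        _fill_cube(cube_par, rng, counts_par, pop, config)
        _fill_cube(cube_perp, rng, counts_perp, pop, config)

    if config.background_rate > 0:
        bg_par = rng.poisson(config.background_rate / 3.0, size=shape)
        bg_perp = rng.poisson(config.background_rate / (3.0 * config.G), size=shape)
        raster_par += bg_par
        raster_perp += bg_perp
        window = config.n_bins * config.bin_width_ns
        for cube, counts in ((cube_par, bg_par), (cube_perp, bg_perp)):
            flat = counts.ravel()
            nz = np.flatnonzero(flat)
            if nz.size:
                pix = np.repeat(nz, flat[nz])
                t = rng.uniform(0.0, window, size=pix.size)
                b = np.floor(t / config.bin_width_ns).astype(np.int64)
                idx = pix * config.n_bins + b
                cube.ravel()[:] += np.bincount(idx, minlength=cube.size).astype(cube.dtype)

    stack = PolarizedFLIMStack(
        raster_par=raster_par,
        raster_perp=raster_perp,
        decay_cube_par=cube_par,
        decay_cube_perp=cube_perp,
        pixel_size_um=config.pixel_size_um,
        G=config.G,
        bin_width_ns=config.bin_width_ns,
    )
    gt = _ground_truth(config, pop_maps, total_maps, mz, my, scale, geom)
    return stack, gt


def _ground_truth(config, pop_maps, total_maps, mz, my, scale, geom) -> GroundTruth:
    # per-population expected total fluorescence in each pooled sector pair
    tz_k = np.array([m[mz].sum() for m in total_maps])
    ty_k = np.array([m[my].sum() for m in total_maps])
    expected_R = float(tz_k.sum() / ty_k.sum()) if ty_k.sum() > 0 else math.inf

    def sector_tau(shares):
        # photons from population k split over components ~ a tau; amplitudes
        # recovered per component are photons / tau
        amp, amp_tau = 0.0, 0.0
        for share, pop in zip(shares, config.populations):
            taus = np.array([t for t, _ in pop.components])
            ph = share * pop.photon_shares
            a = ph / taus
            amp += a.sum()
            amp_tau += (a * taus).sum()
        return amp_tau / amp if amp > 0 else math.nan

    tau_z = sector_tau(tz_k / tz_k.sum()) if tz_k.sum() > 0 else math.nan
    tau_y = sector_tau(ty_k / ty_k.sum()) if ty_k.sum() > 0 else math.nan

    # amplitude-weighted effective orientation (what the inversion estimates)
    weights, c2s = [], []
    iso = False
    for pop in config.populations:
        if pop.nu_deg is None:
            iso = True
            c2 = 1.0 / 3.0
        else:
            c2 = math.cos(math.radians(pop.nu_deg)) ** 2
        weights.append(pop.weight)
        c2s.append(c2)
    c2_eff = float(np.average(c2s, weights=weights))
    nu_eff = math.degrees(math.acos(math.sqrt(c2_eff)))

    # ring-wide expected amplitude fractions over the union of component lifetimes
    ring_share = np.array([m.sum() for m in total_maps])
    ring_share = ring_share / ring_share.sum()
    amp_by_tau: dict[float, float] = {}
    for share, pop in zip(ring_share, config.populations):
        taus = np.array([t for t, _ in pop.components])
        a = share * pop.photon_shares / taus
        for t_ns, a_i in zip(taus, a):
            amp_by_tau[float(t_ns)] = amp_by_tau.get(float(t_ns), 0.0) + float(a_i)
    total_amp = sum(amp_by_tau.values())
    fractions = {f"{t:g}": 100.0 * a / total_amp for t, a in sorted(amp_by_tau.items())}

    return GroundTruth(
        config=config.to_dict(),
        seed=config.seed,
        nu_true_deg=[p.nu_deg for p in config.populations],
        nu_effective_deg=None if iso and len(config.populations) == 1 else nu_eff,
        expected_ratio_R=expected_R,
        expected_tau_Z_ns=float(tau_z),
        expected_tau_Y_ns=float(tau_y),
        expected_fractions_pct=fractions,
        photons_total=float(scale * np.sum([m.sum() for m in total_maps])),
        geometry={
            "center_px": list(geom.center_px),
            "radius_px": geom.radius_px,
            "ring_halfwidth_px": geom.ring_halfwidth_px,
        },
    )


def simulate_decay_histogram(
    components,
    n_photons: int,
    bin_width_ns: float | None = None,
    n_bins: int = 4096,
    irf_sigma_ns: float = 0.0,
    seed: int = 0,
    channel: str = "total",
) -> dc.DecayHistogram:
    """Photon arrival times from an exponential mixture, histogrammed.

    ``components`` are (tau_ns, amplitude) pairs; a photon stems from
    component i with probability proportional to a_i tau_i (its share of
    the emitted intensity).  The default window is 25 ns over 4096 bins.
    Photons falling outside the window are truncated; their number is
    recorded in ``metadata['n_truncated']``.
    """
    if n_photons < 1:
        raise ValueError("need at least one photon")
    if bin_width_ns is None:
        bin_width_ns = 25.0 / n_bins
    pop = Population(nu_deg=None, components=tuple(components))
    rng = np.random.default_rng(seed)
    t = _draw_arrival_times(rng, pop, int(n_photons), irf_sigma_ns)
    return dc.DecayHistogram.from_times(t, bin_width_ns, n_bins, channel=channel)


def simulate_anisotropy_traces(
    r0: float,
    theta_rot_ns: float,
    tau_ns: float,
    n_photons: int,
    G: float = 1.044,
    seed: int = 0,
    bin_width_ns: float | None = None,
    n_bins: int = 4096,
) -> tuple[dc.DecayHistogram, dc.DecayHistogram]:
    """Polarized decay pair for r(t) = r0 exp(-t/theta), I(t) = exp(-t/tau).

    Expected channel intensities per bin: I_par ~ I(t)(1 + 2 r(t))/3 and
    I_perp ~ I(t)(1 - r(t))/(3 G); counts are independent Poisson draws
    normalized so both channels together expect ``n_photons``.
    ``theta_rot_ns=numpy.inf`` models an immobilized fluorophore.
    """
    if not (-0.2 <= r0 <= 0.4):
        raise ValueError(f"non-physical fundamental anisotropy: {r0}")
    if tau_ns <= 0 or theta_rot_ns <= 0:
        raise ValueError("lifetimes must be positive")
    if bin_width_ns is None:
        bin_width_ns = 25.0 / n_bins
    edges = bin_width_ns * np.arange(n_bins + 1)
    t = 0.5 * (edges[:-1] + edges[1:])
    intensity = np.exp(-t / tau_ns)
    r_t = r0 * (np.exp(-t / theta_rot_ns) if np.isfinite(theta_rot_ns) else 1.0)
    lam_par = intensity * (1.0 + 2.0 * r_t) / 3.0
    lam_perp = intensity * (1.0 - r_t) / (3.0 * G)
    norm = n_photons / (lam_par.sum() + lam_perp.sum())
    rng = np.random.default_rng(seed)
    par = dc.DecayHistogram(edges, rng.poisson(norm * lam_par), channel="parallel")
    perp = dc.DecayHistogram(edges, rng.poisson(norm * lam_perp), channel="perpendicular")
    return par, perp


def effective_confocal_volume(y0_nm: float, x0_nm: float, model: str = "gaussian") -> float:
    """Effective confocal detection volume in femtoliters.

    ``y0_nm`` is the lateral and ``x0_nm`` the axial 1/e^2 radius.  The
    default is the Gaussian effective volume V = pi^(3/2) y0^2 x0 of the
    ellipsoidal observation profile; ``model='ellipsoid'`` gives the
    geometric (4/3) pi y0^2 x0 instead.
    """
    if y0_nm <= 0 or x0_nm <= 0:
        raise ValueError("radii must be positive")
    if model == "gaussian":
        factor = math.pi**1.5
    elif model == "ellipsoid":
        factor = 4.0 * math.pi / 3.0
    else:
        raise ValueError(f"model must be 'gaussian' or 'ellipsoid', got {model!r}")
    volume_nm3 = factor * y0_nm**2 * x0_nm
    return volume_nm3 * 1e-9  # 1 fL = 1 um^3 = 1e9 nm^3


def simulate_to_files(config: SimulationConfig, out_dir) -> dict:
    """Simulate and write stack.tif + stack.h5 + ground_truth.json; returns paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    stack, gt = simulate_guv_stack(config)
    tiff_path = os.path.join(out_dir, "stack.tif")
    h5_path = os.path.join(out_dir, "stack.h5")
    gt_path = os.path.join(out_dir, "ground_truth.json")
    write_stack(stack, tiff_path, h5_path)
    write_ground_truth(gt, gt_path)
    return {"tiff": tiff_path, "h5": h5_path, "ground_truth": gt_path}
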