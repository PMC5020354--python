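"""Single-vesicle polarized FLIM image pipeline.

From a two-channel photon-count raster of a GUV equatorial cross-section
(optionally with per-pixel arrival-time histogram cubes): locate the
membrane ring, build the four sector masks about the Z and Y axes, pool the
symmetric sector pairs, fit amplitude-averaged lifetimes, and invert the
lifetime-weighted sector ratio to the mean dipole orientation angle.

Image convention: rows advance along -Z (row 0 is the top of the image,
+Z up) and columns along +Y; the excitation polarization is horizontal in
the image.  The ring position angle psi is measured from the +Y axis.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from . import decay as dc
from . import photoselection as ps

__all__ = [
    "PipelineError",
    "VesicleNotFoundError",
    "PolarizedFLIMStack",
    "VesicleGeometry",
    "SectorMasks",
    "SectorSignal",
    "OrientationReport",
    "OrganizationReport",
    "read_stack",
    "write_stack",
    "detect_vesicle",
    "build_sector_masks",
    "estimate_background",
    "extract_sector_signal",
    "estimate_orientation",
    "cone_aperture_scan",
    "anisotropy_map",
    "fast_lifetime_map",
    "pooled_ring_decay",
    "organization_report",
]


class PipelineError(RuntimeError):
    """Image-pipeline failure (geometry, masks, degenerate signals)."""


class VesicleNotFoundError(PipelineError):
    """No membrane ring rises above the background."""


@dataclass
class PolarizedFLIMStack:
    """Two-channel polarized photon-count rasters plus optional decay cubes.

    ``decay_cube_par``/``decay_cube_perp`` are [rows, cols, time] histograms
    aligned with the rasters; ``G`` is the instrumental polarization
    correction factor applied downstream as F = F_par + 2 G F_perp.
    """

    raster_par: np.ndarray
    raster_perp: np.ndarray
    decay_cube_par: np.ndarray | None = None
    decay_cube_perp: np.ndarray | None = None
    pixel_size_um: float = 0.1
    G: float = 1.0
    bin_width_ns: float | None = None

    def __post_init__(self) -> None:
        self.raster_par = np.asarray(self.raster_par)
        self.raster_perp = np.asarray(self.raster_perp)
        if self.raster_par.shape != self.raster_perp.shape or self.raster_par.ndim != 2:
            raise ValueError("rasters must be two 2-D arrays of identical shape")
        if np.any(self.raster_par < 0) or np.any(self.raster_perp < 0):
            raise ValueError("photon counts must be non-negative")
        for cube in (self.decay_cube_par, self.decay_cube_perp):
            if cube is not None and cube.shape[:2] != self.raster_par.shape:
                raise ValueError("decay cube spatial shape must match the rasters")
        if (self.decay_cube_par is None) != (self.decay_cube_perp is None):
            raise ValueError("provide decay cubes for both channels or neither")
        if self.decay_cube_par is not None and self.bin_width_ns is None:
            raise ValueError("bin_width_ns is required alongside decay cubes")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.G <= 0:
            raise ValueError("G factor must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster_par.shape

    @property
    def has_decay(self) -> bool:
        return self.decay_cube_par is not None

    @property
    def total_map(self) -> np.ndarray:
        """Per-pixel total fluorescence F_par + 2 G F_perp."""
        return dc.total_fluorescence(self.raster_par, self.raster_perp, self.G)


def write_stack(stack: PolarizedFLIMStack, tiff_path, h5_path=None) -> None:
    """Write rasters as a 2-page TIFF (page 0 parallel, page 1 perpendicular)
    and, if present, the decay cubes + metadata into an HDF5 container."""
    pages = np.stack([stack.raster_par, stack.raster_perp]).astype(np.uint32)
    tifffile.imwrite(tiff_path, pages)
    if h5_path is None:
        return
    with h5py.File(h5_path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["pixel_size_um"] = stack.pixel_size_um
        meta.attrs["G"] = stack.G
        if stack.bin_width_ns is not None:
            meta.attrs["bin_width_ns"] = stack.bin_width_ns
        if stack.has_decay:
            for name, cube in (
                ("par", stack.decay_cube_par),
                ("perp", stack.decay_cube_perp),
            ):
                f.create_dataset(
                    f"channels/{name}/decay_cube",
                    data=cube.astype(np.uint32),
                    compression="gzip",
                    compression_opts=1,
                    shuffle=True,
                )


def read_stack(tiff_path, h5_path=None) -> PolarizedFLIMStack:
    pages = tifffile.imread(tiff_path)
    if pages.ndim != 3 or pages.shape[0] < 2:
        raise PipelineError("expected a multi-page TIFF with parallel/perpendicular rasters")
    cube_par = cube_perp = None
    pixel_size, G, bw = 0.1, 1.0, None
    if h5_path is not None:
        with h5py.File(h5_path, "r") as f:
            meta = f["meta"].attrs
            pixel_size = float(meta.get("pixel_size_um", pixel_size))
            G = float(meta.get("G", G))
            bw = float(meta["bin_width_ns"]) if "bin_width_ns" in meta else None
            if "channels" in f:
                cube_par = f["channels/par/decay_cube"][...]
                cube_perp = f["channels/perp/decay_cube"][...]
    return PolarizedFLIMStack(
        raster_par=pages[0],
        raster_perp=pages[1],
        decay_cube_par=cube_par,
        decay_cube_perp=cube_perp,
        pixel_size_um=pixel_size,
        G=G,
        bin_width_ns=bw,
    )


@dataclass(frozen=True)
class VesicleGeometry:
    """Ring center/radius (pixels) and the radial half-width of integration."""

    center_px: tuple[float, float]
    radius_px: float
    ring_halfwidth_px: float

    def __post_init__(self) -> None:
        if self.radius_px <= 3.0 * self.ring_halfwidth_px:
            raise PipelineError(
                "ring radius must exceed 3x the integration half-width "
                f"(radius {self.radius_px:.1f} px, half-width {self.ring_halfwidth_px:.1f} px)"
            )

    def assert_inside(self, shape: tuple[int, int]) -> None:
        r = self.radius_px + self.ring_halfwidth_px
        row, col = self.center_px
        if row - r < 0 or col - r < 0 or row + r > shape[0] - 1 or col + r > shape[1] - 1:
            raise PipelineError("circle not fully inside the raster")


def _pixel_grid(shape, center):
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    dz = -rows  # +Z points up in the image
    dy = cols
    dist = np.hypot(dy, dz)
    return dy, dz, dist


def _radial_profile(total, center, max_radius):
    _, _, dist = _pixel_grid(total.shape, center)
    idx = np.round(dist).astype(int)
    keep = idx <= int(max_radius)
    sums = np.bincount(idx[keep], weights=total[keep])
    n = np.bincount(idx[keep])
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, sums / np.maximum(n, 1), 0.0)


def detect_vesicle(
    stack: PolarizedFLIMStack, ring_halfwidth_px: float | None = None
) -> VesicleGeometry:
    """Locate the vesicle ring: intensity centroid refined on the annulus,
    radius from the peak of the azimuthally averaged radial profile.

    Raises :class:`VesicleNotFoundError` when no radial peak exceeds the
    background by 5 robust standard deviations, and :class:`PipelineError`
    when the fitted circle does not fit inside the raster.
    """
    total = stack.total_map.astype(float)
    bg = float(np.median(total))
    sigma = 1.4826 * float(np.median(np.abs(total - bg))) + 1e-12
    signal = np.clip(total - bg, 0.0, None)
    if signal.sum() <= 0:
        raise VesicleNotFoundError("no vesicle found: image is flat")

    if ring_halfwidth_px is None:
        ring_halfwidth_px = max(2.0, 0.28 / stack.pixel_size_um)

    # first pass: global centroid; second pass: centroid restricted to the annulus
    com = ndimage.center_of_mass(signal)
    center = (float(com[0]), float(com[1]))
    max_r = min(stack.shape) / 2.0
    radius = None
    for _ in range(2):
        profile = _radial_profile(total, center, max_r)
        search = profile[3:]
        if search.size == 0 or search.max() <= bg + 5.0 * sigma:
            raise VesicleNotFoundError("no vesicle found: no radial peak above background + 5 sigma")
        radius = float(np.argmax(search) + 3)
        _, _, dist = _pixel_grid(stack.shape, center)
        ann = np.abs(dist - radius) <= 2.0 * ring_halfwidth_px
        w = signal * ann
        if w.sum() <= 0:
            raise VesicleNotFoundError("no vesicle found: empty annulus")
        com = ndimage.center_of_mass(w)
        center = (float(com[0]), float(com[1]))

    # parabolic sub-pixel refinement of the radial peak
    profile = _radial_profile(total, center, max_r)
    k = int(np.argmax(profile[3:]) + 3)
    if 1 <= k < len(profile) - 1:
        denom = profile[k - 1] - 2 * profile[k] + profile[k + 1]
        if denom < 0:
            radius = k + 0.5 * (profile[k - 1] - profile[k + 1]) / denom
        else:
            radius = float(k)
    geom = VesicleGeometry(center_px=center, radius_px=float(radius), ring_halfwidth_px=float(ring_halfwidth_px))
    geom.assert_inside(stack.shape)
    return geom


@dataclass(frozen=True)
class SectorMasks:
    """Boolean pixel masks for the four sectors (Z+, Z-, Y+, Y-)."""

    z_plus: np.ndarray
    z_minus: np.ndarray
    y_plus: np.ndarray
    y_minus: np.ndarray
    aperture_deg: float

    def pair(self, axis: str) -> np.ndarray:
        if axis.upper() == "Z":
            return self.z_plus | self.z_minus
        if axis.upper() == "Y":
            return self.y_plus | self.y_minus
        raise ValueError(f"axis must be 'Z' or 'Y', got {axis!r}")

    @property
    def union(self) -> np.ndarray:
        return self.z_plus | self.z_minus | self.y_plus | self.y_minus


def build_sector_masks(
    geom: VesicleGeometry, aperture_deg: float, shape: tuple[int, int]
) -> SectorMasks:
    """Annulus pixels within +-aperture/2 of each half-axis.

    For apertures of 90 deg and above neighbouring cones would overlap;
    overlaps are resolved by assigning each pixel to the nearest axis, so an
    aperture of 360 deg degenerates to a four-quadrant partition of the ring.
    """
    if not (0.0 < aperture_deg <= 360.0):
        raise ValueError(f"aperture must lie in (0, 360] deg, got {aperture_deg}")
    dy, dz, dist = _pixel_grid(shape, geom.center_px)
    annulus = np.abs(dist - geom.radius_px) <= geom.ring_halfwidth_px
    theta = np.degrees(np.arctan2(dz, dy))  # angle from +Y axis, (-180, 180]

    def angdist(target):
        d = np.abs(theta - target)
        return np.minimum(d, 360.0 - d)

    targets = {"y_plus": 0.0, "z_plus": 90.0, "y_minus": 180.0, "z_minus": -90.0}
    dists = {k: angdist(v) for k, v in targets.items()}
    half = aperture_deg / 2.0
    masks = {}
    if half < 45.0:
        for k in targets:
            masks[k] = annulus & (dists[k] <= half)
    else:
        stacked = np.stack([dists[k] for k in targets])
        nearest = np.argmin(stacked, axis=0)
        for i, k in enumerate(targets):
            masks[k] = annulus & (dists[k] <= half) & (nearest == i)
    for k, m in masks.items():
        if not m.any():
            raise PipelineError(f"empty sector mask {k!r}")
    return SectorMasks(aperture_deg=aperture_deg, **masks)


def estimate_background(stack: PolarizedFLIMStack, geom: VesicleGeometry) -> float:
    """Per-pixel background of the total map: median outside 1.5x the ring radius."""
    _, _, dist = _pixel_grid(stack.shape, geom.center_px)
    outside = dist > 1.5 * geom.radius_px
    if not outside.any():
        return 0.0
    return float(np.median(stack.total_map[outside]))


@dataclass
class SectorSignal:
    """Pooled signal of one symmetric sector pair (Z or Y)."""

    axis: str
    F_total: float
    pooled_decay: dc.DecayHistogram | None
    tau_amp_ns: float
    n_pixels: int
    lifetime_fit: dc.LifetimeFit | None = None

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise PipelineError("sector has no pixels")
        if self.F_total < 0:
            raise PipelineError("sector fluorescence must be non-negative")


def _fit_sector_tau(pooled: dc.DecayHistogram, tau_fit, library, subset, n_free_components, seed):
    if tau_fit == "library":
        fit = dc.fit_decay_fixed(pooled, library=library, subset=subset)
    elif tau_fit == "free":
        fit = dc.fit_decay_free(pooled, n_components=n_free_components, seed=seed, library=library)
    else:
        raise ValueError(f"tau_fit must be 'library' or 'free', got {tau_fit!r}")
    return fit


def extract_sector_signal(
    stack: PolarizedFLIMStack,
    masks: SectorMasks,
    axis: str,
    background_per_pixel: float = 0.0,
    tau_fit: str = "library",
    library: dc.ComponentLibrary = dc.AMB_LIBRARY,
    subset=dc.TABLE_SUBSET,
    n_free_components: int = 1,
    seed: int = 0,
) -> SectorSignal:
    """Pool the two symmetric sectors of one axis.

    Total fluorescence is the per-pixel F_par + 2 G F_perp summed over both
    sectors minus the background estimate (clamped at zero with a warning);
    the pooled decay is the bin-wise sum of the per-pixel histograms of both
    channels, fitted for the amplitude-averaged lifetime.
    """
    mask = masks.pair(axis)
    n_pix = int(mask.sum())
    if n_pix == 0:
        raise PipelineError(f"empty sector mask for axis {axis}")
    raw = float(stack.total_map[mask].sum())
    if raw <= 0:
        raise PipelineError(f"no signal in the {axis} sectors")
    F = raw - background_per_pixel * n_pix
    if F < 0:
        warnings.warn(
            f"background exceeds signal in the {axis} sectors; clamping at zero", stacklevel=2
        )
        F = 0.0

    pooled = None
    fit = None
    tau = math.nan
    if stack.has_decay:
        counts = (
            stack.decay_cube_par[mask].sum(axis=0).astype(np.int64)
            + stack.decay_cube_perp[mask].sum(axis=0).astype(np.int64)
        )
        edges = stack.bin_width_ns * np.arange(len(counts) + 1)
        pooled = dc.DecayHistogram(edges, counts, channel="total")
        fit = _fit_sector_tau(pooled, tau_fit, library, subset, n_free_components, seed)
        tau = fit.tau_amp_ns
    return SectorSignal(
        axis=axis.upper(),
        F_total=F,
        pooled_decay=pooled,
        tau_amp_ns=tau,
        n_pixels=n_pix,
        lifetime_fit=fit,
    )


@dataclass
class OrientationReport:
    """Orientation inversion result with its per-sector provenance."""

    result: ps.OrientationResult
    observation: ps.SectorObservation
    sector_z: SectorSignal
    sector_y: SectorSignal
    geometry: VesicleGeometry
    background_per_pixel: float
    G: float
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "nu_deg": self.result.nu_deg,
            "sigma_nu_deg": self.result.sigma_nu_deg,
            "cos2nu": self.result.cos2nu,
            "ratio_R": self.result.ratio_R,
            "lifetime_ratio_T": self.result.lifetime_ratio_T,
            "aperture_deg": self.observation.aperture_deg,
            "F_Z": self.observation.F_Z,
            "F_Y": self.observation.F_Y,
            "tau_Z_ns": self.observation.tau_Z_ns,
            "tau_Y_ns": self.observation.tau_Y_ns,
            "n_pixels_Z": self.sector_z.n_pixels,
            "n_pixels_Y": self.sector_y.n_pixels,
            "center_row_px": self.geometry.center_px[0],
            "center_col_px": self.geometry.center_px[1],
            "radius_px": self.geometry.radius_px,
            "ring_halfwidth_px": self.geometry.ring_halfwidth_px,
            "background_per_pixel": self.background_per_pixel,
            "G": self.G,
            **{f"setting_{k}": v for k, v in self.settings.items()},
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])

    def write(self, json_path=None, csv_path=None, provenance: dict | None = None) -> None:
        payload = self.to_dict()
        if provenance:
            payload["provenance"] = provenance
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=2, default=float)
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)


def estimate_orientation(
    stack: PolarizedFLIMStack,
    geom: VesicleGeometry | None = None,
    aperture_deg: float = 20.0,
    tau_fit: str = "library",
    library: dc.ComponentLibrary = dc.AMB_LIBRARY,
    subset=dc.TABLE_SUBSET,
    n_free_components: int = 1,
    seed: int = 0,
) -> OrientationReport:
    """Full orientation analysis of one vesicle stack.

    Composes ring detection, sector masking, background correction, pooled
    lifetime fits and the photoselection inversion.  Without decay cubes the
    lifetime ratio defaults to 1 (equal quantum yields in both fragments),
    with a warning.
    """
    if geom is None:
        geom = detect_vesicle(stack)
    geom.assert_inside(stack.shape)
    bg = estimate_background(stack, geom)
    masks = build_sector_masks(geom, aperture_deg, stack.shape)
    kw = dict(
        background_per_pixel=bg,
        tau_fit=tau_fit,
        library=library,
        subset=subset,
        n_free_components=n_free_components,
        seed=seed,
    )
    sec_z = extract_sector_signal(stack, masks, "Z", **kw)
    sec_y = extract_sector_signal(stack, masks, "Y", **kw)
    if stack.has_decay:
        tau_z, tau_y = sec_z.tau_amp_ns, sec_y.tau_amp_ns
    else:
        warnings.warn("no decay cubes: assuming equal sector lifetimes (T = 1)", stacklevel=2)
        tau_z = tau_y = 1.0
    obs = ps.SectorObservation(
        F_Z=sec_z.F_total,
        F_Y=sec_y.F_total,
        tau_Z_ns=tau_z,
        tau_Y_ns=tau_y,
        aperture_deg=aperture_deg,
    )
    result = ps.invert_observation(obs)
    return OrientationReport(
        result=result,
        observation=obs,
        sector_z=sec_z,
        sector_y=sec_y,
        geometry=geom,
        background_per_pixel=bg,
        G=stack.G,
        settings={"tau_fit": tau_fit, "aperture_deg": aperture_deg},
    )


def cone_aperture_scan(
    stack: PolarizedFLIMStack,
    geom: VesicleGeometry | None = None,
    apertures=(10.0, 20.0, 30.0, 40.0),
    **kwargs,
) -> pd.DataFrame:
    """Orientation estimate as a function of the sector cone aperture.

    The recovered angle depends slightly on the aperture through membrane
    curvature; the scan quantifies that sensitivity.  Requires at least two
    apertures; rows are sorted by aperture.
    """
    apertures = sorted(float(a) for a in apertures)
    if len(apertures) < 2:
        raise ValueError("aperture scan needs at least two apertures")
    if geom is None:
        geom = detect_vesicle(stack)
    rows = []
    for ap in apertures:
        rep = estimate_orientation(stack, geom=geom, aperture_deg=ap, **kwargs)
        rows.append(
            {
                "aperture_deg": ap,
                "nu_deg": rep.result.nu_deg,
                "sigma_nu_deg": rep.result.sigma_nu_deg,
                "ratio_R": rep.result.ratio_R,
                "lifetime_ratio_T": rep.result.lifetime_ratio_T,
            }
        )
    return pd.DataFrame(rows)


def anisotropy_map(stack: PolarizedFLIMStack, min_total: float = 20.0) -> np.ndarray:
    """Per-pixel anisotropy raster, NaN below the minimum-count threshold."""
    total = stack.total_map
    r = dc.anisotropy(stack.raster_par, stack.raster_perp, stack.G)
    out = np.where(total >= min_total, r, np.nan)
    return out.astype(np.float32)


def fast_lifetime_map(stack: PolarizedFLIMStack, min_counts: float = 30.0) -> np.ndarray:
    """Per-pixel mean photon arrival time (centroid shift) in ns.

    For a decay free of instrument-response broadening this approximates the
    intensity-weighted mean lifetime of the local mixture.  Requires the
    decay cubes; pixels below ``min_counts`` photons are NaN.
    """
    if not stack.has_decay:
        raise PipelineError("no time-resolved data: stack has no decay cubes")
    cube = stack.decay_cube_par.astype(np.float64) + stack.decay_cube_perp.astype(np.float64)
    n = cube.sum(axis=2)
    centers = stack.bin_width_ns * (np.arange(cube.shape[2]) + 0.5)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_t = (cube @ centers) / n
    out = np.where(n >= min_counts, mean_t, np.nan)
    return out.astype(np.float32)


def pooled_ring_decay(stack: PolarizedFLIMStack, geom: VesicleGeometry) -> dc.DecayHistogram:
    """Bin-wise sum of per-pixel histograms over the whole membrane annulus."""
    if not stack.has_decay:
        raise PipelineError("no time-resolved data: stack has no decay cubes")
    _, _, dist = _pixel_grid(stack.shape, geom.center_px)
    mask = np.abs(dist - geom.radius_px) <= geom.ring_halfwidth_px
    counts = (
        stack.decay_cube_par[mask].sum(axis=0).astype(np.int64)
        + stack.decay_cube_perp[mask].sum(axis=0).astype(np.int64)
    )
    edges = stack.bin_width_ns * np.arange(len(counts) + 1)
    return dc.DecayHistogram(edges, counts, channel="total")


@dataclass
class OrganizationReport:
    """Organization-form fractions from a library-constrained ring decay fit."""

    fractions_pct: dict
    sigmas_pct: dict
    tau_amp_ns: float
    chi2_reduced: float
    n_photons: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "organization_form": name,
                "fraction_pct": self.fractions_pct[name],
                "sigma_pct": self.sigmas_pct[name],
            }
            for name in self.fractions_pct
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "fractions_pct": self.fractions_pct,
            "sigmas_pct": self.sigmas_pct,
            "tau_amp_ns": self.tau_amp_ns,
            "chi2_reduced": self.chi2_reduced,
            "n_photons": self.n_photons,
        }

    def write(self, json_path=None, csv_path=None, provenance: dict | None = None) -> None:
        if json_path is not None:
            payload = self.to_dict()
            if provenance:
                payload["provenance"] = provenance
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=2, default=float)
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)


def organization_report(
    stack: PolarizedFLIMStack,
    geom: VesicleGeometry | None = None,
    library: dc.ComponentLibrary = dc.AMB_LIBRARY,
    subset=dc.TABLE_SUBSET,
) -> OrganizationReport:
    """Quantify organization-form fractions from the whole-ring pooled decay."""
    if geom is None:
        geom = detect_vesicle(stack)
    pooled = pooled_ring_decay(stack, geom)
    fit = dc.fit_decay_fixed(pooled, library=library, subset=subset)
    fractions = {n: float(f) for n, f in zip(fit.names, fit.fractions_pct)}
    sigmas = {
        n: float(s)
        for n, s in zip(
            fit.names,
            fit.fraction_sigmas_pct
            if fit.fraction_sigmas_pct is not None
            else np.full(len(fit.names), np.nan),
        )
    }
    return OrganizationReport(
        fractions_pct=fractions,
        sigmas_pct=sigmas,
        tau_amp_ns=fit.tau_amp_ns,
        chi2_reduced=fit.chi2_reduced,
        n_photons=pooled.n_photons,
    )
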