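"""Synthetic FIB-SEM phantoms with known ground truth.

Three generators emulate the specimens this package is built to quantify:

* :func:`make_granule_phantom` — a cuticle granule whose lightly-staining
  (ls) sub-phase forms a bicontinuous network of flattened layers with a
  controlled characteristic thickness, volume fraction and mean lamellar
  orientation, modelled as a level set of an oriented band-pass filtered
  Gaussian random field.
* :func:`make_vesicle_phantom` — densely packed spherical secretory
  vesicles, each partitioned into proto-granule (pg), proto-matrix (pm)
  and crescent (cp) phases with prescribed volume fractions and an
  osmium-affinity intensity ordering pm > pg > cp.
* :func:`make_eds_phantom` — per-element Poisson count maps over a 2D
  phase label image, emulating STEM-EDS acquisition statistics.

:func:`degrade_stack` injects the FIB-SEM artefacts the preprocessing
pipeline is designed to remove: per-slice translational jitter, vertical
"waterfall" stripes, additive and shot noise, and optional contrast
inversion.  All randomness is driven by explicit per-config seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.special import ndtri

from .stack import PhantomTruth, PhaseLabelVolume, VolumeStack

__all__ = [
    "GranulePhantomConfig",
    "VesiclePhantomConfig",
    "DegradationConfig",
    "CompositionConfig",
    "EDSMapSet",
    "make_granule_phantom",
    "make_vesicle_phantom",
    "degrade_stack",
    "make_eds_phantom",
    "NATIVE_GRANULE",
    "VESICLE_GLAND",
    "NATIVE_CUTICLE_EDS",
    "VESICLE_GLAND_EDS",
    "PRESETS",
]

# Band-pass centre calibration for the granule generator.  For a narrowband
# Gaussian process thresholded at quantile (1 - phi), the mean excursion
# width follows the Rice level-crossing rate: width = phi / (f0 exp(-c^2/2))
# with c the standard-normal quantile of (1 - phi).  The constant below was
# calibrated once against the local-thickness transform so that the realized
# modal layer thickness matches the requested value (see docs/methods.md).
_BAND_CENTRE_C = 0.50


class PackingError(RuntimeError):
    """Raised when the requested vesicle count cannot be placed."""


@dataclass(frozen=True)
class GranulePhantomConfig:
    """Parameters of the bicontinuous-granule phantom."""

    shape_voxels: tuple[int, int, int] = (96, 128, 128)
    voxel_size_nm: tuple[float, float, float] = (10.5, 4.8, 4.8)
    layer_thickness_nm: float = 20.0
    ls_volume_fraction: float = 0.4
    lamellar_tilt_deg: float = 45.0
    anisotropy: float = 5.0
    granule_radius_nm: float = 450.0
    seed: int = 1234
    # rendered intensity levels, SEM-like contrast (heavier stain brighter,
    # so the lightly-staining phase is dark); normalised [0, 1] grey values
    ls_level: float = 0.30
    hs_level: float = 0.72
    outside_level: float = 0.78

    def validate(self) -> None:
        if len(self.shape_voxels) != 3 or any(int(s) <= 0 for s in self.shape_voxels):
            raise ValueError("shape_voxels must be 3 positive integers")
        if len(self.voxel_size_nm) != 3 or any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel_size_nm must be 3 positive reals")
        if not 0.0 < self.ls_volume_fraction < 1.0:
            raise ValueError("ls_volume_fraction must be strictly in (0, 1)")
        if not 0.0 <= self.lamellar_tilt_deg <= 90.0:
            raise ValueError("lamellar_tilt_deg must be in [0, 90]")
        if self.anisotropy < 1.0:
            raise ValueError("anisotropy must be >= 1")
        if self.layer_thickness_nm < 2.0 * min(self.voxel_size_nm):
            raise ValueError(
                f"layer_thickness_nm={self.layer_thickness_nm} is unresolvable at "
                f"voxel size {self.voxel_size_nm} (needs >= 2 x min voxel size)"
            )
        if self.granule_radius_nm <= 0:
            raise ValueError("granule_radius_nm must be positive")


@dataclass(frozen=True)
class VesiclePhantomConfig:
    """Parameters of the packed secretory-vesicle phantom."""

    n_vesicles: int = 28
    vesicle_radius_nm: float = 300.0
    radius_jitter: float = 0.10  # relative sd of per-vesicle radius
    phase_fractions: tuple[float, float, float] = (0.5, 0.4, 0.1)  # pg, pm, cp
    shape_voxels: tuple[int, int, int] = (128, 224, 224)
    voxel_size_nm: tuple[float, float, float] = (17.5, 12.4, 12.4)
    # TEM-like osmium-affinity grey levels: pm heaviest, cp lightest
    intensity_levels: Mapping[str, float] = field(
        default_factory=lambda: {"pg": 0.50, "pm": 0.80, "cp": 0.20, "background": 0.10}
    )
    # weak isotropic texture of the surrounding intracellular material
    # (and mild within-phase granularity): std of a Gaussian random field
    # with the given correlation length, added to the rendered volume
    background_texture_std: float = 0.08
    texture_corr_nm: float = 80.0
    seed: int = 0
    max_placement_tries: int = 20000

    def validate(self) -> None:
        if self.n_vesicles < 1:
            raise ValueError("n_vesicles must be positive")
        if self.vesicle_radius_nm <= 0:
            raise ValueError("vesicle_radius_nm must be positive")
        f = np.asarray(self.phase_fractions, dtype=float)
        if f.shape != (3,) or (f < 0).any():
            raise ValueError("phase_fractions must be 3 non-negative reals")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("phase_fractions must sum to 1 within 1e-9")
        for k in ("pg", "pm", "cp", "background"):
            if k not in self.intensity_levels:
                raise ValueError(f"intensity_levels missing {k!r}")


@dataclass(frozen=True)
class DegradationConfig:
    """FIB-SEM imaging degradation applied to a clean phantom."""

    shift_sigma_px: float = 2.0
    stripe_amplitude: float = 0.10
    stripe_frequency_band: tuple[float, float] = (0.05, 0.20)  # cycles/px along x
    # slice-to-slice correlation of the stripe pattern: FIB curtaining is
    # topography-driven and evolves slowly along the milling direction
    stripe_z_corr: float = 0.9
    gaussian_noise_sigma: float = 0.05
    shot_noise: bool = False
    shot_scale: float = 255.0  # expected counts at unit intensity
    invert_contrast: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.shift_sigma_px < 0 or self.stripe_amplitude < 0 or self.gaussian_noise_sigma < 0:
            raise ValueError("degradation amplitudes must be non-negative")
        lo, hi = self.stripe_frequency_band
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("stripe_frequency_band must satisfy 0 < lo < hi <= 0.5 cycles/px")
        if self.shot_scale <= 0:
            raise ValueError("shot_scale must be positive")


@dataclass(frozen=True)
class CompositionConfig:
    """Per-phase, per-element expected EDS count rates (counts/pixel at unit exposure)."""

    rates: Mapping[str, Mapping[str, float]]
    background_rate: float = 2.0  # flat continuum, added to every element everywhere
    pixel_size_nm: float = 9.3
    exposure: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for phase, elems in self.rates.items():
            for el, r in elems.items():
                if r < 0:
                    raise ValueError(f"negative rate for {phase}/{el}")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.pixel_size_nm <= 0 or self.exposure <= 0:
            raise ValueError("pixel_size_nm and exposure must be positive")

    @property
    def elements(self) -> list[str]:
        els: list[str] = []
        for elems in self.rates.values():
            for el in elems:
                if el not in els:
                    els.append(el)
        return els


@dataclass
class EDSMapSet:
    """Co-registered per-element 2D count maps."""

    maps: dict[str, np.ndarray]
    pixel_size_nm: float
    exposure: float = 1.0
    labels: np.ndarray | None = None
    phase_names: Mapping[int, str] | None = None
    background_rate: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) != 1:
            raise ValueError("all element maps must share one shape")
        for el, m in self.maps.items():
            if (np.asarray(m) < 0).any():
                raise ValueError(f"negative counts in map {el!r}")
        if self.labels is not None and self.labels.shape not in shapes:
            raise ValueError("labels must be congruent with the element maps")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.maps.values())).shape

    @property
    def elements(self) -> list[str]:
        return list(self.maps)


# ---------------------------------------------------------------------------
# granule phantom
# ---------------------------------------------------------------------------

def _band_centre_frequency(thickness_nm: float, fraction: float) -> float:
    """Centre frequency (cycles/nm) of the oriented band-pass kernel."""
    c = ndtri(1.0 - fraction)
    period = _BAND_CENTRE_C * np.exp(-0.5 * c * c) * thickness_nm / fraction
    return 1.0 / period


def bicontinuous_field(
    shape: tuple[int, int, int],
    voxel_size_nm: tuple[float, float, float],
    layer_thickness_nm: float,
    ls_volume_fraction: float,
    lamellar_tilt_deg: float,
    anisotropy: float,
    rng: np.random.Generator,
    rel_bandwidth: float = 0.15,
) -> np.ndarray:
    """Oriented band-pass filtered Gaussian random field (zero mean).

    The pass band is a Gaussian annulus in physical frequency space centred
    at the calibrated layer frequency along the layer normal (tilted by
    ``lamellar_tilt_deg`` from the fiber axis ``z`` within the z-y plane)
    and compressed in-plane by the anisotropy factor, so that anisotropy 1
    reduces to an isotropic spherical shell.
    """
    noise = rng.standard_normal(shape)
    spec = np.fft.rfftn(noise)
    kz = np.fft.fftfreq(shape[0], d=voxel_size_nm[0])[:, None, None]
    ky = np.fft.fftfreq(shape[1], d=voxel_size_nm[1])[None, :, None]
    kx = np.fft.rfftfreq(shape[2], d=voxel_size_nm[2])[None, None, :]
    tilt = np.deg2rad(lamellar_tilt_deg)
    # fiber axis = y (in the slice plane); the layer normal is tilted from it
    # within the slice (y-x) plane, so layers are resolved at the finer
    # in-plane pixel size and extend along the milling direction z
    normal = np.array([0.0, np.cos(tilt), np.sin(tilt)])  # (z, y, x)
    u = kz * normal[0] + ky * normal[1] + kx * normal[2]
    v2 = np.maximum(kz**2 + ky**2 + kx**2 - u**2, 0.0)
    f0 = _band_centre_frequency(layer_thickness_nm, ls_volume_fraction)
    m = np.sqrt(u**2 + (anisotropy**2) * v2)
    sigma = rel_bandwidth * f0
    spec *= np.exp(-0.5 * ((m - f0) / sigma) ** 2)
    field_ = np.fft.irfftn(spec, s=shape, axes=(0, 1, 2))
    return field_ - field_.mean()


def make_granule_phantom(config: GranulePhantomConfig) -> PhantomTruth:
    """Generate a bicontinuous-granule phantom with ground truth.

    Returns a :class:`PhantomTruth` whose ``ls_mask`` is the binary
    lightly-staining phase clipped to a spherical granule support and whose
    clean volume renders ls dark / hs bright (SEM backscatter contrast).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.shape_voxels)
    vox = config.voxel_size_nm

    field_ = bicontinuous_field(
        shape, vox, config.layer_thickness_nm, config.ls_volume_fraction,
        config.lamellar_tilt_deg, config.anisotropy, rng,
    )

    zz = (np.arange(shape[0]) - (shape[0] - 1) / 2.0)[:, None, None] * vox[0]
    yy = (np.arange(shape[1]) - (shape[1] - 1) / 2.0)[None, :, None] * vox[1]
    xx = (np.arange(shape[2]) - (shape[2] - 1) / 2.0)[None, None, :] * vox[2]
    support = zz**2 + yy**2 + xx**2 <= config.granule_radius_nm**2
    if not support.any():
        raise ValueError("granule_radius_nm too small: empty support")

    # threshold at the quantile achieving the requested ls fraction *inside*
    # the granule support
    thr = np.quantile(field_[support], 1.0 - config.ls_volume_fraction)
    ls_mask = (field_ > thr) & support
    realized_fraction = ls_mask.sum() / support.sum()

    intensity = np.full(shape, config.outside_level, dtype=np.float32)
    intensity[support] = config.hs_level
    intensity[ls_mask] = config.ls_level
    # half-voxel smoothing removes staircase aliasing at phase boundaries
    intensity = ndimage.gaussian_filter(intensity, 0.5)

    clean = VolumeStack(
        intensity, vox, fiber_axis="y",
        meta={"phantom": "granule", "seed": config.seed},
    )
    labels = PhaseLabelVolume(
        ls_mask.astype(np.uint8),
        {0: "hs", 1: "ls"},
        vox,
        instances=support.astype(np.uint16),
    )
    return PhantomTruth(
        clean=clean,
        config=config,
        labels=labels,
        ls_mask=ls_mask,
        support_mask=support,
        realized={
            "ls_fraction": float(realized_fraction),
            "layer_thickness_nm": config.layer_thickness_nm,
            "lamellar_tilt_deg": config.lamellar_tilt_deg,
        },
    )


# ---------------------------------------------------------------------------
# vesicle phantom
# ---------------------------------------------------------------------------

_VESICLE_PHASES = {1: "pg", 2: "pm", 3: "cp"}


def _partition_vesicle(
    coords_nm: np.ndarray,
    fractions: tuple[float, float, float],
    direction: np.ndarray,
) -> np.ndarray:
    """Assign phase codes (1 pg, 2 pm, 3 cp) to vesicle voxels.

    The crescent is a peripheral spherical cap cut along ``direction``; the
    proto-granule is the central ball of the remainder; the proto-matrix is
    the shell between.  Cut positions are count-based quantiles, so realized
    fractions match requests to within one voxel layer.
    """
    f_pg, f_pm, f_cp = fractions
    n = coords_nm.shape[0]
    phase = np.full(n, 2, dtype=np.uint8)  # default pm
    proj = coords_nm @ direction
    if f_cp > 0:
        cut = np.quantile(proj, 1.0 - f_cp)
        is_cp = proj >= cut
    else:
        is_cp = np.zeros(n, dtype=bool)
    rho = np.linalg.norm(coords_nm, axis=1)
    rest = ~is_cp
    if rest.any() and f_pg > 0:
        q = f_pg / max(f_pg + f_pm, 1e-12)
        rcut = np.quantile(rho[rest], q)
        is_pg = rest & (rho <= rcut)
    else:
        is_pg = np.zeros(n, dtype=bool)
    phase[is_cp] = 3
    phase[is_pg] = 1
    return phase


def make_vesicle_phantom(config: VesiclePhantomConfig) -> PhantomTruth:
    """Generate densely packed three-phase secretory vesicles."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.shape_voxels)
    vox = np.asarray(config.voxel_size_nm)

    extent = np.array(shape) * vox
    radii_nm: list[float] = []
    centres_nm: list[np.ndarray] = []
    tries = 0
    while len(radii_nm) < config.n_vesicles and tries < config.max_placement_tries:
        tries += 1
        r = config.vesicle_radius_nm * (1.0 + config.radius_jitter * rng.standard_normal())
        r = float(np.clip(r, 0.3 * config.vesicle_radius_nm, 2.0 * config.vesicle_radius_nm))
        if 2.0 * r > min(extent):
            continue
        c = np.array([rng.uniform(r, e - r) for e in extent])
        ok = all(np.linalg.norm(c - c0) >= r + r0 for c0, r0 in zip(centres_nm, radii_nm))
        if ok:
            centres_nm.append(c)
            radii_nm.append(r)
    if len(radii_nm) < config.n_vesicles:
        raise PackingError(
            f"could only place {len(radii_nm)} of {config.n_vesicles} vesicles in "
            f"{config.max_placement_tries} tries; reduce count or radius"
        )

    phases = np.zeros(shape, dtype=np.uint8)
    instances = np.zeros(shape, dtype=np.uint16)
    per_vesicle = []
    grid = [np.arange(n) * v for n, v in zip(shape, vox)]
    for i, (c, r) in enumerate(zip(centres_nm, radii_nm), start=1):
        lo = [max(int((c[d] - r) / vox[d]) - 1, 0) for d in range(3)]
        hi = [min(int((c[d] + r) / vox[d]) + 2, shape[d]) for d in range(3)]
        sub = tuple(slice(lo[d], hi[d]) for d in range(3))
        zz = (grid[0][sub[0]] - c[0])[:, None, None]
        yy = (grid[1][sub[1]] - c[1])[None, :, None]
        xx = (grid[2][sub[2]] - c[2])[None, None, :]
        inside = zz**2 + yy**2 + xx**2 <= r * r
        if not inside.any():
            continue
        coords = np.stack(np.broadcast_arrays(zz, yy, xx), axis=-1)[inside]
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        ph = _partition_vesicle(coords, config.phase_fractions, direction)
        block_ph = phases[sub]
        block_in = instances[sub]
        block_ph[inside] = ph
        block_in[inside] = i
        n_vox = ph.size
        per_vesicle.append(
            {
                "vesicle_id": i,
                "radius_nm": r,
                "n_voxels": int(n_vox),
                "pg": float((ph == 1).sum() / n_vox),
                "pm": float((ph == 2).sum() / n_vox),
                "cp": float((ph == 3).sum() / n_vox),
            }
        )

    levels = config.intensity_levels
    lut = np.array(
        [levels["background"], levels["pg"], levels["pm"], levels["cp"]], dtype=np.float32
    )
    intensity = lut[phases]
    if config.background_texture_std > 0:
        sig = [config.texture_corr_nm / (2.0 * v) for v in vox]
        tex = ndimage.gaussian_filter(rng.standard_normal(shape), sig)
        sd = tex.std()
        if sd > 0:
            intensity = intensity + (config.background_texture_std / sd) * tex.astype(
                np.float32
            )

    clean = VolumeStack(
        intensity, tuple(vox), fiber_axis="z",
        meta={"phantom": "vesicle", "seed": config.seed},
    )
    labels = PhaseLabelVolume(
        phases, dict(_VESICLE_PHASES), tuple(vox), instances=instances
    )
    return PhantomTruth(
        clean=clean,
        config=config,
        labels=labels,
        realized={"vesicles": per_vesicle},
    )


# ---------------------------------------------------------------------------
# degradation
# ---------------------------------------------------------------------------

def _stripe_pattern(n_cols: int, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited column pattern (1D along x)."""
    white = rng.standard_normal(n_cols)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_cols)
    keep = (f >= band[0]) & (f <= band[1])
    spec[~keep] = 0.0
    s = np.fft.irfft(spec, n=n_cols)
    rms = np.sqrt(np.mean(s**2))
    return s / rms if rms > 0 else s


def degrade_stack(truth: PhantomTruth, config: DegradationConfig) -> VolumeStack:
    """Apply FIB-SEM degradation to a phantom's clean volume.

    Order: per-slice translation, multiplicative column stripes, additive
    Gaussian noise, Poisson shot noise, optional contrast inversion.  The
    injected shifts are recorded in ``truth.shifts_px`` (dy, dx per slice).
    With all amplitudes zero and inversion off, the output equals the clean
    volume exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    vol = truth.clean.data.astype(np.float32).copy()
    nz, ny, nx = vol.shape

    shifts = np.zeros((nz, 2), dtype=float)
    if config.shift_sigma_px > 0:
        shifts = rng.normal(0.0, config.shift_sigma_px, size=(nz, 2))
        shifts[0] = 0.0
        for i in range(1, nz):
            vol[i] = ndimage.shift(vol[i], shifts[i], order=1, mode="nearest")

    if config.stripe_amplitude > 0:
        rho = float(np.clip(config.stripe_z_corr, 0.0, 1.0))
        pattern = _stripe_pattern(nx, config.stripe_frequency_band, rng)
        for i in range(nz):
            if i > 0:
                innov = _stripe_pattern(nx, config.stripe_frequency_band, rng)
                pattern = rho * pattern + np.sqrt(1.0 - rho * rho) * innov
            vol[i] *= (1.0 + config.stripe_amplitude * pattern)[None, :]

    if config.gaussian_noise_sigma > 0:
        vol += rng.normal(0.0, config.gaussian_noise_sigma, size=vol.shape).astype(np.float32)

    if config.shot_noise:
        lam = np.clip(vol, 0.0, None) * config.shot_scale
        vol = rng.poisson(lam).astype(np.float32) / config.shot_scale

    if config.invert_contrast:
        vol = vol.max() + vol.min() - vol

    truth.shifts_px = shifts
    return truth.clean.copy_with(
        vol,
        degraded=True,
        degradation_seed=config.seed,
        inverted_contrast=bool(config.invert_contrast),
    )


# ---------------------------------------------------------------------------
# EDS phantom
# ---------------------------------------------------------------------------

def make_eds_phantom(
    labels: np.ndarray,
    phase_names: Mapping[int, str],
    config: CompositionConfig,
) -> EDSMapSet:
    """Simulate per-element STEM-EDS count maps over a 2D label image.

    Counts are independent Poisson draws with mean
    ``(phase rate + background continuum) x exposure`` per pixel.
    """
    config.validate()
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be a 2D phase image")
    rng = np.random.default_rng(config.seed)

    present = np.unique(labels)
    name_of = dict(phase_names)
    for code in present:
        nm = name_of.get(int(code))
        if nm is None:
            raise ValueError(f"label code {code} has no phase name")
        if nm not in config.rates:
            raise ValueError(f"no composition rates defined for phase {nm!r}")

    elements = config.elements
    maps: dict[str, np.ndarray] = {}
    for el in elements:
        rate = np.full(labels.shape, config.background_rate, dtype=float)
        for code in present:
            nm = name_of[int(code)]
            rate[labels == code] += config.rates[nm].get(el, 0.0)
        maps[el] = rng.poisson(rate * config.exposure).astype(np.int64)

    return EDSMapSet(
        maps=maps,
        pixel_size_nm=config.pixel_size_nm,
        exposure=config.exposure,
        labels=labels,
        phase_names=name_of,
        background_rate=config.background_rate,
        meta={"seed": config.seed, "truth_rates": {p: dict(e) for p, e in config.rates.items()}},
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Native thread-cuticle granule: 20 nm layers tilted 45 deg to the fiber
#: axis, at the thread acquisition voxel size (4.8 nm pixels, 10.5 nm slices).
NATIVE_GRANULE = GranulePhantomConfig()

#: Cuticle-gland secretory vesicles at the foot-tissue acquisition voxel size
#: (12.4 nm pixels, 17.5 nm slices).  The pg/pm/cp volume fractions are
#: plausible placeholders: only their cross-vesicle regularity is documented.
VESICLE_GLAND = VesiclePhantomConfig()

#: Native cuticle composition: equal N in both phases, matrix sulfur rate
#: twice the granule rate, Fe confined to the matrix, V to the granule.
NATIVE_CUTICLE_EDS = CompositionConfig(
    rates={
        "background": {"N": 0.0, "S": 0.0, "Fe": 0.0, "V": 0.0},
        "pg": {"N": 100.0, "S": 30.0, "Fe": 0.0, "V": 15.0},
        "pm": {"N": 100.0, "S": 60.0, "Fe": 20.0, "V": 0.0},
    },
    pixel_size_nm=9.3,
)

#: Secretory-vesicle composition: no transition metals anywhere.
VESICLE_GLAND_EDS = CompositionConfig(
    rates={
        "background": {"N": 10.0, "S": 5.0, "Fe": 0.0, "V": 0.0},
        "pg": {"N": 100.0, "S": 30.0, "Fe": 0.0, "V": 0.0},
        "pm": {"N": 100.0, "S": 60.0, "Fe": 0.0, "V": 0.0},
        "cp": {"N": 80.0, "S": 15.0, "Fe": 0.0, "V": 0.0},
    },
    pixel_size_nm=17.0,
)

PRESETS = {
    "native-granule": NATIVE_GRANULE,
    "vesicle-gland": VESICLE_GLAND,
    "native-cuticle": NATIVE_CUTICLE_EDS,
    "vesicle-gland-eds": VESICLE_GLAND_EDS,
}


def preset(name: str, **overrides):
    """Return a preset config, optionally with replaced fields."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(base, **overrides) if overrides else base
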