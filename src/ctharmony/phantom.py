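"""Synthetic pixel-aligned multi-protocol abdominal-CT phantom cohorts.

Dual-energy CT yields several reconstructions (FBP, IR, virtual
monoenergetic images) of the *same* raw acquisition, so the images of one
subject are voxel-aligned by construction.  This module emulates that
situation: one labeled anatomical phantom per subject, rendered once per
reconstruction protocol with protocol-specific iodine-contrast gain,
point-spread blur and noise magnitude, all protocols sharing a single
noise realisation so pixel-wise correspondence is preserved.

The emulation scales iodine enhancement rather than modelling spectral
physics: low-keV monoenergetic images amplify iodine attenuation, which is
the property radiomics actually sees.  No sinogram-domain reconstruction
is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

# ---------------------------------------------------------------------------
# organ labels
# ---------------------------------------------------------------------------

BACKGROUND, LIVER, SPLEEN, KIDNEY, MUSCLE, VESSEL, AIR, FAT = range(8)

ORGAN_NAMES = {
    BACKGROUND: "background",
    LIVER: "liver",
    SPLEEN: "spleen",
    KIDNEY: "kidney",
    MUSCLE: "muscle",
    VESSEL: "vessel",
    AIR: "air",
    FAT: "fat",
}

# typical portal-phase attenuation (HU) and iodine enhancement (HU)
DEFAULT_BASE_HU = {
    BACKGROUND: 30.0,
    LIVER: 60.0,
    SPLEEN: 50.0,
    KIDNEY: 40.0,
    MUSCLE: 55.0,
    VESSEL: 50.0,
    AIR: -1000.0,
    FAT: -100.0,
}
DEFAULT_ENHANCEMENT_HU = {
    BACKGROUND: 0.0,
    LIVER: 20.0,
    SPLEEN: 40.0,
    KIDNEY: 100.0,
    MUSCLE: 5.0,
    VESSEL: 150.0,
    AIR: 0.0,
    FAT: 0.0,
}


class PhantomSizingError(ValueError):
    """Image too small (or jitter too large) to place an organ or its ROI."""


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry of the synthetic abdomen.

    Organ positions and semi-axes are expressed as fractions of the image
    edge so the same configuration scales from the 256 px desk default to a
    512 px full-resolution preset.
    """

    shape: Tuple[int, int] = (256, 256)
    pixel_spacing_mm: float = 1.0
    base_hu: Dict[int, float] = field(default_factory=lambda: dict(DEFAULT_BASE_HU))
    enhancement_hu: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ENHANCEMENT_HU)
    )
    # per-subject jitter: organ centre shift (fraction of edge) and axis scale
    jitter_shift: float = 0.012
    jitter_scale: float = 0.05
    # inter-subject biological variability: organ attenuation spread (HU) and
    # relative spread of the iodine-enhancement level
    hu_jitter_sd: float = 8.0
    enhancement_jitter_sd: float = 0.15
    # ROI areas, Fig-style convention: small for vessels, larger elsewhere
    vessel_roi_area_mm2: float = 120.0
    other_roi_area_mm2: float = 240.0


# fractional (row, col) centres and (row, col) semi-axes of each organ
_ORGANS: List[Tuple[str, int, Tuple[float, float], Tuple[float, float]]] = [
    ("liver", LIVER, (0.41, 0.355), (0.160, 0.175)),
    ("spleen", SPLEEN, (0.385, 0.70), (0.100, 0.075)),
    ("kidney_left", KIDNEY, (0.625, 0.33), (0.065, 0.050)),
    ("kidney_right", KIDNEY, (0.625, 0.67), (0.065, 0.050)),
    ("muscle_left", MUSCLE, (0.72, 0.42), (0.070, 0.050)),
    ("muscle_right", MUSCLE, (0.72, 0.58), (0.070, 0.050)),
    ("vessel", VESSEL, (0.585, 0.50), (0.036, 0.036)),
    ("air_pocket", AIR, (0.50, 0.60), (0.045, 0.045)),
]

_BODY_AXES = (0.40, 0.45)
_FAT_INNER_AXES = (0.365, 0.415)


@dataclass
class LabeledPhantom:
    """One subject's anatomy: HU maps plus an integer organ-label map."""

    base_hu: np.ndarray
    organ_labels: np.ndarray
    enhancement_hu: np.ndarray
    pixel_spacing_mm: float
    organ_geometry: Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.base_hu.shape != self.organ_labels.shape or (
            self.base_hu.shape != self.enhancement_hu.shape
        ):
            raise ValueError("phantom maps must share one shape")
        if np.any(self.enhancement_hu < 0):
            raise ValueError("enhancement_hu must be nonnegative")
        air = self.organ_labels == AIR
        if air.any() and (
            np.any(self.base_hu[air] > -900) or np.any(self.enhancement_hu[air] != 0)
        ):
            raise ValueError("air pixels must have base_hu <= -900 and no enhancement")


@dataclass(frozen=True)
class ProtocolParams:
    """Rendering parameters of one reconstruction protocol."""

    label: str
    contrast_gain: float = 1.0
    psf_sigma_mm: float = 0.8
    noise_sd_hu: float = 10.0
    noise_corr_sigma_mm: float = 0.7

    def __post_init__(self) -> None:
        if self.contrast_gain <= 0:
            raise ValueError("contrast_gain must be positive")
        if self.noise_sd_hu < 0 or self.psf_sigma_mm < 0:
            raise ValueError("noise_sd_hu and psf_sigma_mm must be nonnegative")


# Default protocol set.  Orderings encode the reconstruction physics the
# radiomics sees: FBP is noisier than IR; 40 keV monoenergetic images
# amplify iodine far more than 70 keV.
DEFAULT_PROTOCOLS: Dict[str, ProtocolParams] = {
    "FBP": ProtocolParams("FBP", contrast_gain=1.0, psf_sigma_mm=0.6,
                          noise_sd_hu=16.0, noise_corr_sigma_mm=0.5),
    "IR": ProtocolParams("IR", contrast_gain=1.0, psf_sigma_mm=0.9,
                         noise_sd_hu=7.0, noise_corr_sigma_mm=0.9),
    "M40": ProtocolParams("M40", contrast_gain=2.2, psf_sigma_mm=0.8,
                          noise_sd_hu=13.0, noise_corr_sigma_mm=0.7),
    "M70": ProtocolParams("M70", contrast_gain=1.0, psf_sigma_mm=0.8,
                          noise_sd_hu=8.0, noise_corr_sigma_mm=0.7),
}

DEFAULT_TARGET = "IR"


@dataclass
class ProtocolStack:
    """Voxel-aligned images of one subject, one per protocol label."""

    subject_id: str
    images: Dict[str, np.ndarray]
    target_label: str = DEFAULT_TARGET
    pixel_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) > 1:
            raise ValueError(f"stack images of {self.subject_id} differ in shape: {shapes}")

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.images.values())).shape

    @property
    def labels(self) -> List[str]:
        return list(self.images)

    def require_target(self) -> None:
        if self.target_label not in self.images:
            raise KeyError(
                f"stack {self.subject_id} lacks target protocol {self.target_label!r}"
            )


@dataclass(frozen=True)
class ROI:
    roi_id: str
    organ_role: str
    center: Tuple[float, float]  # (row, col) in pixels
    radius_mm: float
    slice_index: int = 0

    def mask(self, shape: Tuple[int, int], pixel_spacing_mm: float) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        r_px = self.radius_mm / pixel_spacing_mm
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= r_px**2


@dataclass
class ROISet:
    rois: List[ROI]
    pixel_spacing_mm: float = 1.0

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def roster(self) -> List[Tuple[str, str]]:
        return [(r.roi_id, r.organ_role) for r in self.rois]


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _ellipse_mask(shape, center_frac, axes_frac) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cr, ccen = center_frac[0] * h, center_frac[1] * w
    ar, ac = axes_frac[0] * h, axes_frac[1] * w
    if ar < 1 or ac < 1:
        return np.zeros(shape, dtype=bool)
    return ((rr - cr) / ar) ** 2 + ((cc - ccen) / ac) ** 2 <= 1.0


def make_phantom(config: Optional[GeometryConfig] = None, seed: int = 0) -> LabeledPhantom:
    """Build one labeled abdominal phantom; deterministic for a fixed seed.

    Organs are smooth ellipses on a soft-tissue background inside a fat-rimmed
    body oval; everything outside the body is air.  Per-phantom randomness
    (organ jitter) is controlled by ``seed``.
    """
    cfg = config or GeometryConfig()
    rng = np.random.default_rng(seed)
    shape = tuple(cfg.shape)
    if min(shape) < 64:
        raise PhantomSizingError("image smaller than 64 px cannot place organ 'liver'")

    labels = np.full(shape, AIR, dtype=np.int16)
    body = _ellipse_mask(shape, (0.5, 0.5), _BODY_AXES)
    inner = _ellipse_mask(shape, (0.5, 0.5), _FAT_INNER_AXES)
    labels[body] = FAT
    labels[inner] = BACKGROUND

    geometry: Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]] = {}
    for name, lab, center, axes in _ORGANS:
        dc = rng.uniform(-cfg.jitter_shift, cfg.jitter_shift, size=2)
        ds = rng.uniform(1 - cfg.jitter_scale, 1 + cfg.jitter_scale)
        c = (center[0] + dc[0], center[1] + dc[1])
        a = (axes[0] * ds, axes[1] * ds)
        m = _ellipse_mask(shape, c, a)
        if not m.any():
            raise PhantomSizingError(f"image too small to place organ {name!r}")
        if not inner[m].all() and lab != AIR:
            # organs must stay inside the soft-tissue cavity
            raise PhantomSizingError(f"organ {name!r} does not fit inside the body")
        labels[m] = lab
        geometry[name] = (c, a)

    # inter-subject variability: each soft-tissue compartment's attenuation
    # and the subject's global iodine level differ across people
    enh_factor = float(np.clip(rng.normal(1.0, cfg.enhancement_jitter_sd), 0.5, 1.5))
    base = np.empty(shape, dtype=np.float64)
    enh = np.empty(shape, dtype=np.float64)
    for lab, hu in cfg.base_hu.items():
        offset = 0.0 if lab == AIR else float(rng.normal(0.0, cfg.hu_jitter_sd))
        base[labels == lab] = hu + offset
    for lab, hu in cfg.enhancement_hu.items():
        enh[labels == lab] = hu * enh_factor

    # gentle deterministic large-scale texture so tissue is not flat
    texture = gaussian_filter(rng.standard_normal(shape), 6.0)
    texture /= max(texture.std(), 1e-12)
    soft = (labels != AIR)
    base = base + 3.0 * texture * soft

    return LabeledPhantom(
        base_hu=base,
        organ_labels=labels,
        enhancement_hu=enh,
        pixel_spacing_mm=cfg.pixel_spacing_mm,
        organ_geometry=geometry,
    )


def make_noise_field(shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-variance white field shared by a subject's protocols.

    Stands in for the common raw-data noise realisation; each protocol
    re-filters it with its own correlation length (kernel-dependent noise
    texture) before scaling.
    """
    f = rng.standard_normal(shape)
    return (f - f.mean()) / f.std()


def render_protocol(
    phantom: LabeledPhantom,
    params: ProtocolParams,
    noise_field: np.ndarray,
) -> np.ndarray:
    """Render one protocol image from a phantom and a shared noise field.

    ``image = blur(base + gain * enhancement, psf) + sd * filter(noise)``.
    With ``noise_sd_hu=0, psf_sigma_mm=0, contrast_gain=1`` this is exactly
    ``base + enhancement`` (identity protocol).
    """
    if noise_field.shape != phantom.base_hu.shape:
        raise ValueError(
            f"noise_field shape {noise_field.shape} != phantom shape {phantom.base_hu.shape}"
        )
    clean = phantom.base_hu + params.contrast_gain * phantom.enhancement_hu
    sigma_px = params.psf_sigma_mm / phantom.pixel_spacing_mm
    if sigma_px > 0:
        clean = gaussian_filter(clean, sigma_px)
    if params.noise_sd_hu == 0:
        return clean
    corr_px = params.noise_corr_sigma_mm / phantom.pixel_spacing_mm
    noise = noise_field
    if corr_px > 0:
        noise = gaussian_filter(noise_field, corr_px)
        noise = noise / max(noise.std(), 1e-12)
    return clean + params.noise_sd_hu * noise


def default_roi_set(
    phantom: LabeledPhantom, config: Optional[GeometryConfig] = None
) -> ROISet:
    """The 10-ROI roster: 2 liver, 2 spleen, 2 kidney, 2 muscle, 1 vessel, 1 air.

    Vessel ROIs use the small area convention, all others the larger one.
    Every ROI is checked to lie fully inside its organ's label region.
    """
    cfg = config or GeometryConfig()
    h, w = phantom.base_hu.shape
    sp = phantom.pixel_spacing_mm
    r_small = float(np.sqrt(cfg.vessel_roi_area_mm2 / np.pi))
    r_big = float(np.sqrt(cfg.other_roi_area_mm2 / np.pi))
    geo = phantom.organ_geometry

    def at(organ: str, frac_offset=(0.0, 0.0)) -> Tuple[float, float]:
        c, a = geo[organ]
        return (c[0] * h + frac_offset[0] * a[0] * h, c[1] * w + frac_offset[1] * a[1] * w)

    spec = [
        ("liver_1", "liver", LIVER, at("liver", (0.0, -0.40)), r_big),
        ("liver_2", "liver", LIVER, at("liver", (0.0, 0.40)), r_big),
        ("spleen_1", "spleen", SPLEEN, at("spleen", (-0.35, 0.0)), r_big),
        ("spleen_2", "spleen", SPLEEN, at("spleen", (0.35, 0.0)), r_big),
        ("kidney_1", "kidney", KIDNEY, at("kidney_left"), r_big),
        ("kidney_2", "kidney", KIDNEY, at("kidney_right"), r_big),
        ("muscle_1", "muscle", MUSCLE, at("muscle_left"), r_big),
        ("muscle_2", "muscle", MUSCLE, at("muscle_right"), r_big),
        ("vessel_1", "vessel", VESSEL, at("vessel"), r_small),
        ("air_1", "air", AIR, at("air_pocket"), r_big),
    ]
    rois = []
    for roi_id, role, lab, center, radius in spec:
        roi = ROI(roi_id, role, center, radius)
        m = roi.mask((h, w), sp)
        if not m.any() or not np.all(phantom.organ_labels[m] == lab):
            raise PhantomSizingError(
                f"ROI {roi_id!r} does not fit inside organ {role!r}"
            )
        rois.append(roi)
    return ROISet(rois, pixel_spacing_mm=sp)


def make_cohort(
    n_subjects: int,
    protocol_set: Optional[Dict[str, ProtocolParams]] = None,
    config: Optional[GeometryConfig] = None,
    seed: int = 0,
) -> List[Tuple[ProtocolStack, ROISet]]:
    """Generate ``n_subjects`` aligned protocol stacks with a fixed ROI roster.

    Geometry is jittered across subjects but fixed within a subject; each
    stack's protocols are rendered from one phantom and one shared noise
    field, so pixel-wise correspondence holds per subject.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    protocols = DEFAULT_PROTOCOLS if protocol_set is None else protocol_set
    if not protocols:
        raise ValueError("protocol_set must not be empty")
    cfg = config or GeometryConfig()

    ss = np.random.SeedSequence(seed)
    cohort = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        sub_rng = np.random.default_rng(child)
        phantom = make_phantom(cfg, seed=int(sub_rng.integers(0, 2**31 - 1)))
        field = make_noise_field(tuple(cfg.shape), sub_rng)
        images = {
            label: render_protocol(phantom, params, field)
            for label, params in protocols.items()
        }
        stack = ProtocolStack(
            subject_id=f"subject_{i:03d}",
            images=images,
            target_label=DEFAULT_TARGET if DEFAULT_TARGET in images else next(iter(images)),
            pixel_spacing_mm=cfg.pixel_spacing_mm,
        )
        cohort.append((stack, default_roi_set(phantom, cfg)))
    return cohort
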