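"""Synthetic breast-ultrasound phantoms and NAC time-series cohorts.

Real B-mode images of breast carcinoma show multiplicative speckle, a
hypoechoic (darker-than-background) lesion with a blurred, irregular
boundary, occasional posterior acoustic shadowing, and tumor-resembling
distractor tissue.  During neoadjuvant chemotherapy (NAC) the lesion shrinks
cycle by cycle, faster in patients who go on to achieve pathological
complete response (pCR).  The generators here emulate exactly those
statistical features — enough to exercise segmentation, geometry and
response analysis end to end — without claiming physical wave-propagation
realism.

All randomness flows from explicit integer seeds; per-patient and per-image
child generators are derived deterministically by counter, so identical
specs reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

DEFAULT_PX_PER_CM = 15.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSpec:
    """Geometry and appearance of one synthetic lesion.

    ``boundary_irregularity`` is the amplitude of a low-order radial Fourier
    perturbation of the ellipse outline (0 = exact ellipse); ``contrast`` is
    the fractional intensity drop of the lesion relative to background.
    """

    center: tuple[float, float]           # (row, col) px
    semi_axes: tuple[float, float]        # (a, b) px
    orientation: float = 0.0              # radians
    boundary_irregularity: float = 0.0
    contrast: float = 0.5
    blur_sigma: float = 1.0               # px
    shadow: bool = False

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError("semi_axes must be positive")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must be in (0,1]")
        if self.boundary_irregularity < 0 or self.blur_sigma < 0:
            raise ValueError("irregularity and blur_sigma must be >= 0")


@dataclass(frozen=True)
class UltrasoundImage:
    """Grayscale intensity grid in [0,1] with scale-bar calibration."""

    pixels: np.ndarray
    px_per_cm: float

    def __post_init__(self):
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        p = self.pixels
        if p.ndim != 2 or not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
            raise ValueError("pixels must be a finite 2-D grid in [0,1]")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated NAC cohort.

    Defaults mirror the prospective study setting this toolkit targets:
    57 patients, 29 of whom achieve pCR, baseline lesion areas of a few cm^2
    (log-normal), and a multiplicative per-cycle area retention that is
    smaller (faster shrinkage) in the pCR group.

    Retention is modelled as a persistent patient-level chemosensitivity
    trait (drawn once per patient with the group's mean and sd) plus small
    independent per-cycle jitter (``retention_within_sd``).  The persistent
    trait is what keeps the pCR-discrimination AUC roughly stable across
    cycles, as observed clinically; purely independent per-cycle draws would
    instead drive the AUC toward 1 as cycles accumulate.
    ``early_retention_scale`` optionally scales the trait in cycles 1-2 to
    reproduce the steeper early drop; the default keeps retention
    cycle-constant.
    """

    n_patients: int = 57
    n_cycles: int = 6
    pcr_fraction: float = 29 / 57
    baseline_area_lognorm: tuple[float, float] = (np.log(4.0), 0.5)  # cm^2
    per_cycle_shrink_pcr: tuple[float, float] = (0.60, 0.15)
    per_cycle_shrink_nonpcr: tuple[float, float] = (0.85, 0.15)
    retention_within_sd: float = 0.05
    measurement_noise_sd: float = 0.10
    measurement_floor_cm: float = 0.10
    measurement_floor_cm2: float = 0.15
    early_retention_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pcr_fraction <= 1.0:
            raise ValueError("pcr_fraction must be in [0,1]")
        for mean, _sd in (self.per_cycle_shrink_pcr, self.per_cycle_shrink_nonpcr):
            if not 0.0 < mean < 1.0:
                raise ValueError("retention means must be in (0,1)")
        if self.per_cycle_shrink_pcr[0] >= self.per_cycle_shrink_nonpcr[0]:
            raise ValueError("pCR mean retention must be below non-pCR mean")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")


MEASUREMENT_MODELS = ("LAM", "DAM", "MSM", "DLM")


@dataclass
class CohortRecord:
    """One patient's per-cycle ground truth and measured tumor sizes.

    ``true_areas`` and each ``measurements`` vector run over cycles
    0..n_cycles, cycle 0 being the pre-NAC baseline.  Units: LAM cm, the
    others cm^2.
    """

    patient_id: str
    pcr_label: bool
    true_areas: np.ndarray
    semi_axes_cm: np.ndarray              # (n_cycles+1, 2)
    orientation: float
    measurements: dict[str, np.ndarray]
    images: list[UltrasoundImage] | None = None
    masks: list[np.ndarray] | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.true_areas) - 1


# ---------------------------------------------------------------------------
# lesion mask + rendering
# ---------------------------------------------------------------------------

def generate_lesion_mask(spec: LesionSpec, dims: tuple[int, int],
                         seed: int = 0) -> np.ndarray:
    """Rasterize a radially perturbed ellipse as a binary uint8 mask.

    The boundary is r(phi) = 1 + sum_k c_k cos(k*phi + psi_k) in normalized
    elliptical radius, with harmonics k=2..5 and total amplitude set by
    ``spec.boundary_irregularity``.  Raises if the footprint would leave the
    image bounds.
    """
    h, w = dims
    if h <= 0 or w <= 0:
        raise ValueError("dims must be positive")
    a, b = spec.semi_axes
    rng = np.random.default_rng([int(seed), 2**20])
    amps = np.zeros(6)
    if spec.boundary_irregularity > 0:
        raw = rng.uniform(0.3, 1.0, size=4)
        amps[2:] = spec.boundary_irregularity * raw / raw.sum()
    phases = rng.uniform(0, 2 * np.pi, size=6)

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    dr, dc = rows - spec.center[0], cols - spec.center[1]
    co, si = np.cos(spec.orientation), np.sin(spec.orientation)
    u = (co * dc + si * dr) / a
    v = (-si * dc + co * dr) / b
    rho = np.hypot(u, v)
    phi = np.arctan2(v, u)
    bound = np.ones_like(rho)
    for k in range(2, 6):
        bound += amps[k] * np.cos(k * phi + phases[k])
    bound = np.maximum(bound, 0.2)  # keep the outline star-shaped
    mask = (rho <= bound).astype(np.uint8)

    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("lesion footprint exceeds image bounds")
    max_extent = max(a, b) * (1.0 + spec.boundary_irregularity)
    r0, c0 = spec.center
    if (r0 - max_extent < -0.5 or r0 + max_extent > h - 0.5
            or c0 - max_extent < -0.5 or c0 + max_extent > w - 0.5):
        if not mask.any():
            raise ValueError("lesion footprint exceeds image bounds")
    return mask


def render_ultrasound(mask: np.ndarray, spec: LesionSpec,
                      background_distractors: int = 0, seed: int = 0,
                      px_per_cm: float = DEFAULT_PX_PER_CM,
                      speckle_looks: float | None = 16.0,
                      base_intensity: float = 0.6) -> UltrasoundImage:
    """Render a mask into a speckled B-mode-like image.

    The lesion attenuates the background by ``spec.contrast`` (hypoechoic),
    its edge softened by a Gaussian of ``spec.blur_sigma``; optional
    posterior shadowing darkens a band below the lesion; distractor blobs of
    weaker contrast are placed outside the lesion; finally unit-mean
    gamma-distributed multiplicative speckle is applied
    (``speckle_looks=None`` disables noise).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    h, w = mask.shape
    rng = np.random.default_rng([int(seed), 2**21])

    # smooth large-scale background brightness variation (uneven gain)
    field = rng.standard_normal((h, w))
    field = ndimage.gaussian_filter(field, sigma=max(h, w) / 8.0, mode="reflect")
    sd = field.std()
    background = base_intensity * (1.0 + 0.06 * field / sd if sd > 0 else 1.0)

    soft = mask.astype(np.float64)
    if spec.blur_sigma > 0:
        soft = ndimage.gaussian_filter(soft, sigma=spec.blur_sigma, mode="constant")
    attenuation = 1.0 - spec.contrast * soft

    for _ in range(background_distractors):
        for _attempt in range(50):
            cr = rng.uniform(0.1 * h, 0.9 * h)
            cc = rng.uniform(0.1 * w, 0.9 * w)
            if not mask[int(cr), int(cc)]:
                break
        ra = rng.uniform(0.03, 0.08) * min(h, w)
        rb = ra * rng.uniform(0.5, 1.0)
        rows, cols = np.mgrid[0:h, 0:w]
        blob = np.exp(-0.5 * (((rows - cr) / ra) ** 2 + ((cols - cc) / rb) ** 2))
        blob = blob * (1 - soft)  # never inside the lesion
        attenuation *= 1.0 - rng.uniform(0.1, 0.25) * blob

    if spec.shadow and mask.any():
        lesion_cols = mask.any(axis=0)
        bottom = np.where(mask.any(axis=1))[0].max()
        shadow = np.zeros((h, w))
        depth = np.clip((np.arange(h) - bottom) / max(h - bottom, 1), 0, 1)
        shadow[:, lesion_cols] = depth[:, None] * 0.35
        shadow = ndimage.gaussian_filter(shadow, sigma=2.0)
        attenuation *= 1.0 - shadow

    pixels = background * attenuation
    if speckle_looks is not None and np.isfinite(speckle_looks):
        looks = float(speckle_looks)
        if looks <= 0:
            raise ValueError("speckle_looks must be positive")
        pixels = pixels * rng.gamma(looks, 1.0 / looks, size=(h, w))
    return UltrasoundImage(np.clip(pixels, 0.0, 1.0), px_per_cm)


# ---------------------------------------------------------------------------
# NAC cohort simulation
# ---------------------------------------------------------------------------

def _retention(rng, mean_sd: tuple[float, float], n: int,
               early_scale: float, within_sd: float) -> np.ndarray:
    mean, sd = mean_sd
    trait = mean if sd == 0 else float(np.clip(rng.normal(mean, sd), 0.05, 0.98))
    means = np.full(n, trait)
    means[: min(2, n)] *= early_scale
    if within_sd == 0:
        return means
    return np.clip(rng.normal(means, within_sd), 0.02, 0.999)


def simulate_nac_cohort(spec: CohortSpec, image_dims: tuple[int, int] | None = None,
                        px_per_cm: float = DEFAULT_PX_PER_CM) -> list[CohortRecord]:
    """Simulate per-patient NAC size trajectories (optionally with images).

    Each patient carries a baseline elliptical lesion (log-normal area,
    random aspect ratio and orientation).  Cycle-``c`` true area is the
    baseline times the product of per-cycle retention factors, drawn with a
    smaller mean for pCR patients.  The four measurement models read off the
    ellipse geometry — LAM the longest diameter (cm), DAM the product of the
    two perpendicular diameters (cm^2), MSM and DLM the area (cm^2) — each
    corrupted by independent fractional Gaussian noise.  pCR labels are
    assigned deterministically by count and shuffled by seed.

    With ``image_dims`` set, per-cycle phantom images and masks are rendered
    (a lesion whose axes fall below one pixel is rendered as an empty mask,
    i.e. sonographically resolved).
    """
    master = np.random.default_rng([int(spec.seed), 1])
    n_pcr = int(round(spec.pcr_fraction * spec.n_patients))
    labels = np.zeros(spec.n_patients, dtype=bool)
    labels[:n_pcr] = True
    master.shuffle(labels)

    records = []
    for i in range(spec.n_patients):
        rng = np.random.default_rng([int(spec.seed), 2, i])
        pcr = bool(labels[i])
        mu, sigma = spec.baseline_area_lognorm
        baseline_area = float(np.exp(rng.normal(mu, sigma)))
        aspect = rng.uniform(1.3, 2.5)
        orientation = rng.uniform(0, np.pi)
        shrink = spec.per_cycle_shrink_pcr if pcr else spec.per_cycle_shrink_nonpcr
        retention = _retention(rng, shrink, spec.n_cycles,
                               spec.early_retention_scale, spec.retention_within_sd)
        true_areas = baseline_area * np.concatenate([[1.0], np.cumprod(retention)])

        a_cm = np.sqrt(true_areas * aspect / np.pi)
        b_cm = np.sqrt(true_areas / (np.pi * aspect))
        semi_axes_cm = np.stack([a_cm, b_cm], axis=1)

        meas = {}
        for model in MEASUREMENT_MODELS:
            if model == "LAM":
                base = 2.0 * a_cm
            elif model == "DAM":
                base = 4.0 * a_cm * b_cm
            else:
                base = true_areas.copy()
            if spec.measurement_noise_sd > 0:
                # fractional error plus an absolute precision floor (caliper /
                # tracing precision), which dominates once residuals are small
                floor = (spec.measurement_floor_cm if model == "LAM"
                         else spec.measurement_floor_cm2)
                noise = rng.normal(1.0, spec.measurement_noise_sd, size=base.shape)
                offset = rng.normal(0.0, floor, size=base.shape)
                meas[model] = np.maximum(base * noise + offset, 1e-6)
            else:
                meas[model] = base
        record = CohortRecord(
            patient_id=f"P{i:03d}", pcr_label=pcr, true_areas=true_areas,
            semi_axes_cm=semi_axes_cm, orientation=orientation, measurements=meas,
        )
        if image_dims is not None:
            record.images, record.masks = [], []
            for c in range(spec.n_cycles + 1):
                img, msk = _render_cycle(record, c, image_dims, px_per_cm,
                                         seed_parts=(spec.seed, 3, i, c))
                record.images.append(img)
                record.masks.append(msk)
        records.append(record)
    return records


def _render_cycle(record: CohortRecord, cycle: int, dims: tuple[int, int],
                  px_per_cm: float, seed_parts) -> tuple[UltrasoundImage, np.ndarray]:
    h, w = dims
    a_px = record.semi_axes_cm[cycle, 0] * px_per_cm
    b_px = record.semi_axes_cm[cycle, 1] * px_per_cm
    rng = np.random.default_rng([int(p) for p in seed_parts])
    seed = int(rng.integers(2**31))
    if a_px < 1.0 or b_px < 1.0 or 2 * a_px > 0.8 * min(h, w):
        # resolved below pixel scale (or too large to frame): empty-lesion image
        spec = LesionSpec(center=(h / 2, w / 2), semi_axes=(1.0, 1.0),
                          contrast=0.45, blur_sigma=1.0)
        mask = np.zeros(dims, dtype=np.uint8)
        img = render_ultrasound(mask, spec, background_distractors=2,
                                seed=seed, px_per_cm=px_per_cm)
        return img, mask
    jitter = 0.1 * min(h, w)
    center = (h / 2 + rng.uniform(-jitter, jitter), w / 2 + rng.uniform(-jitter, jitter))
    spec = LesionSpec(center=center, semi_axes=(a_px, b_px),
                      orientation=record.orientation, boundary_irregularity=0.15,
                      contrast=0.45, blur_sigma=1.0)
    mask = generate_lesion_mask(spec, dims, seed=seed)
    img = render_ultrasound(mask, spec, background_distractors=2,
                            seed=seed, px_per_cm=px_per_cm)
    return img, mask


def phantom_training_set(n_images: int, dims: tuple[int, int] = (128, 96),
                         seed: int = 0, px_per_cm: float = DEFAULT_PX_PER_CM,
                         lesion_fraction: float = 0.9):
    """A seeded set of (image, mask) pairs with varied lesion geometry.

    Used for smoke-scale training runs; roughly ``1 - lesion_fraction`` of
    the images contain no lesion (as after complete response).
    """
    h, w = dims
    pairs = []
    for i in range(n_images):
        rng = np.random.default_rng([int(seed), 5, i])
        img_seed = int(rng.integers(2**31))
        if rng.random() > lesion_fraction:
            spec = LesionSpec(center=(h / 2, w / 2), semi_axes=(1.0, 1.0),
                              contrast=0.45, blur_sigma=1.0)
            mask = np.zeros(dims, dtype=np.uint8)
        else:
            a = rng.uniform(0.08, 0.22) * min(h, w)
            b = a / rng.uniform(1.2, 2.5)
            margin = 1.3 * a + 2
            center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            spec = LesionSpec(center=center, semi_axes=(a, b),
                              orientation=rng.uniform(0, np.pi),
                              boundary_irregularity=rng.uniform(0.0, 0.2),
                              contrast=rng.uniform(0.35, 0.55),
                              blur_sigma=rng.uniform(0.5, 1.5),
                              shadow=bool(rng.random() < 0.3))
            mask = generate_lesion_mask(spec, dims, seed=img_seed)
        img = render_ultrasound(mask, spec, background_distractors=int(rng.integers(0, 4)),
                                seed=img_seed, px_per_cm=px_per_cm)
        pairs.append((img, mask))
    return pairs
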