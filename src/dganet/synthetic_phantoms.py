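"""Synthetic abdominal CT phantoms with liver/tumor labels.

Each case is a short stack of identical-geometry slices holding a smoothly
deformed elliptical "liver" region containing a configurable number of
lower-intensity "tumor" blobs whose maximum Feret diameters are drawn from
one of three clinical size strata (<2 cm, 2-5 cm, >5 cm).  HU values are
sampled per region from normal distributions and softened with a 1-pixel
Gaussian blur of the intensity (labels stay crisp).  Generation is fully
deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "PhantomSpec",
    "TumorRecord",
    "PhantomCase",
    "generate_case",
    "add_gaussian_noise",
    "stratify_cases",
    "save_case",
    "load_case",
    "STRATUM_BOUNDS_MM",
]

# [lo, hi) diameter bounds in mm; 20 mm belongs to "medium" (2-5 cm inclusive)
STRATUM_BOUNDS_MM = {
    "small": (6.0, 20.0),
    "medium": (20.0, 50.0 + 1e-9),
    "large": (50.0 + 1e-9, 90.0),
}


def classify_diameter(diameter_mm: float) -> str:
    if diameter_mm < 20.0:
        return "small"
    if diameter_mm <= 50.0:
        return "medium"
    return "large"


@dataclass
class PhantomSpec:
    image_size: int = 96
    spacing_mm: float = 0.7676
    slices: int = 4
    liver_radius_frac: tuple[float, float] = (0.30, 0.40)
    tumor_count_range: tuple[int, int] = (1, 3)
    stratum: str | None = None           # None: any diameter that fits
    background_hu: tuple[float, float] = (-50.0, 20.0)
    liver_hu: tuple[float, float] = (100.0, 15.0)
    tumor_hu: tuple[float, float] = (60.0, 12.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.stratum is not None and self.stratum not in STRATUM_BOUNDS_MM:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.liver_hu[0] == self.tumor_hu[0]:
            raise ValueError("tumor mean HU must differ from liver mean HU")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class TumorRecord:
    center: tuple[float, float]
    diameter_mm: float
    stratum: str


@dataclass
class PhantomCase:
    hu_volume: np.ndarray       # (slices, H, W) float HU
    label_volume: np.ndarray    # (slices, H, W) int {0,1,2}
    spacing: tuple[float, float, float]
    spec: PhantomSpec
    tumors: list[TumorRecord] = field(default_factory=list)

    @property
    def max_tumor_diameter_mm(self) -> float | None:
        if not self.tumors:
            return None
        return max(t.diameter_mm for t in self.tumors)


def _blob_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float,
               wobble: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Rasterize a radially perturbed disk: r(theta) = r0 (1 + sum a_k cos(k theta + phi))."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    theta = np.arctan2(dy, dx)
    limit = np.ones_like(theta) * radius_px
    for k, (a, phi) in enumerate(zip(wobble, phases), start=2):
        limit = limit + radius_px * a * np.cos(k * theta + phi)
    return dy**2 + dx**2 <= limit**2


def _feret_px(mask: np.ndarray) -> float:
    props = measure.regionprops(mask.astype(np.uint8))
    if not props:
        return 0.0
    return float(props[0].feret_diameter_max)


def _make_tumor(rng: np.random.Generator, liver: np.ndarray, diameter_mm: float,
                spacing: float) -> tuple[np.ndarray, TumorRecord] | None:
    """Place one deformed disk of the requested Feret diameter inside the liver."""
    target_px = diameter_mm / spacing
    margin = 2.0
    dist = ndimage.distance_transform_edt(liver)
    r0 = target_px / 2.0
    wobble = phases = center = None
    for _ in range(6):  # resample the deformation until the blob fits somewhere
        wobble = rng.normal(0.0, 0.04, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        need = r0 * (1 + np.abs(wobble).sum()) + margin
        candidates = np.argwhere(dist >= need)
        if len(candidates):
            center = tuple(candidates[rng.integers(len(candidates))].astype(float))
            break
    if center is None:
        return None
    mask = _blob_mask(liver.shape, center, r0, wobble, phases)
    for _ in range(4):  # rescale until the measured caliper diameter matches
        feret = _feret_px(mask)
        if feret == 0.0:
            return None
        if abs(feret - target_px) <= 1.0:
            break
        r0 *= target_px / feret
        mask = _blob_mask(liver.shape, center, r0, wobble, phases)
    if not mask[liver].sum() == mask.sum():  # clipped by liver boundary
        mask &= liver
    if mask.sum() == 0:
        return None
    record = TumorRecord(center=center, diameter_mm=_feret_px(mask) * spacing,
                         stratum=classify_diameter(_feret_px(mask) * spacing))
    return mask, record


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Generate one deterministic phantom case from its spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    shape = (n, n)
    center = (n / 2 + rng.uniform(-n * 0.04, n * 0.04),
              n / 2 + rng.uniform(-n * 0.04, n * 0.04))
    radius = n * rng.uniform(*spec.liver_radius_frac)
    liver = _blob_mask(shape, center, radius, rng.normal(0, 0.05, 3),
                       rng.uniform(0, 2 * np.pi, 3))

    labels = np.zeros(shape, dtype=np.int16)
    labels[liver] = 1
    tumors: list[TumorRecord] = []
    n_tumors = int(rng.integers(spec.tumor_count_range[0], spec.tumor_count_range[1] + 1))
    # conservative bound: leave room for the radial wobble and a 2-px margin
    max_fit_mm = 1.6 * (ndimage.distance_transform_edt(liver).max() - 3.0) * spec.spacing_mm
    for _ in range(n_tumors):
        if spec.stratum is not None:
            lo, hi = STRATUM_BOUNDS_MM[spec.stratum]
            if lo >= max_fit_mm:
                raise ValueError(
                    f"stratum {spec.stratum!r} needs >= {lo:.0f} mm tumors but the liver "
                    f"only fits {max_fit_mm:.0f} mm; enlarge the liver or image, or pick "
                    "a smaller stratum")
            hi = min(hi, max_fit_mm)
        else:
            lo, hi = 6.0, min(40.0, max_fit_mm)
        diameter = float(rng.uniform(lo, hi))
        placed = _make_tumor(rng, liver, diameter, spec.spacing_mm)
        if placed is None:
            raise ValueError(
                f"could not place a {diameter:.1f} mm tumor; enlarge the liver or "
                "pick a smaller stratum")
        mask, record = placed
        labels[mask] = 2
        tumors.append(record)

    hu_slices = []
    for _ in range(spec.slices):
        hu = rng.normal(*spec.background_hu, size=shape)
        hu[labels == 1] = rng.normal(*spec.liver_hu, size=int((labels == 1).sum()))
        hu[labels == 2] = rng.normal(*spec.tumor_hu, size=int((labels == 2).sum()))
        hu_slices.append(ndimage.gaussian_filter(hu, sigma=1.0))
    hu_volume = np.stack(hu_slices)
    label_volume = np.repeat(labels[None], spec.slices, axis=0)

    case = PhantomCase(
        hu_volume=hu_volume,
        label_volume=label_volume,
        spacing=(1.0, spec.spacing_mm, spec.spacing_mm),
        spec=spec,
        tumors=tumors,
    )
    if spec.noise_sd > 0:
        case = add_gaussian_noise(case, spec.noise_sd, seed=spec.seed + 1_000_003)
    assert set(np.unique(case.label_volume)) <= {0, 1, 2}
    assert not ((labels == 2) & ~liver).any(), "tumor escaped the liver support"
    return case


def add_gaussian_noise(case: PhantomCase, sd: float, seed: int = 0) -> PhantomCase:
    """Additive i.i.d. N(0, sd^2) HU noise; labels are untouched."""
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return PhantomCase(case.hu_volume.copy(), case.label_volume.copy(),
                           case.spacing, case.spec, list(case.tumors))
    rng = np.random.default_rng(seed)
    noisy = case.hu_volume + rng.normal(0.0, sd, size=case.hu_volume.shape)
    return PhantomCase(noisy, case.label_volume.copy(), case.spacing,
                       replace(case.spec, noise_sd=sd), list(case.tumors))


def stratify_cases(cases, strata=("small", "medium", "large")) -> dict[str, list]:
    """Group cases by the stratum of their maximum tumor diameter."""
    out: dict[str, list] = {s: [] for s in strata}
    for case in cases:
        d = case.max_tumor_diameter_mm
        if d is None:
            continue
        s = classify_diameter(d)
        if s in out:
            out[s].append(case)
    return out


def save_case(case: PhantomCase, image_path, label_path=None) -> None:
    """Write a case as a NIfTI pair (nibabel) or a single NPZ archive."""
    image_path = str(image_path)
    if image_path.endswith(".npz"):
        np.savez(image_path, hu=case.hu_volume, labels=case.label_volume,
                 spacing=np.asarray(case.spacing))
        return
    import nibabel as nib
    affine = np.diag(list(case.spacing[::-1]) + [1.0])
    nib.save(nib.Nifti1Image(case.hu_volume.astype(np.float32), affine), image_path)
    if label_path is not None:
        nib.save(nib.Nifti1Image(case.label_volume.astype(np.int16), affine),
                 str(label_path))


def load_case(image_path, label_path=None):
    """Load (hu_volume, label_volume, spacing) written by :func:`save_case`."""
    image_path = str(image_path)
    if image_path.endswith(".npz"):
        with np.load(image_path) as z:
            return z["hu"], z["labels"], tuple(z["spacing"])
    import nibabel as nib
    img = nib.load(image_path)
    hu = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(s) for s in img.header.get_zooms()[::-1])
    labels = None
    if label_path is not None:
        labels = np.asarray(nib.load(str(label_path)).dataobj).astype(np.int16)
    return hu, labels, spacing
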