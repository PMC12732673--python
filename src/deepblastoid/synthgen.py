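"""Seeded simulator of brightfield microwell images.

Real blastoid experiments image AggreWell plates in which every microwell
holds at most one stem-cell aggregate; a trained eye sorts the resulting
tiles into the five morphology classes of :mod:`deepblastoid.labels`. This
module draws those morphologies as antialiased intensity primitives — a
bright trophectoderm (TE) ring, a fluid-filled cavity, an inner-cell-mass
(ICM) blob, debris speckle — on a darker well background, and emits a
pixel-level truth mask alongside every image. The mask, not photorealism,
is the ground truth: a small rule-based oracle (:func:`label_from_mask`)
recovers the generating class from the mask alone.

Three interference modes that confound classical image analysis of such
plates are simulated on top: overlapping out-of-plane bodies (the 2-D
projection of a 3-D structure), focal-plane variation (defocus blur), and
uneven illumination (a multiplicative plane ramp).

Every operation is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .labels import ClassLabel, CLASS_NAMES, N_CLASSES

__all__ = [
    "MorphologySpec",
    "InterferenceSpec",
    "SyntheticDatasetSpec",
    "MorphologyError",
    "MASK_BACKGROUND",
    "MASK_RING",
    "MASK_CAVITY",
    "MASK_ICM",
    "MASK_DEBRIS",
    "default_morphology",
    "render_microwell",
    "apply_interference",
    "render_plate",
    "make_dataset",
    "label_from_mask",
    "ring_completeness_from_mask",
    "mask_to_rle",
    "rle_to_mask",
]

# truth-mask codes
MASK_BACKGROUND = 0
MASK_RING = 1
MASK_CAVITY = 2
MASK_ICM = 3
MASK_DEBRIS = 4

# nominal intensities (fraction of full scale) of the rendered primitives
_BG_LEVEL = 0.32
_RING_LEVEL = 0.78
_CAVITY_LEVEL = 0.52
_ICM_LEVEL = 0.88
_DEBRIS_LEVEL = 0.70


class MorphologyError(ValueError):
    """A morphology spec violates the invariants of its class label."""


@dataclasses.dataclass(frozen=True)
class MorphologySpec:
    """Geometric description of one microwell's content, in pixels.

    Parameters
    ----------
    well_diameter_px:
        Diameter of the visible microwell footprint.
    te_ring_radius_px:
        Mean radius of the TE ring.
    te_ring_completeness:
        Fraction of the ring circumference actually present, in [0, 1].
        Complete rings (classes A/B) have >= 0.95; the broken rings of
        class C have < 0.8.
    icm_present, icm_radius_px:
        Whether an ICM blob is drawn and its radius.
    cavity_present:
        Whether the ring encloses a fluid-filled cavity.
    debris_density:
        Number of debris speckles per tile (class D).
    texture_noise_sd:
        Standard deviation of the additive background texture, as a
        fraction of full scale.
    """

    well_diameter_px: float
    te_ring_radius_px: float
    te_ring_completeness: float
    icm_present: bool
    icm_radius_px: float
    cavity_present: bool
    debris_density: int
    texture_noise_sd: float = 0.012
    ring_thickness_px: float = 0.0  # 0 -> 18% of ring radius

    def __post_init__(self) -> None:
        if not 0.0 <= self.te_ring_completeness <= 1.0:
            raise MorphologyError("te_ring_completeness must lie in [0, 1]")
        if self.debris_density < 0:
            raise MorphologyError("debris_density must be >= 0")
        if self.texture_noise_sd < 0:
            raise MorphologyError("texture_noise_sd must be >= 0")


def validate_morphology(label: ClassLabel | str | int, morph: MorphologySpec) -> None:
    """Check a morphology spec against the invariants of its class.

    Raises
    ------
    MorphologyError
        Naming the violated constraint.
    """
    label = ClassLabel.from_any(label)
    if label is ClassLabel.A:
        if not morph.cavity_present:
            raise MorphologyError("class A requires cavity_present")
        if not morph.icm_present:
            raise MorphologyError("class A requires icm_present")
        if morph.te_ring_completeness < 0.95:
            raise MorphologyError("class A requires te_ring_completeness >= 0.95")
    elif label is ClassLabel.B:
        if not morph.cavity_present:
            raise MorphologyError("class B requires cavity_present")
        if morph.icm_present:
            raise MorphologyError("class B requires icm_present = False")
    elif label is ClassLabel.C:
        if not morph.icm_present:
            raise MorphologyError("class C requires icm_present")
        if morph.te_ring_completeness >= 0.8:
            raise MorphologyError("class C requires te_ring_completeness < 0.8")
    elif label is ClassLabel.D:
        if morph.cavity_present:
            raise MorphologyError("class D requires cavity_present = False")
        if morph.debris_density <= 0:
            raise MorphologyError("class D requires debris_density > 0")
    else:  # W
        if morph.cavity_present or morph.icm_present or morph.debris_density > 0:
            raise MorphologyError("class W must have no foreground structure")


def default_morphology(
    label: ClassLabel | str | int,
    image_size: int = 300,
    rng: np.random.Generator | None = None,
) -> MorphologySpec:
    """Class-consistent default morphology, with optional seeded jitter.

    Geometry scales with ``image_size`` so that 64-px desk-scale tiles and
    300-px full-size tiles look alike. Passing ``rng`` jitters radii and
    completeness within each class's allowed band, which is how datasets get
    within-class variability.
    """
    label = ClassLabel.from_any(label)
    s = float(image_size)

    def u(lo: float, hi: float) -> float:
        if rng is None:
            return 0.5 * (lo + hi)
        return float(rng.uniform(lo, hi))

    well = 0.92 * s
    ring_r = u(0.26, 0.33) * s
    icm_r = u(0.09, 0.12) * s
    # deterministic defaults use a fully closed ring; jittered datasets allow
    # near-complete rings within the class invariant
    comp = 1.0 if rng is None else u(0.97, 1.0)
    if label is ClassLabel.A:
        return MorphologySpec(well, ring_r, comp, True, icm_r, True, 0)
    if label is ClassLabel.B:
        return MorphologySpec(well, ring_r, comp, False, 0.0, True, 0)
    if label is ClassLabel.C:
        return MorphologySpec(well, ring_r, u(0.45, 0.7), True, icm_r, True, 0)
    if label is ClassLabel.D:
        return MorphologySpec(well, 0.0, 0.0, False, 0.0, False, int(round(u(5, 9))))
    return MorphologySpec(well, 0.0, 0.0, False, 0.0, False, 0)  # W


def _soft_edge(d: np.ndarray, width: float = 1.0) -> np.ndarray:
    """Antialias coverage from a signed distance (positive = inside)."""
    return np.clip(0.5 + d / width, 0.0, 1.0)


def render_microwell(
    label: ClassLabel | str | int,
    morph: MorphologySpec | None = None,
    seed: int = 0,
    image_size: int | tuple[int, int] = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one microwell tile and its truth mask.

    Parameters
    ----------
    label:
        The morphology class to draw.
    morph:
        Geometry; defaults to :func:`default_morphology` for the class.
        Inconsistent geometry raises :class:`MorphologyError`.
    seed:
        Seeds the background texture and debris placement; the same
        (label, morph, seed, size) reproduces the image bit-exactly.
    image_size:
        Tile side in pixels, or an (h, w) pair. Must be >= 64.

    Returns
    -------
    image : uint16 array (h, w)
        Brightfield-like tile spanning the 16-bit range.
    mask : uint8 array (h, w)
        Truth mask with the ``MASK_*`` codes.
    """
    label = ClassLabel.from_any(label)
    if isinstance(image_size, (int, np.integer)):
        h = w = int(image_size)
    else:
        h, w = (int(v) for v in image_size)
    if min(h, w) < 64:
        raise ValueError("image size must be >= 64 px")
    if morph is None:
        morph = default_morphology(label, min(h, w))
    validate_morphology(label, morph)

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)

    # darker well background with a faint rim at the microwell boundary
    img = np.full((h, w), _BG_LEVEL)
    rim = _soft_edge(r - morph.well_diameter_px / 2.0, 1.5)
    img += 0.05 * rim  # slightly brighter outside the well footprint
    img += rng.normal(0.0, morph.texture_noise_sd, size=(h, w))
    mask = np.zeros((h, w), dtype=np.uint8)

    ring_r = morph.te_ring_radius_px
    thick = morph.ring_thickness_px or 0.18 * ring_r

    if morph.cavity_present:
        cav_cov = _soft_edge((ring_r - thick / 2.0) - r)
        img = img * (1 - cav_cov) + _CAVITY_LEVEL * cav_cov
        mask[cav_cov > 0.5] = MASK_CAVITY

    if ring_r > 0:
        # irregular radius for broken rings; a gap arc removes the missing
        # fraction of the circumference
        wobble = 0.0
        if morph.te_ring_completeness < 0.95:
            phase = rng.uniform(0, 2 * math.pi)
            wobble = 0.10 * ring_r * np.sin(3 * theta + phase)
        ring_cov = _soft_edge(thick / 2.0 - np.abs(r - (ring_r + wobble)))
        gap = 2 * math.pi * (1.0 - morph.te_ring_completeness)
        if gap > 0:
            gap_start = rng.uniform(-math.pi, math.pi)
            ang = np.mod(theta - gap_start, 2 * math.pi)
            ring_cov = np.where(ang < gap, 0.0, ring_cov)
        img = img * (1 - ring_cov) + _RING_LEVEL * ring_cov
        mask[ring_cov > 0.5] = MASK_RING

    if morph.icm_present:
        # ICM sits against the inside of the ring
        icm_off = max(ring_r - thick / 2.0 - morph.icm_radius_px, 0.0)
        ang0 = rng.uniform(0, 2 * math.pi)
        icy = cy + icm_off * math.sin(ang0)
        icx = cx + icm_off * math.cos(ang0)
        d_icm = morph.icm_radius_px - np.hypot(yy - icy, xx - icx)
        icm_cov = _soft_edge(d_icm)
        img = img * (1 - icm_cov) + _ICM_LEVEL * icm_cov
        mask[icm_cov > 0.5] = MASK_ICM

    for _ in range(morph.debris_density):
        rad = rng.uniform(0.025, 0.055) * min(h, w)
        rho = rng.uniform(0, 0.35 * min(h, w))
        ang = rng.uniform(0, 2 * math.pi)
        dy, dx = cy + rho * math.sin(ang), cx + rho * math.cos(ang)
        cov = _soft_edge(rad - np.hypot(yy - dy, xx - dx))
        lvl = _DEBRIS_LEVEL + rng.uniform(-0.08, 0.12)
        img = img * (1 - cov) + lvl * cov
        mask[cov > 0.5] = MASK_DEBRIS

    img16 = np.clip(img, 0.0, 1.0)
    img16 = np.round(img16 * 65535.0).astype(np.uint16)
    return img16, mask


# ---------------------------------------------------------------------------
# interference


@dataclasses.dataclass(frozen=True)
class InterferenceSpec:
    """Imaging interference applied on top of a clean render.

    ``defocus_sigma_px`` blurs with a normalized Gaussian kernel (focal-plane
    variation); ``illumination_gradient`` multiplies by a plane ramp
    ``1 + a*t`` with ``t`` in [-1, 1] along the given direction (uneven
    illumination); ``clutter_count`` adds soft out-of-plane bodies (the 2-D
    projection of overlapping 3-D structure). The all-zero spec is the
    identity.
    """

    defocus_sigma_px: float = 0.0
    illumination_gradient: tuple[float, float] = (0.0, 0.0)  # (angle rad, amplitude)
    clutter_count: int = 0

    def __post_init__(self) -> None:
        if self.defocus_sigma_px < 0:
            raise ValueError("defocus_sigma_px must be >= 0")
        amp = self.illumination_gradient[1]
        if not 0.0 <= amp <= 1.0:
            raise ValueError("illumination amplitude must lie in [0, 1]")
        if self.clutter_count < 0:
            raise ValueError("clutter_count must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.defocus_sigma_px == 0
            and self.illumination_gradient[1] == 0
            and self.clutter_count == 0
        )


def apply_interference(
    image: np.ndarray, spec: InterferenceSpec, seed: int = 0
) -> np.ndarray:
    """Apply an interference spec to an image.

    Clutter is added first (it is part of the scene), then defocus, then the
    illumination ramp (a property of the optics). Integer input comes back in
    the same dtype, clipped to its range; float input stays float and is not
    clipped. The zero spec returns the input unchanged.
    """
    from scipy import ndimage

    image = np.asarray(image)
    if not np.all(np.isfinite(image.astype(np.float64))):
        raise ValueError("image must be finite-valued")
    if spec.is_identity:
        return image

    orig_dtype = image.dtype
    out = image.astype(np.float64)
    scale = 65535.0 if np.issubdtype(orig_dtype, np.integer) else 1.0
    h, w = out.shape
    rng = np.random.default_rng(seed)

    for _ in range(spec.clutter_count):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        sig = rng.uniform(0.05, 0.12) * min(h, w)
        amp = rng.uniform(-0.12, 0.18) * scale
        yy, xx = np.mgrid[0:h, 0:w]
        out = out + amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2)))

    if spec.defocus_sigma_px > 0:
        out = ndimage.gaussian_filter(out, spec.defocus_sigma_px, mode="reflect")

    angle, amp = spec.illumination_gradient
    if amp > 0:
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        proj = xx * math.cos(angle) + yy * math.sin(angle)
        lo, hi = proj.min(), proj.max()
        t = np.zeros_like(proj) if hi == lo else (proj - lo) / (hi - lo) * 2.0 - 1.0
        out = out * (1.0 + amp * t)

    if np.issubdtype(orig_dtype, np.integer):
        info = np.iinfo(orig_dtype)
        out = np.clip(np.round(out), info.min, info.max).astype(orig_dtype)
    return out


# ---------------------------------------------------------------------------
# truth-mask oracle


def ring_completeness_from_mask(mask: np.ndarray, n_bins: int = 72) -> float:
    """Fraction of angular bins around the ring centroid containing ring pixels."""
    ys, xs = np.nonzero(mask == MASK_RING)
    if ys.size == 0:
        return 0.0
    cy, cx = ys.mean(), xs.mean()
    ang = np.arctan2(ys - cy, xs - cx)
    bins = np.floor((ang + math.pi) / (2 * math.pi) * n_bins).astype(int) % n_bins
    return np.unique(bins).size / n_bins


def label_from_mask(mask: np.ndarray) -> ClassLabel:
    """Recover the generating class from a truth mask by inverting the
    class invariants: no foreground -> W; debris without cavity -> D; broken
    ring with an ICM -> C; cavity with/without ICM -> A/B."""
    has_cavity = bool(np.any(mask == MASK_CAVITY))
    has_icm = bool(np.any(mask == MASK_ICM))
    has_debris = bool(np.any(mask == MASK_DEBRIS))
    has_ring = bool(np.any(mask == MASK_RING))
    if not (has_cavity or has_icm or has_debris or has_ring):
        return ClassLabel.W
    if not has_cavity:
        return ClassLabel.D
    if has_icm and ring_completeness_from_mask(mask) < 0.8:
        return ClassLabel.C
    return ClassLabel.A if has_icm else ClassLabel.B


# ---------------------------------------------------------------------------
# plates and datasets


def draw_labels(
    n: int,
    mixture: Sequence[float],
    rng: np.random.Generator,
    exact_counts: bool = False,
) -> np.ndarray:
    """Draw n class codes from a 5-way mixture.

    Multinomial by default; ``exact_counts`` rounds n*mixture to fixed
    per-class counts (largest-remainder) and shuffles, for tests needing
    exact frequencies.
    """
    mixture = np.asarray(mixture, dtype=np.float64)
    if mixture.shape != (N_CLASSES,) or np.any(mixture < 0):
        raise ValueError("mixture must be 5 nonnegative proportions")
    if abs(mixture.sum() - 1.0) > 1e-9:
        raise ValueError("mixture must sum to 1")
    if exact_counts:
        raw = mixture * n
        counts = np.floor(raw).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
        codes = np.repeat(np.arange(N_CLASSES), counts)
        rng.shuffle(codes)
        return codes
    return rng.choice(N_CLASSES, size=n, p=mixture)


def render_plate(
    layout,
    mixture: Sequence[float],
    seed: int = 0,
    interference: InterferenceSpec | None = None,
    exact_counts: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a whole-plate mosaic of microwell tiles.

    Parameters
    ----------
    layout : plate_io.PlateLayout
        Grid geometry; tiles are placed at the layout's pixel boxes.
    mixture:
        Five class proportions summing to 1; realized labels are a seeded
        multinomial draw (or exact counts with ``exact_counts``).
    interference:
        Optional interference applied per tile. The manifest's truth label
        is assigned before interference and is never changed by it.

    Returns
    -------
    plate : uint16 array
        The mosaic.
    manifest : DataFrame
        One row per microwell: row, col, label, x0, y0, x1, y1.
    """
    rng = np.random.default_rng(seed)
    n = layout.rows * layout.cols
    codes = draw_labels(n, mixture, rng, exact_counts=exact_counts)

    th, tw = layout.tile_px[1], layout.tile_px[0]
    ph, pw = layout.plate_extent()
    plate = np.full((ph, pw), int(round(_BG_LEVEL * 65535)), dtype=np.uint16)

    seeds = rng.integers(0, 2**31 - 1, size=n)
    records = []
    for idx in range(n):
        row, col = divmod(idx, layout.cols)
        lbl = ClassLabel(int(codes[idx]))
        morph = default_morphology(lbl, min(th, tw), rng=rng)
        tile, _ = render_microwell(lbl, morph, seed=int(seeds[idx]), image_size=(th, tw))
        if interference is not None and not interference.is_identity:
            tile = apply_interference(tile, interference, seed=int(seeds[idx]))
        x0, y0, x1, y1 = layout.tile_box(row, col)
        plate[y0:y1, x0:x1] = tile
        records.append(
            {"row": row, "col": col, "label": lbl.name, "x0": x0, "y0": y0, "x1": x1, "y1": y1}
        )
    return plate, pd.DataFrame.from_records(records)


@dataclasses.dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Recipe for a labeled synthetic tile dataset.

    ``class_mixture`` gives the five class proportions (must sum to 1);
    ``n_batches`` splits images into equally sized pseudo-batches that get a
    small per-batch global illumination offset, emulating between-experiment
    intensity drift; interference ranges are sampled per image.
    """

    n_images: int
    class_mixture: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    image_size_px: int = 300
    n_batches: int = 1
    seed: int = 0
    defocus_sigma_range: tuple[float, float] = (0.0, 0.0)
    illumination_amp_range: tuple[float, float] = (0.0, 0.0)
    clutter_count_max: int = 0
    batch_offset: float = 0.04  # per-batch illumination offset, fraction of full scale
    exact_counts: bool = False

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        m = np.asarray(self.class_mixture, dtype=np.float64)
        if m.shape != (N_CLASSES,) or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("class_mixture must be 5 proportions summing to 1")


def generate_tiles(spec: SyntheticDatasetSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate a dataset in memory.

    Returns
    -------
    images : uint16 array (n, h, w)
    masks : uint8 array (n, h, w)
    labels : int64 array (n,) class codes
    manifest : DataFrame with columns label, batch, row, col
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_images
    codes = draw_labels(n, spec.class_mixture, rng, exact_counts=spec.exact_counts)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    batch_ids = np.arange(n) * spec.n_batches // n  # contiguous equal batches

    s = spec.image_size_px
    images = np.empty((n, s, s), dtype=np.uint16)
    masks = np.empty((n, s, s), dtype=np.uint8)
    lo_s, hi_s = spec.defocus_sigma_range
    lo_a, hi_a = spec.illumination_amp_range
    for i in range(n):
        lbl = ClassLabel(int(codes[i]))
        morph = default_morphology(lbl, s, rng=rng)
        img, msk = render_microwell(lbl, morph, seed=int(seeds[i]), image_size=s)
        sig = rng.uniform(lo_s, hi_s) if hi_s > 0 else 0.0
        amp = rng.uniform(lo_a, hi_a) if hi_a > 0 else 0.0
        clut = int(rng.integers(0, spec.clutter_count_max + 1)) if spec.clutter_count_max else 0
        isp = InterferenceSpec(sig, (float(rng.uniform(0, 2 * math.pi)), amp), clut)
        if not isp.is_identity:
            img = apply_interference(img, isp, seed=int(seeds[i]))
        if spec.n_batches > 1 and spec.batch_offset:
            off = (batch_ids[i] - (spec.n_batches - 1) / 2.0) * spec.batch_offset * 65535.0
            img = np.clip(img.astype(np.float64) + off, 0, 65535).astype(np.uint16)
        images[i] = img
        masks[i] = msk

    manifest = pd.DataFrame(
        {
            "label": [CLASS_NAMES[c] for c in codes],
            "batch": batch_ids,
            "row": np.zeros(n, dtype=int),
            "col": np.arange(n),
        }
    )
    return images, masks, codes.astype(np.int64), manifest


def make_dataset(spec: SyntheticDatasetSpec, out_dir: str | Path, write_masks: bool = False) -> pd.DataFrame:
    """Write a synthetic dataset to disk: 16-bit PNG tiles plus a CSV manifest
    (columns path, label, batch, row, col) and optionally RLE truth masks as
    JSON. Re-running with an identical spec reproduces identical files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, masks, codes, manifest = generate_tiles(spec)
    paths = []
    for i in range(spec.n_images):
        name = f"tile_{i:05d}_{CLASS_NAMES[codes[i]]}.png"
        iio.imwrite(out_dir / name, images[i])
        paths.append(name)
    manifest = manifest.copy()
    manifest.insert(0, "path", paths)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    if write_masks:
        payload = {p: mask_to_rle(masks[i]) for i, p in enumerate(paths)}
        (out_dir / "masks.json").write_text(json.dumps(payload))
    return manifest


def mask_to_rle(mask: np.ndarray) -> dict:
    """Run-length encode a mask (row-major runs of equal values)."""
    flat = np.asarray(mask).ravel()
    change = np.nonzero(np.diff(flat))[0] + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [flat.size])))
    return {
        "shape": list(mask.shape),
        "values": flat[starts].astype(int).tolist(),
        "lengths": lengths.astype(int).tolist(),
    }


def rle_to_mask(rle: Mapping) -> np.ndarray:
    """Invert :func:`mask_to_rle`."""
    flat = np.repeat(np.asarray(rle["values"], dtype=np.uint8), rle["lengths"])
    return flat.reshape(rle["shape"])


def manifest_checksum(manifest: pd.DataFrame) -> str:
    """Stable SHA-256 of a manifest's CSV serialization."""
    return hashlib.sha256(manifest.to_csv(index=False).encode()).hexdigest()
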