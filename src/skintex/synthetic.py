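"""Deterministic synthetic facial-skin crops with wrinkles, pores and zones.

Real facial-skin photographs used for wrinkle/pore segmentation are private
clinical data, so every stage of this package is exercised on generated
scenes that reproduce the morphology the method exploits:

* a smooth skin-like background with an optional lighting gradient,
* dark curvilinear wrinkle strokes of varying thickness restricted to the
  forehead/T-zone/eye-corner region,
* small dark round pores restricted to the central "butterfly" (nose +
  cheeks) zone,
* distractor dark texture *outside* both zones — locally indistinguishable
  from genuine features, so that only positional information can separate
  them.

Each sample carries exact fine truth masks plus deliberately over-thick
coarse annotations (a disk dilation of the fine mask), mirroring how human
annotators label wrinkles with generous thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_interp_spline
from skimage.morphology import dilation, disk, erosion

__all__ = [
    "SceneSpec",
    "ZoneLayout",
    "SyntheticSample",
    "PlacementError",
    "default_zones",
    "generate_scene",
    "make_coarse_annotation",
    "generate_dataset",
    "train_val_split",
]

#: half-maximum radius of a unit Gaussian profile, in units of sigma
HALF_MAX_SIGMA = 1.1774100226


class PlacementError(RuntimeError):
    """Raised when a requested feature cannot be placed inside its zone."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic skin crop.

    Intensities live in [0, 1]; contrasts are intensity *drops* relative to
    the local background, so a contrast of 0.35 on a 0.62 background gives a
    stroke floor near 0.27.
    """

    height: int = 96
    width: int = 96
    background_mean: float = 0.62
    background_smoothness: float = 8.0
    lighting_gradient: float = 0.06
    n_wrinkles: int = 5
    wrinkle_thickness_range: tuple[float, float] = (1.5, 3.5)
    wrinkle_contrast: float = 0.35
    n_pores: int = 25
    pore_radius_range: tuple[float, float] = (1.0, 1.6)
    pore_contrast: float = 0.45
    n_distractors: int = 10
    annotation_radius: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("height and width must be >= 32")
        for name in ("n_wrinkles", "n_pores", "n_distractors"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("wrinkle_contrast", "pore_contrast"):
            c = getattr(self, name)
            if not (0.0 < c <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("wrinkle_thickness_range", "pore_radius_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or lo > hi:
                raise ValueError(f"{name} must be ordered and positive")
        if self.annotation_radius < 0:
            raise ValueError("annotation_radius must be >= 0")


@dataclass(frozen=True)
class ZoneLayout:
    """Occurrence zones: wrinkles in the forehead band + eye-corner boxes,
    pores in the central butterfly region."""

    wrinkle_zone: np.ndarray
    pore_zone: np.ndarray

    def __post_init__(self) -> None:
        wz, pz = np.asarray(self.wrinkle_zone), np.asarray(self.pore_zone)
        if wz.shape != pz.shape:
            raise ValueError("zone masks must share one shape")
        if not wz.any():
            raise ValueError("wrinkle_zone is empty")
        if not pz.any():
            raise ValueError("pore_zone is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.wrinkle_zone.shape

    @property
    def outside(self) -> np.ndarray:
        """Pixels belonging to neither zone (where distractors live)."""
        return ~(self.wrinkle_zone | self.pore_zone)


def default_zones(height: int, width: int) -> ZoneLayout:
    """Schematic facial layout: top-30% forehead band plus two 15%x15%
    eye-corner boxes at mid-height edges; central 40%x60% butterfly box."""
    wz = np.zeros((height, width), dtype=bool)
    wz[: int(round(0.30 * height)), :] = True
    bh, bw = int(round(0.15 * height)), int(round(0.15 * width))
    r0 = int(round(0.45 * height))
    wz[r0 : r0 + bh, :bw] = True
    wz[r0 : r0 + bh, width - bw :] = True
    pz = np.zeros((height, width), dtype=bool)
    pr0, pr1 = int(round(0.30 * height)), int(round(0.70 * height))
    pc0, pc1 = int(round(0.20 * width)), int(round(0.80 * width))
    pz[pr0:pr1, pc0:pc1] = True
    return ZoneLayout(wrinkle_zone=wz, pore_zone=pz)


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray  # (H, W, 3) float in [0, 1]
    fine_wrinkle_mask: np.ndarray
    fine_pore_mask: np.ndarray
    coarse_wrinkle_annotation: np.ndarray
    coarse_pore_annotation: np.ndarray
    distractor_mask: np.ndarray
    zones: ZoneLayout
    spec: SceneSpec


def make_coarse_annotation(fine_mask: np.ndarray, dilation_radius: int) -> np.ndarray:
    """Thicken a fine mask into an over-inclusive manual-style annotation
    by dilating with a disk structuring element."""
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")
    fine_mask = np.asarray(fine_mask, dtype=bool)
    if dilation_radius == 0:
        return fine_mask.copy()
    return dilation(fine_mask, disk(dilation_radius))


# ---------------------------------------------------------------- internals


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal((spec.height, spec.width))
    low = ndimage.gaussian_filter(noise, spec.background_smoothness, mode="reflect")
    sd = low.std()
    if sd > 0:
        low = low / sd * 0.025
    base = spec.background_mean + low
    if spec.lighting_gradient > 0:
        theta = rng.uniform(0, 2 * np.pi)
        rr, cc = np.meshgrid(
            np.linspace(-0.5, 0.5, spec.height),
            np.linspace(-0.5, 0.5, spec.width),
            indexing="ij",
        )
        base = base + spec.lighting_gradient * (np.cos(theta) * rr + np.sin(theta) * cc)
    return np.clip(base, 0.05, 0.95)


def _sample_in(mask: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise PlacementError("zone too small after margin erosion")
    idx = rng.integers(0, rows.size, size=n)
    return np.stack([rows[idx], cols[idx]], axis=1).astype(float)


def _stroke_drop(
    spec: SceneSpec,
    zone: np.ndarray,
    zone_name: str,
    rng: np.random.Generator,
    thickness: float,
    contrast: float,
    n_ctrl: int,
    length_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One curvilinear dark stroke: control points inside a single connected
    region of ``zone``, cubic spline centerline, Gaussian cross-section."""
    h, w = zone.shape
    sigma = thickness / 2.0
    margin = max(1, int(np.ceil(HALF_MAX_SIGMA * sigma)) + 1)
    labels, n_comp = ndimage.label(zone)
    if n_comp == 0:
        raise PlacementError(f"{zone_name} zone is empty")
    for _ in range(60):
        comp = rng.integers(1, n_comp + 1)
        region = erosion(labels == comp, disk(margin)) if margin else labels == comp
        if not region.any():
            continue
        anchor = _sample_in(region, rng, 1)[0]
        pts = [anchor]
        # random walk of control points, each step a bounded jump kept in-region
        for _ in range(n_ctrl - 1):
            for _try in range(40):
                step = rng.normal(0, length_scale, size=2)
                cand = pts[-1] + step
                r, c = int(round(cand[0])), int(round(cand[1]))
                if 0 <= r < h and 0 <= c < w and region[r, c]:
                    pts.append(cand)
                    break
            else:
                break
        if len(pts) < 2:
            continue
        pts_arr = np.array(pts)
        # chord-length parameterization, spline order limited by point count
        t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts_arr, axis=0), axis=1))])
        if t[-1] < 2.0:
            continue
        t /= t[-1]
        k = min(3, len(pts) - 1)
        spl = make_interp_spline(t, pts_arr, k=k)
        dense = spl(np.linspace(0, 1, max(200, int(t[-1] * 50))))
        rr = np.clip(np.round(dense[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(dense[:, 1]).astype(int), 0, w - 1)
        center = np.zeros((h, w), dtype=bool)
        center[rr, cc] = True
        dist = ndimage.distance_transform_edt(~center)
        drop = contrast * np.exp(-(dist**2) / (2 * sigma**2))
        drop[dist > 4 * sigma] = 0.0
        drop *= zone  # strokes never leak outside their zone
        fine = drop > contrast / 2.0
        if fine.any():
            return drop, fine
    raise PlacementError(f"could not place a stroke inside the {zone_name} zone")


def _pore_drop(
    shape: tuple[int, int], center: np.ndarray, sigma: float, contrast: float
) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    rr, cc = np.ogrid[:h, :w]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    drop = contrast * np.exp(-d2 / (2 * sigma**2))
    drop[d2 > (4 * sigma) ** 2] = 0.0
    fine = d2 <= (HALF_MAX_SIGMA * sigma) ** 2
    return drop, fine


def _place_pores(
    spec: SceneSpec,
    zone: np.ndarray,
    rng: np.random.Generator,
    n: int,
    radius_range: tuple[float, float],
    contrast: float,
    zone_name: str = "pore",
) -> tuple[np.ndarray, np.ndarray]:
    """Place n non-overlapping Gaussian pits inside ``zone``; fine disks are
    separated by >= 2 px so connected components count the pits exactly."""
    h, w = zone.shape
    drop_total = np.zeros((h, w))
    fine_total = np.zeros((h, w), dtype=bool)
    sig_max = radius_range[1]
    margin = max(1, int(np.ceil(HALF_MAX_SIGMA * sig_max)) + 1)
    region = erosion(zone, disk(margin))
    if not region.any():
        raise PlacementError(f"{zone_name} zone too small for radius {sig_max}")
    centers: list[np.ndarray] = []
    sigmas: list[float] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > 400 * max(n, 1):
            raise PlacementError(
                f"could not place {n} non-overlapping pores in the {zone_name} zone"
            )
        c = _sample_in(region, rng, 1)[0]
        s = rng.uniform(*radius_range)
        ok = all(
            np.linalg.norm(c - c0) >= HALF_MAX_SIGMA * (s + s0) + 2.0
            for c0, s0 in zip(centers, sigmas)
        )
        if not ok:
            continue
        centers.append(c)
        sigmas.append(s)
        drop, fine = _pore_drop((h, w), c, s, contrast)
        drop_total = np.maximum(drop_total, drop * zone)
        fine_total |= fine & zone
    return drop_total, fine_total


def _place_distractors(
    spec: SceneSpec, zones: ZoneLayout, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Dark features outside both zones: half pore-like pits, half short
    strokes, visually matched to genuine features."""
    h, w = zones.shape
    outside = zones.outside
    drop_total = np.zeros((h, w))
    support = np.zeros((h, w), dtype=bool)
    n = spec.n_distractors
    if n == 0:
        return drop_total, support
    sig_max = spec.pore_radius_range[1]
    margin = max(1, int(np.ceil(4 * sig_max)))
    region = erosion(outside, disk(margin))
    if not region.any():
        raise PlacementError("outside-zone region too small for distractors")
    for i in range(n):
        if i % 2 == 0:  # pore mimic
            c = _sample_in(region, rng, 1)[0]
            s = rng.uniform(*spec.pore_radius_range)
            drop, fine = _pore_drop((h, w), c, s, spec.pore_contrast)
        else:  # short stroke mimic
            c = _sample_in(region, rng, 1)[0]
            theta = rng.uniform(0, np.pi)
            length = rng.uniform(4, 9)
            ts = np.linspace(-length / 2, length / 2, 60)
            rr = np.clip(np.round(c[0] + ts * np.sin(theta)).astype(int), 0, h - 1)
            cc = np.clip(np.round(c[1] + ts * np.cos(theta)).astype(int), 0, w - 1)
            center = np.zeros((h, w), dtype=bool)
            center[rr, cc] = True
            dist = ndimage.distance_transform_edt(~center)
            sigma = rng.uniform(*spec.wrinkle_thickness_range) / 2.0
            drop = spec.wrinkle_contrast * np.exp(-(dist**2) / (2 * sigma**2))
            drop[dist > 4 * sigma] = 0.0
            fine = drop > spec.wrinkle_contrast / 2.0
        drop *= outside  # distractors never touch the zones
        drop_total = np.maximum(drop_total, drop)
        support |= fine & outside
    return drop_total, support


_SKIN_TINT = np.array([1.0, 0.87, 0.77])


def generate_scene(spec: SceneSpec, zones: ZoneLayout | None = None) -> SyntheticSample:
    """Render one synthetic skin crop from ``spec``.

    Deterministic: an identical spec (including seed) yields a bit-identical
    sample. Raises :class:`PlacementError` naming the zone when a feature
    cannot be placed.
    """
    if zones is None:
        zones = default_zones(spec.height, spec.width)
    if zones.shape != (spec.height, spec.width):
        raise ValueError(
            f"zone shape {zones.shape} does not match spec "
            f"({spec.height}, {spec.width})"
        )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    base = _background(spec, rng)

    drop = np.zeros_like(base)
    fine_w = np.zeros(base.shape, dtype=bool)
    for _ in range(spec.n_wrinkles):
        thickness = rng.uniform(*spec.wrinkle_thickness_range)
        n_ctrl = int(rng.integers(3, 6))
        d, f = _stroke_drop(
            spec,
            zones.wrinkle_zone,
            "wrinkle",
            rng,
            thickness,
            spec.wrinkle_contrast,
            n_ctrl,
            length_scale=max(6.0, 0.12 * min(spec.height, spec.width)),
        )
        drop = np.maximum(drop, d)
        fine_w |= f

    if spec.n_pores > 0:
        d, fine_p = _place_pores(
            spec, zones.pore_zone, rng, spec.n_pores,
            spec.pore_radius_range, spec.pore_contrast,
        )
        drop = np.maximum(drop, d)
    else:
        fine_p = np.zeros(base.shape, dtype=bool)

    d, distractors = _place_distractors(spec, zones, rng)
    drop = np.maximum(drop, d)

    lum = np.clip(base - drop, 0.0, 1.0)
    image = np.clip(lum[:, :, None] * _SKIN_TINT[None, None, :], 0.0, 1.0)

    return SyntheticSample(
        image=image,
        fine_wrinkle_mask=fine_w,
        fine_pore_mask=fine_p,
        coarse_wrinkle_annotation=make_coarse_annotation(fine_w, spec.annotation_radius),
        coarse_pore_annotation=make_coarse_annotation(fine_p, spec.annotation_radius),
        distractor_mask=distractors,
        zones=zones,
        spec=spec,
    )


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    # stable per-sample seeds < 2^31
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31)


def generate_dataset(
    spec_template: SceneSpec,
    n: int,
    seed: int,
    zones: ZoneLayout | None = None,
) -> list[SyntheticSample]:
    """Generate ``n`` samples with per-sample seeds derived from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = _derive_seeds(seed, n)
    return [
        generate_scene(replace(spec_template, seed=int(s)), zones) for s in seeds
    ]


def train_val_split(
    n: int, n_val: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, reproducible train/validation index sets covering 0..n-1."""
    if not (0 <= n_val <= n):
        raise ValueError("need 0 <= n_val <= n")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])
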