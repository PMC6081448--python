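"""Synthetic thoracic CT phantoms with voxel-level ground truth.

The phantom emulates the imaging substrate of pulmonary alveolar proteinosis
(PAP) studies: a soft-tissue body ellipsoid (~+40 HU) in scanner air
(−1000 HU), containing two disjoint aerated lung ellipsoids (~−850 HU), into
which parenchymal lesions are embedded:

* ``ggo`` — ground-glass opacity: overlapping soft-edged spheres of raised
  attenuation (default −350 HU), the dominant PAP pattern;
* ``reticular`` — spherical regions threaded by thin (1–2 voxel)
  high-attenuation septa on a lung-attenuation background;
* ``honeycomb`` — clustered small air cysts (−1000 HU) with ~−100 HU walls;
* ``low_mild`` / ``low_moderate`` / ``low_severe`` — emphysema-like
  low-attenuation regions at −910 / −950 / −980 HU.

Every voxel carries a known organ label and (within lung) a known pattern
class, so segmentation, densitometry and texture classification can all be
scored against truth. Identical seeds give voxelwise-identical phantoms (the
generator is numpy's PCG64, which is platform-stable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import CTVolume, OrganLabelMap, LEFT_LUNG, RIGHT_LUNG, BODY

__all__ = [
    "PATTERN_CLASSES",
    "PATTERN_CODES",
    "LesionSpec",
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "generate_labeled_boxes",
]

#: Canonical parenchymal class order; also the deterministic tie-break order
#: used by the classifier. Codes 1..7 in a pattern-truth grid; 0 = not lung.
PATTERN_CLASSES = (
    "normal",
    "low_mild",
    "low_moderate",
    "low_severe",
    "ggo",
    "reticular",
    "honeycomb",
)
PATTERN_CODES = {name: i + 1 for i, name in enumerate(PATTERN_CLASSES)}

#: Default mean attenuation per class (HU). Reticular and honeycomb are
#: composite textures; the value given is the attenuation of their dense
#: component (septa / cyst walls) drawn over lung or air background.
DEFAULT_CLASS_MEAN_HU = {
    "normal": -850.0,
    "low_mild": -910.0,
    "low_moderate": -950.0,
    "low_severe": -980.0,
    "ggo": -350.0,
    "reticular": -100.0,
    "honeycomb": -100.0,
}


@dataclass(frozen=True)
class LesionSpec:
    """One lesion class to embed in the lungs.

    ``fraction`` is the target fraction of total lung volume the class should
    occupy (placement stops once it is reached within ±0.02 absolute).
    ``mean_hu`` defaults to the class default above; ``sd_hu`` adds per-voxel
    texture on top of the global noise. ``geometry`` is ``"spheres"`` (random
    overlapping balls, the default for every class) or ``"slab"`` (a single
    axial slab, useful for controlled tests). ``radius_range`` is in voxels.
    """

    pattern: str
    fraction: float
    mean_hu: float | None = None
    sd_hu: float = 0.0
    geometry: str = "spheres"
    radius_range: tuple[float, float] = (3.0, 6.0)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_CLASSES or self.pattern == "normal":
            raise ValueError(f"unknown lesion pattern: {self.pattern!r}")
        if self.fraction < 0:
            raise ValueError("lesion fraction must be >= 0")
        if self.sd_hu < 0:
            raise ValueError("sd must be >= 0")
        if self.geometry not in ("spheres", "slab"):
            raise ValueError(f"unknown geometry: {self.geometry!r}")

    @property
    def resolved_mean_hu(self) -> float:
        return DEFAULT_CLASS_MEAN_HU[self.pattern] if self.mean_hu is None else self.mean_hu


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic thorax.

    Defaults give a 96×128×128 grid at (2.5, 2.0, 2.0) mm spacing — coarse
    enough that the whole pipeline runs in seconds, fine enough that a 15-voxel
    sliding box fits comfortably inside the lungs.
    """

    shape: tuple[int, int, int] = (96, 128, 128)
    spacing: tuple[float, float, float] = (2.5, 2.0, 2.0)
    body_mean_hu: float = 40.0
    body_sd_hu: float = 10.0
    lung_mean_hu: float = -850.0
    lung_sd_hu: float = 0.0
    lesions: tuple[LesionSpec, ...] = ()
    noise_sd_hu: float = 5.0
    seed: int = 0
    #: Absolute tolerance on achieved lesion fractions.
    fraction_tol: float = 0.02

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("shape must be three positive integers")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if min(self.body_sd_hu, self.lung_sd_hu, self.noise_sd_hu) < 0:
            raise ValueError("sd must be >= 0")
        total = sum(l.fraction for l in self.lesions)
        if total > 0.9:
            raise ValueError(f"lesion fractions sum to {total:.3f} > 0.9")

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=seed)


@dataclass
class PhantomBundle:
    """A phantom CT plus its ground truth.

    ``pattern_truth`` holds codes from :data:`PATTERN_CODES` on lung voxels and
    0 elsewhere. ``truth_summary`` is one row per parenchymal class with the
    true volume (ml) and fraction of lung volume; fractions sum to 1.
    """

    ct: CTVolume
    organ_truth: OrganLabelMap
    pattern_truth: np.ndarray
    truth_summary: pd.DataFrame
    spec: PhantomSpec

    def __post_init__(self) -> None:
        lung = self.organ_truth.lung_mask()
        if not np.array_equal(self.pattern_truth > 0, lung):
            raise ValueError("pattern_truth must be defined exactly on lung voxels")
        frac_sum = float(self.truth_summary["fraction_of_lung"].sum())
        if abs(frac_sum - 1.0) > 1e-9:
            raise ValueError(f"truth fractions sum to {frac_sum}, expected 1")

    def truth_fraction(self, pattern: str) -> float:
        row = self.truth_summary.loc[self.truth_summary["class"] == pattern]
        return float(row["fraction_of_lung"].iloc[0]) if len(row) else 0.0


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / semiaxes[0]) ** 2
        + ((yy - center[1]) / semiaxes[1]) ** 2
        + ((xx - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _ball_slices(shape, center, radius):
    lo = [max(0, int(np.floor(c - radius))) for c in center]
    hi = [min(n, int(np.ceil(c + radius)) + 1) for c, n in zip(center, shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    zz, yy, xx = np.ogrid[sl[0], sl[1], sl[2]]
    ball = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2) <= radius**2
    return sl, ball


def _anatomy(shape):
    """Body and lung ellipsoids, mirror-symmetric about the mid-sagittal plane."""
    nz, ny, nx = shape
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    body = _ellipsoid_mask(shape, (cz, cy, cx), (0.48 * nz, 0.43 * ny, 0.47 * nx))
    lung_semi = (0.375 * nz, 0.31 * ny, 0.19 * nx)
    dx = 0.235 * nx
    left = _ellipsoid_mask(shape, (cz, cy, cx + dx), lung_semi)
    right = _ellipsoid_mask(shape, (cz, cy, cx - dx), lung_semi)
    # guarantee a chest wall of >= 3 voxels even on coarse grids, where the
    # discretized ellipsoids can otherwise leave the lungs touching outside air
    body |= ndimage.binary_dilation(left | right, iterations=3)
    return body, left, right


# ---------------------------------------------------------------------------
# lesion placement
# ---------------------------------------------------------------------------

def _place_class(
    rng: np.random.Generator,
    lesion: LesionSpec,
    pattern: np.ndarray,
    lung_mask: np.ndarray,
    edt: np.ndarray,
    lung_idx: np.ndarray,
    reserved: np.ndarray | None = None,
) -> np.ndarray:
    """Grow a lesion-class mask until its target lung fraction is met.

    Disease is geographic on CT, so a class is laid down as a few compact
    spheroidal foci rather than an even spray. Each focus is a ball around a
    deep-lung center, clipped to lung tissue not yet claimed by another class,
    with its radius bisected so the focus hits its voxel quota almost exactly;
    foci keep a corridor of spared lung between themselves and any other
    focus. The quota of the largest foci comfortably exceeds the volume of a
    15^3 analysis box, so every class above a few percent of lung volume
    contains box-sized single-class regions to train signatures from.
    Raises ``RuntimeError`` naming the class when the quota cannot be met in
    10x the expected number of focus placements.
    """
    code = PATTERN_CODES[lesion.pattern]
    normal = PATTERN_CODES["normal"]
    n_lung = lung_idx.size
    target_vox = lesion.fraction * n_lung
    if target_vox < 1:
        return np.zeros_like(lung_mask)
    if reserved is None:
        reserved = np.zeros_like(lung_mask)
    tol = 0.02  # absolute fraction tolerance

    mask = np.zeros_like(lung_mask)
    if lesion.geometry == "slab":
        zs = np.unique(lung_idx // (pattern.shape[1] * pattern.shape[2]))
        placed = 0
        # grow an axial slab outward from the mid-lung slice
        order = zs[np.argsort(np.abs(zs - zs.mean()))]
        for z in order:
            sl = lung_mask[z] & (pattern[z] == normal) & ~reserved[z]
            mask[z] |= sl
            placed += int(sl.sum())
            if placed >= target_vox:
                break
        if placed < (lesion.fraction - tol) * n_lung:
            raise RuntimeError(f"could not reach target fraction for class {lesion.pattern!r}")
        return mask

    shape = pattern.shape
    gap = 12.0  # voxels of spared lung kept between separate foci
    # nominal focus size: a third of the burden, but always big enough to
    # contain a 15^3 box and never unmanageably large
    nominal = float(np.clip(target_vox / 3.0, 12000.0, 40000.0))
    expected = max(1, int(np.ceil(target_vox / nominal)) + 2)
    cap = 10 * expected
    placed = 0
    attempts = 0
    zz, yy, xx = np.indices(shape, dtype=np.float32, sparse=True)

    while placed < target_vox - 1:
        attempts += 1
        if attempts > cap:
            if placed >= (lesion.fraction - 0.8 * tol) * n_lung:
                break  # inside the fraction tolerance
            raise RuntimeError(
                f"could not reach target fraction for class {lesion.pattern!r}: "
                f"{placed / n_lung:.3f} of {lesion.fraction:.3f} after {attempts - 1} attempts"
            )
        # spared-lung corridors narrower than the analysis box are kept only
        # against this class's own foci; foci of different classes may abut
        # (no normal sliver forms at a direct interface)
        if mask.any():
            corridor_ok = ndimage.distance_transform_edt(~mask) >= gap
        else:
            corridor_ok = np.ones(shape, dtype=bool)
        allowed = (pattern == normal) & ~reserved & (edt >= 2.0) & corridor_ok
        if allowed.any():
            edt_av = ndimage.distance_transform_edt(allowed)
            deepest = float(edt_av.max())
        else:
            deepest = 0.0
        if deepest < 3.0:
            if placed >= (lesion.fraction - 0.8 * tol) * n_lung:
                break
            raise RuntimeError(
                f"could not reach target fraction for class {lesion.pattern!r}: "
                f"no room left at {placed / n_lung:.3f} of {lesion.fraction:.3f}"
            )
        # prefer centers deep enough that the focus keeps an inscribed ball
        # of radius >= 13 (which contains a 15^3 single-class cube)
        thresh = max(3.0, 0.8 * deepest)
        if deepest >= 14.0:
            thresh = max(thresh, 13.0)
        pool = np.flatnonzero(edt_av >= thresh)
        center = np.unravel_index(pool[rng.integers(0, pool.size)], shape)
        quota = min(
            target_vox - placed, nominal * rng.uniform(0.85, 1.3)
        )
        d2 = (
            (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        )
        # bisect the focus radius to hit the quota within one voxel shell
        r_lo_b, r_hi_b = 2.0, float(max(shape))
        for _ in range(24):
            r_mid = 0.5 * (r_lo_b + r_hi_b)
            count = int(np.count_nonzero(allowed & (d2 <= r_mid * r_mid)))
            if count < quota:
                r_lo_b = r_mid
            else:
                r_hi_b = r_mid
        focus = allowed & (d2 <= r_hi_b * r_hi_b)
        gained = int(focus.sum())
        if gained == 0:
            continue
        mask |= focus
        placed += gained
    return mask


def _reticular_texture(rng: np.random.Generator, mask: np.ndarray, spacing_vox: float = 5.0):
    """Thin septa inside ``mask``: voxels near any of three random plane families."""
    idx = np.argwhere(mask)
    septa = np.zeros(idx.shape[0], dtype=bool)
    for _ in range(3):
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        phase = rng.uniform(0, spacing_vox)
        proj = idx @ normal + phase
        septa |= (proj % spacing_vox) < 1.5  # 1–2 voxel thick sheets
    out = np.zeros_like(mask)
    out[tuple(idx[septa].T)] = True
    return out


def _honeycomb_cysts(rng: np.random.Generator, mask: np.ndarray, cyst_radius: float = 2.0):
    """Small air cysts packed into ``mask``; the rest of the region is wall."""
    n_region = int(mask.sum())
    ball_vol = 4.0 / 3.0 * np.pi * cyst_radius**3
    n_cysts = max(1, int(0.5 * n_region / ball_vol))
    idx = np.argwhere(mask)
    cysts = np.zeros_like(mask)
    for i in rng.integers(0, idx.shape[0], size=n_cysts):
        sl, ball = _ball_slices(mask.shape, idx[i], cyst_radius)
        cysts[sl] |= ball & mask[sl]
    return cysts


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build a phantom thorax with organ and pattern ground truth.

    The voxel grid is filled class-mean first (air −1000, body, lungs, then
    lesions), per-class texture noise is added where requested, ground-glass
    edges are softened by smoothing the lesion's attenuation increment, and
    finally global Gaussian noise of ``spec.noise_sd_hu`` is added everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    body, left, right = _anatomy(shape)

    organ = np.zeros(shape, dtype=np.int16)
    organ[body] = BODY
    organ[left] = LEFT_LUNG
    organ[right] = RIGHT_LUNG
    lung_mask = left | right

    pattern = np.zeros(shape, dtype=np.int8)
    pattern[lung_mask] = PATTERN_CODES["normal"]

    hu = np.full(shape, -1000.0)
    hu[body] = spec.body_mean_hu
    hu[lung_mask] = spec.lung_mean_hu

    # distance (in voxels) to the lung boundary, for wholly-inside placement
    edt = ndimage.distance_transform_edt(lung_mask)
    lung_idx = np.flatnonzero(lung_mask)

    # Reserve one normal core ball per lung (where depth allows) so spared
    # parenchyma always contains a 15^3 single-class region for training
    # boxes, however high the lesion burden.
    reserved = np.zeros(shape, dtype=bool)
    if spec.lesions:
        for side_mask in (left, right):
            # reserve in the upper third so the deep mid/lower lung stays
            # available for lesion foci
            zs = np.argwhere(side_mask.any(axis=(1, 2))).ravel()
            upper = np.zeros(shape, dtype=bool)
            upper[: zs.min() + max(1, (zs.max() - zs.min() + 1) // 3)] = True
            deep = edt * (side_mask & upper)
            if deep.max() >= 14.0:
                center = np.unravel_index(int(deep.argmax()), shape)
                sl, ball = _ball_slices(shape, center, 13.0)
                reserved[sl] |= ball
        if reserved.any():
            # in a cramped lung the reserve would exhaust the deep space the
            # lesion foci themselves need; drop it there (spared lung then
            # keeps box-sized regions simply because lesions stay compact)
            remaining = lung_mask & (edt >= 2.0) & ~reserved
            if ndimage.distance_transform_edt(remaining).max() < 13.5:
                reserved[:] = False

    class_masks: dict[str, np.ndarray] = {}
    for lesion in spec.lesions:
        mask = _place_class(rng, lesion, pattern, lung_mask, edt, lung_idx, reserved)
        pattern[mask] = PATTERN_CODES[lesion.pattern]
        class_masks[lesion.pattern] = mask

    for lesion in spec.lesions:
        mask = class_masks[lesion.pattern]
        if not mask.any():
            continue
        mean = lesion.resolved_mean_hu
        if lesion.pattern == "ggo":
            # soft edge: the attenuation transition is centered on the truth
            # boundary (50% level at the focus surface), emulating partial
            # volume without shifting the lesion's apparent extent
            w = ndimage.gaussian_filter(mask.astype(np.float64), sigma=1.0)
            soft = lung_mask & (w > 1e-3)
            hu[soft] += w[soft] * (mean - spec.lung_mean_hu)
        elif lesion.pattern == "reticular":
            septa = _reticular_texture(rng, mask)
            hu[septa] = mean
        elif lesion.pattern == "honeycomb":
            cysts = _honeycomb_cysts(rng, mask)
            hu[mask] = mean  # walls
            hu[cysts] = -1000.0
        else:  # low-attenuation bands and any plain-mean class
            hu[mask] = mean
        if lesion.sd_hu > 0:
            hu[mask] += rng.normal(0.0, lesion.sd_hu, size=int(mask.sum()))

    if spec.body_sd_hu > 0:
        body_only = body & ~lung_mask
        hu[body_only] += rng.normal(0.0, spec.body_sd_hu, size=int(body_only.sum()))
    if spec.lung_sd_hu > 0:
        normal_mask = pattern == PATTERN_CODES["normal"]
        hu[normal_mask] += rng.normal(0.0, spec.lung_sd_hu, size=int(normal_mask.sum()))
    if spec.noise_sd_hu > 0:
        hu += rng.normal(0.0, spec.noise_sd_hu, size=shape)

    ct = CTVolume(voxels=hu, spacing=spec.spacing)
    organ_map = OrganLabelMap(labels=organ, spacing=spec.spacing)

    vox_ml = ct.voxel_volume_ml
    n_lung = int(lung_mask.sum())
    rows = []
    for name in PATTERN_CLASSES:
        n = int((pattern == PATTERN_CODES[name]).sum())
        rows.append(
            {
                "class": name,
                "voxels": n,
                "volume_ml": n * vox_ml,
                "fraction_of_lung": n / n_lung,
            }
        )
    summary = pd.DataFrame(rows)

    bundle = PhantomBundle(
        ct=ct, organ_truth=organ_map, pattern_truth=pattern, truth_summary=summary, spec=spec
    )
    for lesion in spec.lesions:
        got = bundle.truth_fraction(lesion.pattern)
        if abs(got - lesion.fraction) > spec.fraction_tol:
            raise RuntimeError(
                f"class {lesion.pattern!r} reached fraction {got:.3f}, "
                f"target {lesion.fraction:.3f} ± {spec.fraction_tol}"
            )
    return bundle


def generate_labeled_boxes(
    source: PhantomSpec | PhantomBundle,
    n_per_class: int,
    box_edge: int = 15,
    classes: tuple[str, ...] | None = None,
    seed: int | None = None,
):
    """Sample cubic HU patches drawn entirely from single-truth-class tissue.

    These play the role that radiologist-consensus training regions play in
    production parenchymal classifiers: balanced, labeled examples from which
    per-class histogram signatures are learned.

    Returns a list of ``(patch, class_name)`` with exactly ``n_per_class``
    patches per class (sampling with replacement if a class has few eligible
    centers). A requested class absent from the phantom raises ``ValueError``.
    """
    if box_edge % 2 == 0:
        raise ValueError(f"box_edge must be odd, got {box_edge}")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    bundle = source if isinstance(source, PhantomBundle) else generate_phantom(source)
    if classes is None:
        present = np.unique(bundle.pattern_truth)
        classes = tuple(c for c in PATTERN_CLASSES if PATTERN_CODES[c] in present)
    rng = np.random.default_rng(bundle.spec.seed + 1 if seed is None else seed)

    truth = bundle.pattern_truth

    def _eligible(code: int, edge: int) -> np.ndarray:
        # a center is eligible iff the whole box is one class (and inside the
        # grid: the zero padding of the min/max filters handles grid edges)
        lo = ndimage.minimum_filter(truth, size=edge, mode="constant", cval=0)
        hi = ndimage.maximum_filter(truth, size=edge, mode="constant", cval=0)
        return np.flatnonzero((lo == code) & (hi == code))

    out = []
    for name in classes:
        code = PATTERN_CODES.get(name)
        if code is None:
            raise ValueError(f"unknown class: {name!r}")
        if not np.any(truth == code):
            raise ValueError(f"class {name!r} is absent from the phantom")
        # fall back to smaller odd patches when the class has no box-sized
        # region; the signature is a normalized histogram, so a smaller pure
        # patch estimates the same distribution
        edge = box_edge
        eligible = _eligible(code, edge)
        while eligible.size == 0 and edge > 7:
            edge -= 2
            eligible = _eligible(code, edge)
        if eligible.size == 0:
            raise ValueError(
                f"class {name!r} has no region large enough for a {edge}^3 box"
            )
        half = edge // 2
        picks = rng.choice(eligible, size=n_per_class, replace=eligible.size < n_per_class)
        for flat in picks:
            z, y, x = np.unravel_index(flat, truth.shape)
            patch = bundle.ct.voxels[
                z - half : z + half + 1, y - half : y + half + 1, x - half : x + half + 1
            ].copy()
            out.append((patch, name))
    return out
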