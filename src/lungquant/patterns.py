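"""Sliding-box histogram-signature classification of lung parenchyma.

Every lung voxel is scored from the 15×15×15-voxel box centered on it: the
normalized histogram of in-lung attenuation over fixed HU bins, plus a small
block of auxiliary features (mean, sd, 15th-percentile HU, fraction below
−950 HU, fraction above −300 HU). Each voxel receives the class of the
nearest signature, where signatures are per-class mean feature vectors
learned from labeled single-class training boxes (the stand-in for
radiologist-consensus training regions in production systems).

Distance is a 0.7/0.3 blend of the symmetric chi-square distance between
histograms and a bounded (``e/(1+e)``) Euclidean distance between
standardized aux features, so the histogram term dominates and the aux block
acts as a tiebreaker; exact ties resolve by the fixed class order ``normal,
low_mild, low_moderate, low_severe, ggo, reticular, honeycomb``.

The per-zone rollup reports volume and percent of parenchyma per class, and
the headline severity metric: *involved* lung — ground-glass plus reticular
volume as a percent of total segmented parenchyma (honeycombing can be added
with a flag, but is excluded by default since the involved/uninvolved
dichotomy for alveolar proteinosis names only ground-glass and reticular
densities). Everything else (normal and the low-attenuation subtypes) is
*uninvolved*; the two percentages sum to 100.

The sliding-box pass is vectorized with box-sum filters (one pass per
histogram bin), so a default-size phantom classifies in a few seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import PATTERN_CLASSES, PATTERN_CODES
from .segmentation import ZONE_NAMES, ZoneMap
from .volume_io import CTVolume, OrganLabelMap

__all__ = [
    "BIN_EDGES",
    "AUX_NAMES",
    "PatternSignature",
    "SignatureSet",
    "PatternMap",
    "PatternSummary",
    "box_features",
    "train_signatures",
    "classify_parenchyma",
    "summarize_patterns",
]

#: 32 equal-width histogram bins over [−1024, 100] HU; values outside clamp
#: to the end bins.
BIN_EDGES = np.linspace(-1024.0, 100.0, 33)

AUX_NAMES = ("mean_hu", "sd_hu", "p15_hu", "frac_below_m950", "frac_above_m300")

_CHI2_WEIGHT = 0.7
_AUX_WEIGHT = 0.3
_EPS = 1e-12


@dataclass
class PatternSignature:
    """Per-class mean histogram + mean aux features."""

    class_name: str
    histogram: np.ndarray
    aux: np.ndarray

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram, dtype=float)
        self.aux = np.asarray(self.aux, dtype=float)
        s = self.histogram.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"signature histogram sums to {s}, expected 1")


@dataclass
class SignatureSet:
    """An ordered set of class signatures sharing bin edges and aux scaling.

    Signatures are stored in canonical class order so nearest-signature
    classification (argmin over this order) is independent of the order they
    were supplied in, and ties break deterministically.
    """

    signatures: list[PatternSignature]
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())
    aux_center: np.ndarray | None = None
    aux_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.signatures:
            raise ValueError("signature set is empty")
        order = {c: i for i, c in enumerate(PATTERN_CLASSES)}
        self.signatures = sorted(self.signatures, key=lambda s: order[s.class_name])
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.aux_center is None:
            aux = np.stack([s.aux for s in self.signatures])
            self.aux_center = aux.mean(axis=0)
            self.aux_scale = np.maximum(aux.std(axis=0), 1e-6)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(s.class_name for s in self.signatures)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "bin_edges": self.bin_edges.tolist(),
            "aux_names": list(AUX_NAMES),
            "aux_center": self.aux_center.tolist(),
            "aux_scale": self.aux_scale.tolist(),
            "signatures": [
                {
                    "class": s.class_name,
                    "histogram": s.histogram.tolist(),
                    "aux": s.aux.tolist(),
                }
                for s in self.signatures
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureSet":
        payload = json.loads(Path(path).read_text())
        sigs = [
            PatternSignature(s["class"], np.array(s["histogram"]), np.array(s["aux"]))
            for s in payload["signatures"]
        ]
        return cls(
            signatures=sigs,
            bin_edges=np.array(payload["bin_edges"]),
            aux_center=np.array(payload["aux_center"]),
            aux_scale=np.array(payload["aux_scale"]),
        )


@dataclass
class PatternMap:
    """Per-voxel parenchymal class codes (see ``phantom.PATTERN_CODES``),
    0 outside the lungs."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    class_names: tuple[str, ...] = PATTERN_CLASSES


@dataclass
class PatternSummary:
    """Per-zone and total class volumes/percentages plus involved/uninvolved."""

    per_zone: pd.DataFrame
    totals: dict
    include_honeycomb_in_involved: bool = False

    def __post_init__(self) -> None:
        class_pct_cols = [f"{c}_percent" for c in PATTERN_CLASSES]
        nonempty = self.per_zone[self.per_zone["parenchyma_ml"] > 0]
        sums = nonempty[class_pct_cols].sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValueError("per-zone class percentages must sum to 100")
        t = self.totals
        if abs(t["involved_percent"] + t["uninvolved_percent"] - 100.0) > 1e-6:
            raise ValueError("involved + uninvolved must equal 100")


# ---------------------------------------------------------------------------
# feature computation
# ---------------------------------------------------------------------------

def _histogram(values: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    clipped = np.clip(values, bin_edges[0], np.nextafter(bin_edges[-1], -np.inf))
    hist, _ = np.histogram(clipped, bins=bin_edges)
    return hist / max(values.size, 1)

def _p15_from_hist(hist: np.ndarray, bin_edges: np.ndarray, q: float = 0.15) -> float:
    """15th percentile read off the binned distribution (linear within a bin)."""
    cum = np.cumsum(hist)
    j = int(np.searchsorted(cum, q))
    j = min(j, hist.size - 1)
    prev = cum[j - 1] if j > 0 else 0.0
    width = bin_edges[j + 1] - bin_edges[j]
    frac = (q - prev) / hist[j] if hist[j] > 0 else 0.0
    return float(bin_edges[j] + frac * width)


def box_features(
    ct: CTVolume,
    organ: OrganLabelMap | None,
    center: tuple[int, int, int],
    box_edge: int = 15,
    bin_edges: np.ndarray = BIN_EDGES,
    min_coverage: float = 0.25,
):
    """Histogram + aux features for the box centered on a lung voxel.

    The box is clamped at grid boundaries and restricted to in-lung voxels
    (all voxels when ``organ`` is None, as for training patches). Returns
    ``(histogram, aux)`` or ``None`` when fewer than ``min_coverage`` of the
    nominal box voxels are in-lung (the voxel is then unclassifiable on its
    own and inherits its nearest classified neighbor's label downstream).
    """
    if box_edge % 2 == 0:
        raise ValueError("box_edge must be odd")
    z, y, x = center
    if organ is not None and not organ.lung_mask()[z, y, x]:
        raise ValueError(f"center {center} is not a lung voxel")
    half = box_edge // 2
    sl = tuple(
        slice(max(0, c - half), min(n, c + half + 1))
        for c, n in zip(center, ct.shape)
    )
    patch = ct.voxels[sl]
    if organ is not None:
        values = patch[organ.lung_mask()[sl]]
    else:
        values = patch.ravel()
    if values.size < min_coverage * box_edge**3:
        return None
    hist = _histogram(values, bin_edges)
    aux = np.array(
        [
            values.mean(),
            values.std(),
            _p15_from_hist(hist, bin_edges),
            np.mean(values < -950.0),
            np.mean(values > -300.0),
        ]
    )
    return hist, aux


def train_signatures(labeled_boxes, bin_edges: np.ndarray = BIN_EDGES) -> SignatureSet:
    """Learn per-class signatures from ``(patch, class_name)`` training boxes.

    Requires at least 2 classes and at least 10 boxes per class. The signature
    is the mean normalized histogram and mean aux vector over the class's
    boxes; aux standardization statistics are pooled over all boxes.
    """
    by_class: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for patch, name in labeled_boxes:
        if name not in PATTERN_CODES:
            raise ValueError(f"unknown class label: {name!r}")
        values = np.asarray(patch, dtype=float).ravel()
        hist = _histogram(values, bin_edges)
        aux = np.array(
            [
                values.mean(),
                values.std(),
                _p15_from_hist(hist, bin_edges),
                np.mean(values < -950.0),
                np.mean(values > -300.0),
            ]
        )
        by_class.setdefault(name, []).append((hist, aux))
    if len(by_class) < 2:
        raise ValueError(f"need boxes from >= 2 classes, got {sorted(by_class)}")
    for name, items in by_class.items():
        if len(items) < 10:
            raise ValueError(f"class {name!r} has {len(items)} boxes; need >= 10")

    all_aux = np.stack([aux for items in by_class.values() for _, aux in items])
    sigs = []
    for name, items in by_class.items():
        hist = np.mean([h for h, _ in items], axis=0)
        hist = hist / hist.sum()
        aux = np.mean([a for _, a in items], axis=0)
        sigs.append(PatternSignature(name, hist, aux))
    return SignatureSet(
        signatures=sigs,
        bin_edges=bin_edges,
        aux_center=all_aux.mean(axis=0),
        aux_scale=np.maximum(all_aux.std(axis=0), 1e-6),
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _box_sum(arr: np.ndarray, box_edge: int) -> np.ndarray:
    """Sum of ``arr`` over the box centered on each voxel (zeros outside grid)."""
    return ndimage.uniform_filter(arr, size=box_edge, mode="constant", cval=0.0) * box_edge**3


def classify_parenchyma(
    ct: CTVolume,
    organ: OrganLabelMap,
    signatures: SignatureSet,
    stride: int = 1,
    box_edge: int = 15,
    min_coverage: float = 0.25,
    exclude_vessels: bool = False,
    vessel_threshold: float = -300.0,
) -> PatternMap:
    """Assign every lung voxel the class of its nearest signature.

    Features come from the box centered on the voxel (clamped at lung and grid
    boundaries). Voxels whose box covers < ``min_coverage`` of its nominal
    volume in parenchyma, voxels excluded as vessels, and off-lattice voxels
    when ``stride > 1``, all inherit the label of their nearest classified
    voxel. Deterministic: fixed inputs give identical maps.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if box_edge % 2 == 0:
        raise ValueError("box_edge must be odd")
    lung = organ.lung_mask()
    if not lung.any():
        raise ValueError("no lung voxels in the organ map")
    par = lung & (ct.voxels < vessel_threshold) if exclude_vessels else lung

    hu = ct.voxels
    m = par.astype(np.float64)
    nominal = float(box_edge**3)
    cnt = _box_sum(m, box_edge)
    coverage = cnt / nominal

    classifiable = lung & par & (coverage >= min_coverage)
    if stride > 1:
        lattice = np.zeros_like(lung)
        lattice[::stride, ::stride, ::stride] = True
        classifiable &= lattice
    idx = np.flatnonzero(classifiable)
    if idx.size == 0:
        # degenerate case: no voxel has enough context; everything inherits
        # from the single best global guess
        classifiable = lung & par
        idx = np.flatnonzero(classifiable)
        if idx.size == 0:
            classifiable = lung
            idx = np.flatnonzero(classifiable)

    edges = signatures.bin_edges
    n_bins = edges.size - 1
    flat_cnt = cnt.ravel()[idx]
    flat_cnt = np.maximum(flat_cnt, 1.0)

    # per-voxel normalized histogram over in-parenchyma box voxels
    binned = np.clip(np.digitize(hu, edges) - 1, 0, n_bins - 1)
    hist = np.empty((idx.size, n_bins), dtype=np.float64)
    for b in range(n_bins):
        ind = ((binned == b) & par).astype(np.float64)
        hist[:, b] = _box_sum(ind, box_edge).ravel()[idx]
    hist /= flat_cnt[:, None]

    s1 = _box_sum(hu * m, box_edge).ravel()[idx]
    s2 = _box_sum(hu * hu * m, box_edge).ravel()[idx]
    mean = s1 / flat_cnt
    var = np.maximum(s2 / flat_cnt - mean**2, 0.0)
    below = _box_sum(((hu < -950.0) & par).astype(np.float64), box_edge).ravel()[idx] / flat_cnt
    above = _box_sum(((hu > -300.0) & par).astype(np.float64), box_edge).ravel()[idx] / flat_cnt

    # 15th percentile from the per-voxel binned distribution
    cum = np.cumsum(hist, axis=1)
    j = np.minimum((cum < 0.15).sum(axis=1), n_bins - 1)
    prev = np.where(j > 0, np.take_along_axis(cum, np.maximum(j - 1, 0)[:, None], 1)[:, 0], 0.0)
    hj = np.take_along_axis(hist, j[:, None], 1)[:, 0]
    widths = np.diff(edges)
    frac = np.where(hj > 0, (0.15 - prev) / np.where(hj > 0, hj, 1.0), 0.0)
    p15 = edges[j] + frac * widths[j]

    aux = np.column_stack([mean, np.sqrt(var), p15, below, above])
    aux_z = (aux - signatures.aux_center) / signatures.aux_scale

    k = aux.shape[1]
    dist = np.empty((idx.size, len(signatures.signatures)))
    for ci, sig in enumerate(signatures.signatures):
        sh = sig.histogram[None, :]
        chi2 = (((hist - sh) ** 2) / (hist + sh + _EPS)).sum(axis=1)
        sz = (sig.aux - signatures.aux_center) / signatures.aux_scale
        eucl = np.sqrt(((aux_z - sz[None, :]) ** 2).sum(axis=1) / k)
        # bounded so that an out-of-distribution box (e.g. a mixed boundary
        # box, whose sd far exceeds any pure training box) cannot let the aux
        # block drown out the histogram term
        dist[:, ci] = _CHI2_WEIGHT * chi2 + _AUX_WEIGHT * eucl / (1.0 + eucl)
    best = np.argmin(dist, axis=1)  # first minimum = canonical-order tie-break
    codes = np.array([PATTERN_CODES[s.class_name] for s in signatures.signatures], dtype=np.int8)

    labels = np.zeros(ct.shape, dtype=np.int8)
    labels.ravel()[idx] = codes[best]

    # propagate to unclassified lung voxels from the nearest classified voxel
    remaining = lung & (labels == 0)
    if remaining.any():
        _, nearest = ndimage.distance_transform_edt(labels == 0, return_indices=True)
        labels[remaining] = labels[nearest[0][remaining], nearest[1][remaining], nearest[2][remaining]]
    return PatternMap(labels=labels, spacing=ct.spacing)


# ---------------------------------------------------------------------------
# rollup
# ---------------------------------------------------------------------------

def summarize_patterns(
    pattern_map: PatternMap,
    zone_map: ZoneMap,
    spacing: tuple[float, float, float] | None = None,
    include_honeycomb_in_involved: bool = False,
) -> PatternSummary:
    """Per-zone and whole-lung class volumes, percentages and involved lung.

    Involved = ground-glass + reticular (+ honeycomb with the flag); the
    percentage is the involved volume divided by total segmented parenchymal
    volume. Zone rows sum exactly to the whole-lung totals.
    """
    if pattern_map.labels.shape != zone_map.zones.shape:
        raise ValueError("pattern map and zone map shapes differ")
    spacing = spacing or pattern_map.spacing
    vox_ml = float(np.prod(spacing)) / 1000.0
    involved_classes = ["ggo", "reticular"] + (
        ["honeycomb"] if include_honeycomb_in_involved else []
    )

    rows = []
    for zid in sorted(ZONE_NAMES):
        zmask = zone_map.zones == zid
        n_zone = int(zmask.sum())
        row: dict = {"zone_id": zid, "zone": ZONE_NAMES[zid], "parenchyma_ml": n_zone * vox_ml}
        inv = 0
        for cname in PATTERN_CLASSES:
            n = int((pattern_map.labels[zmask] == PATTERN_CODES[cname]).sum())
            row[f"{cname}_ml"] = n * vox_ml
            row[f"{cname}_percent"] = 100.0 * n / n_zone if n_zone else 0.0
            if cname in involved_classes:
                inv += n
        row["involved_ml"] = inv * vox_ml
        row["involved_percent"] = 100.0 * inv / n_zone if n_zone else 0.0
        rows.append(row)
    per_zone = pd.DataFrame(rows)

    n_lung = int((pattern_map.labels > 0).sum())
    if n_lung == 0:
        raise ValueError("pattern map contains no lung voxels")
    totals: dict = {"parenchyma_ml": n_lung * vox_ml}
    inv_n = 0
    for cname in PATTERN_CLASSES:
        n = int((pattern_map.labels == PATTERN_CODES[cname]).sum())
        totals[f"{cname}_ml"] = n * vox_ml
        totals[f"{cname}_percent"] = 100.0 * n / n_lung
        if cname in involved_classes:
            inv_n += n
    totals["involved_ml"] = inv_n * vox_ml
    totals["involved_percent"] = 100.0 * inv_n / n_lung
    totals["uninvolved_ml"] = (n_lung - inv_n) * vox_ml
    totals["uninvolved_percent"] = 100.0 * (n_lung - inv_n) / n_lung

    return PatternSummary(
        per_zone=per_zone,
        totals=totals,
        include_honeycomb_in_involved=include_honeycomb_in_involved,
    )
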