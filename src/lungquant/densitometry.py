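"""Lung densitometry: mean attenuation, density, volume, mass, and the
height-predicted total lung mass.

The physical chain is: mean lung attenuation (HU) → tissue density ρCT (g/ml)
→ mass = volume × density. Because lung tissue is a mixture of air (−1000 HU,
~0 g/ml) and water-like tissue (0 HU, 1 g/ml), attenuation maps linearly onto
density as ρ = (1000 + HU)/1000 — the ``air_referenced`` convention and the
default here. An alternative ``as_printed`` convention, ρ = (1000 − HU)/1000,
is provided for auditing against reports that state the formula in that form
(it assigns air a density of 2 g/ml, so it is not the default).

Total lung mass (TLM) scales with subject height; the built-in linear
reference, predicted TLM (g) = 9.8759 × height (cm) − 1019.1, was derived
from standard CT of healthy adults and is used as-is (refitting it is out of
scope). Percent error = 100 × (TLM − predicted)/predicted, and percent of
predicted = 100 + percent error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume_io import CTVolume, LEFT_LUNG, OrganLabelMap, RIGHT_LUNG, ResultTable

__all__ = [
    "hu_to_density",
    "lung_volume",
    "predicted_tlm",
    "percent_error",
    "run_densitometry",
    "DensitometryResult",
    "LungStats",
    "PREDICTED_TLM_SLOPE",
    "PREDICTED_TLM_INTERCEPT",
]

#: Coefficients of the height → predicted-TLM reference line (g per cm, g).
PREDICTED_TLM_SLOPE = 9.8759
PREDICTED_TLM_INTERCEPT = -1019.1

_SIDES = {"left": (LEFT_LUNG,), "right": (RIGHT_LUNG,), "both": (LEFT_LUNG, RIGHT_LUNG)}


def hu_to_density(mean_hu: float, convention: str = "air_referenced") -> float:
    """Convert a mean lung attenuation (HU) to tissue density ρCT in g/ml."""
    if not np.isfinite(mean_hu):
        raise ValueError("mean_hu must be finite")
    if convention == "air_referenced":
        return (1000.0 + mean_hu) / 1000.0
    if convention == "as_printed":
        return (1000.0 - mean_hu) / 1000.0
    raise ValueError(f"unknown density convention: {convention!r}")


def lung_volume(organ: OrganLabelMap, spacing=None, side: str = "both") -> float:
    """Lung volume in ml: voxel count × voxel volume.

    ``side`` is ``"left"``, ``"right"`` or ``"both"``; the side's label must be
    present in the map.
    """
    if side not in _SIDES:
        raise ValueError(f"unknown side: {side!r}")
    spacing = spacing or organ.spacing
    vox_ml = float(np.prod(spacing)) / 1000.0
    total = 0.0
    for lab in _SIDES[side]:
        n = int((organ.labels == lab).sum())
        if n == 0:
            raise ValueError(f"label for side {side!r} absent from the organ map")
        total += n * vox_ml
    return total


def predicted_tlm(height_cm: float) -> float:
    """Height-predicted total lung mass in g (linear reference in healthy adults)."""
    if height_cm <= 0:
        raise ValueError("height must be positive")
    if not (100.0 <= height_cm <= 220.0):
        warnings.warn(
            f"height {height_cm} cm is outside the 100–220 cm range the reference "
            "line was intended for",
            stacklevel=2,
        )
    return PREDICTED_TLM_SLOPE * height_cm + PREDICTED_TLM_INTERCEPT


def percent_error(tlm: float, predicted: float) -> float:
    """Percent deviation of measured TLM from the height-predicted value."""
    if predicted == 0:
        raise ValueError("predicted TLM must be nonzero")
    return (tlm - predicted) / predicted * 100.0


@dataclass
class LungStats:
    """Densitometry readout for one lung (or both combined)."""

    mean_hu: float
    density_g_ml: float
    volume_ml: float
    mass_g: float


@dataclass
class DensitometryResult:
    left: LungStats
    right: LungStats
    both: LungStats
    tlm_g: float
    convention: str
    height_cm: float | None = None
    predicted_tlm_g: float | None = None
    percent_error: float | None = None
    percent_of_predicted: float | None = None

    def __post_init__(self) -> None:
        if abs(self.tlm_g - (self.left.mass_g + self.right.mass_g)) > 1e-6:
            raise ValueError("TLM must equal left + right lung mass")
        if self.percent_error is not None and self.percent_of_predicted is not None:
            if abs(self.percent_of_predicted - (100.0 + self.percent_error)) > 1e-9:
                raise ValueError("percent_of_predicted must equal 100 + percent_error")

    def to_result_table(self, provenance: dict | None = None) -> ResultTable:
        table = ResultTable(provenance=provenance or {})
        for side in ("left", "right", "both"):
            st: LungStats = getattr(self, side)
            table.add(f"{side}_mean_hu", st.mean_hu, "HU")
            table.add(f"{side}_density", st.density_g_ml, "g/ml")
            table.add(f"{side}_volume", st.volume_ml, "ml")
            table.add(f"{side}_mass", st.mass_g, "g")
        table.add("tlm", self.tlm_g, "g")
        if self.predicted_tlm_g is not None:
            table.add("height", self.height_cm, "cm")
            table.add("predicted_tlm", self.predicted_tlm_g, "g")
            table.add("percent_error", self.percent_error, "%")
            table.add("percent_of_predicted", self.percent_of_predicted, "%")
        return table


def run_densitometry(
    ct: CTVolume,
    organ: OrganLabelMap,
    height_cm: float | None = None,
    convention: str = "air_referenced",
    exclude_vessels: bool = False,
    vessel_threshold: float = -300.0,
) -> DensitometryResult:
    """Full densitometry readout for a segmented chest CT.

    Per lung: mean HU over all lung-labeled voxels (optionally excluding
    voxels above ``vessel_threshold`` when ``exclude_vessels``), density via
    :func:`hu_to_density`, volume as voxel sum, mass = volume × density.
    TLM is the sum of the two lung masses. When ``height_cm`` (or the
    volume's ``subject_height_cm``) is available, the predicted TLM and the
    percent-error fields are populated; otherwise they are ``None``.
    """
    if ct.shape != organ.shape:
        raise ValueError("CT volume and organ map shapes differ")
    height_cm = height_cm if height_cm is not None else ct.subject_height_cm
    vox_ml = ct.voxel_volume_ml
    stats: dict[str, LungStats] = {}
    for side, labs in _SIDES.items():
        mask = np.isin(organ.labels, labs)
        if not mask.any():
            raise ValueError(f"label for side {side!r} absent from the organ map")
        n_all = int(mask.sum())
        if exclude_vessels:
            mask = mask & (ct.voxels < vessel_threshold)
            if not mask.any():
                raise ValueError(f"no parenchymal voxels left on side {side!r}")
        mean_hu = float(ct.voxels[mask].mean())
        density = hu_to_density(mean_hu, convention)
        volume = n_all * vox_ml  # volume always counts the full lung label
        stats[side] = LungStats(mean_hu, density, volume, volume * density)

    tlm = stats["left"].mass_g + stats["right"].mass_g
    pred = perr = pofp = None
    if height_cm is not None:
        pred = predicted_tlm(height_cm)
        perr = percent_error(tlm, pred)
        pofp = 100.0 + perr
    return DensitometryResult(
        left=stats["left"],
        right=stats["right"],
        both=stats["both"],
        tlm_g=tlm,
        convention=convention,
        height_cm=height_cm,
        predicted_tlm_g=pred,
        percent_error=perr,
        percent_of_predicted=pofp,
    )
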