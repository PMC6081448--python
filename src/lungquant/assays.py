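"""Bench-assay derived quantities as pure, unit-checked calculations.

These are the small arithmetic steps that sit between raw instrument readings
and reported biology in alveolar-proteinosis work:

* radiolabelled cholesterol efflux — percent of label transferred from cells
  to the medium in the presence of an acceptor (Apo-A1 or HDL);
* esterified cholesterol — total minus free, both per mg cell protein;
* the cholesterol : phospholipid ratio of surfactant (a dimensionless ratio;
  its units depend on the upstream assays, so they are carried by the caller);
* lavage-fluid turbidity — optical density at 600 nm scaled by the dilution
  factor, a global sediment-accumulation readout;
* qPCR — amplification efficiency from a serial-dilution standard curve, and
  efficiency-corrected relative expression normalized to a reference gene
  (36b4 in the original context), in the Pfaffl ratio form
  ``E_target^dCq_target / E_ref^dCq_ref`` with ``dCq = Cq(calibrator) −
  Cq(sample)``; the classic ``2^−ddCq`` is available as a flag and equals the
  Pfaffl form when both efficiencies are 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EffluxCounts",
    "CholesterolPanel",
    "efflux_percent",
    "esterified_cholesterol",
    "chol_pl_ratio",
    "bal_turbidity",
    "qpcr_efficiency",
    "relative_expression",
]


@dataclass(frozen=True)
class EffluxCounts:
    """Scintillation counts (dpm) recovered from medium and cell fractions."""

    media_dpm: float
    cell_dpm: float

    def __post_init__(self) -> None:
        if self.media_dpm < 0 or self.cell_dpm < 0:
            raise ValueError("radioactive counts must be >= 0")
        if self.media_dpm == 0 and self.cell_dpm == 0:
            raise ValueError("media and cell counts cannot both be zero")


@dataclass(frozen=True)
class CholesterolPanel:
    """Cholesterol measurements (µg per mg protein); phospholipid optional."""

    total: float
    free: float
    phospholipid: float | None = None

    def __post_init__(self) -> None:
        if self.free < 0 or self.total < 0:
            raise ValueError("concentrations must be >= 0")
        if self.free > self.total:
            raise ValueError(
                f"free cholesterol ({self.free}) exceeds total ({self.total}): "
                "measurement inconsistency"
            )


def efflux_percent(counts: EffluxCounts) -> float:
    """Cholesterol efflux as percent of total label found in the medium:
    100 × media / (media + cells). Always in [0, 100]."""
    return 100.0 * counts.media_dpm / (counts.media_dpm + counts.cell_dpm)


def esterified_cholesterol(panel: CholesterolPanel) -> float:
    """Esterified cholesterol = total − free (same units as the panel)."""
    return panel.total - panel.free


def chol_pl_ratio(panel: CholesterolPanel) -> float:
    """Ratio of total cholesterol to total phospholipid (assay-dependent units)."""
    if panel.phospholipid is None or panel.phospholipid == 0:
        raise ValueError("phospholipid concentration is absent or zero")
    return panel.total / panel.phospholipid


def bal_turbidity(od600: float, sample_vol_ul: float, diluent_vol_ul: float) -> float:
    """Lavage turbidity: OD600 × dilution factor.

    The dilution factor is (sample + diluent)/sample, e.g. 250 µl of lavage
    fluid into 750 µl of buffer gives a factor of 4.
    """
    if sample_vol_ul <= 0 or diluent_vol_ul < 0:
        raise ValueError("sample volume must be > 0 and diluent volume >= 0")
    return od600 * (sample_vol_ul + diluent_vol_ul) / sample_vol_ul


def qpcr_efficiency(log10_input, cq) -> float:
    """Amplification efficiency from a serial-dilution standard curve.

    Fits Cq against log10 input amount by least squares; the per-cycle
    efficiency is ``E = 10^(−1/slope)`` (slope −3.3219 ⇒ E = 2, perfect
    doubling). Requires ≥ 4 points spanning ≥ 3 logs and a physically sensible
    slope (|slope| ≥ 1).
    """
    log10_input = np.asarray(log10_input, dtype=float)
    cq = np.asarray(cq, dtype=float)
    if log10_input.size != cq.size:
        raise ValueError("input and Cq arrays differ in length")
    if log10_input.size < 4:
        raise ValueError("standard curve needs at least 4 points")
    span = log10_input.max() - log10_input.min()
    if span < 3.0:
        raise ValueError(f"standard curve spans {span:.2f} logs; need >= 3")
    if np.any(cq <= 0):
        raise ValueError("Cq values must be positive")
    slope, _ = np.polyfit(log10_input, cq, 1)
    if abs(slope) < 1.0:
        raise ValueError(f"slope {slope:.3f} too shallow for a real amplification curve")
    return float(10.0 ** (-1.0 / slope))


def relative_expression(
    e_target: float,
    e_ref: float,
    cq_target_sample: float,
    cq_target_calibrator: float,
    cq_ref_sample: float,
    cq_ref_calibrator: float,
    method: str = "pfaffl",
) -> float:
    """Efficiency-corrected fold change of a target gene vs a calibrator sample,
    normalized to a reference gene.

    ``pfaffl`` (default): ``E_t^(Cq_t,cal − Cq_t,s) / E_r^(Cq_r,cal − Cq_r,s)``.
    ``ddcq``: ``2^−ddCq`` with ``ddCq = (Cq_t,s − Cq_r,s) − (Cq_t,cal −
    Cq_r,cal)`` — identical to Pfaffl when both efficiencies are 2.
    """
    for e, who in ((e_target, "target"), (e_ref, "reference")):
        if not (1.0 < e <= 2.2):
            raise ValueError(f"{who} efficiency {e} outside (1, 2.2]")
    d_target = cq_target_calibrator - cq_target_sample
    d_ref = cq_ref_calibrator - cq_ref_sample
    if method == "pfaffl":
        return float(e_target**d_target / e_ref**d_ref)
    if method == "ddcq":
        ddcq = (cq_target_sample - cq_ref_sample) - (cq_target_calibrator - cq_ref_calibrator)
        return float(2.0 ** (-ddcq))
    raise ValueError(f"unknown method: {method!r}")
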