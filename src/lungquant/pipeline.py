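"""End-to-end orchestration: phantom or CT file → segmentation → densitometry
→ pattern quantification, with deterministic reports and full provenance.

A pipeline run is described by a single JSON-able config dict with exactly one
image source:

* ``{"phantom": {...PhantomSpec fields..., "lesions": [...]}}`` — generate a
  synthetic thorax (ground truth is written next to the reports), or
* ``{"input": "ct.nii.gz"}`` — analyze an existing scan.

Optional keys: ``height_cm``, ``seed``, ``segmentation`` (SegmentationParams
fields), ``densitometry`` ({"convention", "exclude_vessels"}), ``patterns``
({"stride", "box_edge", "signatures" path, "n_train_per_class",
"include_honeycomb_in_involved"}). For phantom runs signatures are trained
from the phantom's own truth boxes unless a signature file is given; for file
inputs a signature file is required to run the pattern stage (it is skipped,
with a note in the provenance, when absent).

Outputs in ``out_dir``: ``densitometry.json``, ``patterns_zones.csv``,
``patterns_summary.json``, ``provenance.json`` (plus the phantom volumes for
phantom runs). Reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .densitometry import run_densitometry
from .phantom import LesionSpec, PhantomSpec, generate_labeled_boxes, generate_phantom
from .patterns import SignatureSet, classify_parenchyma, summarize_patterns, train_signatures
from .segmentation import SegmentationParams, build_zone_map, segment_lungs
from .volume_io import (
    OrganLabelMap,
    read_volume,
    write_labelmap,
    write_report,
    write_volume,
)

__all__ = ["ConfigError", "StageError", "phantom_spec_from_dict", "run_pipeline"]


class ConfigError(ValueError):
    """The pipeline config violates its schema."""


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    lesions = tuple(
        LesionSpec(**{**l, "radius_range": tuple(l.get("radius_range", (3.0, 6.0)))})
        for l in d.pop("lesions", [])
    )
    for key in ("shape", "spacing"):
        if key in d:
            d[key] = tuple(d[key])
    try:
        return PhantomSpec(lesions=lesions, **d)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _validate(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a JSON object")
    has_input = "input" in cfg
    has_phantom = "phantom" in cfg
    if has_input == has_phantom:
        raise ConfigError("config must contain exactly one of 'input' or 'phantom'")
    known = {
        "input",
        "phantom",
        "height_cm",
        "seed",
        "segmentation",
        "densitometry",
        "patterns",
        "out_dir",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Run every stage the config enables and write reports into ``out_dir``.

    Returns a dict of output paths plus the in-memory stage results. Raises
    :class:`ConfigError` for schema violations and :class:`StageError` when a
    stage fails.
    """
    _validate(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    provenance: dict = {"software_version": __version__, "seed": seed, "config": cfg}
    outputs: dict = {"out_dir": str(out_dir)}

    # --- image source -----------------------------------------------------
    bundle = None
    if "phantom" in cfg:
        try:
            spec = phantom_spec_from_dict({"seed": seed, **cfg["phantom"]})
            bundle = generate_phantom(spec)
            ct = bundle.ct
            write_volume(ct, out_dir / "phantom_ct.nii.gz")
            write_labelmap(bundle.organ_truth, out_dir / "phantom_organ_truth.nii.gz")
            bundle.truth_summary.to_csv(out_dir / "phantom_truth_summary.csv", index=False)
            provenance["phantom_spec"] = json.loads(json.dumps(asdict(spec)))
        except ConfigError:
            raise
        except Exception as exc:
            raise StageError("phantom", exc) from exc
    else:
        try:
            ct = read_volume(cfg["input"])
            provenance["input"] = str(cfg["input"])
        except Exception as exc:
            raise StageError("read", exc) from exc

    # --- segmentation -----------------------------------------------------
    seg_cfg = cfg.get("segmentation", {})
    try:
        params = SegmentationParams(**seg_cfg)
        organ = segment_lungs(ct, params)
        zones = build_zone_map(organ, ct.spacing, params)
        write_labelmap(organ, out_dir / "organ_labels.nii.gz")
        provenance["segmentation"] = asdict(params)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("segmentation", exc) from exc

    # --- densitometry -----------------------------------------------------
    dens_cfg = cfg.get("densitometry", {})
    try:
        result = run_densitometry(
            ct,
            organ,
            height_cm=cfg.get("height_cm"),
            convention=dens_cfg.get("convention", "air_referenced"),
            exclude_vessels=dens_cfg.get("exclude_vessels", False),
        )
        table = result.to_result_table(provenance={**provenance, "stage": "densitometry"})
        outputs["densitometry"] = str(write_report(table, out_dir / "densitometry.json"))
        outputs["densitometry_result"] = result
    except Exception as exc:
        raise StageError("densitometry", exc) from exc

    # --- parenchymal patterns --------------------------------------------
    pat_cfg = cfg.get("patterns", {})
    sigs = None
    try:
        if pat_cfg.get("signatures"):
            sigs = SignatureSet.from_json(pat_cfg["signatures"])
        elif bundle is not None:
            boxes = generate_labeled_boxes(
                bundle,
                n_per_class=int(pat_cfg.get("n_train_per_class", 30)),
                box_edge=int(pat_cfg.get("box_edge", 15)),
            )
            sigs = train_signatures(boxes)
            sigs.to_json(out_dir / "signatures.json")
        if sigs is None:
            provenance["patterns"] = "skipped: no signature set supplied"
        else:
            pmap = classify_parenchyma(
                ct,
                organ,
                sigs,
                stride=int(pat_cfg.get("stride", 1)),
                box_edge=int(pat_cfg.get("box_edge", 15)),
            )
            summary = summarize_patterns(
                pmap,
                zones,
                ct.spacing,
                include_honeycomb_in_involved=bool(
                    pat_cfg.get("include_honeycomb_in_involved", False)
                ),
            )
            summary.per_zone.to_csv(out_dir / "patterns_zones.csv", index=False)
            (out_dir / "patterns_summary.json").write_text(
                json.dumps(summary.totals, indent=2, sort_keys=True) + "\n"
            )
            outputs["patterns_zones"] = str(out_dir / "patterns_zones.csv")
            outputs["patterns_summary"] = str(out_dir / "patterns_summary.json")
            outputs["pattern_summary_result"] = summary
    except Exception as exc:
        raise StageError("patterns", exc) from exc

    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str) + "\n"
    )
    outputs["provenance"] = str(out_dir / "provenance.json")
    return outputs
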