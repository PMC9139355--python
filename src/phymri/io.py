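"""Reading and writing cases, maps and reports.

Volumes are stored as NIfTI (one file per series/map) with a JSON sidecar
carrying the entity label, seeds and scalar ground truth; feature tables
and confusion matrices as CSV; evaluation reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .cohort import SyntheticCase

__all__ = ["write_case", "read_case", "validate_geometry",
           "write_report", "read_report"]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_case(case: SyntheticCase, directory) -> Path:
    """Write one case as NIfTI volumes plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(case.spacing)

    def save(name, array):
        img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), aff)
        nib.save(img, directory / f"{name}.nii.gz")

    for name, arr in case.series.items():
        save(name, arr)
    save("mask_tumor", case.tumor_mask.astype(np.uint8))
    save("mask_edema", case.edema_mask.astype(np.uint8))
    for name, arr in case.truth.items():
        if isinstance(arr, np.ndarray):
            save(f"truth_{name}", arr.astype(np.float32))
    sidecar = {
        "entity_label": case.entity_label,
        "spacing": list(case.spacing),
        "seed": case.seed,
        "mti_clockwise": bool(case.truth.get("mti_clockwise", False)),
        "aif_ge": None if case.aif_ge is None else case.aif_ge.tolist(),
        "aif_se": None if case.aif_se is None else case.aif_se.tolist(),
    }
    (directory / "case.json").write_text(json.dumps(sidecar, indent=1))
    return directory


def read_case(directory) -> SyntheticCase:
    """Read a case written by :func:`write_case`; validates the geometry."""
    directory = Path(directory)
    sidecar = json.loads((directory / "case.json").read_text())
    volumes = {}
    for path in sorted(directory.glob("*.nii.gz")):
        img = nib.load(path)
        volumes[path.name.replace(".nii.gz", "")] = np.asarray(img.dataobj)
    validate_geometry({k: v for k, v in volumes.items()})
    series = {k: v for k, v in volumes.items()
              if not k.startswith(("mask_", "truth_"))}
    truth = {k[len("truth_"):]: v for k, v in volumes.items()
             if k.startswith("truth_")}
    truth["brain_mask"] = truth.get(
        "brain_mask", np.ones(volumes["mask_tumor"].shape)).astype(bool)
    truth["mti_clockwise"] = sidecar["mti_clockwise"]
    case = SyntheticCase(
        entity_label=sidecar["entity_label"],
        spacing=tuple(sidecar["spacing"]),
        tumor_mask=volumes["mask_tumor"].astype(bool),
        edema_mask=volumes["mask_edema"].astype(bool),
        truth=truth,
        series=series,
        seed=sidecar["seed"],
    )
    if sidecar.get("aif_ge") is not None:
        case.aif_ge = np.asarray(sidecar["aif_ge"])
    if sidecar.get("aif_se") is not None:
        case.aif_se = np.asarray(sidecar["aif_se"])
    return case


def validate_geometry(volumes: dict) -> None:
    """Check that all volumes share the same spatial grid."""
    ref_name, ref_shape = None, None
    for name, arr in volumes.items():
        shape = np.asarray(arr).shape[:3]
        if ref_shape is None:
            ref_name, ref_shape = name, shape
        elif shape != ref_shape:
            raise ValueError(
                f"volume {name!r} grid {shape} differs from "
                f"{ref_name!r} grid {ref_shape}")


def _jsonable(obj):
    import pandas as pd

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report, path) -> Path:
    """Serialize an :class:`~phymri.classify.EvaluationReport` to JSON."""
    from dataclasses import asdict

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = _jsonable(asdict(report))
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
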