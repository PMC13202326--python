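"""Case persistence: one directory per case, NIfTI volumes + YAML metadata.

Layout::

    <case_dir>/
      ct.nii.gz            CT in HU (float32)
      dose.nii.gz          reference dose, relative units (float32)
      masks/<name>.nii.gz  binary structure masks (uint8)
      case.yaml            case_id, prescription, flags, meta, grid geometry

The affine is diagonal spacing with the origin in the translation column
(RL/AP/SI axis order).  Reading revalidates every case invariant.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List

import nibabel as nib
import numpy as np
import yaml

from .core import (
    Case,
    Prescription,
    StructureMask,
    StructureSet,
    VolumeGrid,
    REQUIRED_STRUCTURES,
)

__all__ = ["write_case", "read_case", "read_dataset", "run_manifest"]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _save_volume(path: Path, values: np.ndarray, spacing, origin, dtype) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=dtype), _affine(spacing, origin))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def _load_volume(path: Path):
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return np.asarray(img.dataobj), spacing, origin


def write_case(case: Case, case_dir) -> None:
    """Serialize one case (volumes as NIfTI, metadata as YAML)."""
    case_dir = Path(case_dir)
    (case_dir / "masks").mkdir(parents=True, exist_ok=True)
    sp, og = case.ct.spacing, case.ct.origin
    _save_volume(case_dir / "ct.nii.gz", case.ct.values, sp, og, np.float32)
    _save_volume(case_dir / "dose.nii.gz", case.dose.values, sp, og, np.float32)
    for name, sm in sorted(case.structures.masks.items()):
        _save_volume(case_dir / "masks" / f"{name}.nii.gz", sm.mask.astype(np.uint8), sp, og, np.uint8)
    meta = {
        "case_id": case.case_id,
        "prescription": {
            "dose_gy_rbe": case.prescription.dose_gy_rbe,
            "fractions": case.prescription.fractions,
            "protocol_id": case.prescription.protocol_id,
        },
        "spacing_mm": list(sp),
        "origin_mm": list(og),
        "flags": {k: bool(v) for k, v in sorted(case.structures.flags.items())},
        "meta": case.meta,
    }
    (case_dir / "case.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_case(case_dir, validate: bool = True) -> Case:
    """Load a case directory and revalidate its invariants."""
    case_dir = Path(case_dir)
    meta_path = case_dir / "case.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"{meta_path} missing; not a case directory")
    meta = yaml.safe_load(meta_path.read_text())
    ct_vals, spacing, origin = _load_volume(case_dir / "ct.nii.gz")
    file_sp = tuple(float(s) for s in meta["spacing_mm"])
    if not np.allclose(spacing, file_sp, atol=1e-5):
        raise ValueError(f"spacing mismatch between NIfTI ({spacing}) and case.yaml ({file_sp})")
    dose_vals, d_sp, d_og = _load_volume(case_dir / "dose.nii.gz")
    if not (np.allclose(spacing, d_sp, atol=1e-5) and np.allclose(origin, d_og, atol=1e-4)):
        raise ValueError("dose grid geometry differs from CT")
    if dose_vals.shape != ct_vals.shape:
        raise ValueError("dose shape differs from CT")

    ss = StructureSet(flags={k: bool(v) for k, v in meta.get("flags", {}).items()})
    for mask_file in sorted((case_dir / "masks").glob("*.nii.gz")):
        name = mask_file.name[: -len(".nii.gz")]
        mvals, m_sp, _ = _load_volume(mask_file)
        if not np.allclose(spacing, m_sp, atol=1e-5):
            raise ValueError(f"mask '{name}' spacing differs from CT")
        if mvals.shape != ct_vals.shape:
            raise ValueError(f"mask '{name}' shape differs from CT")
        ss.add(StructureMask(name, mvals.astype(bool), spacing))
    ss.require(REQUIRED_STRUCTURES)

    rx = meta["prescription"]
    case = Case(
        case_id=str(meta["case_id"]),
        ct=VolumeGrid(np.asarray(ct_vals, float), spacing, origin),
        structures=ss,
        dose=VolumeGrid(np.asarray(dose_vals, float), spacing, origin),
        prescription=Prescription(
            float(rx["dose_gy_rbe"]), int(rx["fractions"]), str(rx.get("protocol_id", ""))
        ),
        meta=meta.get("meta", {}) or {},
    )
    if validate:
        case.validate(normalized=True)
    return case


def read_dataset(data_dir) -> List[Case]:
    """Load every case directory (those containing case.yaml) under data_dir."""
    data_dir = Path(data_dir)
    dirs = sorted(p.parent for p in data_dir.glob("*/case.yaml"))
    if not dirs:
        raise FileNotFoundError(f"no case directories under {data_dir}")
    return [read_case(d) for d in dirs]


def run_manifest(config: Dict) -> Dict:
    """Reproducibility manifest: config hash plus library versions."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "gradose_version": __version__,
        "numpy_version": np.__version__,
    }
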