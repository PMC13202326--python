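"""Domain types and grid-level operations for dose-prediction workflows.

The package works on regular 3D grids with physical voxel spacing in mm, with
axes fixed as (Right–Left, Anterior–Posterior, Superior–Inferior).  A *case*
bundles a CT volume (HU), a named set of binary structure masks, a reference
dose volume in relative units, and the prescription that anchors absolute
dose thresholds.

Dose normalization follows the clinical convention of the modelled cohort:
the dose covering 50% of the CTV (its voxel-wise median) is scaled to 1.0,
so trained models operate on relative dose regardless of protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "StructureMask",
    "StructureSet",
    "Prescription",
    "Case",
    "REQUIRED_STRUCTURES",
    "normalize_ct",
    "normalize_dose_to_ctv",
    "rescale_prediction_to_prescription",
    "expand_mask",
    "derived_masks",
    "mask_volume_cm3",
]

#: Structures every valid case must carry (optional: GTV).
REQUIRED_STRUCTURES = ("CTV", "PTV", "liver", "spinal_cord", "intestines", "body")

#: Default HU window for min-max CT normalization (air to dense bone).
DEFAULT_HU_RANGE = (-1000.0, 2000.0)


@dataclass
class VolumeGrid:
    """A scalar field on a regular 3D grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values (HU, relative dose, or unitless).
    spacing : tuple of float
        Voxel spacing (sx, sy, sz) in mm; strictly positive.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry and different values."""
        return VolumeGrid(values=values, spacing=self.spacing, origin=self.origin)

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class StructureMask:
    """A named binary region of interest on a regular grid."""

    name: str
    mask: np.ndarray
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 3:
            raise ValueError(f"mask '{self.name}' must be 3D, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask '{self.name}' must be binary, found values {uniq[:5]}")
            arr = arr.astype(bool)
        self.mask = arr
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def __bool__(self) -> bool:  # nonempty test
        return bool(self.mask.any())


@dataclass
class StructureSet:
    """Named binary masks sharing one grid.

    ``flags`` records provenance decisions (e.g. ``normal_liver_from_ctv``
    when the GTV is absent and the normal liver falls back to liver minus CTV).
    """

    masks: Dict[str, StructureMask] = field(default_factory=dict)
    flags: Dict[str, bool] = field(default_factory=dict)

    def __getitem__(self, name: str) -> StructureMask:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(f"structure '{name}' not present; have {sorted(self.masks)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> Tuple[str, ...]:
        return tuple(self.masks)

    def add(self, mask: StructureMask) -> None:
        self.masks[mask.name] = mask

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.masks]
        if missing:
            raise KeyError(f"missing required structure(s): {missing}")

    def validate(self) -> None:
        """Check shape agreement, required names, and containment invariants."""
        self.require(REQUIRED_STRUCTURES)
        shapes = {m.mask.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks disagree on shape: {shapes}")
        body = self["body"].mask
        for name, sm in self.masks.items():
            if name == "body":
                continue
            if np.any(sm.mask & ~body):
                raise ValueError(f"structure '{name}' extends outside the body mask")
        if np.any(self["CTV"].mask & ~self["PTV"].mask):
            raise ValueError("CTV is not contained in PTV")


@dataclass(frozen=True)
class Prescription:
    """Prescribed total dose and fractionation.

    The two protocols of the modelled cohort are 66 Gy(RBE) in 10 fractions
    (primary tumours) and 64 Gy(RBE) in 8 fractions (metastases); other
    protocols are accepted but not sampled by the phantom generator.
    """

    dose_gy_rbe: float
    fractions: int
    protocol_id: str = ""

    def __post_init__(self) -> None:
        if self.dose_gy_rbe <= 0:
            raise ValueError("prescription dose must be positive")
        if self.fractions <= 0:
            raise ValueError("fraction count must be positive")

    @property
    def dose_per_fraction(self) -> float:
        return self.dose_gy_rbe / self.fractions


PROTOCOL_66_10 = Prescription(66.0, 10, "66Gy(RBE)/10fx")
PROTOCOL_64_8 = Prescription(64.0, 8, "64Gy(RBE)/8fx")


@dataclass
class Case:
    """CT + structures + reference dose + prescription: the unit of training."""

    case_id: str
    ct: VolumeGrid
    structures: StructureSet
    dose: VolumeGrid
    prescription: Prescription
    meta: Dict = field(default_factory=dict)

    def validate(self, normalized: bool = True) -> None:
        self.structures.validate()
        for name, grid in (("dose", self.dose),):
            if not self.ct.same_geometry(grid):
                raise ValueError(f"{name} grid geometry differs from CT")
        for name, sm in self.structures.masks.items():
            if sm.mask.shape != self.ct.shape:
                raise ValueError(f"mask '{name}' shape differs from CT")
        if np.any(self.dose.values < 0):
            raise ValueError("dose contains negative values")
        if normalized:
            ctv = self.structures["CTV"].mask
            med = float(np.median(self.dose.values[ctv]))
            if abs(med - 1.0) > 1e-6:
                raise ValueError(f"median CTV dose is {med:.8f}, expected 1.0 +/- 1e-6")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def normalize_ct(ct: VolumeGrid, hu_range: Tuple[float, float] = DEFAULT_HU_RANGE) -> VolumeGrid:
    """Min-max rescale HU values to [0, 1], clipping outside ``hu_range``."""
    low, high = float(hu_range[0]), float(hu_range[1])
    if not low < high:
        raise ValueError(f"hu_range must satisfy low < high, got {hu_range}")
    v = ct.values
    if not np.all(np.isfinite(v)):
        raise ValueError("CT contains non-finite HU values")
    out = np.clip((v - low) / (high - low), 0.0, 1.0)
    return ct.with_values(out)


def normalize_dose_to_ctv(dose: VolumeGrid, ctv: StructureMask) -> Tuple[VolumeGrid, float]:
    """Scale the dose so its CTV median (D50%) equals 1.0.

    Returns the scaled grid and the applied scale factor 1 / median.
    """
    if not ctv:
        raise ValueError("CTV mask is empty; cannot normalize")
    med = float(np.median(dose.values[ctv.mask]))
    if med <= 0:
        raise ValueError(f"median CTV dose is {med}; degenerate plan")
    scale = 1.0 / med
    return dose.with_values(dose.values * scale), scale


def rescale_prediction_to_prescription(pred: VolumeGrid, ctv: StructureMask) -> VolumeGrid:
    """Renormalize a predicted dose so the prescription covers 50% of the CTV.

    Identical contract to :func:`normalize_dose_to_ctv`; applied to every
    model output before evaluation.
    """
    out, _ = normalize_dose_to_ctv(pred, ctv)
    return out


def _ellipsoid_footprint(
    margins_mm: Tuple[float, float, float], spacing: Tuple[float, float, float]
) -> np.ndarray:
    """Binary structuring element: voxel centers inside the margin ellipsoid."""
    radii_vox = [m / s for m, s in zip(margins_mm, spacing)]
    half = [int(np.floor(r)) for r in radii_vox]
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    q = np.zeros_like(grids[0], dtype=float)
    for g, m, s in zip(grids, margins_mm, spacing):
        if m > 0:
            q = q + (g * s / m) ** 2
        else:
            # zero margin on this axis: only the zero offset is admissible
            q = q + np.where(g == 0, 0.0, np.inf)
    return q <= 1.0 + 1e-12


def expand_mask(mask: StructureMask, margins_mm: Tuple[float, float, float]) -> StructureMask:
    """Minkowski dilation by an anisotropic ellipsoid given in physical mm.

    An output voxel is set iff some input voxel center lies within the
    ellipsoid with semi-axes ``margins_mm`` centered on it.  Margins of zero
    give the identity.
    """
    margins = tuple(float(m) for m in margins_mm)
    if any(m < 0 for m in margins):
        raise ValueError(f"margins must be non-negative, got {margins}")
    if all(m == 0 for m in margins):
        return StructureMask(mask.name, mask.mask.copy(), mask.spacing)
    footprint = _ellipsoid_footprint(margins, mask.spacing)
    dilated = ndimage.binary_dilation(mask.mask, structure=footprint)
    return StructureMask(mask.name, dilated, mask.spacing)


def derived_masks(ss: StructureSet) -> StructureSet:
    """Add the derived ROIs used by the DVH loss and evaluation.

    ``normal_liver``   liver minus GTV (falls back to liver minus CTV when the
                       GTV is absent; flagged as ``normal_liver_from_ctv``).
    ``out_of_roi_body``  body minus (CTV | PTV | liver | spinal_cord | intestines);
                       the region whose 10%-isodose volume tracks the beam path.
    """
    ss.require(REQUIRED_STRUCTURES)
    liver = ss["liver"].mask
    spacing = ss["liver"].spacing
    out = StructureSet(masks=dict(ss.masks), flags=dict(ss.flags))
    if "GTV" in ss and ss["GTV"]:
        normal_liver = liver & ~ss["GTV"].mask
        out.flags["normal_liver_from_ctv"] = False
    else:
        normal_liver = liver & ~ss["CTV"].mask
        out.flags["normal_liver_from_ctv"] = True
    union = np.zeros_like(liver)
    for name in ("CTV", "PTV", "liver", "spinal_cord", "intestines"):
        union |= ss[name].mask
    out.add(StructureMask("normal_liver", normal_liver, spacing))
    out.add(StructureMask("out_of_roi_body", ss["body"].mask & ~union, spacing))
    return out


def mask_volume_cm3(mask: StructureMask) -> float:
    """Physical volume of a mask in cm^3 (voxel count x voxel volume)."""
    sx, sy, sz = mask.spacing
    return mask.voxel_count * sx * sy * sz / 1000.0
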