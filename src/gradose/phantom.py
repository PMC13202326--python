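"""Seeded synthetic phantoms emulating passively scattered proton plans.

Each phantom is a liver-embedded spherical target inside an elliptical
soft-tissue body, with posterior spinal cord and anterior intestines.  The
target hierarchy follows clinical margining: CTV = GTV + 5 mm, PTV = CTV +
5 mm (RL/AP) / 7 mm (SI).  Dose is an analytic spread-out-Bragg-peak (SOBP)
surrogate: along each beam a reduced entrance plateau ramps up to a flat
SOBP spanning the PTV depth extent, then falls as a half-Gaussian beyond the
distal edge; laterally the beam is shaped by the PTV projection dilated by
an aperture margin and smoothed by a penumbra sigma.  Two beam angles are
chosen per case by a planner surrogate — shortest tissue path to the
target, organ-at-risk avoidance, and a prior for the clinically frequent
sectors (left-lateral entries excluded) — so beam placement is a function
of the visible anatomy, as in clinical practice.  The two beams are summed
and the result normalized so the CTV median dose equals the prescription.

The surrogate is geometric (depth is not water-equivalent) — it reproduces
the *shape* features the dose-gradient loss targets (flat plateau, sharp
distal and lateral fall-off, beam corridors), not a commissioned beam model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    PROTOCOL_64_8,
    PROTOCOL_66_10,
    Case,
    Prescription,
    StructureMask,
    StructureSet,
    VolumeGrid,
    derived_masks,
    expand_mask,
    normalize_dose_to_ctv,
)
from .losses import gradient_magnitude

__all__ = [
    "PhantomConfig",
    "TRAIN_SECTOR_WEIGHTS",
    "build_anatomy",
    "beam_dose",
    "compose_case",
    "generate_dataset",
    "gradient_contrast",
]

#: Beam-angle frequency (%) per 30 deg sector observed in the modelled
#: clinical training cohort; sectors 60-145 deg (left-lateral, through
#: bowel/stomach) were never used and are excluded from sampling.
TRAIN_SECTOR_WEIGHTS: Dict[int, float] = {
    0: 10.8, 30: 0.6, 150: 9.1, 180: 23.4, 210: 4.9,
    240: 7.1, 270: 33.8, 300: 5.8, 330: 4.5,
}


@dataclass
class PhantomConfig:
    """Geometry, beam, and sampling parameters of the phantom generator."""

    shape: Tuple[int, int, int] = (48, 48, 48)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    gtv_radius_range_mm: Tuple[float, float] = (6.0, 10.0)
    ctv_margin_mm: Tuple[float, float, float] = (5.0, 5.0, 5.0)
    ptv_margin_mm: Tuple[float, float, float] = (5.0, 5.0, 7.0)
    n_beams: int = 2
    min_beam_separation_deg: float = 30.0
    sector_weights: Dict[int, float] = field(default_factory=lambda: dict(TRAIN_SECTOR_WEIGHTS))
    entrance_plateau_fraction: float = 0.7
    distal_falloff_sigma_mm: float = 3.0
    lateral_penumbra_sigma_mm: float = 4.0
    aperture_margin_mm: float = 7.0
    sobp_margin_mm: float = 3.0
    min_entry_depth_mm: float = 18.0  # GTV clearance below the body surface
    p_protocol_66: float = 0.75  # ~3:1 mixture of 66 Gy/10 fx vs 64 Gy/8 fx
    hu_noise_sd: float = 8.0
    max_tries: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.entrance_plateau_fraction < 1.0:
            raise ValueError("entrance plateau fraction must be in (0, 1)")
        if self.distal_falloff_sigma_mm <= 0 or self.lateral_penumbra_sigma_mm <= 0:
            raise ValueError("fall-off sigmas must be positive")
        total = sum(self.sector_weights.values())
        if total <= 0:
            raise ValueError("sector weights must have positive sum")
        self.sector_weights = {k: v / total for k, v in self.sector_weights.items()}

    @property
    def origin(self) -> Tuple[float, float, float]:
        # grid centered on the physical origin
        return tuple(-(n - 1) * s / 2.0 for n, s in zip(self.shape, self.spacing))


def _coords_mm(cfg: PhantomConfig):
    ax = [o + np.arange(n) * s for o, n, s in zip(cfg.origin, cfg.shape, cfg.spacing)]
    return np.meshgrid(*ax, indexing="ij")


def _ellipsoid(x, y, z, center, semi) -> np.ndarray:
    q = ((x - center[0]) / semi[0]) ** 2 + ((y - center[1]) / semi[1]) ** 2
    if semi[2] is not None:
        q = q + ((z - center[2]) / semi[2]) ** 2
    return q <= 1.0


def build_anatomy(cfg: PhantomConfig, rng) -> Tuple[VolumeGrid, StructureSet]:
    """Sample CT and structure set: body, liver, cord, intestines, GTV/CTV/PTV.

    The GTV center is drawn uniformly from liver voxels deep enough (by the
    Euclidean distance transform) that the whole sphere stays inside the
    liver; after ``max_tries`` failed radius draws a ValueError is raised.
    """
    rng = np.random.default_rng(rng)
    x, y, z = _coords_mm(cfg)
    Lx = cfg.shape[0] * cfg.spacing[0]
    Ly = cfg.shape[1] * cfg.spacing[1]
    Lz = cfg.shape[2] * cfg.spacing[2]

    jit = lambda lo, hi: float(rng.uniform(lo, hi))
    body = _ellipsoid(x, y, z, (0.0, 0.0, 0.0), (jit(0.44, 0.48) * Lx, jit(0.38, 0.42) * Ly, None))
    liver_center = (jit(-0.20, -0.14) * Lx, jit(-0.10, -0.04) * Ly, jit(-0.04, 0.04) * Lz)
    liver = _ellipsoid(
        x, y, z, liver_center,
        (jit(0.24, 0.28) * Lx, jit(0.20, 0.24) * Ly, jit(0.30, 0.36) * Lz),
    ) & body
    cord = (((x - 0.0) ** 2 + (y - 0.30 * Ly) ** 2) <= 4.0 ** 2) & body
    intestines = _ellipsoid(
        x, y, z, (jit(0.10, 0.18) * Lx, jit(-0.30, -0.24) * Ly, 0.0),
        (0.18 * Lx, 0.12 * Ly, 0.26 * Lz),
    ) & body & ~liver

    # GTV: sphere fully inside the liver, deep enough below the body
    # surface that the PTV plus aperture margin keeps an entrance path
    # (the modelled protocols require comparable clearances)
    depth_mm = ndimage.distance_transform_edt(liver, sampling=cfg.spacing)
    body_depth_mm = ndimage.distance_transform_edt(body, sampling=cfg.spacing)
    gtv = None
    radius = None
    for _ in range(cfg.max_tries):
        r = float(rng.uniform(*cfg.gtv_radius_range_mm))
        candidates = np.argwhere(
            (depth_mm >= r + max(cfg.spacing))
            & (body_depth_mm >= r + cfg.min_entry_depth_mm)
        )
        if len(candidates) == 0:
            continue
        ci, cj, ck = candidates[rng.integers(len(candidates))]
        center = (x[ci, cj, ck], y[ci, cj, ck], z[ci, cj, ck])
        gtv = _ellipsoid(x, y, z, center, (r, r, r))
        radius = r
        break
    if gtv is None:
        raise ValueError(
            f"no GTV of radius in {cfg.gtv_radius_range_mm} mm fits inside the liver "
            f"after {cfg.max_tries} tries"
        )

    sp = cfg.spacing
    gtv_m = StructureMask("GTV", gtv, sp)
    ctv_m = expand_mask(gtv_m, cfg.ctv_margin_mm)
    ctv_m = StructureMask("CTV", ctv_m.mask & body, sp)
    ptv_m = expand_mask(ctv_m, cfg.ptv_margin_mm)
    ptv_m = StructureMask("PTV", ptv_m.mask & body, sp)

    hu = np.full(cfg.shape, -1000.0)
    hu[body] = 40.0
    hu[intestines] = 30.0
    hu[liver] = 60.0
    hu[cord] = 45.0
    hu[gtv] = 70.0
    hu[body] += rng.normal(0.0, cfg.hu_noise_sd, size=int(body.sum()))
    ct = VolumeGrid(hu, sp, cfg.origin)

    ss = StructureSet()
    for m in (
        StructureMask("body", body, sp),
        StructureMask("liver", liver, sp),
        StructureMask("spinal_cord", cord, sp),
        StructureMask("intestines", intestines, sp),
        gtv_m, ctv_m, ptv_m,
    ):
        ss.add(m)
    ss.meta_gtv_radius_mm = radius  # type: ignore[attr-defined]
    return ct, ss


# ---------------------------------------------------------------------------
# Beam model
# ---------------------------------------------------------------------------

def _beam_geometry(ss: StructureSet, angle_deg: float, cfg: PhantomConfig) -> Dict:
    """Shared ray-binning geometry for one axial beam angle.

    Angle 0 enters anteriorly; angles increase so that ~270 deg enters from
    the patient's right (through the liver), matching the dominant clinical
    sector.  Rays run along the propagation direction u; each voxel is keyed
    to a (lateral, SI) ray bin to find the per-ray body entry depth.
    """
    if angle_deg % 5 != 0:
        raise ValueError(f"beam angle must lie on the 5-degree grid, got {angle_deg}")
    body = ss["body"].mask
    ptv = ss["PTV"].mask
    if not ptv.any():
        raise ValueError("PTV is empty; beam has no target")
    sp = ss["body"].spacing
    shape = body.shape
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, sp))
    ax = [o + np.arange(n) * s for o, n, s in zip(origin, shape, sp)]
    x, y, _ = np.meshgrid(*ax, indexing="ij")

    th = np.deg2rad(angle_deg)
    ux, uy = -np.sin(th), np.cos(th)
    t = x * ux + y * uy                     # along-beam coordinate (mm)
    s = x * np.cos(th) + y * np.sin(th)     # in-plane lateral coordinate (mm)

    hs = min(sp[0], sp[1])
    s_min = s.min()
    i_s = np.clip(np.rint((s - s_min) / hs).astype(np.int64), 0, None)
    n_s = int(i_s.max()) + 1
    i_z = np.broadcast_to(np.arange(shape[2]), shape)
    key = i_s * shape[2] + i_z

    t0 = np.full(n_s * shape[2], np.inf)
    np.minimum.at(t0, key[body], t[body])

    proj = np.zeros((n_s, shape[2]), dtype=bool)
    proj[i_s[ptv], i_z[ptv]] = True
    # aperture = PTV projection + margin (ellipse in physical mm)
    rm_s = cfg.aperture_margin_mm / hs
    rm_z = cfg.aperture_margin_mm / sp[2]
    ds, dz = np.meshgrid(
        np.arange(-int(rm_s), int(rm_s) + 1), np.arange(-int(rm_z), int(rm_z) + 1), indexing="ij"
    )
    foot = (ds / max(rm_s, 1e-9)) ** 2 + (dz / max(rm_z, 1e-9)) ** 2 <= 1.0
    aperture = ndimage.binary_dilation(proj, structure=foot)

    return {
        "t": t, "key": key, "t0_ray": t0, "i_s": i_s, "i_z": i_z,
        "aperture": aperture, "proj": proj, "hs": hs, "sz": sp[2],
        "t_prox": float(t[ptv].min()), "t_dist": float(t[ptv].max()),
        "body": body, "shape": shape, "spacing": sp, "origin": origin,
    }


def beam_dose(ss: StructureSet, angle_deg: float, cfg: PhantomConfig) -> VolumeGrid:
    """Analytic SOBP dose of a single beam (relative units, SOBP plateau = 1)."""
    g = _beam_geometry(ss, angle_deg, cfg)
    t, body = g["t"], g["body"]
    t0 = g["t0_ray"][g["key"]]
    tp = g["t_prox"] - cfg.sobp_margin_mm
    td = g["t_dist"] + cfg.sobp_margin_mm
    pf = cfg.entrance_plateau_fraction
    sig = cfg.distal_falloff_sigma_mm

    with np.errstate(invalid="ignore", divide="ignore"):
        ramp_len = tp - t0
        frac = np.where(ramp_len > 1e-9, (t - t0) / np.where(ramp_len > 1e-9, ramp_len, 1.0), 1.0)
        entrance = pf + (1.0 - pf) * np.clip(frac, 0.0, 1.0)
    past = t - td
    distal = np.exp(-0.5 * (np.maximum(past, 0.0) / sig) ** 2)
    longitudinal = np.where(t < tp, entrance, np.where(t <= td, 1.0, distal))
    longitudinal = np.where(past > 4.0 * sig, 0.0, longitudinal)
    longitudinal = np.where(np.isfinite(t0), longitudinal, 0.0)

    smooth = ndimage.gaussian_filter(
        g["aperture"].astype(float),
        sigma=(cfg.lateral_penumbra_sigma_mm / g["hs"], cfg.lateral_penumbra_sigma_mm / g["sz"]),
    )
    transverse = smooth[g["i_s"], g["i_z"]]

    dose = longitudinal * transverse
    dose[~body] = 0.0
    np.clip(dose, 0.0, None, out=dose)
    return VolumeGrid(dose, g["spacing"], g["origin"])


def _angle_score(ss: StructureSet, angle_deg: int, cfg: PhantomConfig) -> float:
    """Plan-quality surrogate for one candidate angle (lower is better).

    Mean tissue path length from body entry to the PTV, plus penalties for
    the corridor traversing the spinal cord or intestines, plus a prior
    favouring the clinically frequent sectors.  Deterministic given the
    anatomy, so beam placement is predictable from the network inputs —
    the premise that lets a mask-driven model learn beam paths.
    """
    g = _beam_geometry(ss, angle_deg, cfg)
    ptv = ss["PTV"].mask
    t0 = g["t0_ray"][g["key"]]
    depth = float(np.mean((g["t"] - t0)[ptv]))
    proj_corridor = g["proj"][g["i_s"], g["i_z"]]
    corridor = g["body"] & proj_corridor & (g["t"] <= g["t_dist"])
    n_corr = max(int(corridor.sum()), 1)
    frac_cord = float((corridor & ss["spinal_cord"].mask).sum()) / n_corr
    frac_int = float((corridor & ss["intestines"].mask).sum()) / n_corr
    sector = (angle_deg // 30) * 30
    prior = -5.0 * np.log(max(cfg.sector_weights.get(sector, 0.0), 1e-12))
    return depth + 400.0 * frac_cord + 150.0 * frac_int + prior


def _sample_angles(ss: StructureSet, cfg: PhantomConfig, rng) -> List[int]:
    """Choose beam angles with the planner surrogate (seeded tie-break).

    The first beam is drawn from the three best-scoring candidates; further
    beams are the best-scoring candidates at least ``min_beam_separation_deg``
    away from every chosen one.
    """
    candidates = [s + 5 * i for s in sorted(cfg.sector_weights) for i in range(6)]
    scores = {a: _angle_score(ss, a, cfg) for a in candidates}
    order = sorted(candidates, key=lambda a: scores[a])
    angles: List[int] = [int(order[int(rng.integers(0, 3))])]
    for _ in range(cfg.n_beams - 1):
        def sep(a):
            return min(
                d if (d := abs(a - b) % 360) <= 180 else 360 - d for b in angles
            )
        legal = [a for a in order if sep(a) >= cfg.min_beam_separation_deg]
        if not legal:
            raise RuntimeError("could not find sufficiently separated beam angles")
        angles.append(int(legal[0]))
    return angles


def compose_case(cfg: PhantomConfig, seed: int, case_id: Optional[str] = None) -> Case:
    """One complete phantom case: anatomy + two-beam dose + prescription."""
    rng = np.random.default_rng(seed)
    ct, ss = build_anatomy(cfg, rng)
    angles = _sample_angles(ss, cfg, rng)
    dose_vals = np.zeros(cfg.shape)
    for ang in angles:
        dose_vals += beam_dose(ss, ang, cfg).values
    dose_vals /= len(angles)
    dose = VolumeGrid(dose_vals, cfg.spacing, cfg.origin)
    dose, scale = normalize_dose_to_ctv(dose, ss["CTV"])
    prescription = PROTOCOL_66_10 if rng.random() < cfg.p_protocol_66 else PROTOCOL_64_8
    case = Case(
        case_id=case_id or f"phantom_{seed:08d}",
        ct=ct,
        structures=derived_masks(ss),
        dose=dose,
        prescription=prescription,
        meta={
            "seed": int(seed),
            "beam_angles_deg": [int(a) for a in angles],
            "gtv_radius_mm": float(getattr(ss, "meta_gtv_radius_mm", np.nan)),
            "dose_scale": float(scale),
        },
    )
    case.validate(normalized=True)
    return case


def generate_dataset(
    cfg: PhantomConfig,
    n_cases: int,
    seed: int,
    out_dir: Optional[Path] = None,
    overwrite: bool = False,
) -> Tuple[List[Case], Dict]:
    """Generate ``n_cases`` phantoms with per-case seeds spawned from ``seed``.

    When ``out_dir`` is given, cases are written in the NIfTI-per-case layout
    together with a ``manifest.json`` recording every per-case seed, the beam
    angles and the sampled protocol.
    """
    child_seeds = [
        int(s.generate_state(1)[0] % (2 ** 31))
        for s in np.random.SeedSequence(seed).spawn(n_cases)
    ]
    cases = [compose_case(cfg, cs, case_id=f"case_{i:04d}") for i, cs in enumerate(child_seeds)]
    manifest = {
        "seed": int(seed),
        "n_cases": n_cases,
        "config": {k: v for k, v in asdict(cfg).items()},
        "cases": [
            {
                "case_id": c.case_id,
                "seed": c.meta["seed"],
                "beam_angles_deg": c.meta["beam_angles_deg"],
                "protocol": c.prescription.protocol_id,
                "gtv_radius_mm": c.meta["gtv_radius_mm"],
            }
            for c in cases
        ],
    }
    if out_dir is not None:
        from .io import write_case  # local import to avoid cycle

        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(f"output directory {out_dir} is not empty (use overwrite)")
        out_dir.mkdir(parents=True, exist_ok=True)
        for c in cases:
            write_case(c, out_dir / c.case_id)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cases, manifest


def gradient_contrast(case: Case, cfg: PhantomConfig, shell_mm: float = 6.0) -> float:
    """Ratio of mean |grad D| in the distal fall-off shell vs the entrance plateau.

    The distal shell spans ``shell_mm`` beyond the PTV's distal edge inside
    each beam's aperture corridor; the entrance region spans from 2 mm past
    body entry to 4 mm before the SOBP start.  A ratio well above 1 is the
    spatial signature the dose-gradient loss is designed to learn.
    """
    G = gradient_magnitude(case.dose).values
    ss = case.structures
    distal = np.zeros(case.dose.shape, dtype=bool)
    entrance = np.zeros(case.dose.shape, dtype=bool)
    beams = {}
    for ang in case.meta["beam_angles_deg"]:
        g = _beam_geometry(ss, ang, cfg)
        # corridor core: aperture eroded back by its own margin, i.e. the
        # target projection, away from the lateral penumbra
        rm_s = cfg.aperture_margin_mm / g["hs"]
        rm_z = cfg.aperture_margin_mm / g["sz"]
        ds, dz = np.meshgrid(
            np.arange(-int(rm_s), int(rm_s) + 1),
            np.arange(-int(rm_z), int(rm_z) + 1),
            indexing="ij",
        )
        foot = (ds / max(rm_s, 1e-9)) ** 2 + (dz / max(rm_z, 1e-9)) ** 2 <= 1.0
        core = ndimage.binary_erosion(g["aperture"], structure=foot)
        in_core = core[g["i_s"], g["i_z"]]
        # widened corridor: aperture plus the 2-sigma penumbra tail
        n_tail_s = max(int(np.ceil(2 * cfg.lateral_penumbra_sigma_mm / g["hs"])), 1)
        n_tail_z = max(int(np.ceil(2 * cfg.lateral_penumbra_sigma_mm / g["sz"])), 1)
        ts, tz = np.meshgrid(
            np.arange(-n_tail_s, n_tail_s + 1), np.arange(-n_tail_z, n_tail_z + 1), indexing="ij"
        )
        tail_foot = (ts / n_tail_s) ** 2 + (tz / n_tail_z) ** 2 <= 1.0
        wide = ndimage.binary_dilation(g["aperture"], structure=tail_foot)
        in_wide = wide[g["i_s"], g["i_z"]]
        td = g["t_dist"] + cfg.sobp_margin_mm
        # another beam's sharp zones: lateral penumbra band (incl. tail)
        # and distal fall-off
        sharp = (in_wide & ~in_core) | (in_wide & (g["t"] > td))
        beams[ang] = (g, in_core, td, sharp)
    body_interior = ndimage.binary_erosion(ss["body"].mask)
    for ang, (g, in_core, td, _) in beams.items():
        t, body = g["t"], g["body"]
        t0 = g["t0_ray"][g["key"]]
        tp = g["t_prox"] - cfg.sobp_margin_mm
        distal |= body & in_core & (t > td) & (t <= td + shell_mm)
        # entrance plateau: proximal corridor core clear of any other
        # beam's penumbra or distal fall-off (those are not plateau dose)
        # and of the body surface voxels, whose dose-to-air step is not
        # plateau structure either
        for off in (4.0, 2.0, 0.0):  # shallow targets get a shorter window
            ent = body_interior & in_core & (t >= t0 + off) & (t <= tp - off)
            for other, (_, _, _, sharp) in beams.items():
                if other != ang:
                    ent &= ~sharp
            if ent.any():
                break
        entrance |= ent
    distal &= ~ss["PTV"].mask
    if not distal.any() or not entrance.any():
        raise ValueError("degenerate beam regions; cannot compute gradient contrast")
    return float(G[distal].mean() / G[entrance].mean())
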