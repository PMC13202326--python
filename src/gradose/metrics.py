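"""Hard (non-differentiable) dosimetric evaluation.

All quantities follow standard DVH conventions: D_p% is the
linear-interpolated dose covering p% of a structure's volume; V_t uses the
>= threshold convention and V_<t its strict complement, so the pair
partitions the volume.  Target D-metrics are reported in % of prescription,
normal-liver V30 in %, V_<15 in cm^3, and 10%-isodose volumes in cm^3.

Spinal cord and intestines are excluded from quantitative metrics (their
doses sit below 10% of the prescription in the modelled cohort); their masks
still enter the weighted-MSE loss and the out-of-ROI body region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import Case, StructureMask, StructureSet, VolumeGrid, derived_masks
from .losses import gradient_magnitude

__all__ = [
    "dose_at_volume",
    "volume_at_dose",
    "mean_dose",
    "paddick_ci",
    "isodose_mask",
    "isodose_volume_errors",
    "dsc",
    "dvh_curve",
    "gradient_and_difference_maps",
    "paired_compare",
    "group_compare",
    "case_metrics",
    "cohort_report",
    "CaseMetrics",
    "CohortReport",
]


def _masked(dose, mask) -> np.ndarray:
    vals = dose.values if isinstance(dose, VolumeGrid) else np.asarray(dose)
    m = mask.mask if isinstance(mask, StructureMask) else np.asarray(mask, dtype=bool)
    out = vals[m]
    if out.size == 0:
        raise ValueError("empty mask in dose metric")
    return out


def dose_at_volume(dose, mask, p: float) -> float:
    """D_p%: the dose d such that p% of the mask's voxels receive >= d."""
    d = _masked(dose, mask)
    return float(np.percentile(d, 100.0 - p, method="linear"))


def volume_at_dose(dose, mask, threshold: float, mode: str = "percent", voxel_cm3: Optional[float] = None) -> float:
    """V_t in percent or cm^3, or V_<t in cm^3 (``mode='below_cm3'``)."""
    d = _masked(dose, mask)
    if mode == "percent":
        return float(100.0 * np.count_nonzero(d >= threshold) / d.size)
    if voxel_cm3 is None:
        if isinstance(mask, StructureMask):
            sx, sy, sz = mask.spacing
            voxel_cm3 = sx * sy * sz / 1000.0
        else:
            raise ValueError("voxel_cm3 required for volume modes with bare arrays")
    if mode == "cm3":
        return float(np.count_nonzero(d >= threshold) * voxel_cm3)
    if mode == "below_cm3":
        return float(np.count_nonzero(d < threshold) * voxel_cm3)
    raise ValueError(f"unknown mode '{mode}'")


def mean_dose(dose, mask) -> float:
    """Mean dose over the mask (relative dose)."""
    return float(_masked(dose, mask).mean())


def paddick_ci(dose, target_mask, body_mask=None, prescription_level: float = 1.0) -> float:
    """Paddick conformity index TV_PIV^2 / (TV * PIV).

    PIV is the prescription isodose volume anywhere in the body (standard
    Paddick scoping); returns 0 (flagged via the value itself) when PIV is
    empty.
    """
    vals = dose.values if isinstance(dose, VolumeGrid) else np.asarray(dose)
    tv = target_mask.mask if isinstance(target_mask, StructureMask) else np.asarray(target_mask, bool)
    piv = vals >= prescription_level
    if body_mask is not None:
        bm = body_mask.mask if isinstance(body_mask, StructureMask) else np.asarray(body_mask, bool)
        piv = piv & bm
    n_tv = int(tv.sum())
    n_piv = int(piv.sum())
    if n_tv == 0:
        raise ValueError("empty target mask in conformity index")
    if n_piv == 0:
        return 0.0
    n_ov = int((tv & piv).sum())
    return float(n_ov * n_ov / (n_tv * n_piv))


def isodose_mask(dose, level: float = 0.10, body_mask=None) -> StructureMask:
    """Voxels with relative dose >= level, restricted to the body."""
    if isinstance(dose, VolumeGrid):
        vals, spacing = dose.values, dose.spacing
    else:
        vals, spacing = np.asarray(dose), (1.0, 1.0, 1.0)
    m = vals >= level
    if body_mask is not None:
        bm = body_mask.mask if isinstance(body_mask, StructureMask) else np.asarray(body_mask, bool)
        m = m & bm
    return StructureMask(f"isodose_{level:g}", m, spacing)


def isodose_volume_errors(errors_cm3: Sequence[float]) -> Tuple[float, float]:
    """MAE and RMSE (cm^3) of per-case signed isodose-volume errors."""
    e = np.asarray(errors_cm3, dtype=float)
    if e.size == 0:
        raise ValueError("no volume errors supplied")
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e * e)))
    return mae, rmse


def dsc(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1.0 if both empty."""
    am = a.mask if isinstance(a, StructureMask) else np.asarray(a, bool)
    bm = b.mask if isinstance(b, StructureMask) else np.asarray(b, bool)
    na, nb = int(am.sum()), int(bm.sum())
    if na + nb == 0:
        return 1.0  # identical emptiness (flagged convention)
    return float(2.0 * int((am & bm).sum()) / (na + nb))


def dvh_curve(dose, mask, n_bins: int = 200, d_max: Optional[float] = None) -> pd.DataFrame:
    """Cumulative DVH: percent of the structure receiving >= each dose level."""
    d = _masked(dose, mask)
    if d_max is None:
        d_max = float(d.max())
    edges = np.linspace(0.0, max(d_max, 1e-12), n_bins)
    vol = np.array([100.0 * np.count_nonzero(d >= t) / d.size for t in edges])
    return pd.DataFrame({"dose": edges, "volume_pct": vol})


def gradient_and_difference_maps(pre: VolumeGrid, cli: VolumeGrid):
    """(G(pre), G(cli), pre - cli) for visual fall-off inspection."""
    return (
        gradient_magnitude(pre),
        gradient_magnitude(cli),
        pre.with_values(pre.values - cli.values),
    )


def plot_dvh(curves: Dict[str, pd.DataFrame], path, title: str = "") -> None:
    """Render one case's DVH curves (reference solid, predicted dashed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    colors = {"CTV": "tab:red", "PTV": "tab:orange", "normal_liver": "tab:green"}
    for name, df in curves.items():
        struct, kind = name.rsplit("_", 1)
        ax.plot(
            df.dose, df.volume_pct,
            color=colors.get(struct, "tab:gray"),
            linestyle="-" if kind == "cli" else "--",
            label=f"{struct} ({kind})",
        )
    ax.set_xlabel("relative dose")
    ax.set_ylabel("volume (%)")
    ax.set_ylim(0, 102)
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def paired_compare(pre_values: Sequence[float], cli_values: Sequence[float]) -> Dict[str, float]:
    """Two-sided Wilcoxon signed-rank test of paired metrics (zeros dropped).

    Exact small-sample p-values are used when n <= 25 and the differences are
    tie-free; all-zero differences return p = 1 with ``all_zero`` flagged.
    """
    a = np.asarray(pre_values, dtype=float)
    b = np.asarray(cli_values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return {"statistic": 0.0, "p_value": 1.0, "n_effective": 0, "all_zero": True}
    method = "exact" if (nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size) else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_effective": int(nz.size),
        "all_zero": False,
    }


def group_compare(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Two-sided Mann–Whitney U rank-sum test for independent groups."""
    res = stats.mannwhitneyu(np.asarray(x, float), np.asarray(y, float), alternative="two-sided")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Per-case and cohort reports
# ---------------------------------------------------------------------------

#: metric name -> (structure, kind, extra) rows of the per-case report
_METRIC_ORDER = [
    "ctv_d98_pct", "ctv_d2_pct", "ctv_ci",
    "ptv_d98_pct", "ptv_d2_pct", "ptv_ci",
    "nl_dmean_pct", "nl_v30_pct", "nl_vlt15_cm3",
    "isodose10_cm3",
]


@dataclass
class CaseMetrics:
    """Dose metrics of one case for the reference and predicted dose."""

    case_id: str
    cli: Dict[str, float]
    pre: Dict[str, float]
    dsc10: float

    @property
    def diff(self) -> Dict[str, float]:
        return {k: self.pre[k] - self.cli[k] for k in self.cli}


@dataclass
class CohortReport:
    """Cohort-level summary: per-case metrics, mean+-SD, isodose errors, tests."""

    cases: List[CaseMetrics]
    summary: pd.DataFrame
    isodose_mae_cm3: float
    isodose_rmse_cm3: float
    mean_dsc10: float
    p_values: Dict[str, Dict[str, float]]
    dvh_curves: Dict[str, Dict[str, pd.DataFrame]] = field(default_factory=dict)

    def to_json_dict(self) -> Dict:
        return {
            "n_cases": len(self.cases),
            "isodose10_mae_cm3": self.isodose_mae_cm3,
            "isodose10_rmse_cm3": self.isodose_rmse_cm3,
            "mean_dsc10": self.mean_dsc10,
            "summary": {
                metric: {col: float(self.summary.loc[metric, col]) for col in self.summary.columns}
                for metric in self.summary.index
            },
            "p_values": self.p_values,
        }


def _one_dose_metrics(dose: VolumeGrid, ss: StructureSet, prescription) -> Dict[str, float]:
    rx = prescription.dose_gy_rbe
    body = ss["body"]
    voxel_cm3 = dose.voxel_volume_mm3 / 1000.0
    return {
        "ctv_d98_pct": 100.0 * dose_at_volume(dose, ss["CTV"], 98.0),
        "ctv_d2_pct": 100.0 * dose_at_volume(dose, ss["CTV"], 2.0),
        "ctv_ci": paddick_ci(dose, ss["CTV"], body),
        "ptv_d98_pct": 100.0 * dose_at_volume(dose, ss["PTV"], 98.0),
        "ptv_d2_pct": 100.0 * dose_at_volume(dose, ss["PTV"], 2.0),
        "ptv_ci": paddick_ci(dose, ss["PTV"], body),
        "nl_dmean_pct": 100.0 * mean_dose(dose, ss["normal_liver"]),
        "nl_v30_pct": volume_at_dose(dose, ss["normal_liver"], 30.0 / rx, "percent"),
        "nl_vlt15_cm3": volume_at_dose(dose, ss["normal_liver"], 15.0 / rx, "below_cm3", voxel_cm3),
        "isodose10_cm3": volume_at_dose(dose, body, 0.10, "cm3", voxel_cm3),
    }


def case_metrics(case: Case, pre_dose: VolumeGrid) -> CaseMetrics:
    """All per-case metrics for a (reference, predicted) dose pair.

    ``pre_dose`` must already be rescaled to the prescription convention.
    """
    ss = case.structures
    if "normal_liver" not in ss:
        ss = derived_masks(ss)
    cli_m = _one_dose_metrics(case.dose, ss, case.prescription)
    pre_m = _one_dose_metrics(pre_dose, ss, case.prescription)
    d = dsc(
        isodose_mask(case.dose, 0.10, ss["body"]),
        isodose_mask(pre_dose, 0.10, ss["body"]),
    )
    return CaseMetrics(case.case_id, cli_m, pre_m, d)


def cohort_report(
    cases: Sequence[Case],
    pre_doses: Sequence[VolumeGrid],
    dvh_cases: Sequence[str] = (),
    dvh_bins: int = 120,
) -> CohortReport:
    """Evaluate a cohort of (case, predicted dose) pairs.

    Computes per-case metrics, cohort mean+-SD per metric for both dose sets
    and their difference, MAE/RMSE of the 10%-isodose volumes, mean DSC, and
    paired Wilcoxon tests per metric.  DVH curves (CTV, PTV, normal liver)
    are extracted for the case ids listed in ``dvh_cases``.
    """
    if len(cases) != len(pre_doses):
        raise ValueError("cases and predicted doses must pair up")
    per_case = [case_metrics(c, p) for c, p in zip(cases, pre_doses)]

    rows = {}
    p_values = {}
    for metric in _METRIC_ORDER:
        cli_v = np.array([cm.cli[metric] for cm in per_case])
        pre_v = np.array([cm.pre[metric] for cm in per_case])
        rows[metric] = {
            "cli_mean": cli_v.mean(), "cli_sd": cli_v.std(ddof=1) if len(cli_v) > 1 else 0.0,
            "pre_mean": pre_v.mean(), "pre_sd": pre_v.std(ddof=1) if len(pre_v) > 1 else 0.0,
            "diff_mean": (pre_v - cli_v).mean(),
            "diff_sd": (pre_v - cli_v).std(ddof=1) if len(cli_v) > 1 else 0.0,
        }
        p_values[metric] = paired_compare(pre_v, cli_v)
    summary = pd.DataFrame(rows).T

    errors = [cm.pre["isodose10_cm3"] - cm.cli["isodose10_cm3"] for cm in per_case]
    mae, rmse = isodose_volume_errors(errors)
    mean_dsc = float(np.mean([cm.dsc10 for cm in per_case]))

    curves: Dict[str, Dict[str, pd.DataFrame]] = {}
    want = set(dvh_cases)
    for case, pre in zip(cases, pre_doses):
        if case.case_id not in want:
            continue
        ss = derived_masks(case.structures) if "normal_liver" not in case.structures else case.structures
        curves[case.case_id] = {}
        for sname in ("CTV", "PTV", "normal_liver"):
            dmax = float(max(case.dose.values.max(), pre.values.max()))
            curves[case.case_id][f"{sname}_cli"] = dvh_curve(case.dose, ss[sname], dvh_bins, dmax)
            curves[case.case_id][f"{sname}_pre"] = dvh_curve(pre, ss[sname], dvh_bins, dmax)

    return CohortReport(per_case, summary, mae, rmse, mean_dsc, p_values, curves)
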