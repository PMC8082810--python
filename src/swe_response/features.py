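"""Derived shear-wave-elastography (SWE) features.

Each patient visit contributes three 3-mm tumor regions of interest (ROIs)
placed at the stiffest part of the lesion and one normal-tissue ROI; the
scanner reports mean/min/max shear-wave speed (SWS, m/s) per ROI.  This
module turns those raw measurements into the quantities used downstream:

* ``E_mean``, ``E_max`` — mean and maximum elasticity (kPa) of the tumor,
  from the ROI-averaged SWS via the linear-elastic conversion E = 3*rho*c^2;
* ``E_mean_ratio``, ``E_max_ratio`` — tumor-to-normal elasticity ratios;
* ``f_mass`` — mass characteristic frequency (Hz), 1000 * V_min / d, where
  V_min is the ROI-averaged minimum SWS (m/s) and d the largest B-mode mass
  dimension (mm).  Physically the inverse of the maximum shear-wave
  propagation time across the mass;
* ``V_MRI`` — MRI volume as the product of the AP/trans/SI dimensions (mm^3);
* visit-to-visit change scores, always earlier minus later.

Missing inputs propagate as NaN, never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ROIMeasurement",
    "VisitRecord",
    "VisitFeatures",
    "ChangeScores",
    "sws_to_elasticity",
    "aggregate_tumor_rois",
    "compute_f_mass",
    "compute_visit_features",
    "compute_change_scores",
    "pe_mri_volume",
    "visit_features_table",
    "change_scores_table",
]

#: assumed tissue density (kg/m^3) in the SWS -> Young's modulus conversion
TISSUE_DENSITY = 1000.0

#: change-score definitions: output column -> (feature, earlier visit, later visit)
CHANGE_SCORE_DEFS = {
    "e_mean_1_2": ("e_mean", 1, 2),
    "e_mean_1_3": ("e_mean", 1, 3),
    "e_max_1_2": ("e_max", 1, 2),
    "e_max_1_3": ("e_max", 1, 3),
    "f_mass_1_2": ("f_mass", 1, 2),
    "f_mass_1_3": ("f_mass", 1, 3),
}


@dataclass(frozen=True)
class ROIMeasurement:
    """Shear-wave-speed statistics of one region of interest (m/s)."""

    sws_mean: float
    sws_min: float
    sws_max: float
    sws_sd: float = float("nan")
    kind: str = "tumor"  # "tumor" or "normal"

    def __post_init__(self) -> None:
        if self.kind not in ("tumor", "normal"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        vals = (self.sws_mean, self.sws_min, self.sws_max)
        if any(v < 0 for v in vals if not math.isnan(v)):
            raise ValueError("shear-wave speeds must be non-negative")
        if not any(math.isnan(v) for v in vals) and not (
            self.sws_min <= self.sws_mean <= self.sws_max
        ):
            raise ValueError("ROI must satisfy sws_min <= sws_mean <= sws_max")


@dataclass(frozen=True)
class VisitRecord:
    """One patient-visit of raw measurements.

    ``mass_size_d`` is the greatest dimension of the mass on the B-mode
    image (mm).  MRI dimensions are optional (NaN when the visit had no MRI).
    """

    patient_id: str
    visit: int
    mass_size_d: float = float("nan")
    tumor_rois: tuple = ()
    normal_roi: Optional[ROIMeasurement] = None
    mri_ap: float = float("nan")
    mri_trans: float = float("nan")
    mri_si: float = float("nan")

    def __post_init__(self) -> None:
        if self.visit not in (1, 2, 3):
            raise ValueError(f"visit must be 1, 2 or 3, got {self.visit}")
        if not math.isnan(self.mass_size_d) and self.mass_size_d <= 0:
            raise ValueError("mass_size_d must be positive when present")


@dataclass(frozen=True)
class VisitFeatures:
    """Derived features of one visit (NaN where undefined)."""

    patient_id: str
    visit: int
    e_mean: float = float("nan")   # kPa
    e_max: float = float("nan")    # kPa
    e_mean_ratio: float = float("nan")
    e_max_ratio: float = float("nan")
    f_mass: float = float("nan")   # Hz
    v_mri: float = float("nan")    # mm^3


@dataclass(frozen=True)
class ChangeScores:
    """Earlier-minus-later differences of visit features (NaN where a visit is absent)."""

    patient_id: str
    e_mean_1_2: float = float("nan")
    e_mean_1_3: float = float("nan")
    e_max_1_2: float = float("nan")
    e_max_1_3: float = float("nan")
    f_mass_1_2: float = float("nan")
    f_mass_1_3: float = float("nan")


def sws_to_elasticity(c, density: float = TISSUE_DENSITY):
    """Convert shear-wave speed (m/s) to elasticity (kPa) via E = 3*rho*c^2.

    With the default soft-tissue density rho = 1000 kg/m^3 this reduces to
    E[kPa] = 3 * c^2.  Accepts scalars or arrays; NaN propagates.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c[~np.isnan(c)] < 0):
        raise ValueError("shear-wave speed must be non-negative")
    e = 3.0 * density * c**2 / 1000.0
    return float(e) if e.ndim == 0 else e


def aggregate_tumor_rois(rois) -> dict:
    """Average the three tumor ROIs statistic-by-statistic.

    Returns ``{"mean_sws", "min_sws", "max_sws"}``, each the arithmetic mean
    of the corresponding per-ROI statistic (the tumor SWS "is represented by
    the average values of the three ROIs").
    """
    rois = tuple(rois)
    if len(rois) != 3:
        raise ValueError(f"exactly 3 tumor ROIs required, got {len(rois)}")
    if any(r.kind != "tumor" for r in rois):
        raise ValueError("all aggregated ROIs must be tumor ROIs")
    return {
        "mean_sws": float(np.mean([r.sws_mean for r in rois])),
        "min_sws": float(np.mean([r.sws_min for r in rois])),
        "max_sws": float(np.mean([r.sws_max for r in rois])),
    }


def compute_f_mass(v_min, d):
    """Mass characteristic frequency f_mass = 1000 * V_min / d  (Hz).

    ``v_min`` is the ROI-averaged minimum SWS (m/s), ``d`` the largest
    B-mode mass dimension (mm).  Full precision is returned; round to the
    nearest integer Hz for display.
    """
    v_min = np.asarray(v_min, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(v_min[~np.isnan(v_min)] < 0):
        raise ValueError("v_min must be non-negative")
    if np.any(d[~np.isnan(d)] <= 0):
        raise ValueError("mass size d must be positive")
    f = 1000.0 * v_min / d
    return float(f) if f.ndim == 0 else f


def _ratio(num: float, den: float) -> float:
    if math.isnan(num) or math.isnan(den) or den == 0:
        return float("nan")
    return num / den


def compute_visit_features(
    v: VisitRecord, ratio_scale: str = "elasticity"
) -> VisitFeatures:
    """Derive all per-visit features from one raw :class:`VisitRecord`.

    ``ratio_scale`` chooses whether tumor/normal ratios are formed on the
    elasticity (kPa, default) or raw shear-wave-speed scale; with E = 3*rho*c^2
    the elasticity ratio equals the squared speed ratio.
    """
    if ratio_scale not in ("elasticity", "speed"):
        raise ValueError(f"unknown ratio_scale {ratio_scale!r}")

    e_mean = e_max = e_mean_ratio = e_max_ratio = f_mass = float("nan")
    if len(v.tumor_rois) == 3:
        agg = aggregate_tumor_rois(v.tumor_rois)
        e_mean = sws_to_elasticity(agg["mean_sws"])
        e_max = sws_to_elasticity(agg["max_sws"])
        if not math.isnan(v.mass_size_d):
            f_mass = compute_f_mass(agg["min_sws"], v.mass_size_d)
        if v.normal_roi is not None:
            if ratio_scale == "elasticity":
                e_mean_ratio = _ratio(e_mean, sws_to_elasticity(v.normal_roi.sws_mean))
                e_max_ratio = _ratio(e_max, sws_to_elasticity(v.normal_roi.sws_max))
            else:
                e_mean_ratio = _ratio(agg["mean_sws"], v.normal_roi.sws_mean)
                e_max_ratio = _ratio(agg["max_sws"], v.normal_roi.sws_max)

    v_mri = float("nan")
    if not any(math.isnan(x) for x in (v.mri_ap, v.mri_trans, v.mri_si)):
        v_mri = v.mri_ap * v.mri_trans * v.mri_si

    return VisitFeatures(
        patient_id=v.patient_id,
        visit=v.visit,
        e_mean=e_mean,
        e_max=e_max,
        e_mean_ratio=e_mean_ratio,
        e_max_ratio=e_max_ratio,
        f_mass=f_mass,
        v_mri=v_mri,
    )


def compute_change_scores(
    f1: Optional[VisitFeatures],
    f2: Optional[VisitFeatures],
    f3: Optional[VisitFeatures],
) -> ChangeScores:
    """Earlier-minus-later change scores across visits.

    Each score needs both of its visits; a missing visit (or feature) yields
    NaN for the scores that involve it and leaves the others defined.
    """
    by_visit = {1: f1, 2: f2, 3: f3}
    pid = next(f.patient_id for f in by_visit.values() if f is not None)

    def diff(attr: str, a: int, b: int) -> float:
        fa, fb = by_visit[a], by_visit[b]
        if fa is None or fb is None:
            return float("nan")
        return getattr(fa, attr) - getattr(fb, attr)

    return ChangeScores(
        patient_id=pid,
        **{
            col: diff(attr, a, b)
            for col, (attr, a, b) in CHANGE_SCORE_DEFS.items()
        },
    )


def pe_mri_volume(s0, s1, voxel_volume: float, threshold_pct: float = 70.0) -> float:
    """Contrast-MRI tumor volume by percentage-enhancement thresholding.

    PE = (S1 - S0)/S0 * 100% per voxel; the volume is ``voxel_volume`` times
    the number of voxels with PE >= ``threshold_pct`` (boundary inclusive).
    """
    s0 = np.asarray(s0, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    if s0.shape != s1.shape:
        raise ValueError("s0 and s1 must have the same shape")
    if np.any(s0 <= 0):
        raise ValueError("all precontrast intensities must be positive")
    pe = (s1 - s0) / s0 * 100.0
    return float(voxel_volume * np.count_nonzero(pe >= threshold_pct))


# ---------------------------------------------------------------------------
# table-level API (long-format CSV schema, one row per patient-visit)
# ---------------------------------------------------------------------------

RAW_VISIT_COLUMNS = (
    ["patient_id", "visit", "mass_size_mm"]
    + [f"roi{i}_sws_{s}" for i in (1, 2, 3) for s in ("mean", "min", "max", "sd")]
    + [f"normal_sws_{s}" for s in ("mean", "min", "max", "sd")]
    + ["mri_ap_mm", "mri_trans_mm", "mri_si_mm"]
)


def _record_from_row(row: pd.Series) -> VisitRecord:
    def g(col: str) -> float:
        val = row.get(col, float("nan"))
        return float("nan") if pd.isna(val) else float(val)

    rois = []
    for i in (1, 2, 3):
        stats = {s: g(f"roi{i}_sws_{s}") for s in ("mean", "min", "max", "sd")}
        if not all(math.isnan(stats[s]) for s in ("mean", "min", "max")):
            rois.append(
                ROIMeasurement(
                    sws_mean=stats["mean"],
                    sws_min=stats["min"],
                    sws_max=stats["max"],
                    sws_sd=stats["sd"],
                    kind="tumor",
                )
            )
    normal = None
    nstats = {s: g(f"normal_sws_{s}") for s in ("mean", "min", "max", "sd")}
    if not all(math.isnan(nstats[s]) for s in ("mean", "min", "max")):
        normal = ROIMeasurement(
            sws_mean=nstats["mean"],
            sws_min=nstats["min"],
            sws_max=nstats["max"],
            sws_sd=nstats["sd"],
            kind="normal",
        )
    return VisitRecord(
        patient_id=str(row["patient_id"]),
        visit=int(row["visit"]),
        mass_size_d=g("mass_size_mm"),
        tumor_rois=tuple(rois),
        normal_roi=normal,
        mri_ap=g("mri_ap_mm"),
        mri_trans=g("mri_trans_mm"),
        mri_si=g("mri_si_mm"),
    )


def visit_features_table(raw: pd.DataFrame, ratio_scale: str = "elasticity") -> pd.DataFrame:
    """Derive per-visit features for every row of a long-format raw table."""
    dup = raw.duplicated(subset=["patient_id", "visit"])
    if dup.any():
        raise ValueError("at most one record per (patient, visit)")
    rows = []
    for _, row in raw.iterrows():
        feats = compute_visit_features(_record_from_row(row), ratio_scale=ratio_scale)
        rows.append(
            {
                "patient_id": feats.patient_id,
                "visit": feats.visit,
                "mass_size_mm": row.get("mass_size_mm", float("nan")),
                "e_mean": feats.e_mean,
                "e_max": feats.e_max,
                "e_mean_ratio": feats.e_mean_ratio,
                "e_max_ratio": feats.e_max_ratio,
                "f_mass": feats.f_mass,
                "v_mri": feats.v_mri,
            }
        )
    return pd.DataFrame(rows)


def change_scores_table(features: pd.DataFrame) -> pd.DataFrame:
    """Per-patient change scores from a per-visit feature table."""
    out = []
    for pid, grp in features.groupby("patient_id", sort=True):
        by_visit = {int(r["visit"]): r for _, r in grp.iterrows()}
        rec: dict = {"patient_id": pid}
        for col, (attr, a, b) in CHANGE_SCORE_DEFS.items():
            va = by_visit.get(a)
            vb = by_visit.get(b)
            if va is None or vb is None:
                rec[col] = float("nan")
            else:
                rec[col] = va[attr] - vb[attr]
        out.append(rec)
    return pd.DataFrame(out)
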