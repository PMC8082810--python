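"""Residual cancer burden (RCB) scoring, response labels and St. Gallen subtypes.

RCB is computed from the surgical-pathology report as

    RCB = 1.4 * (f_inv * d_prim)^0.17 + [4 * (1 - 0.75^LN) * d_met]^0.17

with f_inv the invasive-cancer fraction of the tumor bed, d_prim the primary
tumor-bed dimension (mm), LN the number of positive lymph nodes and d_met the
diameter of the largest nodal metastasis (mm).  Scores are binned as category
0 (RCB = 0), I (0 < RCB <= 1.36), II (1.36 < RCB <= 3.28) or III (RCB > 3.28);
categories 0/I define responders, II/III (and patients who never reached
surgery) non-responders.

Receptor status follows ASCO/CAP practice: ER/PR positive at >= 1% immuno-
reactive cells; HER2 positive at IHC 3+ or IHC 2+ with FISH amplification.
St. Gallen subtypes partition resolved marker combinations into Luminal A,
Luminal B (HER2-), Luminal B (HER2+), HER2-positive and triple-negative,
with Ki-67 at 14% separating Luminal A from Luminal B (HER2-).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RCBInputs",
    "IHCPanel",
    "MarkerStatus",
    "ResponseLabel",
    "rcb_score",
    "rcb_category",
    "responder_label",
    "marker_status",
    "st_gallen_subtype",
    "score_pathology_table",
    "KI67_LUMINAL_THRESHOLD",
    "RCB_CATEGORY_BOUNDS",
]

KI67_LUMINAL_THRESHOLD = 14.0  # % — Luminal A vs Luminal B (HER2-) split
RCB_CATEGORY_BOUNDS = (1.36, 3.28)  # upper bounds (inclusive) of categories I and II

ER_PR_POSITIVE_PCT = 1.0  # % immunoreactive cells


@dataclass(frozen=True)
class RCBInputs:
    f_inv: float     # fraction (0-1) of invasive cancer in the tumor bed
    d_prim: float    # mm, primary tumor-bed dimension
    ln_pos: int      # number of positive lymph nodes
    d_met: float     # mm, diameter of largest nodal metastasis

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_inv <= 1.0:
            raise ValueError("f_inv must lie in [0, 1]")
        if self.d_prim < 0 or self.d_met < 0:
            raise ValueError("dimensions must be non-negative")
        if self.ln_pos < 0 or int(self.ln_pos) != self.ln_pos:
            raise ValueError("ln_pos must be a non-negative integer")


@dataclass(frozen=True)
class IHCPanel:
    er_pct: float
    pr_pct: float
    her2_ihc: str                       # "0", "1+", "2+", "3+"
    her2_fish: str = "not_done"         # "amplified", "not_amplified", "not_done"
    ki67_pct: float = float("nan")

    def __post_init__(self) -> None:
        for name, pct in (("er_pct", self.er_pct), ("pr_pct", self.pr_pct)):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")
        if self.her2_ihc not in ("0", "1+", "2+", "3+"):
            raise ValueError(f"invalid her2_ihc {self.her2_ihc!r}")
        if self.her2_fish not in ("amplified", "not_amplified", "not_done"):
            raise ValueError(f"invalid her2_fish {self.her2_fish!r}")
        if not math.isnan(self.ki67_pct) and not 0.0 <= self.ki67_pct <= 100.0:
            raise ValueError("ki67_pct must lie in [0, 100]")


@dataclass(frozen=True)
class MarkerStatus:
    """Resolved receptor statuses; ``her2_pos`` is None when IHC 2+ lacks FISH."""

    er_pos: bool
    pr_pos: bool
    her2_pos: Optional[bool]


@dataclass(frozen=True)
class ResponseLabel:
    patient_id: str
    rcb_score: float          # NaN when no surgery
    rcb_category: Optional[str]  # "0", "I", "II", "III" or None
    responder: bool
    no_surgery: bool


def rcb_score(inputs: RCBInputs) -> float:
    """Residual cancer burden on the continuous scale."""
    primary = 1.4 * (inputs.f_inv * inputs.d_prim) ** 0.17
    nodal = (4.0 * (1.0 - 0.75 ** inputs.ln_pos) * inputs.d_met) ** 0.17
    return primary + nodal


def rcb_category(score: float) -> str:
    """Map a continuous RCB score to category "0", "I", "II" or "III"."""
    if math.isnan(score) or score < 0:
        raise ValueError("RCB score must be a non-negative number")
    if score == 0:
        return "0"
    if score <= RCB_CATEGORY_BOUNDS[0]:
        return "I"
    if score <= RCB_CATEGORY_BOUNDS[1]:
        return "II"
    return "III"


def responder_label(
    patient_id: str,
    category: Optional[str] = None,
    no_surgery: bool = False,
    score: float = float("nan"),
) -> ResponseLabel:
    """Responder (RCB 0/I) vs non-responder (RCB II/III, or no surgery).

    Patients who never reached surgery (e.g. progression/death on treatment)
    carry no RCB category and are labelled non-responders.
    """
    if no_surgery:
        if category is not None:
            raise ValueError("no-surgery patients cannot carry an RCB category")
        return ResponseLabel(patient_id, float("nan"), None, False, True)
    if category is None:
        raise ValueError("either an RCB category or no_surgery=True is required")
    if category not in ("0", "I", "II", "III"):
        raise ValueError(f"invalid RCB category {category!r}")
    return ResponseLabel(patient_id, score, category, category in ("0", "I"), False)


def marker_status(panel: IHCPanel) -> MarkerStatus:
    """ER/PR/HER2 positivity from the IHC (+FISH) panel."""
    er_pos = panel.er_pct >= ER_PR_POSITIVE_PCT
    pr_pos = panel.pr_pct >= ER_PR_POSITIVE_PCT
    if panel.her2_ihc in ("0", "1+"):
        her2_pos: Optional[bool] = False
    elif panel.her2_ihc == "3+":
        her2_pos = True
    else:  # equivocal 2+ — resolved by FISH
        if panel.her2_fish == "amplified":
            her2_pos = True
        elif panel.her2_fish == "not_amplified":
            her2_pos = False
        else:
            her2_pos = None  # unresolved
    return MarkerStatus(er_pos=er_pos, pr_pos=pr_pos, her2_pos=her2_pos)


def st_gallen_subtype(
    status: MarkerStatus,
    ki67_pct: float = float("nan"),
    ki67_threshold: float = KI67_LUMINAL_THRESHOLD,
) -> str:
    """St. Gallen molecular subtype from resolved marker statuses.

    Returns one of ``luminal_a``, ``luminal_b_her2neg``, ``luminal_b_her2pos``,
    ``her2_pos``, ``tn`` or ``unclassified``.  ``unclassified`` covers any
    combination the rule set does not resolve: unresolved HER2, missing Ki-67
    where the Luminal A/B split needs it, and ER-/PR+ tumors (not covered by
    the printed five-subtype criteria).
    """
    if status.er_pos:
        if status.her2_pos is None:
            return "unclassified"
        if status.her2_pos:
            return "luminal_b_her2pos"  # any Ki-67
        if math.isnan(ki67_pct):
            return "unclassified"
        return "luminal_a" if ki67_pct < ki67_threshold else "luminal_b_her2neg"
    if status.pr_pos:
        return "unclassified"  # ER-/PR+ not covered by the rule set
    if status.her2_pos is None:
        return "unclassified"
    return "her2_pos" if status.her2_pos else "tn"


# ---------------------------------------------------------------------------
# table-level API
# ---------------------------------------------------------------------------

RAW_PATIENT_COLUMNS = [
    "patient_id", "er_pct", "pr_pct", "her2_ihc", "her2_fish", "ki67_pct",
    "f_inv", "d_prim_mm", "ln_pos", "d_met_mm", "no_surgery",
]


def score_pathology_table(patients: pd.DataFrame) -> pd.DataFrame:
    """Score every patient row: RCB, category, responder flag, markers, subtype."""
    out = []
    for _, row in patients.iterrows():
        pid = str(row["patient_id"])
        no_surgery = bool(row.get("no_surgery", False))
        if no_surgery:
            label = responder_label(pid, no_surgery=True)
        else:
            score = rcb_score(
                RCBInputs(
                    f_inv=float(row["f_inv"]),
                    d_prim=float(row["d_prim_mm"]),
                    ln_pos=int(row["ln_pos"]),
                    d_met=float(row["d_met_mm"]),
                )
            )
            label = responder_label(pid, category=rcb_category(score), score=score)

        ki67 = row.get("ki67_pct", float("nan"))
        ki67 = float("nan") if pd.isna(ki67) else float(ki67)
        panel = IHCPanel(
            er_pct=float(row["er_pct"]),
            pr_pct=float(row["pr_pct"]),
            her2_ihc=str(row["her2_ihc"]),
            her2_fish=str(row.get("her2_fish", "not_done")),
            ki67_pct=ki67,
        )
        status = marker_status(panel)
        out.append(
            {
                "patient_id": pid,
                "rcb_score": label.rcb_score,
                "rcb_category": label.rcb_category if label.rcb_category else "",
                "responder": label.responder,
                "no_surgery": label.no_surgery,
                "er_pos": status.er_pos,
                "pr_pos": status.pr_pos,
                "her2_pos": np.nan if status.her2_pos is None else status.her2_pos,
                "ki67_pct": ki67,
                "subtype": st_gallen_subtype(status, ki67),
            }
        )
    return pd.DataFrame(out)
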