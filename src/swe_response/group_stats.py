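"""Responder vs non-responder group comparisons.

Reproduces the layout of the study's summary tables: per variable and visit,
complete-case n / mean / SD for each response group with a Kruskal-Wallis
p-value for continuous variables and a Pearson chi-squared p-value for
categorical ones.  Both test statistics are implemented from their textbook
formulas (rank-based H with tie correction; sum of (O-E)^2/E without
continuity correction) and are validated against scipy in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "kruskal_wallis",
    "chi_squared",
    "build_group_tables",
    "format_group_table",
    "TABLE2_VARIABLES",
]

ALPHA = 0.05

#: per-visit continuous variables, in published table order
TABLE2_VARIABLES = ["v_mri", "mass_size_mm", "e_mean", "e_max", "e_mean_ratio",
                    "e_max_ratio", "f_mass"]
CHANGE_VARIABLES = ["e_mean_1_2", "e_mean_1_3", "e_max_1_2", "e_max_1_3",
                    "f_mass_1_2", "f_mass_1_3"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> TestResult:
    """Kruskal-Wallis rank test with tie correction.

    H = [12 / (N(N+1)) * sum n_i rbar_i^2 - 3(N+1)] / [1 - sum(t^3 - t)/(N^3 - N)],
    compared to a chi-squared distribution with k-1 degrees of freedom.
    When every observation is tied the tie-corrected statistic is taken as 0
    (limit convention) with p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("at least two groups with data are required")
    for lab in labels:
        if not np.any(groups == lab):
            raise ValueError(f"group {lab!r} has no non-missing values")

    n_total = values.size
    ranks = stats.rankdata(values)  # average ranks for ties
    h = 0.0
    for lab in labels:
        r = ranks[groups == lab]
        h += r.size * (r.mean() ** 2)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)

    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    if denom <= 0:  # all observations identical
        return TestResult(0.0, 1.0, len(labels) - 1)
    h /= denom
    df = len(labels) - 1
    return TestResult(float(h), float(stats.chi2.sf(h, df)), df)


def chi_squared(table) -> TestResult:
    """Pearson chi-squared test of independence on an r x c count table,
    without continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal in contingency table")
    expected = row @ col / total
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(stat, float(stats.chi2.sf(stat, df)), df)


def _summarize_continuous(
    name: str, values: pd.Series, responder: pd.Series
) -> dict:
    rec: dict = {"variable": name, "kind": "continuous"}
    groups_present = []
    for gname, mask in (("responder", responder), ("nonresponder", ~responder)):
        v = values[mask].dropna()
        rec[f"{gname}_n"] = int(v.size)
        rec[f"{gname}_mean"] = float(v.mean()) if v.size else float("nan")
        rec[f"{gname}_sd"] = float(v.std(ddof=1)) if v.size > 1 else float("nan")
        if v.size:
            groups_present.append(gname)
    if len(groups_present) == 2 and responder.nunique() == 2:
        res = kruskal_wallis(values.to_numpy(), responder.to_numpy())
        rec["statistic"], rec["p_value"] = res.statistic, res.p_value
    else:
        rec["statistic"] = rec["p_value"] = float("nan")
    rec["significant"] = bool(rec["p_value"] < ALPHA) if not math.isnan(
        rec["p_value"]
    ) else False
    return rec


def _summarize_categorical(
    name: str, values: pd.Series, responder: pd.Series
) -> dict:
    keep = values.notna() & (values.astype(str) != "")
    v = values[keep].astype(str)
    resp = responder[keep]
    counts = pd.crosstab(resp, v)
    rec: dict = {
        "variable": name,
        "kind": "categorical",
        "responder_n": int(resp.sum()),
        "nonresponder_n": int((~resp).sum()),
        "responder_mean": float("nan"),
        "responder_sd": float("nan"),
        "nonresponder_mean": float("nan"),
        "nonresponder_sd": float("nan"),
        "levels": "|".join(counts.columns.astype(str)),
    }
    try:
        res = chi_squared(counts.to_numpy())
        rec["statistic"], rec["p_value"] = res.statistic, res.p_value
    except ValueError:
        rec["statistic"] = rec["p_value"] = float("nan")
    rec["significant"] = bool(rec["p_value"] < ALPHA) if not math.isnan(
        rec["p_value"]
    ) else False
    return rec


def build_group_tables(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    change_scores: Optional[pd.DataFrame] = None,
    categorical: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-variable group summaries in published-table order.

    ``features`` is the per-visit feature table (long format, one row per
    patient-visit); ``labels`` must carry ``patient_id`` and boolean
    ``responder``; ``change_scores`` optionally carries per-patient change
    columns; ``categorical`` optionally carries per-patient categorical
    columns (e.g. subtype, marker statuses) compared with the chi-squared
    test.  Analysis is complete-case per variable.
    """
    lab = labels.set_index("patient_id")["responder"].astype(bool)
    rows = []
    for var in TABLE2_VARIABLES:
        if var not in features.columns:
            continue
        for visit in sorted(features["visit"].dropna().unique()):
            sub = features[features["visit"] == visit]
            responder = sub["patient_id"].map(lab)
            rec = _summarize_continuous(
                f"{var}_{int(visit)}", sub[var].reset_index(drop=True),
                responder.reset_index(drop=True),
            )
            rows.append(rec)

    if change_scores is not None:
        responder = change_scores["patient_id"].map(lab)
        for var in CHANGE_VARIABLES:
            if var not in change_scores.columns:
                continue
            rows.append(
                _summarize_continuous(
                    var, change_scores[var].reset_index(drop=True),
                    responder.reset_index(drop=True),
                )
            )

    if categorical is not None:
        responder = categorical["patient_id"].map(lab)
        for col in categorical.columns:
            if col == "patient_id":
                continue
            rows.append(
                _summarize_categorical(
                    col, categorical[col].reset_index(drop=True),
                    responder.reset_index(drop=True),
                )
            )
    return pd.DataFrame(rows)


def format_group_table(summary: pd.DataFrame) -> str:
    """Markdown rendering of a group summary, mean +/- SD (n), star at p < 0.05."""
    lines = [
        "| Variable | Responder | Non-responder | p |",
        "| --- | --- | --- | --- |",
    ]
    for _, r in summary.iterrows():
        if r["kind"] == "continuous":
            resp = f"{r['responder_mean']:.1f} ± {r['responder_sd']:.1f} ({r['responder_n']})"
            nonr = f"{r['nonresponder_mean']:.1f} ± {r['nonresponder_sd']:.1f} ({r['nonresponder_n']})"
        else:
            resp = f"n={r['responder_n']}"
            nonr = f"n={r['nonresponder_n']}"
        p = r["p_value"]
        ptxt = "—" if math.isnan(p) else (f"{p:.3f}" + ("*" if p < ALPHA else ""))
        lines.append(f"| {r['variable']} | {resp} | {nonr} | {ptxt} |")
    return "\n".join(lines) + "\n"
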