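"""Synthetic longitudinal SWE cohorts.

Generates per-patient, per-visit raw measurement tables with the statistical
structure the downstream analysis assumes: per-group/per-visit marginal
distributions of mass size, mean/maximum elasticity, tumor-to-normal
elasticity ratios and MRI volume; within-patient correlation across visits
through a shared latent factor (Gaussian copula); marker/subtype composition
and Ki-67; residual-cancer-burden pathology consistent with each patient's
response group; and per-(group, visit) missingness counts.

The generator emits *raw* shear-wave speeds and ROI statistics, not derived
features: elasticity targets are inverted through E = 3*rho*c^2 to speeds,
the three tumor ROIs are built to average exactly to the intended aggregate,
and ``f_mass`` is always exactly 1000 * V_min / d of the generated latents.
Running the feature-engineering module on a generated cohort therefore
reproduces the generator's recorded ground truth to floating-point accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .distributions import (
    lognormal_from_z,
    trunc_normal_from_z,
    trunc_normal_params,
)
from .features import RAW_VISIT_COLUMNS, sws_to_elasticity
from .pathology import RAW_PATIENT_COLUMNS, rcb_category, rcb_score, RCBInputs

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "default_config",
    "generate_cohort",
    "inject_missingness",
    "binormal_auc",
]

GROUPS = ("responder", "nonresponder")
VISITS = (1, 2, 3)
#: per-visit continuous variables with (mean, sd) targets
VISIT_VARIABLES = ("mass_size", "e_mean", "e_max", "e_mean_ratio", "e_max_ratio", "v_mri")
#: variables whose target CV exceeds what a zero-truncated normal can realize
LOGNORMAL_VARIABLES = ("e_mean_ratio", "e_max_ratio", "v_mri")

SUBTYPE_SLOTS = (
    "luminal_a",
    "luminal_b_her2neg",
    "luminal_b_her2pos",
    "her2_pos",
    "tn",
    "unclassified_fish_not_done",
    "unclassified_ki67_missing",
    "unclassified_er_neg_pr_pos",
)


@dataclass(frozen=True)
class VariableTarget:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("target SD must be positive")


@dataclass(frozen=True)
class VisitTargets:
    n_swe: int
    n_mri: int
    targets: dict  # variable name -> VariableTarget


@dataclass(frozen=True)
class GroupConfig:
    n: int
    n_no_surgery: int
    ki67: VariableTarget
    ki67_n_measured: int
    er_pos_pr_neg: int
    subtypes: dict        # slot name -> count
    visits: dict          # visit index -> VisitTargets


@dataclass(frozen=True)
class CohortConfig:
    groups: dict          # group name -> GroupConfig
    rho: float = 0.5
    roi_min_frac: tuple = (0.7, 1.0)
    pcr_fraction: float = 0.35
    rcb_iii_fraction: float = 0.4
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        lo, hi = self.roi_min_frac
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("roi_min_frac must satisfy 0 < lo <= hi <= 1")
        for frac in (self.pcr_fraction, self.rcb_iii_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for gname, g in self.groups.items():
            slot_total = sum(g.subtypes.get(s, 0) for s in SUBTYPE_SLOTS)
            if slot_total != g.n:
                raise ValueError(
                    f"{gname}: subtype counts sum to {slot_total}, expected n={g.n}"
                )
            required_measured = g.subtypes.get("luminal_a", 0) + g.subtypes.get(
                "luminal_b_her2neg", 0
            )
            required_missing = g.subtypes.get("unclassified_ki67_missing", 0)
            if not required_measured <= g.ki67_n_measured <= g.n - required_missing:
                raise ValueError(f"{gname}: infeasible Ki-67 measured count")
            if g.n_no_surgery > g.n:
                raise ValueError(f"{gname}: n_no_surgery exceeds n")
            for v, vt in g.visits.items():
                if not 0 <= vt.n_swe <= g.n or not 0 <= vt.n_mri <= g.n:
                    raise ValueError(f"{gname} visit {v}: missingness count exceeds n")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        groups = {}
        for gname, gd in d["groups"].items():
            visits = {}
            for v, vd in gd["visits"].items():
                targets = {
                    var: VariableTarget(**vd[var]) for var in VISIT_VARIABLES
                }
                visits[int(v)] = VisitTargets(
                    n_swe=int(vd["n_swe"]), n_mri=int(vd["n_mri"]), targets=targets
                )
            groups[gname] = GroupConfig(
                n=int(gd["n"]),
                n_no_surgery=int(gd.get("n_no_surgery", 0)),
                ki67=VariableTarget(gd["ki67"]["mean"], gd["ki67"]["sd"]),
                ki67_n_measured=int(gd["ki67"]["n_measured"]),
                er_pos_pr_neg=int(gd.get("er_pos_pr_neg", 0)),
                subtypes={s: int(gd["subtypes"].get(s, 0)) for s in SUBTYPE_SLOTS},
                visits=visits,
            )
        return cls(
            groups=groups,
            rho=float(d.get("rho", 0.5)),
            roi_min_frac=tuple(d.get("roi_min_frac", (0.7, 1.0))),
            pcr_fraction=float(d.get("pcr_fraction", 0.35)),
            rcb_iii_fraction=float(d.get("rcb_iii_fraction", 0.4)),
            rng_seed=d.get("rng_seed"),
        )

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_group_sizes(self, n_per_group: int) -> "CohortConfig":
        """Scaled copy with ``n_per_group`` patients per group, no missingness,
        all surgeries performed, and subtype counts rescaled proportionally."""
        groups = {}
        for gname, g in self.groups.items():
            counts = _rescale_counts(g.subtypes, n_per_group)
            visits = {
                v: VisitTargets(n_swe=n_per_group, n_mri=n_per_group, targets=vt.targets)
                for v, vt in g.visits.items()
            }
            required = counts.get("luminal_a", 0) + counts.get("luminal_b_her2neg", 0)
            groups[gname] = GroupConfig(
                n=n_per_group,
                n_no_surgery=0,
                ki67=g.ki67,
                ki67_n_measured=max(
                    required, n_per_group - counts.get("unclassified_ki67_missing", 0)
                ),
                er_pos_pr_neg=round(g.er_pos_pr_neg * n_per_group / g.n),
                subtypes=counts,
                visits=visits,
            )
        return CohortConfig(
            groups=groups,
            rho=self.rho,
            roi_min_frac=self.roi_min_frac,
            pcr_fraction=self.pcr_fraction,
            rcb_iii_fraction=self.rcb_iii_fraction,
            rng_seed=self.rng_seed,
        )


def _rescale_counts(counts: dict, n: int) -> dict:
    """Largest-remainder rescaling of integer counts to a new total."""
    total = sum(counts.values())
    raw = {k: v * n / total for k, v in counts.items()}
    out = {k: int(math.floor(x)) for k, x in raw.items()}
    short = n - sum(out.values())
    for k in sorted(raw, key=lambda k: raw[k] - out[k], reverse=True)[:short]:
        out[k] += 1
    return out


def default_config() -> CohortConfig:
    """The shipped configuration encoding the published study summaries."""
    path = resources.files("swe_response.data") / "default_cohort.yaml"
    with path.open() as fh:
        return CohortConfig.from_dict(yaml.safe_load(fh))


@dataclass
class SyntheticCohort:
    """Generated cohort: raw tables plus ground truth.

    ``patients`` follows the pathology input schema plus group/ground-truth
    columns; ``visits`` follows the raw SWE/MRI visit schema (with NaN for
    injected missingness); ``truth`` records the generator's per-visit derived
    features before missingness.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig
    seed: Optional[int] = None

    def copy(self) -> "SyntheticCohort":
        return SyntheticCohort(
            self.patients.copy(), self.visits.copy(), self.truth.copy(),
            self.config, self.seed,
        )


def binormal_auc(mean_neg: float, sd_neg: float, mean_pos: float, sd_pos: float) -> float:
    """Closed-form AUC of a single Gaussian feature separating two classes,
    Phi(|mu_pos - mu_neg| / sqrt(sd_pos^2 + sd_neg^2))."""
    return float(
        stats.norm.cdf(abs(mean_pos - mean_neg) / math.hypot(sd_pos, sd_neg))
    )


# ---------------------------------------------------------------------------
# patient-level generation (markers, Ki-67, pathology)
# ---------------------------------------------------------------------------

def _ki67_value(u: float, target: VariableTarget, lo: float, hi: float) -> float:
    """Quantile of the group Ki-67 distribution conditioned to [lo, hi]."""
    mu, s = trunc_normal_params(target.mean, target.sd, 0.0, 100.0)
    a, b = (0.0 - mu) / s, (100.0 - mu) / s
    dist = stats.truncnorm(a, b, loc=mu, scale=s)
    f_lo, f_hi = dist.cdf(lo), dist.cdf(hi)
    return float(dist.ppf(f_lo + u * (f_hi - f_lo)))


def _marker_fields(slot: str, rng: np.random.Generator) -> dict:
    er_pos = slot in (
        "luminal_a", "luminal_b_her2neg", "luminal_b_her2pos",
        "unclassified_ki67_missing",
    )
    pr_pos = er_pos or slot == "unclassified_er_neg_pr_pos"
    if slot in ("luminal_b_her2pos", "her2_pos"):
        her2_ihc, her2_fish = "3+", "not_done"
    elif slot == "unclassified_fish_not_done":
        her2_ihc, her2_fish = "2+", "not_done"
    else:
        her2_ihc, her2_fish = "1+", "not_done"
    return {
        "er_pct": round(float(rng.uniform(10, 100)), 1) if er_pos else 0.0,
        "pr_pct": round(float(rng.uniform(10, 100)), 1) if pr_pos else 0.0,
        "her2_ihc": her2_ihc,
        "her2_fish": her2_fish,
    }


def _rcb_inputs_for_target(target_score: float, rng: np.random.Generator) -> RCBInputs:
    """Pathology inputs whose RCB score equals ``target_score`` exactly.

    Node involvement is drawn category-appropriately, then the invasive
    primary term is solved for the remainder of the score.
    """
    if target_score == 0:
        return RCBInputs(f_inv=0.0, d_prim=0.0, ln_pos=0, d_met=0.0)
    if target_score <= 1.36:
        ln, d_met = 0, 0.0
    elif target_score <= 3.28:
        ln = int(rng.integers(0, 3))
        d_met = float(rng.uniform(2, 8)) if ln else 0.0
    else:
        ln = int(rng.integers(3, 9))
        d_met = float(rng.uniform(8, 20))
    nodal = (4.0 * (1.0 - 0.75**ln) * d_met) ** 0.17
    if nodal >= target_score - 0.15:  # leave room for the primary term
        ln, d_met, nodal = 0, 0.0, 0.0
    prod = ((target_score - nodal) / 1.4) ** (1.0 / 0.17)  # f_inv * d_prim
    f_inv = float(rng.uniform(0.3, 0.9))
    return RCBInputs(f_inv=f_inv, d_prim=prod / f_inv, ln_pos=ln, d_met=d_met)


def _generate_patients(
    config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    pid = 0
    for gname in GROUPS:
        g = config.groups[gname]
        slots = [s for s in SUBTYPE_SLOTS for _ in range(g.subtypes.get(s, 0))]
        slots = [slots[i] for i in rng.permutation(len(slots))]

        # PR-negative assignment among ER+ slots
        er_pos_idx = [
            i for i, s in enumerate(slots)
            if s in ("luminal_a", "luminal_b_her2neg", "luminal_b_her2pos",
                     "unclassified_ki67_missing")
        ]
        pr_neg_idx = set(
            rng.choice(er_pos_idx, size=g.er_pos_pr_neg, replace=False).tolist()
        ) if g.er_pos_pr_neg else set()

        # Ki-67 measured/missing assignment honoring subtype requirements
        required_measured = [
            i for i, s in enumerate(slots) if s in ("luminal_a", "luminal_b_her2neg")
        ]
        required_missing = [
            i for i, s in enumerate(slots) if s == "unclassified_ki67_missing"
        ]
        free = [
            i for i in range(g.n)
            if i not in required_measured and i not in required_missing
        ]
        n_extra = g.ki67_n_measured - len(required_measured)
        extra = rng.choice(free, size=n_extra, replace=False).tolist() if n_extra else []
        measured = set(required_measured) | set(extra)

        # pathology targets
        no_surgery = set(
            rng.choice(g.n, size=g.n_no_surgery, replace=False).tolist()
        ) if g.n_no_surgery else set()
        with_surgery = [i for i in range(g.n) if i not in no_surgery]
        if gname == "responder":
            n_pcr = round(config.pcr_fraction * len(with_surgery))
            chosen = rng.permutation(len(with_surgery))
            score_targets = {}
            for rank, j in enumerate(chosen):
                i = with_surgery[j]
                score_targets[i] = (
                    0.0 if rank < n_pcr else float(rng.uniform(0.2, 1.35))
                )
        else:
            n_iii = round(config.rcb_iii_fraction * len(with_surgery))
            chosen = rng.permutation(len(with_surgery))
            score_targets = {}
            for rank, j in enumerate(chosen):
                i = with_surgery[j]
                score_targets[i] = (
                    float(rng.uniform(3.3, 4.2)) if rank < n_iii
                    else float(rng.uniform(1.45, 3.25))
                )

        for i, slot in enumerate(slots):
            pid += 1
            markers = _marker_fields(slot, rng)
            if i in pr_neg_idx:
                markers["pr_pct"] = 0.0

            u = float(rng.uniform())
            if i in measured:
                if slot == "luminal_a":
                    ki67 = _ki67_value(u, g.ki67, 0.0, 13.99)
                elif slot == "luminal_b_her2neg":
                    ki67 = _ki67_value(u, g.ki67, 14.0, 100.0)
                else:
                    ki67 = _ki67_value(u, g.ki67, 0.0, 100.0)
                ki67 = round(ki67, 1)
            else:
                ki67 = float("nan")

            if i in no_surgery:
                rcb_in = None
                true_score = float("nan")
                true_cat = ""
            else:
                rcb_in = _rcb_inputs_for_target(score_targets[i], rng)
                true_score = rcb_score(rcb_in)
                true_cat = rcb_category(true_score)

            rows.append(
                {
                    "patient_id": f"P{pid:03d}",
                    **markers,
                    "ki67_pct": ki67,
                    "f_inv": rcb_in.f_inv if rcb_in else float("nan"),
                    "d_prim_mm": rcb_in.d_prim if rcb_in else float("nan"),
                    "ln_pos": rcb_in.ln_pos if rcb_in else np.nan,
                    "d_met_mm": rcb_in.d_met if rcb_in else float("nan"),
                    "no_surgery": i in no_surgery,
                    "group": gname,
                    "true_subtype": (
                        slot if not slot.startswith("unclassified") else "unclassified"
                    ),
                    "true_rcb_score": true_score,
                    "true_rcb_category": true_cat,
                    "true_responder": gname == "responder",
                }
            )
    cols = RAW_PATIENT_COLUMNS + [
        "group", "true_subtype", "true_rcb_score", "true_rcb_category",
        "true_responder",
    ]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# visit-level generation
# ---------------------------------------------------------------------------

def _copula_scores(
    z_patient: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    return math.sqrt(rho) * z_patient + math.sqrt(1.0 - rho) * rng.standard_normal(
        z_patient.shape
    )


def _draw(var: str, z: np.ndarray, t: VariableTarget) -> np.ndarray:
    if var in LOGNORMAL_VARIABLES:
        return lognormal_from_z(z, t.mean, t.sd)
    return trunc_normal_from_z(z, t.mean, t.sd)


def _roi_offsets(c_mean: np.ndarray, c_min: np.ndarray, rng: np.random.Generator):
    """Centered per-ROI offsets; averaging the three ROIs recovers the aggregate."""
    off = rng.normal(0.0, 1.0, size=(c_mean.size, 3)) * (0.04 * c_mean)[:, None]
    off -= off.mean(axis=1, keepdims=True)
    cap = 0.5 * c_min
    amax = np.abs(off).max(axis=1)
    scale = np.where(amax > cap, cap / np.where(amax > 0, amax, 1.0), 1.0)
    return off * scale[:, None]


def _generate_visits(
    config: CohortConfig, patients: pd.DataFrame, rng: np.random.Generator
):
    eps = 1e-12
    visit_rows = []
    truth_rows = []
    for gname in GROUPS:
        g = config.groups[gname]
        mask = patients["group"] == gname
        ids = patients.loc[mask, "patient_id"].to_numpy()
        n = ids.size
        z_patient = rng.standard_normal(n)
        for visit in VISITS:
            vt = g.visits[visit]
            z_size = _copula_scores(z_patient, config.rho, rng)
            z_swe = _copula_scores(z_patient, config.rho, rng)
            z_ratio = _copula_scores(z_patient, config.rho, rng)
            z_vmri = _copula_scores(z_patient, config.rho, rng)

            d = _draw("mass_size", z_size, vt.targets["mass_size"])
            e_mean = _draw("e_mean", z_swe, vt.targets["e_mean"])
            e_max = np.maximum(
                _draw("e_max", z_swe, vt.targets["e_max"]), e_mean * (1 + eps)
            )
            r_mean = _draw("e_mean_ratio", z_ratio, vt.targets["e_mean_ratio"])
            r_max = _draw("e_max_ratio", z_ratio, vt.targets["e_max_ratio"])
            v_mri = _draw("v_mri", z_vmri, vt.targets["v_mri"])

            # invert E = 3*rho*c^2 to tumor speeds; V_min as a fraction of V_mean
            c_mean = np.sqrt(e_mean / 3.0)
            c_max = np.sqrt(e_max / 3.0)
            u_min = rng.uniform(*config.roi_min_frac, size=n)
            c_min = u_min * c_mean

            # normal tissue from the ratio targets (ordering guarded)
            e_n_mean = e_mean / r_mean
            e_n_max = np.maximum(e_max / r_max, e_n_mean * (1 + eps))
            cn_mean = np.sqrt(e_n_mean / 3.0)
            cn_max = np.sqrt(e_n_max / 3.0)
            cn_min = rng.uniform(*config.roi_min_frac, size=n) * cn_mean

            off = _roi_offsets(c_mean, c_min, rng)
            roi_sd = 0.08 * c_mean[:, None] * (1.0 + 0.25 * rng.uniform(size=(n, 3)))

            # MRI dimensions whose product is exactly V_MRI
            cbrt = np.cbrt(v_mri)
            a = rng.uniform(0.8, 1.25, size=n)
            b = rng.uniform(0.8, 1.25, size=n)
            ap, trans, si = cbrt * a, cbrt * b, cbrt / (a * b)

            rec = {"patient_id": ids, "visit": visit, "mass_size_mm": d}
            for j in (1, 2, 3):
                rec[f"roi{j}_sws_mean"] = c_mean + off[:, j - 1]
                rec[f"roi{j}_sws_min"] = c_min + off[:, j - 1]
                rec[f"roi{j}_sws_max"] = c_max + off[:, j - 1]
                rec[f"roi{j}_sws_sd"] = roi_sd[:, j - 1]
            rec.update(
                normal_sws_mean=cn_mean,
                normal_sws_min=cn_min,
                normal_sws_max=cn_max,
                normal_sws_sd=0.08 * cn_mean,
                mri_ap_mm=ap,
                mri_trans_mm=trans,
                mri_si_mm=si,
            )
            visit_rows.append(pd.DataFrame(rec))

            truth_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": ids,
                        "visit": visit,
                        "group": gname,
                        "mass_size_mm": d,
                        "e_mean": sws_to_elasticity(c_mean),
                        "e_max": sws_to_elasticity(c_max),
                        "e_mean_ratio": sws_to_elasticity(c_mean)
                        / sws_to_elasticity(cn_mean),
                        "e_max_ratio": sws_to_elasticity(c_max)
                        / sws_to_elasticity(cn_max),
                        "f_mass": 1000.0 * c_min / d,
                        "v_mri": ap * trans * si,
                    }
                )
            )

    visits = pd.concat(visit_rows, ignore_index=True)[RAW_VISIT_COLUMNS]
    truth = pd.concat(truth_rows, ignore_index=True)
    order = ["patient_id", "visit"]
    return (
        visits.sort_values(order, kind="stable").reset_index(drop=True),
        truth.sort_values(order, kind="stable").reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

SWE_COLUMNS = [c for c in RAW_VISIT_COLUMNS if "sws" in c] + ["mass_size_mm"]
MRI_COLUMNS = ["mri_ap_mm", "mri_trans_mm", "mri_si_mm"]


def inject_missingness(
    cohort: SyntheticCohort,
    counts: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticCohort:
    """Blank visit measurements so that exactly the configured number of
    patients per (group, visit) retain SWE and MRI data.

    ``counts`` maps ``(group, visit)`` to ``{"swe": n_present, "mri": n_present}``
    and defaults to the cohort's configuration.  Removal is completely at
    random under ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.seed)
    if counts is None:
        counts = {
            (gname, v): {"swe": vt.n_swe, "mri": vt.n_mri}
            for gname, g in cohort.config.groups.items()
            for v, vt in g.visits.items()
        }
    out = cohort.copy()
    visits = out.visits
    for (gname, visit), c in sorted(counts.items()):
        ids = out.patients.loc[out.patients["group"] == gname, "patient_id"]
        n = ids.size
        for kind, cols in (("swe", SWE_COLUMNS), ("mri", MRI_COLUMNS)):
            keep = int(c[kind])
            if not 0 <= keep <= n:
                raise ValueError(
                    f"{gname} visit {visit}: {kind} count {keep} outside [0, {n}]"
                )
            drop_ids = rng.choice(ids.to_numpy(), size=n - keep, replace=False)
            sel = visits["patient_id"].isin(drop_ids) & (visits["visit"] == visit)
            visits.loc[sel, cols] = np.nan
    out.visits = visits
    return out


def generate_cohort(
    config: Optional[CohortConfig] = None,
    seed: Optional[int] = None,
    complete: bool = False,
) -> SyntheticCohort:
    """Generate a synthetic cohort; fully reproducible from ``seed``.

    ``complete=True`` skips missingness injection (every patient retains all
    measurements), which is what large-sample calibration checks want.
    """
    if config is None:
        config = default_config()
    if seed is None:
        seed = config.rng_seed
    if seed is None:
        raise ValueError("a seed is required (argument or config.rng_seed)")
    rng = np.random.default_rng(seed)
    patients = _generate_patients(config, rng)
    visits, truth = _generate_visits(config, patients, rng)
    cohort = SyntheticCohort(
        patients=patients, visits=visits, truth=truth, config=config, seed=seed
    )
    if complete:
        return cohort
    return inject_missingness(cohort, rng=rng)
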