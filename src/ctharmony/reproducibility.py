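"""Reproducibility of radiomics features across reconstruction protocols.

Protocols act as raters: for each feature an n x k matrix (analysis units x
protocols) feeds a two-way ANOVA intraclass correlation coefficient.  A
feature is *reproducible* when its ICC meets the threshold (default 0.85).
Two complementary analyses are run:

* region-based — subjects are the analysis units, one ICC per (ROI,
  feature); organs with two ROIs count a feature only if it passes in both.
* patient-based — each patient's ROIs are the analysis units, one ICC per
  (patient, feature).

A two-stage redundancy rule removes feature groups that are insensitive to
protocol differences (high ICC everywhere even without harmonization) from
the reported denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .radiomics import FeatureSchema, build_schema

logger = logging.getLogger(__name__)

AGREEMENT = "two-way-agreement"
CONSISTENCY = "two-way-consistency"

# ICC of an all-identical matrix: identical measurements are perfectly
# reproducible by any reading, but the ANOVA is 0/0; use a sentinel.
DEGENERATE_ICC = 1.0


class SampleSizeError(ValueError):
    pass


@dataclass(frozen=True)
class ICCConfig:
    model: str = AGREEMENT
    threshold: float = 0.85
    n_min: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.n_min < 3:
            raise ValueError("n_min must be >= 3")
        if self.model not in (AGREEMENT, CONSISTENCY):
            raise ValueError(f"unknown ICC model {self.model!r}")


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    degenerate: bool = False


def _anova_mean_squares(x: np.ndarray) -> Tuple[float, float, float]:
    """Two-way ANOVA mean squares: rows (subjects), columns (raters), residual."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse


def icc(
    data: np.ndarray,
    model: str = AGREEMENT,
    n_min: int = 3,
    alpha: float = 0.05,
) -> ICCResult:
    """Single-measurement two-way ICC with a 95% F-based confidence interval.

    ``model='two-way-consistency'`` gives ICC(3,1) = (MSR-MSE)/(MSR+(k-1)MSE);
    ``model='two-way-agreement'`` gives ICC(2,1) =
    (MSR-MSE)/(MSR+(k-1)MSE+(k/n)(MSC-MSE)).  Zero-variance data returns the
    degenerate-reproducible sentinel (ICC 1).
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("data must be an n x k matrix with k >= 2")
    n, k = x.shape
    if n < n_min:
        raise SampleSizeError(f"need at least {n_min} rows, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("data must be finite")

    msr, msc, mse = _anova_mean_squares(x)
    if msr <= 0 and msc <= 0 and mse <= 0:
        return ICCResult(DEGENERATE_ICC, DEGENERATE_ICC, DEGENERATE_ICC, n, k, True)

    if model == CONSISTENCY:
        denom = msr + (k - 1) * mse
        value = (msr - mse) / denom if denom > 0 else DEGENERATE_ICC
        # Shrout & Fleiss F-interval for ICC(3,1)
        if mse > 0:
            f_obs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        else:
            lo = hi = value
        return ICCResult(float(value), float(lo), float(hi), n, k, False)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    value = (msr - mse) / denom if denom > 0 else DEGENERATE_ICC
    if mse > 0:
        # McGraw & Wong Satterthwaite interval for ICC(2,1)
        r = float(value)
        a = (k * r) / (n * (1 - r)) if r < 1 else np.inf
        b = 1 + (k * r * (n - 1)) / (n * (1 - r)) if r < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else 1.0
            f_star_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_star_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (
                n * (msr - f_star_l * mse)
                / (f_star_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            hi = (
                n * (f_star_u * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f_star_u * msr)
            )
        else:
            lo = hi = value
    else:
        lo = hi = value
    return ICCResult(float(value), float(lo), float(hi), n, k, False)


# ---------------------------------------------------------------------------
# table plumbing
# ---------------------------------------------------------------------------


def _icc_vectorized(
    arr: np.ndarray, model: str, alpha: float = 0.05
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-way ICC over a stack of matrices, shape (F, n, k).

    Same algebra as :func:`icc`, applied along the leading axis; used for
    whole-table analyses where a per-feature python loop would dominate the
    runtime.  Returns (icc, ci_low, ci_high, degenerate).
    """
    f, n, k = arr.shape
    grand = arr.mean(axis=(1, 2), keepdims=True)
    row_means = arr.mean(axis=2, keepdims=True)
    col_means = arr.mean(axis=1, keepdims=True)
    ssr = k * ((row_means - grand) ** 2).sum(axis=(1, 2))
    ssc = n * ((col_means - grand) ** 2).sum(axis=(1, 2))
    sst = ((arr - grand) ** 2).sum(axis=(1, 2))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = np.maximum(sst - ssr - ssc, 0.0) / ((n - 1) * (k - 1))

    degenerate = (msr <= 0) & (msc <= 0) & (mse <= 0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if model == CONSISTENCY:
            denom = msr + (k - 1) * mse
            value = np.where(denom > 0, (msr - mse) / denom, DEGENERATE_ICC)
            f_obs = np.where(mse > 0, msr / np.where(mse > 0, mse, 1.0), np.inf)
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fq = stats.f.ppf(1 - alpha / 2, df1, df2)
            fq2 = stats.f.ppf(1 - alpha / 2, df2, df1)
            fl, fu = f_obs / fq, f_obs * fq2
            lo = np.where(mse > 0, (fl - 1) / (fl + k - 1), value)
            hi = np.where(mse > 0, (fu - 1) / (fu + k - 1), value)
        else:
            denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
            value = np.where(denom > 0, (msr - mse) / denom, DEGENERATE_ICC)
            r = value
            ok = (mse > 0) & (r < 1)
            safe = np.where(r < 1, 1 - r, 1.0)
            a = (k * r) / (n * safe)
            b = 1 + (k * r * (n - 1)) / (n * safe)
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
            f_star_l = stats.f.ppf(1 - alpha / 2, n - 1, np.maximum(v, 1e-12))
            f_star_u = stats.f.ppf(1 - alpha / 2, np.maximum(v, 1e-12), n - 1)
            lo_v = (
                n * (msr - f_star_l * mse)
                / (f_star_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            hi_v = (
                n * (f_star_u * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f_star_u * msr)
            )
            lo = np.where(ok, lo_v, value)
            hi = np.where(ok, hi_v, value)
    value = np.where(degenerate, DEGENERATE_ICC, value)
    lo = np.where(degenerate, DEGENERATE_ICC, lo)
    hi = np.where(degenerate, DEGENERATE_ICC, hi)
    return value, lo, hi, degenerate


def _icc_table_for_unit(
    sub: pd.DataFrame, row_key: str, protocols: List[str], cfg: "ICCConfig"
) -> List[tuple]:
    """Per-feature ICC rows for one analysis unit (one ROI or one patient).

    Uses the vectorized path when the (row, protocol) grid is complete and
    finite; falls back to the scalar routine feature by feature otherwise.
    """
    piv = sub.pivot_table(
        index=["feature", row_key], columns="protocol", values="value",
        aggfunc="first",
    )
    try:
        piv = piv[protocols]
    except KeyError:
        return []
    features = piv.index.get_level_values(0).unique()
    n_rows = piv.index.get_level_values(1).nunique()
    k = len(protocols)
    complete = len(piv) == len(features) * n_rows and not piv.isna().any().any()
    out: List[tuple] = []
    if complete and n_rows >= cfg.n_min:
        arr = piv.to_numpy().reshape(len(features), n_rows, k)
        vals, lo, hi, dg = _icc_vectorized(arr, cfg.model)
        for i, feat in enumerate(features):
            out.append(
                (feat, float(vals[i]), float(lo[i]), float(hi[i]), n_rows, k,
                 bool(dg[i]))
            )
        return out
    for feat in features:
        wide = piv.xs(feat, level=0).dropna()
        if len(wide) < cfg.n_min:
            continue
        res = icc(wide.to_numpy(), cfg.model, cfg.n_min)
        out.append((feat, res.icc, res.ci_low, res.ci_high, res.n, res.k,
                    res.degenerate))
    return out


def _matrix(
    sub: pd.DataFrame, row_key: str, protocols: Sequence[str]
) -> Optional[np.ndarray]:
    """Pivot one feature's slice of a long table into rows x protocols."""
    wide = sub.pivot_table(index=row_key, columns="protocol", values="value",
                           aggfunc="first")
    try:
        wide = wide[list(protocols)]
    except KeyError:
        return None
    wide = wide.dropna()
    return wide.to_numpy() if len(wide) else None


def icc_by_roi(
    table: pd.DataFrame, config: Optional[ICCConfig] = None
) -> pd.DataFrame:
    """ICC per (roi, feature) with subjects as rows, protocols as raters."""
    cfg = config or ICCConfig()
    protocols = sorted(table["protocol"].unique())
    rows = []
    for roi, sub in table.groupby("roi", observed=True, sort=False):
        for row in _icc_table_for_unit(sub, "subject", protocols, cfg):
            rows.append((roi, *row))
    return pd.DataFrame(
        rows,
        columns=["roi", "feature", "icc", "ci_low", "ci_high", "n", "k", "degenerate"],
    )


def icc_by_patient(
    table: pd.DataFrame, config: Optional[ICCConfig] = None
) -> pd.DataFrame:
    """ICC per (patient, feature) with that patient's ROIs as rows."""
    cfg = config or ICCConfig()
    protocols = sorted(table["protocol"].unique())
    rows = []
    for subject, sub in table.groupby("subject", observed=True, sort=False):
        for row in _icc_table_for_unit(sub, "roi", protocols, cfg):
            rows.append((subject, *row))
    out = pd.DataFrame(
        rows,
        columns=["subject", "feature", "icc", "ci_low", "ci_high", "n", "k",
                 "degenerate"],
    )
    skipped = set(table["subject"].unique()) - set(out["subject"].unique())
    for s in sorted(skipped):
        logger.warning("patient %s skipped: fewer ROIs than n_min", s)
    return out


# ---------------------------------------------------------------------------
# region- and patient-based analyses
# ---------------------------------------------------------------------------

ROI_ORGAN = {
    "liver_1": "liver", "liver_2": "liver",
    "spleen_1": "spleen", "spleen_2": "spleen",
    "kidney_1": "kidney", "kidney_2": "kidney",
    "muscle_1": "muscle", "muscle_2": "muscle",
    "vessel_1": "vessel", "air_1": "air", "air_2": "air", "vessel_2": "vessel",
}

ORGAN_ORDER = ["liver", "spleen", "vessel", "kidney", "muscle", "air"]


@dataclass
class RegionSummary:
    """Per-organ reproducible-feature counts for original vs harmonized tables."""

    table: pd.DataFrame  # columns: organ, n_features, count/pct original & harmonized
    icc_original: pd.DataFrame
    icc_harmonized: pd.DataFrame


def _organ_of(roi_id: str, roster: Optional[Dict[str, str]] = None) -> str:
    roster = roster or ROI_ORGAN
    return roster.get(roi_id, roi_id.rsplit("_", 1)[0])


def _region_pass(
    icc_table: pd.DataFrame, threshold: float, features: Sequence[str]
) -> Dict[str, set]:
    """Features with ICC >= threshold in *every* ROI of each organ."""
    passing: Dict[str, set] = {}
    icc_table = icc_table[icc_table["feature"].isin(features)]
    for roi, sub in icc_table.groupby("roi", observed=True):
        organ = _organ_of(str(roi))
        ok = set(sub.loc[sub["icc"] >= threshold, "feature"])
        passing[organ] = passing[organ] & ok if organ in passing else ok
    return passing


def region_based_analysis(
    original: pd.DataFrame,
    harmonized: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    config: Optional[ICCConfig] = None,
) -> RegionSummary:
    """Table-3-style per-organ reproducibility before/after harmonization.

    ``features`` restricts the analysis (e.g. the retained set after
    redundancy exclusion); percentages use its size as denominator.
    """
    cfg = config or ICCConfig()
    if features is None:
        features = sorted(original["feature"].unique())
    features = list(features)
    icc_o = icc_by_roi(original[original["feature"].isin(features)], cfg)
    icc_h = icc_by_roi(harmonized[harmonized["feature"].isin(features)], cfg)
    pass_o = _region_pass(icc_o, cfg.threshold, features)
    pass_h = _region_pass(icc_h, cfg.threshold, features)
    organs = [o for o in ORGAN_ORDER if o in pass_o] + sorted(
        set(pass_o) - set(ORGAN_ORDER)
    )
    nf = len(features)
    rows = []
    for organ in organs:
        co, ch = len(pass_o.get(organ, set())), len(pass_h.get(organ, set()))
        rows.append(
            {
                "organ": organ,
                "n_features": nf,
                "count_original": co,
                "pct_original": 100.0 * co / nf,
                "count_harmonized": ch,
                "pct_harmonized": 100.0 * ch / nf,
                "increase_pct": 100.0 * (ch - co) / nf,
            }
        )
    return RegionSummary(pd.DataFrame(rows), icc_o, icc_h)


@dataclass
class PatientSummary:
    """Per-patient reproducible-feature counts and their cohort statistics."""

    per_patient: pd.DataFrame  # subject, count_original, count_harmonized, gain
    mean_original: float
    sd_original: float
    mean_harmonized: float
    sd_harmonized: float
    mean_gain: float
    n_features: int
    heatmap_original: pd.DataFrame  # patients x features ICC matrix
    heatmap_harmonized: pd.DataFrame


def patient_based_analysis(
    original: pd.DataFrame,
    harmonized: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    config: Optional[ICCConfig] = None,
) -> PatientSummary:
    """Per-patient reproducibility: each patient's ROIs are the ICC subjects."""
    cfg = config or ICCConfig()
    if features is None:
        features = sorted(original["feature"].unique())
    features = list(features)
    icc_o = icc_by_patient(original[original["feature"].isin(features)], cfg)
    icc_h = icc_by_patient(harmonized[harmonized["feature"].isin(features)], cfg)
    hm_o = icc_o.pivot_table(index="subject", columns="feature", values="icc",
                             aggfunc="first")
    hm_h = icc_h.pivot_table(index="subject", columns="feature", values="icc",
                             aggfunc="first")
    subjects = sorted(set(hm_o.index) & set(hm_h.index))
    rows = []
    for s in subjects:
        co = int((hm_o.loc[s] >= cfg.threshold).sum())
        ch = int((hm_h.loc[s] >= cfg.threshold).sum())
        rows.append({"subject": s, "count_original": co, "count_harmonized": ch,
                     "gain": ch - co})
    per = pd.DataFrame(rows)
    return PatientSummary(
        per_patient=per,
        mean_original=float(per["count_original"].mean()),
        sd_original=float(per["count_original"].std(ddof=1)) if len(per) > 1 else 0.0,
        mean_harmonized=float(per["count_harmonized"].mean()),
        sd_harmonized=float(per["count_harmonized"].std(ddof=1)) if len(per) > 1 else 0.0,
        mean_gain=float(per["gain"].mean()),
        n_features=len(features),
        heatmap_original=hm_o,
        heatmap_harmonized=hm_h,
    )


# ---------------------------------------------------------------------------
# redundancy exclusion
# ---------------------------------------------------------------------------


@dataclass
class RedundancyReport:
    stage1_flags: Dict[str, bool]          # group -> flagged in training cohort
    stage2_patient_fraction: Dict[str, float]  # group -> fraction of patients
    excluded_groups: List[str]
    retained_features: List[str]

    @property
    def retained_count(self) -> int:
        return len(self.retained_features)

    def to_json_dict(self) -> dict:
        return {
            "stage1_flags": self.stage1_flags,
            "stage2_patient_fraction": self.stage2_patient_fraction,
            "excluded_groups": self.excluded_groups,
            "retained_count": self.retained_count,
        }


def _group_pass_fraction(icc_sub: pd.DataFrame, members: Sequence[str],
                         threshold: float) -> float:
    vals = icc_sub[icc_sub["feature"].isin(members)]
    if not len(vals):
        return 0.0
    return float((vals["icc"] >= threshold).sum()) / len(members)


def redundancy_exclusion(
    training_icc: pd.DataFrame,
    external_patient_icc: pd.DataFrame,
    schema: Optional[FeatureSchema] = None,
    config: Optional[ICCConfig] = None,
) -> RedundancyReport:
    """Two-stage redundant-feature-group exclusion.

    Stage 1 (training cohort, per-ROI ICC table): a group is flagged if, in
    every ROI, strictly more than half of its features have ICC >= threshold
    — such groups fail to capture protocol differences anywhere.
    Stage 2 (external cohort, per-patient ICC table): a flagged group is
    excluded if strictly more than half of the patients individually satisfy
    the same >50% rule.  Both "more than half" comparisons are strict.
    """
    schema = schema or build_schema()
    cfg = config or ICCConfig()
    groups = schema.groups
    for g in groups:
        if not schema.group_members(g):
            raise ValueError(f"empty schema group {g!r}")

    stage1: Dict[str, bool] = {}
    rois = list(training_icc["roi"].unique()) if len(training_icc) else []
    for g in groups:
        members = schema.group_members(g)
        flagged = bool(rois)
        for roi in rois:
            sub = training_icc[training_icc["roi"] == roi]
            if _group_pass_fraction(sub, members, cfg.threshold) <= 0.5:
                flagged = False
                break
        stage1[g] = flagged

    stage2_frac: Dict[str, float] = {}
    patients = list(external_patient_icc["subject"].unique())
    for g in groups:
        members = schema.group_members(g)
        hits = 0
        for p in patients:
            sub = external_patient_icc[external_patient_icc["subject"] == p]
            if _group_pass_fraction(sub, members, cfg.threshold) > 0.5:
                hits += 1
        stage2_frac[g] = hits / len(patients) if patients else 0.0

    excluded = [g for g in groups if stage1[g] and stage2_frac[g] > 0.5]
    excluded_set = set(excluded)
    retained = [e.feature_id for e in schema.entries if e.group not in excluded_set]
    return RedundancyReport(stage1, stage2_frac, excluded, retained)


def retained_after_exclusion(
    schema: FeatureSchema, excluded_groups: Iterable[str]
) -> List[str]:
    """Feature ids remaining once the given groups are removed."""
    excluded = set(excluded_groups)
    unknown = excluded - set(schema.groups)
    if unknown:
        raise ValueError(f"unknown groups: {sorted(unknown)}")
    return [e.feature_id for e in schema.entries if e.group not in excluded]
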