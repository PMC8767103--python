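"""Survival association of repertoire features.

Each feature enters a Cox proportional-hazards model as a continuous term,
adjusted for age (continuous), sex (binary) and tumor stage (binary
early/late), with Efron handling of tied event times and complete-case
exclusion of missing covariates. Tumor types qualify only with at least 40
observed events (about 10 events per predictor). Benjamini-Hochberg
adjustment is applied within each tumor type across all chain x feature
models; Kaplan-Meier median splits are a presentation aid only — the
annotated p-values come from the adjusted Cox models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .association import bh_adjust
from .diversity import FEATURE_COLUMNS

ADJUSTMENT_COVARIATES = ("age_at_diagnosis", "sex", "stage_group")


def eligible_tumor_types(
    clinical: pd.DataFrame, min_events: int = 40, group_col: str = "tumor_type"
) -> set[str]:
    """Tumor types with at least ``min_events`` observed events."""
    df = clinical.dropna(subset=["os_event"])
    counts = df.groupby(group_col)["os_event"].sum()
    return set(counts[counts >= min_events].index)


@dataclass
class CoxFit:
    hazard_ratio: float
    p_value: float
    coef: float
    se: float
    ci_lower: float           # 95% CI on the log-hazard coefficient
    ci_upper: float
    n: int
    n_events: int
    covariates_used: tuple[str, ...]
    converged: bool = True
    message: str = ""

    @property
    def missing(self) -> bool:
        return not self.converged or np.isnan(self.hazard_ratio)


def _design_frame(data: pd.DataFrame, feature: str) -> pd.DataFrame:
    cols = {"feature": pd.to_numeric(data[feature], errors="coerce")}
    if "age_at_diagnosis" in data:
        cols["age"] = pd.to_numeric(data["age_at_diagnosis"], errors="coerce")
    if "sex" in data:
        cols["is_male"] = data["sex"].map({"male": 1.0, "female": 0.0})
    if "stage_group" in data:
        cols["is_late"] = data["stage_group"].map({"late": 1.0, "early": 0.0})
    cols["os_time"] = pd.to_numeric(data["os_time"], errors="coerce")
    cols["os_event"] = pd.to_numeric(data["os_event"], errors="coerce")
    df = pd.DataFrame(cols).dropna()
    return df[df["os_time"] > 0]


def cox_feature_model(data: pd.DataFrame, feature: str) -> CoxFit:
    """Adjusted Cox model for one feature on one cohort subset.

    ``data`` must carry the feature column plus os_time, os_event and the
    adjustment covariates. Covariates that are constant after complete-case
    filtering (e.g. sex in a single-sex cohort) are dropped automatically; a
    constant feature, too few events, or non-convergence yields a missing
    (NaN) fit with a diagnostic message rather than an exception.
    """

    def _missing(msg: str, n: int = 0, n_events: int = 0) -> CoxFit:
        nan = float("nan")
        return CoxFit(nan, nan, nan, nan, nan, nan, n, n_events, (), False, msg)

    df = _design_frame(data, feature)
    n, n_events = len(df), int(df["os_event"].sum())
    if n_events < 1:
        return _missing("no events", n, n_events)
    if df["feature"].nunique() <= 1:
        return _missing("constant feature", n, n_events)
    keep = ["feature"] + [
        c for c in ("age", "is_male", "is_late")
        if c in df.columns and df[c].nunique() > 1
    ]
    fit_df = df[keep + ["os_time", "os_event"]]
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col="os_time", event_col="os_event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        return _missing(f"fit failed: {exc}", n, n_events)
    summary = cph.summary.loc["feature"]
    return CoxFit(
        hazard_ratio=float(summary["exp(coef)"]),
        p_value=float(summary["p"]),
        coef=float(summary["coef"]),
        se=float(summary["se(coef)"]),
        ci_lower=float(summary["coef lower 95%"]),
        ci_upper=float(summary["coef upper 95%"]),
        n=n,
        n_events=n_events,
        covariates_used=tuple(c for c in keep if c != "feature"),
    )


def survival_scan(
    data: pd.DataFrame,
    features: Sequence[str] = tuple(FEATURE_COLUMNS),
    group_col: str = "tumor_type",
    chain_col: str = "chain",
    min_events: int = 40,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """One adjusted Cox model per group x chain x feature.

    Groups (tumor types or subtypes) with fewer than ``min_events`` events
    among unique participants are omitted. BH adjustment runs within each
    group over all its chain x feature models; rows at FDR below
    ``fdr_threshold`` are flagged significant.
    """
    per_sample = data.drop_duplicates("sample_id")
    ok_groups = eligible_tumor_types(per_sample, min_events, group_col)
    rows = []
    for group, block in data.groupby(group_col, sort=True):
        if group not in ok_groups:
            continue
        for chain, sub in block.groupby(chain_col, sort=True):
            for feat in features:
                fit = cox_feature_model(sub, feat)
                rows.append(
                    {
                        group_col: group,
                        "chain": chain,
                        "feature": feat,
                        "hazard_ratio": fit.hazard_ratio,
                        "coef": fit.coef,
                        "p_value": fit.p_value,
                        "n": fit.n,
                        "n_events": fit.n_events,
                        "covariates_used": ",".join(fit.covariates_used),
                        "converged": fit.converged,
                    }
                )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = np.nan
    for group, idx in out.groupby(group_col).groups.items():
        out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p_value"])
    out["significant"] = out["fdr"] < fdr_threshold
    return out


@dataclass
class KMSplit:
    low: pd.DataFrame             # columns: time, at_risk, survival
    high: pd.DataFrame
    n_low: int
    n_high: int
    threshold: float


def _km_table(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
    return pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        }
    )


def km_median_split(data: pd.DataFrame, feature: str) -> KMSplit:
    """Kaplan-Meier curves for samples below/above the median feature value.

    Ties at the median go to the low group (deterministic). The split is
    purely descriptive; significance annotations should come from the
    adjusted Cox model, not a log-rank test on this split.
    """
    df = data.dropna(subset=[feature, "os_time", "os_event"])
    values = df[feature].to_numpy(dtype=float)
    if np.unique(values).size <= 1:
        raise ValueError("feature is constant; median split is degenerate")
    threshold = float(np.median(values))
    low_mask = values <= threshold
    if low_mask.sum() < 2 or (~low_mask).sum() < 2:
        raise ValueError("median split leaves fewer than 2 samples on a side")
    times = df["os_time"].to_numpy(dtype=float)
    events = df["os_event"].to_numpy(dtype=float)
    return KMSplit(
        low=_km_table(times[low_mask], events[low_mask]),
        high=_km_table(times[~low_mask], events[~low_mask]),
        n_low=int(low_mask.sum()),
        n_high=int((~low_mask).sum()),
        threshold=threshold,
    )
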