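"""Covariate association scans over the repertoire feature table.

Continuous covariates (mutation load, age) are tested with Spearman rank
correlation; categorical covariates (tumor vs adjacent tissue, early vs
late stage, sex) with the two-sided Wilcoxon rank-sum test plus the log2
ratio of group means. P-values are adjusted with Benjamini-Hochberg within
each tumor type, across all chain x feature tests for one covariate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import FEATURE_COLUMNS


@dataclass(frozen=True)
class CovariateSpec:
    """What to test: a continuous column, or a binary contrast A vs B."""

    name: str
    kind: str  # "continuous" | "binary"
    group_a: str | None = None
    group_b: str | None = None


def spearman_assoc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided p.

    Pairs with a missing value in either vector are dropped; fewer than 3
    complete pairs, or a constant vector, yields a missing (NaN, NaN)
    result. For very small samples (n <= 8) the p-value is the exact
    permutation tail P(|rho_perm| >= |rho_obs|) over all n! pairings;
    larger samples use the asymptotic approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    if x.size <= 8:
        rx = stats.rankdata(x) - stats.rankdata(x).mean()
        ry = stats.rankdata(y) - stats.rankdata(y).mean()
        denom = np.sqrt((rx**2).sum() * (ry**2).sum())
        hits = total = 0
        for perm in itertools.permutations(range(x.size)):
            r = float(rx @ ry[list(perm)]) / denom
            total += 1
            hits += abs(r) >= abs(rho) - 1e-12
        p = hits / total
    return float(rho), float(p)


def wilcoxon_assoc(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, float]:
    """Rank-sum statistic, two-sided p, and log2 ratio of group means.

    The statistic is the rank sum of group ``a``; the p-value is the
    two-sided Wilcoxon rank-sum (Mann-Whitney) p with tie correction
    (exact when samples are small and untied). The fold ratio is
    log2(mean(a)/mean(b)), missing if either mean is non-positive.
    """
    a = np.asarray(a, dtype=float)
    a = a[~np.isnan(a)]
    b = np.asarray(b, dtype=float)
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0 or a.size + b.size < 4:
        return float("nan"), float("nan"), float("nan")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    rank_sum = float(u) + a.size * (a.size + 1) / 2.0
    mean_a, mean_b = a.mean(), b.mean()
    if mean_a <= 0 or mean_b <= 0:
        lfr = float("nan")
    else:
        lfr = float(np.log2(mean_a / mean_b))
    return rank_sum, float(p), lfr


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    NaN entries are passed through and excluded from the family size.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum() > 0:
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def association_scan(
    data: pd.DataFrame,
    spec: CovariateSpec,
    features: Sequence[str] = tuple(FEATURE_COLUMNS),
    group_col: str = "tumor_type",
    chain_col: str = "chain",
    min_group_a: int | None = None,
    min_group_b: int | None = None,
) -> pd.DataFrame:
    """Run one covariate across every tumor type x chain x feature cell.

    ``data`` is the tidy feature table already joined with clinical
    covariates (one row per sample x chain). The BH family is all chain x
    feature tests within one tumor type. Tumor types failing a per-group
    minimum (binary contrasts only) keep their rows but with missing
    statistics and ``insufficient=True`` — nothing is dropped silently.
    """
    results = []
    for tumor_type, block in data.groupby(group_col, sort=True):
        insufficient = False
        if spec.kind == "binary":
            per_sample = block.drop_duplicates("sample_id")
            n_a = (per_sample[spec.name] == spec.group_a).sum()
            n_b = (per_sample[spec.name] == spec.group_b).sum()
            if min_group_a is not None and n_a < min_group_a:
                insufficient = True
            if min_group_b is not None and n_b < min_group_b:
                insufficient = True
        for chain, sub in block.groupby(chain_col, sort=True):
            for feat in features:
                row = {
                    group_col: tumor_type,
                    "chain": chain,
                    "feature": feat,
                    "covariate": spec.name,
                    "test": "spearman" if spec.kind == "continuous" else "wilcoxon",
                    "statistic": float("nan"),
                    "p_value": float("nan"),
                    "log2_fold_ratio": float("nan"),
                    "n": 0,
                    "insufficient": insufficient,
                }
                if not insufficient:
                    if spec.kind == "continuous":
                        rho, p = spearman_assoc(sub[feat], sub[spec.name])
                        keep = ~(sub[feat].isna() | sub[spec.name].isna())
                        row.update(statistic=rho, p_value=p, n=int(keep.sum()))
                    else:
                        a = sub.loc[sub[spec.name] == spec.group_a, feat]
                        b = sub.loc[sub[spec.name] == spec.group_b, feat]
                        w, p, lfr = wilcoxon_assoc(a, b)
                        row.update(
                            statistic=w,
                            p_value=p,
                            log2_fold_ratio=lfr,
                            n=int(a.notna().sum() + b.notna().sum()),
                        )
                results.append(row)
    out = pd.DataFrame(results)
    if out.empty:
        return out
    out["fdr"] = np.nan
    for tumor_type, idx in out.groupby(group_col).groups.items():
        out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p_value"])
    return out


def tumor_vs_adjacent_scan(
    data: pd.DataFrame,
    features: Sequence[str] = tuple(FEATURE_COLUMNS),
    min_adjacent: int = 10,
) -> pd.DataFrame:
    """Primary-tumor vs adjacent-non-tumor contrast per tumor type.

    Requires a ``sample_class`` column; tumor types with fewer than
    ``min_adjacent`` adjacent samples are flagged insufficient. Fold ratios
    are oriented tumor over adjacent.
    """
    spec = CovariateSpec(
        name="sample_class",
        kind="binary",
        group_a="primary_tumor",
        group_b="adjacent_non_tumor",
    )
    return association_scan(
        data, spec, features=features, min_group_b=min_adjacent
    )
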