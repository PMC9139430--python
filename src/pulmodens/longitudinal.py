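"""Longitudinal statistics linking density dynamics to lung function.

The chain per subvolume (dose range) and PFT parameter is:

1. per patient, the Pearson correlation r between n_rho(t) and PFT(t) over
   the three time points (tpre, t3m, t6m);
2. Fisher z-transformation z = atanh(r), variance-stabilizing so values can
   be averaged across patients (|r| = 1, which has positive probability with
   three points, is clamped to 1 - eps to stay finite);
3. a one-sample, right-tailed t-test of the cohort's z values against zero —
   the null being "no or negative correlation";
4. Bonferroni correction over the family of ranges tested.

Two further analyses reuse the same machinery: paired tests on the relative
temporal change of n_rho and PFT values versus baseline, and the
cross-patient correlation between the relative *size* of a dose subvolume
and the relative PFT change (does the anatomy of the dose distribution
predict functional decline?).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dose_volumes import triangle_ranges
from .types import TIMEPOINTS, VolumeRange

logger = logging.getLogger(__name__)

#: Clamp for |r| before atanh so three-point |r| = 1 stays finite.
FISHER_CLAMP_EPS = 1e-7

STATUS_OK = "ok"
STATUS_DEGENERATE = "degenerate"
STATUS_INSUFFICIENT = "insufficient"


def pearson_three_point(x: Sequence[float], y: Sequence[float]) -> tuple[float, str]:
    """Pearson moment correlation over paired values (designed for 3 points).

    Returns ``(r, status)``; pairs with a missing member are dropped first.
    Fewer than 3 complete pairs → (nan, "insufficient"); zero variance in
    either series → (nan, "degenerate").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        return math.nan, STATUS_INSUFFICIENT
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return math.nan, STATUS_DEGENERATE
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    return min(1.0, max(-1.0, r)), STATUS_OK


def fisher_z(r: float, eps: float = FISHER_CLAMP_EPS) -> float:
    """atanh of r, with |r| clamped to 1 - eps so the result is always finite."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    r_clamped = math.copysign(min(abs(r), 1.0 - eps), r)
    return math.atanh(r_clamped)


def bonferroni(p_raw: float, m: int) -> float:
    """min(1, m * p), the Bonferroni-corrected p-value for a family of m tests."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p_raw}")
    if m < 1 or int(m) != m:
        raise ValueError(f"family size must be a positive integer, got {m}")
    return min(1.0, m * p_raw)


def significance_tier(p: float) -> str:
    """Three-tier encoding: high (< 0.01), moderate (< 0.05), ns."""
    if p < 0.01:
        return "high"
    if p < 0.05:
        return "moderate"
    return "ns"


def cohort_test(z_values: Sequence[float]) -> tuple[float, float, int]:
    """One-sample, right-tailed t-test of the cohort's Fisher z values vs 0.

    Returns (t_statistic, p_raw, n). With fewer than 2 values the result is
    (nan, nan, n). A zero-variance sample is degenerate for the t statistic;
    by convention a zero-variance, zero-mean sample reports p = 1 (no
    evidence either way) and a zero-variance sample with positive (negative)
    mean reports p = 0 (p = 1); both cases are logged.
    """
    z = np.asarray([v for v in z_values if np.isfinite(v)], dtype=float)
    n = z.size
    if n < 2:
        return math.nan, math.nan, n
    if float(z.std(ddof=1)) == 0.0:
        mean = float(z.mean())
        logger.warning("cohort_test: zero-variance z sample (mean %.3g)", mean)
        if mean == 0.0:
            return 0.0, 1.0, n
        return math.copysign(math.inf, mean), 0.0 if mean > 0 else 1.0, n
    res = sps.ttest_1samp(z, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue), n


def _pivot_timepoints(df: pd.DataFrame, value: str) -> pd.DataFrame:
    """patient_id × (tpre, t3m, t6m) matrix of ``value``; patients lacking a
    time point get NaN there."""
    piv = df.pivot_table(index="patient_id", columns="timepoint", values=value,
                         aggfunc="first")
    return piv.reindex(columns=list(TIMEPOINTS))


def patient_correlations(
    density_df: pd.DataFrame,
    pft_df: pd.DataFrame,
    rng: Union[VolumeRange, str],
    parameter: str = "dlco",
) -> pd.DataFrame:
    """Per-patient r and Fisher z between n_rho(t) and the PFT parameter.

    Patients lacking any of the three time points (CT or PFT) are reported
    with status ``insufficient``; zero-variance series with ``degenerate``.
    Only ``ok`` rows enter cohort tests.
    """
    label = rng.label if isinstance(rng, VolumeRange) else rng
    den = _pivot_timepoints(density_df[density_df["range"] == label], "n_rho")
    pft = _pivot_timepoints(pft_df, parameter)
    patients = sorted(set(den.index) | set(pft.index))
    rows = []
    for pid in patients:
        x = den.loc[pid].to_numpy() if pid in den.index else np.full(3, np.nan)
        y = pft.loc[pid].to_numpy() if pid in pft.index else np.full(3, np.nan)
        r, status = pearson_three_point(x, y)
        rows.append(
            {
                "patient_id": pid,
                "range": label,
                "pft_parameter": parameter,
                "r": r,
                "z": fisher_z(r) if status == STATUS_OK else math.nan,
                "n_timepoints": int(np.sum(np.isfinite(x) & np.isfinite(y))),
                "status": status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "range", "pft_parameter", "r", "z",
                 "n_timepoints", "status"],
    )


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r per row of two (n, k) matrices; rows with zero variance → NaN."""
    dx = x - x.mean(axis=1, keepdims=True)
    dy = y - y.mean(axis=1, keepdims=True)
    sxx = (dx * dx).sum(axis=1)
    syy = (dy * dy).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dx * dy).sum(axis=1) / np.sqrt(sxx * syy)
    r[(sxx == 0) | (syy == 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlation_triangle(
    density_df: pd.DataFrame,
    pft_df: pd.DataFrame,
    parameter: str = "dlco",
    pairs: Optional[Sequence[VolumeRange]] = None,
    family_size: Optional[int] = None,
) -> pd.DataFrame:
    """Cohort test per (high, low) isodose cell of the correlation triangle.

    ``pairs`` defaults to the standard triangle family (high in
    {Dmax, 95, 85, 75, 65}, low in {95 ... 5}). The Bonferroni family size
    defaults to the number of cells actually tested. The significance tier
    encodes the raw p-value in three levels (high / moderate / ns); the
    corrected p-value is reported alongside.
    """
    if pairs is None:
        pairs = triangle_ranges()
    m = int(family_size) if family_size is not None else len(pairs)
    pft = _pivot_timepoints(pft_df, parameter).dropna()
    y_index = pft.index
    rows = []
    den_by_range = dict(tuple(density_df.groupby("range")))
    for rng in pairs:
        sub = den_by_range.get(rng.label)
        out = {
            "range": rng.label,
            "high": ("Dmax" if rng.is_open_top else rng.high),
            "low": rng.low,
            "pft_parameter": parameter,
        }
        if sub is None:
            rows.append({**out, "n_patients": 0, "n_degenerate": 0,
                         "mean_z": math.nan, "t_statistic": math.nan,
                         "p_raw": math.nan, "p_corrected": math.nan,
                         "family_size": m, "tier": "insufficient"})
            continue
        den = _pivot_timepoints(sub, "n_rho").dropna()
        common = den.index.intersection(y_index)
        x = den.loc[common].to_numpy()
        y = pft.loc[common].to_numpy()
        r = _rowwise_pearson(x, y)
        ok = np.isfinite(r)
        n_degenerate = int((~ok).sum())
        z = np.array([fisher_z(v) for v in r[ok]])
        t_stat, p_raw, n = cohort_test(z)
        p_corr = bonferroni(p_raw, m) if np.isfinite(p_raw) else math.nan
        tier = significance_tier(p_raw) if np.isfinite(p_raw) else "insufficient"
        rows.append({**out, "n_patients": n, "n_degenerate": n_degenerate,
                     "mean_z": float(z.mean()) if z.size else math.nan,
                     "t_statistic": t_stat, "p_raw": p_raw,
                     "p_corrected": p_corr, "family_size": m, "tier": tier})
    return pd.DataFrame(
        rows,
        columns=["range", "high", "low", "pft_parameter", "n_patients",
                 "n_degenerate", "mean_z", "t_statistic", "p_raw",
                 "p_corrected", "family_size", "tier"],
    )


@dataclass
class ChangeTestResult:
    quantity: str
    comparison: str
    n_pairs: int
    mean_relative_change_pct: float
    p_value: float


def _relative_change_pct(baseline: np.ndarray, later: np.ndarray) -> np.ndarray:
    return (later - baseline) / baseline * 100.0


def change_tests(
    density_df: pd.DataFrame,
    pft_df: pd.DataFrame,
    quantities: Optional[Sequence[str]] = None,
    comparisons: Sequence[tuple[str, str]] = (("tpre", "t3m"), ("tpre", "t6m")),
    two_sided: bool = True,
) -> pd.DataFrame:
    """Relative temporal change of n_rho and PFT values versus baseline.

    Per patient: (value(t) - value(tpre)) / value(tpre) * 100; per quantity
    and comparison a paired (one-sample-on-differences) t-test, two-sided by
    default. Quantities are PFT parameter names ("dlco", "fev1") or density
    range labels ("V65-45%"). Patients with a zero baseline are excluded and
    logged.
    """
    if quantities is None:
        quantities = ["dlco", "fev1"] + sorted(density_df["range"].unique())
    pivots: dict[str, pd.DataFrame] = {}
    for q in quantities:
        if q in ("dlco", "fev1"):
            pivots[q] = _pivot_timepoints(pft_df, q)
        else:
            pivots[q] = _pivot_timepoints(
                density_df[density_df["range"] == q], "n_rho"
            )
    rows = []
    for q in quantities:
        piv = pivots[q]
        for t0, t1 in comparisons:
            sub = piv[[t0, t1]].dropna()
            base = sub[t0].to_numpy()
            nonzero = base != 0
            if not np.all(nonzero):
                logger.warning(
                    "change_tests: %d zero-baseline patients excluded for %s",
                    int((~nonzero).sum()), q,
                )
            changes = _relative_change_pct(base[nonzero], sub[t1].to_numpy()[nonzero])
            n = changes.size
            if n < 2:
                rows.append(ChangeTestResult(q, f"{t0}->{t1}", n, math.nan, math.nan))
                continue
            if float(np.std(changes, ddof=1)) == 0.0:
                p = 1.0 if float(changes.mean()) == 0.0 else 0.0
            else:
                res = sps.ttest_1samp(
                    changes, 0.0,
                    alternative="two-sided" if two_sided else "less",
                )
                p = float(res.pvalue)
            rows.append(
                ChangeTestResult(q, f"{t0}->{t1}", n, float(changes.mean()), p)
            )
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["quantity", "comparison", "n_pairs",
                 "mean_relative_change_pct", "p_value"],
    )


def volume_size_prediction(
    sizes_df: pd.DataFrame,
    pft_df: pd.DataFrame,
    ranges: Sequence[VolumeRange],
    parameter: str = "dlco",
    timepoint: str = "t3m",
    family_size: Optional[int] = None,
) -> pd.DataFrame:
    """Does the relative size of a dose subvolume predict PFT decline?

    For each range, the cross-patient Pearson correlation between the
    subvolume's relative size (% of lung) and the *relative change* of the
    PFT parameter at ``timepoint`` versus baseline. Negative r means larger
    subvolumes go with larger declines. p-values are two-sided, Bonferroni
    corrected over ``family_size`` (default: number of ranges tested).
    """
    if timepoint not in TIMEPOINTS or timepoint == "tpre":
        raise ValueError(f"timepoint must be t3m or t6m, got {timepoint!r}")
    m = int(family_size) if family_size is not None else len(ranges)
    pft = _pivot_timepoints(pft_df, parameter)[["tpre", timepoint]].dropna()
    pft = pft[pft["tpre"] != 0]
    change = pd.Series(
        _relative_change_pct(pft["tpre"].to_numpy(), pft[timepoint].to_numpy()),
        index=pft.index,
    )
    sizes_by_range = dict(tuple(sizes_df.groupby("range")))
    rows = []
    for rng in ranges:
        sub = sizes_by_range.get(rng.label)
        out = {"range": rng.label, "timepoint": timepoint, "pft_parameter": parameter}
        if sub is None:
            rows.append({**out, "n_patients": 0, "r": math.nan, "p_raw": math.nan,
                         "p_corrected": math.nan, "family_size": m,
                         "status": STATUS_INSUFFICIENT})
            continue
        size = sub.set_index("patient_id")["relative_size_pct"]
        common = size.index.intersection(change.index)
        x = size.loc[common].to_numpy(dtype=float)
        y = change.loc[common].to_numpy(dtype=float)
        n = x.size
        if n < 3:
            rows.append({**out, "n_patients": n, "r": math.nan, "p_raw": math.nan,
                         "p_corrected": math.nan, "family_size": m,
                         "status": STATUS_INSUFFICIENT})
            continue
        if float(np.std(x)) == 0.0 or float(np.std(y)) == 0.0:
            rows.append({**out, "n_patients": n, "r": math.nan, "p_raw": math.nan,
                         "p_corrected": math.nan, "family_size": m,
                         "status": STATUS_DEGENERATE})
            continue
        res = sps.pearsonr(x, y)
        p_raw = float(res.pvalue)
        rows.append({**out, "n_patients": n, "r": float(res.statistic),
                     "p_raw": p_raw, "p_corrected": bonferroni(p_raw, m),
                     "family_size": m, "status": STATUS_OK})
    return pd.DataFrame(
        rows,
        columns=["range", "timepoint", "pft_parameter", "n_patients", "r",
                 "p_raw", "p_corrected", "family_size", "status"],
    )
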