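"""Equivalence, reliability and paired-comparison statistics.

The statistical layer answers three questions about paired volume (or
timing) measurements:

* **Is the new method equivalent to the reference?**  Two one-sided tests
  (TOST) on the paired differences with equivalence margin ±0.15 cm^3:
  equivalence is declared when both one-sided tests reject at α, which is
  the same event as the (1−2α) = 90 % confidence interval of the mean
  difference lying entirely inside the margin.  The standard paired t-test
  (NHST) is reported alongside.
* **Is the measurement repeatable?**  Intraclass correlation from a
  two-way mixed-effects model with single measurements, absolute agreement
  — ICC(A,1) — for test–retest of the same rater, with the F-distribution
  confidence interval and the Koo–Li interpretation bands
  (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, ≥ 0.9 excellent).
  Consistency ICC(C,1) is available via a flag.
* **Do paired non-normal samples differ?**  Wilcoxon signed-rank on the
  paired differences (zeros dropped, ties mid-ranked; exact null
  distribution for n ≤ 25, normal approximation with continuity correction
  beyond).

Pairs with a missing side are excluded from analysis and counted
explicitly (complete-case analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import IncompleteDesignError, SchemaError

DEFAULT_MARGIN_CM3 = 0.15
DEFAULT_ALPHA = 0.05

_EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedMeasurements:
    """Per-specimen paired values (method A vs method B)."""

    specimens: np.ndarray
    method_a: np.ndarray
    method_b: np.ndarray

    n_excluded: int = 0  # pairs dropped for a missing side

    @classmethod
    def from_arrays(cls, specimens, a, b) -> "PairedMeasurements":
        specimens = np.asarray(specimens)
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if not (len(specimens) == len(a) == len(b)):
            raise SchemaError("specimen ids and both value arrays must align")
        ok = np.isfinite(a) & np.isfinite(b)
        return cls(
            specimens=specimens[ok],
            method_a=a[ok],
            method_b=b[ok],
            n_excluded=int((~ok).sum()),
        )

    @property
    def differences(self) -> np.ndarray:
        return self.method_a - self.method_b

    def __len__(self) -> int:
        return len(self.method_a)


@dataclass
class EquivalenceResult:
    mean_difference: float
    ci90: tuple
    ci95: tuple
    tost_p: float
    nhst_p: float
    margin: float
    alpha: float
    n: int
    n_excluded: int
    equivalent: bool
    different_from_zero: bool


@dataclass
class ICCResult:
    icc: float
    ci95: tuple
    model: str
    interpretation: str
    anova: dict = field(default_factory=dict)


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_used: int
    n_zero: int
    method: str  # "exact" | "approx" | "degenerate"


def _t_ci(d: np.ndarray, level: float) -> tuple:
    n = len(d)
    m = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n))
    if se == 0.0:
        return (m, m)
    tcrit = sps.t.ppf(0.5 + level / 2.0, n - 1)
    return (m - tcrit * se, m + tcrit * se)


def tost_paired(
    pairs: PairedMeasurements,
    margin: float = DEFAULT_MARGIN_CM3,
    alpha: float = DEFAULT_ALPHA,
) -> EquivalenceResult:
    """TOST equivalence + paired NHST t-test on method_a − method_b.

    ``tost_p`` is the larger of the two one-sided p-values (mean > −margin
    and mean < +margin); equivalence at level α is the same decision as the
    (1−2α) CI lying inside (−margin, +margin).
    """
    if margin <= 0:
        raise ValueError("equivalence margin must be positive")
    d = pairs.differences
    n = len(d)
    if n < 3:
        raise SchemaError(f"need at least 3 complete pairs, got {n}")
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    df = n - 1
    if se == 0.0:
        # all differences identical: degenerate, decide by the mean alone
        inside = abs(m) < margin
        return EquivalenceResult(
            mean_difference=m,
            ci90=(m, m),
            ci95=(m, m),
            tost_p=0.0 if inside else 1.0,
            nhst_p=1.0 if m == 0 else 0.0,
            margin=margin,
            alpha=alpha,
            n=n,
            n_excluded=pairs.n_excluded,
            equivalent=inside,
            different_from_zero=m != 0,
        )
    t_lower = (m + margin) / se  # H0: mean <= -margin
    t_upper = (m - margin) / se  # H0: mean >= +margin
    p_lower = float(sps.t.sf(t_lower, df))
    p_upper = float(sps.t.cdf(t_upper, df))
    tost_p = max(p_lower, p_upper)
    t_nhst = m / se
    nhst_p = float(2 * sps.t.sf(abs(t_nhst), df))
    ci90 = _t_ci(d, 1 - 2 * alpha)
    return EquivalenceResult(
        mean_difference=m,
        ci90=ci90,
        ci95=_t_ci(d, 1 - alpha),
        tost_p=tost_p,
        nhst_p=nhst_p,
        margin=margin,
        alpha=alpha,
        n=n,
        n_excluded=pairs.n_excluded,
        equivalent=tost_p < alpha,
        different_from_zero=nhst_p < alpha,
    )


def interpret_icc(icc: float) -> str:
    """Koo–Li reliability bands for an ICC point estimate."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def icc_two_way_mixed_single(
    ratings: np.ndarray, alpha: float = DEFAULT_ALPHA, agreement: bool = True
) -> ICCResult:
    """Two-way mixed-effects, single-measure ICC over an (n_subjects, 2) array.

    ``agreement=True`` gives absolute agreement, ICC(A,1) — the test–retest
    form (the two columns are the same quantity measured at t0 and t1) —
    with the McGraw–Wong F-based confidence interval.  ``agreement=False``
    gives consistency, ICC(C,1).
    """
    X = np.asarray(ratings, float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise IncompleteDesignError("ratings must be an (n_subjects, 2) array")
    if not np.isfinite(X).all():
        raise IncompleteDesignError("every subject needs both ratings")
    n, k = X.shape
    if n < 5:
        raise IncompleteDesignError(f"need at least 5 subjects, got {n}")

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    SSR = k * ((row_means - grand) ** 2).sum()  # subjects
    SSC = n * ((col_means - grand) ** 2).sum()  # timepoints
    SST = ((X - grand) ** 2).sum()
    SSE = SST - SSR - SSC
    MSR = SSR / (n - 1)
    MSC = SSC / (k - 1)
    MSE = SSE / ((n - 1) * (k - 1))

    if agreement:
        denom = MSR + (k - 1) * MSE + (k / n) * (MSC - MSE)
        icc = (MSR - MSE) / denom if denom > 0 else 1.0
        # McGraw & Wong CI for ICC(A,1)
        r = icc
        if MSE == 0 and MSC == MSR:
            lo, hi = 1.0, 1.0
        else:
            a = (k * r) / (n * (1 - r)) if r < 1 else np.inf
            b = 1 + (k * r * (n - 1)) / (n * (1 - r)) if r < 1 else np.inf
            if np.isinf(a):
                lo, hi = 1.0, 1.0
            else:
                num = (a * MSC + b * MSE) ** 2
                den = (a * MSC) ** 2 / (k - 1) + (b * MSE) ** 2 / ((n - 1) * (k - 1))
                v = num / den if den > 0 else n - 1
                f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
                f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
                lo = (n * (MSR - f_l * MSE)) / (
                    f_l * (k * MSC + (k * n - k - n) * MSE) + n * MSR
                )
                hi = (n * (f_u * MSR - MSE)) / (
                    k * MSC + (k * n - k - n) * MSE + n * f_u * MSR
                )
        model = "two-way mixed, single measures, absolute agreement (A,1)"
    else:
        denom = MSR + (k - 1) * MSE
        icc = (MSR - MSE) / denom if denom > 0 else 1.0
        if MSE == 0:
            lo, hi = 1.0, 1.0
        else:
            F = MSR / MSE
            f_l = F / sps.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
            f_u = F * sps.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
            lo = (f_l - 1) / (f_l + k - 1)
            hi = (f_u - 1) / (f_u + k - 1)
        model = "two-way mixed, single measures, consistency (C,1)"

    icc = float(min(icc, 1.0))
    return ICCResult(
        icc=icc,
        ci95=(float(min(lo, 1.0)), float(min(hi, 1.0))),
        model=model,
        interpretation=interpret_icc(icc),
        anova={"MSR": MSR, "MSC": MSC, "MSE": MSE, "n": n, "k": k},
    )


def wilcoxon_signed_rank(pairs: PairedMeasurements) -> WilcoxonResult:
    """Two-sided paired signed-rank test on method_a − method_b.

    Zeros are dropped; ties are mid-ranked.  Exact null distribution for
    n ≤ 25 remaining differences, normal approximation with continuity
    correction beyond.
    """
    d = pairs.differences
    nz = d[d != 0]
    n_zero = len(d) - len(nz)
    if len(nz) == 0:
        return WilcoxonResult(
            statistic=0.0, p_value=1.0, n_used=0, n_zero=n_zero, method="degenerate"
        )
    if len(nz) < 5:
        raise SchemaError(f"need at least 5 non-zero differences, got {len(nz)}")
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    if len(nz) <= _EXACT_WILCOXON_MAX_N and not has_ties:
        res = sps.wilcoxon(nz, zero_method="wilcox", method="exact")
        stat, p, method = float(res.statistic), float(res.pvalue), "exact"
    elif len(nz) <= 12:
        # ties break the standard exact recursion; with so few pairs the
        # 2^n sign-assignment null distribution is enumerated directly
        stat, p = _enumerated_signed_rank(nz)
        method = "exact"
    else:
        res = sps.wilcoxon(
            nz, zero_method="wilcox", correction=True, method="approx"
        )
        stat, p, method = float(res.statistic), float(res.pvalue), "approx"
    return WilcoxonResult(
        statistic=stat,
        p_value=p,
        n_used=len(nz),
        n_zero=n_zero,
        method=method,
    )


def _enumerated_signed_rank(d: np.ndarray):
    """Exact two-sided signed-rank p over all 2^n sign assignments
    (mid-ranked ties), for small n."""
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mean_w = ranks.sum() / 2.0
    # all subset rank-sums via bit masks
    masks = np.arange(2**n, dtype=np.uint32)
    sums = np.zeros(2**n)
    for i in range(n):
        sums[(masks >> i) & 1 == 1] += ranks[i]
    p = float(
        (np.abs(sums - mean_w) >= abs(w_obs - mean_w) - 1e-12).mean()
    )
    return min(w_obs, ranks.sum() - w_obs), p


REQUIRED_COLUMNS = {"specimen", "technique", "method", "timepoint", "value"}


def summarize_table(
    measurements: pd.DataFrame,
    margin: float = DEFAULT_MARGIN_CM3,
    alpha: float = DEFAULT_ALPHA,
    value_column: str = "value",
    wilcoxon: bool = False,
) -> pd.DataFrame:
    """Per-technique/timepoint summary of two paired measurement methods.

    Expects a tidy table with columns ``specimen, technique, method,
    timepoint`` and a value column; the two levels of ``method`` are paired
    on specimen within each technique × timepoint cell.  Emits mean ± SD per
    method, n per cell, the mean difference with 90 % CI and TOST/NHST p —
    and, with ``wilcoxon=True``, the paired signed-rank p instead of TOST
    (the timing-comparison layout).
    """
    if measurements is None or len(measurements) == 0:
        raise SchemaError("empty measurement table")
    required = (REQUIRED_COLUMNS - {"value"}) | {value_column}
    missing = required - set(measurements.columns)
    if missing:
        raise SchemaError(f"measurement table is missing columns {sorted(missing)}")
    methods = sorted(measurements["method"].unique())
    if len(methods) != 2:
        raise SchemaError(f"need exactly 2 methods to compare, got {methods}")
    ma, mb = methods

    rows = []
    for (tech, tp), cell in measurements.groupby(["technique", "timepoint"]):
        wide = cell.pivot_table(
            index="specimen", columns="method", values=value_column, aggfunc="first"
        )
        a = wide[ma] if ma in wide else pd.Series(dtype=float)
        b = wide[mb] if mb in wide else pd.Series(dtype=float)
        wide = wide.reindex(columns=[ma, mb])
        pairs = PairedMeasurements.from_arrays(
            wide.index.to_numpy(), wide[ma].to_numpy(), wide[mb].to_numpy()
        )
        row = {
            "technique": tech,
            "timepoint": tp,
            f"mean_{ma}": float(np.nanmean(wide[ma])) if wide[ma].notna().any() else np.nan,
            f"sd_{ma}": float(np.nanstd(wide[ma], ddof=1)),
            f"n_{ma}": int(wide[ma].notna().sum()),
            f"mean_{mb}": float(np.nanmean(wide[mb])) if wide[mb].notna().any() else np.nan,
            f"sd_{mb}": float(np.nanstd(wide[mb], ddof=1)),
            f"n_{mb}": int(wide[mb].notna().sum()),
            "n_pairs": len(pairs),
            "n_excluded": pairs.n_excluded,
        }
        if wilcoxon:
            w = wilcoxon_signed_rank(pairs)
            row.update({"wilcoxon_p": w.p_value, "wilcoxon_method": w.method})
        else:
            eq = tost_paired(pairs, margin=margin, alpha=alpha)
            row.update(
                {
                    "mean_difference": eq.mean_difference,
                    "ci90_lower": eq.ci90[0],
                    "ci90_upper": eq.ci90[1],
                    "tost_p": eq.tost_p,
                    "nhst_p": eq.nhst_p,
                    "equivalent": eq.equivalent,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
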