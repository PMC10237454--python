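"""Concurrent-validity and test-retest agreement statistics.

Pearson r with interpretation bands, two-way mixed consistency ICC for
the average of k=2 measurements (ICC(3,2), Shrout-Fleiss), and
Bland-Altman 95% limits of agreement with outlier counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tugspeed.errors import InvalidInputError

__all__ = [
    "PairedTable",
    "ValidityResult",
    "ReliabilityResult",
    "BlandAltmanResult",
    "pearson_validity",
    "icc_3_2",
    "bland_altman",
    "read_paired_csv",
]

#: |r| interpretation cut-points: low < 0.50 <= moderate < 0.70 <= high;
#: r > 0.90 is very high (0.90 itself still counts as high).
_R_BANDS = ((0.50, "low"), (0.70, "moderate"), (0.90, "high"))

#: ICC interpretation: poor < 0.50 <= moderate < 0.70 <= good; >= 0.90 excellent.
_ICC_BANDS = ((0.50, "poor"), (0.70, "moderate"), (0.90, "good"))

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedTable:
    """Per-subject paired measurements (system A/B or session 1/2)."""

    value_a: np.ndarray
    value_b: np.ndarray
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        object.__setattr__(self, "value_a", np.asarray(self.value_a, dtype=np.float64))
        object.__setattr__(self, "value_b", np.asarray(self.value_b, dtype=np.float64))
        if self.value_a.shape != self.value_b.shape or self.value_a.ndim != 1:
            raise InvalidInputError("paired columns must be 1-D and equally long")
        if len(self.value_a) < 3:
            raise InvalidInputError(f"need >= 3 pairs, got {len(self.value_a)}")
        if not (np.isfinite(self.value_a).all() and np.isfinite(self.value_b).all()):
            raise InvalidInputError("paired values must be finite")

    def __len__(self) -> int:
        return len(self.value_a)


@dataclass(frozen=True)
class ValidityResult:
    r: float
    p_value: float
    n: int
    band: str


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    band: str


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    n_outside: int
    pct_outside: float


def _band(value: float, cuts) -> str:
    for cut, name in cuts:
        if value < cut:
            return name
    return "very high" if cuts is _R_BANDS else "excellent"


def pearson_validity(table: PairedTable) -> ValidityResult:
    """Sample Pearson r with a two-sided t-test p (n-2 df)."""
    if np.std(table.value_a) == 0 or np.std(table.value_b) == 0:
        raise InvalidInputError("zero variance in a column: correlation undefined")
    res = stats.pearsonr(table.value_a, table.value_b)
    r = float(res.statistic)
    return ValidityResult(r=r, p_value=float(res.pvalue), n=len(table), band=_band(abs(r), _R_BANDS))


def _anova_two_way(a: np.ndarray, b: np.ndarray):
    """Mean squares of the two-way (subjects x measurements) decomposition."""
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    ss_cols = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_err = np.sum((data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand) ** 2)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ss_cols / (k - 1), ms_err, n, k


def icc_3_2(table: PairedTable, alpha: float = 0.05, consistency: bool = True) -> ReliabilityResult:
    """Two-way mixed, average-measures intraclass correlation (k = 2).

    The default is the consistency form ICC(C,k) = (MS_R - MS_E) / MS_R,
    with the 95% CI and p from the F = MS_R / MS_E distribution
    (Shrout-Fleiss).  ``consistency=False`` switches to absolute agreement
    ICC(A,k) (McGraw-Wong two-way mixed with the column mean square in the
    denominator); its CI uses the Satterthwaite approximation.
    """
    ms_r, ms_c, ms_e, n, k = _anova_two_way(table.value_a, table.value_b)
    if ms_r <= 0:
        raise InvalidInputError("zero between-subject variance: ICC undefined")
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = ms_r / ms_e
    p = float(stats.f.sf(f_obs, df1, df2))
    if consistency:
        icc = (ms_r - ms_e) / ms_r
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci_low, ci_high = 1 - 1 / f_l, 1 - 1 / f_u
    else:
        icc = (ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n)
        ci_low, ci_high = _icc_a_k_ci(ms_r, ms_c, ms_e, n, k, alpha)
    band = _band(icc, _ICC_BANDS)
    return ReliabilityResult(
        icc=float(icc),
        ci_low=float(min(ci_low, icc)),
        ci_high=float(max(ci_high, icc)),
        p_value=p,
        n=n,
        band=band,
    )


def _icc_a_k_ci(ms_r, ms_c, ms_e, n, k, alpha):
    """McGraw-Wong CI for the absolute-agreement average-measures ICC.

    The single-measures bounds (with Satterthwaite degrees of freedom) are
    stepped up with the Spearman-Brown relation.
    """
    icc1 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)
    a = k * icc1 / (n * (1 - icc1))
    b = 1 + k * icc1 * (n - 1) / (n * (1 - icc1))
    nu = (a * ms_c + b * ms_e) ** 2 / (
        (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, nu)
    f_u = stats.f.ppf(1 - alpha / 2, nu, n - 1)
    lo1 = n * (ms_r - f_l * ms_e) / (f_l * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r)
    hi1 = n * (f_u * ms_r - ms_e) / (k * ms_c + (k * n - k - n) * ms_e + n * f_u * ms_r)
    step_up = lambda r1: k * r1 / (1 + (k - 1) * r1)  # noqa: E731
    return step_up(lo1), step_up(hi1)


def bland_altman(table: PairedTable) -> BlandAltmanResult:
    """Mean difference +/- 1.96 SD limits of agreement (sample SD, n-1)."""
    diff = table.value_a - table.value_b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    loa_low = mean_diff - LOA_MULTIPLIER * sd_diff
    loa_high = mean_diff + LOA_MULTIPLIER * sd_diff
    outside = (diff < loa_low) | (diff > loa_high)
    n = len(table)
    n_outside = int(outside.sum())
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        n=n,
        n_outside=n_outside,
        pct_outside=100.0 * n_outside / n,
    )


def read_paired_csv(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a per-subject table: column ``subject_id`` plus value columns."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise InvalidInputError(f"{path}: missing 'subject_id' column")
    return df["subject_id"].to_numpy(), df.set_index("subject_id")
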