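"""Reliability and agreement statistics for repeated angle measurements.

Implements the full test-retest / inter-rater / inter-instrument workflow
used to validate photographic goniometry:

* ICC from the two-way ANOVA mean squares, with 95% CI from the
  F-distribution (McGraw & Wong formulation). Default form is ICC(2,1) —
  two-way random effects, absolute agreement, single measurement — with
  ICC(3,1) (two-way mixed, consistency) available by config.
* Qualitative bands per Koo & Li: <0.50 poor, 0.50-0.75 moderate,
  0.75-0.90 good, >=0.90 excellent.
* SEM = SD * sqrt(1 - ICC) and MDC95 = 1.96 * sqrt(2) * SEM.
* CV% = SD / mean * 100, averaged across conditions.
* Pearson correlation with banding (strong > 0.70, moderate 0.50-0.70,
  low < 0.30; the 0.30-0.50 gap is tagged "unclassified").
* Bland-Altman bias and 95% limits of agreement, plus the
  between-instrument SEM = SD(differences) / sqrt(2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DesignColumnsMissing,
    IccAboveOne,
    InsufficientSubjects,
    NonPositiveMean,
    ZeroVariance,
)
from .geometry import AngleRecord

logger = logging.getLogger(__name__)

MDC_FACTOR = 1.96 * math.sqrt(2.0)

DESIGNS = ("test_retest", "inter_rater", "inter_instrument")
#: which long-format column distinguishes the two conditions of each design
DESIGN_CONDITION_COLUMN = {
    "test_retest": "occasion",
    "inter_rater": "rater_id",
    "inter_instrument": "instrument",
}

__all__ = [
    "MeasurementTable",
    "ReliabilityReport",
    "AgreementResult",
    "icc_two_way",
    "classify_icc",
    "sem",
    "mdc95",
    "cv_percent",
    "pearson",
    "bland_altman",
    "build_report",
]


# ----------------------------------------------------------------------
# measurement table


@dataclass
class MeasurementTable:
    """Long-format collection of angle records for one reliability design."""

    data: pd.DataFrame  # columns: subject_id, rater_id, occasion, instrument, angle_deg
    design: str = "test_retest"

    REQUIRED = ("subject_id", "rater_id", "occasion", "instrument", "angle_deg")

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}, got {self.design!r}")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise DesignColumnsMissing(f"table lacks column(s): {missing}")
        keys = self.data[["subject_id", "rater_id", "occasion", "instrument"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate measurement key {dup}")

    @classmethod
    def from_records(cls, records: Iterable[AngleRecord], design: str = "test_retest") -> "MeasurementTable":
        from .geometry import records_to_frame

        return cls(records_to_frame(records), design=design)

    @classmethod
    def from_csv(cls, path: str | Path, design: str = "test_retest") -> "MeasurementTable":
        return cls(pd.read_csv(path), design=design)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def pivot(self) -> pd.DataFrame:
        """Subjects x 2-condition wide matrix for this table's design.

        The condition column is ``occasion`` (test-retest), ``rater_id``
        (inter-rater) or ``instrument`` (inter-instrument); exactly two
        levels must be present. Subjects missing either cell are dropped
        with a logged warning (listwise deletion, no imputation).
        """
        cond = DESIGN_CONDITION_COLUMN[self.design]
        levels = sorted(self.data[cond].unique())
        if len(levels) != 2:
            raise DesignColumnsMissing(
                f"design {self.design!r} needs exactly 2 levels of {cond!r}, "
                f"found {levels}"
            )
        wide = self.data.pivot_table(
            index="subject_id", columns=cond, values="angle_deg", aggfunc="mean"
        )
        complete = wide.dropna()
        n_dropped = len(wide) - len(complete)
        if n_dropped:
            logger.warning(
                "%d subject(s) dropped for missing cells in %s design", n_dropped, self.design
            )
        return complete


# ----------------------------------------------------------------------
# ICC


def _mean_squares(matrix: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares (rows=subjects, columns=conditions)."""
    y = np.asarray(matrix, dtype=float)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)  # guard rounding below zero
    return msr, msc, mse, n, k


def icc_two_way(
    matrix: np.ndarray | pd.DataFrame,
    form: str = "icc2_1",
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """ICC point estimate and (1-alpha) CI from a subjects x conditions matrix.

    ``form`` is ``"icc2_1"`` (two-way random, absolute agreement, single
    measurement; the default, appropriate when raters/occasions should
    generalize) or ``"icc3_1"`` (two-way mixed, consistency). The CI comes
    from the F-distribution; for ICC(2,1) the denominator degrees of
    freedom use the Satterthwaite approximation.

    Raises :class:`InsufficientSubjects` for n < 3 and
    :class:`ZeroVariance` when every value is identical.
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError(f"need a 2-D subjects x conditions matrix, got shape {y.shape}")
    msr, msc, mse, n, k = _mean_squares(y)
    if n < 3:
        raise InsufficientSubjects(f"ICC needs >= 3 subjects, got {n}")
    if np.allclose(y, y.flat[0]):
        raise ZeroVariance("all measurements identical; ICC undefined")

    if form == "icc2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom <= 0:
            raise ZeroVariance("zero total variance; ICC undefined")
        icc = (msr - mse) / denom
        if mse == 0.0 and msc == 0.0:
            # perfect agreement with subject variance: CI collapses to 1
            return 1.0, (1.0, 1.0)
        a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else math.inf
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
        if not math.isfinite(a):
            return icc, (1.0, 1.0)
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den if v_den > 0 else 1.0
        f_lower = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_upper = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lo = n * (msr - f_lower * mse) / (
            f_lower * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_upper * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_upper * msr
        )
    elif form == "icc3_1":
        denom = msr + (k - 1) * mse
        if denom <= 0:
            raise ZeroVariance("zero variance; ICC undefined")
        icc = (msr - mse) / denom
        if mse == 0.0:
            return icc, (icc, icc)
        f_obs = msr / mse
        df2 = (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1.0 - alpha / 2.0, n - 1, df2)
        fu = f_obs * stats.f.ppf(1.0 - alpha / 2.0, df2, n - 1)
        lo = (fl - 1.0) / (fl + k - 1.0)
        hi = (fu - 1.0) / (fu + k - 1.0)
    else:
        raise ValueError(f"unknown ICC form {form!r} (use 'icc2_1' or 'icc3_1')")

    lo = min(lo, icc)
    hi = max(hi, icc)
    return float(icc), (float(max(lo, -1.0)), float(min(hi, 1.0)))


def classify_icc(icc: float) -> str:
    """Koo-Li qualitative band for an ICC point estimate."""
    if not (-1.0 <= icc <= 1.0):
        raise ValueError(f"ICC must lie in [-1, 1], got {icc}")
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"


# ----------------------------------------------------------------------
# derived indices


def sem(sd: float, icc: float) -> float:
    """Standard error of measurement: SD * sqrt(1 - ICC)."""
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if icc > 1.0:
        raise IccAboveOne(f"ICC must be <= 1, got {icc}")
    return sd * math.sqrt(1.0 - icc)


def mdc95(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence: 1.96 * sqrt(2) * SEM."""
    if sem_value < 0:
        raise ValueError(f"sem must be >= 0, got {sem_value}")
    return MDC_FACTOR * sem_value


def cv_percent(matrix: np.ndarray | pd.DataFrame) -> tuple[float, list[float]]:
    """Coefficient of variation, percent.

    Per condition, CV = SD/mean * 100 (sample SD, n-1); returns the
    arithmetic mean across conditions together with the per-condition
    values. Means must be positive.
    """
    y = np.asarray(matrix, dtype=float)
    means = y.mean(axis=0)
    if np.any(means <= 0):
        raise NonPositiveMean(f"condition means must be > 0, got {means}")
    sds = y.std(axis=0, ddof=1)
    per_condition = (sds / means * 100.0).tolist()
    return float(np.mean(per_condition)), per_condition


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Product-moment correlation, two-sided p from the t-transform, and band.

    Banding follows |r|: strong > 0.70, moderate in [0.50, 0.70], low
    < 0.30, and the unnamed [0.30, 0.50) gap is tagged "unclassified".
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = xv.size
    if n < 3:
        raise ValueError(f"need >= 3 pairs, got {n}")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVariance("constant input; correlation undefined")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p), _pearson_band(abs(r))


def _pearson_band(r_abs: float) -> str:
    if r_abs > 0.70:
        return "strong"
    if r_abs >= 0.50:
        return "moderate"
    if r_abs < 0.30:
        return "low"
    return "unclassified"


# ----------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class AgreementResult:
    """Pearson + Bland-Altman agreement between two instruments."""

    pearson_r: float
    r_pvalue: float
    r_band: str
    bias: float
    loa_low: float
    loa_high: float
    pairs: list[tuple[float, float]]  # (mean of two, difference)
    between_instrument_sem: float

    def to_dict(self) -> dict:
        return {
            "pearson_r": round(self.pearson_r, 4),
            "r_pvalue": self.r_pvalue,
            "r_band": self.r_band,
            "bias": round(self.bias, 4),
            "loa_low": round(self.loa_low, 4),
            "loa_high": round(self.loa_high, 4),
            "between_instrument_sem": round(self.between_instrument_sem, 4),
            "n_pairs": len(self.pairs),
        }

    def pairs_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pairs, columns=["mean", "difference"])
        df["bias"] = self.bias
        df["loa_low"] = self.loa_low
        df["loa_high"] = self.loa_high
        return df


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Bland-Altman agreement of two paired measurement vectors.

    Differences d = x - y; bias = mean(d); 95% limits of agreement
    bias +/- 1.96 * SD(d) (sample SD, n-1); the between-instrument SEM is
    SD(d)/sqrt(2). Pearson r of the raw vectors is attached for the
    concurrent-validity readout.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1 or xv.size < 3:
        raise ValueError("need equal-length vectors with >= 3 pairs")
    d = xv - yv
    bias = float(d.mean())
    sd_d = float(d.std(ddof=1))
    try:
        r, p, band = pearson(xv, yv)
    except ZeroVariance:
        r, p, band = float("nan"), float("nan"), "unclassified"
    return AgreementResult(
        pearson_r=r,
        r_pvalue=p,
        r_band=band,
        bias=bias,
        loa_low=bias - 1.96 * sd_d,
        loa_high=bias + 1.96 * sd_d,
        pairs=list(zip(((xv + yv) / 2.0).tolist(), d.tolist())),
        between_instrument_sem=sd_d / math.sqrt(2.0),
    )


# ----------------------------------------------------------------------
# full report


@dataclass(frozen=True)
class ReliabilityReport:
    """All reliability indices for one design, one table row per analysis."""

    icc: float
    icc_ci95: tuple[float, float]
    icc_band: str
    sem_deg: float
    mdc95_deg: float
    cv_pct: float
    cv_by_condition: list[float]
    mean_by_condition: list[float]
    sd_by_condition: list[float]
    condition_labels: list[str]
    n_subjects: int
    icc_form: str
    design: str
    sd_pooling: str

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "n_subjects": self.n_subjects,
            "icc_form": self.icc_form,
            "icc": round(self.icc, 3),
            "icc_ci95": [round(v, 3) for v in self.icc_ci95],
            "icc_band": self.icc_band,
            "sem_deg": round(self.sem_deg, 2),
            "mdc95_deg": round(self.mdc95_deg, 2),
            "cv_pct": round(self.cv_pct, 2),
            "cv_by_condition": [round(v, 2) for v in self.cv_by_condition],
            "mean_by_condition": [round(v, 2) for v in self.mean_by_condition],
            "sd_by_condition": [round(v, 2) for v in self.sd_by_condition],
            "condition_labels": [str(c) for c in self.condition_labels],
            "sd_pooling": self.sd_pooling,
        }

    def table_row(self) -> pd.DataFrame:
        """One-row frame shaped like the familiar reliability-study tables."""
        row = {}
        for label, m, s in zip(self.condition_labels, self.mean_by_condition, self.sd_by_condition):
            row[f"{label} (M ± SD)"] = f"{m:.2f} ± {s:.2f}°"
        row["ICC"] = f"{self.icc:.3f}"
        row["CI 95%"] = f"{self.icc_ci95[0]:.3f}–{self.icc_ci95[1]:.3f}"
        row["SEM"] = f"{self.sem_deg:.2f}°"
        row["MDC"] = f"{self.mdc95_deg:.2f}°"
        row["CV"] = f"{self.cv_pct:.2f}%"
        return pd.DataFrame([row])


def _pooled_sd(matrix: np.ndarray, rule: str) -> float:
    """SD entering the SEM formula, per pooling rule.

    ``pooled``: sqrt of the mean of the per-condition variances (default);
    ``baseline``: SD of the first condition only; ``all_values``: SD of
    the flattened matrix.
    """
    y = np.asarray(matrix, dtype=float)
    if rule == "pooled":
        return float(np.sqrt(np.mean(y.var(axis=0, ddof=1))))
    if rule == "baseline":
        return float(y[:, 0].std(ddof=1))
    if rule == "all_values":
        return float(y.ravel().std(ddof=1))
    raise ValueError(f"unknown sd_pooling rule {rule!r}")


def build_report(
    table: MeasurementTable,
    icc_form: str = "icc2_1",
    sd_pooling: str = "pooled",
) -> ReliabilityReport:
    """Run the full reliability workflow on one measurement table."""
    wide = table.pivot()
    if len(wide) < 3:
        raise InsufficientSubjects(f"need >= 3 complete subjects, got {len(wide)}")
    y = wide.to_numpy(dtype=float)
    icc, ci = icc_two_way(y, form=icc_form)
    band = classify_icc(icc)
    sd_for_sem = _pooled_sd(y, sd_pooling)
    sem_deg = sem(sd_for_sem, icc)
    cv_mean, cv_each = cv_percent(y)
    return ReliabilityReport(
        icc=icc,
        icc_ci95=ci,
        icc_band=band,
        sem_deg=sem_deg,
        mdc95_deg=mdc95(sem_deg),
        cv_pct=cv_mean,
        cv_by_condition=cv_each,
        mean_by_condition=y.mean(axis=0).tolist(),
        sd_by_condition=y.std(axis=0, ddof=1).tolist(),
        condition_labels=[str(c) for c in wide.columns],
        n_subjects=len(wide),
        icc_form=icc_form,
        design=table.design,
        sd_pooling=sd_pooling,
    )
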