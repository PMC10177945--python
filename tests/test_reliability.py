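"""Reliability statistics against brute-force oracles and pingouin.

The ICC oracle computes the two-way ANOVA mean squares with explicit
Python double loops and applies the ICC(2,1)/ICC(3,1) formulas directly;
pingouin's intraclass_corr is a second, independent cross-check.
"""

import math

import numpy as np
import pandas as pd
import pytest

from valguscv import (
    AngleRecord,
    MeasurementTable,
    TableSpec,
    bland_altman,
    build_report,
    classify_icc,
    cv_percent,
    icc_two_way,
    mdc95,
    pearson,
    sem,
    simulate_table,
)
from valguscv.errors import (
    DesignColumnsMissing,
    IccAboveOne,
    InsufficientSubjects,
    NonPositiveMean,
    ZeroVariance,
)


# ---------------------------------------------------------------- oracles


def anova_icc_oracle(matrix, form="icc2_1"):
    """ICC from mean squares computed with explicit double loops."""
    y = [[float(v) for v in row] for row in matrix]
    n, k = len(y), len(y[0])
    grand = sum(sum(row) for row in y) / (n * k)
    row_means = [sum(row) / k for row in y]
    col_means = [sum(y[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((y[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if form == "icc2_1":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (k - 1) * mse)


def random_integer_matrices(n_matrices, rng, shape=(5, 2)):
    out = []
    while len(out) < n_matrices:
        m = rng.integers(0, 10, size=shape).astype(float)
        if not np.allclose(m, m.flat[0]):
            out.append(m)
    return out


# ------------------------------------------------------------------- ICC


def test_perfect_agreement_gives_icc_one():
    col = np.array([150.0, 155.0, 160.0, 152.0, 158.0])
    icc, ci = icc_two_way(np.column_stack([col, col]))
    assert icc == pytest.approx(1.0, abs=1e-12)
    assert ci == (1.0, 1.0)


@pytest.mark.parametrize("form", ["icc2_1", "icc3_1"])
def test_icc_matches_double_loop_oracle(form):
    rng = np.random.default_rng(42)
    for m in random_integer_matrices(50, rng):
        icc, _ = icc_two_way(m, form=form)
        assert icc == pytest.approx(anova_icc_oracle(m, form), abs=1e-10)


@pytest.mark.parametrize("form,pg_type", [("icc2_1", "ICC(A,1)"), ("icc3_1", "ICC(C,1)")])
def test_icc_and_ci_match_pingouin(form, pg_type):
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    for m in random_integer_matrices(10, rng, shape=(8, 2)):
        df = pd.DataFrame(
            {"s": np.repeat(np.arange(8), 2), "r": np.tile([0, 1], 8), "y": m.ravel()}
        )
        res = pg.intraclass_corr(df, targets="s", raters="r", ratings="y").set_index("Type")
        icc, ci = icc_two_way(m, form=form)
        row = res.loc[pg_type]
        assert icc == pytest.approx(row.ICC, abs=1e-9)
        lo, hi = np.clip(row.CI95, -1.0, 1.0)  # pingouin leaves bounds unclamped
        assert ci[0] == pytest.approx(lo, abs=0.02)
        assert ci[1] == pytest.approx(hi, abs=0.02)


def test_icc_recovers_simulated_truth():
    """Mean ICC(2,1) over replicates of n=42 tables lands near the
    generating ICC 0.933."""
    from valguscv import icc_to_variances

    ss, se = icc_to_variances(0.933, 5.22, 0.5)
    est = []
    for rep in range(200):
        t = simulate_table(TableSpec(sd_subject=ss, sd_condition=0.5, sd_error=se, seed=rep))
        icc, _ = icc_two_way(t.pivot().to_numpy())
        est.append(icc)
    assert np.mean(est) == pytest.approx(0.933, abs=0.02)


def test_icc_point_estimate_within_its_ci():
    rng = np.random.default_rng(5)
    for m in random_integer_matrices(20, rng, shape=(10, 2)):
        icc, (lo, hi) = icc_two_way(m)
        assert lo <= icc <= hi


def test_icc_errors():
    with pytest.raises(InsufficientSubjects):
        icc_two_way(np.array([[1.0, 2.0], [3.0, 4.0]]))
    with pytest.raises(ZeroVariance):
        icc_two_way(np.full((5, 2), 150.0))
    with pytest.raises(ValueError):
        icc_two_way(np.arange(10.0).reshape(5, 2), form="icc9_9")


# ---------------------------------------------------------------- banding


@pytest.mark.parametrize(
    "icc,band",
    [
        (0.933, "excellent"), (0.859, "good"), (0.658, "moderate"),
        (0.50, "moderate"), (0.75, "good"), (0.90, "excellent"),
        (0.49, "poor"), (-0.2, "poor"),
    ],
)
def test_icc_bands(icc, band):
    assert classify_icc(icc) == band


def test_band_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_icc(1.2)


# ---------------------------------------------------------------- SEM/MDC


def test_sem_limits():
    assert sem(3.7, 1.0) == 0.0
    assert sem(3.7, 0.0) == pytest.approx(3.7)


def test_sem_table_value():
    # pooled SD over the two occasions (6.72, 6.38) at ICC 0.933
    pooled = math.sqrt((6.72**2 + 6.38**2) / 2)
    assert pooled == pytest.approx(6.552, abs=1e-3)
    assert sem(pooled, 0.933) == pytest.approx(1.696, abs=1e-3)


def test_sem_strictly_decreasing_in_icc():
    vals = [sem(5.0, icc) for icc in np.linspace(0.0, 1.0, 21)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_sem_rejects_icc_above_one():
    with pytest.raises(IccAboveOne):
        sem(5.0, 1.01)


@pytest.mark.parametrize(
    "sem_value,expected", [(1.69, 4.68), (3.50, 9.70), (0.0, 0.0)]
)
def test_mdc95_values(sem_value, expected):
    assert round(mdc95(sem_value), 2) == expected


def test_mdc_sem_ratio_constant():
    for s in (0.1, 1.69, 3.5, 10.0):
        assert mdc95(s) / s == pytest.approx(1.96 * math.sqrt(2), abs=1e-12)


# -------------------------------------------------------------------- CV


def test_cv_zero_for_constant_columns():
    mean_cv, per = cv_percent(np.full((5, 2), 150.0))
    assert mean_cv == 0.0 and per == [0.0, 0.0]


def test_cv_direct_evaluation():
    """Columns matching the printed occasion means/SDs give per-condition
    CVs 4.35% and 4.16%, mean 4.26% (direct formula evaluation)."""
    rng = np.random.default_rng(0)

    def column(mean, sd, n=42):
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std(ddof=1)
        return mean + sd * z

    m = np.column_stack([column(154.42, 6.72), column(153.34, 6.38)])
    mean_cv, per = cv_percent(m)
    assert per[0] == pytest.approx(6.72 / 154.42 * 100, abs=1e-9)
    assert per[1] == pytest.approx(6.38 / 153.34 * 100, abs=1e-9)
    assert round(per[0], 2) == 4.35
    assert round(per[1], 2) == 4.16
    assert round(mean_cv, 2) == 4.26


def test_cv_scale_invariant():
    rng = np.random.default_rng(1)
    m = rng.uniform(140, 170, size=(10, 2))
    assert cv_percent(m)[0] == pytest.approx(cv_percent(2 * m)[0], abs=1e-12)


def test_cv_rejects_nonpositive_mean():
    with pytest.raises(NonPositiveMean):
        cv_percent(np.array([[1.0, -1.0]] * 4))


# --------------------------------------------------------------- Pearson


def test_pearson_identity_and_negation():
    x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
    r, p, band = pearson(x, x)
    assert r == pytest.approx(1.0, abs=1e-12)
    assert band == "strong" and p < 1e-10
    r, _, _ = pearson(x, -x)
    assert r == pytest.approx(-1.0, abs=1e-12)


def test_pearson_matches_hand_covariance_oracle():
    x = [1.0, 2.0, 3.0, 5.0, 8.0, 9.0]
    y = [2.0, 1.0, 4.0, 4.0, 9.0, 7.0]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    r, p, _ = pearson(x, y)
    assert r == pytest.approx(cov / (sx * sy), abs=1e-12)
    from scipy import stats

    r_ref, p_ref = stats.pearsonr(x, y)
    assert r == pytest.approx(r_ref, abs=1e-12)
    assert p == pytest.approx(p_ref, rel=1e-9)


def test_pearson_of_affine_map_is_sign_of_slope():
    rng = np.random.default_rng(2)
    x = rng.normal(size=20)
    for b in (-3.0, 0.5, 2.0):
        r, _, _ = pearson(x, 1.7 + b * x)
        assert r == pytest.approx(math.copysign(1.0, b), abs=1e-12)


@pytest.mark.parametrize(
    "r,band",
    [(0.931, "strong"), (0.71, "strong"), (0.70, "moderate"), (0.50, "moderate"),
     (0.40, "unclassified"), (0.29, "low")],
)
def test_pearson_bands(r, band):
    from valguscv.reliability import _pearson_band

    assert _pearson_band(r) == band


def test_pearson_zero_variance():
    with pytest.raises(ZeroVariance):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ----------------------------------------------------------- Bland-Altman


def test_bland_altman_identity_pairs():
    x = np.array([150.0, 155.0, 160.0, 152.0])
    res = bland_altman(x, x)
    assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0


def test_bland_altman_pure_offset():
    x = np.array([150.0, 155.0, 160.0, 152.0])
    res = bland_altman(x + 2.0, x)
    assert res.bias == pytest.approx(2.0)
    assert res.loa_low == pytest.approx(2.0) and res.loa_high == pytest.approx(2.0)


def test_bland_altman_matches_direct_oracle():
    rng = np.random.default_rng(9)
    x = rng.normal(158.5, 5.2, size=10)
    y = x + rng.normal(0.5, 1.4, size=10)
    res = bland_altman(x, y)
    d = x - y
    sd = math.sqrt(sum((v - d.mean()) ** 2 for v in d) / (len(d) - 1))
    assert res.bias == pytest.approx(d.mean(), abs=1e-12)
    assert res.loa_low == pytest.approx(d.mean() - 1.96 * sd, abs=1e-12)
    assert res.loa_high == pytest.approx(d.mean() + 1.96 * sd, abs=1e-12)
    assert res.between_instrument_sem == pytest.approx(sd / math.sqrt(2), abs=1e-12)
    assert len(res.pairs) == 10
    assert res.pairs[0][0] == pytest.approx((x[0] + y[0]) / 2)


def test_bland_altman_limits_cover_95pct_gaussian():
    rng = np.random.default_rng(11)
    x = rng.normal(158.5, 5.2, size=10_000)
    y = x + rng.normal(0.0, 1.5, size=10_000)
    res = bland_altman(x, y)
    d = x - y
    inside = np.mean((d >= res.loa_low) & (d <= res.loa_high)) * 100
    assert 93.0 <= inside <= 97.0


# ----------------------------------------------------------- full report


def _table_from_matrix(y, design="test_retest"):
    recs = []
    for i, row in enumerate(y):
        for j, v in enumerate(row):
            rater = "R1" if design == "test_retest" else f"R{j + 1}"
            occ = j + 1 if design == "test_retest" else 1
            recs.append(AngleRecord(angle_deg=float(v), subject_id=f"S{i:02d}",
                                    rater_id=rater, occasion=occ))
    return MeasurementTable.from_records(recs, design=design)


def test_report_fields_consistent():
    t = simulate_table(TableSpec(seed=4))
    rep = build_report(t)
    assert rep.n_subjects == 42
    assert rep.icc_ci95[0] <= rep.icc <= rep.icc_ci95[1]
    assert rep.mdc95_deg == pytest.approx(1.96 * math.sqrt(2) * rep.sem_deg, abs=1e-12)
    assert rep.icc_band == classify_icc(rep.icc)
    assert all(np.isfinite(v) for v in
               [rep.icc, rep.sem_deg, rep.mdc95_deg, rep.cv_pct] + rep.mean_by_condition)
    row = rep.table_row()
    assert {"ICC", "CI 95%", "SEM", "MDC", "CV"} <= set(row.columns)


def test_report_duplicated_column_perfect():
    col = np.array([150.0, 155.0, 160.0, 152.0, 158.0])
    rep = build_report(_table_from_matrix(np.column_stack([col, col])))
    assert rep.icc == pytest.approx(1.0)
    assert rep.sem_deg == 0.0 and rep.mdc95_deg == 0.0


def test_report_sd_pooling_rules():
    rng = np.random.default_rng(8)
    # records round to 2 dp on serialization, so generate at that precision
    y = np.round(rng.normal(158, 5, size=(20, 2)), 2)
    t = _table_from_matrix(y)
    pooled = build_report(t, sd_pooling="pooled")
    baseline = build_report(t, sd_pooling="baseline")
    allv = build_report(t, sd_pooling="all_values")
    assert pooled.sem_deg == pytest.approx(
        math.sqrt(np.mean(y.var(axis=0, ddof=1))) * math.sqrt(1 - pooled.icc)
    )
    assert baseline.sem_deg == pytest.approx(
        y[:, 0].std(ddof=1) * math.sqrt(1 - baseline.icc)
    )
    assert allv.sem_deg == pytest.approx(
        y.ravel().std(ddof=1) * math.sqrt(1 - allv.icc)
    )


def test_report_single_subject_rejected():
    recs = [
        AngleRecord(angle_deg=150.0, subject_id="S1", rater_id="R1", occasion=1),
        AngleRecord(angle_deg=151.0, subject_id="S1", rater_id="R1", occasion=2),
    ]
    t = MeasurementTable.from_records(recs)
    with pytest.raises(InsufficientSubjects):
        build_report(t)


def test_pivot_drops_incomplete_subjects(caplog):
    recs = [
        AngleRecord(angle_deg=150.0 + i, subject_id=f"S{i}", rater_id="R1", occasion=o)
        for i in range(5) for o in (1, 2)
    ]
    recs.append(AngleRecord(angle_deg=155.0, subject_id="S9", rater_id="R1", occasion=1))
    t = MeasurementTable.from_records(recs)
    wide = t.pivot()
    assert len(wide) == 5 and "S9" not in wide.index


def test_wrong_design_columns():
    recs = [
        AngleRecord(angle_deg=150.0 + i, subject_id=f"S{i}", rater_id="R1", occasion=1)
        for i in range(5)
    ]
    t = MeasurementTable.from_records(recs, design="inter_rater")
    with pytest.raises(DesignColumnsMissing):
        t.pivot()


def test_duplicate_measurement_key_rejected():
    recs = [
        AngleRecord(angle_deg=150.0, subject_id="S1", rater_id="R1", occasion=1),
        AngleRecord(angle_deg=151.0, subject_id="S1", rater_id="R1", occasion=1),
    ]
    with pytest.raises(ValueError):
        MeasurementTable.from_records(recs)
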