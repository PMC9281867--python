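"""Cohort container, statistics, tertiles, heatmap data, correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from thrombosim import (
    CohortTable,
    FactorPanel,
    assign_tertiles,
    carriage_frequency,
    compare_categorical,
    compare_groups,
    compare_groups_from_stats,
    correlate_factors_with_effects,
    heatmap_matrix,
    normal_range,
    tertile_stratify,
)
from thrombosim.scheme import MEASURED_FACTORS
from thrombosim.units import PanelError


def _panel(donor_id, group="control", sex="male", **levels):
    base = {f: 100.0 for f in MEASURED_FACTORS}
    base.update(TF=5.0, TFPI=1.0)
    base.update(levels)
    return FactorPanel(donor_id=donor_id, group=group, sex=sex, levels=base)


# -- container ---------------------------------------------------------------

def test_duplicate_donor_ids_rejected():
    with pytest.raises(PanelError, match="duplicate"):
        CohortTable([_panel("a"), _panel("a")])


def test_cohort_csv_round_trip(tmp_path):
    cohort = CohortTable([
        _panel("a", "case", "male", FII=87.5),
        _panel("b", "control", "female", TF=3.25),
    ])
    path = tmp_path / "cohort.csv"
    cohort.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == (
        "donor_id,group,sex,genotype_20210,FII_pct,FV_pct,FVII_pct,FVIII_pct,"
        "FIX_pct,FX_pct,AT_pct,TF_pM,TFPI_U_per_mL"
    )
    back = CohortTable.from_csv(path)
    pd.testing.assert_frame_equal(back.to_dataframe(), cohort.to_dataframe())


# -- normal range, t-test, chi-squared, carriage -----------------------------

def test_normal_range_mean_pm_two_sd():
    assert normal_range([90, 100, 110]) == pytest.approx((80.0, 120.0))


def test_normal_range_constant_values_zero_width():
    lo, hi = normal_range([42.0] * 5)
    assert lo == hi == 42.0


def test_normal_range_bruteforce_oracle():
    rng = np.random.default_rng(9)
    x = rng.normal(100, 17, size=50)
    m = sum(x) / 50
    sd = math.sqrt(sum((v - m) ** 2 for v in x) / 49)
    assert normal_range(x) == pytest.approx((m - 2 * sd, m + 2 * sd))


def test_normal_range_needs_two_values():
    with pytest.raises(ValueError):
        normal_range([100.0])


def test_t_test_identical_groups():
    t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_t_test_zero_variance_equal_means_convention():
    assert compare_groups([5.0, 5.0], [5.0, 5.0]) == (0.0, 1.0)


def test_t_test_matches_permutation_oracle():
    rng = np.random.default_rng(2)
    a = rng.normal(0.0, 1.0, 8)
    b = rng.normal(1.2, 1.0, 8)
    t_obs, p = compare_groups(a, b)
    pooled = np.concatenate([a, b])
    count = 0
    n_perm = 20000
    prng = np.random.default_rng(3)
    for _ in range(n_perm):
        perm = prng.permutation(pooled)
        t_perm, _ = sps.ttest_ind(perm[:8], perm[8:])
        if abs(t_perm) >= abs(t_obs):
            count += 1
    p_perm = count / n_perm
    # the pooled t reference distribution and the exact permutation null
    # differ slightly at n = 8 per group; they must agree to ~0.02
    assert p == pytest.approx(p_perm, abs=0.02)


def test_welch_option_differs_under_unequal_variance():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 0.5, 10)
    b = rng.normal(0.5, 3.0, 40)
    _, p_pooled = compare_groups(a, b, equal_var=True)
    _, p_welch = compare_groups(a, b, equal_var=False)
    assert p_pooled != p_welch


def test_summary_statistic_t_test():
    t, p = compare_groups_from_stats(162, 3.13, 0.76, 186, 2.83, 0.61)
    assert p < 1e-4
    assert t > 0


def test_chi2_proportional_table_is_null():
    stat, p = compare_categorical([[20, 40], [10, 20]])
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi2_diagonal_table_closed_form():
    stat, _ = compare_categorical([[10, 0], [0, 10]])
    assert stat == pytest.approx(20.0)


def test_chi2_orders_tables_like_fisher_exact():
    tables = [
        [[8, 2], [2, 8]],
        [[7, 3], [3, 7]],
        [[6, 4], [4, 6]],
        [[5, 5], [5, 5]],
    ]
    chi_ps = [compare_categorical(t)[1] for t in tables]
    fisher_ps = [sps.fisher_exact(t)[1] for t in tables]
    for (c1, f1), (c2, f2) in itertools.combinations(zip(chi_ps, fisher_ps), 2):
        assert (c1 - c2) * (f1 - f2) >= 0


def test_chi2_zero_marginal_rejected():
    with pytest.raises(ValueError):
        compare_categorical([[0, 0], [5, 5]])


def test_carriage_frequency_printed_counts():
    assert carriage_frequency(3, 162) == pytest.approx(1.85, abs=0.01)
    assert carriage_frequency(6, 186) == pytest.approx(3.22, abs=0.01)
    assert carriage_frequency(0, 100) == 0.0
    with pytest.raises(ValueError):
        carriage_frequency(1, 0)
    with pytest.raises(ValueError):
        carriage_frequency(5, 4)


# -- tertiles ----------------------------------------------------------------

def test_tertiles_of_nine_distinct_values_balanced():
    s = pd.Series(range(9), index=[f"d{i}" for i in range(9)])
    labels = assign_tertiles(s)
    assert labels.value_counts().to_dict() == {"low": 3, "medium": 3, "high": 3}


def test_tertiles_of_ten_values_remainder_to_lower():
    s = pd.Series(range(10), index=[f"d{i}" for i in range(10)])
    counts = assign_tertiles(s).value_counts().to_dict()
    assert counts == {"low": 4, "medium": 3, "high": 3}


def test_tertiles_match_bruteforce_sort_and_cut():
    rng = np.random.default_rng(5)
    for trial in range(100):
        n = int(rng.integers(3, 40))
        vals = pd.Series(
            rng.normal(size=n), index=[f"d{i:02d}" for i in range(n)]
        )
        labels = assign_tertiles(vals)
        order = sorted(vals.index, key=lambda i: (vals[i], i))
        base, rem = divmod(n, 3)
        sizes = [base + (1 if k < rem else 0) for k in range(3)]
        expected = {}
        pos = 0
        for lab, size in zip(("low", "medium", "high"), sizes):
            for i in order[pos:pos + size]:
                expected[i] = lab
            pos += size
        assert labels.to_dict() == expected


def test_tertile_stratify_degenerate_key():
    summ = pd.DataFrame({"peak_FIIa": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
    out = tertile_stratify(summ)
    assert (out["tertile"] == "degenerate").all()


def test_tertile_sizes_never_differ_by_more_than_one():
    rng = np.random.default_rng(6)
    for n in (5, 17, 100, 348):
        s = pd.Series(rng.normal(size=n), index=[f"d{i:04d}" for i in range(n)])
        counts = assign_tertiles(s).value_counts()
        assert counts.max() - counts.min() <= 1


# -- heatmap matrix ----------------------------------------------------------

def _small_cohort_with_summaries():
    cohort = CohortTable([
        _panel("a", "case", "male", FII=120.0),
        _panel("b", "control", "female", FII=100.0),
        _panel("c", "control", "male", FII=80.0),
    ])
    summ = pd.DataFrame({"peak_FIIa": [3e-7, 2e-7, 1e-7]}, index=["a", "b", "c"])
    summ.index.name = "donor_id"
    return cohort, summ


def test_heatmap_matrix_shape_and_annotations():
    cohort, summ = _small_cohort_with_summaries()
    assignment = tertile_stratify(summ, cohort=cohort)
    matrix = heatmap_matrix(cohort, assignment, summaries=summ)
    factor_cols = [f"{f}_tertile" for f in MEASURED_FACTORS]
    assert all(c in matrix.columns for c in factor_cols + ["sex", "group", "tertile"])
    assert len(matrix) == 3


def test_heatmap_row_order_deterministic():
    cohort, summ = _small_cohort_with_summaries()
    assignment = tertile_stratify(summ, cohort=cohort)
    m1 = heatmap_matrix(cohort, assignment, summaries=summ)
    m2 = heatmap_matrix(cohort, assignment.sample(frac=1, random_state=0),
                        summaries=summ)
    pd.testing.assert_frame_equal(m1, m2)


def test_heatmap_csv_round_trip(tmp_path):
    cohort, summ = _small_cohort_with_summaries()
    assignment = tertile_stratify(summ, cohort=cohort)
    effects = pd.DataFrame({
        "donor_id": ["a", "b", "c"],
        "drug": ["warfarin"] * 3,
        "pct_peak_reduction": [80.0, 70.0, 60.0],
        "pct_time_to_peak_change": [30.0, 20.0, 10.0],
    })
    matrix = heatmap_matrix(cohort, assignment, drug_effects=effects, summaries=summ)
    path = tmp_path / "m.csv"
    matrix.to_csv(path)
    back = pd.read_csv(path, index_col=0)
    back.index.name = matrix.index.name
    pd.testing.assert_frame_equal(back, matrix, check_dtype=False)


# -- correlations ------------------------------------------------------------

def _effects_from(cohort, values):
    return pd.DataFrame({
        "donor_id": [p.donor_id for p in cohort],
        "drug": "warfarin",
        "pct_peak_reduction": values,
    })


def test_exact_linear_relation_gives_r_minus_one():
    panels = [_panel(f"d{i}", FII=100.0 + i * 10) for i in range(5)]
    cohort = CohortTable(panels)
    effects = _effects_from(cohort, [-2.0 * p["FII"] for p in panels])
    rep = correlate_factors_with_effects(cohort, effects).set_index("factor")
    assert rep.loc["FII", "r"] == pytest.approx(-1.0)


def test_constant_factor_flagged_undefined():
    cohort = CohortTable([_panel(f"d{i}") for i in range(5)])
    effects = _effects_from(cohort, list(range(5)))
    rep = correlate_factors_with_effects(cohort, effects).set_index("factor")
    assert not rep.loc["FII", "defined"]
    assert math.isnan(rep.loc["FII", "r"])


def test_correlation_matches_textbook_formula():
    rng = np.random.default_rng(8)
    fii = rng.uniform(60, 140, 20)
    panels = [_panel(f"d{i:02d}", FII=float(v)) for i, v in enumerate(fii)]
    cohort = CohortTable(panels)
    y = rng.normal(size=20)
    effects = _effects_from(cohort, list(y))
    rep = correlate_factors_with_effects(cohort, effects).set_index("factor")
    x = fii
    r_manual = (((x - x.mean()) * (y - y.mean())).sum()
                / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
    assert rep.loc["FII", "r"] == pytest.approx(r_manual, abs=1e-12)
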