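from math import comb

import numpy as np
import pandas as pd
import pytest

from synaptoshift import (
    ConfigurationError,
    InsufficientDataError,
    cross_platform_correlation,
    covariate_screen,
    delta_delta_ct,
    demographics_compare,
    reference_value,
)
from conftest import make_sample_sheet


def ct_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "gene", "ct", "replicate"])


def build_ct_table(sheet, target_cts, hk_ct=20.0, gene="TG"):
    """One target gene plus GAPDH/ACTB housekeeping per sample."""
    rows = []
    for sample, ct in zip(sheet["sample_id"], target_cts):
        rows.append((sample, gene, ct, 1))
        rows.append((sample, "GAPDH", hk_ct, 1))
        rows.append((sample, "ACTB", hk_ct, 1))
    return ct_frame(rows)


class TestReferenceValue:
    @pytest.mark.parametrize(
        "cts,expected",
        [((16, 4), 8.0), ((20, 20, 20), 20.0), ((18, 20, 22), (18 * 20 * 22) ** (1 / 3))],
    )
    def test_geometric_mean(self, cts, expected):
        assert reference_value(cts) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            reference_value([20, -1])


class TestDeltaDeltaCt:
    @pytest.fixture
    def sheet(self):
        return make_sample_sheet(n_control=3, n_case=3, fractions=("total",))

    def test_livak_formula(self, sheet):
        # control dCt mean 3, case dCt mean 2 -> ddCt -1 -> FC 2
        table = build_ct_table(sheet, target_cts=[23, 23.5, 22.5, 22, 22.5, 21.5])
        res = delta_delta_ct(table, sheet)
        assert res.at["TG", "fold_change"] == pytest.approx(2.0)

    def test_equal_groups_give_unit_fold_change(self, sheet):
        table = build_ct_table(sheet, target_cts=[23, 24, 25, 25, 24, 23])
        res = delta_delta_ct(table, sheet)
        assert res.at["TG", "fold_change"] == pytest.approx(1.0)

    def test_downregulation(self, sheet):
        # case dCt one cycle above control -> half the expression
        table = build_ct_table(sheet, target_cts=[24, 24, 24, 25, 25, 25])
        res = delta_delta_ct(table, sheet)
        assert res.at["TG", "fold_change"] == pytest.approx(0.5)

    def test_invariant_to_constant_ct_offset(self, sheet, rng):
        cts = list(20 + rng.normal(0, 1, 6))
        base = delta_delta_ct(build_ct_table(sheet, cts, hk_ct=20.0), sheet)
        shifted = build_ct_table(sheet, [c + 5 for c in cts], hk_ct=25.0)
        res = delta_delta_ct(shifted, sheet)
        assert res.at["TG", "fold_change"] == pytest.approx(base.at["TG", "fold_change"])
        assert res.at["TG", "p_value"] == pytest.approx(base.at["TG", "p_value"])

    def test_reciprocal_symmetry_under_group_swap(self, sheet, rng):
        cts = list(20 + rng.normal(0, 1, 6))
        table = build_ct_table(sheet, cts)
        fc = delta_delta_ct(table, sheet).at["TG", "fold_change"]
        swapped = sheet.copy()
        swapped["group"] = swapped["group"].map({"control": "MDD", "MDD": "control"})
        fc_swapped = delta_delta_ct(table, swapped).at["TG", "fold_change"]
        assert fc * fc_swapped == pytest.approx(1.0)

    def test_replicates_collapse_to_mean(self, sheet):
        rows = []
        for sample, ct in zip(sheet["sample_id"], [23, 23, 23, 22, 22, 22]):
            rows += [(sample, "TG", ct - 0.5, 1), (sample, "TG", ct + 0.5, 2),
                     (sample, "GAPDH", 20.0, 1)]
        res = delta_delta_ct(ct_frame(rows), sheet)
        assert res.at["TG", "fold_change"] == pytest.approx(2.0)

    def test_missing_group_raises(self, sheet):
        ctrl_only = sheet[sheet["group"] == "control"]
        table = build_ct_table(ctrl_only, [23, 23, 23])
        with pytest.raises(ConfigurationError):
            delta_delta_ct(table, ctrl_only)


class TestCrossPlatformCorrelation:
    def test_perfect_agreement(self):
        fc = {f"g{i}": 0.5 + 0.25 * i for i in range(8)}
        r, p, n = cross_platform_correlation(fc, fc)
        assert r == pytest.approx(1.0)
        assert n == 8

    def test_perfect_negative_affine(self):
        fc = {f"g{i}": 0.5 + 0.25 * i for i in range(8)}
        neg = {g: -v + 10 for g, v in fc.items()}
        r, _, _ = cross_platform_correlation(fc, neg)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self, rng):
        x = rng.normal(1.2, 0.3, 8)
        y = x + rng.normal(0, 0.1, 8)
        genes = [f"g{i}" for i in range(8)]
        r, _, _ = cross_platform_correlation(dict(zip(genes, x)), dict(zip(genes, y)))
        expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(expected)

    def test_affine_invariance(self, rng):
        x = rng.normal(1, 0.3, 10)
        y = rng.normal(1, 0.3, 10)
        genes = [f"g{i}" for i in range(10)]
        r1, _, _ = cross_platform_correlation(dict(zip(genes, x)), dict(zip(genes, y)))
        r2, _, _ = cross_platform_correlation(dict(zip(genes, 3 * x + 2)), dict(zip(genes, y)))
        assert r1 == pytest.approx(r2)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            cross_platform_correlation({"a": 1, "b": 2}, {"a": 1, "b": 2})


class TestCovariateScreen:
    def test_expression_equal_to_age(self):
        sheet = make_sample_sheet(3, 3, fractions=("total",), age=[40, 50, 60, 45, 55, 65])
        expr = pd.Series(dict(zip(sheet["sample_id"], sheet["age"].astype(float))))
        res = covariate_screen(expr, sheet)
        assert res.at["age", "statistic"] == pytest.approx(1.0)

    def test_constant_covariate_not_assessable(self):
        sheet = make_sample_sheet(3, 3, fractions=("total",), ph=[6.5] * 6)
        expr = pd.Series(dict(zip(sheet["sample_id"], [1.0, 2, 3, 4, 5, 6])))
        res = covariate_screen(expr, sheet)
        assert not res.at["ph", "assessable"]

    def test_binary_covariate_sign_matches_planted_direction(self):
        anti = ["no", "no", "no", "yes", "yes", "yes"]
        sheet = make_sample_sheet(3, 3, fractions=("total",), antidepressant=anti)
        expr = pd.Series(dict(zip(sheet["sample_id"], [1.0, 1.2, 0.9, 3.0, 3.1, 2.9])))
        res = covariate_screen(expr, sheet)
        assert res.at["antidepressant", "statistic"] > 0


def fisher_two_sided_oracle(table):
    """Point-probability two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


class TestDemographics:
    def test_identical_continuous_lists(self):
        sheet = make_sample_sheet(3, 3, fractions=("total",), age=[40, 50, 60, 40, 50, 60])
        res = demographics_compare(sheet)
        assert res.at["age", "p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("counts", [((8, 7), (7, 8)), ((10, 0), (0, 10)), ((5, 2), (1, 6))])
    def test_fisher_matches_enumeration_oracle(self, counts):
        (a, b), (c, d) = counts
        sex = ["male"] * a + ["female"] * b + ["male"] * c + ["female"] * d
        sheet = make_sample_sheet(a + b, c + d, fractions=("total",), sex=sex)
        res = demographics_compare(sheet)
        expected = fisher_two_sided_oracle(((a, b), (c, d)))
        assert res.at["sex", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_balanced_table_is_null(self):
        sex = ["male"] * 8 + ["female"] * 7 + ["male"] * 7 + ["female"] * 8
        sheet = make_sample_sheet(15, 15, fractions=("total",), sex=sex)
        res = demographics_compare(sheet)
        assert res.at["sex", "p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_extreme_table_is_tiny(self):
        sex = ["male"] * 10 + ["female"] * 10
        sheet = make_sample_sheet(10, 10, fractions=("total",), sex=sex)
        res = demographics_compare(sheet)
        assert res.at["sex", "p_value"] == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_empty_group_raises(self):
        sheet = make_sample_sheet(3, 0, fractions=("total",), age=[40, 50, 60])
        with pytest.raises(ConfigurationError):
            demographics_compare(sheet)
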