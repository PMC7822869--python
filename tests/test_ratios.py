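import numpy as np
import pandas as pd
import pytest

from synaptoshift import (
    PairingError,
    classify_enrichment,
    shift_test,
    subject_ratios,
    top_bottom,
    validate_ratio_table,
)
from synaptoshift import SimulationConfig, simulate_study
from conftest import make_matrix, make_sample_sheet


@pytest.fixture
def paired_sheet():
    return make_sample_sheet(n_control=3, n_case=3)


def paired_matrix(values, sheet):
    return make_matrix(values, list(sheet["sample_id"]))


class TestSubjectRatios:
    def test_direct_ratio(self, paired_sheet):
        # columns alternate total/synaptic per subject
        m = paired_matrix({"g": [4.0, 2.0] * 6}, paired_sheet)
        sr = subject_ratios(m, paired_sheet)
        assert (sr.ratios.loc["g"] == 0.5).all()

    def test_identity_when_fractions_equal(self, paired_sheet):
        m = paired_matrix({"g": [3.0] * 12}, paired_sheet)
        sr = subject_ratios(m, paired_sheet)
        assert (sr.ratios.loc["g"] == 1.0).all()

    def test_pseudocount_symmetry_on_double_zero(self, paired_sheet):
        m = paired_matrix({"g": [0.0] * 12}, paired_sheet)
        sr = subject_ratios(m, paired_sheet, pseudocount=0.01)
        assert (sr.ratios.loc["g"] == 1.0).all()

    def test_zero_denominator_excluded_without_pseudocount(self, paired_sheet):
        values = [0.0, 2.0] + [4.0, 2.0] * 5  # first subject's total is 0
        m = paired_matrix({"g": values}, paired_sheet)
        sr = subject_ratios(m, paired_sheet)
        assert sr.ratios.loc["g"].isna().sum() == 1

    def test_missing_fraction_names_subject(self, paired_sheet):
        broken = paired_sheet[paired_sheet["sample_id"] != "C1_syn"]
        m = make_matrix({"g": [1.0] * 11}, list(broken["sample_id"]))
        with pytest.raises(PairingError, match="C1"):
            subject_ratios(m, broken)

    def test_swapping_fraction_labels_inverts_ratios(self, rng, paired_sheet):
        m = paired_matrix({f"g{i}": rng.lognormal(1, 0.5, 12) for i in range(5)}, paired_sheet)
        sr = subject_ratios(m, paired_sheet)
        flipped = paired_sheet.copy()
        flipped["fraction"] = flipped["fraction"].map({"total": "synaptic", "synaptic": "total"})
        sr_flip = subject_ratios(m, flipped)
        np.testing.assert_allclose(sr_flip.ratios, 1.0 / sr.ratios)


class TestShiftTest:
    def test_identical_groups(self, paired_sheet):
        m = paired_matrix({"g": [2.0, 1.0] * 6}, paired_sheet)
        res = shift_test(subject_ratios(m, paired_sheet))
        assert res.at["g", "mdd_over_ct"] == pytest.approx(1.0)
        assert res.at["g", "p_value"] == 1.0

    @pytest.mark.parametrize(
        "ct_mean,mdd_mean,expected",
        [
            (0.442945, 0.759169, 1.713913),  # published ACAD11 row
            (0.862628, 1.521691, 1.764017),  # published GUCA1B row
        ],
    )
    def test_ratio_of_ratios_matches_published_rows(self, ct_mean, mdd_mean, expected):
        # build subject ratios whose group means equal the published ones
        sheet = make_sample_sheet(n_control=2, n_case=2)
        m = paired_matrix(
            {"g": [1.0, ct_mean * 0.9, 1.0, ct_mean * 1.1, 1.0, mdd_mean * 0.9, 1.0, mdd_mean * 1.1]},
            sheet,
        )
        res = shift_test(subject_ratios(m, sheet))
        assert res.at["g", "mdd_over_ct"] == pytest.approx(expected, abs=1e-4)

    def test_group_means_are_arithmetic(self, paired_sheet):
        # control subject ratios 0.5, 1.0, 1.5 -> mean 1.0; case 2,2,2 -> 2.0
        values = [2.0, 1.0, 1.0, 1.0, 1.0, 1.5, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0]
        m = paired_matrix({"g": values}, paired_sheet)
        res = shift_test(subject_ratios(m, paired_sheet))
        assert res.at["g", "ct_ratio"] == pytest.approx(1.0)
        assert res.at["g", "mdd_ratio"] == pytest.approx(2.0)
        assert res.at["g", "mdd_over_ct"] == pytest.approx(2.0)


class TestValidateRatioTable:
    def test_planted_inconsistency_reported(self):
        table = pd.DataFrame(
            {
                "gene_symbol": ["OK", "BAD"],
                "ensembl_id": ["E1", "E2"],
                "ct_ratio": [0.5, 1.0],
                "mdd_ratio": [1.0, 2.0],
                "mdd_over_ct": [2.0, 3.0],
                "p_value": [0.01, 0.01],
            }
        )
        report = validate_ratio_table(table, tolerance=1e-4)
        assert report.n_fail == 1
        assert list(report.failures["gene_symbol"]) == ["BAD"]
        assert report.failures["discrepancy"].iloc[0] == pytest.approx(1.0)


class TestClassifyEnrichment:
    def test_hand_enumerated_four_ratios(self):
        records = pd.DataFrame({"ct_ratio": [0.4, 0.9, 1.6, 2.5]}, index=list("abcd"))
        s = classify_enrichment(records, "control")
        assert (s.n_above_1, s.n_below_1) == (2, 2)
        assert s.median_ratio == pytest.approx(1.25)
        assert s.pct_enriched_1p5 == 50.0
        assert s.pct_enriched_2 == 25.0
        assert s.pct_depleted_1p5 == 25.0
        assert s.pct_depleted_2 == 25.0

    def test_all_ones_counted_in_neither_bucket(self):
        records = pd.DataFrame({"mdd_ratio": [1.0, 1.0, 1.0]}, index=list("abc"))
        s = classify_enrichment(records, "MDD")
        assert s.n_above_1 == s.n_below_1 == 0
        assert s.median_ratio == 1.0
        assert s.pct_enriched_1p5 == 0.0

    def test_single_extreme_gene(self):
        records = pd.DataFrame({"ct_ratio": [8.9]}, index=["EPDR"])
        s = classify_enrichment(records, "control")
        assert s.pct_enriched_2 == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_enrichment(pd.DataFrame(columns=["ct_ratio"]))


class TestTopBottom:
    def test_basic_ordering(self):
        records = pd.DataFrame({"ct_ratio": [2.0, 0.5, 1.0]}, index=["A", "B", "C"])
        top, bottom = top_bottom(records, 1)
        assert top == ["A"] and bottom == ["B"]

    def test_ties_break_lexicographically(self):
        records = pd.DataFrame({"ct_ratio": [1.0, 1.0, 1.0]}, index=["C", "A", "B"])
        top, bottom = top_bottom(records, 2)
        assert top == ["A", "B"] and bottom == ["A", "B"]

    def test_planted_extreme_shift_ranks_first_in_case_group(self):
        cfg = SimulationConfig(
            n_genes=120, n_subjects_per_group=6, frac_shift=1 / 120,
            frac_de_total=0, frac_de_synaptic=0,
            shift_effect_log2=3.0, noise_log2_sd=0.2, seed=21,
        )
        study = simulate_study(cfg)
        (planted,) = study.truth_shift
        res = shift_test(subject_ratios(study.expression, study.samples))
        top, _ = top_bottom(res, 1, group="MDD")
        assert top == [planted]
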