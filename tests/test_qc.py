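import numpy as np
import pandas as pd
import pytest

from singulor import (
    basic_cell_filters,
    classify_sex,
    erythroid_score,
    flag_contaminated,
    flag_erythroid_high,
    infer_sample_sex,
    log_normalize,
    sex_qc,
    sex_score,
)
from singulor.qc import SexQCResult

from conftest import make_count_matrix, make_gene_table


def complexity_matrix(n_genes_per_cell, n_mito_per_cell=0, total_genes=600, n_mito_genes=10):
    """Cells expressing a controlled number of genes at one count each,
    plus mito counts concentrated on the mito panel."""
    rows = []
    for n_expr, n_mito in zip(n_genes_per_cell, n_mito_per_cell):
        row = np.zeros(total_genes + n_mito_genes, dtype=int)
        row[:n_expr] = 1
        row[total_genes : total_genes + min(n_mito, n_mito_genes)] = 1
        if n_mito > n_mito_genes:
            row[total_genes] += n_mito - n_mito_genes
        rows.append(row)
    cm = make_count_matrix(np.array(rows))
    genes = make_gene_table(
        list(cm.gene_ids),
        marker_role=["none"] * total_genes + ["mitochondrial"] * n_mito_genes,
    )
    return cm, genes


class TestBasicFilters:
    def test_low_gene_cell_removed_and_boundary_kept(self):
        # 499 expressed genes fails the <500 rule; exactly 500 passes
        cm, genes = complexity_matrix([499, 500, 550], [0, 0, 0])
        rep = basic_cell_filters(cm, genes, mad_k=100)
        assert list(rep.per_cell["kept"]) == [False, True, True]
        assert rep.per_cell["low_genes"].iloc[0]

    def test_umi_boundary(self):
        cm, genes = complexity_matrix([499, 500], [1, 0])
        # first cell: 499 genes + 1 mito count = 500 UMIs but 500 genes detected
        rep = basic_cell_filters(cm, genes, mad_k=100)
        assert rep.per_cell["n_umis"].iloc[0] == 500
        assert not rep.per_cell["low_umis"].iloc[0]

    def test_mito_boundary_five_percent_kept(self):
        # 570 background + 30 mito = 5.0% exactly -> kept; 31 mito -> removed
        cm, genes = complexity_matrix([570, 570], [30, 32], total_genes=600)
        rep = basic_cell_filters(cm, genes, mad_k=100)
        assert rep.per_cell["pct_mito"].iloc[0] == pytest.approx(5.0)
        assert rep.per_cell["kept"].iloc[0]
        assert not rep.per_cell["kept"].iloc[1]

    def test_identical_cells_no_mad_removals(self):
        cm, genes = complexity_matrix([520] * 6, [0] * 6)
        rep = basic_cell_filters(cm, genes)
        assert not rep.per_cell["mad_flag"].any()
        assert rep.per_cell["kept"].all()

    def test_mad_outlier_removed(self):
        cm, genes = complexity_matrix([520, 521, 522, 520, 521, 605], [0] * 6)
        rep = basic_cell_filters(cm, genes, mad_k=5)
        assert rep.per_cell["mad_flag"].iloc[-1]

    def test_no_mito_genes_warns_and_skips(self):
        cm = make_count_matrix(np.ones((2, 600), dtype=int))
        genes = make_gene_table(list(cm.gene_ids))
        with pytest.warns(UserWarning, match="mito"):
            rep = basic_cell_filters(cm, genes)
        assert not rep.per_cell["high_mito"].any()


def norm_with_markers(dense, roles):
    cm = make_count_matrix(dense)
    genes = make_gene_table(list(cm.gene_ids), marker_role=roles)
    return log_normalize(cm), genes


class TestSexScore:
    def test_hand_value_against_formula(self):
        # scores operate on whatever values the matrix carries; use raw-count
        # scale by normalizing a single-gene-dominated cell is awkward, so
        # check the formula algebraically on normalized values instead
        norm, genes = norm_with_markers([[3, 0, 0]], ["xist", "y_linked", "none"])
        x = norm.values[0, 0]
        s = sex_score(norm, genes, pseudocount=1.0)
        assert s[0] == pytest.approx(np.log2((x + 1) / 1))

    def test_symmetry_and_antisymmetry(self):
        norm, genes = norm_with_markers(
            [[5, 5, 0], [2, 7, 0], [7, 2, 0]], ["xist", "y_linked", "none"]
        )
        s = sex_score(norm, genes)
        assert s[0] == pytest.approx(0.0)
        assert s[1] == pytest.approx(-s[2])

    def test_missing_xist_rejected(self):
        norm, genes = norm_with_markers([[1, 1]], ["none", "y_linked"])
        with pytest.raises(ValueError, match="XIST"):
            sex_score(norm, genes)


class TestClassifySex:
    @pytest.mark.parametrize(
        "score,call",
        [(2.0, "female_like"), (0.0, "ambiguous"), (-1.0, "male_like"),
         (1.0, "female_like"), (-0.99, "ambiguous")],
    )
    def test_default_thresholds_boundary_inclusive(self, score, call):
        assert classify_sex(np.array([score]))[0] == call

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_sex(np.array([0.0]), t_female=-1, t_male=1)


class TestErythroidScore:
    def test_additivity_and_zero(self):
        norm, genes = norm_with_markers(
            [[0, 0, 5], [2, 3, 5]], ["hemoglobin", "hemoglobin", "none"]
        )
        e = erythroid_score(norm, genes)
        assert e[0] == 0.0
        assert e[1] == pytest.approx(norm.values[1, 0] + norm.values[1, 1])

    def test_empty_panel_rejected(self):
        norm, genes = norm_with_markers([[1]], ["none"])
        with pytest.raises(ValueError, match="hemoglobin"):
            erythroid_score(norm, genes)


class TestErythroidFlag:
    def test_distinct_values_flag_exactly_five_percent(self):
        flags = flag_erythroid_high(np.arange(100, dtype=float))
        assert flags.sum() == 5

    def test_constant_vector_flags_nothing(self):
        assert flag_erythroid_high(np.full(50, 3.0)).sum() == 0

    def test_single_cell_flags_nothing(self):
        assert flag_erythroid_high(np.array([7.0])).sum() == 0


class TestSampleSex:
    def test_strict_majority(self):
        calls = np.array(["female_like"] * 6 + ["male_like"] * 2 + ["ambiguous"] * 2)
        assert infer_sample_sex(calls) == "female"

    def test_exact_half_undetermined(self):
        calls = np.array(["female_like"] * 5 + ["male_like"] * 5)
        assert infer_sample_sex(calls) == "undetermined"

    def test_all_ambiguous_undetermined(self):
        assert infer_sample_sex(np.array(["ambiguous"] * 4)) == "undetermined"


def build_result(calls, ehigh, samples, inferred):
    per_cell = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(calls))],
            "sample": samples,
            "sex_score": 0.0,
            "sex_call": calls,
            "erythroid_score": 0.0,
            "erythroid_high": ehigh,
            "contaminated": False,
        }
    )
    per_sample = pd.DataFrame(
        {
            "sample": sorted(set(samples)),
            "inferred_sex": inferred,
            "n_cells": [samples.count(s) for s in sorted(set(samples))],
            "removal_fraction": 0.0,
        }
    )
    return SexQCResult(per_cell, per_sample)


class TestFlagContaminated:
    def test_conjunction_required(self):
        res = build_result(
            ["male_like", "male_like", "female_like", "ambiguous"],
            [True, False, True, True],
            ["A"] * 4,
            ["female"],
        )
        out = flag_contaminated(res)
        # discordant AND erythroid-high only
        assert list(out.per_cell["contaminated"]) == [True, False, False, False]
        assert out.per_sample["removal_fraction"].iloc[0] == pytest.approx(0.25)

    def test_undetermined_sample_warns_and_flags_nothing(self):
        res = build_result(
            ["male_like", "female_like"], [True, True], ["A", "A"], ["undetermined"]
        )
        with pytest.warns(UserWarning, match="undetermined"):
            out = flag_contaminated(res)
        assert not out.per_cell["contaminated"].any()

    def test_drop_ambiguous_marks_cells(self):
        res = build_result(
            ["ambiguous", "female_like"], [True, False], ["A", "A"], ["female"]
        )
        out = flag_contaminated(res, drop_ambiguous=True)
        assert list(out.per_cell["dropped_ambiguous"]) == [True, False]

    def test_flags_subset_of_erythroid_high(self, default_cohort):
        _, cm, genes, cells, _ = default_cohort
        res = flag_contaminated(sex_qc(log_normalize(cm), genes, cells))
        flagged = res.per_cell["contaminated"].to_numpy()
        assert np.all(res.per_cell["erythroid_high"].to_numpy()[flagged])

    def test_clean_concordant_cohort_no_flags(self, clean_cohort):
        _, cm, genes, cells, _ = clean_cohort
        res = flag_contaminated(sex_qc(log_normalize(cm), genes, cells))
        # no planted contamination and concordant sexes: nothing flagged
        assert res.per_cell["contaminated"].sum() == 0
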