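"""2^-ddCT folds, the CT quantification limit, concordance validation,
reference-gene stability, and the paired t-test closed form."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from embryorigin.expression_calls import ThresholdConfig
from embryorigin.io_formats import QpcrTable
from embryorigin.qpcr_validation import (
    FoldChangeRecord,
    fold_change_ddct,
    paired_t_test,
    replicate_validates,
    select_reference_gene,
    summarize_validation,
    validate_genes,
)


def qpcr_from_rows(rows) -> QpcrTable:
    return QpcrTable(
        pd.DataFrame(rows, columns=["replicate", "group", "gene_id", "ct"])
    )


class TestFoldChange:
    def test_worked_example(self):
        rec = fold_change_ddct(20, 15, 22, 15)
        assert rec.fold == pytest.approx(4.0)
        assert rec.delta_ct_case == pytest.approx(5.0)
        assert rec.delta_ct_control == pytest.approx(7.0)

    def test_equal_cts_give_fold_one(self):
        assert fold_change_ddct(25, 25, 25, 25).fold == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "cts",
        [
            (34, 15, 22, 15),      # target case beyond quantification
            (20, 15, 33.1, 15),    # strictly above 33 fails
            (float("nan"), 15, 22, 15),  # missing CT
        ],
    )
    def test_unquantifiable_inputs(self, cts):
        rec = fold_change_ddct(*cts)
        assert not rec.quantifiable
        assert math.isnan(rec.fold)

    def test_ct_exactly_33_is_quantifiable(self):
        assert fold_change_ddct(33.0, 15, 22, 15).quantifiable

    @settings(max_examples=100, deadline=None)
    @given(
        cts=st.lists(st.floats(10, 33, allow_nan=False), min_size=4,
                     max_size=4),
        shift=st.floats(-5, 0),
    )
    def test_swap_symmetry_and_global_shift_invariance(self, cts, shift):
        tc, rc, tt, rt = cts
        fwd = fold_change_ddct(tc, rc, tt, rt).fold
        rev = fold_change_ddct(tt, rt, tc, rc).fold
        assert fwd * rev == pytest.approx(1.0, rel=1e-9)
        shifted = fold_change_ddct(tc + shift, rc + shift, tt + shift,
                                   rt + shift).fold
        assert shifted == pytest.approx(fwd, rel=1e-9)


class TestReferenceGene:
    def test_smallest_ct_sd_wins(self):
        rows = [(r, g, gene, ct) for r, g, gene, ct in [
            (1, "high", "ACTB", 15.0), (1, "low", "ACTB", 15.1),
            (2, "high", "ACTB", 15.05), (2, "low", "ACTB", 15.0),
            (1, "high", "B2M", 18.0), (1, "low", "B2M", 20.0),
            (2, "high", "B2M", 16.0), (2, "low", "B2M", 19.0),
        ]]
        assert select_reference_gene(qpcr_from_rows(rows),
                                     ["ACTB", "B2M"]) == "ACTB"

    def test_tie_breaks_lexicographically(self):
        rows = [
            (1, "high", "A", 15.0), (2, "high", "A", 15.5),
            (1, "high", "B", 20.0), (2, "high", "B", 20.5),
        ]
        assert select_reference_gene(qpcr_from_rows(rows), ["B", "A"]) == "A"

    def test_candidate_beyond_ct_limit_excluded(self):
        rows = [
            (1, "high", "X", 34.0), (2, "high", "X", 35.0),  # all CTs > 33
            (1, "high", "Y", 20.0), (2, "high", "Y", 22.0),
        ]
        assert select_reference_gene(qpcr_from_rows(rows), ["X", "Y"]) == "Y"

    def test_all_candidates_excluded_raises(self):
        rows = [(1, "high", "X", 34.0), (2, "high", "X", 35.0)]
        with pytest.raises(ValueError, match="quantifiable"):
            select_reference_gene(qpcr_from_rows(rows), ["X", "X2"])


def make_records(folds, dcase=None, dctrl=None):
    dcase = dcase or [1.0] * len(folds)
    dctrl = dctrl or [1.0] * len(folds)
    return [
        FoldChangeRecord("g", i + 1, f, dc, dt)
        for i, (f, dc, dt) in enumerate(zip(folds, dcase, dctrl))
    ]


class TestSummarizeValidation:
    def test_upregulated_all_validate(self):
        s = summarize_validation(make_records([2.0, 2.5, 2.9]), "up")
        assert s.n_validated == 3
        assert s.mean_fold == pytest.approx(2.467, abs=1e-3)

    def test_downregulated_threshold_is_reciprocal(self):
        # 0.9 > 1/1.5 ~ 0.667 fails; 0.5 and 0.6 validate
        s = summarize_validation(make_records([0.5, 0.6, 0.9]), "down")
        assert s.n_validated == 2

    def test_zero_quantifiable_replicates_flagged_not_raised(self):
        recs = [FoldChangeRecord("g", i, float("nan"), float("nan"),
                                 float("nan")) for i in (1, 2, 3)]
        s = summarize_validation(recs, "up")
        assert not s.quantifiable
        assert math.isnan(s.mean_fold) and math.isnan(s.paired_t_p)

    def test_paired_t_runs_on_delta_cts(self):
        recs = make_records([2.0, 2.1, 2.2], dcase=[3.0, 3.1, 2.9],
                            dctrl=[4.0, 4.2, 3.9])
        s = summarize_validation(recs, "up")
        t, p = paired_t_test([3.0, 3.1, 2.9], [4.0, 4.2, 3.9])
        assert s.paired_t_p == pytest.approx(p)

    def test_geometric_mean_option(self):
        s = summarize_validation(make_records([2.0, 8.0]), "up",
                                 fold_average="geometric")
        assert s.mean_fold == pytest.approx(4.0)

    @settings(max_examples=50, deadline=None)
    @given(
        folds=st.lists(st.floats(0.05, 20, allow_nan=False), min_size=1,
                       max_size=6),
        thr_lo=st.floats(1.1, 3.0),
        bump=st.floats(0.1, 2.0),
        direction=st.sampled_from(["up", "down"]),
    )
    def test_raising_threshold_never_validates_more(self, folds, thr_lo,
                                                    bump, direction):
        lo = summarize_validation(
            make_records(folds), direction,
            ThresholdConfig(fold_validation=thr_lo),
        )
        hi = summarize_validation(
            make_records(folds), direction,
            ThresholdConfig(fold_validation=thr_lo + bump),
        )
        assert hi.n_validated <= lo.n_validated


class TestPairedT:
    def test_identical_vectors(self):
        assert paired_t_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_closed_form_example(self):
        t, p = paired_t_test([1, 2, 3], [0, 0, 0])
        assert t == pytest.approx(2 / (1 / math.sqrt(3)), rel=1e-9)
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_constant_nonzero_difference_degenerates(self):
        t, p = paired_t_test([2, 2, 2], [1, 1, 1])
        assert math.isinf(t) and p == 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            paired_t_test([1], [2])

    def test_matches_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(2, 12)
            x, y = rng.normal(size=n), rng.normal(size=n)
            t, p = paired_t_test(x, y)
            ref = sps.ttest_rel(x, y)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestValidateGenes:
    def test_table_shape_and_unquantifiable_row(self):
        rows = []
        for rep in (1, 2, 3):
            rows += [
                (rep, "high", "ACTB", 15.0), (rep, "low", "ACTB", 15.0),
                (rep, "high", "GOOD", 23.0), (rep, "low", "GOOD", 24.3),
                (rep, "high", "DARK", 34.5), (rep, "low", "DARK", 35.0),
            ]
        out = validate_genes(qpcr_from_rows(rows),
                             {"GOOD": "up", "DARK": "up"}, "ACTB")
        good = out[out["gene_id"] == "GOOD"].iloc[0]
        assert good["n_validated"] == 3
        assert good["mean_fold"] == pytest.approx(2 ** 1.3, rel=1e-9)
        dark = out[out["gene_id"] == "DARK"].iloc[0]
        assert dark["n_quantifiable"] == 0
        assert math.isnan(dark["mean_fold"])  # reported NA, not an error
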