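"""NB exact test vs sample-level enumeration oracle, BH vs independent
step-up, dispersion recovery, and the run_de driver."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from embryorigin.diffexpr import (
    DispersionEstimate,
    bh_adjust,
    equalize_library_sizes,
    estimate_common_dispersion,
    nb_exact_test,
    run_de,
)
from embryorigin.io_formats import GeneCountTable, SampleMeta
from embryorigin.synthetic_data import SimulationConfig, simulate_dataset


def brute_force_exact_p(n_a: int, n_b: int, split_a: int, total: int,
                        dispersion: float) -> float:
    """Independent oracle: enumerate every per-sample count vector of
    length n_a + n_b summing to ``total``, accumulate the joint NB
    probability of each group-sum split, and apply the two-sided
    'sum of splits no more likely than observed' rule."""
    n = n_a + n_b
    mu = total / n
    if dispersion == 0:
        pmf = stats.poisson.pmf(np.arange(total + 1), mu)
    else:
        r = 1.0 / dispersion
        pmf = stats.nbinom.pmf(np.arange(total + 1), r, r / (r + mu))

    split_prob = np.zeros(total + 1)
    # compositions of `total` into n non-negative parts
    for cuts in itertools.combinations(range(total + n - 1), n - 1):
        parts, prev = [], -1
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(total + n - 2 - prev)
        prob = np.prod(pmf[parts])
        split_prob[sum(parts[:n_a])] += prob
    split_prob /= split_prob.sum()
    obs = split_prob[split_a]
    return float(min(1.0, split_prob[split_prob <= obs * (1 + 1e-12)].sum()))


def make_embryo_table(counts: np.ndarray, n_high: int = 3,
                      n_low: int = 3) -> GeneCountTable:
    samples = [
        SampleMeta(f"h{i}", "embryo", "high", i + 1) for i in range(n_high)
    ] + [SampleMeta(f"l{i}", "embryo", "low", i + 1) for i in range(n_low)]
    df = pd.DataFrame(
        np.asarray(counts, dtype=np.int64),
        index=pd.Index([f"g{i}" for i in range(len(counts))], name="gene_id"),
        columns=[s.sample_id for s in samples],
    )
    return GeneCountTable(df, samples)


class TestNbExactTest:
    def test_balanced_split_gives_p_one(self):
        for disp in (0.0, 0.3):
            assert nb_exact_test([10, 10, 10], [10, 10, 10], disp) == 1.0

    def test_poisson_extreme_split_closed_form(self):
        # dispersion 0, equal group sizes, sums 0 vs 10: conditionally the
        # group-A sum is Binomial(10, 1/2), so p = 2 * P(X = 0) = 2/1024
        p = nb_exact_test([0, 0], [6, 4], 0.0)
        assert p == pytest.approx(2 / 1024, rel=1e-10)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 30, size=3)
            b = rng.integers(0, 30, size=3)
            for disp in (0.0, 0.5):
                assert nb_exact_test(a, b, disp) == pytest.approx(
                    nb_exact_test(b, a, disp), rel=1e-12
                )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            nb_exact_test([-1, 2], [3, 4], 0.1)

    def test_all_zero_total_gives_p_one(self):
        assert nb_exact_test([0, 0], [0, 0], 0.2) == 1.0

    @pytest.mark.parametrize("dispersion", [0.0, 0.5])
    def test_matches_sample_level_enumeration_oracle(self, dispersion):
        # spot-check in the unit suite; the exhaustive sweep over all
        # totals <= 30 runs in the acceptance suite
        for total in (1, 4, 9, 14):
            for s in range(total + 1):
                got = nb_exact_test([s, 0], [total - s, 0], dispersion)
                want = brute_force_exact_p(2, 2, s, total, dispersion)
                assert got == pytest.approx(want, abs=1e-10)

    def test_unequal_group_sizes_match_oracle(self):
        for total in (5, 8):
            for s in range(total + 1):
                got = nb_exact_test([s], [total - s, 0], 0.5)
                want = brute_force_exact_p(1, 2, s, total, 0.5)
                assert got == pytest.approx(want, abs=1e-10)


def reference_bh(pvalues):
    """Independently coded step-up: walk ranks from largest to smallest,
    carrying the running minimum."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_saturated(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_independent_oracle_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(rng.integers(1, 60))
            q = bh_adjust(p)
            assert q == pytest.approx(reference_bh(p), abs=1e-12)
            assert q == pytest.approx(
                multipletests(p, method="fdr_bh")[1], abs=1e-12
            )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        p = rng.random(40)
        perm = rng.permutation(40)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))


class TestDispersionEstimation:
    def test_poisson_counts_give_near_zero(self):
        ds = simulate_dataset(
            SimulationConfig(seed=3, n_genes=2000, nb_dispersion=0.0,
                             de_fraction=0.0)
        )
        est = estimate_common_dispersion(ds.embryo)
        assert est.common_dispersion < 0.02

    def test_recovers_planted_dispersion(self):
        ds = simulate_dataset(
            SimulationConfig(seed=4, n_genes=2000, nb_dispersion=0.2,
                             de_fraction=0.0)
        )
        est = estimate_common_dispersion(ds.embryo)
        assert est.common_dispersion == pytest.approx(0.2, abs=0.05)

    def test_all_zero_matrix_rejected(self):
        table = make_embryo_table(np.zeros((10, 6)))
        with pytest.raises(ValueError, match="all-zero"):
            estimate_common_dispersion(table)

    def test_single_sample_group_rejected(self):
        table = make_embryo_table(np.ones((5, 3)), n_high=1, n_low=2)
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_common_dispersion(table)

    def test_negative_dispersion_invalid(self):
        with pytest.raises(ValueError):
            DispersionEstimate(-0.1)


class TestRunDe:
    def test_no_signal_when_groups_identical(self):
        rng = np.random.default_rng(7)
        base = rng.poisson(50, size=(300, 3))
        table = make_embryo_table(np.hstack([base, base]))
        de = run_de(table)
        assert int(de["significant"].sum()) == 0
        assert (de.loc[de["tested"], "log2fc"].abs() < 1e-9).all()

    def test_low_count_genes_flagged_untested(self):
        counts = np.vstack([np.full(6, 100), np.full(6, 2)])
        table = make_embryo_table(counts)
        de = run_de(table)
        assert bool(de.loc[de["gene_id"] == "g0", "tested"].iloc[0])
        row = de[de["gene_id"] == "g1"].iloc[0]
        assert not row["tested"] and not row["significant"]
        assert np.isnan(row["pvalue"])

    def test_gene_relabeling_leaves_pvalues_unchanged(self):
        ds = simulate_dataset(SimulationConfig(seed=8, n_genes=200))
        de1 = run_de(ds.embryo)
        renamed = ds.embryo.counts.copy()
        renamed.index = [f"Z{i}" for i in range(len(renamed))]
        de2 = run_de(GeneCountTable(renamed, ds.embryo.samples))
        assert de1["pvalue"].to_numpy() == pytest.approx(
            de2["pvalue"].to_numpy(), nan_ok=True
        )

    def test_equalize_library_sizes_levels_depths(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson([20, 40, 80], size=(500, 3))
        df = pd.DataFrame(counts, columns=list("abc"))
        eq = equalize_library_sizes(df)
        depths = eq.sum(axis=0)
        assert depths.max() / depths.min() < 1.02
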