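"""TMM normalization, common dispersion and the NB exact test."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, rankdata

from stressflux import (
    ConfigurationError,
    CountMatrix,
    FormatError,
    NormFactors,
    SimCountSpec,
    estimate_common_dispersion,
    exact_test,
    simulate_counts,
    summarize_de,
    tmm_factors,
    top_regulated,
)
from stressflux.data import top_regulated_table
from stressflux.dge import _double_tail_p

from conftest import make_detable


def _matrix(values, n_ctrl, n_trt, genes=None):
    n = len(values)
    samples = [f"c{i}" for i in range(n_ctrl)] + [f"t{i}" for i in range(n_trt)]
    counts = pd.DataFrame(values, index=genes or [f"g{i}" for i in range(n)], columns=samples)
    design = pd.Series(["control"] * n_ctrl + ["treated"] * n_trt, index=samples)
    return CountMatrix(counts, design)


def unit_factors(cm):
    return NormFactors(
        pd.Series(1.0, index=cm.sample_ids), reference_sample=cm.sample_ids[0]
    )


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        cm = _matrix(np.tile([[10], [200], [3000], [40], [500], [60]], (1, 4)), 2, 2)
        nf = tmm_factors(cm)
        assert np.allclose(nf.factors, 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        base = np.array([13, 250, 3100, 47, 520, 66])
        cm = _matrix(np.column_stack([base, 2 * base]), 1, 1)
        nf = tmm_factors(cm)
        assert np.allclose(nf.factors, 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self, small_counts):
        cm, _ = small_counts
        nf = tmm_factors(cm)
        assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-12)

    def test_inflated_gene_matches_hand_computed_formula(self):
        # 6 genes, 2 samples, one strongly inflated gene in sample B
        a = np.array([100.0, 200.0, 300.0, 400.0, 500.0, 1000.0])
        b = np.array([110.0, 190.0, 310.0, 390.0, 480.0, 9000.0])
        cm = _matrix(np.column_stack([a, b]).astype(int), 1, 1)
        na, nb = a.sum(), b.sum()
        # direct transcription of the published TMM formula
        m = np.log2((b / nb) / (a / na))
        aval = 0.5 * np.log2((b / nb) * (a / na))
        w = (nb - b) / (nb * b) + (na - a) / (na * a)
        n = len(m)
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        keep = (
            (rankdata(m) >= lo_m)
            & (rankdata(m) <= hi_m)
            & (rankdata(aval) >= lo_a)
            & (rankdata(aval) <= hi_a)
        )
        expected_pair = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        nf = tmm_factors(cm)
        assert nf.factors.iloc[1] / nf.factors.iloc[0] == pytest.approx(
            expected_pair, rel=1e-10
        )

    def test_matches_edger_reference_implementation(self):
        cm, _ = simulate_counts(SimCountSpec(n_genes=80, library_size_mean=2e4, seed=3))
        nf = tmm_factors(cm)
        script = (
            "suppressMessages(library(edgeR));"
            "x <- matrix(scan('stdin', quiet=TRUE), nrow=80, byrow=TRUE);"
            "cat(sprintf('%.12f\\n', calcNormFactors(x, method='TMM')))"
        )
        proc = subprocess.run(
            ["Rscript", "-e", script],
            input="\n".join(" ".join(map(str, row)) for row in cm.counts.to_numpy()),
            capture_output=True,
            text=True,
            check=True,
        )
        ref = np.array([float(v) for v in proc.stdout.split()])
        assert np.allclose(nf.factors.to_numpy(), ref, atol=1e-9)

    def test_gene_permutation_equivariance(self, small_counts):
        cm, _ = small_counts
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cm.gene_ids))
        shuffled = CountMatrix(cm.counts.iloc[perm], cm.design.copy())
        pd.testing.assert_series_equal(
            tmm_factors(cm).factors, tmm_factors(shuffled).factors
        )

    def test_error_cases(self):
        cm = _matrix([[5, 0], [7, 0]], 1, 1)
        with pytest.raises(FormatError, match="all-zero"):
            tmm_factors(cm)
        good = _matrix([[5, 6], [7, 8]], 1, 1)
        with pytest.raises(ConfigurationError, match="trim_m"):
            tmm_factors(good, trim_m=0.6)


class TestCommonDispersion:
    def test_poisson_data_estimates_near_zero(self):
        cm, _ = simulate_counts(
            SimCountSpec(
                n_genes=400, library_size_mean=4e5, dispersion=0.0,
                de_fraction=0.0, library_size_cv=0.0, seed=21,
            )
        )
        phi = estimate_common_dispersion(cm, tmm_factors(cm))
        assert 0.0 <= phi <= 0.05

    def test_parameter_recovery_with_many_replicates(self):
        cm, _ = simulate_counts(
            SimCountSpec(
                n_genes=400, n_reps_per_group=50, library_size_mean=2e5,
                dispersion=0.2, de_fraction=0.0, seed=9,
            )
        )
        phi = estimate_common_dispersion(cm, tmm_factors(cm))
        assert phi == pytest.approx(0.2, rel=0.3)

    def test_constant_counts_give_zero(self):
        cm = _matrix(np.tile([[50], [70], [90]], (1, 6)), 3, 3)
        phi = estimate_common_dispersion(cm, unit_factors(cm))
        assert phi == 0.0

    def test_single_replicate_per_group_rejected(self):
        cm = _matrix([[5, 6], [7, 8]], 1, 1)
        with pytest.raises(ConfigurationError, match="fixed dispersion"):
            estimate_common_dispersion(cm, unit_factors(cm))


class TestExactTest:
    def test_identical_group_sums_are_null(self):
        cm = _matrix([[10, 20, 20, 10], [50, 50, 50, 50]], 2, 2)
        de = exact_test(cm, unit_factors(cm), dispersion=0.0)
        assert de.frame["p_value"].iloc[0] == pytest.approx(1.0)
        assert (de.frame["status"] == "ns").all()

    def test_poisson_limit_matches_exact_binomial(self):
        # equal library sizes -> pseudo-counts equal raw counts, so the
        # phi=0 conditional test is the exact binomial on group sums
        vals = np.array([[12, 18, 40, 30], [48, 42, 20, 30], [40, 40, 40, 40]])
        cm = _matrix(vals, 2, 2)
        de = exact_test(cm, unit_factors(cm), dispersion=0.0)
        for i, g in enumerate(cm.gene_ids):
            s1 = int(vals[i, :2].sum())
            s2 = int(vals[i, 2:].sum())
            expected = binomtest(s1, s1 + s2, 0.5).pvalue
            assert de.frame.loc[g, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_double_tail_symmetry_and_range(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            s1, s2 = map(int, rng.integers(0, 400, size=2))
            phi = float(rng.uniform(0, 0.5))
            p = _double_tail_p(s1, s2, 4, 4, phi)
            assert 0.0 < p <= 1.0
            assert p == pytest.approx(_double_tail_p(s2, s1, 4, 4, phi), rel=1e-9)

    def test_null_pvalues_near_uniform(self):
        cm, _ = simulate_counts(
            SimCountSpec(
                n_genes=2000, library_size_mean=1e6, dispersion=0.1,
                de_fraction=0.0, seed=11,
            )
        )
        nf = tmm_factors(cm)
        phi = estimate_common_dispersion(cm, nf)
        de = exact_test(cm, nf, phi)
        p = de.frame["p_value"].to_numpy()
        for q in (0.1, 0.25, 0.5):
            # 4 sigma binomial band around the uniform quantile
            half = 4 * np.sqrt(q * (1 - q) / len(p))
            assert abs((p < q).mean() - q) < half + 0.01

    def test_status_sign_invariants(self, small_counts):
        cm, _ = small_counts
        nf = tmm_factors(cm)
        de = exact_test(cm, nf, dispersion=0.1, alpha=0.05)
        up = de.frame[de.frame["status"] == "up"]
        down = de.frame[de.frame["status"] == "down"]
        assert (up["log2fc"] > 0).all() and (up["p_value"] < 0.05).all()
        assert (down["log2fc"] < 0).all() and (down["p_value"] < 0.05).all()
        assert (up["fold_change_signed"] > 0).all()
        assert (down["fold_change_signed"] < 0).all()

    def test_invalid_alpha_rejected(self, small_counts):
        cm, _ = small_counts
        with pytest.raises(ConfigurationError, match="alpha"):
            exact_test(cm, unit_factors(cm), dispersion=0.1, alpha=1.5)


class TestSummaries:
    def test_study_table_arithmetic(self):
        de = make_detable(
            {f"u{i}": 2.0 for i in range(411)} | {f"d{i}": -2.0 for i in range(298)}
        )
        s = summarize_de(de, n_mapped=3898)
        assert (s.n_de, s.pct_de) == (709, 18.2)
        assert (s.pct_up_of_de, s.pct_down_of_de) == (58, 42)

    def test_empty_table_all_zero(self):
        de = make_detable({}, ns_genes=("a", "b"))
        s = summarize_de(de)
        assert (s.n_de, s.n_up, s.n_down, s.pct_de) == (0, 0, 0, 0.0)

    def test_forced_arithmetic_small_case(self):
        de = make_detable({"a": 1.0, "b": -1.0})
        s = summarize_de(de, n_mapped=2)
        assert (s.pct_de, s.pct_up_of_de, s.pct_down_of_de) == (100.0, 50, 50)

    def test_summary_is_a_pure_tally(self, small_counts):
        cm, _ = small_counts
        nf = tmm_factors(cm)
        de = exact_test(cm, nf, dispersion=0.1)
        assert summarize_de(de) == summarize_de(de)

    def test_n_mapped_below_table_size_rejected(self):
        de = make_detable({"a": 1.0, "b": -1.0})
        with pytest.raises(ConfigurationError, match="n_mapped"):
            summarize_de(de, n_mapped=1)


class TestTopRegulated:
    def test_published_rankings(self):
        table = top_regulated_table()
        top_up = top_regulated(table, 20, "up")
        assert top_up.index[0] == "b1743"  # spy
        assert top_up["fold_change_signed"].iloc[0] == pytest.approx(6447)
        top_down = top_regulated(table, 20, "down")
        assert top_down.index[0] == "b2725"  # hycA
        assert top_down["fold_change_signed"].iloc[0] == pytest.approx(-520)

    def test_ties_break_lexicographically(self):
        de = make_detable({"zzz": 2.0, "aaa": 2.0, "mmm": 3.0})
        top = top_regulated(de, 3, "up")
        assert list(top.index) == ["mmm", "aaa", "zzz"]

    def test_n_larger_than_available_returns_all(self):
        de = make_detable({"a": 1.0, "b": -1.0})
        assert len(top_regulated(de, 10, "up")) == 1
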