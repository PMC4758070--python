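import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from gase.gene import (
    augment_pseudocounts,
    build_null_distribution,
    cd_gate_from_static,
    empirical_pvalue,
    run_gene_ase,
    snv_statistic_icd,
    snv_statistic_static,
    stouffer_combine,
)
from gase.io import BetaBinomNull, CountTable2x2


class TestPseudocounts:
    def test_2x2_with_zero_increments_every_cell(self):
        out = augment_pseudocounts(np.array([[5, 0], [3, 2]]))
        np.testing.assert_array_equal(out, [[6, 1], [4, 3]])

    def test_2x2_without_zero_unchanged(self):
        table = np.array([[5, 2], [3, 2]])
        np.testing.assert_array_equal(augment_pseudocounts(table), table)

    def test_2x1_table(self):
        np.testing.assert_array_equal(augment_pseudocounts(np.array([0, 7])), [1, 8])

    def test_count_table_object(self):
        out = augment_pseudocounts(CountTable2x2(5, 0, 5, 5))
        assert (out.alt_T, out.ref_T, out.alt_U, out.ref_U) == (6, 1, 6, 6)


class TestSnvStatistics:
    def test_balanced_static_counts_give_zero(self):
        assert snv_statistic_static(5, 5).statistic == 0.0

    def test_static_symmetry_under_allele_swap(self):
        for a, b in [(2, 8), (1, 30), (7, 9)]:
            assert snv_statistic_static(a, b).statistic == pytest.approx(
                snv_statistic_static(b, a).statistic
            )

    def test_static_wilson_se_matches_independent_interval(self):
        # oracle: statsmodels' Wilson interval, endpoints mapped to log-odds
        for ref, alt in [(8, 2), (5, 15), (30, 30), (1, 40)]:
            lo, hi = proportion_confint(alt, ref + alt, alpha=0.05, method="wilson")
            se = (math.log(hi / (1 - hi)) - math.log(lo / (1 - lo))) / (2 * 1.959963984540054)
            expected = abs(math.log(alt / ref)) / se
            assert snv_statistic_static(ref, alt).statistic == pytest.approx(
                expected, rel=1e-9
            ), (ref, alt)

    def test_static_delta_method_switch(self):
        stat = snv_statistic_static(2, 8, se_method="delta")
        assert stat.statistic == pytest.approx(
            abs(math.log(4)) / math.sqrt(1 / 2 + 1 / 8)
        )

    def test_icd_balanced_or_gives_zero(self):
        assert snv_statistic_icd(CountTable2x2(4, 4, 7, 7)).statistic == 0.0

    def test_icd_closed_form(self):
        got = snv_statistic_icd(CountTable2x2(8, 2, 2, 8)).statistic
        assert got == pytest.approx(
            abs(math.log(16)) / math.sqrt(1 / 8 + 1 / 2 + 1 / 2 + 1 / 8), rel=1e-9
        )

    def test_icd_condition_swap_symmetry(self):
        a = snv_statistic_icd(CountTable2x2(8, 2, 3, 9)).statistic
        b = snv_statistic_icd(CountTable2x2(3, 9, 8, 2)).statistic
        assert a == pytest.approx(b)


class TestStouffer:
    def test_single_statistic_passthrough(self):
        assert stouffer_combine([3.3]) == pytest.approx(3.3)

    def test_equal_statistics_closed_form(self):
        assert stouffer_combine([2, 2, 2, 2]) == pytest.approx(4.0)

    def test_two_values(self):
        assert stouffer_combine([1, 3]) == pytest.approx(4 / math.sqrt(2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stouffer_combine([])

    @given(st.lists(st.floats(0, 50), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_scales_as_sqrt_k(self, values):
        got = stouffer_combine(values)
        assert got == pytest.approx(sum(values) / math.sqrt(len(values)))


class TestEmpiricalPvalue:
    def test_observed_above_all(self):
        null = np.arange(9999, dtype=float)
        assert empirical_pvalue(1e9, null) == pytest.approx(1e-4)

    def test_observed_below_all(self):
        assert empirical_pvalue(-1.0, np.arange(100, dtype=float)) == 1.0

    def test_observed_at_median(self, rng):
        null = rng.normal(size=10_000)
        p = empirical_pvalue(float(np.median(null)), null)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_ties_count_toward_numerator(self):
        null = np.array([1.0, 2.0, 2.0, 3.0])
        assert empirical_pvalue(2.0, null) == pytest.approx(4 / 5)


class TestNullDistribution:
    def test_deterministic_given_seed(self):
        null = BetaBinomNull(p0=0.5, rho0=0.1)
        a = build_null_distribution(3, [20, 50], null, N=500, rng=11)
        b = build_null_distribution(3, [20, 50], null, N=500, rng=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_values_nonnegative(self):
        null = BetaBinomNull(p0=0.5, rho0=0.22)
        for mode in ("static", "icd"):
            nd = build_null_distribution(2, [30], null, N=1000, mode=mode, rng=0)
            assert (nd.values >= 0).all()

    def test_binomial_limit_matches_brute_force_resampling(self, rng):
        # independent oracle at rho = 0, k = 1, fixed depth: resample
        # binomial counts and compute the statistic with its own arithmetic
        null = BetaBinomNull(p0=0.5, rho0=0.0)
        nd = build_null_distribution(1, [50], null, N=10_000, mode="icd", rng=rng)
        oracle = []
        rng2 = np.random.default_rng(999)
        for _ in range(10_000):
            au, at = rng2.binomial(50, 0.5, size=2)
            ru, rt = 50 - au, 50 - at
            if 0 in (au, at, ru, rt):
                au, at, ru, rt = au + 1, at + 1, ru + 1, rt + 1
            eff = math.log((at / rt) / (au / ru))
            se = math.sqrt(1 / at + 1 / rt + 1 / au + 1 / ru)
            oracle.append(abs(eff) / se)
        ks = stats.ks_2samp(nd.values, oracle)
        assert ks.pvalue > 0.01

    def test_empty_depth_pool_rejected(self):
        with pytest.raises(ValueError):
            build_null_distribution(1, [], BetaBinomNull(0.5, 0.0), N=100)


class TestRunGeneAse:
    @pytest.fixture
    def null(self):
        return BetaBinomNull(p0=0.5, rho0=0.0)

    def _static_dataset(self, rng, n_genes=50, k=2, depth=50):
        rows = []
        for i in range(n_genes):
            alt = rng.binomial(depth, 0.5, size=k)
            for j in range(k):
                rows.append(
                    {
                        "sample_id": "s1",
                        "variant_id": f"g{i}_v{j}",
                        "gene_id": f"g{i:03d}",
                        "ref_count": depth - alt[j],
                        "alt_count": alt[j],
                    }
                )
        return pd.DataFrame(rows)

    def test_single_variant_gene_excluded_by_default(self, rng, null):
        df = self._static_dataset(rng, n_genes=5, k=1)
        res = run_gene_ase(df, null, n_resamples=200, seed=0)
        assert len(res) == 0
        res1 = run_gene_ase(df, null, n_resamples=200, min_variants=1, seed=0)
        assert len(res1) == 5

    def test_non_dbsnp_variants_ignored(self, rng, null):
        df = self._static_dataset(rng, n_genes=4, k=2)
        df["in_dbsnp"] = [True, False] * 4  # leaves every gene with k=1
        res = run_gene_ase(df, null, n_resamples=200, seed=0)
        assert len(res) == 0

    def test_k1_gene_pvalue_equals_snv_empirical_pvalue(self, rng, null):
        # with one variant the gene test is the variant test under the
        # same null draws
        df = self._static_dataset(rng, n_genes=10, k=1)
        res = run_gene_ase(df, null, n_resamples=2000, min_variants=1, seed=7)
        from gase.gene import _augment_pairs, _static_statistic

        nd = build_null_distribution(
            1,
            (df["ref_count"] + df["alt_count"]).to_numpy(),
            null,
            N=2000,
            mode="static",
            rng=np.random.default_rng(7),
        )
        for row in res.itertuples():
            sub = df.loc[df["gene_id"] == row.gene_id]
            alt, ref = _augment_pairs(
                sub["alt_count"].to_numpy(), sub["ref_count"].to_numpy()
            )
            eff, se = _static_statistic(alt, ref)
            assert row.p_value == pytest.approx(
                empirical_pvalue(float(abs(eff / se)[0]), nd.values)
            )

    def test_strong_icd_signal_is_significant(self, null):
        # OR = 16 at depth 100 per condition, rho = 0: power ~ 1
        rng = np.random.default_rng(3)
        rows = []
        for i in range(30):
            p_t = 16 / 17 if i < 10 else 0.5
            for j in range(2):
                au = rng.binomial(100, 0.5)
                at = rng.binomial(100, p_t)
                rows.append(
                    {
                        "sample_id": "s1",
                        "variant_id": f"g{i}_v{j}",
                        "gene_id": f"g{i:03d}",
                        "ref_count_U": 100 - au,
                        "alt_count_U": au,
                        "ref_count_T": 100 - at,
                        "alt_count_T": at,
                    }
                )
        res = run_gene_ase(pd.DataFrame(rows), null, mode="icd", n_resamples=5000, seed=0)
        sig = set(res.loc[res["p_adjusted"] < 0.05, "gene_id"])
        assert {f"g{i:03d}" for i in range(10)} <= sig

    def test_missing_null_model_rejected(self, rng):
        with pytest.raises(ValueError):
            run_gene_ase(self._static_dataset(rng), None)

    def test_k_cap_aggregated_null_used(self, rng, null):
        df = self._static_dataset(rng, n_genes=3, k=7)
        res = run_gene_ase(df, null, n_resamples=300, k_cap=5, seed=0)
        assert len(res) == 3
        assert (res["k"] == 7).all()
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()


class TestCdGate:
    def test_gate_logic(self):
        u = pd.DataFrame({"gene_id": ["gA", "gB", "gC"], "p_value": [0.15, 0.25, 0.20]})
        t = pd.DataFrame({"gene_id": ["gA", "gB", "gC"], "p_value": [0.90, 0.30, 0.95]})
        eligible = cd_gate_from_static(u, t)
        assert eligible == {"gA", "gC"}  # 0.20 is inclusive; gB excluded
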