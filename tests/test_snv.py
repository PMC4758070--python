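import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gase.io import CountTable2x2
from gase.snv import (
    ase_threshold_from_percentile,
    bh_adjust,
    fisher_exact_icd,
    gene_snr,
    icd_effect_size,
    modified_binomial_test,
    static_effect_size,
    sustained_effect_variants,
)


def binom_twosided_enumeration(alt, n, q):
    """Independent oracle: minimum-likelihood two-sided exact binomial p."""
    x = np.arange(n + 1)
    pmf = stats.binom.pmf(x, n, q)
    return float(pmf[pmf <= pmf[alt] * (1 + 1e-12)].sum())


def fisher_twosided_enumeration(a, b, c, d):
    """Independent oracle: enumerate the hypergeometric support of the 2x2
    table with fixed margins; sum probabilities <= that of the observed."""
    n = a + b + c + d
    r, k = a + b, a + c
    lo, hi = max(0, r + k - n), min(r, k)
    x = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(x, n, k, r)
    return float(pmf[pmf <= pmf[a - lo] * (1 + 1e-12)].sum())


class TestStaticEffectSize:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [(5, 5, 0.0), (0, 10, 0.5), (1, 3, 0.25)],
    )
    def test_anchor_values(self, ref, alt, expected):
        assert static_effect_size(ref, alt) == pytest.approx(expected, abs=0)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            static_effect_size(0, 0)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(1, 20))
    @settings(max_examples=100, deadline=None)
    def test_allele_swap_and_scaling_invariance(self, ref, alt, factor):
        if ref + alt == 0:
            return
        e = static_effect_size(ref, alt)
        assert e == pytest.approx(static_effect_size(alt, ref))
        assert e == pytest.approx(static_effect_size(ref * factor, alt * factor))
        assert 0.0 <= e <= 0.5


class TestIcdEffectSize:
    def test_balanced_or_is_zero(self):
        assert icd_effect_size(CountTable2x2(4, 4, 7, 7)) == 0.0

    def test_or_sixteen_is_log2_four(self):
        assert icd_effect_size(CountTable2x2(8, 2, 2, 8)) == pytest.approx(4.0)

    def test_zero_cell_requires_pseudocounts(self):
        with pytest.raises(ValueError, match="pseudo"):
            icd_effect_size(CountTable2x2(5, 0, 5, 5))
        from gase.gene import augment_pseudocounts

        t = augment_pseudocounts(CountTable2x2(5, 0, 5, 5))
        assert icd_effect_size(t) == pytest.approx(math.log2(6))


class TestModifiedBinomial:
    @pytest.mark.parametrize(
        "ref,alt,q,expected",
        [
            (5, 5, 0.5, 1.0),
            (10, 0, 0.5, 2 * 0.5**10),
            (2, 8, 0.8, 1.0),  # 8/10 is the mode under q = 0.8
        ],
    )
    def test_anchor_values(self, ref, alt, q, expected):
        assert modified_binomial_test(ref, alt, q) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("q", [0.5, 0.8, 0.37])
    def test_matches_enumeration_for_all_small_tables(self, q):
        for n in range(1, 41):
            for alt in range(n + 1):
                expected = binom_twosided_enumeration(alt, n, q)
                assert modified_binomial_test(n - alt, alt, q) == pytest.approx(
                    expected, rel=1e-9
                ), (n, alt, q)

    @given(st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_at_half(self, a, b):
        if a + b == 0:
            return
        assert modified_binomial_test(a, b, 0.5) == pytest.approx(
            modified_binomial_test(b, a, 0.5)
        )

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            modified_binomial_test(0, 0, 0.5)


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact_icd(CountTable2x2(5, 5, 5, 5)) == 1.0

    def test_extreme_table(self):
        assert fisher_exact_icd(CountTable2x2(10, 0, 0, 10)) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9
        )

    def test_small_table_brute_force(self):
        # all 5 tables with margins (4,4)x(4,4); 34/70 of probability mass
        # is at or below the observed table's likelihood
        assert fisher_exact_icd(CountTable2x2(3, 1, 1, 3)) == pytest.approx(
            34 / 70, rel=1e-9
        )

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_icd(CountTable2x2(0, 0, 5, 5))

    def test_matches_enumeration_total_up_to_20(self):
        # full sweep to 40 lives in the acceptance suite; a 20 sweep here
        for n in range(2, 21):
            for r in range(1, n):
                for k in range(1, n):
                    lo, hi = max(0, r + k - n), min(r, k)
                    for a in range(lo, hi + 1):
                        b, c, d = r - a, k - a, n - r - k + a
                        expected = fisher_twosided_enumeration(a, b, c, d)
                        got = fisher_exact_icd(CountTable2x2(a, b, c, d))
                        assert got == pytest.approx(expected, rel=1e-8), (a, b, c, d)


class TestBhAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_dominates_input_and_permutation_equivariant(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(np.asarray(p)[perm]), adj[perm])


class TestGeneSnr:
    def test_zero_spread_is_infinite_and_consistent(self):
        assert gene_snr([2, 2, 2]) == math.inf

    def test_two_values(self):
        assert gene_snr([1.0, 3.0]) == pytest.approx(2 / math.sqrt(2))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            gene_snr([1.0])


class TestSustainedEffect:
    @pytest.fixture
    def effects(self):
        return pd.DataFrame(
            {
                "variant_id": ["rs1", "rs1", "rs2", "rs3", "rs3"],
                "sample_id": ["i1", "i2", "i1", "i3", "i4"],
                "abs_delta_ase": [0.8, 0.8, 0.8, 0.5, 0.9],
            }
        )

    def test_recurrent_strong_effect_included(self, effects):
        hits = sustained_effect_variants(effects, threshold=0.61)
        assert "rs1" in hits

    def test_single_individual_excluded(self, effects):
        hits = sustained_effect_variants(effects, threshold=0.61)
        assert "rs2" not in hits and "rs3" not in hits

    def test_percentile_convention(self):
        mags = np.linspace(0.1, 1.0, 10)
        assert ase_threshold_from_percentile(mags, 90) == pytest.approx(0.91)
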