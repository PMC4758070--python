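"""Single-variant allelic-imbalance effect sizes and significance tests.

Static ASE for a variant is measured as the deviation of the alt-allele
fraction from one half, ``ASE = |p - 0.5|`` with ``p = alt / (alt + ref)``,
so 0 means perfect balance and 0.5 monoallelic expression. Condition-
dependent ASE between a treated (T) and untreated (U) sample is the log2
odds ratio ``dASE = log2(odds(p_T) / odds(p_U))``.

Significance at the variant level uses the exact binomial test against a
variant-specific null ratio (0.5, or a mapping-bias-adjusted value) for
static ASE, and Fisher's exact test on the 2x2 condition table for
condition-dependent ASE; both use the minimum-likelihood two-sided rule.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountTable2x2

__all__ = [
    "static_effect_size",
    "icd_effect_size",
    "modified_binomial_test",
    "fisher_exact_icd",
    "bh_adjust",
    "gene_snr",
    "CONSISTENT_SNR_THRESHOLD",
    "ase_threshold_from_percentile",
    "sustained_effect_variants",
]

#: within-gene signal-to-noise ratio at or above which a gene's
#: condition-dependent effects are called consistent across its variants
CONSISTENT_SNR_THRESHOLD = 2.0


def static_effect_size(ref_count, alt_count):
    """Static ASE effect size |p - 0.5|, in [0, 0.5].

    Accepts scalars or arrays; total depth must be positive.
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    n = ref + alt
    if np.any(n <= 0):
        raise ValueError("total read depth must be positive")
    out = np.abs(alt / n - 0.5)
    return float(out) if out.ndim == 0 else out


def icd_effect_size(table: CountTable2x2) -> float:
    """Condition-dependent effect size: log2 odds ratio T vs U.

    Cells must be positive (apply the pseudo-count rule first if a zero is
    present); a zero cell would make the odds ratio zero or infinite.
    """
    a = table.as_array()
    if np.any(a <= 0):
        raise ValueError(
            "zero cell in 2x2 table; augment pseudo-counts before computing the odds ratio"
        )
    odds_t = table.alt_T / table.ref_T
    odds_u = table.alt_U / table.ref_U
    return math.log2(odds_t / odds_u)


def modified_binomial_test(ref_count: int, alt_count: int, null_ratio: float = 0.5) -> float:
    """Exact two-sided binomial test of the alt-allele count against a
    variant-specific null ratio.

    ``null_ratio`` is the expected alt fraction at a no-ASE site — 0.5, or
    the mapping ratio of simulated unbiased reads when a reference-mapping-
    bias correction is available upstream.
    """
    n = ref_count + alt_count
    if n <= 0:
        raise ValueError("total read depth must be positive")
    if not 0.0 < null_ratio < 1.0:
        raise ValueError(f"null_ratio must lie in (0, 1), got {null_ratio}")
    return stats.binomtest(alt_count, n, null_ratio).pvalue


def fisher_exact_icd(table: CountTable2x2) -> float:
    """Two-sided Fisher's exact p-value for the alt/ref x T/U count table."""
    a = table.as_array()
    if (a[0].sum() == 0) or (a[1].sum() == 0):
        raise ValueError("a condition with zero total reads cannot be tested")
    return float(stats.fisher_exact(a, alternative="two-sided")[1])


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_snr(delta_ase_values: Sequence[float]) -> float:
    """Within-gene consistency score: mean(|dASE|) / sd(|dASE|).

    Uses the sample (n-1) standard deviation; returns +inf for zero spread
    with a positive mean. Genes scoring at or above
    :data:`CONSISTENT_SNR_THRESHOLD` are deemed consistent. Needs >= 2 values.
    """
    v = np.asarray(delta_ase_values, dtype=float)
    if v.size < 2:
        raise ValueError("within-gene SNR requires at least two variants")
    sd = v.std(ddof=1)
    mean = v.mean()
    if sd == 0:
        return math.inf if mean > 0 else 0.0
    return float(mean / sd)


def ase_threshold_from_percentile(magnitudes: Sequence[float], q: float = 90.0) -> float:
    """Effect-size threshold as the q-th percentile of observed significant
    |dASE| magnitudes (linear interpolation between order statistics)."""
    return float(np.percentile(np.asarray(magnitudes, dtype=float), q))


def sustained_effect_variants(
    effects: pd.DataFrame,
    threshold: float,
    min_individuals: int = 2,
) -> set[str]:
    """Variants whose |dASE| exceeds ``threshold`` in at least
    ``min_individuals`` individuals.

    ``effects`` needs columns ``variant_id``, ``sample_id`` and
    ``abs_delta_ase``. This sustained-effect criterion recovers variants
    whose per-individual test may be underpowered at low depth but whose
    effect magnitude recurs across individuals.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    hit = effects.loc[effects["abs_delta_ase"] > threshold]
    counts = hit.groupby("variant_id")["sample_id"].nunique()
    return set(counts.index[counts >= min_individuals])
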