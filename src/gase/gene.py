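"""Gene-level test of allelic imbalance by resampling a variant null model.

A gene's evidence is built from its k heterozygous variants without
haplotype phasing:

1. each variant's allele-count table (2x1 for static ASE, 2x2 for
   condition-dependent ASE) gets a pseudo-count of 1 added to every cell
   if any cell is zero;
2. each variant yields a normalized statistic |effect| / se — the log-odds
   of the alt fraction with a Wilson-interval standard error (static), or
   the log odds ratio between conditions with the Woolf standard error
   sqrt(1/a + 1/b + 1/c + 1/d) (condition-dependent). Absolute values make
   the statistic phase-free; the log is variance-stabilizing;
3. the k statistics are combined by Stouffer's method, sum / sqrt(k);
4. the combined statistic is referred to a resampled null distribution:
   alt counts are drawn from the fitted beta-binomial null BB(p0, rho0) at
   depths resampled from the analyzed data, pushed through steps 1-3, N
   times. One null distribution is built per variant count k (shared by all
   genes with that k, up to a cap above which genes are pooled), and the
   empirical p-value is (1 + #{null >= observed}) / (N + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaBinomNull, CountTable2x2, SnvStatistic
from .null_model import _RHO_BINOMIAL_LIMIT, betabinom_alpha_beta
from .snv import bh_adjust

__all__ = [
    "NullDistribution",
    "augment_pseudocounts",
    "snv_statistic_static",
    "snv_statistic_icd",
    "stouffer_combine",
    "build_null_distribution",
    "empirical_pvalue",
    "run_gene_ase",
    "cd_gate_from_static",
]

_Z95 = stats.norm.ppf(0.975)

#: genes with more variants than this share one aggregated null distribution
K_CAP = 100


@dataclass
class NullDistribution:
    """Resampled null combined statistics for genes with k variants."""

    k: int
    values: np.ndarray
    N: int
    mode: str = "static"
    depth_pool_id: str = "pooled"
    _sorted: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.N:
            raise ValueError("null distribution length must equal N")
        self._sorted = np.sort(self.values)

    def pvalue(self, observed) -> np.ndarray | float:
        """Empirical upper-tail p-value(s) with the add-one convention."""
        obs = np.asarray(observed, dtype=float)
        n_ge = self.N - np.searchsorted(self._sorted, obs, side="left")
        p = (1.0 + n_ge) / (self.N + 1.0)
        return float(p) if obs.ndim == 0 else p


def augment_pseudocounts(table):
    """Add a pseudo-count of 1 to every cell if any cell is zero.

    Accepts a 2-element (alt, ref) pair, a 2x2 array, or a
    :class:`CountTable2x2`; returns the same shape. Tables without zeros
    pass through unchanged.
    """
    if isinstance(table, CountTable2x2):
        arr = table.as_array()
        if (arr == 0).any():
            arr = arr + 1
        return CountTable2x2(*arr.ravel().tolist())
    arr = np.asarray(table)
    if (arr == 0).any():
        arr = arr + 1
    return arr


def _augment_pairs(alt: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pseudo-count rule for batched 2x1 tables."""
    zero = (alt == 0) | (ref == 0)
    return alt + zero, ref + zero


def _augment_tables(cells: list[np.ndarray]) -> list[np.ndarray]:
    """Row-wise pseudo-count rule for batched 2x2 tables (4 parallel arrays)."""
    zero = np.zeros(cells[0].shape, dtype=bool)
    for c in cells:
        zero |= c == 0
    return [c + zero for c in cells]


def _wilson_logodds_se(alt: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Standard error of the log-odds from the 95% Wilson score interval.

    Both interval endpoints are strictly inside (0, 1), so the log-odds
    transform is finite even for monoallelic counts.
    """
    n = alt + ref
    phat = alt / n
    z2 = _Z95**2
    denom = 1.0 + z2 / n
    center = (phat + z2 / (2 * n)) / denom
    half = _Z95 * np.sqrt(phat * (1 - phat) / n + z2 / (4 * n**2)) / denom
    lo = center - half
    hi = center + half
    return (np.log(hi / (1 - hi)) - np.log(lo / (1 - lo))) / (2 * _Z95)


def _static_statistic(
    alt: np.ndarray, ref: np.ndarray, se_method: str = "wilson"
) -> tuple[np.ndarray, np.ndarray]:
    """(effect, se) for pseudo-count-augmented 2x1 tables; natural log scale."""
    alt = np.asarray(alt, dtype=float)
    ref = np.asarray(ref, dtype=float)
    effect = np.log(alt / ref)
    if se_method == "wilson":
        se = _wilson_logodds_se(alt, ref)
    elif se_method == "delta":
        se = np.sqrt(1.0 / alt + 1.0 / ref)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return effect, se


def _icd_statistic(
    alt_t: np.ndarray, ref_t: np.ndarray, alt_u: np.ndarray, ref_u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(effect, se) for pseudo-count-augmented 2x2 tables; natural log scale."""
    cells = [np.asarray(c, dtype=float) for c in (alt_t, ref_t, alt_u, ref_u)]
    alt_t, ref_t, alt_u, ref_u = cells
    effect = np.log((alt_t / ref_t) / (alt_u / ref_u))
    se = np.sqrt(1 / alt_t + 1 / ref_t + 1 / alt_u + 1 / ref_u)
    return effect, se


def snv_statistic_static(
    ref_count: int, alt_count: int, variant_id: str = "", se_method: str = "wilson"
) -> SnvStatistic:
    """Normalized static statistic for one variant (pseudo-counts applied)."""
    alt, ref = _augment_pairs(np.asarray([alt_count]), np.asarray([ref_count]))
    effect, se = _static_statistic(alt, ref, se_method)
    return SnvStatistic(variant_id=variant_id, effect=float(effect[0]), se=float(se[0]))


def snv_statistic_icd(table: CountTable2x2, variant_id: str = "") -> SnvStatistic:
    """Normalized condition-dependent statistic for one variant."""
    table = augment_pseudocounts(table)
    effect, se = _icd_statistic(
        np.asarray([table.alt_T]),
        np.asarray([table.ref_T]),
        np.asarray([table.alt_U]),
        np.asarray([table.ref_U]),
    )
    return SnvStatistic(variant_id=variant_id, effect=float(effect[0]), se=float(se[0]))


def stouffer_combine(statistics: Sequence[float]) -> float:
    """Combine k variant statistics into a gene statistic: sum / sqrt(k)."""
    s = np.asarray(statistics, dtype=float)
    if s.size == 0:
        raise ValueError("cannot combine an empty list of statistics")
    if not np.all(np.isfinite(s)):
        raise ValueError("statistics must be finite")
    return float(s.sum() / math.sqrt(s.size))


def _sample_alt(
    depths: np.ndarray, p0: float, rho0: float, rng: np.random.Generator
) -> np.ndarray:
    if rho0 < _RHO_BINOMIAL_LIMIT:
        return rng.binomial(depths, p0)
    a, b = betabinom_alpha_beta(p0, rho0)
    theta = rng.beta(a, b, size=depths.shape)
    return rng.binomial(depths, theta)


def build_null_distribution(
    k: int,
    depth_pool,
    null: BetaBinomNull,
    N: int = 10_000,
    mode: Literal["static", "icd"] = "static",
    rng: np.random.Generator | int | None = 0,
    se_method: str = "wilson",
) -> NullDistribution:
    """Resample the combined-statistic null for genes with k variants.

    For each of N replicates and each of k pseudo-variants, a depth is drawn
    with replacement from ``depth_pool`` (for icd a (pool_U, pool_T) pair,
    or one pool used for both conditions), an alt count is drawn from the
    fitted null BB(p0, rho0), the count table is formed and pushed through
    the same pseudo-count, statistic and Stouffer steps as observed data.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if k < 1 or N < 1:
        raise ValueError("k and N must be >= 1")
    if mode == "static":
        pool = np.asarray(depth_pool, dtype=int)
        if pool.size == 0:
            raise ValueError("empty depth pool")
        depths = rng.choice(pool, size=(N, k), replace=True)
        alt = _sample_alt(depths, null.p0, null.rho0, rng)
        ref = depths - alt
        alt, ref = _augment_pairs(alt, ref)
        effect, se = _static_statistic(alt, ref, se_method)
    elif mode == "icd":
        if isinstance(depth_pool, tuple):
            pool_u, pool_t = (np.asarray(p, dtype=int) for p in depth_pool)
        else:
            pool_u = pool_t = np.asarray(depth_pool, dtype=int)
        if pool_u.size == 0 or pool_t.size == 0:
            raise ValueError("empty depth pool")
        d_u = rng.choice(pool_u, size=(N, k), replace=True)
        d_t = rng.choice(pool_t, size=(N, k), replace=True)
        # paired null: the no-change hypothesis shares one latent allele
        # fraction theta per pseudo-variant across both conditions (static
        # imbalance and variant-level noise are allowed under the icd null;
        # only a condition-dependent shift is not)
        if null.rho0 < _RHO_BINOMIAL_LIMIT:
            theta = np.full((N, k), null.p0)
        else:
            a, b = betabinom_alpha_beta(null.p0, null.rho0)
            theta = rng.beta(a, b, size=(N, k))
        alt_u = rng.binomial(d_u, theta)
        alt_t = rng.binomial(d_t, theta)
        alt_t, ref_t, alt_u, ref_u = _augment_tables(
            [alt_t, d_t - alt_t, alt_u, d_u - alt_u]
        )
        effect, se = _icd_statistic(alt_t, ref_t, alt_u, ref_u)
    else:
        raise ValueError(f"mode must be 'static' or 'icd', got {mode!r}")
    combined = np.abs(effect / se).sum(axis=1) / math.sqrt(k)
    return NullDistribution(k=k, values=combined, N=N, mode=mode)


def empirical_pvalue(observed: float, null_values: np.ndarray) -> float:
    """Upper-tail empirical p-value, (1 + #{null >= observed}) / (N + 1).

    The add-one convention keeps p strictly positive; ties count toward the
    numerator (conservative).
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("null_values must be non-empty")
    return float((1.0 + np.sum(null_values >= observed)) / (null_values.size + 1.0))


def _observed_gene_stats(
    df: pd.DataFrame, mode: str, se_method: str
) -> pd.DataFrame:
    """Per-(sample, gene) combined statistic and k, vectorized over rows."""
    if mode == "static":
        alt, ref = _augment_pairs(
            df["alt_count"].to_numpy(), df["ref_count"].to_numpy()
        )
        effect, se = _static_statistic(alt, ref, se_method)
    else:
        alt_t, ref_t, alt_u, ref_u = _augment_tables(
            [
                df["alt_count_T"].to_numpy(),
                df["ref_count_T"].to_numpy(),
                df["alt_count_U"].to_numpy(),
                df["ref_count_U"].to_numpy(),
            ]
        )
        effect, se = _icd_statistic(alt_t, ref_t, alt_u, ref_u)
    work = pd.DataFrame(
        {
            "sample_id": df["sample_id"].to_numpy(),
            "gene_id": df["gene_id"].to_numpy(),
            "stat": np.abs(effect / se),
        }
    )
    g = work.groupby(["sample_id", "gene_id"], sort=True)["stat"].agg(["sum", "size"])
    g["statistic"] = g["sum"] / np.sqrt(g["size"])
    g = g.rename(columns={"size": "k"}).reset_index()
    return g[["sample_id", "gene_id", "k", "statistic"]]


def run_gene_ase(
    counts: pd.DataFrame,
    null: BetaBinomNull,
    mode: Literal["static", "icd"] = "static",
    n_resamples: int = 100_000,
    min_variants: int = 2,
    k_cap: int = K_CAP,
    se_method: str = "wilson",
    require_dbsnp: bool = True,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Run the gene-level ASE test on a validated, depth-filtered count table.

    Genes with fewer than ``min_variants`` (default 2) known-SNP variants
    are not tested; set ``min_variants=1`` to test single-variant genes.
    Null distributions are built once per observed k (genes beyond
    ``k_cap`` variants share one aggregated null built by resampling k from
    the observed over-cap values) and shared by all genes with that k; the
    depth pool is the empirical depth distribution of all analyzed variants
    in the dataset, per condition for icd. Benjamini-Hochberg adjustment is
    applied within each sample. Returns a frame with columns sample_id,
    gene_id, k, statistic, p_value, p_adjusted, mode, sorted by adjusted p
    then gene id.
    """
    if null is None:
        raise ValueError("a fitted null model is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = counts
    if require_dbsnp and "in_dbsnp" in df.columns:
        df = df.loc[df["in_dbsnp"]]
    if len(df) == 0:
        return pd.DataFrame(
            columns=["sample_id", "gene_id", "k", "statistic", "p_value", "p_adjusted", "mode"]
        )
    if mode == "static":
        depth_pool = (df["ref_count"] + df["alt_count"]).to_numpy()
    else:
        depth_pool = (
            (df["ref_count_U"] + df["alt_count_U"]).to_numpy(),
            (df["ref_count_T"] + df["alt_count_T"]).to_numpy(),
        )

    obs = _observed_gene_stats(df, mode, se_method)
    obs = obs.loc[obs["k"] >= min_variants].reset_index(drop=True)
    if len(obs) == 0:
        return pd.DataFrame(
            columns=["sample_id", "gene_id", "k", "statistic", "p_value", "p_adjusted", "mode"]
        )

    k_values = sorted(obs["k"].unique())
    small_k = [k for k in k_values if k <= k_cap]
    over_cap = [k for k in k_values if k > k_cap]
    nulls: dict[int, NullDistribution] = {}
    for k in small_k:
        nulls[k] = build_null_distribution(
            k, depth_pool, null, N=n_resamples, mode=mode, rng=rng, se_method=se_method
        )
    agg_null: NullDistribution | None = None
    if over_cap:
        agg_null = _aggregate_null(
            obs.loc[obs["k"] > k_cap, "k"].to_numpy(),
            depth_pool,
            null,
            n_resamples,
            mode,
            rng,
            se_method,
        )

    pvals = np.empty(len(obs))
    for k in small_k:
        mask = (obs["k"] == k).to_numpy()
        pvals[mask] = nulls[k].pvalue(obs.loc[mask, "statistic"].to_numpy())
    if agg_null is not None:
        mask = (obs["k"] > k_cap).to_numpy()
        pvals[mask] = agg_null.pvalue(obs.loc[mask, "statistic"].to_numpy())
    obs["p_value"] = pvals
    obs["p_adjusted"] = np.nan
    for sample, idx in obs.groupby("sample_id").groups.items():
        obs.loc[idx, "p_adjusted"] = bh_adjust(obs.loc[idx, "p_value"].to_numpy())
    obs["mode"] = mode
    obs = obs.sort_values(["p_adjusted", "gene_id"], kind="mergesort").reset_index(drop=True)
    return obs


def _aggregate_null(
    observed_over_cap_ks: np.ndarray,
    depth_pool,
    null: BetaBinomNull,
    N: int,
    mode: str,
    rng: np.random.Generator,
    se_method: str,
) -> NullDistribution:
    """One shared null for all genes beyond the k cap: each replicate uses a
    k resampled uniformly from the observed over-cap variant counts."""
    ks = rng.choice(np.unique(observed_over_cap_ks), size=N, replace=True)
    values = np.empty(N)
    pos = 0
    for k in np.unique(ks):
        n_k = int(np.sum(ks == k))
        nd = build_null_distribution(
            int(k), depth_pool, null, N=n_k, mode=mode, rng=rng, se_method=se_method
        )
        values[pos : pos + n_k] = nd.values
        pos += n_k
    return NullDistribution(k=-1, values=values, N=N, mode=mode, depth_pool_id="aggregate")


def cd_gate_from_static(
    static_results_u: pd.DataFrame,
    static_results_t: pd.DataFrame,
    threshold: float = 0.2,
) -> set[str]:
    """Genes eligible for condition-dependent testing: nominal static
    p-value <= threshold (inclusive) in at least one condition.

    Weak static imbalance in either condition is taken as a hint that the
    gene's alleles are distinguishable enough for the paired comparison,
    without demanding significant static ASE.
    """
    eligible_u = set(
        static_results_u.loc[static_results_u["p_value"] <= threshold, "gene_id"]
    )
    eligible_t = set(
        static_results_t.loc[static_results_t["p_value"] <= threshold, "gene_id"]
    )
    return eligible_u | eligible_t
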