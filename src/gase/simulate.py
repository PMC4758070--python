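"""Count-level synthetic allele data and evaluation experiments.

Synthetic data are generated at the allele-count level: per variant a read
depth is drawn (fixed, from a pool, or from a callable), and the alt count
follows a beta-binomial with overdispersion rho. Static imbalance shifts
the mean alt fraction to 0.5 + s*e with a gene-level random sign s and
amplitude e in [0, 0.5); condition-dependent imbalance keeps the untreated
condition balanced (p_U = 0.5) and multiplies the treated odds by OR^s.
Zero effect (e = 0 or OR = 1) reduces every generator to the null.

The experiment drivers reproduce the method's evaluation protocol on such
data: calibration (uniform p-values under the null), statistical power at
a Benjamini-Hochberg FDR level, ROC/AUC against a naive per-variant
comparator, count-level SNV FDR, and robustness to a uniform reference-
mapping-bias perturbation of the counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene import run_gene_ase
from .io import BetaBinomNull, CountTable2x2
from .null_model import _RHO_BINOMIAL_LIMIT, betabinom_alpha_beta, fit_betabinomial
from .snv import bh_adjust, fisher_exact_icd, modified_binomial_test

__all__ = [
    "SimScenario",
    "ExperimentReport",
    "simulate_dna_counts",
    "simulate_static_gene",
    "simulate_icd_gene",
    "simulate_dataset",
    "perturb_mapping_bias",
    "run_calibration",
    "run_power",
    "run_roc",
    "run_snv_fdr",
]

#: overdispersion estimated from genomic DNA data in the source study;
#: default technical-noise level for the simulators
DNA_RHO = 0.22

DepthSpec = int | Sequence[int] | np.ndarray | Callable


@dataclass
class SimScenario:
    """Generative settings for one synthetic-count experiment."""

    mode: Literal["static", "icd"] = "static"
    n_genes: int = 2000
    k: int = 2
    depth: DepthSpec = 50
    effect: float = 0.0
    rho: float = DNA_RHO
    null_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode == "static" and not 0.0 <= self.effect < 0.5:
            raise ValueError("static effect must lie in [0, 0.5)")
        if self.mode == "icd" and self.effect != 0.0 and self.effect < 1.0:
            raise ValueError("icd effect is an odds ratio >= 1 (sign gives direction)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


@dataclass
class ExperimentReport:
    """Outcome of one simulation experiment, reproducible from (scenario, seed)."""

    scenario: SimScenario
    metric: str
    value: float
    n_replicates: int
    seed: int
    details: dict = field(default_factory=dict)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_depths(depth: DepthSpec, size, rng: np.random.Generator) -> np.ndarray:
    if callable(depth):
        return np.asarray(depth(rng, size), dtype=int)
    arr = np.asarray(depth)
    if arr.ndim == 0:
        return np.full(size, int(arr))
    return rng.choice(arr.astype(int), size=size, replace=True)


def _bb_alt(depths: np.ndarray, p: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    if rho < _RHO_BINOMIAL_LIMIT:
        return rng.binomial(depths, p)
    a, b = betabinom_alpha_beta(p, rho)
    theta = rng.beta(a, b, size=depths.shape)
    return rng.binomial(depths, theta)


def simulate_dna_counts(
    n_sites: int,
    depth: DepthSpec = 50,
    p0: float = 0.5,
    rho: float = DNA_RHO,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Beta-binomial DNA allele counts at no-ASE heterozygous sites.

    These emulate the genomic-sequencing counts from which the variant null
    model is fitted; at DNA level both alleles are present in one copy, so
    deviation from p0 = 0.5 beyond binomial sampling is technical noise.
    """
    rng = _as_rng(rng)
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    d = _draw_depths(depth, n_sites, rng)
    alt = _bb_alt(d, p0, rho, rng)
    return pd.DataFrame({"ref_count": d - alt, "alt_count": alt})


def simulate_static_gene(
    k: int,
    depth: DepthSpec,
    effect: float,
    rho: float,
    rng: np.random.Generator | int = 0,
    gene_id: str = "gene",
    sample_id: str = "sim",
) -> pd.DataFrame:
    """Counts for one gene with static imbalance of amplitude ``effect``.

    All k variants share a single gene-level random sign s, so the mean alt
    fraction is 0.5 + s*effect at every variant; effect = 0 is the null.
    """
    if not 0.0 <= effect < 0.5:
        raise ValueError("static effect must lie in [0, 0.5)")
    rng = _as_rng(rng)
    s = rng.choice([-1, 1])
    d = _draw_depths(depth, k, rng)
    alt = _bb_alt(d, 0.5 + s * effect, rho, rng)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "variant_id": [f"{gene_id}_v{j}" for j in range(k)],
            "gene_id": gene_id,
            "ref_count": d - alt,
            "alt_count": alt,
        }
    )


def simulate_icd_gene(
    k: int,
    depth: DepthSpec,
    odds_ratio: float,
    rho: float,
    rng: np.random.Generator | int = 0,
    gene_id: str = "gene",
    sample_id: str = "sim",
) -> pd.DataFrame:
    """Paired-condition counts for one gene with condition-dependent
    imbalance of the given odds ratio.

    The generative model is paired at the variant level: each variant's
    latent untreated allele fraction theta_U is Beta-distributed around
    p_U = 0.5 with overdispersion rho (capturing static imbalance and
    technical noise shared by both conditions), and treatment multiplies
    the odds, odds(theta_T) = OR^s * odds(theta_U), with a gene-level
    random sign s. Counts are binomial per condition given the thetas and
    independently drawn depths. OR = 1 makes theta_T = theta_U, the
    no-change null.
    """
    if odds_ratio < 1.0:
        raise ValueError("odds_ratio must be >= 1; direction comes from the random sign")
    rng = _as_rng(rng)
    s = rng.choice([-1, 1])
    d_u = _draw_depths(depth, k, rng)
    d_t = _draw_depths(depth, k, rng)
    if rho < _RHO_BINOMIAL_LIMIT:
        theta_u = np.full(k, 0.5)
    else:
        a, b = betabinom_alpha_beta(0.5, rho)
        theta_u = rng.beta(a, b, size=k)
    odds_t = odds_ratio**s * theta_u / (1.0 - theta_u)
    theta_t = odds_t / (1.0 + odds_t)
    alt_u = rng.binomial(d_u, theta_u)
    alt_t = rng.binomial(d_t, theta_t)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "variant_id": [f"{gene_id}_v{j}" for j in range(k)],
            "gene_id": gene_id,
            "ref_count_U": d_u - alt_u,
            "alt_count_U": alt_u,
            "ref_count_T": d_t - alt_t,
            "alt_count_T": alt_t,
        }
    )


def simulate_dataset(
    mode: Literal["static", "icd"],
    n_alt: int,
    n_null: int,
    k: int,
    depth: DepthSpec,
    effect: float,
    rho: float,
    rng: np.random.Generator | int = 0,
    sample_id: str = "sim",
) -> tuple[pd.DataFrame, set[str]]:
    """A labelled mixture of alternative and null genes.

    Returns (counts table, set of alternative gene ids). Null genes use
    effect 0 (static) or odds ratio 1 (icd).
    """
    rng = _as_rng(rng)
    sim_gene = simulate_static_gene if mode == "static" else simulate_icd_gene
    null_effect = 0.0 if mode == "static" else 1.0
    frames = []
    alt_genes: set[str] = set()
    for i in range(n_alt + n_null):
        gid = f"g{i:05d}"
        is_alt = i < n_alt
        if is_alt:
            alt_genes.add(gid)
        frames.append(
            sim_gene(
                k,
                depth,
                effect if is_alt else null_effect,
                rho,
                rng,
                gene_id=gid,
                sample_id=sample_id,
            )
        )
    return pd.concat(frames, ignore_index=True), alt_genes


def perturb_mapping_bias(counts: pd.DataFrame, bias_fraction: float) -> pd.DataFrame:
    """Uniformly inflate reference and deflate alternative read counts.

    Emulates reference-mapping bias: ref' = round(ref * (1 + b)),
    alt' = max(0, round(alt * (1 - b))), applied to every count column
    (both conditions for paired tables).
    """
    if not 0.0 <= bias_fraction < 1.0:
        raise ValueError("bias_fraction must lie in [0, 1)")
    out = counts.copy()
    for col in out.columns:
        if col.startswith("ref_count"):
            out[col] = np.rint(out[col] * (1.0 + bias_fraction)).astype(int)
        elif col.startswith("alt_count"):
            out[col] = np.maximum(0, np.rint(out[col] * (1.0 - bias_fraction))).astype(int)
    return out


def _fit_companion_null(
    rho: float,
    rng: np.random.Generator,
    n_sites: int = 5000,
    dna_depth: int = 50,
) -> BetaBinomNull:
    """Fit the variant null from companion simulated DNA counts, mirroring
    the method's step 1 (the experiments never use the true parameters)."""
    dna = simulate_dna_counts(n_sites, dna_depth, 0.5, rho, rng)
    return fit_betabinomial(dna, min_depth=10)


def run_calibration(
    mode: Literal["static", "icd"] = "static",
    depth: DepthSpec = 50,
    k: int = 2,
    rho: float = DNA_RHO,
    n_genes: int = 2000,
    n_resamples: int = 10_000,
    seed: int = 0,
    null: BetaBinomNull | None = None,
) -> ExperimentReport:
    """Null calibration: p-value uniformity and type-I error.

    Simulates ``n_genes`` genes under the fitted null (the null model is
    first fitted from companion simulated DNA counts, then genes are drawn
    from that fitted model so the test sees exactly its own null), runs the
    gene-level test, and reports the Kolmogorov-Smirnov uniformity p-value
    plus empirical type-I error at alpha 0.05 and 0.1.
    """
    rng = np.random.default_rng(seed)
    if null is None:
        null = _fit_companion_null(rho, rng)
    sim_gene = simulate_static_gene if mode == "static" else simulate_icd_gene
    null_effect = 0.0 if mode == "static" else 1.0
    frames = [
        sim_gene(k, depth, null_effect, null.rho0, rng, gene_id=f"g{i:05d}")
        for i in range(n_genes)
    ]
    counts = pd.concat(frames, ignore_index=True)
    res = run_gene_ase(
        counts, null, mode=mode, n_resamples=n_resamples, min_variants=1, seed=rng
    )
    p = res["p_value"].to_numpy()
    ks_stat, ks_p = stats.kstest(p, "uniform")
    scenario = SimScenario(
        mode=mode, n_genes=n_genes, k=k, depth=depth, effect=null_effect, rho=rho, seed=seed
    )
    return ExperimentReport(
        scenario=scenario,
        metric="ks_uniformity",
        value=float(ks_p),
        n_replicates=n_genes,
        seed=seed,
        details={
            "ks_stat": float(ks_stat),
            "type1_at_0.05": float(np.mean(p <= 0.05)),
            "type1_at_0.10": float(np.mean(p <= 0.10)),
            "p_values": p,
            "statistics": res["statistic"].to_numpy(),
            "null_model": null,
        },
    )


def run_power(
    mode: Literal["static", "icd"] = "icd",
    depth: DepthSpec = 50,
    effect: float = 10.0,
    rho: float = DNA_RHO,
    n_alt_genes: int = 500,
    n_null_genes: int = 500,
    k: int = 2,
    fdr_level: float = 0.05,
    n_resamples: int = 10_000,
    seed: int = 0,
    null: BetaBinomNull | None = None,
) -> ExperimentReport:
    """Statistical power at a Benjamini-Hochberg FDR level.

    Simulates a mixture of alternative and null genes at fixed per-variant
    (per-condition, for icd) depth, runs the gene-level test with the
    companion fitted null, BH-adjusts within the mixture, and reports the
    fraction of alternative genes declared significant at ``fdr_level``.
    """
    if not 0.0 < fdr_level < 1.0:
        raise ValueError("fdr_level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if null is None:
        null = _fit_companion_null(rho, rng)
    counts, alt_genes = simulate_dataset(
        mode, n_alt_genes, n_null_genes, k, depth, effect, rho, rng
    )
    res = run_gene_ase(
        counts, null, mode=mode, n_resamples=n_resamples, min_variants=min(2, k), seed=rng
    )
    sig = set(res.loc[res["p_adjusted"] <= fdr_level, "gene_id"])
    power = len(sig & alt_genes) / n_alt_genes
    n_false = len(sig - alt_genes)
    scenario = SimScenario(
        mode=mode, n_genes=n_alt_genes + n_null_genes, k=k, depth=depth,
        effect=effect, rho=rho, null_fraction=n_null_genes / (n_alt_genes + n_null_genes),
        seed=seed,
    )
    return ExperimentReport(
        scenario=scenario,
        metric="power",
        value=float(power),
        n_replicates=n_alt_genes + n_null_genes,
        seed=seed,
        details={
            "n_significant": len(sig),
            "n_false_positive": n_false,
            "realized_fdr": n_false / len(sig) if sig else float("nan"),
            "fdr_level": fdr_level,
        },
    )


def _naive_gene_pvalues(
    counts: pd.DataFrame, mode: str, null_ratio: float = 0.5
) -> pd.DataFrame:
    """Comparator: per-variant exact-test p-values converted to z-scores and
    Stouffer-combined per gene (no resampled null)."""
    if mode == "static":
        p_snv = np.array(
            [
                modified_binomial_test(r, a, null_ratio)
                for r, a in zip(counts["ref_count"], counts["alt_count"])
            ]
        )
    else:
        p_snv = np.array(
            [
                fisher_exact_icd(CountTable2x2(at, rt, au, ru))
                for au, ru, at, rt in zip(
                    counts["alt_count_U"],
                    counts["ref_count_U"],
                    counts["alt_count_T"],
                    counts["ref_count_T"],
                )
            ]
        )
    z = stats.norm.isf(np.clip(p_snv, 1e-300, 1.0 - 1e-16))
    work = pd.DataFrame({"gene_id": counts["gene_id"], "z": z})
    g = work.groupby("gene_id")["z"].agg(["sum", "size"])
    zg = g["sum"] / np.sqrt(g["size"])
    return pd.DataFrame({"gene_id": g.index, "p_value": stats.norm.sf(zg)}).reset_index(
        drop=True
    )


def _auc(scores_alt: np.ndarray, scores_null: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney U relation (ties at 1/2)."""
    u = stats.mannwhitneyu(scores_alt, scores_null, alternative="two-sided").statistic
    return float(u / (len(scores_alt) * len(scores_null)))


def _roc_points(scores_alt: np.ndarray, scores_null: np.ndarray):
    scores = np.concatenate([scores_alt, scores_null])
    labels = np.concatenate([np.ones(len(scores_alt)), np.zeros(len(scores_null))])
    order = np.argsort(-scores, kind="mergesort")
    tp = np.cumsum(labels[order])
    fp = np.cumsum(1 - labels[order])
    tpr = np.concatenate([[0.0], tp / len(scores_alt)])
    fpr = np.concatenate([[0.0], fp / len(scores_null)])
    return fpr, tpr


def run_roc(
    mode: Literal["static", "icd"] = "static",
    effect_grid: Sequence[float] = (0.05, 0.1, 0.2, 0.3),
    depth: DepthSpec = 50,
    rho: float = DNA_RHO,
    n_genes_per_effect: int = 2000,
    k: int = 2,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """ROC/AUC over an effect-size grid, with the naive comparator.

    For each effect, equal numbers of alternative and null genes are
    simulated and ranked by gene p-value; the table reports the trapezoidal
    AUC of the resampling test (``auc``) and of the naive Stouffer-combined
    per-variant exact tests (``auc_naive``). ROC points are in the
    ``fpr``/``tpr`` list columns.
    """
    rng = np.random.default_rng(seed)
    null = _fit_companion_null(rho, rng)
    rows = []
    for effect in effect_grid:
        half = n_genes_per_effect // 2
        counts, alt_genes = simulate_dataset(
            mode, half, n_genes_per_effect - half, k, depth, effect, rho, rng
        )
        res = run_gene_ase(
            counts, null, mode=mode, n_resamples=n_resamples, min_variants=min(2, k),
            seed=rng,
        )
        naive = _naive_gene_pvalues(counts, mode)
        row = {"effect": effect}
        for name, frame in (("", res), ("_naive", naive)):
            score = -np.log(frame["p_value"].to_numpy())
            is_alt = frame["gene_id"].isin(alt_genes).to_numpy()
            fpr, tpr = _roc_points(score[is_alt], score[~is_alt])
            row[f"auc{name}"] = _auc(score[is_alt], score[~is_alt])
            row[f"fpr{name}"] = fpr
            row[f"tpr{name}"] = tpr
        rows.append(row)
    return pd.DataFrame(rows)


def run_snv_fdr(
    mode: Literal["static", "icd"] = "icd",
    depth: DepthSpec = 100,
    effect: float = 4.0,
    rho: float = DNA_RHO,
    n_alt: int = 500,
    n_null: int = 500,
    fdr_level: float = 0.05,
    seed: int = 0,
) -> ExperimentReport:
    """Count-level false-discovery rate of the per-variant exact tests.

    Simulates labelled null and alternative variants, applies the modified
    binomial (static) or Fisher's exact (icd) test with BH correction at
    ``fdr_level``, and reports FP / positives (NaN when nothing is called).
    This is a count-level analogue only: read-level artefacts such as
    multiple variants per read are outside the generative model.
    """
    rng = np.random.default_rng(seed)
    counts, alt_genes = simulate_dataset(
        mode, n_alt, n_null, 1, depth, effect, rho, rng
    )
    naive = _naive_gene_pvalues(counts, mode)  # k=1: per-variant exact test
    padj = bh_adjust(naive["p_value"].to_numpy())
    sig = naive["gene_id"].to_numpy()[padj <= fdr_level]
    n_pos = len(sig)
    n_fp = len(set(sig) - alt_genes)
    value = n_fp / n_pos if n_pos else float("nan")
    scenario = SimScenario(
        mode=mode, n_genes=n_alt + n_null, k=1, depth=depth,
        effect=effect, rho=rho, null_fraction=n_null / (n_alt + n_null), seed=seed,
    )
    return ExperimentReport(
        scenario=scenario,
        metric="fdr",
        value=value,
        n_replicates=n_alt + n_null,
        seed=seed,
        details={"n_positive": n_pos, "n_false_positive": n_fp},
    )
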