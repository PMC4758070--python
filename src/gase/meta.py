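"""Cohort meta-analysis of per-individual gene ASE p-values.

Individuals are treated as biological replicates, but genotypes differ, so
a gene is testable only in the individuals where it carries usable
heterozygous variants. Per-gene evidence is combined across the m samples
where the gene was tested with Fisher's method: chi2 = -2 sum(ln p) is
chi-square with 2m degrees of freedom under the global null. A gene is
reported in the final union set if it is significant in the meta-analysis
or in at least one individual on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .snv import bh_adjust

__all__ = ["MetaResult", "fisher_method", "meta_across_samples", "significant_union"]


@dataclass
class MetaResult:
    gene_id: str
    m: int
    chi2: float
    p_meta: float
    p_meta_adjusted: float = float("nan")
    contributing_sample_ids: tuple[str, ...] = ()


def fisher_method(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's combination: returns (chi2, p_meta).

    chi2 = -2 sum(ln p) with survival probability from chi-square on 2m
    degrees of freedom, m the number of combined p-values. For m = 1 this
    is the identity p_meta = p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    return chi2, float(stats.chi2.sf(chi2, df=2 * p.size))


def meta_across_samples(
    per_sample_results: Mapping[str, pd.DataFrame] | Iterable[pd.DataFrame],
) -> pd.DataFrame:
    """Combine per-sample gene results across the cohort by Fisher's method.

    Input: per-sample gene result frames (columns ``gene_id``, ``p_value``,
    and ``sample_id`` unless given as a mapping sample_id -> frame). A gene
    absent from a sample (untestable genotype) simply contributes nothing
    there; genes testable in zero samples are omitted. Output columns:
    gene_id, m, chi2, p_meta, p_meta_adjusted (BH across genes),
    contributing_sample_ids.
    """
    if isinstance(per_sample_results, Mapping):
        frames = []
        for sid, frame in per_sample_results.items():
            f = frame.loc[:, ["gene_id", "p_value"]].copy()
            f["sample_id"] = sid
            frames.append(f)
    else:
        frames = [f.loc[:, ["gene_id", "p_value", "sample_id"]] for f in per_sample_results]
    if not frames:
        raise ValueError("no per-sample results supplied")
    stacked = pd.concat(frames, ignore_index=True)

    rows = []
    for gene, grp in stacked.groupby("gene_id", sort=True):
        chi2, p_meta = fisher_method(grp["p_value"].to_numpy())
        rows.append(
            {
                "gene_id": gene,
                "m": len(grp),
                "chi2": chi2,
                "p_meta": p_meta,
                "contributing_sample_ids": ",".join(sorted(grp["sample_id"].astype(str))),
            }
        )
    meta = pd.DataFrame(rows)
    meta["p_meta_adjusted"] = bh_adjust(meta["p_meta"].to_numpy())
    meta = meta.sort_values(["p_meta_adjusted", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )
    return meta[
        ["gene_id", "m", "chi2", "p_meta", "p_meta_adjusted", "contributing_sample_ids"]
    ]


def significant_union(
    meta_results: pd.DataFrame,
    per_sample_results: Mapping[str, pd.DataFrame] | Iterable[pd.DataFrame],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Union of meta-significant and per-sample-significant genes.

    Significance means BH-adjusted p <= ``fdr`` in the meta-analysis
    (``p_meta_adjusted``) or within any single sample (``p_adjusted``).
    Returns gene_id plus a provenance flag: "meta", "individual", or "both".
    """
    meta_sig = set(
        meta_results.loc[meta_results["p_meta_adjusted"] <= fdr, "gene_id"]
    )
    if isinstance(per_sample_results, Mapping):
        frames = list(per_sample_results.values())
    else:
        frames = list(per_sample_results)
    indiv_sig: set[str] = set()
    for f in frames:
        indiv_sig |= set(f.loc[f["p_adjusted"] <= fdr, "gene_id"])
    rows = []
    for gene in sorted(meta_sig | indiv_sig):
        src = "both" if gene in meta_sig and gene in indiv_sig else (
            "meta" if gene in meta_sig else "individual"
        )
        rows.append({"gene_id": gene, "source": src})
    return pd.DataFrame(rows, columns=["gene_id", "source"])
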