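"""Input/output and domain types for allele-count tables and test results.

Allele counts are exchanged as flat tab-separated tables with a header row.
Two schemas exist, one per analysis mode:

``static`` (one condition)
    sample_id, variant_id, gene_id, ref_count, alt_count
    [+ optional in_dbsnp, null_ratio]

``icd`` (two paired conditions, untreated U and treated T)
    sample_id, variant_id, gene_id, ref_count_U, alt_count_U,
    ref_count_T, alt_count_T  [+ optional in_dbsnp]

All statistics operate on counts keyed by ``variant_id``; genomic
coordinates, when present in ``variant_id`` (chrom:pos), are informational.
Missing ``in_dbsnp`` defaults to True and missing ``null_ratio`` (the
mapping-bias-adjusted binomial null for the variant) defaults to 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "SnvCounts",
    "CountTable2x2",
    "BetaBinomNull",
    "SnvStatistic",
    "GeneAseResult",
    "STATIC_COLUMNS",
    "ICD_COLUMNS",
    "read_snv_counts",
    "write_snv_counts",
    "read_dna_counts",
    "apply_depth_filter",
    "write_results",
    "vcf_to_counts",
]


class SchemaError(ValueError):
    """A required column is missing or the header does not match the mode."""


class ValidationError(ValueError):
    """A row violates a value constraint (negative count, duplicate key, ...)."""


STATIC_COLUMNS = ["sample_id", "variant_id", "gene_id", "ref_count", "alt_count"]
ICD_COLUMNS = [
    "sample_id",
    "variant_id",
    "gene_id",
    "ref_count_U",
    "alt_count_U",
    "ref_count_T",
    "alt_count_T",
]


@dataclass
class SnvCounts:
    """Ref/alt read counts for one heterozygous SNV in one sample.

    ``condition`` is "U"/"T" for two-condition data and "NA" for
    single-condition (static) data. ``null_ratio`` is the expected alt-allele
    fraction under the no-ASE null for this variant (0.5 unless a
    mapping-bias estimate is supplied).
    """

    variant_id: str
    gene_id: str
    ref_count: int
    alt_count: int
    sample_id: str = "sample"
    condition: str = "NA"
    in_dbsnp: bool = True
    null_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(
                f"negative count for variant {self.variant_id!r}"
            )
        if not 0.0 < self.null_ratio < 1.0:
            raise ValidationError(
                f"null_ratio must lie in (0, 1), got {self.null_ratio}"
            )


@dataclass
class CountTable2x2:
    """Allele counts for one variant in two conditions (alt/ref x T/U)."""

    alt_T: int
    ref_T: int
    alt_U: int
    ref_U: int

    def as_array(self) -> np.ndarray:
        return np.array([[self.alt_T, self.ref_T], [self.alt_U, self.ref_U]])


@dataclass
class BetaBinomNull:
    """Fitted variant-level beta-binomial null BB(p0, rho0).

    ``p0`` is the mean alt-allele fraction at a no-ASE site and ``rho0`` the
    intraclass-correlation overdispersion; ``rho0 = 0`` is an ordinary
    binomial.
    """

    p0: float
    rho0: float
    n_sites: int = 0
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")
        if not 0.0 <= self.rho0 < 1.0:
            raise ValueError(f"rho0 must lie in [0, 1), got {self.rho0}")

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(
            json.dumps(
                {
                    "p0": self.p0,
                    "rho0": self.rho0,
                    "n_sites": self.n_sites,
                    "loglik": self.loglik,
                },
                indent=1,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BetaBinomNull":
        import json

        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class SnvStatistic:
    """Per-variant normalized test statistic |effect| / se.

    ``effect`` is the natural-log odds (static) or natural-log odds ratio
    (icd); ``se`` its standard error on the same scale.
    """

    variant_id: str
    effect: float
    se: float
    statistic: float = field(init=False)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        self.statistic = abs(self.effect) / self.se


@dataclass
class GeneAseResult:
    """Gene-level test result: combined statistic and empirical p-value."""

    gene_id: str
    k: int
    statistic: float
    p_value: float
    p_adjusted: float = float("nan")
    mode: str = "static"
    sample_id: str = "sample"


def _required_columns(mode: str) -> list[str]:
    if mode == "static":
        return STATIC_COLUMNS
    if mode == "icd":
        return ICD_COLUMNS
    raise ValueError(f"mode must be 'static' or 'icd', got {mode!r}")


def _count_columns(mode: str) -> list[str]:
    return [c for c in _required_columns(mode) if "count" in c]


def read_snv_counts(path: str | Path, mode: Literal["static", "icd"]) -> pd.DataFrame:
    """Read and validate an allele-count table.

    Returns a DataFrame with the mode's schema; count columns are integer,
    ``in_dbsnp`` boolean, and (static mode) ``null_ratio`` float. Raises
    :class:`SchemaError` for missing columns and :class:`ValidationError`
    for negative counts (with the offending row number) or duplicate
    (sample, variant) keys.
    """
    required = _required_columns(mode)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "variant_id": str, "gene_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} for mode {mode!r}"
        )
    for col in _count_columns(mode):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValidationError(
                f"{path}: column {col!r} has a non-integer or negative value at line {row}"
            )
        df[col] = vals.astype(int)
    if "in_dbsnp" not in df.columns:
        df["in_dbsnp"] = True
    else:
        df["in_dbsnp"] = df["in_dbsnp"].astype(bool)
    if mode == "static":
        if "null_ratio" not in df.columns:
            df["null_ratio"] = 0.5
        else:
            df["null_ratio"] = df["null_ratio"].astype(float)
            if ((df["null_ratio"] <= 0) | (df["null_ratio"] >= 1)).any():
                raise ValidationError(f"{path}: null_ratio must lie in (0, 1)")
    dup = df.duplicated(subset=["sample_id", "variant_id"])
    if dup.any():
        dups = df.loc[dup, "variant_id"].unique()[:5].tolist()
        raise ValidationError(
            f"{path}: duplicate (sample, variant) rows, e.g. {dups}"
        )
    return df


def write_snv_counts(df: pd.DataFrame, path: str | Path, mode: Literal["static", "icd"]) -> None:
    """Write an allele-count table; inverse of :func:`read_snv_counts`."""
    cols = _required_columns(mode) + [
        c for c in ("in_dbsnp", "null_ratio") if c in df.columns
    ]
    df.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_dna_counts(path: str | Path, min_depth: int = 10) -> pd.DataFrame:
    """Read DNA (genomic) ref/alt allele counts used to fit the null model.

    The file needs two integer columns named ``ref_count`` and ``alt_count``
    (extra columns are ignored). Returns a frame with ``depth`` and a
    ``pass_depth`` flag marking sites with depth >= ``min_depth``; sites
    below the floor are kept but flagged for exclusion from the fit.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("ref_count", "alt_count"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
        df[col] = pd.to_numeric(df[col]).astype(int)
        if (df[col] < 0).any():
            raise ValidationError(f"{path}: negative value in column {col!r}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no DNA count rows; cannot fit a null model")
    df["depth"] = df["ref_count"] + df["alt_count"]
    df["pass_depth"] = df["depth"] >= min_depth
    return df


def apply_depth_filter(
    df: pd.DataFrame,
    min_depth: int,
    scope: Literal["per_sample", "summed_conditions"] = "per_sample",
) -> pd.DataFrame:
    """Filter variants by read depth.

    ``per_sample`` keeps rows whose depth within each measurement reaches
    ``min_depth`` (for two-condition tables, both conditions must reach it).
    ``summed_conditions`` keeps rows whose depth summed over both conditions
    and alleles reaches ``min_depth`` (two-condition tables only). Filters
    are idempotent and commute with each other.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be non-negative")
    icd = "ref_count_U" in df.columns
    if scope == "per_sample":
        if icd:
            keep = (df["ref_count_U"] + df["alt_count_U"] >= min_depth) & (
                df["ref_count_T"] + df["alt_count_T"] >= min_depth
            )
        else:
            keep = df["ref_count"] + df["alt_count"] >= min_depth
    elif scope == "summed_conditions":
        if not icd:
            raise ValueError("summed_conditions filter requires a two-condition table")
        keep = (
            df["ref_count_U"] + df["alt_count_U"] + df["ref_count_T"] + df["alt_count_T"]
            >= min_depth
        )
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return df.loc[keep].reset_index(drop=True)


_RESULT_COLUMNS = {
    "snv": ["sample_id", "variant_id", "effect_size", "p_value", "p_adjusted"],
    "gene": ["sample_id", "gene_id", "k", "statistic", "p_value", "p_adjusted", "mode"],
    "meta": ["gene_id", "m", "chi2", "p_meta", "p_meta_adjusted", "contributing_sample_ids"],
}


def write_results(
    results: pd.DataFrame | Sequence,
    path: str | Path,
    level: Literal["snv", "gene", "meta"] = "gene",
) -> None:
    """Write a result table as TSV with a deterministic column order.

    Rows are sorted by adjusted p-value, ties broken by gene (or variant)
    id; floats are written at six significant digits. An empty input
    produces a header-only file.
    """
    cols = _RESULT_COLUMNS[level]
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([vars(r).copy() for r in results])
    if len(results) == 0:
        pd.DataFrame(columns=cols).to_csv(path, sep="\t", index=False)
        return
    missing = [c for c in cols if c not in results.columns]
    if missing:
        raise SchemaError(f"result table lacks column(s) {missing} for level {level!r}")
    sort_keys = {
        "snv": ["p_adjusted", "variant_id"],
        "gene": ["p_adjusted", "gene_id"],
        "meta": ["p_meta_adjusted", "gene_id"],
    }[level]
    out = results.loc[:, cols].sort_values(sort_keys, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def vcf_to_counts(
    vcf_path: str | Path,
    sample: str | None = None,
    gene_field: str | None = None,
) -> pd.DataFrame:
    """Extract ref/alt allele depths (FORMAT/AD) from a VCF into a static
    count table.

    Heterozygous biallelic SNVs only. ``gene_field`` names an INFO field to
    use as gene id; otherwise gene_id is left empty for downstream
    annotation. Requires pysam (optional dependency).
    """
    import pysam  # deferred: optional dependency

    vf = pysam.VariantFile(str(vcf_path))
    if sample is None:
        sample = list(vf.header.samples)[0]
    rows = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        call = rec.samples[sample]
        gt = call.get("GT")
        if gt is None or set(gt) != {0, 1}:
            continue
        ad = call.get("AD")
        if ad is None or len(ad) < 2:
            continue
        gene = ""
        if gene_field is not None and gene_field in rec.info:
            val = rec.info[gene_field]
            gene = val[0] if isinstance(val, tuple) else str(val)
        rows.append(
            {
                "sample_id": sample,
                "variant_id": rec.id or f"{rec.chrom}:{rec.pos}",
                "gene_id": gene,
                "ref_count": int(ad[0]),
                "alt_count": int(ad[1]),
            }
        )
    return pd.DataFrame(rows, columns=STATIC_COLUMNS)
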