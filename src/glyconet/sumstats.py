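"""Reading, harmonization, genomic control and inverse-variance meta-analysis
of per-cohort GWAS summary statistics.

Summary statistics are carried as pandas DataFrames with one row per
SNP x trait x cohort association (the "sumstats schema"):

    snp, chr, pos, ea, oa, eaf, beta, se, p, n, info [, trait_id, cohort_id]

Traits are assumed rank-transformed to a standard normal, so effect sizes
are in standardized-trait units per effect allele.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: median of the chi-square distribution with 1 degree of freedom,
#: the null expectation used by the genomic-control inflation factor
CHI2_1_MEDIAN = 0.4549364231195724

SUMSTAT_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n", "info"]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumStatError(ValueError):
    """Raised for malformed or irreconcilable summary statistics."""


@dataclass(frozen=True)
class GCReport:
    """Genomic-control inflation factor and the number of SNPs it used."""

    lambda_gc: float
    n_snps_used: int

    def __post_init__(self) -> None:
        if self.lambda_gc <= 0:
            raise SumStatError("lambda_gc must be positive")


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw table into (valid, rejected-with-reason) per the schema
    invariants: se > 0, eaf in (0,1), p in (0,1], ea != oa, SNV alleles only."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & (reasons == "")
        reasons[new] = reason

    flag(~(df["se"] > 0), "nonpositive standard error")
    flag(~((df["eaf"] > 0) & (df["eaf"] < 1)), "allele frequency outside (0,1)")
    flag(~((df["p"] > 0) & (df["p"] <= 1)), "p-value outside (0,1]")
    ea = df["ea"].astype(str).str.upper()
    oa = df["oa"].astype(str).str.upper()
    flag(ea == oa, "identical alleles")
    flag(~(ea.isin(_VALID_ALLELES) & oa.isin(_VALID_ALLELES)), "non-SNV allele")
    flag(~(df["n"] > 0), "nonpositive sample size")
    for col in ("beta", "se", "eaf", "p"):
        flag(df[col].isna(), f"missing {col}")

    bad = reasons != ""
    rejected = df.loc[bad].copy()
    rejected["reject_reason"] = reasons[bad]
    valid = df.loc[~bad].copy()
    valid["ea"] = ea[~bad]
    valid["oa"] = oa[~bad]
    return valid, rejected


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    cohort_id: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a (possibly gzip-compressed) TSV of summary statistics.

    Parameters
    ----------
    column_map
        Maps file column names to schema names, e.g. ``{"SNP": "snp"}``.
        Identity for columns already in schema spelling.
    trait_id, cohort_id
        Optional labels attached to every record.

    Returns
    -------
    (records, rejected)
        ``records`` satisfies the schema invariants; ``rejected`` carries a
        ``reject_reason`` column so no row is dropped without account.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chr": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df[SUMSTAT_COLUMNS].copy()
    for col in ("eaf", "beta", "se", "p", "info"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    valid, rejected = _validate_rows(df)
    if trait_id is not None:
        valid["trait_id"] = trait_id
    if cohort_id is not None:
        valid["cohort_id"] = cohort_id
    return valid.reset_index(drop=True), rejected.reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write records as TSV (gzip if the path ends in .gz)."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            df.to_csv(fh, sep="\t", index=False)
    else:
        df.to_csv(path, sep="\t", index=False)


def harmonize_alleles(
    records: pd.DataFrame,
    reference: pd.DataFrame,
    drop_palindromic: bool = False,
) -> pd.DataFrame:
    """Orient records to a reference effect/other allele pair per SNP.

    ``reference`` has columns snp, ea, oa. A record whose alleles match the
    reference directly is kept as is; a swapped record gets beta -> -beta and
    eaf -> 1-eaf; strand flips are resolved by complementing both alleles and
    then applying the swap rule. Palindromic (A/T, C/G) SNPs are flagged in a
    ``palindromic`` column and retained unless ``drop_palindromic``.

    Raises
    ------
    SumStatError
        If any record's alleles cannot be reconciled with the reference
        ("allele mismatch").
    """
    ref = reference.set_index("snp")
    out = records.copy()
    out["palindromic"] = False
    ref_ea = ref["ea"].reindex(out["snp"]).to_numpy()
    ref_oa = ref["oa"].reindex(out["snp"]).to_numpy()
    if pd.isna(ref_ea).any():
        missing = out.loc[pd.isna(ref_ea), "snp"].iloc[0]
        raise SumStatError(f"allele mismatch: SNP {missing} absent from reference")

    ea = out["ea"].to_numpy(dtype=object)
    oa = out["oa"].to_numpy(dtype=object)
    comp_ea = np.array([_COMPLEMENT[a] for a in ea], dtype=object)
    comp_oa = np.array([_COMPLEMENT[a] for a in oa], dtype=object)

    palindromic = ea == comp_oa
    direct = (ea == ref_ea) & (oa == ref_oa)
    swapped = (ea == ref_oa) & (oa == ref_ea)
    # strand-flip cases; for palindromic SNPs these coincide with the above
    flip_direct = (comp_ea == ref_ea) & (comp_oa == ref_oa) & ~palindromic
    flip_swapped = (comp_ea == ref_oa) & (comp_oa == ref_ea) & ~palindromic

    unresolved = ~(direct | swapped | flip_direct | flip_swapped)
    if unresolved.any():
        snp = out.loc[unresolved, "snp"].iloc[0]
        raise SumStatError(f"allele mismatch: SNP {snp} irreconcilable with reference")

    need_swap = swapped | flip_swapped
    out.loc[need_swap, "beta"] = -out.loc[need_swap, "beta"]
    out.loc[need_swap, "eaf"] = 1.0 - out.loc[need_swap, "eaf"]
    flipped = flip_direct | flip_swapped
    out.loc[flipped, "ea"] = comp_ea[flipped]
    out.loc[flipped, "oa"] = comp_oa[flipped]
    out.loc[need_swap, ["ea", "oa"]] = out.loc[need_swap, ["oa", "ea"]].to_numpy()
    out["palindromic"] = palindromic
    if drop_palindromic:
        out = out.loc[~out["palindromic"]].reset_index(drop=True)
    return out


def gc_lambda(
    z: Sequence[float] | None = None,
    p: Sequence[float] | None = None,
    min_snps: int = 100,
) -> GCReport:
    """Genomic-control inflation factor lambda = median(z^2) / 0.4549.

    Accepts either z-scores or two-sided p-values (converted back to |z|).
    """
    if (z is None) == (p is None):
        raise SumStatError("provide exactly one of z or p")
    if z is not None:
        z2 = np.asarray(z, dtype=float) ** 2
    else:
        pv = np.asarray(p, dtype=float)
        z2 = stats.norm.isf(pv / 2.0) ** 2
    z2 = z2[np.isfinite(z2)]
    if z2.size < min_snps:
        raise SumStatError(
            f"insufficient SNPs for λ: {z2.size} < floor {min_snps}"
        )
    lam = float(np.median(z2) / CHI2_1_MEDIAN)
    return GCReport(lambda_gc=lam, n_snps_used=int(z2.size))


def gc_correct(records: pd.DataFrame, lambda_gc: float) -> pd.DataFrame:
    """Deflate test statistics by the genomic-control factor.

    When lambda > 1, standard errors are inflated by sqrt(lambda) and z/p
    recomputed (equivalent to dividing chi-square statistics by lambda);
    lambda <= 1 leaves records unchanged. The applied lambda is recorded in
    ``df.attrs["lambda_gc"]`` either way.
    """
    if lambda_gc <= 0:
        raise SumStatError("lambda_gc must be positive")
    out = records.copy()
    if lambda_gc > 1.0:
        out["se"] = out["se"] * np.sqrt(lambda_gc)
        z = out["beta"] / out["se"]
        out["p"] = 2.0 * stats.norm.sf(np.abs(z))
    out.attrs["lambda_gc"] = float(lambda_gc)
    return out


def ivw_meta(records: pd.DataFrame) -> pd.Series:
    """Fixed-effect inverse-variance meta-analysis of one SNP x trait.

    ``records`` holds one row per cohort, already harmonized to a common
    orientation. Weights are w_i = 1/se_i^2; the pooled effect is
    sum(w b)/sum(w) with se 1/sqrt(sum w). The p-value comes from the normal
    tail of z = beta_meta/se_meta, and ``direction`` concatenates per-cohort
    effect signs in cohort order.
    """
    if len(records) == 0:
        raise SumStatError("no records to meta-analyze")
    if records["snp"].nunique() > 1 or (
        "trait_id" in records and records["trait_id"].nunique() > 1
    ):
        raise SumStatError("records span multiple SNPs or traits")
    if records["ea"].nunique() > 1 or records["oa"].nunique() > 1:
        raise SumStatError("harmonize first: mixed allele orientation")
    w = 1.0 / records["se"].to_numpy() ** 2
    beta = records["beta"].to_numpy()
    beta_meta = float(np.sum(w * beta) / np.sum(w))
    se_meta = float(1.0 / np.sqrt(np.sum(w)))
    z = beta_meta / se_meta
    direction = "".join("+" if b > 0 else "-" if b < 0 else "0" for b in beta)
    return pd.Series(
        {
            "snp": records["snp"].iloc[0],
            "trait_id": records["trait_id"].iloc[0] if "trait_id" in records else None,
            "beta": beta_meta,
            "se": se_meta,
            "z": z,
            "p": float(2.0 * stats.norm.sf(abs(z))),
            "n": float(records["n"].sum()),
            "n_cohorts": int(len(records)),
            "direction": direction,
            "eaf": float(np.average(records["eaf"], weights=records["n"])),
            "ea": records["ea"].iloc[0],
            "oa": records["oa"].iloc[0],
        }
    )


def meta_analyze(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized fixed-effect IVW meta-analysis over all SNP x trait groups.

    Equivalent to applying :func:`ivw_meta` group-by-group but implemented
    with grouped sums so genome-scale tables pool in seconds.
    """
    df = records.copy()
    if "trait_id" not in df:
        df["trait_id"] = "trait"
    df = df.sort_values(["trait_id", "snp", "cohort_id"] if "cohort_id" in df else ["trait_id", "snp"], kind="mergesort")
    w = 1.0 / df["se"].to_numpy() ** 2
    df["_w"] = w
    df["_wb"] = w * df["beta"].to_numpy()
    df["_wn"] = df["n"].to_numpy()
    df["_weaf"] = df["n"].to_numpy() * df["eaf"].to_numpy()
    df["_sign"] = np.where(df["beta"] > 0, "+", np.where(df["beta"] < 0, "-", "0"))
    agg: dict[str, tuple[str, str]] = {
        "_w": ("_w", "sum"),
        "_wb": ("_wb", "sum"),
        "n": ("_wn", "sum"),
        "_weaf": ("_weaf", "sum"),
        "n_cohorts": ("snp", "size"),
        "direction": ("_sign", "sum"),
        "ea": ("ea", "first"),
        "oa": ("oa", "first"),
    }
    for col in ("chr", "pos"):
        if col in df:
            agg[col] = (col, "first")
    g = df.groupby(["snp", "trait_id"], sort=False)
    out = g.agg(**agg).reset_index()
    out["beta"] = out["_wb"] / out["_w"]
    out["se"] = 1.0 / np.sqrt(out["_w"])
    out["z"] = out["beta"] / out["se"]
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["z"]))
    out["eaf"] = out["_weaf"] / out["n"]
    return out.drop(columns=["_w", "_wb", "_weaf"])
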