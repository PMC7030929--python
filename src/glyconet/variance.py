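"""Phenotypic variance explained by associated variants.

For a standardized (rank-normal) trait, a SNP with minor-allele frequency p
(major q = 1-p) and per-allele effect beta explains sigma = 2*p*q*beta^2 of
the trait variance. The joint contribution of a SNP that survives
conditional analysis is 2*p*q*beta_u*beta_j, pairing the marginal
(univariate) and joint effect estimates; it can be negative when the two
disagree in sign, and is reported as such. Per-glycan totals sum over the
contributing SNP set.

Joint effect estimates come from an external conditional analysis (e.g.
GCTA-COJO output); this module consumes them, it does not re-estimate them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class VarianceError(ValueError):
    pass


def fold_to_minor(freq: float) -> float:
    """Fold an allele frequency to the minor allele (<= 0.5)."""
    if not (0.0 < freq < 1.0):
        raise VarianceError("allele frequency must be in (0,1)")
    return min(freq, 1.0 - freq)


def univariate_variance(p_freq: float, beta_u: float) -> float:
    """Explained-variance fraction 2*p*q*beta^2 of one SNP.

    The effect sign is irrelevant; frequencies are folded to the minor
    allele (the formula is symmetric in p and q so folding is a convention,
    not a correction).
    """
    p = fold_to_minor(p_freq)
    return 2.0 * p * (1.0 - p) * beta_u**2


def joint_variance(p_freq: float, beta_u: float, beta_j: float | None) -> float:
    """Joint contribution 2*p*q*beta_u*beta_j of one conditionally
    independent SNP. Negative when the marginal and joint estimates
    disagree in sign (reported, not clipped)."""
    if beta_j is None or (isinstance(beta_j, float) and np.isnan(beta_j)):
        raise VarianceError("joint effect estimate missing")
    p = fold_to_minor(p_freq)
    return 2.0 * p * (1.0 - p) * beta_u * beta_j


def per_glycan_totals(records: pd.DataFrame, mode: str = "univariate") -> pd.Series:
    """Total explained variance per glycan trait.

    ``records`` columns: snp, trait_id, maf, beta_u [, beta_j]. In
    univariate mode each SNP contributes 2*p*q*beta_u^2; in joint mode
    2*p*q*beta_u*beta_j over the independently contributing SNPs (rows with
    a joint estimate). Traits with an empty SNP set are absent from the
    output; totals do not depend on SNP order.
    """
    if mode not in {"univariate", "joint"}:
        raise VarianceError(f"unknown mode {mode!r}")
    df = records.copy()
    maf = df["maf"].to_numpy(dtype=float)
    if np.any((maf <= 0) | (maf >= 1)):
        raise VarianceError("allele frequency must be in (0,1)")
    maf = np.minimum(maf, 1.0 - maf)
    if mode == "univariate":
        df["sigma"] = 2.0 * maf * (1.0 - maf) * df["beta_u"].to_numpy() ** 2
    else:
        df = df.loc[df["beta_j"].notna()].copy()
        maf = np.minimum(
            df["maf"].to_numpy(dtype=float), 1.0 - df["maf"].to_numpy(dtype=float)
        )
        df["sigma"] = (
            2.0 * maf * (1.0 - maf) * df["beta_u"].to_numpy() * df["beta_j"].to_numpy()
        )
    totals = df.groupby("trait_id")["sigma"].sum()
    return totals.sort_index()


def read_variance_input(path: str | Path) -> pd.DataFrame:
    """Read a variance-input TSV: snp, trait_id, maf, beta_u [, beta_j]."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp", "trait_id", "maf", "beta_u"}
    missing = required - set(df.columns)
    if missing:
        raise VarianceError(f"missing column(s): {', '.join(sorted(missing))}")
    return df


def variance_report(records: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP sigma values (univariate and, where available, joint)."""
    out = records.copy()
    out["sigma_u"] = [
        univariate_variance(p, b) for p, b in zip(out["maf"], out["beta_u"])
    ]
    if "beta_j" in out:
        out["sigma_j"] = [
            joint_variance(p, bu, bj) if pd.notna(bj) else np.nan
            for p, bu, bj in zip(out["maf"], out["beta_u"], out["beta_j"])
        ]
    return out
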