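"""Summary-based Mendelian randomization (SMR) and heterogeneity testing.

SMR asks whether a variant's effect on an outcome (disease risk, gene
expression) is proportional to its effect on an exposure (here, a glycan
trait or vice versa), estimating b_xy = beta_outcome / beta_exposure at the
top associated SNP and testing it with

    T_SMR = z_x^2 * z_y^2 / (z_x^2 + z_y^2)  ~  chi2(1)  under the null.

A significant SMR signal is compatible with both a single shared causal
variant (pleiotropy) and distinct causal variants in LD. The HEIDI-style
heterogeneity test distinguishes them: under a shared causal variant, every
SNP in LD with it estimates the same b_xy, so the deviations
d_i = b_xy(i) - b_xy(top), standardized by a delta-method variance that
propagates both traits' sampling error and the LD-induced covariance with
the top SNP, behave like correlated standard normals; sum(z_d^2) is
referred to a chi-square with (number of eligible SNPs) degrees of freedom.
Heterogeneity (small HEIDI p) argues for linkage rather than pleiotropy.

The HLA region (chr6:29,570,005-33,377,657, GRCh37) is excluded by default:
its LD is too complex for this machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SMR_ALPHA = {"expression": 1.9e-5, "complex_trait": 9.1e-4}
HEIDI_ALPHA = 0.05
HLA_REGION = ("6", 29_570_005, 33_377_657)  # GRCh37

# HEIDI instrument-selection defaults
HEIDI_EXPOSURE_P_FLOOR = 1.6e-4
HEIDI_R2_RANGE = (0.05, 0.90)
HEIDI_MAX_SNPS = 20


class PleiotropyError(ValueError):
    pass


@dataclass
class SMRResult:
    locus: str
    exposure: str
    outcome: str
    b_xy: float
    t_smr: float
    p_smr: float
    p_heidi: float | None
    n_heidi_snps: int
    verdict: str  # pleiotropy | linkage | not_significant | not_testable
    direction: str  # "+" or "-"


def smr_test(
    beta_exp: float, se_exp: float, beta_out: float, se_out: float
) -> tuple[float, float, float]:
    """SMR ratio estimate and test at the top SNP.

    Returns (b_xy, t_smr, p_smr) with b_xy = beta_out/beta_exp and t_smr as
    in the module docstring, referred to chi-square(1).
    """
    if beta_exp == 0:
        raise PleiotropyError("undefined ratio: exposure beta is zero")
    if se_exp <= 0 or se_out <= 0:
        raise PleiotropyError("standard errors must be positive")
    z_x = beta_exp / se_exp
    z_y = beta_out / se_out
    b_xy = beta_out / beta_exp
    zx2, zy2 = z_x * z_x, z_y * z_y
    if zx2 + zy2 == 0:
        return b_xy, 0.0, 1.0
    t_smr = zx2 * zy2 / (zx2 + zy2)
    p_smr = float(stats.chi2.sf(t_smr, df=1))
    return float(b_xy), float(t_smr), p_smr


def heidi_test(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: np.ndarray,
    top_snp: str,
    exposure_p_floor: float = HEIDI_EXPOSURE_P_FLOOR,
    r2_range: tuple[float, float] = HEIDI_R2_RANGE,
    max_snps: int = HEIDI_MAX_SNPS,
) -> tuple[float | None, int]:
    """Heterogeneity-in-dependent-instruments test around the top SNP.

    ``exposure`` and ``outcome`` are regional summary tables (columns snp,
    beta, se) over the same SNPs, in the same order as the rows of the LD
    correlation matrix ``ld``. Eligible instruments are non-top SNPs with
    exposure p below the floor and LD r^2 with the top SNP inside
    ``r2_range``; the ``max_snps`` strongest exposure associations are kept.

    Returns (p_heidi, n_heidi_snps); p_heidi is None ("not testable") when
    fewer than 3 eligible instruments remain.
    """
    snps = list(exposure["snp"])
    if list(outcome["snp"]) != snps:
        raise PleiotropyError("exposure and outcome tables must align")
    if ld.shape != (len(snps), len(snps)):
        raise PleiotropyError("LD matrix does not cover the regional SNPs")
    try:
        t = snps.index(top_snp)
    except ValueError as exc:
        raise PleiotropyError(f"top SNP {top_snp} not in region") from exc

    bx = exposure["beta"].to_numpy(dtype=float)
    sx = exposure["se"].to_numpy(dtype=float)
    by = outcome["beta"].to_numpy(dtype=float)
    sy = outcome["se"].to_numpy(dtype=float)
    zx = bx / sx
    px = 2.0 * stats.norm.sf(np.abs(zx))
    r_top = ld[:, t]
    r2 = r_top**2

    eligible = (
        (np.arange(len(snps)) != t)
        & (px < exposure_p_floor)
        & (r2 >= r2_range[0])
        & (r2 <= r2_range[1])
        & (bx != 0)
    )
    idx = np.flatnonzero(eligible)
    if idx.size > max_snps:
        idx = idx[np.argsort(px[idx], kind="mergesort")[:max_snps]]
    if idx.size < 3:
        return None, int(idx.size)

    b_top = by[t] / bx[t]
    z_d2 = []
    for i in idx:
        b_i = by[i] / bx[i]
        d = b_i - b_top
        # delta-method variance of b_xy at each SNP
        var_i = sy[i] ** 2 / bx[i] ** 2 + (by[i] ** 2 / bx[i] ** 4) * sx[i] ** 2
        var_t = sy[t] ** 2 / bx[t] ** 2 + (by[t] ** 2 / bx[t] ** 4) * sx[t] ** 2
        r = r_top[i]
        cov = (
            r * sy[i] * sy[t] / (bx[i] * bx[t])
            + (by[i] * by[t] / (bx[i] ** 2 * bx[t] ** 2)) * r * sx[i] * sx[t]
        )
        var_d = var_i + var_t - 2.0 * cov
        if var_d <= 0:
            continue
        z_d2.append(d * d / var_d)
    if len(z_d2) < 3:
        return None, int(len(z_d2))
    statistic = float(np.sum(z_d2))
    p = float(stats.chi2.sf(statistic, df=len(z_d2)))
    return p, len(z_d2)


def classify_pleiotropy(
    p_smr: float,
    p_heidi: float | None,
    context: str = "complex_trait",
    heidi_alpha: float = HEIDI_ALPHA,
    smr_alpha: float | None = None,
) -> str:
    """Three-way verdict from the SMR and HEIDI p-values.

    pleiotropy: p_smr significant for the context (expression 1.9e-5,
    complex traits 9.1e-4) and p_heidi >= 0.05 (no heterogeneity — shared
    causal variant); linkage: significant SMR but heterogeneous ratios;
    not_significant otherwise. A significant SMR with no computable HEIDI is
    not_testable.
    """
    if smr_alpha is None:
        try:
            smr_alpha = SMR_ALPHA[context]
        except KeyError as exc:
            raise PleiotropyError(f"unknown context {context!r}") from exc
    if p_smr > smr_alpha:
        return "not_significant"
    if p_heidi is None:
        return "not_testable"
    return "pleiotropy" if p_heidi >= heidi_alpha else "linkage"


def in_hla_region(chrom: str, pos: int) -> bool:
    c, start, end = HLA_REGION
    return str(chrom) == c and start <= pos <= end


def smr_heidi(
    locus: str,
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: np.ndarray,
    context: str = "complex_trait",
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    top_snp: str | None = None,
) -> SMRResult:
    """Full SMR + HEIDI pass for one region.

    The top SNP defaults to the strongest exposure association (smallest p,
    ties on snp id), mirroring the instrument choice of using only the SNP
    with the lowest exposure p-value per region.
    """
    if top_snp is None:
        zx = (exposure["beta"] / exposure["se"]).abs()
        order = pd.DataFrame({"snp": exposure["snp"], "zx": zx}).sort_values(
            ["zx", "snp"], ascending=[False, True], kind="mergesort"
        )
        top_snp = str(order["snp"].iloc[0])
    e_top = exposure.loc[exposure["snp"] == top_snp].iloc[0]
    o_top = outcome.loc[outcome["snp"] == top_snp].iloc[0]
    b_xy, t_smr, p_smr = smr_test(
        float(e_top["beta"]), float(e_top["se"]), float(o_top["beta"]), float(o_top["se"])
    )
    p_heidi, n_heidi = heidi_test(exposure, outcome, ld, top_snp)
    verdict = classify_pleiotropy(p_smr, p_heidi, context=context)
    return SMRResult(
        locus=locus,
        exposure=exposure_name,
        outcome=outcome_name,
        b_xy=b_xy,
        t_smr=t_smr,
        p_smr=p_smr,
        p_heidi=p_heidi,
        n_heidi_snps=n_heidi,
        verdict=verdict,
        direction="+" if b_xy > 0 else "-",
    )


def direction_report(results: Sequence[SMRResult]) -> pd.DataFrame:
    """Sign table of b_xy per locus x outcome (Table-3-style layout)."""
    rows = [
        {
            "locus": r.locus,
            "exposure": r.exposure,
            "outcome": r.outcome,
            "direction": r.direction,
            "verdict": r.verdict,
            "p_smr": r.p_smr,
            "p_heidi": r.p_heidi,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
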