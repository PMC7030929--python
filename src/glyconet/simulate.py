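"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: multi-cohort
multi-trait GWAS summary statistics with a planted cluster structure over
associated loci, derived (re-normalized) traits, LD genotype panels, paired
exposure/outcome eQTL regions under shared-causal / linkage / null
scenarios, and motif-disruption datasets for the TFBS module.

The generative model for associated loci mirrors the assumption the
effect-correlation network method rests on: loci in the same latent
regulatory cluster share a trait-effect template, so their lead SNPs'
glycome-wide z-score vectors are monotone transforms of each other.
Lead-SNP effects are

    beta[l, t] = effect_scale * a_l * w[c(l), t] + eps,   eps ~ N(0, noise_sd^2)

with one template w_c ~ N(0, 1) per cluster over direct traits and a
positive locus loading a_l ~ |N(1, 0.2)|. Standard errors use the
standardized-trait approximation se = 1/sqrt(2 p q N), appropriate because
the traits are rank-transformed to a normal distribution before GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SUMSTAT_COLUMNS

#: discovery-cohort sample sizes (four cohorts totalling 8090)
DEFAULT_COHORT_SIZES = (849, 802, 1960, 4479)


class SimulationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class SimulationConfig:
    """Parameters of the multi-cohort GWAS generator.

    Defaults reproduce the study's dimensions: 62 directly measured glycan
    traits (15 more derived ones are added by :func:`derive_normalized_traits`
    for 77 in total), 27 associated loci in 3 latent clusters, four cohorts
    of 849/802/1960/4479 samples.
    """

    n_cohorts: int = 4
    n_traits_direct: int = 62
    n_derived: int = 15
    n_loci: int = 27
    n_clusters: int = 3
    snps_per_locus: int = 5
    background_pool_size: int = 2000
    cohort_sizes: Sequence[int] = DEFAULT_COHORT_SIZES
    effect_scale: float = 0.15
    noise_sd: float = 0.02
    eaf_range: tuple[float, float] = (0.05, 0.95)
    #: within-locus LD decay per 5 kb step; tight enough that every member
    #: pair stays above a 0.5 r^2 clumping floor (0.95^4 squared = 0.66), so
    #: a planted block is tagged as one locus whichever member leads it
    member_ld_r: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_cohorts": self.n_cohorts,
            "n_traits_direct": self.n_traits_direct,
            "n_loci": self.n_loci,
            "n_clusters": self.n_clusters,
            "snps_per_locus": self.snps_per_locus,
            "background_pool_size": self.background_pool_size,
        }
        for name, v in counts.items():
            if v < 1:
                raise SimulationError(f"{name} must be >= 1, got {v}")
        if self.n_clusters > self.n_loci:
            raise SimulationError("n_clusters must not exceed n_loci")
        if len(self.cohort_sizes) != self.n_cohorts:
            raise SimulationError("cohort_sizes length must equal n_cohorts")
        if any(n <= 0 for n in self.cohort_sizes):
            raise SimulationError("cohort sample sizes must be positive")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise SimulationError("eaf_range must be inside (0,1)")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be non-negative")
        if self.n_derived > self.n_traits_direct:
            raise SimulationError("cannot derive more traits than direct parents")


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated dataset."""

    locus_cluster: dict[str, int]
    cluster_templates: pd.DataFrame  # cluster x trait effect templates
    locus_loading: dict[str, float]
    lead_snps: dict[str, str]  # locus_id -> lead snp id
    snp_locus: dict[str, str | None]  # snp -> locus (None for background)
    true_beta: pd.DataFrame  # snp x trait true effects (locus SNPs only)
    ld_r2: pd.DataFrame  # snp_a, snp_b, r2 for within-locus pairs
    snp_meta: pd.DataFrame  # snp, chr, pos, eaf
    derived_parent: dict[str, str] = field(default_factory=dict)
    eqtl_scenarios: dict[str, str] = field(default_factory=dict)
    tfbs_flags: pd.DataFrame | None = None

    def cluster_labels(self) -> pd.Series:
        """Planted cluster label per locus, ordered by locus id."""
        return pd.Series(self.locus_cluster).sort_index()


def _pvalue(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def simulate_multicohort_gwas(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate per-cohort, per-trait GWAS summary statistics.

    Returns
    -------
    (sumstats, truth)
        ``sumstats`` is one long table in the sumstats schema plus
        ``trait_id``/``cohort_id`` columns: one row per SNP x trait x cohort.
        Background-pool SNPs have null effects (their p-values are uniform);
        locus SNPs carry the planted cluster structure, with non-lead members
        attenuated by their LD correlation with the lead.
    """
    rng = np.random.default_rng(config.seed)
    traits = [f"IGP{i + 1}" for i in range(config.n_traits_direct)]

    # --- planted architecture -------------------------------------------
    clusters = np.arange(config.n_loci) % config.n_clusters
    templates = rng.normal(size=(config.n_clusters, config.n_traits_direct))
    loadings = np.abs(rng.normal(1.0, 0.2, size=config.n_loci))

    locus_ids = [f"locus{l + 1:02d}" for l in range(config.n_loci)]
    spl = config.snps_per_locus
    lead_idx = spl // 2

    snp_rows = []
    ld_rows = []
    true_beta_rows: dict[str, np.ndarray] = {}
    lead_snps: dict[str, str] = {}
    snp_locus: dict[str, str | None] = {}

    for l, locus in enumerate(locus_ids):
        chrom = (l % 22) + 1
        base = 1_000_000 * (l // 22 + 1) + 10_000_000
        lead_beta = config.effect_scale * loadings[l] * templates[clusters[l]]
        lead_beta = lead_beta + rng.normal(0.0, config.noise_sd, size=lead_beta.shape)
        members = []
        for j in range(spl):
            snp = f"rs{l + 1:02d}{j:02d}"
            members.append(snp)
            pos = base + 5_000 * j
            snp_rows.append((snp, str(chrom), pos))
            snp_locus[snp] = locus
            r = config.member_ld_r ** abs(j - lead_idx)
            true_beta_rows[snp] = r * lead_beta
        lead_snps[locus] = members[lead_idx]
        for i in range(spl):
            for j in range(i + 1, spl):
                r = config.member_ld_r ** abs(i - j)
                ld_rows.append((members[i], members[j], r * r))

    for b in range(config.background_pool_size):
        snp = f"rsbg{b + 1:06d}"
        chrom = (b % 22) + 1
        pos = 200_000_000 + 1_000 * b
        snp_rows.append((snp, str(chrom), pos))
        snp_locus[snp] = None

    snp_meta = pd.DataFrame(snp_rows, columns=["snp", "chr", "pos"])
    lo, hi = config.eaf_range
    snp_meta["eaf"] = rng.uniform(lo, hi, size=len(snp_meta))

    n_snps = len(snp_meta)
    beta_true = np.zeros((n_snps, config.n_traits_direct))
    for i, snp in enumerate(snp_meta["snp"]):
        if snp in true_beta_rows:
            beta_true[i] = true_beta_rows[snp]

    # --- alleles: effect allele A, other allele G everywhere ------------
    eaf = snp_meta["eaf"].to_numpy()

    frames = []
    for c in range(config.n_cohorts):
        n = int(config.cohort_sizes[c])
        se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)  # per SNP
        # observed betas: truth + sampling noise, per trait
        noise = rng.normal(size=(n_snps, config.n_traits_direct)) * se[:, None]
        beta_hat = beta_true + noise
        z = beta_hat / se[:, None]
        p = _pvalue(z)
        info = rng.uniform(0.9, 1.0, size=n_snps)
        for t, trait in enumerate(traits):
            frames.append(
                pd.DataFrame(
                    {
                        "snp": snp_meta["snp"],
                        "chr": snp_meta["chr"],
                        "pos": snp_meta["pos"],
                        "ea": "A",
                        "oa": "G",
                        "eaf": eaf,
                        "beta": beta_hat[:, t],
                        "se": se,
                        "p": p[:, t],
                        "n": n,
                        "info": info,
                        "trait_id": trait,
                        "cohort_id": f"cohort{c + 1}",
                    }
                )
            )
    sumstats = pd.concat(frames, ignore_index=True)

    truth = TruthRecord(
        locus_cluster={locus_ids[l]: int(clusters[l]) for l in range(config.n_loci)},
        cluster_templates=pd.DataFrame(templates, columns=traits),
        locus_loading={locus_ids[l]: float(loadings[l]) for l in range(config.n_loci)},
        lead_snps=lead_snps,
        snp_locus=snp_locus,
        true_beta=pd.DataFrame(
            {s: true_beta_rows[s] for s in true_beta_rows}, index=traits
        ).T,
        ld_r2=pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"]),
        snp_meta=snp_meta,
    )
    return sumstats, truth


def resimulate_cohorts(
    truth: TruthRecord,
    cohort_sizes: Sequence[int],
    seed: int,
    cohort_prefix: str = "repl",
) -> pd.DataFrame:
    """Draw fresh cohorts around an existing truth (e.g. a replication panel).

    True effects and SNP frequencies are taken from ``truth``; only the
    sampling noise (and cohort sizes) differ, so discovery and replication
    share ground truth as independent studies of the same architecture.
    """
    if any(n <= 0 for n in cohort_sizes):
        raise SimulationError("cohort sample sizes must be positive")
    rng = np.random.default_rng(seed)
    traits = list(truth.cluster_templates.columns)
    snp_meta = truth.snp_meta
    eaf = snp_meta["eaf"].to_numpy()
    n_snps = len(snp_meta)
    beta_true = np.zeros((n_snps, len(traits)))
    for i, snp in enumerate(snp_meta["snp"]):
        if snp in truth.true_beta.index:
            beta_true[i] = truth.true_beta.loc[snp].to_numpy()
    frames = []
    for c, n in enumerate(cohort_sizes):
        n = int(n)
        se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)
        beta_hat = beta_true + rng.normal(size=beta_true.shape) * se[:, None]
        z = beta_hat / se[:, None]
        p = _pvalue(z)
        info = rng.uniform(0.9, 1.0, size=n_snps)
        for t, trait in enumerate(traits):
            frames.append(
                pd.DataFrame(
                    {
                        "snp": snp_meta["snp"],
                        "chr": snp_meta["chr"],
                        "pos": snp_meta["pos"],
                        "ea": "A",
                        "oa": "G",
                        "eaf": eaf,
                        "beta": beta_hat[:, t],
                        "se": se,
                        "p": p[:, t],
                        "n": n,
                        "info": info,
                        "trait_id": trait,
                        "cohort_id": f"{cohort_prefix}{c + 1}",
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def derive_normalized_traits(
    sumstats: pd.DataFrame,
    truth: TruthRecord,
    n_derived: int = 15,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Append derived traits that re-normalize directly measured parents.

    Each derived trait is a noisy positive affine re-scaling of one direct
    trait: its effect estimates are ``c * beta_parent`` (standard errors
    scaled by the same c, so z-scores are preserved at zero noise), plus
    optional Gaussian noise on beta. Derived trait ids continue the parent
    numbering, e.g. 62 direct traits gain IGP63..IGP77, making the
    downstream derived-trait exclusion step consequential and testable.
    """
    rng = np.random.default_rng(seed)
    traits = sorted(
        sumstats["trait_id"].unique(), key=lambda t: int(t.replace("IGP", ""))
    )
    if n_derived > len(traits):
        raise SimulationError("more derived traits requested than direct parents")
    n_direct = len(traits)
    frames = [sumstats]
    derived_parent: dict[str, str] = {}
    for k in range(n_derived):
        parent = traits[k]
        derived = f"IGP{n_direct + k + 1}"
        derived_parent[derived] = parent
        c = rng.uniform(0.5, 1.5)
        block = sumstats.loc[sumstats["trait_id"] == parent].copy()
        block["beta"] = c * block["beta"].to_numpy()
        block["se"] = c * block["se"].to_numpy()
        if noise_sd > 0:
            block["beta"] += rng.normal(0.0, noise_sd, size=len(block))
        z = block["beta"].to_numpy() / block["se"].to_numpy()
        block["p"] = _pvalue(z)
        block["trait_id"] = derived
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    truth.derived_parent = derived_parent
    return out, truth


def simulate_ld_panel(
    n_blocks: int,
    block_size: int,
    within_block_r: float,
    n_individuals: int,
    eaf_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a genotype reference panel with block LD structure.

    Within each block every SNP pair has expected genotype correlation
    ``within_block_r``; blocks are independent. Haplotype alleles copy a
    per-haplotype block template with probability sqrt(r) and are drawn
    fresh otherwise, which yields the target correlation exactly in
    expectation at any allele frequency (a Gaussian-copula construction
    would attenuate it). Only r in [0, 1) is representable by this shared
    -template mechanism; equicorrelated negative LD across a whole block is
    not realizable in general.

    Returns
    -------
    (genotypes, metadata)
        genotypes: (n_individuals, n_blocks*block_size) int array in {0,1,2};
        metadata: snp, block, pos, eaf.
    """
    if block_size < 1:
        raise SimulationError("block_size must be >= 1")
    if not (0.0 <= within_block_r < 1.0):
        raise SimulationError("within_block_r must be in [0, 1)")
    rng = np.random.default_rng(seed)
    m = n_blocks * block_size
    copy_p = np.sqrt(within_block_r)
    lo, hi = eaf_range
    freqs = np.repeat(rng.uniform(lo, hi, size=n_blocks), block_size)
    geno = np.zeros((n_individuals, m), dtype=np.int8)
    for _hap in range(2):
        template = rng.random((n_individuals, n_blocks)) < freqs[::block_size]
        template = np.repeat(template, block_size, axis=1)
        fresh = rng.random((n_individuals, m)) < freqs
        use_template = rng.random((n_individuals, m)) < copy_p
        geno += np.where(use_template, template, fresh).astype(np.int8)
    meta = pd.DataFrame(
        {
            "snp": [f"ld{j + 1:05d}" for j in range(m)],
            "block": np.repeat(np.arange(n_blocks), block_size),
            "pos": 1_000 * np.arange(m) + 1,
            "eaf": freqs,
        }
    )
    return geno, meta


def ar1_corr(m: int, rho: float) -> np.ndarray:
    """AR(1)-style LD correlation matrix r_ij = rho^|i-j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_eqtl_scenario(
    scenario: str,
    ld: np.ndarray | None = None,
    n_snps: int = 30,
    ld_rho: float = 0.9,
    b_exposure: float = 0.5,
    b_outcome: float = 0.1,
    n_exposure: int = 350,
    n_outcome: int = 8090,
    causal_gap: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, str]:
    """Simulate paired exposure/outcome regional summary statistics.

    Scenarios:

    - ``shared``: one causal SNP drives both the exposure (e.g. gene
      expression) and the outcome (glycan level) — a pleiotropy truth.
    - ``linkage``: two distinct causal SNPs ``causal_gap`` positions apart
      (LD r = ld_rho**causal_gap) drive one trait each.
    - ``null``: the outcome is unassociated.

    Marginal effect estimates are drawn from the standard summary-statistic
    model for standardized genotypes and traits: beta_hat ~ MVN(R @ gamma,
    R/n) with se = 1/sqrt(n), independently for the two traits (they come
    from non-overlapping samples).

    Returns (exposure_df, outcome_df, ld_matrix, scenario).
    """
    if scenario not in {"shared", "linkage", "null"}:
        raise SimulationError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    if ld is None:
        ld = ar1_corr(n_snps, ld_rho)
    m = ld.shape[0]
    if scenario == "linkage" and m < 2:
        raise SimulationError("linkage scenario requires at least two SNPs")
    chol = np.linalg.cholesky(ld + 1e-10 * np.eye(m))

    j1 = m // 2
    gamma_x = np.zeros(m)
    gamma_y = np.zeros(m)
    gamma_x[j1] = b_exposure
    if scenario == "shared":
        gamma_y[j1] = b_outcome
    elif scenario == "linkage":
        j2 = min(j1 + causal_gap, m - 1)
        if j2 == j1:
            raise SimulationError("linkage scenario needs room for a second causal SNP")
        gamma_y[j2] = b_outcome

    def draw(gamma: np.ndarray, n: int) -> pd.DataFrame:
        mean = ld @ gamma
        se = 1.0 / np.sqrt(n)
        beta = mean + se * (chol @ rng.normal(size=m))
        z = beta / se
        return pd.DataFrame(
            {
                "snp": [f"snp{j + 1:03d}" for j in range(m)],
                "beta": beta,
                "se": se,
                "z": z,
                "p": _pvalue(z),
                "n": n,
            }
        )

    exposure = draw(gamma_x, n_exposure)
    outcome = draw(gamma_y, n_outcome)
    return exposure, outcome, ld, scenario


# ---------------------------------------------------------------------------
# TFBS disruption dataset
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def sharp_pwm_counts(consensus: str, n_seqs: int = 100, off: int = 1) -> dict[str, list[int]]:
    """Count matrix concentrated on a consensus (off-consensus count ``off``)."""
    counts: dict[str, list[int]] = {b: [] for b in "ACGT"}
    for base in consensus:
        for b in "ACGT":
            counts[b].append(n_seqs - 3 * off if b == base else off)
    return counts


def simulate_tfbs_dataset(
    motif_consensus: str = "ACGTGCATTACGCA",
    n_assoc: int = 200,
    n_nonassoc: int = 200,
    planted_fold: float = 4.0,
    base_rate: float = 0.08,
    flank: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, list[int]]]:
    """Plant motif disruptions at associated SNPs at ``planted_fold`` times
    the non-associated rate.

    A disrupting SNP sits inside an embedded motif consensus: its reference
    allele is the consensus base at that motif position and the alternate
    allele breaks the match. Non-disrupting SNPs sit in random sequence.

    Returns
    -------
    (table, sequences, pwm_counts)
        table: snp_id, group (associated/nonassociated), ref, alt,
        snp_offset, planted (truth flag); sequences: snp_id -> flank with
        the reference allele at snp_offset; pwm_counts: the count matrix of
        the planted motif (JASPAR-style dict) for scoring.
    """
    if planted_fold < 1:
        raise SimulationError("planted_fold must be >= 1")
    L = len(motif_consensus)
    seq_len = 2 * flank + 1
    if L > seq_len:
        raise SimulationError("motif longer than flank sequence")
    assoc_rate = min(1.0, base_rate * planted_fold)
    rng = np.random.default_rng(seed)

    rows = []
    seqs: dict[str, str] = {}
    for group, n_group, rate in (
        ("associated", n_assoc, assoc_rate),
        ("nonassociated", n_nonassoc, base_rate),
    ):
        for i in range(n_group):
            snp_id = f"{group[:3]}{i + 1:05d}"
            seq = rng.choice(_BASES, size=seq_len)
            planted = bool(rng.random() < rate)
            if planted:
                # embed the consensus so a uniformly chosen motif position
                # lands on the SNP (the sequence centre)
                k = int(rng.integers(L))
                start = flank - k
                if start < 0 or start + L > seq_len:
                    k = L // 2
                    start = flank - k
                seq[start : start + L] = list(motif_consensus)
                ref = motif_consensus[k]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            else:
                ref = str(seq[flank])
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            seq[flank] = ref
            seqs[snp_id] = "".join(seq)
            rows.append((snp_id, group, ref, alt, flank, planted))
    table = pd.DataFrame(
        rows, columns=["snp_id", "group", "ref", "alt", "snp_offset", "planted"]
    )
    return table, seqs, sharp_pwm_counts(motif_consensus)


def write_cohort_tables(
    sumstats: pd.DataFrame, outdir, gzip_output: bool = False
) -> list[str]:
    """Write one TSV per cohort x trait (the pipeline's on-disk input form)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    suffix = ".tsv.gz" if gzip_output else ".tsv"
    for (cohort, trait), block in sumstats.groupby(["cohort_id", "trait_id"]):
        p = outdir / f"{cohort}_{trait}{suffix}"
        block[SUMSTAT_COLUMNS].to_csv(p, sep="\t", index=False)
        paths.append(str(p))
    return paths
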