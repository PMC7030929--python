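"""Significance classification, locus definition and replication.

Associations are called at a genome-wide threshold Bonferroni-corrected for
the number of independent traits (0.05/21 independent glycan traits on top
of the conventional 5e-8, i.e. ~2.4e-9), with a suggestive band one order
of magnitude above. Loci are greedy LD clumps around lead SNPs, merged when
their spans overlap; replication requires both a Bonferroni-adjusted
p-value (0.05 / number of discovered loci) and a concordant effect sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENOME_WIDE_ALPHA = 5e-8
N_INDEPENDENT_TRAITS = 21


class LocusError(ValueError):
    pass


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance threshold alpha/m."""
    if not (0.0 < alpha < 1.0):
        raise LocusError("alpha must be in (0,1)")
    if m < 1:
        raise LocusError("m must be >= 1")
    return alpha / m


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class AssociationCall:
    snp_id: str
    trait_id: str
    p: float
    tier: str  # significant | suggestive | none


def classify_association(
    p: float,
    significant: float | None = None,
    suggestive: float | None = None,
    snp_id: str = "",
    trait_id: str = "",
) -> AssociationCall:
    """Three-tier call; boundary p equal to a threshold falls in the
    stricter tier (<= semantics).

    Defaults: significant 2.4e-9 (5e-8 / 21 independent traits), suggestive
    band up to 2.4e-8.
    """
    if significant is None:
        significant = bonferroni_threshold(GENOME_WIDE_ALPHA, N_INDEPENDENT_TRAITS)
    if suggestive is None:
        suggestive = 10 * significant
    if not (0.0 < p <= 1.0):
        raise LocusError("p must be in (0,1]")
    if p <= significant:
        tier = "significant"
    elif p <= suggestive:
        tier = "suggestive"
    else:
        tier = "none"
    return AssociationCall(snp_id=snp_id, trait_id=trait_id, p=p, tier=tier)


def classify_associations(
    meta: pd.DataFrame,
    significant: float | None = None,
    suggestive: float | None = None,
) -> pd.DataFrame:
    """Vectorized tier classification of a meta-analysis table."""
    if significant is None:
        significant = bonferroni_threshold(GENOME_WIDE_ALPHA, N_INDEPENDENT_TRAITS)
    if suggestive is None:
        suggestive = 10 * significant
    out = meta.copy()
    out["tier"] = np.where(
        out["p"] <= significant,
        "significant",
        np.where(out["p"] <= suggestive, "suggestive", "none"),
    )
    return out


@dataclass
class Locus:
    """A genomic region spanned by SNPs in LD with its lead variant.

    Coordinates are 1-based inclusive; rendered "chr:start-end".
    """

    chr: str
    start: int
    end: int
    members: list[str]
    lead_snp: str
    lead_trait: str = ""
    lead_p: float = float("nan")
    n_associated_glycans: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise LocusError("locus start must not exceed end")
        if self.lead_snp not in self.members:
            raise LocusError("lead SNP must be a locus member")

    @property
    def label(self) -> str:
        return f"{self.chr}:{self.start}-{self.end}"


class LDSource:
    """Pairwise LD r-squared lookup built from a long (snp_a, snp_b, r2)
    table; symmetric, with r2(s, s) = 1."""

    def __init__(self, table: pd.DataFrame):
        self._r2: dict[tuple[str, str], float] = {}
        self._partners: dict[str, set[str]] = {}
        for a, b, r2 in table[["snp_a", "snp_b", "r2"]].itertuples(index=False):
            self._r2[(a, b)] = float(r2)
            self._r2[(b, a)] = float(r2)
            self._partners.setdefault(a, set()).add(b)
            self._partners.setdefault(b, set()).add(a)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get((a, b), 0.0)

    def partners(self, snp: str) -> set[str]:
        return self._partners.get(snp, set())

    def __contains__(self, snp: str) -> bool:
        return snp in self._partners


def define_loci(
    calls: pd.DataFrame,
    ld: LDSource,
    r2_min: float = 0.5,
    max_span: int = 1_000_000,
    warn: bool = True,
) -> list[Locus]:
    """Greedy LD clumping of called SNPs into loci.

    Called SNPs (tier != none) are visited in ascending p order; each unclaimed
    SNP seeds a locus and claims all unclaimed called SNPs with r2 >= r2_min
    within max_span of it. SNPs absent from the LD source become singleton
    loci (with a warning). Output is deterministic: ties in p break on snp id.
    """
    import warnings

    hits = calls.loc[calls["tier"] != "none"]
    # collapse to per-SNP minimum p (a SNP may be called for several traits)
    per_snp = (
        hits.sort_values(["p", "trait_id"], kind="mergesort")
        .groupby("snp", sort=False)
        .first()
        .reset_index()
    )
    per_snp = per_snp.sort_values(["p", "snp"], kind="mergesort")

    pos = per_snp.set_index("snp")["pos"].to_dict()
    chrom = per_snp.set_index("snp")["chr"].to_dict()
    claimed: set[str] = set()
    loci: list[Locus] = []
    for row in per_snp.itertuples(index=False):
        snp = row.snp
        if snp in claimed:
            continue
        if snp not in ld and warn:
            warnings.warn(f"SNP {snp} absent from LD source; singleton locus")
        members = [snp]
        claimed.add(snp)
        for other in sorted(ld.partners(snp)):
            if other in claimed or other not in pos:
                continue
            if chrom[other] != row.chr:
                continue
            if abs(pos[other] - row.pos) > max_span:
                continue
            if ld.r2(snp, other) >= r2_min:
                members.append(other)
                claimed.add(other)
        positions = [pos[m] for m in members]
        loci.append(
            Locus(
                chr=str(row.chr),
                start=min(positions),
                end=max(positions),
                members=sorted(members),
                lead_snp=snp,
                lead_trait=row.trait_id,
                lead_p=float(row.p),
            )
        )
    return merge_overlapping(sorted(loci, key=lambda l: (l.chr, l.start)))


def merge_overlapping(loci: list[Locus]) -> list[Locus]:
    """Transitively merge overlapping loci on the same chromosome.

    The lead of a merged locus is the member lead with the smallest p
    (ties break on snp id).
    """
    merged: list[Locus] = []
    for locus in sorted(loci, key=lambda l: (l.chr, l.start)):
        if merged and merged[-1].chr == locus.chr and locus.start <= merged[-1].end:
            prev = merged[-1]
            better = min(
                (prev, locus), key=lambda l: (l.lead_p, l.lead_snp)
            )
            merged[-1] = Locus(
                chr=prev.chr,
                start=min(prev.start, locus.start),
                end=max(prev.end, locus.end),
                members=sorted(set(prev.members) | set(locus.members)),
                lead_snp=better.lead_snp,
                lead_trait=better.lead_trait,
                lead_p=better.lead_p,
            )
        else:
            merged.append(locus)
    return merged


def select_lead_snp(locus: Locus, meta: pd.DataFrame) -> tuple[str, str]:
    """Lead SNP and its best trait: the global minimum p over member SNPs
    across all traits, ties broken by (p, snp, trait) lexicographically."""
    if not locus.members:
        raise LocusError("empty locus")
    rows = meta.loc[meta["snp"].isin(locus.members)]
    if rows.empty:
        raise LocusError("no meta results for locus members")
    rows = rows.sort_values(["p", "snp", "trait_id"], kind="mergesort")
    top = rows.iloc[0]
    return str(top["snp"]), str(top["trait_id"])


def count_locus_glycans(
    locus: Locus, calls: pd.DataFrame, include_lead_trait: bool = False
) -> int:
    """Number of distinct *other* glycan traits with at least one
    suggestive-or-better call among the locus members (the lead trait is
    excluded unless ``include_lead_trait``)."""
    hits = calls.loc[
        calls["snp"].isin(locus.members) & (calls["tier"] != "none"), "trait_id"
    ].unique()
    traits = set(hits)
    if not include_lead_trait:
        traits.discard(locus.lead_trait)
    return len(traits)


def evaluate_replication(
    beta_disc: float,
    beta_repl: float,
    p_repl: float,
    n_loci: int,
    alpha: float = 0.05,
) -> dict:
    """Replication verdict for one discovery lead SNP/trait pair.

    Replicated iff p_repl <= alpha/n_loci AND the effect sign agrees with
    discovery; the direction flag is reported separately so sign-discordant
    near-misses are visible.
    """
    threshold = bonferroni_threshold(alpha, n_loci)
    direction_consistent = bool(np.sign(beta_disc) == np.sign(beta_repl))
    replicated = bool(p_repl <= threshold and direction_consistent)
    return {
        "replicated": replicated,
        "direction_consistent": direction_consistent,
        "p_repl": p_repl,
        "threshold": threshold,
    }


def loci_to_bed(loci: Iterable[Locus], path: str | Path) -> None:
    """Export loci as BED (0-based half-open, converted from the internal
    1-based inclusive convention)."""
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(f"{locus.chr}\t{locus.start - 1}\t{locus.end}\t{locus.lead_snp}\n")


def loci_table(loci: Iterable[Locus]) -> pd.DataFrame:
    """Locus report with the "chr:start-end" rendering."""
    return pd.DataFrame(
        {
            "locus": [l.label for l in loci],
            "chr": [l.chr for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "lead_snp": [l.lead_snp for l in loci],
            "lead_trait": [l.lead_trait for l in loci],
            "lead_p": [l.lead_p for l in loci],
            "n_members": [len(l.members) for l in loci],
            "n_other_glycans": [l.n_associated_glycans for l in loci],
        }
    )
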