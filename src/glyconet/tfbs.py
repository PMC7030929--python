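"""Allele-level transcription-factor binding-site scoring.

Reference and alternate alleles of a SNP are substituted into its flanking
sequence and scanned against position weight matrices (PWMs, log-odds
against a background base distribution, both strands, every window covering
the SNP). A match is significant when the background probability of an
equal-or-better score (the score p-value) falls below a Bonferroni
threshold; an allele change that removes a significant match disrupts the
site, one that creates it introduces a site. Disruption frequencies are
then compared between trait-associated and non-associated SNPs: associated
SNPs being at least twice as likely to alter binding flags an enriched
locus/TF pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G

DEFAULT_BINDING_ALPHA = 1.8e-8  # 0.05 Bonferroni-corrected for ~2.76M tests


class PWMError(ValueError):
    pass


@dataclass
class PWM:
    """Position weight matrix in log2-odds form.

    ``weights`` has shape (length, 4) in A, C, G, T column order;
    ``background`` is the base distribution the odds are taken against.
    """

    name: str
    weights: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    _dist: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise PWMError("weight matrix must have 4 columns (A,C,G,T)")
        if not np.isclose(self.background.sum(), 1.0):
            raise PWMError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.weights, axis=1))

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())


def pwm_from_counts(
    name: str,
    counts: Mapping[str, Sequence[float]],
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
) -> PWM:
    """Convert a 4 x L count matrix to a log2-odds PWM.

    Pseudocounts are added per cell before normalization; a zero count with
    a zero pseudocount is rejected (log of zero).
    """
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    mat = np.array([counts[b] for b in "ACGT"], dtype=float).T  # L x 4
    if mat.size == 0:
        raise PWMError("empty count matrix")
    if np.any(mat < 0):
        pos = int(np.argwhere(mat < 0)[0][0])
        raise PWMError(f"negative count at position {pos + 1}")
    if pseudocount == 0 and np.any(mat == 0):
        pos = int(np.argwhere(mat == 0)[0][0])
        raise PWMError(f"zero cell requires pseudocount (position {pos + 1})")
    mat = mat + pseudocount
    probs = mat / mat.sum(axis=1, keepdims=True)
    return PWM(name=name, weights=np.log2(probs / bg), background=bg)


def read_pwm(
    path: str | Path,
    fmt: str = "jaspar",
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
) -> list[PWM]:
    """Read PWMs from a JASPAR (``fmt='jaspar'``) or MEME minimal motif
    (``fmt='meme'``) text file and convert to log2-odds.

    MEME letter-probability matrices are rescaled by their nsites to recover
    counts, so the same underlying counts give identical log-odds in either
    encoding.
    """
    fmt = fmt.lower()
    if fmt not in {"jaspar", "meme"}:
        raise PWMError(f"unsupported PWM format {fmt!r}")
    parser_fmt = "jaspar" if fmt == "jaspar" else "minimal"
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, parser_fmt)
    out = []
    for m in parsed:
        name = m.name or getattr(m, "matrix_id", None) or "motif"
        if fmt == "jaspar":
            counts = {b: list(m.counts[b]) for b in "ACGT"}
        else:
            nsites = getattr(m, "num_occurrences", 0) or 20
            counts = {
                b: [p * nsites for p in m.pwm[b]] for b in "ACGT"
            }
        out.append(
            pwm_from_counts(name, counts, pseudocount=pseudocount, background=background)
        )
    return out


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise PWMError(f"non-ACGT base in sequence: {exc}") from exc


def score_allele(
    pwm: PWM, flank: str, allele: str, snp_offset: int
) -> float:
    """Best log-odds score over all windows covering the SNP, both strands.

    The allele is substituted at ``snp_offset`` (0-based) before scanning.
    """
    if len(allele) != 1:
        raise PWMError("only single-base alleles supported")
    if not (0 <= snp_offset < len(flank)):
        raise PWMError("snp_offset outside flank")
    if len(flank) < pwm.length:
        raise PWMError("flank shorter than motif")
    enc = _encode(flank)
    enc[snp_offset] = _BASE_INDEX[allele.upper()]
    L = pwm.length
    lo = max(0, snp_offset - L + 1)
    hi = min(len(flank) - L, snp_offset)
    best = -np.inf
    rev_weights = pwm.weights[::-1][:, _COMPLEMENT_IDX]
    idx = np.arange(L)
    for s in range(lo, hi + 1):
        window = enc[s : s + L]
        fwd = pwm.weights[idx, window].sum()
        rev = rev_weights[idx, window].sum()
        best = max(best, fwd, rev)
    return float(best)


def _score_distribution(
    pwm: PWM, resolution: float = 1e-4, method: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the score of a random background sequence of motif
    length: (sorted unique scores, upper-tail probabilities P(S >= s)).

    Exact enumeration (outer-sum convolution over positions) for length
    <= 8; dynamic programming on a discretized score grid otherwise.
    ``method`` forces ``'enum'`` or ``'dp'``.
    """
    if method is None:
        method = "enum" if pwm.length <= 8 else "dp"
    if method in pwm._dist:
        return pwm._dist[method]
    bg = pwm.background
    if method == "enum":
        scores = np.zeros(1)
        probs = np.ones(1)
        for row in pwm.weights:
            scores = (scores[:, None] + row[None, :]).ravel()
            probs = (probs[:, None] * bg[None, :]).ravel()
        order = np.argsort(scores)
        scores, probs = scores[order], probs[order]
        # merge numerically identical scores
        uniq, inv = np.unique(np.round(scores, 12), return_inverse=True)
        mass = np.bincount(inv, weights=probs)
        tail = np.cumsum(mass[::-1])[::-1]
        dist = (uniq, tail)
    else:
        q = np.round(pwm.weights / resolution).astype(np.int64)
        row_mins = q.min(axis=1)
        cur = np.array([1.0])
        for row_q, row_min in zip(q, row_mins):
            nxt = np.zeros(cur.size + int(row_q.max() - row_min))
            for b in range(4):
                shift = int(row_q[b] - row_min)
                nxt[shift : shift + cur.size] += bg[b] * cur
            cur = nxt
        grid = (np.arange(cur.size) + int(row_mins.sum())) * resolution
        tail = np.cumsum(cur[::-1])[::-1]
        dist = (grid, tail)
    pwm._dist[method] = dist
    return dist


def score_pvalue(pwm: PWM, score: float, method: str | None = None) -> float:
    """Probability that a random background sequence of motif length scores
    at least ``score``. Monotone non-increasing in score; a score above the
    maximum attainable returns the consensus mass point; one below the
    minimum returns 1.
    """
    if not np.isfinite(score):
        raise PWMError("score must be finite")
    if method is None:
        method = "enum" if pwm.length <= 8 else "dp"
    grid, tail = _score_distribution(pwm, method=method)
    # tolerance covers per-position quantization drift of the DP grid
    tol = 1e-4 * (pwm.length + 1) if method == "dp" else 1e-9
    if score > grid[-1] + tol:
        return float(tail[-1])
    i = int(np.searchsorted(grid, score - tol, side="left"))
    return float(tail[min(i, len(tail) - 1)])


@dataclass(frozen=True)
class BindingCall:
    """Allele-level TF-binding impact of one SNP against one PWM."""

    snp_id: str
    tf: str
    ref_score: float
    ref_p: float
    alt_score: float
    alt_p: float
    call: str  # disrupts | introduces | no_effect | ambiguous


def classify_allele_effect(
    ref_score: float,
    ref_p: float,
    alt_score: float,
    alt_p: float,
    alpha: float = DEFAULT_BINDING_ALPHA,
    score_tolerance: float = 1.0,
    snp_id: str = "",
    tf: str = "",
) -> BindingCall:
    """Call the allele effect on TF binding.

    disrupts: reference allele has a significant match, alternate does not;
    introduces: the reverse; alleles whose best scores differ by less than
    ``score_tolerance`` bits are filtered to no_effect regardless of
    significance; both alleles significant with dissimilar scores is
    ambiguous. Swapping ref and alt swaps disrupts and introduces.
    """
    ref_sig = ref_p <= alpha
    alt_sig = alt_p <= alpha
    if abs(ref_score - alt_score) < score_tolerance:
        call = "no_effect"
    elif ref_sig and not alt_sig:
        call = "disrupts"
    elif alt_sig and not ref_sig:
        call = "introduces"
    elif ref_sig and alt_sig:
        call = "ambiguous"
    else:
        call = "no_effect"
    return BindingCall(
        snp_id=snp_id,
        tf=tf,
        ref_score=ref_score,
        ref_p=ref_p,
        alt_score=alt_score,
        alt_p=alt_p,
        call=call,
    )


def call_dataset(
    table: pd.DataFrame,
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    alpha: float = DEFAULT_BINDING_ALPHA,
    score_tolerance: float = 1.0,
) -> pd.DataFrame:
    """Score every SNP x PWM pair of a flanking-sequence dataset.

    ``table`` columns: snp_id, ref, alt, snp_offset (plus any annotation
    such as ``group``); ``sequences`` maps snp_id to its flank carrying the
    reference allele.
    """
    rows = []
    for rec in table.itertuples(index=False):
        seq = sequences[rec.snp_id]
        for pwm in pwms:
            ref_score = score_allele(pwm, seq, rec.ref, rec.snp_offset)
            alt_score = score_allele(pwm, seq, rec.alt, rec.snp_offset)
            call = classify_allele_effect(
                ref_score,
                score_pvalue(pwm, ref_score),
                alt_score,
                score_pvalue(pwm, alt_score),
                alpha=alpha,
                score_tolerance=score_tolerance,
                snp_id=rec.snp_id,
                tf=pwm.name,
            )
            rows.append(call.__dict__ | {"group": getattr(rec, "group", "")})
    return pd.DataFrame(rows)


def enrichment_ratio(
    associated_calls: pd.DataFrame, nonassociated_calls: pd.DataFrame
) -> dict:
    """Ratio of binding-alteration frequencies: associated vs nonassociated.

    A SNP counts as altering binding if any of its PWM calls is disrupts or
    introduces. The flag is raised when the ratio is at least 2. A zero
    non-associated frequency yields an infinite ratio, reported with counts
    so the caller can judge the evidence.
    """
    effects = {"disrupts", "introduces"}

    def frac(calls: pd.DataFrame, label: str) -> tuple[float, int, int]:
        if len(calls) == 0:
            raise PWMError(f"empty class: {label}")
        per_snp = calls.groupby("snp_id")["call"].apply(
            lambda c: bool(set(c) & effects)
        )
        return float(per_snp.mean()), int(per_snp.sum()), int(len(per_snp))

    f_a, n_hit_a, n_a = frac(associated_calls, "associated")
    f_n, n_hit_n, n_n = frac(nonassociated_calls, "nonassociated")
    ratio = float("inf") if f_n == 0 else f_a / f_n
    return {
        "ratio": ratio,
        "flag": bool(ratio >= 2.0),
        "frac_associated": f_a,
        "frac_nonassociated": f_n,
        "n_associated": n_a,
        "n_nonassociated": n_n,
        "n_hits_associated": n_hit_a,
        "n_hits_nonassociated": n_hit_n,
    }
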