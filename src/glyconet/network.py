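"""Glycome-wide effect-vector correlation network.

A lead SNP's glycome-wide effect is its vector of association z-scores
(z = beta/se) across the retained glycan traits (derived re-normalized
traits are excluded first). Loci whose lead SNPs have similar glycome-wide
effects are hypothesized to act in the same regulatory pathway; similarity
is Spearman correlation, reported in absolute value because the sign is an
artifact of effect-allele choice. The network of all pairwise correlations
is pruned at a Bonferroni edge threshold, validated against a permutation
null built from non-associated genome-wide SNPs, and clustered
hierarchically (Euclidean distance, complete linkage).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage


class NetworkError(ValueError):
    pass


def build_effect_vectors(
    lead_snps: Sequence[str],
    meta: pd.DataFrame,
    excluded_traits: Iterable[str] = (),
) -> pd.DataFrame:
    """One z-score vector per lead SNP over the retained traits.

    Returns a DataFrame indexed by snp with one column per retained trait,
    identical trait order for every vector. A missing (snp, trait) meta
    result is a hard error — no silent imputation.
    """
    excluded = set(excluded_traits)
    sub = meta.loc[meta["snp"].isin(set(lead_snps)) & ~meta["trait_id"].isin(excluded)]
    if "z" in sub.columns:
        z = sub["z"]
    else:
        z = sub["beta"] / sub["se"]
    wide = sub.assign(z=z).pivot_table(
        index="snp", columns="trait_id", values="z", aggfunc="first"
    )
    traits = sorted(wide.columns)
    wide = wide.reindex(index=list(lead_snps), columns=traits)
    if wide.isna().any().any():
        snp = wide.index[wide.isna().any(axis=1)][0]
        trait = wide.columns[wide.loc[snp].isna()][0]
        raise NetworkError(f"missing meta result for SNP {snp}, trait {trait}")
    return wide


def _spearman_p(rho: float, n: int) -> float:
    """Two-sided p-value from the t-approximation with n-2 df."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_edge(
    v1: np.ndarray, v2: np.ndarray, method: str = "t"
) -> dict:
    """Spearman correlation of two effect vectors with its p-value.

    Ties receive average ranks. ``method='t'`` (default) uses the
    t-approximation with n-2 degrees of freedom; ``method='exact'`` uses an
    exact permutation p-value (only sensible for n < 10).
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise NetworkError("vectors must be 1-D and of equal length")
    if v1.size < 4:
        raise NetworkError("vectors must have length >= 4")
    if np.all(v1 == v1[0]) or np.all(v2 == v2[0]):
        raise NetworkError("degenerate vector: all values constant")
    r1 = stats.rankdata(v1)
    r2 = stats.rankdata(v2)
    rho = float(np.corrcoef(r1, r2)[0, 1])
    if method == "t":
        p = _spearman_p(rho, v1.size)
    elif method == "exact":
        res = stats.permutation_test(
            (r1, r2),
            lambda x, y: np.corrcoef(x, y)[0, 1],
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        p = float(res.pvalue)
    else:
        raise NetworkError(f"unknown method {method!r}")
    return {"rho": rho, "abs_rho": abs(rho), "p": p}


def _rank_standardize(mat: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and scaled to unit norm, so that
    Spearman rho is a plain dot product between rows."""
    ranks = stats.rankdata(mat, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise NetworkError("degenerate vector: all values constant")
    return ranks / norms


def build_network(vectors: pd.DataFrame) -> pd.DataFrame:
    """All n(n-1)/2 pairwise Spearman edges between effect vectors.

    ``vectors`` is the snp x trait frame from :func:`build_effect_vectors`.
    """
    if len(vectors) < 2:
        raise NetworkError("need at least two vectors")
    snps = list(vectors.index)
    R = _rank_standardize(vectors.to_numpy())
    corr = R @ R.T
    n = vectors.shape[1]
    rows = []
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            rho = float(np.clip(corr[i, j], -1.0, 1.0))
            rows.append((snps[i], snps[j], rho, abs(rho), _spearman_p(rho, n)))
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "rho", "abs_rho", "p"])


def prune_network(edges: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep edges significant after Bonferroni correction for the number of
    edges tested; the applied threshold is stored in ``attrs['threshold']``."""
    threshold = alpha / len(edges) if len(edges) else alpha
    out = edges.loc[edges["p"] <= threshold].reset_index(drop=True)
    out.attrs["threshold"] = threshold
    return out


def build_permutation_pool(
    snp_min_p: pd.DataFrame,
    locus_members: Iterable[str],
    p_filter: float = 5e-5,
) -> tuple[list[str], dict[str, int]]:
    """Construct the null SNP pool for permutation validation.

    Starting from all SNPs (``snp_min_p``: columns snp, min_p where min_p is
    the SNP's minimum association p-value over all glycan traits), remove
    (i) every SNP inside an associated locus, then (ii) every remaining SNP
    with min_p <= p_filter in any trait. Provenance counts are recorded at
    each stage.
    """
    members = set(locus_members)
    initial = len(snp_min_p)
    stage1 = snp_min_p.loc[~snp_min_p["snp"].isin(members)]
    after_locus = len(stage1)
    stage2 = stage1.loc[stage1["min_p"] > p_filter]
    final = len(stage2)
    if final == 0:
        raise NetworkError("empty permutation pool")
    provenance = {
        "initial": initial,
        "after_locus_removal": after_locus,
        "n_p_filtered": after_locus - final,
        "final": final,
    }
    return stage2["snp"].tolist(), provenance


def permutation_null(
    top_vectors: pd.DataFrame,
    pool_vectors: pd.DataFrame,
    k: int,
    seed: int,
    shared_sample: bool = True,
) -> dict[str, np.ndarray]:
    """Null distribution of |rho| for each top SNP against k random pool SNPs.

    k pool SNPs are sampled without replacement once and the same sample is
    reused for every top SNP (``shared_sample=False`` resamples per top SNP).
    Returns a dict mapping top snp id to its sorted array of k |rho| values.
    """
    if k > len(pool_vectors):
        raise NetworkError(f"k={k} exceeds pool size {len(pool_vectors)}")
    rng = np.random.default_rng(seed)
    top = _rank_standardize(top_vectors.to_numpy())
    pool_mat = pool_vectors.to_numpy()
    out: dict[str, np.ndarray] = {}
    if shared_sample:
        idx = rng.choice(len(pool_vectors), size=k, replace=False)
        null_mat = _rank_standardize(pool_mat[idx])
        corr = np.abs(top @ null_mat.T)
        for i, snp in enumerate(top_vectors.index):
            out[str(snp)] = np.sort(corr[i])
    else:
        for i, snp in enumerate(top_vectors.index):
            idx = rng.choice(len(pool_vectors), size=k, replace=False)
            null_mat = _rank_standardize(pool_mat[idx])
            out[str(snp)] = np.sort(np.abs(null_mat @ top[i]))
    return out


def null_quantile(observed_abs_rho: float, null: np.ndarray) -> float:
    """Upper-tail quantile: the fraction of null |rho| values >= observed.

    0 means no permuted SNP reached the observed correlation.
    """
    null = np.asarray(null)
    if null.size == 0:
        raise NetworkError("empty null distribution")
    return float(np.mean(null >= observed_abs_rho))


def edge_null_quantiles(
    edges: pd.DataFrame, nulls: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Annotate each edge with the permutation quantile of its |rho| in the
    null distribution of each endpoint (Table-2-style columns)."""
    out = edges.copy()
    out["quant_a"] = [
        null_quantile(r, nulls[a]) for a, r in zip(out["snp_a"], out["abs_rho"])
    ]
    out["quant_b"] = [
        null_quantile(r, nulls[b]) for b, r in zip(out["snp_b"], out["abs_rho"])
    ]
    return out


@dataclass
class ClusterResult:
    """Hierarchical clustering of loci by their correlation profiles."""

    linkage: np.ndarray  # scipy linkage matrix (complete, Euclidean)
    labels: pd.Series  # cluster label per locus at the requested cut
    k: int


def correlation_matrix(edges: pd.DataFrame, nodes: Sequence[str]) -> pd.DataFrame:
    """Square symmetric |rho| matrix with unit diagonal from an edge list."""
    mat = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
    for a, b, r in edges[["snp_a", "snp_b", "abs_rho"]].itertuples(index=False):
        mat.loc[a, b] = r
        mat.loc[b, a] = r
    return mat


def cluster_loci(matrix: pd.DataFrame, k: int = 3) -> ClusterResult:
    """Complete-linkage hierarchical clustering of the correlation matrix.

    Rows of the (symmetric, unit-diagonal) matrix are the feature vectors;
    distances are Euclidean between rows. Returns the dendrogram (scipy
    linkage matrix) and flat labels at the requested number of clusters.
    """
    arr = matrix.to_numpy()
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-8):
        raise NetworkError("correlation matrix must be square and symmetric")
    if arr.shape[0] == 1:
        return ClusterResult(
            linkage=np.empty((0, 4)),
            labels=pd.Series([1], index=matrix.index),
            k=1,
        )
    Z = linkage(arr, method="complete", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(linkage=Z, labels=pd.Series(labels, index=matrix.index), k=k)


def export_network(
    edges: pd.DataFrame,
    node_annotations: Mapping[str, Mapping[str, str]] | None,
    graphml_path: str | Path,
    tsv_path: str | Path | None = None,
) -> nx.Graph:
    """Write the pruned network as GraphML (plus an optional TSV edge list).

    Nodes carry locus/gene annotations; edges carry rho, rho^2 (the display
    convention for edge weight) and the edge p-value.
    """
    G = nx.Graph()
    annotations = node_annotations or {}
    if len(set(annotations)) != len(annotations):
        raise NetworkError("duplicate node ids in annotations")
    for node, attrs in annotations.items():
        G.add_node(node, **dict(attrs))
    for row in edges.itertuples(index=False):
        G.add_edge(
            row.snp_a,
            row.snp_b,
            rho=float(row.rho),
            rho2=float(row.rho) ** 2,
            p=float(row.p),
        )
    nx.write_graphml(G, graphml_path)
    if tsv_path is not None:
        out = edges.copy()
        out["rho2"] = out["rho"] ** 2
        out.to_csv(tsv_path, sep="\t", index=False)
    return G


def write_null_distributions(
    nulls: Mapping[str, np.ndarray], path: str | Path
) -> None:
    """Store null distributions as a two-column TSV (top_snp, abs_rho)."""
    frames = [
        pd.DataFrame({"top_snp": snp, "abs_rho": vals}) for snp, vals in nulls.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
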