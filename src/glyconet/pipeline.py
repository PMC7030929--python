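"""End-to-end orchestration with deterministic seeding and a run manifest.

A single configuration drives simulate -> meta-analyze -> call loci ->
build the effect network -> permutation validation -> clustering ->
report tables. Each stage gets its own seed derived from the global one by
a fixed offset scheme, so stages can be re-run in isolation and a fixed
global seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import loci as loci_mod
from . import network as net_mod
from . import simulate as sim_mod
from . import sumstats as ss_mod
from . import variance as var_mod

# fixed per-stage seed offsets (global_seed + offset, kept below 2**31)
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "derive": 101,
    "replication": 202,
    "permute": 303,
}


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run (thresholds default to the
    study's values)."""

    outdir: str = "glyconet_run"
    seed: int = 0
    simulation: dict[str, Any] = field(default_factory=dict)
    n_derived: int = 15
    replication_cohorts: tuple[int, ...] = (575, 552, 494, 747)
    gc_correction: bool = True
    significant_p: float = loci_mod.bonferroni_threshold(5e-8, 21)
    suggestive_p: float = loci_mod.bonferroni_threshold(5e-8, 21) * 10
    r2_min: float = 0.5
    max_span: int = 1_000_000
    edge_alpha: float = 0.05
    permutation_k: int = 10_000
    pool_p_filter: float = 5e-5
    cluster_k: int = 3

    def __post_init__(self) -> None:
        for name in ("significant_p", "suggestive_p", "edge_alpha", "r2_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    On a stage failure the manifest written so far is stored with a
    ``partial`` marker naming the failed stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in {"outdir"}
        },
        "stages": [],
        "outputs": {},
    }
    results: dict[str, Any] = {}
    try:
        _run_stages(config, outdir, manifest, results)
    except Exception as exc:  # halt with stage context, keep partial outputs
        manifest["partial"] = True
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else None
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.graphml")):
        manifest["outputs"][p.name] = _digest(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results


def _run_stages(
    config: PipelineConfig, outdir: Path, manifest: dict, results: dict
) -> None:
    # --- simulate -------------------------------------------------------
    manifest["stages"].append("simulate")
    sim_cfg = sim_mod.SimulationConfig(
        seed=config.stage_seed("simulate"), **config.simulation
    )
    sumstats, truth = sim_mod.simulate_multicohort_gwas(sim_cfg)
    sumstats, truth = sim_mod.derive_normalized_traits(
        sumstats, truth, n_derived=config.n_derived, seed=config.stage_seed("derive")
    )
    results["truth"] = truth

    # --- meta-analysis --------------------------------------------------
    manifest["stages"].append("meta")
    meta = ss_mod.meta_analyze(sumstats)
    if config.gc_correction:
        null_mask = ~meta["snp"].isin(truth.true_beta.index)
        lam = ss_mod.gc_lambda(z=meta.loc[null_mask, "z"]).lambda_gc
        meta = ss_mod.gc_correct(meta, lam)
        meta["z"] = meta["beta"] / meta["se"]
        manifest.setdefault("lambda_gc", lam)
    meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    results["meta"] = meta

    # --- locus calling --------------------------------------------------
    manifest["stages"].append("loci")
    calls = loci_mod.classify_associations(
        meta, significant=config.significant_p, suggestive=config.suggestive_p
    )
    ld = loci_mod.LDSource(truth.ld_r2)
    found = loci_mod.define_loci(
        calls, ld, r2_min=config.r2_min, max_span=config.max_span, warn=False
    )
    for locus in found:
        locus.n_associated_glycans = loci_mod.count_locus_glycans(locus, calls)
    loci_mod.loci_table(found).to_csv(outdir / "loci.tsv", sep="\t", index=False)
    loci_mod.loci_to_bed(found, outdir / "loci.bed")
    results["loci"] = found
    results["calls"] = calls

    # --- replication ----------------------------------------------------
    manifest["stages"].append("replication")
    repl = sim_mod.resimulate_cohorts(
        truth, config.replication_cohorts, seed=config.stage_seed("replication")
    )
    # re-derive the normalized traits with the same seed, hence the same
    # affine coefficients: the replication study measures all 77 traits
    repl, _ = sim_mod.derive_normalized_traits(
        repl, truth, n_derived=config.n_derived, seed=config.stage_seed("derive")
    )
    repl_meta = ss_mod.meta_analyze(repl)
    rep_rows = []
    for locus in found:
        lead, trait = locus.lead_snp, locus.lead_trait
        disc = meta.loc[(meta["snp"] == lead) & (meta["trait_id"] == trait)]
        rep = repl_meta.loc[(repl_meta["snp"] == lead) & (repl_meta["trait_id"] == trait)]
        if disc.empty or rep.empty:
            continue
        verdict = loci_mod.evaluate_replication(
            float(disc["beta"].iloc[0]),
            float(rep["beta"].iloc[0]),
            float(rep["p"].iloc[0]),
            n_loci=len(found),
        )
        rep_rows.append(
            {
                "locus": locus.label,
                "lead_snp": lead,
                "trait_id": trait,
                "beta_disc": float(disc["beta"].iloc[0]),
                "p_disc": float(disc["p"].iloc[0]),
                "beta_repl": float(rep["beta"].iloc[0]),
                **verdict,
            }
        )
    replication = pd.DataFrame(rep_rows)
    replication.to_csv(outdir / "replication.tsv", sep="\t", index=False)
    results["replication"] = replication

    # --- effect network -------------------------------------------------
    manifest["stages"].append("network")
    leads = [l.lead_snp for l in found]
    excluded = sorted(truth.derived_parent)
    vectors = net_mod.build_effect_vectors(leads, meta, excluded_traits=excluded)
    edges = net_mod.build_network(vectors)
    pruned = net_mod.prune_network(edges, alpha=config.edge_alpha)
    results["vectors"] = vectors
    results["edges"] = edges

    # --- permutation ----------------------------------------------------
    manifest["stages"].append("permute")
    min_p = meta.groupby("snp")["p"].min().rename("min_p").reset_index()
    members = [m for l in found for m in l.members]
    pool, provenance = net_mod.build_permutation_pool(
        min_p, members, p_filter=config.pool_p_filter
    )
    manifest["permutation_pool"] = provenance
    k = min(config.permutation_k, len(pool))
    pool_vectors = net_mod.build_effect_vectors(pool, meta, excluded_traits=excluded)
    nulls = net_mod.permutation_null(
        vectors, pool_vectors, k=k, seed=config.stage_seed("permute")
    )
    net_mod.write_null_distributions(nulls, outdir / "null_distributions.tsv")
    edges_q = net_mod.edge_null_quantiles(pruned, nulls)
    results["pruned_edges"] = edges_q
    results["nulls"] = nulls

    # --- clustering -----------------------------------------------------
    manifest["stages"].append("cluster")
    mat = net_mod.correlation_matrix(edges, list(vectors.index))
    clustering = net_mod.cluster_loci(mat, k=config.cluster_k)
    results["clusters"] = clustering

    # --- variance explained --------------------------------------------
    manifest["stages"].append("variance")
    sig = calls.loc[
        (calls["tier"] == "significant") & calls["snp"].isin(leads),
        ["snp", "trait_id", "eaf", "beta"],
    ].rename(columns={"eaf": "maf", "beta": "beta_u"})
    if len(sig):
        totals = var_mod.per_glycan_totals(sig, mode="univariate")
        totals.rename("total_sigma_u").to_frame().reset_index().to_csv(
            outdir / "variance.tsv", sep="\t", index=False
        )
        results["variance_totals"] = totals

    # --- reports --------------------------------------------------------
    manifest["stages"].append("report")
    report_tables(results, outdir)
    annotations = {l.lead_snp: {"locus": l.label} for l in found}
    net_mod.export_network(
        edges_q, annotations, outdir / "network.graphml", outdir / "network_edges.tsv"
    )


def report_tables(results: dict, outdir: Path) -> None:
    """Render the locus / network-edge / cluster report tables as TSV."""
    outdir = Path(outdir)
    found = results["loci"]
    meta = results["meta"]
    repl = results.get("replication", pd.DataFrame())
    rows = []
    for locus in found:
        hit = meta.loc[
            (meta["snp"] == locus.lead_snp) & (meta["trait_id"] == locus.lead_trait)
        ].iloc[0]
        row = {
            "locus": locus.label,
            "snp": locus.lead_snp,
            "ea": hit["ea"],
            "oa": hit["oa"],
            "eaf": round(float(hit["eaf"]), 3),
            "glycan": locus.lead_trait,
            "n_glycans": locus.n_associated_glycans,
            "beta": float(hit["beta"]),
            "p": float(hit["p"]),
        }
        if len(repl):
            r = repl.loc[repl["lead_snp"] == locus.lead_snp]
            if len(r):
                row["beta_repl"] = float(r["beta_repl"].iloc[0])
                row["p_repl"] = float(r["p_repl"].iloc[0])
                row["replicated"] = bool(r["replicated"].iloc[0])
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "table_loci.tsv", sep="\t", index=False)

    if "pruned_edges" in results:
        results["pruned_edges"].to_csv(outdir / "table_edges.tsv", sep="\t", index=False)
    if "clusters" in results:
        results["clusters"].labels.rename("cluster").to_frame().reset_index(
            names="snp"
        ).to_csv(outdir / "table_clusters.tsv", sep="\t", index=False)
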