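# glyconet

A summary-statistics toolkit for multi-trait GWAS of the IgG N-glycome:
fixed-effect meta-analysis across cohorts, genomic control, locus mapping,
a glycome-wide SNP-effect correlation network with permutation validation
and hierarchical clustering, explained-variance calculus, allele-level
transcription-factor binding-site (TFBS) disruption scoring, and SMR/HEIDI
pleiotropy classification — with a synthetic-data generator that plants a
known regulatory cluster structure so every stage can be tested against
ground truth.

## The problem

IgG carries a single conserved N-glycosylation site whose glycan composition
switches antibody effector functions; its ~77 quantifiable glycan traits are
heritable, and genome-wide association studies find dozens of loci, most with
no obvious glycosylation role. The central analytical idea implemented here:
a variant's **glycome-wide effect** is its vector of association z-scores
(z = β/se) across all directly measured glycan traits, and two loci whose
lead SNPs have similar glycome-wide effects (high |Spearman ρ|) plausibly act
in the same regulatory pathway — e.g. a transcription factor locus clustering
with the glycosyltransferase it regulates. The toolkit builds that network
from summary statistics alone, prunes it at a Bonferroni edge threshold,
validates edges against a permutation null of random genome-wide SNPs, and
cuts the hierarchical clustering into candidate regulatory modules.

Around that core it implements the standard machinery the analysis needs:

- **sumstats** — harmonization to a reference allele orientation,
  genomic-control λ = median(z²)/0.4549 with se·√λ deflation, and
  inverse-variance fixed-effect pooling (β_meta = Σwβ/Σw, w = 1/se²).
- **loci** — three-tier significance calls (genome-wide p ≤ α/m for m
  independent traits, suggestive one decade above), greedy LD clumping,
  transitive merging of overlapping loci, lead-SNP selection, and
  sign-consistent Bonferroni replication.
- **variance** — per-SNP explained variance σ = 2pqβ² (and the joint form
  2pqβᵤβⱼ for conditionally independent SNPs) with per-glycan totals.
- **tfbs** — JASPAR/MEME PWM parsing, both-strand log-odds scanning of
  ref/alt alleles, exact/DP score p-values, disruption–introduction calls,
  and associated-vs-nonassociated enrichment ratios.
- **pleiotropy** — the SMR ratio test (T = z_x²z_y²/(z_x²+z_y²) ~ χ²₁) and a
  HEIDI-style heterogeneity test that separates a shared causal variant
  (pleiotropy) from distinct causal variants in LD.

## Worked example

Run the full pipeline on synthetic data from one config:

```python
from glyconet import pipeline

cfg = pipeline.PipelineConfig(
    outdir="demo_run", seed=17,
    simulation={"n_loci": 6, "n_clusters": 3,
                "background_pool_size": 300, "noise_sd": 0.0},
    permutation_k=200,
)
results = pipeline.run(cfg)
print(len(results["loci"]), "loci;",
      results["clusters"].labels.nunique(), "clusters;",
      int(results["replication"]["replicated"].sum()), "replicated")
```

prints

```
6 loci; 3 clusters; 6 replicated
```

— the six planted loci are each recovered as exactly one locus, the
complete-linkage cut at k = 3 reproduces the planted 3-cluster regulatory
structure, and every locus replicates in the independent (3.4× smaller)
synthetic replication cohorts with a sign-consistent effect at the
Bonferroni-adjusted replication threshold, as expected with zero generative
noise. `demo_run/`
contains the meta-analysis, locus/edge/cluster report tables, the GraphML
network and a manifest with per-stage seeds and output digests.

The same stages are available from the shell:

```bash
glyconet simulate --outdir demo --seed 3 --n-loci 4 --n-clusters 2
glyconet meta --input demo/sumstats.tsv --output demo/meta.tsv
glyconet loci --meta demo/meta.tsv --ld demo/ld.tsv --out-prefix demo/loci
```

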