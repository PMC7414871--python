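# founderscan

Founder-event analysis of disease mutations from phased SNP data.

When the same pathogenic mutation appears in several nominally unrelated
families (and in apparently sporadic cases), the question is whether those
chromosomes descend from one ancestral founder or arose independently.
`founderscan` answers it the way identity-by-descent (IBD) studies of
disease cohorts do — the motivating use case being *SOD1* mutations in
familial ALS:

1. **IBD detection** — GERMLINE-style windowed hashing over phased
   haplotypes: exact-match SNP windows, merged into segments, retained at
   ≥ 3 cM (genetic map interpolated from a PLINK-style `.map`; optional
   BED masks).
2. **Relatedness degrees** — per pair, the kinship coefficient
   φ̂ = (¼·L_IBD1 + ½·L_IBD2)/L_genome is mapped to a degree via
   d = round(−log₂ φ̂) − 1 (φ = 2^(−d−1): 1st = siblings, 3rd = first
   cousins, 7th = third cousins), with parent–offspring recognized by
   near-total IBD1 and no IBD2; cross-family pairs at ≤ 7th degree are
   reported as novel relatives.
3. **Locus network** — samples sharing any IBD segment over the target
   locus are joined; connected components are the candidate founder
   clusters; edges between carriers of discordant mutations are flagged.
4. **Founder haplotypes** — per cluster, the intersection of member-pair
   segments defines the interval; the single haplotype carried by every
   member is extracted, re-reported over the clusters' common SNP set, and
   pruned to the alleles that distinguish founder events.
5. **Dating** — the Gamma method: one-sided ancestral haplotype lengths
   erode as Exp(g) per Morgan over g generations, so summed two-sided
   lengths are Gamma(2n, g); ĝ = 2n/ΣL with an exact-pivot 95% interval,
   plus a correlated-genealogy correction for samples sharing ancestry
   below the founder. Generations convert to years at 20 years each.

Real cohorts of this kind are consent-restricted, so the package bundles a
gene-dropping simulator (Haldane recombination, star founder genealogies,
minimal pedigrees for relative pairs, unrelated background) that emits
phased VCF + map + truth tables, giving every stage an oracle. See
`docs/methods.md` for models, assumptions and limitations.

## Worked example

Simulate the five-founder-event cohort (clusters of 22/33/6/3/3 carriers,
founder depths 10/8/5/3/4 generations, mutations inside
chr21:33,031,935–33,041,243) and run the whole pipeline:

```python
from founderscan.network import LocusSpec
from founderscan.pipeline import DatingOptions, RunConfig, run_all
from founderscan.simulate import SOD1_LOCUS, five_cluster_config

config = RunConfig(out_dir="bundle", seed=42,
                   simulate=five_cluster_config(seed=42),
                   locus=LocusSpec(*SOD1_LOCUS),
                   dating=DatingOptions(min_degree=1))
result = run_all(config)
print(result.summary)
```

prints (excerpt):

```
samples: 87
segments_genome_wide: 753
segments_at_locus: 550
clusters: 5
cluster_C1_size: 29
cluster_C2_size: 18
cluster_C3_size: 4
cluster_C4_size: 3
cluster_C5_size: 3
flagged_edges: 0
tmrca_C4: TMRCA (independent genealogy): 6.2 generations (95% CI 2-12
generations, 40-240 years at 20-year generation time; n=3, total length
96.5 cM)
```

All 67 planted carriers with detectable sharing sort into exactly five
pure clusters (a few carriers whose retained ancestral tract fell under
the 3 cM floor are omitted from the network, which is why cluster sizes
sit slightly below the planted 33/22/6/3/3). `bundle/` holds
`segments.tsv`, `pairs.tsv`, `novel_relatives.tsv`, `network.json`,
`haplotypes.tsv`, `tmrca.json` and `summary.txt`, each stamped with the
tool version, seed and config hash. Note the summary's `tmrca_*` lines
date each cluster from *pairwise* segment lengths (the study-shaped
procedure), which track the pairwise coalescence depth; dating a cluster
from per-carrier ancestral-length proxies recovers the planted founder
depth itself, e.g.

```python
from founderscan.experiments import tmrca_recovery_experiment
print(tmrca_recovery_experiment(seed=42))
# {'cluster': 'C2', 'true_g': 8, 'g_hat': 8.83,
#  'ci_low': 6.77, 'ci_high': 11.16, 'n': 31}
```

The same stages are exposed as a CLI:

```sh
founderscan simulate --config sim.yaml --out cohort/
founderscan ibd --vcf cohort/cohort.vcf --map cohort/genome.map \
    --min-cm 3 --window 64 --out segments.tsv
founderscan network --segments segments.tsv \
    --locus 21:33,031,935-33,041,243 --mutations cohort/mutations.tsv \
    --out network.json
founderscan date --segments segments.tsv \
    --locus 21:33,031,935-33,041,243 --out tmrca.json
founderscan run --config run.yaml
```

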