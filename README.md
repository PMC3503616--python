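# labstrain

Strain typing and community profiling for gut lactic acid bacteria (LAB),
built around the question of whether strains of a species such as
*Lactobacillus johnsonii* are specific to their animal hosts. The package
implements the full computational side of such a study as a tested,
reusable pipeline:

* **Genome repeat screen** — detection of perfect simple sequence repeats
  (SSR/VNTR, motif ≥ 3 bp repeated ≥ 3 times), mononucleotide repeats
  (runs ≥ 6 bp) and non-perfect SSRs (copies > 70 % identical to the array
  consensus), and ranking of candidate typing loci by copy number.
* **In-silico tRFLP** — terminal restriction fragment prediction
  (3′-anchored primer matching, MspI `C^CGG` digestion), conversion of
  measured peak tables into relative-abundance profiles
  (area / total area), 8-level abundance matrices, and per-peak one-way
  ANOVA across host groups.
* **Multi-locus genotyping** — SSR allele calling with null alleles
  (no amplification product is an allele category of its own), 0/1
  allele-presence encoding, Simpson-type diversity *D* = 1 − Σ*P*²ⱼ per
  locus, SSR-type and MLST sequence-type assignment, and SNP summaries
  over pre-aligned conserved genes.
* **Clustering** — Nei–Li / Dice association distance on presence/absence
  profiles, *d* = 1 − 2a/(2a + b + c); p-distance with pairwise deletion
  for sequences; UPGMA dendrograms with column-resampled bootstrap
  supports; flat cluster extraction and within/between-cluster distance
  summaries.
* **Synthetic data** — a seeded generator producing every input the
  pipeline consumes (genome with planted repeats, host-structured strain
  genotypes and gene sequences, fecal-community peak tables) together with
  ground truth, so the whole pipeline runs and is tested without any
  download.

## Worked example

```python
import labstrain as ls

# a 47-strain cohort: 3 host groups x 13 strains + 8 singleton isolates
gts, genes, truth = ls.simulate_strain_population(ls.GeneratorConfig(seed=42))
nonsingletons = [s for s, c in truth.cluster_of.items() if c is not None]

res = ls.run_ssr_workflow(gts, k=3, n_bootstrap=200, seed=42,
                          cluster_ids=nonsingletons)
print(len(gts), len(res["binary_matrix"].columns), res["n_ssr_types"])
for s in res["summaries"]:
    print(f"cluster {s.label}: within {s.within_mean:.2f}±{s.within_sd:.2f} "
          f"between {s.between_mean:.2f}±{s.between_sd:.2f}")

mres = ls.run_mlst_workflow(genes, n_bootstrap=0)
ss = mres["snp_summary"]
print(f"{ss.n_snps} SNPs / {ss.total_bp} bp = {ss.pct}%")
```

prints

```
47 95 47
cluster 1: within 0.40±0.12 between 1.00±0.02
cluster 2: within 0.35±0.14 between 1.00±0.02
cluster 3: within 0.41±0.16 between 1.00±0.02
235 SNPs / 1921 bp = 12.2%
```

47 strains typed at 11 SSR loci encode to 95 presence/absence columns here
(one column per observed allele per locus, nulls included); the three
planted host groups are far tighter internally (mean Dice distance
0.35–0.41) than against the rest of the cohort (≈ 1.0), which is exactly
the pattern that supports host specificity; and the three conserved genes
carry 12.2 % polymorphic sites. The same stages are available from the
shell via `labstrain {screen, trflp, type, tree, clusters, simulate,
run-ssr, run-mlst}`.

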