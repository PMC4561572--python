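# hybridtrace

Microsatellite analysis of hybridization and clinal introgression between
two sibling taxa sampled at paired (sympatric) sites — written for hybrid-
zone and invasion-genetics studies where two closely related species meet
on different host plants and the questions are: *are they exchanging genes
now, at what per-generation rate, and is there a geographic signal of
adaptive introgression toward a focal region?*

The package provides, as a library and a CLI:

- **Genotype I/O** — Genepop and STRUCTURE text dialects, site-geography
  and climate-covariate tables; allele calls stay as fragment lengths.
- **Population statistics** — allele frequencies (ML or Dirichlet-
  smoothed), observed/unbiased expected heterozygosity, inbreeding
  coefficient f = 1 − H₀/Hₑ.
- **Distance network** — Nei's (1972) standard distance
  D = −ln(Jxy/√(JxJy)) with pairwise locus deletion, deterministic
  neighbor joining, and a loci-resampling bootstrap (supports on
  bipartitions, Newick export).
- **Hybrid classification** — supervised posterior probabilities over
  {pure-natal, migrant, F1, backcross-natal, backcross-non-natal} from
  smoothed reference frequencies and a migration prior ν, with
  leave-one-out references; per-generation rates
  *hybridization* = #F1/N and *migration* = (#migrants + ½#F1)/N.
- **Clinal tests** — per-paired-site total-variation divergence
  ½Σ|p_A − p_B| averaged over loci, Pearson regression on great-circle
  distance to a focal site, a one-tailed within-taxon genotype-permutation
  null with p = (1 + #{r* ≥ r})/(1 + B), climate-covariate correlations,
  and Mantel / partial Mantel tests.
- **Private alleles** — per-taxon private counts, χ² test of the split,
  and null expectations for rare-allele sharing at sympatric pairs.
- **Simulator** — Balding–Nichols two-taxon divergence (F ≈ FST), nine
  paired sites on a transect, exponential introgression clines
  α_s = α_max e^(−d_s/λ) at a subset of loci, injected F1/migrant/
  backcross individuals, full ground truth for recovery tests.

## Worked example

Simulate the default study design (2 taxa × 9 paired sites × 30 diploids,
19 loci, FST 0.15, a 7-locus cline toward site s9, 1.5% F1s) and run the
whole pipeline:

```sh
printf 'rate_f1: 0.015\n' > sim.yaml
hybridtrace simulate --config sim.yaml --seed 7 --out demo
hybridtrace all --in demo.gen --geo demo_geo.tsv --focal s9 \
    --nu 0.01 --nperm 999 --nboot 1000 --seed 7 --outdir results
```

`results/rates.tsv` (seed 7):

```
natal_taxon  n    n_f1  n_migrant  n_backcross  hybridization_rate  migration_rate
pom          270  2     0          0            0.00740...          0.00370...
zeph         270  2     0          0            0.00740...          0.00370...
```

Two flies per host sample were classified F1, giving a hybridization rate
of 0.74% per generation in each direction and a migration rate of 0.37%
(each F1 contributes half an immigrant genome). The cline table header
reports the across-loci test:

```
# seed=7 n_perm=999 focal=s9 overall_r=0.6246 overall_p=0.037
locus  linkage_group  r        p
p1                    0.5631   0.058
p2                    0.2974   0.222
p3                    -0.6821  0.980
```

The mean allele-frequency difference between the taxa declines toward s9
(overall r = 0.62, one-tailed permutation p = 0.037): the taxon-A
populations near the focal site are measurably more "taxon-B-like", as
expected from the simulated introgression cline. `results/nj_tree.nwk`
holds the unrooted NJ network (the two taxa separate with bootstrap
support 1.0 at default divergence), and `results/private_alleles.txt`
the private-allele summary (here 18 private alleles, 12 in the taxon
receiving introgressed alleles).

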