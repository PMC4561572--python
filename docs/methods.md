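# Methods

`hybridtrace` analyses diploid microsatellite genotypes from two sibling
taxa sampled at paired (sympatric) sites, asking three questions: are the
taxa exchanging genes now (hybrid and migrant detection, per-generation
rates); how are populations structured (Nei-distance neighbor-joining
network); and is there a geographic signal of introgression — do the taxa
converge in allele frequency toward a focal site (permutation-calibrated
cline test, climate covariates, Mantel tests)? Private-allele accounting
provides an independent, rate-free line of evidence on how freely alleles
move between the taxa.

## Data model

Genotypes are unordered pairs of fragment lengths (positive integers) per
individual per locus; a call is either complete or missing. Allele labels
are never recoded to indices at the I/O layer, so outputs remain
comparable to published allele tables ("allele 226 at locus p7"). Each
individual carries a sampling-site and a host/species label; sites of the
two taxa sharing a location form a sympatric pair (by default, pair = site).
Genepop (2-/3-digit, auto-detected) and STRUCTURE one-/two-row matrices are
supported. Genepop has no slot for individual ids or species: the name
field carries the population label `site_species` (split on the last
underscore) and ids are autogenerated as `label_ordinal`, so round-trips
are exact for datasets following that convention (the simulator emits it).

## Population statistics

Allele frequencies are maximum-likelihood counts/(2n) per population and
locus; a cell with no scored individual is reported *empty*, never
zero-filled. For classification, frequencies are Dirichlet-smoothed over
the union allele set observed across all populations at a locus,
(count + λ)/(2n + λK), default λ = 1/K — the convention assignment methods
use so every observed allele has positive probability in both gene pools.
Heterozygosity uses the unbiased expected form He = (2n/(2n−1))(1 − Σp²)
and the inbreeding coefficient is f = 1 − Ho/He, left undefined at
monomorphic loci and excluded from per-population means. This simple f is
deliberate; a Weir–Cockerham FIS would weight loci differently and is out
of scope.

## Distances and trees

Nei's standard distance D = −ln(Jxy/√(Jx·Jy)) with the gene identities
averaged arithmetically across loci. Populations unscored at a locus are
handled by pairwise locus deletion; if two populations share no scored
locus that pair is an error, and fully disjoint allele sets give D = +∞
(which neighbor joining refuses — resolve upstream). NJ is Saitou–Nei with
two determinism rules: Q-matrix ties resolve to the lowest (row, col)
index pair, and a negative branch length is clamped to zero with the
excess moved to its sister so the joined pair's path length is preserved;
the final three branches solve the three-point formulas (clamped at 0).
Bootstrap support resamples loci with replacement (individuals are not
resampled), recomputes distances and the tree, and reports the fraction of
completed replicates containing each original bipartition; replicates with
unusable matrices are dropped and counted, with a warning above 1%.

## Genotype-class classification

Five ancestry classes relative to an individual's natal host taxon:
pure-natal, pure-non-natal (migrant genotype), F1, backcross-to-natal,
backcross-to-non-natal. Generations are truncated at two, so F2 and later
backcross generations fold into the backcross classes — these are not
distinguishable from each other with ~19 loci anyway. Gamete
distributions: pure = (p, p), F1 = (pA, pB), backcross = (p, (pA+pB)/2);
an unordered genotype (x, y) has probability q1(x)q2(y) + q1(y)q2(x) for
x ≠ y. Per-locus probabilities multiply across scored loci (log domain)
and combine with the migration prior ν: P(pure-natal) = 1 − ν and ν/4 for
each other class. This is a fixed-frequency empirical-Bayes classifier:
reference frequencies come from the sampled populations (per sympatric
pair by default; poolable), optionally with the focal individual's own
alleles removed from its natal reference (leave-one-out), rather than
being integrated over by MCMC. It is deterministic and fast, and the
downstream rate estimators consume only the class calls. Assignment is by
argmax with ties resolving toward pure-natal; the full posterior vector is
always reported so users can apply thresholds.

Rates per generation in a host sample S: hybridization = #F1/|S|;
migration into S's taxon = (#migrant genotypes + ½·#F1)/|S| (each F1
carries one immigrant gamete).

On synthetic data at the emulated study scale (~278 flies per host sample,
19 loci, FST 0.15), the classifier recovers an injected 1.5% F1 fraction
within the estimate's 95% binomial interval and mislabels clearly pure
individuals as F1 at well under 1%; about a third of true F1s are called
backcross instead, the familiar F1/later-generation ambiguity at this
marker resolution.

## Clinal introgression test

Between-taxon divergence at a paired site is the total-variation distance
½Σ|pA − pB| per locus, averaged over the loci scored in both populations
(the site's locus count is reported, mirroring sites scored for fewer
loci). The divergence statistic itself is a package choice: it is bounded
in [0, 1], a metric, and reduces to the simple frequency difference at a
diallelic locus. The cline statistic is the Pearson r of divergence on
great-circle (haversine, R = 6371.0088 km) distance to a focal site. The
null reassigns individuals among sites uniformly *within* each taxon,
preserving per-site sample sizes, and the one-tailed p-value is
(1 + #{r_perm ≥ r_obs})/(1 + n_perm) — the add-one convention keeps p off
zero; n_perm defaults to 9999. Climate covariates (e.g. seasonal
precipitation, summer high, winter low) correlate against the same mean
divergence. Mantel tests correlate upper triangles of distance matrices
with joint row/column permutation of the first matrix; the partial version
(Smouse–Long–Sokal) correlates residual matrices after regressing each on
the third matrix and permutes the residual matrix of the first. A matrix
fully explained by the conditioning matrix leaves nothing to correlate;
that degenerate case returns r = 0, p = 1.

## Private alleles

An allele is private to a taxon if observed in ≥1 of its populations and
none of the other's; presence/absence only, no frequency filter. The
report tallies how many populations carry each allele and flags
two-population alleles whose carriers are a sympatric cross-taxon pair —
under free local introgression such pairs should be common. Two null
expectations for that count are provided: the ordered-pair form
(m/(P(P−1)))·n and the unordered combinatorial form (m/C(P,2))·n, which is
exactly twice the first; both are reported because published analyses have
used the ordered-pair arithmetic while the uniform-random-pair model gives
the combinatorial value. A Monte Carlo mode (uniform placement of each
allele on a random unordered pair) converges to the combinatorial form and
serves as a run-time guard. The taxon split of private-allele counts is
tested with a df = 1 goodness-of-fit χ² against equal expectation, no
continuity correction.

## Synthetic data

The simulator emulates the assumed study design: 9 paired sites on a
~320 km linear transect (40 km spacing, focal site at one end), 19 loci on
5 linkage groups, 8 alleles per locus, 30 diploids per population, 2%
missing calls. Divergence is Balding–Nichols: ancestral p ~ Dirichlet(1),
taxon frequencies ~ Dirichlet(p(1−F)/F) with F = 0.15, so F is the
expected between-taxon FST (realized mean 0.149 over 200 replicates).
Because both taxa share each locus's allele support, strong divergence
arises without fixed differences (none in 40/40 default replicates) and
private alleles arise by sampling, as in real microsatellite data. At a
configurable subset of loci (default 7/19) the taxon-A site frequencies
are mixed toward taxon B with weight α_s = α_max·exp(−d_s/λ), α_max = 0.4,
λ = 150 km — a smooth exponential cline over the transect; taxon B is
unaffected unless the symmetric flag is set, mirroring an asymmetric-
introgression hypothesis. Genotypes are drawn under Hardy–Weinberg;
injected F1s, migrants and backcrosses use the classifier's own gamete
model, with the true class of every individual recorded for recovery
tests. All randomness flows from one seed; a fixed seed fixes the dataset
byte-for-byte through the writers.

What the simulator does *not* model: stepwise mutation, linkage between
loci, site-level drift within taxa, temporal dynamics, or allele-size
homoplasy. Passing tests therefore demonstrate correctness of the
estimators under the stated generative assumptions, not robustness to
those real-data complications.

## Test and calibration scale

Stochastic calibration tests run at sizes chosen to keep the suite quick
while leaving Monte Carlo error well inside the asserted tolerances:
type-I error of the cline test uses 500 null replicates at n_perm = 199
(tolerance 3 binomial SEs around 0.05); power uses 100 replicates at
n_perm = 999 against the ≥80% bar (measured true power 0.877 ± 0.019 at
300 replicates); Mantel calibration uses 500 replicate 18-label matrices;
FST calibration averages 200 frequency replicates. The bootstrap default
of 10 000 replicates matches field practice; tests use smaller counts
since support fractions, not their precision, are under test.

## Numerical conventions

Posteriors are computed in the log domain and renormalized after
subtracting the maximum. Frequencies sum to 1 within 1e−9. Permutation
p-values always use the add-one convention. Pearson r is undefined (NaN)
under zero variance or fewer than 3 points, and such cells are reported
missing rather than silently dropped.
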