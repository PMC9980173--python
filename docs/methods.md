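# Methods

This note records the models, parameter choices, and numerical conventions
behind `chromatlas`, and what the synthetic-data generator does and does
not emulate.

## Coordinates, bins, and contact I/O

Contact positions follow the `.pairs` convention (1-based); bins are
0-based half-open and tile each chromosome in `ceil(L / bin_size)` bins,
the last possibly short. The only conversion point is `BinIndex.locate`
(`floor((pos - 1) / bin_size)`), which keeps off-by-one arithmetic out of
every other module. Contacts are canonicalised on read (`chrom_a <=
chrom_b` in assembly order, `pos_a <= pos_b` for intra-chromosomal pairs);
strand columns are ignored because nothing downstream is strand-aware, and
duplicate contacts are kept as-is. CpG density is counted per bin as CG
dinucleotides divided by bin width; a CG straddling a bin boundary is
credited to the bin of its C, a deterministic rule that makes the brute-
force oracle exact.

## scA/B

scA/B is computed contact-based: for bin *i*, the mean reference value
(CpG density) of the partner bins over all contacts with exactly one end
in *i*, counting intra-chromosomal contacts at or beyond `min_distance`
(default 1 Mb, which also guarantees the two ends fall in different 1-Mb
bins) and all inter-chromosomal contacts. This is a deliberate design
choice: no 3D structure reconstruction is in scope, and the contact-
partner average captures the same euchromatic-neighbourhood signal. Bins
with fewer than 5 partners are missing; cells with fewer than 5 000
contacts, or no observed bin, are dropped at QC (real single-cell depths
of several hundred thousand contacts sit far above both floors; the
defaults only guard degenerate inputs). Rows are z-scored per cell over
observed bins; missing entries are imputed with 0 — the post-normalisation
mean — for embedding and clustering only, and tracked as missing in the
stored matrix. The matrix covers autosomes only, so sex never drives
clustering.

## Structure typing and staging

Embedding always starts from PCA (20 components by default, deterministic
sign convention, PC1 optionally oriented so the oldest cells score
positive); t-SNE (perplexity 30) and UMAP run on the PCs under a fixed
seed. Clustering is Ward linkage on Euclidean distance over the top 50 %
most-variable bins — variance filtering stabilises high-dimensional Ward
and concentrates the lifespan signal. Stages are the k = 5 clusters
ordered by ascending mean donor age, ties broken by mean PC1; with no ages
the ordering falls back to PC1 with a warning, which fixes the order but
not the direction of the lifespan axis. Stage-abundance curves are the
per-age-point stage fractions (summing to 1 wherever a cell exists); a
stage's peak age is the argmax of its curve.

## Contact statistics

All intra-chromosomal statistics discard distances below a 10-kb QC floor
(self-ligation artifacts); the ultra-long-range boundary is an inclusive
≥ 10 Mb. Distance histograms use log10-spaced edges with out-of-range
distances clipped into the end bins, so totals are conserved. Aggregated
maps sum binned contacts symmetrically (same-bin contacts once on the
diagonal); coverage normalisation is 10 rounds of symmetric marginal
scaling (divide by the square root of row/column sums) rather than full
matrix balancing, because aggregated single-cell maps are sparse.
Relative-change maps are `log2((late + p) / (early + p))` on
coverage-normalised inputs with p defaulting to 1e-6 of the matrix mean,
so pixels empty in both maps are exactly zero.

Inter-chromosomal enrichment is obs/exp on pooled contacts (pooling, not
per-cell averaging, was chosen for stability at sparse per-cell trans
counts). The default expected model is the length-product null — pair
(i, j) expected in proportion to L_i·L_j over distinct pairs — which is
unbiased under uniformly placed trans contacts. The more common
observed-marginal product is available (`expected_model="marginal"`,
fitted by iterative scaling on the off-diagonal), but note that the naive
`m_i·m_j / total` form is biased upward by n/(n-1) with n chromosomes,
which matters at n < ~20. Hubs are operationalised as maximal cliques of
chromosome pairs whose enrichment strictly increases at every stage step
with a total gain above threshold; monotonically decreasing pairs are
reported separately as weakening.

## scA/B dynamics

Stage means are computed per 1-Mb autosomal region, ignoring missing
entries, with stages weighted equally regardless of cell count. The
dynamic-region filter keeps exactly `floor(0.20 · R)` regions by
population (ddof = 0) between-stage variance, ties broken toward the lower
region ordinal. Temporal modes are average-linkage clusters (k = 2) on
correlation distance between stage trajectories, named "up"/"down" by the
sign of the cluster-mean S5 − S1 difference. Genes map to bins by the
gene-body midpoint; the aggregated marker-set trajectory reports the
fraction of member regions increasing from first to last stage.

## Pop-C demultiplexing

The X:A ratio divides X-endpoint density by autosomal endpoint density
(two endpoints per contact); the sex boundary of 0.75 is the midpoint of
the expected male (0.5) and female (1.0) ratios, and at 20 000 contacts
per cell the two distributions are separated by dozens of standard errors.
Genotype assignment scores each read as alt with probability
`(g/2)(1-ε) + (1-g/2)ε` (ε = 0.01 by default), sums log-likelihoods over
reads, and scores every donor pair as an exact 50/50 mixture; a cell is a
doublet when the best pair beats the best single donor by more than 2
log-units, and ambiguous when the top two singles are within 2 log-units.
Ambient contamination and unbalanced doublets are not modelled. The
genotype-free path is a binomial-mixture EM over per-SNP alt fractions
(fractions clamped to [1e-4, 1-1e-4] to avoid degenerate likelihoods),
best of 5 restarts by final log-likelihood, deterministic given a seed.

## The synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions the acceptance checks run under.

**Genome.** Five autosomes plus an X, 100 Mb each, 1-Mb bins, alternating
5-Mb A/B compartment blocks. CpG density is Gaussian per compartment
(A: 0.012, B: 0.008, s.d. 0.001 — the ~1.5× A/B contrast typical of
mammalian 1-Mb bins), truncated at zero. 20 % of autosomal bins are
dynamic: half start B-like and interpolate linearly to A-like as the
stage scalar runs 0 → 1 (the "up" mode), half the reverse; their CpG is
intermediate, as befits regions without a fixed compartment identity.

**Contacts.** Each intra-chromosomal contact is drawn from a two-component
distance mixture: with probability `w_long`, log-uniform on [10 Mb,
min(100 Mb, L)]; otherwise a truncated power law `s^-1.5` on [10 kb,
10 Mb) — a generic polymer-like decay; no P(s) fit is attempted. Because
the components partition at exactly 10 Mb, the expected ≥ 10 Mb fraction
equals `w_long`, making the calibration a pure binomial. Long-range and
inter-chromosomal endpoint pairs pass an acceptance-rejection step that
favours same-compartment bins: acceptance interpolates between 1 and
1/checker_strength via `(1 + v_i·v_j)/2`, with distance and position
redrawn together on rejection (cap 100) so the surviving population's
same:cross odds equal the multiplier — redrawing only the position would
dilute the odds, since on a blocked genome the drawn distance itself
partly determines compartment parity. Male cells halve the X chromosome's
sampling weight (one X versus diploid autosomes). Inter-chromosomal
contacts pick chromosome pairs from the length-product null; hub pairs
are pinned to multiplier × null with the remainder renormalised over
non-hub pairs, so measured obs/exp enrichment recovers the planted
multiplier exactly.

**Presets.** `preset_library()` carries per-type `w_long` calibrations
(granule stages S1…S5 linearly interpolated between the 0.19/0.33 human
and 0.19/0.34 mouse endpoints — only the endpoints are constrained, the
monotone trend is the claim being modelled — plus forebrain, Purkinje,
microglia, and oligodendrocyte values), checkerboard strengths growing
2 → 6 across granule stages, a granule hub on chr1/2/3 growing 1× → 3×,
and 10 % inter-chromosomal contacts. Non-granule types additionally carry
a type signature — a seed-determined sign flip of 25 % of static autosomal
bins — because real cell types differ in *which* regions are A versus B,
not merely in compartment strength; without it, a mature granule cell and
a microglia-like cell would have identical scA/B profiles and structure
typing could not separate them.

**Pools.** Donor genotypes are Hardy-Weinberg draws at uniform minor-allele
frequencies in [0.1, 0.5]; each cell observes a Poisson number of reads
spread uniformly over SNPs, with symmetric per-read allele errors and
50/50 doublets at a configurable rate.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: TAD/loop structure, cell-cycle and
replication effects, biological within-stage overdispersion (only sampling
noise separates cells of one preset), read-level artifacts, ambient
contamination in pools, and realistic chromosome-scale karyotype
differences. The generator validates the measurement machinery against
planted truth; it does not validate biological discovery power.

## Problem sizes and determinism

Test and acceptance cohorts use 100–250 cells at 20 000–50 000 contacts
per cell — sizes at which every calibrated statistic is measured to a few
parts per thousand while the full suite runs in well under a minute. All
randomness flows from integer seeds through `numpy` `SeedSequence`
spawning (one child stream per cell, so cohorts are reproducible and
order-insensitive); clustering and embedding are deterministic given the
data and seed, and the pipeline's output tables are byte-identical across
reruns of the same configuration.
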