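# Methods

## Overview

`popaf` analyses an admixed population through two complementary data
types: a large array-genotyped cohort (breadth) and a handful of deeply
sequenced genomes (depth). The array cohort yields a local allele-frequency
panel used to annotate and prioritize the WGS variants; population
structure estimated from the same cohort guides which individuals are worth
sequencing; concordance against the array validates the sequencing calls;
and a two-caller intersection yields conservative structural-variant sets.
Because the data such studies use are controlled-access, the package ships
a generator that emulates the full study design with known ground truth,
and all tests and acceptance checks run against that generator.

## Synthetic cohort model

Per locus *m* an ancestral allele frequency `p_m ~ Uniform(0.05, 0.95)` is
drawn; the bounds reflect array ascertainment (array loci are chosen to be
polymorphic) and keep every locus informative. Population AFs follow the
Balding–Nichols F-model,

    f_km ~ Beta( p_m (1−c)/c , (1−p_m)(1−c)/c ),

with divergence `c` acting as Fst (default 0.1, a realistic continental-
scale value; the admixture-recovery study uses 0.15). This is the standard
F-model and exactly the likelihood the supervised-admixture estimator
assumes. Per-sample admixture `q_i ~ Dirichlet(α)` with `α = 1_K` by
default — uniform on the simplex, emulating a gradient-continuum admixed
population rather than discrete clusters. Genotypes are
`g_im ~ Binomial(2, q_i·f_·m)`; loci are independent (no linkage
disequilibrium), entries are set missing independently at `missing_rate`
(default 0.01), and a fraction `known_fraction` (default 0.9725, i.e. 2.75%
novel) of loci belongs to the known-sites set. Alleles are ordered pairs of
distinct bases drawn uniformly, so palindromic (A/T, C/G) pairs occur at
their natural 1/3 rate and exercise the strand-confusion filter, and the
expected Ti/Tv of simulated SNVs is 0.5 (4 transition / 8 transversion
ordered pairs) rather than the ≈2.05 of real genomes.

All randomness derives from one global seed through named substreams
(seed + CRC32 of a key tuple feeding `numpy` `default_rng`), so adding an
output stream never perturbs existing draws and identical configs give
byte-identical files.

Per-sample VCFs contain the sample's non-hom-ref genotypes at array loci
plus `extra_loci` WGS-only variants (default 2,000 in the demo;
`indel_fraction` = 0.2 of the extras are indels, matching the ~80/20
SNP/indel split of human call sets). Injected discordance flips
het↔hom-alt among the emitted array-locus records only, so every corrupted
locus remains comparable and the expected concordance is exactly
`100·(1−rate)` — corruptions toward hom-ref would silently leave the
comparison set under intersection semantics and bias the statistic.

Structural variants are placed without overlap on one contig (70% DEL,
15% INV, 15% INS; DEL/INV spans 100–10,000 bp, INS sizes 50–1,000 bp),
reported by each caller with its sensitivity and Gaussian breakpoint
jitter (default sd 20 bp), and a `db_fraction` (default 0.865, i.e. 13.5%
novel) of true SVs populates the background database.

## Allele-frequency panel

`af = n_alt / (2·n_called)`, `an = 2·n_called`, missing genotypes excluded
from numerator and denominator; loci below `min_call_rate` (default 0.95)
or with zero calls are dropped with a logged count. AF is defined relative
to the panel's own declared ref/alt pair and strand; reconciling strand
against other resources is the concordance module's job. Multiallelic
array loci must be split upstream; the container enforces unique
(chrom,pos,ref,alt) keys.

## Z-score prioritization

The pooled two-proportion statistic on allele counts:

    p̄ = (p₁n₁ + p₂n₂)/(n₁+n₂)
    Z  = (p₁ − p₂) / sqrt( p̄(1−p̄)(1/n₁ + 1/n₂) )

No continuity correction is applied: the cutpoints (±1.96, ±4) are used
comparatively to tier variants, not for inference. Degenerate pooled
proportions (p̄ ∈ {0,1}) give Z = 0. Ties at a threshold fall into the
tail (≤/≥). Null calibration is verified at the study scale (1,000 local
vs 5,000 reference samples): the |Z| ≥ 1.96 rate lies in [4.2%, 5.8%] and
the |Z| ≥ 4 rate below 5·10⁻⁴.

Aggregation across reference populations defaults to `global` — the
panels are pooled by allele-count-weighted AF into one combined panel —
because a single well-defined comparison is the cleanest operating mode.
`strictest_vs_all` is provided for the reading where a variant counts as
deviating only against *every* reference population: all per-population Z
must share a sign, and the smallest magnitude governs; otherwise Z = 0.
Variants absent from the local panel are `unscored` and excluded from the
summary denominators. A reference panel record lacking AN falls back to a
configurable default of 251,496 alleles (a 125,748-sample,
gnomAD-exome-sized aggregate). Indels are scored only under exact
(chrom,pos,ref,alt) match; inputs are assumed left-normalized.

The summary table counts, per annotation category, the scored members and
the two Z tails; the bare local-AF category uses the strong threshold
(t = 4) while annotation categories (ClinVar non-benign, ClinVar
pathogenic/risk, SIFT deleterious, SIFT-or-PolyPhen deleterious, protein
altering) use t = 1.96, both exposed as configuration.

## QC metrics

Het counts genotype 0/1 (phase ignored), Hom counts 1/1; half-calls are
treated as missing. The Het/Hom denominator covers all biallelic records
by default (`het_hom_over="snp"` restricts to SNPs — the literature is
split on this and the choice is visible in the report). Ti/Tv is computed
over SNPs only, overall and split by exact-key membership in the
known-sites set. Unsplit multiallelic records are rejected with a counted
warning. The share partition keys variants by (chrom,pos,ref,alt) and
assigns every union member to exactly one presence subset (bitmask), so
cells sum to the union size by construction.

## Concordance

The filter cascade runs in a fixed order — missing array call, array
indel, multiallelic VCF record, palindromic array pair, allele
reconciliation — and every array locus lands in exactly one of
{dropped_*, compared, absent_from_vcf}. "Strand confusion" is
operationalized as (a) removing palindromic A/T and C/G loci, whose
orientation cannot be inferred from the alleles, and (b) accepting
complemented and/or ref/alt-swapped allele pairs for the rest, with
genotypes recoded `g → 2−g` under a swap — the standard practice when
merging array data of unknown strand convention. Array loci absent from
the VCF are excluded (intersection semantics), not assumed hom-ref, since
single-sample VCFs do not distinguish hom-ref from no-call. Agreement is
per diploid genotype by default; an allele-level mode counts shared
dosage out of two alleles. Zero comparable loci yields an explicit
`undefined` status rather than 0%.

## PCA and supervised admixture

Genotypes are standardized per locus by mean `2p̂` and scale
`sqrt(2p̂(1−p̂))` (p̂ from the reference cohort itself); missing entries
are mean-imputed, i.e. standardized zeros, which keeps projection linear.
Monomorphic loci are dropped and recorded in the model. The top-d
components come from the SVD of the standardized matrix; sign is fixed by
making each component's largest-magnitude loading positive, and
eigenvalues are reported as coordinate variances (sum of retained
eigenvalues equals total coordinate variance).

Supervised admixture maximizes the binomial likelihood of one genotype
vector with the population AF matrix **F** held fixed, by EM:

    q_k ← q_k/(2M′) · Σ_m [ g_m f_km / p_m + (2−g_m)(1−f_km)/(1−p_m) ],
    p_m = Σ_k q_k f_km,  M′ = #non-missing loci.

**F** is built from labeled reference panels and clipped to
[10⁻⁶, 1−10⁻⁶] (unclipped vertices produce zero/undefined EM weights).
The likelihood is concave in **q** for fixed **F**, so the uniform start
1/K matters only for ties; convergence is declared at a log-likelihood
gain below 10⁻⁷ or 2,000 sweeps, and the log-likelihood is nondecreasing
at every step (asserted in tests). A vectorized batch variant fits all
cohort samples at once with a total-log-likelihood tolerance — adequate
for descriptive cohort Q estimates; the demo pipeline runs it on a
4,000-locus subsample, which keeps the full run under a minute while
estimating Q to well under the tolerance that representative grouping
needs.

Representatives are chosen per group as the sample minimizing Euclidean
distance to the group centroid in the top-D PC plane (D = 2 by default,
the standard visualization plane); ties break by higher dominant-ancestry
Q, then lexicographic id. The centrality metric is this package's
explicit choice — "central in the subpopulation" admits several
formalizations and centroid distance in PC space is the simplest
defensible one.

## IBS distances and neighbor joining

`d(i,j) = 1 − Σ_m (2 − |g_im − g_jm|) / (2M_ij)` over mutually
non-missing loci: 0 for identical genotypes, 1 for opposite homozygotes.
Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion with the usual limb-length formulas; ties in Q break by node
index for determinism; negative limb lengths are clamped to zero with the
deficit moved to the sibling limb, preserving the pair's total. For any
additive matrix the recovered tree reproduces all path distances to
1e-9. Trees serialize to newick (rooted at an internal node, so the root
is a trifurcation as usual for unrooted NJ trees).

## SV intersection

Two same-type same-chromosome intervals match when the reciprocal overlap
`min(ov/len_a, ov/len_b)` reaches `ro_min` (default 0.5, the community
convention for database comparison). Insertions are points, so they match
by breakpoint distance ≤ 100 bp and size ratio ≥ 0.5 instead. Matching is
one-to-one greedy by descending score with ties broken by smaller start —
deterministic and near-optimal at realistic call densities (verified
equal to an independent all-pairs matcher on simulated sets); optimal
bipartite matching was deliberately not used. The consensus interval is
the union of the two supports. Novelty uses the same criterion against
the background database. Coordinates are 0-based half-open internally;
readers accept 1-based inclusive input via a dialect flag, and the
symbolic-ALT VCF writer anchors POS at the base preceding the event.

## Pipeline

One YAML config drives all stages; ranges are validated (and any
user-supplied input paths checked for existence) before any stage runs,
and a failing stage aborts with its name. The manifest records per-stage
parameters and sha256 hashes of outputs with outdir-relative paths, so
two runs with the same config and seed produce identical manifests —
asserted in tests. Demo problem sizes (200 samples × 20,000 loci, 2,000
WGS extras, 200 true SVs, 5,000-sample reference panels) were chosen as
the smallest scale at which every statistical check is comfortably
powered.

## What the synthetic data does not show

Passing tests demonstrate correctness of the statistics and algorithms
under the generator's assumptions; they do not certify behaviour on real
data with linkage disequilibrium, genotyping batch effects, reference
bias, indel representation ambiguity (no left-alignment is performed),
sex chromosomes, caller-specific SV artifacts, or Ti/Tv profiles of real
mutation spectra. The generator's uniform allele pairs deliberately
produce Ti/Tv ≈ 0.5, so the QC module's known/novel Ti/Tv split is
exercised numerically but at a non-biological operating point. Array
genotypes and WGS calls share a coordinate system by construction;
build-mismatch detection and liftover are out of scope.
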