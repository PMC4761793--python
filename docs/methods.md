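# Methods

## Data model and the inbred assumption

The package operates on individuals × markers tables of dominant binary
calls: band present (1), absent (0) or missing. Dominant assays cannot
separate heterozygotes from dominant homozygotes; for panels of inbred
lines (selfing crops such as bread wheat) heterozygosity is negligible, so
the band-presence frequency *f* at a locus is interpreted directly as the
allele frequency. This assumption is declared once in the data model and
inherited everywhere — no Hardy–Weinberg √-of-null-frequency correction for
outbred dominant data is offered.

Group structure is carried as per-individual labels at up to two levels
(e.g. breeding program or country, nested inside region). The nesting is
validated: a level-1 group may not span regions.

## Marker quality control

Four filters in a fixed, logged order:

1. **quality** — keep markers with assay quality Q strictly above `min_q`
   (default 80). "Above" is read literally: Q = 80 is removed.
2. **missingness** — remove markers missing in ≥ `max_missing_frac`
   (default 0.10, boundary removed).
3. **MAF** — remove markers with min(f, 1−f) < `min_maf` (default 0.05,
   boundary retained), f computed over non-missing calls. Markers with no
   scored call are removed here and reported under a separate key.
4. **correlation thinning** — one greedy pass in input order dropping any
   marker whose |Pearson r| with an already-retained marker exceeds
   `max_abs_r` (default 0.95), r computed over individuals scored for
   both. Keeping the *earlier* marker makes the pass deterministic;
   zero-variance pairs have undefined r, treated as 0 with a warning.

All boundary conventions are parameters; the defaults encode the common
literal reading of the thresholds. The chain order itself (quality →
missingness → MAF → correlation) is a package choice — sources for such
pipelines rarely state it — and is enforced so that filter reports always
reconcile against a single declared sequence.

## Diversity indices

Per locus, with q = 1 − f: Sh = −(f log f + q log q) (0·log 0 ≡ 0),
Ne = 1/(f²+q²), He = 1 − f² − q², PIC = 1 − (f²+q²) − 2f²q². Bounds for a
biallelic locus: Sh ≤ log 2, Ne ≤ 2, He ≤ 0.5, PIC ≤ 0.375, all attained at
f = 0.5 and all zero (Ne = 1) iff the locus is monomorphic.

The Shannon log base defaults to **2**, under which Sh ∈ [0, 1] on
biallelic data — the scale on which published dominant-marker diversity
tables with Sh ≈ 0.8 at He ≈ 0.375 are internally consistent (natural logs
would cap well below such pairs of values). The base is a parameter.

Group summaries report %P (share of analyzed markers with both states
observed in the group), means of the four indices over loci, and the
rarity index. Means include loci monomorphic within the group
(contributing 0, or 1 for Ne) by default; `include_monomorphic=False`
restricts to within-group polymorphic loci, since published tables do not
always state which convention they use. Loci with no scored call in a
group are excluded from that group's means.

**Rarity index.** RI_j = (1/I) Σ_i p_ij / P_i, the mean over loci of the
group frequency divided by the whole-panel frequency. Markers absent from
the whole panel (P_i = 0, possible in subsets after filtering) are skipped
with I reduced, rather than raising. Without missing data
Σ_j n_j p_ij = N P_i exactly, so the size-weighted mean of RI over any
partition is 1; missingness perturbs this identity only slightly, which
the test suite exploits as an invariant.

**Group comparison.** Published analyses of per-locus index differences
often use repeated-measures ANOVA; this package instead ships a
**locus-paired permutation test** targeting the same null (no group effect
given locus): the observed statistic is the mean over loci of the
within-locus difference, and the null distribution flips the group
assignment independently per locus. The permutation analogue is
distribution-free and honest for the strongly non-normal per-locus index
distributions; pairwise p-values are Bonferroni-multiplied by the number
of pairs. This substitution is deliberate and documented here.

## Distances and trees

**Dice dissimilarity** for a pair, over loci scored in both:
D = 1 − 2a/(2a+b+c) with a the shared presences and b, c the one-sided
presences. D ∈ [0,1], D(x,x) = 0, symmetric; the triangle inequality is
*not* guaranteed and not asserted. A pair with no jointly scored locus is
an error (a complete matrix is required downstream); a pair with no
presences at all gets D = 0 with a warning.

**Neighbor-Joining** follows Saitou–Nei agglomeration. Determinism: ties
in the Q criterion resolve to the pair with the lowest original input
indices. Negative branch-length estimates are clamped to zero with the
deficit moved to the sister edge, preserving the joined pair's path
length. On distances that are exactly additive, the source tree's topology
and all leaf-to-leaf path lengths are recovered at machine precision
(tested on 4- and 5-taxon trees).

**UPGMA** uses size-weighted average-linkage updates (distances between
clusters stay arithmetic means over original leaf pairs), node heights at
half the merge distance, the same lowest-index tie rule; output is always
ultrametric.

**Bootstrap support** resamples marker *columns* with replacement — the
natural resampling unit for a fixed panel of individuals — rebuilds the NJ
tree per replicate, and reports for each internal edge of the
point-estimate tree the percentage of replicates containing the same leaf
bipartition (canonicalised so rooted/unrooted encodings compare equal).
Support values are stored as internal node labels in Newick output.

## AMOVA

The squared inter-individual distance is the raw mismatch count over
jointly scored loci (the squared Euclidean distance for binary vectors).
It is deliberately *not* rescaled to a common locus count under
missingness — matching the conventional treatment of binary data — though
a rescaling option exists.

For a set S, SSD(S) = (1/|S|) Σ_{i<j∈S} d²(i,j). One level: SSD(total) =
SSD(among) + SSD(within); with G groups of sizes n_g (N total),

    σ²_w = SSD(within)/(N−G)
    n′  = (N − Σ n_g²/N)/(G−1)
    σ²_a = (SSD(among)/(G−1) − σ²_w)/n′
    Φ_ST = σ²_a/(σ²_a + σ²_w).

n′ is the method-of-moments effective group size: E[MS_among] =
σ²_w + n′σ²_a for unequal n_g, reducing to n_g when sizes are equal.

Two levels (R regions, G groups nested inside): SSD(within regions) splits
into among-groups-within-regions and within-groups terms, and with

    n1 = (N − Σ_r Σ_{g∈r} n_g²/n_r)/(G−R)
    n2 = (Σ_r Σ_{g∈r} n_g²/n_r − Σ_g n_g²/N)/(R−1)
    n3 = (N − Σ_r n_r²/N)/(R−1)

σ²_c = MS(within), σ²_b = (MS(groups in regions) − σ²_c)/n1, σ²_a =
(MS(regions) − σ²_c − n2·σ²_b)/n3, giving Φ_CT = σ²_a/σ²_tot, Φ_SC =
σ²_b/(σ²_b+σ²_c), Φ_ST = (σ²_a+σ²_b)/σ²_tot. The degenerate one-group-per-
region design collapses σ²_b to 0 by convention, with Φ_CT equal to the
one-level Φ_ST.

Negative variance components are reported as estimated — the
method-of-moments estimator legitimately goes below zero when the true
component is near zero — and percentages of total variance are taken over
the signed total.

**Permutation tests** use the scheme proper to each statistic: Φ_ST
permutes individuals among groups over the whole panel; Φ_SC permutes
individuals among groups within their region; Φ_CT permutes whole groups
among regions (group sizes preserved). p = (#{Φ_perm ≥ Φ_obs}+1)/(n_perm+1),
so p > 0 always; the default n_perm is 10,000. For small panels an exact
mode enumerates every distinct arrangement of the label multiset and
reports #{≥ obs}/#arrangements; the Monte-Carlo p converges to it (both
are exercised in the tests).

Pairwise Φ_ST entries are full one-level AMOVAs on each two-group
submatrix; negative entries are retained in the table and clipped at zero
only when the matrix doubles as a distance input to UPGMA.

## Factorial correspondence analysis

Dominant 0/1 tables are **doubled** before CA — a presence and an absence
column per marker — so row sums are constant (equal row masses) and
absences carry inertia symmetrically; this reproduces the classical FCA
treatment of dominant genotype data. A raw single-column CA is available
behind a flag. Missing calls are mean-imputed per marker beforehand (with
a warning); the true behaviour of legacy FCA software on missing dominant
calls is undocumented, so the policy is explicit and parameterised here.
The decomposition is the SVD of the standardized residuals
(P − rcᵀ)/√(rcᵀ); axis inertias are squared singular values, percentages
are over all non-null axes (they sum to 100), and individuals are reported
in principal coordinates with group barycentres as unweighted member
means. Numerical rank is cut at max(machine-eps-scaled, 1e−12) singular
values.

## Clustering post-processing

ΔK(K) = |mean lnP(K+1) − 2 mean lnP(K) + mean lnP(K−1)| / sd(lnP(K)),
defined on interior K of a contiguous range with ≥ 2 runs per K. A zero
between-run sd leaves ΔK *undefined* at that K (reported NaN), not
infinite. ΔK is invariant to shifting all lnP and scales as 1/c when the
run sd scales by c.

Per-individual admixture is the Shannon entropy of the membership row;
log base defaults to **10**, the scale on which published group-level
entropies of ~5-cluster membership vectors (e.g. Sh ≈ 0.58 for a mean row
dominated by proportions 0.46/0.29) are consistent — natural logs would
more than double them. The choice is a parameter, and the headline
within/among split is base-invariant in any case: within% =
100·Sh_mean/Sh_total, among% = 100 − within%, with Sh_total the entropy of
the group-mean row and Sh_mean the mean member entropy. Concavity of
entropy guarantees Sh_mean ≤ Sh_total, with equality iff all member rows
are identical; Sh_total = 0 (everyone fully assigned to one common
cluster) leaves the percentages undefined (NaN).

Membership classes by the largest row entry: strictly above 0.90 →
representative; in [0.75, 0.90] → intermediate; below 0.75 → mixed. The
boundary placement (0.90 and 0.75 both fall to intermediate) follows a
strict reading of "more than 90%" and an inclusive "between 75 and 90";
both thresholds are parameters.

## Synthetic data

The generator exists so that every method has inputs with known truth.

Markers follow the **Balding–Nichols** model: ancestral frequency
p ~ Beta(a,b) per locus (default a = b = 0.8, a mildly U-shaped spectrum
typical of ascertained array markers), population frequency
p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with mean p and variance F·p(1−p), so
the generator's F is, in expectation, the Φ_ST-scale differentiation that
AMOVA estimates. Balding–Nichols was chosen over a coalescent island
model precisely because it parameterises the quantity the estimator
targets; the F ↔ Φ̂_ST mapping is nevertheless approximate (ascertainment,
finite loci, MAF spectrum), so recovery is tested as an interval
([0.2, 0.4] at F = 0.3), never a point. A nested variant draws region
frequencies first (region-level F), then population frequencies within
regions (smaller F), so two-level AMOVA should find Φ_CT > Φ_SC.
Individuals are inbred: one Bernoulli draw per locus at the
ancestry-mixed frequency; optional Dirichlet admixture mixes population
frequencies within an individual. Missing calls are masked uniformly.

Q matrices are Dirichlet rows with per-group concentration and optional
cluster bias; likelihood tables are piecewise-linear mean curves with a
slope knee of `knee_size` at K_true plus Gaussian run noise.

Presets mirror the two study shapes the analysis scripts use: "cbp"
(two programs, 63 + 26 individuals, 1,229 loci, F = 0.06 — the scale of
differentiation typical between sister breeding programs) and "ebp"
(seven countries of 89/22/214/99/11/10/78 individuals in two regions, 166
loci, region F = 0.16 over country F = 0.04, echoing a strong
regional split over weak within-region structure). Both default to 2%
missing calls.

What the generator does **not** emulate: linkage along chromosomes
(markers are independent), ascertainment against the reference panel,
genotyping error, temporal structure within programs, and real MCMC
behaviour of clustering software (the likelihood curves are a stylised
stand-in). Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to those real-data
features.

All generators are pure functions of (spec, seed) via
`numpy.random.default_rng`, giving bit-identical output across runs and
platforms.

## Problem sizes in the test and acceptance runs

The statistical suites run at deliberately modest sizes chosen for tight
Monte-Carlo control at interactive runtimes: null calibration uses 500
replicates of 2 × 30 individuals × 300 loci with 200 permutations
(rejection rate at α = 0.05 expected in [0.03, 0.07]); recovery uses 30
replicates per F level; oracle equivalence uses 200 random designs of ≤ 8
individuals checked to 1e−10 against direct SSD evaluation, plus a
99,999-permutation Monte-Carlo vs exhaustive-enumeration comparison;
tree, FCA and index checks are exact at machine-level tolerances.

## Known limitations

- Dominant-marker frequencies are taken at face value (inbred panels
  only); outbred dominant data would need a different estimator.
- The AMOVA implementation covers the binary/haplotypic case without a
  within-individual stratum.
- NJ/UPGMA tie-breaking and negative-branch policy are principled but not
  the only conventions in circulation; exact topologies from other
  software may differ on tied or non-additive inputs.
- Pairwise Φ_ST p-values are not multiplicity-adjusted in the matrix
  itself.
- FCA missing-call imputation is a pragmatic policy, not a reconstruction
  of any particular legacy implementation.
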