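# Methods and design notes

This note records the statistical conventions, default parameters and
deliberate design choices behind `oleakit`, in the spirit of the
methods documentation of packages such as statsmodels or scanpy.  It
states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and file conventions

All tables are plain delimited text with `,` or `;` separators
(auto-sniffed, overridable); decimal commas are rejected with an
explicit error rather than silently misparsed.  Genotype tables use
the wide, GenAlEx-style layout — two columns per locus, allele sizes
in bp — with a long-format importer as alternative.  A genotype call
is atomic: if either allele of a locus is blank the whole call is
missing, because a lone size cannot distinguish a homozygote from a
half-call.  Alleles are stored sorted (a1 ≤ a2).

Dendrograms export to Newick under the **midpoint (cophenetic)
convention**: a node created at merge height *h* sits at height *h*/2,
so the path length between two leaves equals the height at which they
merge.  This is the convention that makes the tree's cophenetic
distances reproduce the linkage heights; it is stated here because
alternative conventions (leaf-to-root = root height) exist and differ
by a factor of two.

Geographic output uses GeoJSON rather than shapefiles.  Coordinates
are written as-is in projected UTM metres; to overlay on web maps,
reproject to WGS84 with any GIS tool (e.g. `ogr2ogr -t_srs EPSG:4326`).

## Per-locus diversity indices

For a locus typed in N samples, frequencies are counted over the 2N
allele draws.  He uses the uncorrected estimator 1 − Σf²; uHe carries
the 2N/(2N−1) factor; both are reported separately because both are
conventional.  Ne = 1/Σf².  The null-allele estimator is Brookfield's
first formula r = (He − Ho)/(1 + He), clamped at zero — appropriate
when no separate null-homozygote class was scored; it is monotone in
the He−Ho gap and equals 0 whenever Ho ≥ He.

### Hardy–Weinberg exact test (Monte Carlo)

The test statistic is the conditional probability of the observed
genotype array given the allele counts,

P(array | counts) = N! 2^h Π_a n_a! / ( (2N)! Π_g n_g! ),

with h the heterozygote count.  The null is simulated by re-pairing
the 2N-allele vector uniformly at random (a uniform draw over perfect
matchings); p = (1 + #{pairings with P ≤ P_obs}) / (n_perm + 1).  Only
the terms that vary under re-pairing (h log 2 − Σ_g log n_g!) are
computed, vectorised over permutation chunks, so 100,000 permutations
on ~170 samples take seconds.  The default permutation count is
100,000; the test suite uses 10³–10⁴ for speed.  A monomorphic locus
returns p = 1 with a warning.  Tests verify the Monte-Carlo p against
full enumeration of all perfect matchings at n ≤ 6 and its uniformity
under data simulated in equilibrium.

Pgen multiplies f² (homozygous loci) or 2ff′ (heterozygous) across a
sample's typed loci; untyped loci contribute factor 1 and are listed
in the result.  Frequencies are pooled over the whole table by
default, with a per-site option (`pgen_by_site`), since clone
collections are usually screened within sites.

### Clone detection

Samples are grouped into multilocus genotypes by single-linkage over a
pairwise match relation: two samples match when, over loci typed in
both, at most `max_mismatch_loci` loci differ, a locus agreeing when
both sorted alleles are within `allele_tolerance_bp`.  The tolerance
default is 0 (exact identity); a tolerance of 2–3 bp treats somatic
variants of one genet as the same genotype.  Tolerance matching is not
transitive, so transitive closure (union-find) defines the genets; a
chain of tolerated variants therefore forms one genet by design.

## Genetic distances and trees

The binary allele matrix has one column per observed (locus, allele)
pair; untyped loci are masked (NaN), never coded 0.  Dice–Sørensen
similarity is computed over mutually typed columns
(pairwise-complete), so a sample missing most loci remains placeable.
The genetic distance defaults to d = √(1−s): the square-root transform
makes Dice dissimilarities Euclidean-embeddable, which suits Ward
linkage; plain 1−s is available by flag since the linear form is also
in common use.

Ward trees use the Ward.D2 Lance–Williams update on the given
dissimilarities (scipy's `linkage(..., "ward")`), deterministic given
input order.  Identical profiles (clones) merge at height 0 first.

Model-based admixture inference (STRUCTURE-like MCMC) is out of scope;
the package consumes its outputs: a Q-matrix is reduced to hard
memberships by row argmax (ties to the lowest column index, with a
warning), and Evanno's ΔK(K) = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) is
computed from replicate log-likelihoods, excluding any K whose
replicates are constant (sd = 0) with a warning.

## Nonparametric trait pipeline

α = 0.05 throughout by default.  Levene's test is mean-centred as
originally defined (`center="median"` gives Brown–Forsythe).
Kruskal–Wallis uses the tie-corrected H with χ²(k−1) p-values.  The
post-hoc grid follows Siegel–Castellan: pair (i, j) is significant
when |R̄ᵢ − R̄ⱼ| exceeds z(α/(k(k−1))) √(N(N+1)/12 (1/nᵢ + 1/nⱼ)); no
additional multiplicity correction is applied across variables (the
per-pair z already carries the within-variable correction), matching
the T/F-grid reporting style of field surveys.

MUFA/PUFA classifies the ten assayed acids chemically: MUFA =
{C16:1, C17:1, C18:1, C18:1t, C20:1}, PUFA = {C18:2, C18:3};
saturated acids (C16:0, C20:0, C22:0) belong to neither.  Zero-PUFA
samples yield +inf with a warning and should be excluded from
summaries.

## Multivariate block

PCA centres and, by default, unit-scales variables — fatty-acid
abundances span four orders of magnitude (0.01–80%), and unscaled PCA
would be an oleic-acid axis.  A flag disables scaling.  Signs are
fixed by making each component's largest-magnitude loading positive.
Missing values are refused, not imputed.

PAM implements BUILD (greedy seeding from the most central point) and
best-improvement SWAP, ties to the lowest sample index.  BUILD+SWAP is
a local search; on instances with n ≤ 25 the search deterministically
restarts from every sample as the BUILD seed and keeps the best
solution, which in measured practice returns the exhaustive optimum on
all tiny instances (the single-start variant, like the reference R
implementation, reaches it on only ~90% of random 5 ≤ n ≤ 8 draws).
Above n = 25 a single standard BUILD is used for cost.  k = 1 is
allowed (the medoid minimising total dissimilarity) so the same
clusterer serves the gap statistic's null curve.

The gap statistic uses within-cluster dispersion
W_k = Σ_r (1/2n_r) Σ_{i,i'∈C_r} d²(i,i') (squared Euclidean, the
original formulation; note some implementations default to unsquared
distances), B = 50 uniform reference draws over the observed
per-feature ranges, s_k inflated by √(1+1/B), and the first-SE-max
rule: the smallest k with gap(k) ≥ gap(k+1) − s_{k+1}.  B = 50 is a
compromise between reference noise and runtime; the whole curve is
reproducible from the seed.

Silhouette widths come from the precomputed-distance path of
scikit-learn; singleton clusters receive width 0 by convention.

## Distance integration and the Mantel test

Geography and morphometrics use Euclidean distance (geography on raw
UTM metres — projected coordinates make this a distance in metres;
morphometrics on raw units by default with a z-scaling flag, since
grams and cm² are heterogeneous).  Fatty acids use Canberra distance,
whose per-variable normalisation makes a trace-level acid absent in
the other sample contribute a full unit — the desired biomarker
emphasis; 0/0 terms contribute 0.  SSR profiles use the Dice–Sørensen
distance above.

The Mantel statistic is the Pearson correlation of the n(n−1)/2
upper-triangle entries; significance is one-tailed for positive
association, p = (1 + #{r* ≥ r}) / (n_perm + 1) over seeded joint
row/column permutations of the second matrix.  The default is 100,000
permutations; desk-scale runs (tests, CLI default) use 10,000 or
fewer.  The whole all-pairs report is bit-reproducible from one seed.
A genets-only subset (samples belonging to genotypes with at least a
configurable number of clones) supports the common comparison of the
full collection against well-replicated genets.

## Synthetic survey generator

The generator emulates the structure of a four-site survey of ancient
Campanian olive trees; its defaults are the study conditions, not
tuning knobs:

- sites CE/CM/OIR/OSE with 62/33/48/26 trees (169 total); site
  centroids on a UTM 33T-like grid with 1.5 km isotropic within-site
  spread;
- six SSR loci with the published pooled allele-frequency profiles
  (9–13 alleles per locus, 64 in total).  Per-site profiles tilt the
  pooled frequencies toward different parts of each locus's
  allele-size spectrum (`site_differentiation`, default 3), creating
  geographic genetic structure while keeping the pooled profile close
  to the input;
- non-clonal genotypes drawn under within-site Hardy–Weinberg; a
  `clone_fraction` (default 0.55, matching ~45% unique genotypes) of
  each site's trees copies an earlier tree of the same site, with
  probability 0.1 of one somatic variant — a shift of one allele to a
  neighbouring pool allele ≤ 3 bp away, so variants stay inside the
  inventory;
- 3% missing locus calls (whole-call missingness), matching typed-N
  between ~150 and ~168 of 169;
- fatty-acid rows: published site means + truncated Gaussian noise at
  the published sds, renormalised to the site's mean total, with
  structural zeros (acids absent from a site) held at exactly 0;
- morphometrics: published site means + Gaussian noise, optional
  within-site northing gradient.

With `ensure_allele_coverage` (default on), any configured allele the
random draw left unobserved is planted once into a typed, clone-free
founder: the configured pool plays the role of the survey's *observed*
allele inventory, which by construction contains every listed allele.
Calibration checks (HWE uniformity, per-site frequency recovery)
disable coverage and cloning to test the pure equilibrium regime.

Two named variants support specific analyses: `three_profile_config`
gives OSE exactly OIR's oil profile (three biochemical profiles across
four sites — the regime where the gap statistic should choose k = 3
while sites number 4), and `strong_separation_config` doubles every
site's contrast from the across-site mean profile (renormalised,
structural zeros kept), quarters the within-site sds and strengthens
genetic differentiation — the regime for end-to-end recovery checks
(PAM on two PCs vs true sites, geography–oil Mantel).

### What the generator does not emulate

Real fatty-acid compositions are compositional data with a full
covariance structure; the generator uses independent truncated
Gaussians plus renormalisation, not logistic-normal machinery.  SSR
mutation follows no stepwise model; clones are copied verbatim.
Coordinates are isotropic Gaussian around centroids, not road- or
terrain-constrained.  Passing tests on synthetic data therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not field validity of any biological conclusion.

## Degenerate inputs and numerical conventions

Monomorphic loci: HWE p = 1 with warning; He = 0.  All-missing loci
raise.  Samples untyped at every locus become singleton genets with a
warning.  Constant vectors raise in Shapiro–Wilk and Spearman; fully
tied Kruskal–Wallis returns H = 0, p = 1 with a warning.  Constant
distance matrices make Mantel r undefined and raise.  Distance-matrix
constructors enforce symmetry, zero diagonal and non-negativity at
1e-8 tolerance and symmetrise the tiny float asymmetry of computed
inputs.  All Monte-Carlo p-values use the (1 + hits)/(n + 1)
convention, so p ≥ 1/(n_perm + 1) always.

## Problem sizes used in the shipped checks

The test suite runs the full 169-tree pipeline where it is cheap
(generation, clone detection, Ward trees) and desk-scale sizes for
permutation-heavy oracles: HWE enumeration at n ≤ 6, Mantel
enumeration at n = 4, PAM brute force at n ≤ 8, HWE calibration with
150 replicates of a 50-tree site at 1,000 permutations, Mantel
calibration at 199–999 permutations.  The API defaults remain at the
survey-scale 100,000 permutations.
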