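# Methods

This note records the models implemented in `aflpop`, the defaults and
their units, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Data model

Dominant markers are coded as haploid Bernoulli characters: one band
observation per locus per individual, band probability equal to the
population band frequency.  This is a deliberate simplification of AFLP
dominance (a band is really "at least one dominant allele" of a diploid
genotype).  The alternative Hardy–Weinberg square-root correction
(allele frequency p = 1 − √(1 − band frequency)) is available wherever
allele frequencies are estimated (`freq_model="zygotic_sqrt"`, the
default for per-locus FST reports); the clustering and simulation code
use the haploid coding throughout so that generator, scans and admixture
model share one likelihood.  Consequences: absolute FST values on
band-frequency and allele-frequency scales differ somewhat (their
rankings correlate at ρ ≈ 0.8–0.95), and all calibration tests pair each
scan with a simulator using the *same* coding.

## Synthetic flock generator

Species band frequencies follow the Balding–Nichols parameterisation:
for ancestral frequency p and target differentiation F, species
frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F), which has mean p and
variance F·p(1−p) — i.e. Wright's FST equals F by construction.
Defaults describe a six-species crater-lake flock: sample sizes
(18, 21, 20, 20, 19, 22), 2297 loci, 2% of loci at F = 0.5 against a
neutral background of F = 0.10, seven introgressed individuals of the
open-water species carrying four fixed private bands, and per-species
sudden-expansion histories (τ, θ₀, θ₁) matching the fitted values for
the six species (e.g. τ = 1.4, θ₀ = 0.032, θ₁ = 2.95 for the benthic
species with 76 sampled sequences).  Ancestral frequencies are uniform
on (0.1, 0.9).

Hybrids draw each band independently from the ancestry-weighted mixture
of parental frequencies (F1 = ½/½, one grandparent = ¼/¾) — no linkage,
mirroring how unlinked dominant loci are treated throughout.  The
introgressed subgroup's private bands are planted exactly (a guard
redraws any other locus that would by chance be fixed-private to the
subgroup, so construction checks are exact).  mtDNA for all species
derives from one shared ancestral haplotype, each species accumulating
its own expansion-era mutations; this reproduces the star-like
central-haplotype pattern of very young radiations.  What the generator
does *not* emulate: linkage disequilibrium, scoring error/band
homoplasy of real AFLP gels, within-species geographic structure, and
shared ancestral polymorphism beyond the single common haplotype.
Passing tests therefore demonstrate statistical correctness of the
methods under their own assumptions, not robustness to AFLP scoring
artefacts.

## Coalescent and mismatch model

Sequences are simulated under Hudson's coalescent with one instantaneous
size change, with time in mutational units (τ = 2ut): coalescence rate
k(k−1)/2/θ₁ more recently than τ and /θ₀ beyond, mutations Poisson with
rate ½ per unit branch length, infinite sites on L positions (an error
is raised rather than re-using a site).  θ₀ = 0 collapses the remaining
lineages into a star at τ.  At equilibrium E[π] = θ (verified against
msprime as an independent oracle).

The expected mismatch distribution has the closed form

    F_i = Fhat_i(θ₁) · P(i+1, (1+1/θ₁)τ)
        + e^{−(1+1/θ₁)τ} Σ_{j≤i} Fhat_{i−j}(θ₀) τ^j / j!

with Fhat_i(θ) = θ^i/(1+θ)^{i+1} and P the regularised lower incomplete
gamma function, derived by integrating the Poisson mixture over the
pair-coalescence time.  Limits: τ = 0 → θ₀-equilibrium; θ₀ = θ₁ →
geometric for all τ; θ₀ = 0 → Poisson(τ).  Monte-Carlo agreement with
the simulator is within total-variation 0.005 at 2×10⁴ replicates.

Fitting minimises the SSD between observed and expected relative
frequencies over classes 0..max observed: a coarse grid (τ, θ₀, θ₁)
followed by Nelder–Mead, with θ₁ capped at 99999 (the conventional
printed cap) and the cap flagged.  Because the model is τ-invariant when
θ₀ = θ₁, an infinitesimal penalty (10⁻⁸·τ) breaks exact ties toward
τ = 0.  The goodness-of-fit p is a parametric bootstrap (default 1000
replicates; simulate n sequences under the fitted model, refit with the
coarse grid, compare SSDs).  Known limitation: τ and θ₁ trade off along
a likelihood ridge, so for moderate expansions the SSD minimiser may cap
θ₁ and absorb diversity into a smaller τ; τ is reliably identified only
for strong expansions (θ₁ ≫ θ₀, τ below the sample's resolution limit).
The parameter-recovery check therefore runs in the strong-expansion
regime (τ = 0.7, θ₀ = 0, θ₁ = 99999, n = 76, 100 datasets; median τ̂
within 10% of truth).  Rate conversion uses t = τ/(2u) with the
per-sequence rate u = μ_site·L/10⁶ per year (μ_site in substitutions
per site per MY per lineage).

## Trees and hybridization diagnostics

Distances: Jaccard d = 1 − a/(a+b+c), band-sharing (Dice/Link)
d = 1 − 2a/(2a+b+c), and the simple mismatch proportion.  The
band-sharing form is the one dominant-marker tree software customarily
offers; since 2a/(2a+b+c) ≥ a/(a+b+c), d_link ≤ d_jaccard always.  Pairs
sharing no scored band are an error for the similarity-based measures.

Neighbor-joining is the standard Saitou–Nei agglomeration with
deterministic tie-breaking (first minimum of the Q-matrix in row-major
order) and negative branch lengths clamped to zero with the deficit
moved to the sibling (the pair sum is preserved).  Verified against an
additive-matrix oracle and against scikit-bio's implementation on random
matrices.  Bootstrap resamples loci (columns), never individuals.

Leaf stability is the quartet-frequency mean: for each quartet
containing the taxon, the frequency of its most common resolution across
bootstrap trees, averaged.  (Other published variants — maximum
difference, entropy — exist; the frequency mean is implemented.)
Lineage movement classifies each bootstrap tree by whether the query
group is monophyletic and, if so, whether some bipartition side S with
query ⊊ S ⊆ query ∪ reference exists ("inside"); non-monophyly is
reported separately as "dispersed", and sister-group compositions are
tabulated.  The homoplasy-excess scan reports, per removal set, each
tracked clade's support before (plain bipartition of the full bootstrap,
so a hybrid nesting inside a clade destroys its monophyly) and after
(restricted to retained taxa on the reduced-matrix bootstrap); clades
can be supplied explicitly so species monophyly is tracked even when the
full-matrix tree does not show it.

## Median-joining networks

Haplotypes collapse by identity at unmasked sites; gaps are a fifth
character state by default (the convention for control-region data), or
missing data, in which case identity is closed transitively.  The
network construction iterates: ε-relaxed minimum spanning network
(Kruskal grouped by weight level, so all minimum spanning trees are
contained; deterministic tie order), quasi-median addition for triples
sharing a network neighbour (per-site majority; three-state sites expand
combinatorially and are capped at 729 variants per triple), and pruning
of inferred nodes with degree < 3.  ε = 0 by default with uniform
character weights.  Verified against a brute-force minimal Steiner tree
on small cases.

## AMOVA and F-statistics

One-level AMOVA on squared inter-individual distances (Excoffier-style
sums of squares, variance components via expected mean squares with
n′ = (N − Σn_g²/N)/(G−1)).  Pairwise statistics are two-group AMOVAs of
the same form: with band-difference counts as squared distances this is
the pairwise-difference FST; with squared Jaccard-transformed distances
it is the Φ_ST variant.  Permutation tests shuffle individuals among
groups (default 10,100 permutations, p = (b+1)/(m+1)); pairwise p-values
are sequential-Bonferroni (Holm) adjusted.  Negative variance-component
estimates are reported unclamped; a zero-total-variance comparison is
defined as 0 with a warning.  For mtDNA the distance matrix can be built
either from pairwise nucleotide differences (the distance-weighted
variant, primary) or from haplotype identity (0/1), which reduces the
statistic to haplotype frequencies only.

## Outlier scans

FDIST-style: the baseline FST is the multi-locus ratio-of-summed-
variance-components estimator (far less biased than averaging per-locus
ratios; the trimmed variant drops 30% of loci at each FST tail first).
Neutral loci are simulated under the Balding–Nichols island model at the
baseline F with uniform ancestral frequencies, binomial sampling at the
observed per-species sample sizes, and the same estimator as the data;
flagging is one-sided above the conditional (1−α) FST quantile within
heterozygosity bins (20 quantile bins).  Type-I error is calibrated to
within the binomial interval of nominal α on neutral simulations.

Bayesian: band counts per species and locus follow a beta-binomial with
ancestral frequency q_l and differentiation F_lj, where
logit(F_lj) = δ_l·α_l + β_j.  Priors: α_l ~ N(0, 2²), β_j ~ N(−1, 1.8²),
δ_l Bernoulli with even prior odds (so BF > 100 and posterior
probability > 0.99 select the same loci — Jeffreys' "decisive").
Sampling is Metropolis-within-Gibbs, vectorised across loci, with
inactive α_l refreshed from the prior so that indicator flips are valid
Gibbs-variable-selection moves.  Desk defaults (2000 burn-in, 8000
iterations, thinning 5) finish in ~2 minutes on 2000 loci × 6 species.
There is no reference implementation in the environment; the scan is
validated by simulation (≥ 8/10 planted strong outliers recovered, all
outliers with realized FST > 0.35, false-positive rate < 1%) and by
concordance with the FDIST-style scan on strongly divergent loci.

## Admixture model

STRUCTURE-style Gibbs sampler on haploid bands with correlated allele
frequencies: p_kl ~ Beta(p_Al(1−F_k)/F_k, (1−p_Al)(1−F_k)/F_k) with
per-cluster drift F_k; per-individual ancestry Q_i ~ Dirichlet(α);
latent per-locus origins z_il.  α, λ (the ancestral-frequency shape),
p_Al and F_k are updated by Metropolis steps.  Model evidence per run is
estimated from the post-burn-in log-likelihood trace as
mean(L) − var(L)/2 ("LnP(D)"); ΔK is the absolute second difference of
mean LnP(D) over K divided by its replicate SD.  Cluster frequencies are
initialised from the band profiles of K randomly chosen individuals per
replicate — data-informed, replicate-specific starting points that cut
the burn-in needed at desk scale without changing the stationary
distribution.  Runs whose kept-trace linear drift exceeds 2 trace-SDs
are flagged non-converged (the screening that replaces visual
log-probability plots).  Desk-scale defaults are 5k burn-in / 10k kept
sweeps / 5 replicates; the acceptance checks use 400/1200/3, which the
fixed-seed runs show is sufficient at their information level.

The ancestry test uses plug-in species frequencies (posterior means with
a Jeffreys prior, leave-one-out for the focal individual) and evaluates
the hypothesis set {pure} ∪ {ancestor at generation g from species s},
g ≤ 2.  Prior mass ν sits on the non-pure hypotheses, split over
generations proportionally to 2^(−g) and evenly over source species; an
ancestor at generation g contributes genome fraction 2^(−g), giving a
two-population mixture likelihood per locus.  The generation-weighting
split is a design choice (the original description leaves it open);
results on clear cases are stable across ν ∈ {0.1, 0.05, 0.01}.

PCA is column-centred covariance PCA via SVD; variance-explained
percentages are non-increasing and sum to 100.

## Desk-scale problem sizes

The acceptance script and test suite run everything at sizes chosen to
finish in minutes on one core while preserving the statistical signal:

* outlier scans at the full 2000-locus scale (they are cheap);
* the Evanno sweep on an information-equivalent reduction of the flock —
  600 loci at neutral FST 0.2 instead of 2297 at 0.1 (the product L·F²,
  which governs cluster separability, is preserved), 12 individuals per
  species, K = 1..8 × 3 replicates;
* mismatch recovery over 100 datasets of 76 sequences;
* the homoplasy-excess scenario at 3 species × 6 individuals, 400 loci,
  neutral FST 0.15, 1000 bootstrap replicates.

Scenario seeds are fixed; the homoplasy scenario's effect (both parental
clades gaining > 10 support points upon hybrid removal) holds for the
majority of generator seeds at this configuration, with the remainder
showing one large and one moderate gain — the hybrid often damages one
parental clade more than the other.

## Known limitations

* The haploid band coding ignores AFLP dominance in the likelihoods; the
  square-root correction is exposed but not propagated into the MCMC.
* τ is unidentifiable along the θ₁ ridge for moderate expansions (a
  property of the sudden-expansion SSD surface itself, visible in the
  conventional θ₁ = 99999 caps).
* Median-joining quasi-median expansion is capped per triple; extremely
  homoplasious triples are connected through the MSN only.
* The hierarchical AMOVA is one-level (separate runs per grouping), not
  the nested two-level decomposition.
* No linkage model anywhere; all loci are treated as exchangeable and
  unlinked.
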