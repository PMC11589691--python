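# Methods

This note documents the statistical methods implemented in `amtscan`, the
assumptions behind them, the synthetic study system used to exercise them,
and the numerical and design choices that were genuinely open.

## Study design and coordinate conventions

The package analyses a paired design: in each of several rivers, one
anadromous (below-falls, migratory) and one resident (above-falls,
landlocked) population of the same species, each with diploid genotype
calls at biallelic SNPs from a multi-sample VCF. Internally all
coordinates are 0-based half-open; VCF (1-based) and GFF3 (1-based closed)
are converted at the boundary. The genome is tiled with non-overlapping
windows (default 10 kb); a window's `callable_sites` L is the number of
bases of the callable mask (BED) it intersects, and windows with
L < `min_sites` (default 500) are excluded from all statistics.

The **minor allele is defined once, globally across all samples, at load
time**, and per-population frequencies are frequencies of that same
allele. This keeps frequencies comparable across populations; every
statistic downstream is invariant to which orientation is labelled minor
(folding symmetry is property-tested).

Filtering is two-tier. Frequency-spectrum statistics (SFS, θ_W, π,
Tajima's D, windowed F_ST, the beta-like score) are computed on **all**
segregating sites with a non-missing call fraction of at least 0.8 — a
minor-allele-frequency cut would bias the spectrum, deflating the
rare-variant classes that carry the sweep signal. The stricter SNP set
with global MAF ≥ `maf_min` (default 0.05) is used only by the
allele-frequency contrast, whose model assumes reasonably informative
per-population frequencies. These called-genotype filters stand in for
read- and genotype-likelihood-level filters (depth bounds, SNP p-values)
that have no exact analogue on called genotypes; the mapping is
deliberately simple and is stated here rather than hidden.

## Diversity statistics

Per population and window, with S the number of segregating sites among
non-missing calls and L callable bases:

* Watterson's estimator: θ̂_W = S / (a₁ L), a₁ = Σ_{i<n} 1/i.
* Pairwise diversity: π = (1/L) Σ_i 2 m_i (n_i − m_i) / (n_i (n_i − 1)),
  using each site's exact non-missing chromosome count n_i and minor count
  m_i.
* Tajima's D with the 1989 normalisation constants; because per-site
  sample sizes vary with missingness, D uses the modal n across the
  window's segregating sites (a documented approximation; π itself is
  exact). D is a missing value when S = 0 or the window is excluded —
  propagating a zero instead would bias the Z-standardisation.
* Z_TD: per population, (D − mean)/sd over non-excluded windows (population
  sd). Z_TD > 0 marks windows with more intermediate-frequency variation
  than that population's genomic average; the standardisation makes
  populations with different demographic histories comparable.

The folded SFS is indexed by minor count 1…⌊n/2⌋. With heterogeneous
per-site sample sizes, sites are projected down to the smallest common n
by hypergeometric expectation before folding. An EM estimator over
genotype likelihoods is provided for low-coverage designs: per site the
likelihood of a total alt count j is computed by the exchangeable
dynamic-programming convolution over samples (each sample contributes
(L_RR, 2·L_RA, L_AA)), divided by C(2N, j); a folded class m < n/2 is the
even mixture of counts m and n−m (folding carries no information about
orientation, so the class likelihood is their average — this makes
symmetric, uninformative likelihoods an exact fixed point of the EM). The
EM log-likelihood is monotone non-decreasing (asserted in tests);
non-convergence sets a flag rather than raising.

## The dual outlier scan

**Windowed F_ST.** Hudson's estimator in the Bhatia et al. (2013) form,

    num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    den = p₁(1−p₂) + p₂(1−p₁)

computed per site from called-genotype frequencies of the pooled ecotype
groups (or of the two populations within one river for local scans) and
aggregated per window as a **ratio of sums** Σnum/Σden — not the mean of
per-site ratios, which would up-weight low-information sites. Negative
window values are retained (they rank naturally below any positive
threshold). Outliers are windows at or above the top quantile (default
1%); ties at the threshold are all included, so reported counts are
reproducible.

**Whitened frequency contrast.** Per SNP, the standardised residual of
population j is z_j = (p_j − p̄)/√(p̄(1−p̄)) with p̄ the across-population
mean. The among-population covariance Ω is the moment estimate
(ZᵀZ)/J over polymorphic SNPs plus a ridge εI (ε = 10⁻³) guaranteeing
positive definiteness. The contrast statistic for the ecotype split is
C = (cᵀz)²/(cᵀΩc) with c = +1/k_A on anadromous and −1/k_R on resident
populations; under neutrality and the fitted Ω, C is approximately
χ²(1). Whitening by Ω absorbs shared demographic structure, protecting the
scan against the Wahlund effect that a naive pooled comparison would
suffer. Instead of an analytic cutoff, the significance threshold is
calibrated on pseudo-observed data (PODs): each POD SNP draws p̄* from the
empirical pool of across-population means, residuals from N(0, Ω),
reconstructs frequencies clipped to the observable range
[1/(2n_j), 1−1/(2n_j)], and is scored by the same statistic; the default
threshold is the 99th percentile of 10,000 POD statistics. The calibration
is checked on fully neutral synthetic data, where the threshold must flag
1% ± 0.3% of SNPs.

**Intersection.** AMT outlier windows are F_ST outlier windows containing
at least one contrast-significant SNP (half-open window assignment). By
construction the AMT set is a subset of the F_ST outlier set, asserted on
every run.

## Trait classes

Per window, Z_TD is averaged (unweighted) over the populations of each
ecotype pool; the outlier windows are then split by the lower tertile of
each pool's pooled-score distribution into LA_LR / LA_MHR / MHA_LR /
MHA_MHR ("low" = at or below the lower-tertile cut point, inclusive).
Whether the tertiles should be computed on the outlier windows themselves
or genome-wide is ambiguous in principle; both are implemented
(`tertile_mode = "amt" | "genome"`), with the outlier-window distribution
as the default. Pooling is an unweighted mean over populations, not a
sample-size-weighted one. Genes are assigned to an outlier window when the
gene interval intersects the window extended by a symmetric 10 kb flank
(half-open arithmetic: a gene ending exactly at `start − flank` is not
assigned). Gene-set overlap is tested both by the hypergeometric tail and
by permutation (resampling same-size sets from the universe,
p = (1 + #{overlap* ≥ obs})/(n_perm + 1)).

Under a random two-way tertile partition the four classes have chance
shares 1/9, 2/9, 2/9 and 4/9; these are the baselines used when testing
whether a planted regime is enriched in its predicted class.

## Balancing-selection screens

* **Permutation mean shift**: observed difference of mean pooled Z_TD,
  outliers minus background; the null permutes the outlier/background
  labels; one-sided (greater), since the hypothesis is elevated diversity
  at outliers. p = (1 + #{diff* ≥ obs})/(n_perm + 1), a valid (slightly
  conservative) p-value.
* **Top-percentile enrichment**: O = outlier windows at or above the
  track-wide q-quantile of the pooled score; E = (1−q)·n_outliers;
  χ² = (O−E)²/E with one degree of freedom. This one-cell goodness-of-fit
  form is used because it is the unique simple statistic consistent with
  the reported values it is checked against.
* **Beta-like score**: per population and window, SNPs with
  per-population frequency outside [0.1, 0.9] are excluded; folded
  frequencies φ = min(p, 1−p) then lie in [0.1, 0.5]. For a core SNP c,
  s_c = Σ_{i≠c} max(0, 1 − |φ_i − φ_c|/d), its genome-wide expectation is
  ŝ_c = (S−1) Σ_k q_k max(0, 1 − |φ_k − φ_c|/d) over folded-frequency
  classes (centres 0.10…0.50, step 0.05, proportions q estimated
  genome-wide per population), and the window score is max_c (s_c − ŝ_c);
  missing with fewer than two usable SNPs. This is a concrete
  frequency-similarity excess statistic built to capture the same signal
  as published long-term balancing-selection scans — clusters of variants
  at matching intermediate frequencies — and is labelled *beta-like*
  throughout because it is not a reimplementation of any published β
  estimator. Scores are Z-standardised per population like Tajima's D.
* **Pool comparisons**: Pearson correlation of pooled Z_TD between
  ecotypes, separately for outlier and background windows (selection
  acting differently in the two environments decorrelates the outliers),
  and two-sided Wilcoxon rank-sum comparisons of window-level tracks
  between pools. Window values are not independent observations — the
  rank-sum results carry an explicit caveat flag and should be read as
  descriptive.

## Synthetic study system

The generator emulates the paired-river design: an ancestral population
(N_e = 500) splits into five river demes (anadromous, N_e = 500) that
exchange migrants (0.005 per generation, island model); at the falls
split, each river founds a resident deme by a bottleneck (N_e = 100) that
then evolves in isolation (one-way resident→anadromous seepage supported,
default 0). Twenty diploids are sampled per population, matching typical
per-site sample sizes of such studies. Defaults: T_river = 400 and
T_falls = 200 generations ago — long enough that the resident bottleneck
leaves its characteristic signature (reduced θ_W, elevated Tajima's D,
reproduced in 5/5 rivers) and that selection signatures are
distinguishable from drift; mutation rate 4.5×10⁻⁷ /bp/gen, chosen so
that 4N_eμ ≈ 0.9×10⁻³ matches the anadromous per-site θ_W such studies
report; recombination 10⁻⁷ /bp/gen (ρ < θ, preserving haplotype structure
at the compressed timescale); genome 5 chromosomes with tapering lengths
totalling 5,000 windows of 10 kb. These are scaled parameters: small deme
sizes, short times and strong selection coefficients (default s = 0.5,
h = 0.5) stand in for larger populations over longer times.

Each window is simulated independently (free recombination between
windows — a documented limitation: no between-window LD). Fully neutral
windows use msprime's discrete-time Wright–Fisher model under the exact
demography above (switching to the standard coalescent beyond the
structured phase). Windows with planted selection run through the
in-package forward Wright–Fisher engine — diploid viability selection
(fitnesses 1, 1+hs, 1+s; overdominance 1, 1+s, 1), single-crossover
recombination, infinite-sites mutation, migration by whole-offspring
ancestry — whose ancestral standing variation is itself drawn from an
msprime simulation of the ancestral population, so background variation is
statistically consistent across the two routes. Everything is
deterministic given the master seed (per-window seeds are spawned from
it), and emitted files are byte-identical across reruns.

Planted regimes follow the four trait-class predictions (default plan: 12
windows per regime, evenly spaced, regimes interleaved):

* `DIVERGENT_BOTH` (migration-propensity): two young alleles, each
  planted at the falls split at 5% frequency on a single donor haplotype
  background shared across demes (the allele arose once; backgrounds of
  the two alleles disjoint), one favoured in every anadromous deme and
  the other in every resident deme — both pools sweep, in opposite
  directions, giving near-complete differentiation and low Tajima's D in
  both pools.
* `SWEEP_ANAD` (migratory-lifestyle) / `SWEEP_RES` (residency): one young
  allele planted the same way, favoured only in the demes of one ecotype;
  the other ecotype drifts.
* `BALANCED_ANAD`: the ancestral population is built as an **ancient
  balanced dimorphism**: half its haplotypes come from an independent
  coalescent simulation, plus stem mutations fixed within one allelic
  class (Poisson with mean μ·L·`balanced_allele_age`, default age 4,000
  generations) — the deep allelic genealogy long-term balancing selection
  produces. Asymmetric heterozygote advantage (fitnesses 1−s, 1+s, 1;
  equilibrium focal frequency 2/3) maintains the dimorphism in all
  anadromous demes from the river split onward, tipping the balance
  toward one variant, while residents are selected against the focal
  class and fix the other. Lost balanced alleles trigger a bounded
  re-seed of the window (logged).

The young-allele construction gives hard selective sweeps (complete
hitchhiking of one background, post-sweep rebound of rare variants over
the remaining ~170 generations); the ancient-dimorphism construction
pins many class-diagnostic sites at intermediate frequency, producing the
elevated Tajima's D and folded-frequency clustering the balancing screens
target. Planting young alleles copies a donor haplotype onto 5% of each
deme — a small, documented perturbation of neutral variation at planted
windows.

What the generator does **not** emulate: sequencing error and genotype
uncertainty (except through the separate genotype-likelihood fixture
generator, a Poisson-depth symmetric-error read model), between-window
linkage, variable callable masks (the default mask covers everything),
sex-specific selection, and realistic site spectra distortions from
paralogy or mapping artefacts. Passing the recovery tests therefore shows
the pipeline detects and classifies the intended signals under clean
conditions, not that it is robust to those artefacts.

## Problem sizes and numerical choices

The default scenario (5,000 windows, 12 planted windows per regime,
≈0.96% of windows planted) is sized so that a top-1% scan can contain the
planted windows; the calibration dataset is 1,500 fully neutral windows.
PODs and permutations default to 10,000. Quantile thresholds use linear
interpolation with inclusive (≥) membership. The ridge ε = 10⁻³ guarantees
a Cholesky-factorable Ω. Frequencies at beta-score bounds are compared on
integer counts so the filter is exactly symmetric under allele
relabelling. Permutation and POD p-values use the +1 convention. All
stochastic operations take explicit seeds; the pipeline derives per-stage
seeds from one master seed by hashing the stage name.

## Known limitations

* Tajima's D uses the modal per-site n within a window under missingness.
* The contrast statistic's χ²(1) behaviour is approximate for strongly
  skewed frequencies; the POD calibration, not the asymptotic
  distribution, sets the threshold.
* The beta-like score is a construction in the spirit of published
  balancing-selection statistics, not a replica of any of them.
* Trait-class tertiles on the outlier set make class labels relative to
  the outlier composition; the `genome` mode avoids this at the cost of
  unbalanced class sizes.
* Window-level tests treat windows as exchangeable; physical linkage makes
  neighbouring windows correlated, so genome-wide p-values are
  descriptive.
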