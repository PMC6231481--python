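# Methods

## The synthetic system

The generator (`landgen.simulate`) emulates a mountain-belt sampling design:
`n_pops` demes (default 17) of `n_ind_per_pop` diploids (default 6) on an
east–west landscape, four bioclimatic surfaces — temperature seasonality
(bio4), minimum temperature of the coldest month (bio6), precipitation
seasonality (bio15), precipitation of the wettest quarter (bio16) — and a
SNP panel whose default class counts (5,183 neutral, 74 elevated-F_ST, 97
climate-associated; 5,354 total) follow the proportions of a typical
reduced-representation panel for a widespread outcrossing tree. Tests and
the acceptance script use smaller panels (hundreds to 2,000 loci) through
explicit configs; the mechanism is identical at any size.

Climate surfaces are mean level + planar gradient + a sum of low-frequency
cosine waves with random coefficients; bio15 carries the dominant east–west
gradient (site values correlate with longitude at |r| ≈ 0.85 under the
defaults). Future climate is built per ensemble member as an additive shift
plus a smooth random anomaly, then averaged cell-wise; members are retained
on the returned grid so the averaging is auditable. Averaging is computed
as `base + mean(member − base)` so that identical members reproduce the
current grid bit for bit.

Allele frequencies follow the island-model beta decomposition: ancestral
frequency p₀ ~ U(0.1, 0.9) (which enforces expected MAF ≥ 0.10), deme
frequency p_j ~ Beta(p₀θ, (1−p₀)θ) with θ = (1−F)/F, so E(F_ST) = F.
Background F = 0.056 and elevated F = 0.196 by default (0.25 in the
acceptance power fixture). Climate loci instead follow a deterministic
logistic cline, logit p_j = logit p₀ + c·z_j, in the standardised value of
one uniformly assigned climate variable (slope c = `clim_effect`, default
1 per SD). Genotypes are Binomial(2, p_j); missingness is uniform at 2 %;
per-genotype depth is Poisson(21.8). The generator deliberately omits
linkage disequilibrium between loci, depth-dependent missingness and
coalescent realism: passing tests demonstrate correct behaviour of the
estimators under the island model they assume, not robustness to demographic
misspecification.

All draws come from named substreams (`landscape`, `freqs`, `genotypes`,
`missingness`, `depth`, `future`) of one master seed, so each stage is
independently reproducible.

## Filtering

Filters run in a fixed order — diallelic → call rate ≥ 0.95 → mean depth
≥ 5 (skipped when no DP is present) → pooled MAF ≥ 0.10 (inclusive,
evaluated in integer arithmetic to avoid float boundary artefacts) — and
the report reconciles removals exactly. VIF pruning slides windows of five
loci by five; within a window missing dosages are mean-imputed (storage
keeps the missing code), each locus is regressed on the others, and while
any VIF = 1/(1−R²) exceeds 2 the worst locus is removed. Exact ties
(duplicated loci) drop the later position; the greedy order is a
determinism choice — the conventional tool leaves it undocumented.

## Population genetics

H_E uses the small-sample correction 2n/(2n−1)·(1−p²−q²); F_IS is the
ratio-of-sums 1 − ΣH_O/ΣH_E over loci within each population. F_ST is
Weir & Cockerham (1984): per-locus components a (among populations), b
(among individuals within), c (within individuals), with the multilocus
estimate Σa/Σ(a+b+c) (negative per-locus estimates retained, never
truncated); monomorphic loci contribute zero components and drop out of the
ratio. Distances are haversine on a 6371-km sphere — the analysis is
projection-free at these extents. The Mantel statistic is z = Σ over
unordered pairs of cell products, r the Pearson correlation of off-diagonal
vectors, and p one-sided (greater) from simultaneous row/column
permutations, 9,999 by default.

## F_ST-outlier scan

Differentiation is decomposed on the logistic scale, logit F_ST,ij = α_i +
β_j. The deme frequency is integrated out analytically: minor-allele counts
are beta-binomial with shape θ_ij p_i, θ_ij(1−p_i), θ_ij = 1/F_ST,ij − 1.
This marginalisation (rather than sampling every deme frequency) shrinks
the MCMC state to (p_i, α_i, β_j) and is the package's main computational
choice; the F_ST decomposition is unchanged. Priors: α_i ~ N(0,1) when
included (prior inclusion 1/(1+prior_odds), prior odds 10), β_j ~ N(−1,1),
p_i ~ U(0,1). Updates are Metropolis-within-Gibbs, vectorised across loci;
the reversible-jump toggle proposes α from its prior, so its acceptance
ratio is the likelihood ratio times the prior odds. Pilot runs adapt
proposal widths into the 0.25–0.45 acceptance band. q-values are the
running mean of (1−P) down the P-ranking (the Bayesian FDR of each
rejection set), and candidates are diversifying only: q < 0.05 (strict)
with positive posterior mean α.

A caveat established analytically (numeric quadrature of the per-locus
Bayes factor, which the sampler reproduces): with 6 diploids per deme the
evidence per locus is modest, and the expected power to flag a planted
F_ST = 0.25 locus at q < 0.05 is ≈ 0.3–0.45 depending on the realised
frequency draws. Power statements at this sample size should be read
against that ceiling.

## Environment association

Genotypes are mean-imputed, centered, and regressed per locus on one
standardised site-level climate value broadcast to individuals, with K
latent factor scores as covariates. The fit alternates a randomised
truncated SVD of the environmental residual (per-run random sketch) with
per-locus least squares — a deterministic-per-seed alternative to a Gibbs
sampler that exposes the same z-score interface; run-to-run variation comes
from the random initialisation and the median |z| over five runs is
reported (observed coefficient of variation across runs < 7 % on
fixtures). K can be chosen by the sequential Tracy–Widom test with the
effective-marker normalisation (TW1 tail probabilities interpolated from
the standard published quantile anchors — adequate for threshold decisions;
null calibration is verified by simulation) or set directly; the default
configuration uses the structure-consistent K = 2 and reports the
Tracy–Widom value alongside. Genomic control uses the exact χ²₁ median
(0.4549). Benjamini–Hochberg runs within each variable (four families),
and a locus significant for several variables is assigned the one with the
largest median |z|.

## Spatial eigenvectors

PCNM: truncation t = the longest minimum-spanning-tree edge; distances
beyond t replaced by 4t (the original recipe's constant); Gower
double-centering of −½D²; symmetric eigendecomposition. "Significant
positive" eigenvalues are implemented as positive above 10⁻¹⁰ × max — no
permutation screen is applied by default since none is standard here.
"First half" uses the ceiling for odd counts. Eigenvector signs are fixed
by making the largest-magnitude loading positive, so bases are reproducible
across orderings up to permutation of equal eigenvalues.

## Turnover and offset

Each SNP's population allele frequencies are fit by 2,000 shallow CART
regression trees, each grown on a random ~63.2 % subset of populations
(no bootstrap duplication), depth limited to max(1, round(log₂(0.368·n)/2))
— depth 1 at n = 17. Tree growth is vectorised across the whole ensemble
(candidate thresholds are midpoints of consecutive sorted unique predictor
values; mtry = ⌊P/3⌋ features per node). Out-of-bag R² uses the ensemble
OOB prediction. Predictor importance is conditional permutation: the
predictor is permuted within joint quartile strata of all predictors
correlated with it above 0.5 (three permutations averaged), and the OOB-MSE
increase, clipped at zero, partitions the SNP's R² into per-predictor
importances.

Every split's impurity reduction is recorded at its threshold and binned
into 200 equal-width bins per predictor; bin masses are standardised by a
Gaussian-kernel estimate of the predictor's sampling density (a plain
histogram is zero between observations, exactly where thresholds fall),
accumulated, and rescaled so each SNP's curve rises to its importance. The
ensemble turnover function is the R²-weighted mean over SNPs with positive
R²; its total rise is the reported predictor importance, so conservation
(rise = importance) holds by construction. The transform F(v) is the
cumulative mass of bins entirely below v, clamped to the training range:
F(min) = 0, F(max) = total importance, monotone non-decreasing.

Prediction points are sampled uniformly in the convex hull of the sites
buffered by 0.5° (10,000 by default). Genetic space is visualised by
centered (unscaled) PCA with PC1–3 min-max scaled to RGB; SNP sets are
compared by least-squares Procrustes superimposition of PCA scores with
per-point residuals min-max rescaled to [0,1] (numerically zero disparity
maps to all-zero residuals). Genetic offset is the Euclidean distance
between current and future transformed values; MEM predictors are held
fixed across epochs (geography does not change) and therefore contribute
zero, and future climate is the ensemble mean before transformation.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at desk scale: F_ST
recovery at 20 seeds × 2,000 loci; the outlier scan at 500 loci with a
reduced chain (10 pilot runs × 500, 10,000 burn-in, 1,000 samples thinned
by 10 — the full-scale defaults of 20 × 5,000 pilots, 50,000 burn-in and
5,000 samples remain the function defaults); environment-association
calibration at 2,000 null loci and twenty 300-locus planted fixtures;
turnover at 200 SNPs × 2,000 trees. Ties in the VIF and forest argmax
steps resolve to the first candidate; all stochastic components accept a
seed and are bit-reproducible under it.

## Known limitations

Loci are modelled as independent throughout (no LD-aware null); the
outlier scan reports diversifying candidates only; the Tracy–Widom tail is
interpolated, not exact, away from the tabulated anchors; the turnover
forest's importance partition is an explicit approximation to
conditional-permutation importance and is validated against planted-truth
fixtures rather than against any external implementation bit for bit; and
range masks are convex-hull approximations unless a polygon is supplied.
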