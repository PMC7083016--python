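# Methods

## The problem and the model

A microbiome mediation study asks which microbial taxa carry part of the
effect of host gene expression on a clinical outcome: gene → taxon → disease.
Regression-based structural equation models struggle here — exposures and
mediators are both high-dimensional (n ≪ p), taxa are overdispersed
zero-inflated counts, and the gene–taxon relationships need not be linear.

NPEM (nonparametric entropy mediation) replaces regression coefficients with
information overlap.  For taxon *j* the two sides of the mediation bridge are

* the **α side** — does at least one gene share information with taxon *j*
  beyond what estimation bias and the already-selected genes explain?
* the **β₂ side** — does taxon *j* share information with the outcome *Y*
  that the other taxa do not already carry?  (Information shared by taxon
  and outcome *through* the genes — the β₁ overlap — does not count:
  a taxon whose only outcome signal is collinear with the exposure is not
  a mediator.)

A taxon is called a mediator only when both sides reject.

## Information measures

Shannon entropy is estimated by the resubstitution plug-in rule
Ĥ = −(1/n) Σᵢ log p̂(xᵢ) with kernel density estimates p̂: a second-order
Gaussian kernel for continuous variables (Silverman rule-of-thumb bandwidth
1.06·min(sd, IQR/1.34)·n^(−1/5)) and the Aitchison–Aitken kernel for
categorical ones (smoothing λ = 0 by default, so categorical entropies reduce
exactly to empirical contingency-table values).  Joint distributions of mixed
variable sets use product kernels, evaluated only at the observed rows — no
integration grids.  Mutual information is MI(X,Y) = Ĥ(X)+Ĥ(Y)−Ĥ(X,Y), and the
*contributed information* of a candidate X for target Y given the selected
prior set W is

    C(X, Y, W) = MI(X, Y) − (1/|W|) Σ_{w∈W} MI(X, w),

i.e. MI penalised by the mean redundancy with what has already been selected.
The penalty divisor is |W| by default; a |W|² variant is available
(`penalty_norm="card_squared"`) because the choice is genuinely open.
Natural logarithms are used throughout; both test statistics are invariant to
the base.

Plug-in MI is biased upward at finite n.  NPEM does not debias the estimate;
it exploits the assumption that most candidates are null, takes the pool mean
φ of the C scores as a conservative bias estimate, and asks whether the
*largest* score is an outlier relative to the pool.

## The greedy tests

**Univariate (UV/UVS).**  Each taxon enters as a single Gaussian-kernel
variable (log1p counts).  At each step of a greedy search the contributed
information of every unselected candidate is recomputed, and the one-sided
extreme studentized deviate statistic G = (C₍₁₎ − C̄)/sd(C) of the maximum is
referred to the upper tail of t(df−2), df = pool size.  UV stops at the first
failed test; UVS completes the greedy ordering and keeps the p-value recorded
at each step.  Untested candidates get p = 1.

Two structural properties worth knowing:

* G is bounded by (k−1)/√k for a pool of k scores, so very small candidate
  sets cannot produce small p-values no matter how strong the association.
* Referring the *maximum* to an uncorrected t tail is anticonservative at
  each single step (the max of ~20 null scores usually exceeds the plain t
  threshold).  Error control therefore does not live in the stopping rule;
  it lives in the downstream Benjamini–Hochberg correction and the composite
  rule, which is where we test it (measured feature-level null FDR call rate
  ≈ 2% at the 5% level, per-taxon false positive rate ≈ 0.2–1.7%).

**Bivariate (BV/BVS).**  Zero-inflated counts break a single Gaussian kernel
(the point mass at zero shrinks the bandwidth), so each taxon is decomposed
into a presence/absence channel Z (Aitchison–Aitken) and a nonzero-count
channel M′ (log1p of counts at nonzero positions, 0 at zeros; the zero
pattern lives in Z, so the fill value matters little — mean-fill is
available).  Each candidate receives a score pair (C_Z, C_M′); the pool mean
and covariance are re-estimated from the current unselected candidates at
every step, and the largest squared Mahalanobis distance is referred to
χ²(2), whose upper tail is exp(−MD/2).  Singular covariances are
ridge-regularised (1e−8 · trace), falling back to the dominant channel's
squared z-score if still degenerate.  Because Mahalanobis distance is
direction-blind, only candidates with at least one channel above its pool
mean are eligible for selection (`require_positive`, default on).

**Composite rule.**  Per taxon, the gene-level p-values are BH-corrected
within the taxon and p_α,j is the smallest corrected value (the existential
hypothesis: at least one gene).  The taxon-level β₂ search is run once
against the outcome and BH-corrected across taxa.  The final mediation
p-value is the conservative composite p_j = max(p_α,j, p_β,j); significance
calls use p_j < 0.05.  A further BH pass over the composite vector is
reported as `p_adjusted` — a stricter diagnostic that preserves the
composite's ordering — but calls are made on the composite itself, which is
already the maximum of two FDR-corrected quantities; stacking a third
correction on top of it suppresses essentially all power at realistic sizes.

## The synthetic study generator

The generator emulates a two-group design (n_per_group samples each).

* **Genes**: 300 by default, normal; first half sd 0.5, second half sd 2.0.
  Genes in γ′-bearing blocks get a between-group mean shift δ = s·σ where
  s = `signal_strength` (δ/σ, the standardized group difference) and σ is the
  per-gene sd.
* **Taxa**: 300 by default, partitioned into eight relationship blocks in the
  proportions 10:10:10:120 per gene half (largest-remainder allocation at
  other sizes).  Baseline abundances λ_j are log-normal(meanlog 3, sdlog 1),
  a moderate rank-abundance spread.  α-linked blocks add
  `alpha_link` (default 1.0) times the standardized partner-gene-block mean
  to the log mean; β₂-linked blocks add s·sdlog to the diseased group's log
  mean.  Only blocks carrying γ′, α and β₂ together (the first block of each
  half — 20 taxa at reference scale) are true mediators.
* **Counts**: negative binomial with variance λ + c (reading the
  overdispersion relation κ = c/λ + 1 with κ the variance-to-mean ratio, so
  c = 1000 is the high-dispersion setting; the literal κ = cλ + 1 reading is
  available as `dispersion_form="kappa_linear"`).
* **Excess zeros**: per-taxon Bernoulli zeroing with probabilities
  proportional to bounded weights from the log ratio of abundance to the
  population mean — below-mean taxa are zeroed preferentially, emulating
  detection-limit dropout — globally rescaled by bisection against the
  realized NB zero fractions so the marginal zero fraction matches
  `zero_level` (calibrated to ±0.03).  Weights are bounded (relative range
  [1, 3], per-taxon cap 0.95) so no taxon is erased outright; an unbounded
  weighting pointed the inflation at the abundant taxa and deterministically
  destroyed the planted outcome signal, which no study design would do.

The scenario grids: setting (i) crosses sample size {40, 80}/group with zero
level {0.50, 0.80} at signal 0.50; setting (ii) crosses signal {0.50, 0.10}
with zero level at n = 40/group; setting (iii) crosses dispersion
c ∈ {100, 1000} with signal at 80% zeros.

What the generator does *not* emulate: compositionality (counts are not
normalised to library size), phylogenetic correlation between taxa,
gene–gene co-expression networks, and longitudinal structure.  Passing tests
therefore demonstrate calibration and ordering properties under clean
block-structured signals, not performance on real 16S data.

## Benchmark and reported numbers

`run_scenario` generates replicate datasets with seeds derived from one
master seed (`numpy.random.SeedSequence`), fits the requested variants — all
variants of one replicate share a single mutual-information cache — and
scores calls at composite p < 0.05 against the generator's truth labels:
power = TP/(TP+FN), FPR = FP/(FP+TN), with Monte-Carlo standard errors
sd/√R over replicates.

Desk-scale defaults are 50 genes × 50 taxa, 40 samples/group, 10 replicates
(block proportions preserved), chosen so a full four-variant benchmark of
one scenario completes in about a minute on one CPU; the reference
300 × 300 × 20-replicate grid is available through the same interface and
scales roughly quadratically in the feature count.  At desk scale the false
positive rates sit near 0.01 for every variant, the sequential univariate
test has the best power at strong signal, and the single-test bivariate
variant is at least as good as UV when signal is weak and zeros plentiful —
but absolute power at desk scale is modest (≈ 0.05 at signal 0.5), since the
outlier statistic's resolution grows with the candidate-pool size.

## Numerical and degenerate-input choices

* Constant continuous variables get the bandwidth floor 1e−6; their kernel
  matrix is constant, so they contribute exactly zero MI rather than erroring.
* sd(C) = 0 in the ESD step returns p = 1 (no outlier detectable).
* Ties at the argmax of C or MD break to the lowest candidate index.
* Joint densities are clipped at 1e−300 before the log; with valid kernels
  the density at an observed point is strictly positive.
* All-zero (or all-positive) taxa have a constant presence channel; the
  covariance regularisation degrades the bivariate test toward a 1-df check
  on the live channel.
* Every stochastic component takes a `numpy` Generator or integer seed;
  identical seeds give byte-identical outputs.

## Known limitations

* The method tests the *existence* of mediation; it does not estimate effect
  sizes or confidence intervals, and offers no covariate adjustment.
* The per-step test is anticonservative by construction (see above); raw
  step p-values should not be interpreted in isolation.
* Bandwidths are rule-of-thumb; leave-one-out cross-validation would be more
  accurate and proportionally slower.
* The β₂ search conditions on previously selected taxa only through mean
  redundancy, so strongly collinear taxon clusters can mask one another.
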