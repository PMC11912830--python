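# Methods

## Model

`transectne` infers a trajectory of diploid effective population sizes
**Ne** = (Ne[0], …, Ne[Tmax−1]) from identity-by-descent (IBD) segments
shared within and across sample sets collected at different times. Time is a
single global integer generation clock, with 0 at the most recent sample set
and indices increasing backward. A pair of haplotypes sampled at generations
`ti` and `tj` that coalesces at global generation `g` has total branch
length `t* = (g − ti) + (g − tj)` meioses, the familiar `2t − Δt` when `t`
is counted from the younger sample and `Δt = |ti − tj|`.

The expected number of IBD segments of length `l` (Morgans) on a chromosome
of genetic length `L` factorizes into a segment-count term and a coalescence
term:

* segment-count density after `t*` meioses (Poisson recombination):
  `fK(l, t*) = 2 t* e^{−t* l} + (L − l) t*² e^{−t* l}` — chromosome-end
  segments plus interior segments. Its integral over `(0, L]` is
  `1 + t*L − e^{−t*L}` (the `e^{−t*L}` is the no-recombination point mass
  sitting exactly at `l = L`, which a density cannot carry), and it accounts
  for total length `L(1 − e^{−t*L})`; for `t*L ≳ 20` these reduce to the
  ideal `1 + t*L` and `L` to below 1e−6.
* single-locus coalescence pmf over `g ≥ gmin = max(ti, tj)`:
  `φ(g) = (1/2Ne[g]) Π_{i=gmin}^{g−1} (1 − 1/2Ne[i])`. The survival product
  starts at `gmin`, making φ a proper inhomogeneous-geometric distribution
  (constant Ne: `(1/2Ne)(1−1/2Ne)^{g−gmin}`) and matching an exact
  Wright–Fisher pair; this also reconciles the likelihood's inclusive lower
  summation limit with the coalescent recursion without double-counting a
  survival-free generation.

The per-pair expected density sums `fK(l, t*(g)) φ(g)` over
`g = gmin … G + gmin` and over chromosomes. Because the upper limit is
inclusive, the trajectory stores `G + max(T) + 1` generations. For constant
Ne a continuous-time closed form exists; our implementation carries the
final term with a **positive** sign,
`e^{−lΔt}/(1+4Ne·l)³ · (8Ne(1+4Ne·L) + 2Δt(1+4Ne·L)(1+4Ne·l) + (L−l)(Δt+4Ne·l·Δt)²)`,
which is what the defining integral evaluates to (verified symbolically and
by adaptive quadrature to 1e−9) and which is positive everywhere; with a
negative sign the expression goes negative at large `Δt`. The discrete
generation sum and this continuous form agree to ~1e−4 for contemporaneous
pairs; for `Δt > 0` they differ by O(l·Δt) relative (≈2% at Δt=10, l=10 cM)
— an inherent discrete-vs-continuous gap, which is why the closed form is
used only for the constant-Ne initialization.

## Likelihood

Observed segments are binned in left-closed, right-open bins of width
0.25 cM between 8 and 20 cM (all configurable; 8 cM is the reliable calling
threshold for imputed aDNA, 20 cM caps residual close-kin outliers,
segments outside the range are counted and excluded). Each
(sample-set pair, chromosome, bin) cell is Poisson with mean
`nhap · fN(midpoint) · Δl`. Within a set of `n` diploids the default
`nhap = 2n(n−1)` counts only inter-individual haplotype pairs, matching
callers that never report within-individual segments (a switch restores the
literal `C(2n, 2)`); across sets `nhap = 4 nA nB`. The composite
log-likelihood sums all `n + n(n−1)/2` pair terms, dropping the data-only
`log n!`. Keeping chromosomes as separate Poisson cells makes the
likelihood exactly additive over chromosomes, which the chromosome
bootstrap and cross-validation exploit. When an error model is supplied the
false-positive term is genome-wide, so the error-corrected likelihood pools
chromosomes within each pair (and scales the false-positive rate by the
resampled-to-original genome-length ratio under the bootstrap).

## Regularization and optimization

The objective is `−loglik + α P1(log Ne) + β P2(log Ne)` with `P1` the sum
of squared second differences (curvature) and `P2` the sum of squared first
differences weighted by `w_t = exp(−9(t−Tmax)²/(2Tmax²))`, which rises from
≈0.011 at t=0 to 1 at the deep end, pinning the trajectory where IBD
carries no signal. Penalties act on log Ne since sizes span orders of
magnitude. Optimization is L-BFGS-B over `x = log Ne` with analytic
gradients (the Poisson term's gradient flows through φ by a reverse
cumulative sum; unit tests check agreement with finite differences to
1e−4 relative) and box bounds `Ne ∈ [10, 10^8]`. Initialization: the
constant-Ne maximum-likelihood estimate (closed-form rates, started at
Ne=1000) plus i.i.d. Gaussian noise with standard deviation `Ne_const/20`
— we read the published noise parameter as a standard deviation, the usual
`N(·|μ, σ)` convention — clipped from below to the search box.

`β = 250` by default. `α` is selected by leave-chromosomes-out
cross-validation over the grid `10^{−2} … 10^{4}` (7 log-spaced points):
folds of chromosomes are held out (11 folds of 2 autosomes by default; the
recovery experiments use 3 folds for speed), each candidate α is fit on the
training chromosomes and scored by the mean held-out composite
log-likelihood, and we keep the **largest** α within 2 log-likelihood units
of the best — maximizing smoothing until the fit to held-out data degrades.
The exact statistic and threshold are this package's design choice.
Single-chromosome data require a manual α.

Confidence intervals bootstrap chromosome labels with replacement (200
replicates by default); a duplicated chromosome contributes its counts and
expected rates twice. Each replicate refits at the full-data α — refitting
α per replicate would mix hyperparameter noise into the sampling noise —
and the envelope is the per-generation 2.5/97.5 empirical percentile band.

`G` defaults to 150 generations: under the fitted demographies essentially
all ≥8 cM segments coalesce within ~50 generations, so the deeper tail is
regularization-dominated anyway.

## TMRCA posterior

The coalescence-generation posterior of a segment of length `l` is
proportional to `(t*)² l e^{−t* l} · φ(g)` (Erlang-2 length likelihood,
ignoring chromosome edges). Against the exact edge-aware likelihood mixed
over the 22 autosomes the posteriors differ by ≈1.3% total variation at
8 cM (1.7% at 10 cM, 2.0% at 12 cM, constant Ne=2000) — close, but worth
remembering for edge-dominated analyses of short chromosome arms.

## Detection-error model

Observed rates are `λ̂(y) = FP(y) + Σ_z λ(z)·Recall(z)·R(y|z)·Δz` with
Δz=0.25 cM, `R` a Gaussian length-noise kernel (σ = 1.5 cM by default)
truncated to ±5 cM around `y` and deliberately *not* renormalized (the
truncated mass at 3.33σ is ≤0.3%); the theory grid therefore extends 5 cM
beyond the fitting range on both sides, and insufficient coverage is an
error rather than silent zero-padding. σ is length-independent, as length
bias varies little across segment lengths; it is configurable per dataset.
The simulation default uses the expected sharing of a constant population
of 25,000 as the false-positive density (roughly 1:1 noise-to-signal in the
bottleneck scenario) and the parametric recall
`1 − 1/(1 + 0.025 l e^{0.25 l})` (≈0.60 at 8 cM). Empirical models are
consumed as 3-column tables (midpoint, FP density per pair per cM, recall)
plus a scalar σ; estimating them from sequence data is out of scope.

The generative counterpart (`inject_errors`) adds
`Poisson(FP(mid)·Δl·nhap)` false positives at bin midpoints, thins true
segments by `Recall(l)`, perturbs kept lengths by `N(0, σ)` and discards
results below the 8 cM cutoff — the exact forward process the corrected
likelihood inverts in expectation.

## Synthetic data

Two generators verify the stack end to end.

The **model-based Poisson sampler** draws cell counts at the model's own
expected rates — the exact inverse of the observation model — and drives the
parameter-recovery experiments at the published study conditions: a
constant population of 25,000; an instantaneous 10-fold bottleneck
(50,000 → 5,000) 30 generations ago with exponential regrowth to 100,000;
and exponential growth from 10,000 to 250,000 beginning 50 generations ago,
sampled e.g. at t = 0/25/35 with 30 diploids per set on a 22-autosome map.

The **pairwise coalescent-with-recombination oracle** is independent of the
model's factorization: it tracks the ancestral material of two haplotypes
(sampled Δt apart) backward through discrete generations — Poisson
crossovers at 1 per Morgan per meiosis split lineages, every cut is a
permanent segment boundary, and lineages merge by Wright–Fisher parent
choice (two meiosis products occupy the two haplotypes of one parent, so
they can never coalesce with each other). Where material ancestral to both
samples overlaps in a merging lineage, that overlap has found its MRCA and
is emitted as an IBD segment. Discrete generations are intentional: the
inference model is discrete, so the oracle matches its assumptions while
sharing none of its algebra; a continuous-time simulator would differ
detectably at very small Ne. Atoms shorter than the smallest reported
length may be pruned — an exact optimization for analyses restricted to a
length range — which also terminates replicates early. Mean binned counts
over 10,000 replicates (constant Ne=2,000, L=1 Morgan, Δt ∈ {0, 15}) agree
with the expected density within 3 Monte-Carlo standard errors in every
0.25 cM bin from 2–20 cM; the Monte-Carlo SE is the empirical
across-replicate SE (counts are genealogy-correlated and over-dispersed
relative to Poisson), with the Poisson SE as a floor in tail bins with no
observed variance.

What the generators do *not* emulate: linkage between bins and pairs (real
segment counts are correlated through shared genealogies — exactly the
dependence the composite likelihood ignores), population structure,
admixture, date uncertainty, and caller-specific artifacts beyond the
three-part error model. Passing recovery tests therefore demonstrate
correctness of the estimator under its own assumptions, not robustness to
their violation.

## Preprocessing

Close relatives are removed before inference: a pair sharing ≥3 segments
longer than 12 cM, or more than 100 cM total in such segments, is flagged,
and the lower-coverage member is dropped (lexicographic tie-break),
iterating until no flagged pair remains. Dates (calendar CE or years BP,
explicit unit) are converted to generations before the most recent
individual at 29 years per generation and floored into 5-generation
windows anchored at the most recent date (the anchor is our choice); each
non-empty window becomes a sample set at `window_index × window`
generations. Grouping is invariant under uniform date translation. An
experimental helper averages expected densities over ±radius generations
of sampling-time offset for sets with heterogeneous internal dates; it is a
synthetic stand-in for a proper date-uncertainty model and is labelled as
such.

## Numerical choices and degenerate inputs

* Cells whose expected rate is zero while the observed count is positive
  (e.g. a segment longer than every resampled chromosome) make the
  log-likelihood −∞ rather than being silently dropped.
* `t* = 0` (contemporaneous pair, coalescence generation 0) contributes
  zero segment density and is excluded from the Erlang-2 likelihood.
* Expected rates are floored at 1e−300 inside logs during optimization;
  bounds keep `log Ne` finite.
* All randomness (sampler, oracle, injector, initialization noise, CV fold
  assignment, bootstrap resampling) flows from one seed through
  `numpy.random.SeedSequence` spawning, so every pipeline is byte-
  reproducible.
* Default problem sizes in the tests and the acceptance script — 10,000
  oracle replicates, 10 recovery seeds, 3 CV folds, 2,000 oracle replicates
  in the script — are chosen to keep each experiment's Monte-Carlo error
  well inside the assertion bands.

## Known limitations

* The composite likelihood ignores dependence between bins and pairs, so
  the Poisson information overstates certainty; the chromosome bootstrap is
  the honest uncertainty measure.
* A smooth penalized estimator cannot represent an instantaneous size jump;
  the bottleneck experiments assess the crash depth and the recovered
  levels on either side, not the unrecoverable discontinuity itself.
* The single-panmictic-population assumption means migration, structure,
  selection and admixture all masquerade as Ne changes.
* α selection maximizes held-out fit under heavy smoothing; with very
  little data the trajectory flattens toward the constant estimate by
  design.
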