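# Methods

## Model and assumptions

`countseg` segments a genome into K chromatin states with a hidden Markov
model over fixed-width bins. Assumptions, in decreasing order of
importance:

1. **Conditional independence of tracks.** Given the state, the D count
   tracks in a bin are independent: ψ_k(o_t) = Π_d ψ_{k,d}(o_{t,d}).
   Dependence between marks is carried entirely by the state definition.
2. **Overdispersed counts.** Per-bin read counts from sequencing assays
   have variance well above their mean. Both emission families are Poisson
   mixtures — negative binomial (Gamma-distributed rate; mean μ, size r,
   variance μ + μ²/r) and Poisson-lognormal (lognormal rate; log λ ~
   N(μ_log, σ²)) — with a separate variance per state *and* track.
3. **Markov segment lengths.** Geometric state-duration distributions; at
   200 bp bins with self-transitions ≈ 0.95 this matches the kilobase
   scale of promoter/enhancer elements.
4. **Multiplicative depth differences.** Between cell types, a track
   differs only by sequencing depth, handled by total-count size factors
   (below), not by refitting per cell type.

## Library-size correction

For track d and cell type l with read total r_{d,l}, the stored factor is
s_{d,l} = (1/r_{d,l}) · mean_k r_{d,k}: multiplying *counts* by s puts
every library at the track's mean depth, and s_{d,l}·r_{d,l} is constant
across cell types. Because counts must stay integer for the count pmfs,
the correction is applied on the model side instead: the emission mean for
cell type l is scaled by the *relative depth* 1/s_{d,l} = r_{d,l} /
mean_k r_{d,k} (`SizeFactors.mean_scaling`). A library twice as deep as
average is modeled with doubled per-state means. Writing the scaling this
way round is forced by internal consistency: a duplicate cell type whose
counts are 3× larger must be modeled with a 3× mean, and the invariance
test (`test_size_factor_invariance_of_emission_means`) holds only under
this reading. The `size_factor` argument of the pmf functions themselves
is always the plain mean multiplier.

## Poisson-lognormal quadrature

The poilog pmf ∫ Poisson(x|e^z) N(z; μ, σ²) dz has no closed form. The
log-integrand h(z) = xz − e^z − (z−μ)²/2σ² is strictly concave, so its
mode is found by damped Newton (global convergence; |step| ≤ 2 prevents
overflow en route). Quadrature nodes are panelled 10-point Gauss–Legendre
with panel edges growing geometrically from the mode (at 0.5–512 local
scales σ* = (e^ẑ + 1/σ²)^{-1/2} on each side). The geometric growth is the
point: near the mode the integrand varies on the likelihood scale σ*,
while the left tail decays on the prior scale σ, which can be ~40× larger
(x = 100, σ = 4); uniform panels would have to resolve the smaller scale
everywhere. Against `scipy.integrate.quad` the absolute pmf error is below
4·10⁻¹³ over x ≤ 100, σ ≤ 4 (the contract is 10⁻⁸). Evaluation is
vectorized over counts; summation is by logsumexp, so tail probabilities
down to exp(−700) are representable.

## Emission fitting

The M-step objective Σ_c f_c log ψ(c) is evaluated on counts grouped by
unique (count, size-factor) pairs — an exact rewrite of the per-bin sum
(tested to 10⁻¹⁰ relative). Optimization is bounded quasi-Newton in log
parameters:

* **NB, common size factor** (the usual case): the mean MLE is the
  weighted sample mean divided by s *in closed form*, for any r, so only
  log r is optimized (1-D bounded search, r ∈ [10⁻⁴, 10⁸]).
* **NB, heterogeneous size factors**: 2-D L-BFGS-B on (log μ, log r) with
  a moment warm start and perturbed restarts.
* **Poilog**: L-BFGS-B on (μ_log, log σ), σ ∈ [10⁻², 10], moment warm
  start plus 2 perturbed restarts (seeded; restart seeds derive from the
  Baum–Welch seed).

The returned parameters never score below the incoming ones (the init is
kept on optimizer failure), which preserves EM monotonicity. Degenerate
groups with all weight on zero counts get a floored mean of 10⁻³
reads/bin; all pmf evaluations inside EM are floored at 10⁻³⁰⁰ so outlier
bins cannot produce −∞ log-likelihoods.

## HMM inference and initialization

Forward–backward and Viterbi run in log space (numba-compiled; exact
logsumexp recursions, no scaling factors), validated against exhaustive
path enumeration to 10⁻¹⁰ on small instances. Viterbi ties break toward
the lower state index; posterior decoding (per-bin argmax, same tie rule)
is the default for annotation output because the benchmark statistics are
bin-level; Viterbi is available via `--method viterbi`.

Initialization: per track, the threshold n_d is the smallest count with
Poisson upper-tail mass < 10⁻⁴ at the track mean; sub-threshold counts are
zeroed; bins that are then all-zero form the background cluster; k-means
(pseudocount 1, log transform, 10 seeded restarts, empty clusters reseeded
from the farthest points) partitions the remaining bins into K−1 clusters.
Cluster states are ordered by mean total count for determinism. Emission
parameters come from cluster moments on the raw counts (NB: r = μ²/(v−μ)
clamped to [10⁻², 10⁴]; poilog: σ² = log(1+(v−μ)/μ²) clamped at the σ
bounds); π and A start uniform. Clustering uses raw pooled counts across
cell types; size factors enter only the likelihood.

Convergence: relative log-likelihood improvement < 10⁻⁶ or 100 iterations
(both configurable). On the synthetic defaults the fit typically converges
in 5–10 iterations because the k-means initialization already sits in the
right basin.

## Evaluation and enrichment choices

* Overlap predicate is ≥1 bp intersection (configurable minimum);
  reference regions are merged before recall counting.
* Segment-level recall counts merged reference regions; bin-level recall
  counts reference bins.
* "Decreasing precision" and "increasing FDR" orderings coincide
  (single-state FDR = 1 − precision); ties break by state label order.
* AUC uses the state's precision rank as a bin score with standard tie
  handling (trapezoidal over tied groups, via `roc_auc_score`), verified
  against the exhaustive pairwise-comparison estimator.
* TF enrichment is nucleotide-level on merged intervals; e = 1 exactly for
  a state covering the whole genome. Co-binding is site-level Jaccard with
  co-occurrences counted as greedily 1-1 matched overlapping pairs among
  sites intersecting the state (so |A∪B| = |A|+|B|−n_co is well defined);
  a nucleotide-level mode is available.
* GWAS traits need ≥20 variants; each is tested one-sided (enrichment)
  against the rest of the catalog; BY adjustment is applied across all
  (trait, cell type) tests. SNPs are 1 bp points.
* Coverage-controlled recall draws whole segments without replacement
  until the target coverage is first reached (overshoot allowed on the
  final draw), 100 draws, empirical 2.5/97.5 percentiles.

## Synthetic data: what it emulates, what it does not

`synthetic.default_model` mimics the structure of real chromatin data:
state 0 is low-coverage background (0.3 reads/bin); each signal state is
high (30 reads/bin, NB size 10) in *its own* track and low (2) in the
others, like a promoter state in H3K4me3 versus an enhancer state in
H3K4me1; signal states are entered from and mostly return to background,
which therefore carries roughly half the stationary mass. This matters for
initialization realism: the Poisson-tail thresholds assume a
background-dominated genome. Cell types share one state path (chromatin
state is a property of the genome in one tissue context) and differ by
depth and emission noise. Planted reference regions are clipped to the
segment they land in; planted GWAS catalogs give one trait a density ratio
ρ inside enhancer segments, background traits are uniform, and trait sizes
are Poisson-jittered (floored at the 20-variant filter) like real,
variably-sized studies — this also keeps the null Fisher p-value
distribution smooth enough for a meaningful uniformity test.

Not emulated: read-level artifacts (GC bias, mappability, duplicates),
correlated marks within a state, non-geometric segment lengths, LD
structure among GWAS variants, and the signal-poor extreme of whole-genome
data (the synthetic genome is ~50% background versus ~80–90% in real
genomes). Passing tests therefore demonstrate correctness of the
inference and statistics, not robustness to real-data artifacts upstream
of binned counts.

## Problem sizes and numerical conventions

Test and acceptance runs use T = 300–50 000 bins, K = 3, D = 2 — chosen so
exact oracles (path enumeration, pairwise AUC, hypergeometric sums) and
multi-seed calibration loops stay cheap while estimation error at
T = 50 000 is a fraction of the tested tolerances. Probabilities are
floored at 10⁻³⁰⁰ inside EM; k-means and all simulations take explicit
seeds; every CLI output embeds its configuration, and outputs are
byte-reproducible given the seed (provenance headers aside, which embed
paths).

## Known limitations

* K is user-chosen; no statistical model-selection criterion is provided.
* Emission updates are numerical; monotonicity is guaranteed only up to
  the optimizer's achieved improvement (enforced ≥ init − 10⁻⁹).
* The NB size parameter is weakly identified on equidispersed data (it
  runs to its upper bound, correctly approaching the Poisson limit).
* Fragment-shift estimation is a plain strand cross-correlation on 5'-end
  coverage at 1 bp resolution; no smoothing or phantom-peak masking.
* Missing track × cell-type combinations are a hard error, not imputed.
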