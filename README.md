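# countseg

De novo chromatin-state annotation from multivariate sequencing count
tracks, for epigenomics analysts who want promoter/enhancer-grade
segmentations directly from binned ChIP-seq / DNase-seq read counts —
without binarizing the data first — plus the statistics to benchmark the
resulting annotation.

## The model

The genome is partitioned into fixed-width bins (200 bp by default). The
observed data are count vectors *o<sub>t</sub>* = (*o<sub>t,d</sub>*)
over tracks *d* (histone marks, accessibility, ...). A hidden Markov model
assigns each bin a chromatin state *s<sub>t</sub>* ∈ {1..K} with initial
probabilities π and transition matrix A; given the state, the tracks are
independent, each with an overdispersed count emission ψ<sub>k,d</sub>:

* **negative binomial** — mean μ, size r, variance μ + μ²/r (a
  Poisson–Gamma mixture), or
* **Poisson-lognormal** — Poisson rate λ with log λ ~ N(μ, σ²); its pmf
  has no closed form and is evaluated by deterministic quadrature.

Crucially the variance is estimated per state *and* per track. Differences
in sequencing depth between cell types enter as total-count size factors
s<sub>d,l</sub> = (1/r<sub>d,l</sub>) · mean<sub>k</sub> r<sub>d,k</sub>
(r<sub>d,l</sub> = read total of track d in cell type l); emission means
scale with each library's relative depth.

Fitting is Baum–Welch: forward–backward posteriors (log-space, compiled),
then per-state weighted maximum-likelihood emission updates computed on
counts *grouped by unique value* — the objective
Σ<sub>c</sub> f<sub>c</sub> log ψ(c) with
f<sub>c</sub> = Σ<sub>t: o<sub>t,d</sub>=c</sub> Pr(s<sub>t</sub>=i|O) is an
exact rewrite of the per-bin sum that scales with the number of distinct
counts instead of genome size. Initialization thresholds each track at the
Poisson upper-tail count n<sub>d</sub> (Pr(X > n<sub>d</sub>) < 10⁻⁴ at the
track mean), sends all-zero bins to a background cluster, and k-means the
rest into K−1 clusters on log counts.

Benchmarking turns a segmentation into a classifier of reference regions
(TSSs, HOT regions): states are ranked by precision, cumulative recall/FDR
curves are computed by adding states in that order, and each bin scored by
its state's rank yields an AUC. Enrichment statistics include nucleotide-level
TF enrichment (TF<sub>s</sub><sup>nt</sup>/TF<sup>nt</sup>)/(s<sup>nt</sup>/l)
normalized across states, site-level Jaccard TF co-binding within a state,
and GWAS trait enrichment (one-sided Fisher tests of each ≥20-variant trait
against the rest of the catalog, Benjamini–Yekutieli adjusted) with
coverage-controlled SNP recall by segment subsampling.

A fully specified synthetic-data module simulates counts from a known model
(shared state path, per-cell-type depths), plants reference regions and
GWAS catalogs with known enrichment, so the entire pipeline is testable
end-to-end with exact ground truth.

## Worked example

Simulate a 5 000-bin genome from a 3-state model (background plus two
mark-specific signal states), fit, decode, and benchmark against the
planted references:

```sh
countseg simulate --seed 11 --bins 5000 --out-dir fix
printf 'chrS\t1000000\n' > genome.sizes
countseg fit --counts fix/counts.tsv --states 3 --family nb --seed 0 --out model.json
countseg decode --model model.json --counts fix/counts.tsv --out states.bed
countseg benchmark --states states.bed --genome genome.sizes \
    --reference fix/refs.bed --out curve.tsv
```

which prints:

```
fit converged=True iterations=6 loglik=-19306.5602
wrote states.bed: 242 segments
AUC = 0.9775
S2	precision=0.8699	recall=0.9991	FDR=0.1301
S1	precision=0.0004	recall=1.0000	FDR=0.6838
S3	precision=0.0000	recall=1.0000	FDR=0.7712
```

State S2 is the recovered signal state carrying the planted reference
regions: 87% of its bins overlap a reference (precision), on its own it
already recalls 99.9% of reference bins, and the rank-scored segmentation
separates reference from non-reference bins with AUC 0.98. The remaining
states add only false positives, which is exactly how a background state
should behave. The same workflow applies unchanged to real tagAlign/BED
inputs via `countseg bin` and to multiple cell types via repeated
`--counts` (size factors are then estimated automatically).

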