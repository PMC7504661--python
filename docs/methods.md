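# Methods

## Per-gene Bayesian null and up-regulation calling

Control expression of each gene is modeled as x ~ Normal(μ, σ²) with
independent priors μ ~ Normal(w₀, v₀) and σ² ~ InverseGamma(a₀, b₀);
defaults w₀ = 0, v₀ = 10⁴, a₀ = b₀ = 10⁻³ make the priors effectively
uninformative at typical expression scales. Both full conditionals of
this semi-conjugate model are available in closed form, so the posterior
is simulated by a Gibbs sampler rather than a generic MCMC kernel:

* μ | σ², D ~ Normal with precision 1/v₀ + n/σ²,
* σ² | μ, D ~ InverseGamma(a₀ + n/2, b₀ + SSE/2).

The updates are vectorized across genes (each gene still evolves as its
own independent chain), which makes whole-matrix fits cheap. Defaults:
2 chains × 2000 kept draws after 1000 tuning iterations, overdispersed
chain starts around the sample moments, split-R̂ computed per gene
(arviz); R̂ > 1.05 is recorded as a warning on the model, not an error.

One posterior-predictive draw x ~ Normal(μ, σ²) is taken per (resampled)
posterior draw. The decision variable is y = 2x. Its density is a
Gaussian KDE (Silverman bandwidth) tabulated on an even grid spanning the
doubled draws ± 3 bandwidths (1024 points), renormalized to integrate to
exactly 1; tail masses come from trapezoidal quadrature of that grid,
clamped to [0, 1], with linear interpolation between grid points.

**Numerical choices.**

* *Predictive draw count:* 16 000 (resampled with replacement from the
  4000 posterior draws). The KDE's smoothing bias in the tail scales with
  the bandwidth; at 4000 draws the tabulated tail can deviate from the
  empirical tail fraction by up to ~0.008, at 16 000 by ~0.003, which
  keeps the density-based p-value within the package's stated 0.005
  agreement tolerance against the raw draws.
* *Working scale:* the doubling y = 2x and the fold-change gate are
  defined on linear-scale expression. log2-transformed inputs are
  exponentiated on load (`scale="log2"`); calling the rule on log2 values
  would square linear expression, which is a different (and much harsher)
  test.
* *Zero-variance controls:* a constant control vector degenerates the
  inverse-gamma posterior and is a hard error by default; an explicit
  `zero_variance="jitter"` option adds Normal(0, 10⁻⁶) jitter and records
  a warning. The pipeline's noiseless-simulation mode uses this fallback.
* *Fold change* divides by the arithmetic control mean; non-positive
  means are rejected (they indicate a wrong scale flag).
* *Probability reading:* downstream stages need a per-gene "probability
  of up-regulation". The tail-complement 1 − P(Y ≥ x) is used: it is in
  [0, 1] and monotone in x, whereas the density value at x is neither.
* No multiple-testing correction is applied at the raw 0.05 gate; a
  Benjamini–Hochberg option exists on the enrichment stage but is off by
  default, matching the calling rule's design.

A gene is called up-regulated in a tumor sample iff fold ≥ 2 AND
P(Y ≥ x) ≤ 0.05. The deliberate strictness of the doubled variable is the
point of the scheme: a plain t-test or MLE null calls far too many genes
on cohort-sized data.

## TF activation

One-sided hypergeometric over-representation of a TF's targets among a
sample's called genes: p = P(X ≥ k) with X ~ Hypergeom(N, K, m). The
universe N is the set of assayed genes (rows of the expression matrix);
network edges to genes outside it are dropped before counting. Only
over-representation is tested (under-representation has no "activated"
reading), TFs are not required to be up-regulated themselves, and no TF
pruning by target-set size is applied. Activation gate: p ≤ 0.05,
inclusive.

## Subgrouping

k-modes on the binary samples × TFs activation matrix: Hamming
dissimilarity, per-column majority mode updates (ties keep the previous
mode bit, which makes iterations deterministic), Huang density
initialization for the first start plus random distinct-row restarts
(n_init = 10 total), best final cost wins. k defaults to 3 and is a
parameter; since there is no closed-form selection rule, the analysis
driver also emits a cost-vs-k elbow table. Groups are renumbered by
descending size for stable reports. The subgroup is characterized by its
center sample — the member with minimal Hamming distance to the mode,
ties broken by lexicographic sample id. A mode vector need not equal any
observed profile, so the nearest member (not the mode itself) is the
representative. The 2-D view of the profiles is the projection onto the
first two principal components of the centered binary matrix (SVD).

## Upstream cascades

Start nodes are in-degree-0 genes; a fully cyclic pathway falls back to
the members of source strongly-connected components, with a warning.
All simple start → TF paths with ≤ 12 edges are enumerated
(deterministically ordered), with a hard budget of 10⁵ paths per
(pathway, TF) pair — dense signaling graphs can have exponentially many
simple paths, and the cap turns silent blow-up into an explicit error.
Each cascade is scored by the arithmetic mean of its member genes'
up-regulation probabilities in the subgroup's center sample; genes
without a probability (e.g. pathway nodes absent from the assay) score 0
with a warning. The top 3 cascades per (pathway, TF) pair are retained —
the per-pair scope is a deliberate reading of an ambiguous rule, chosen
because it keeps every pathway and every TF represented; ties break by
shorter path, then lexicographic node order, so pruning is input-order
invariant. Retained cascades are merged into a core network; node roles
are start / transduction / tf, edge signs come from the source pathways,
and sign conflicts between pathways are kept and flagged rather than
resolved. Signs do not enter enumeration or scoring; they matter only to
the perturbation stage.

## Perturbation factors

PF(gᵢ) = ΔE(gᵢ) + Σⱼ βᵢⱼ PF(gⱼ)/N_ds(gⱼ) over direct upstream genes gⱼ.
ΔE is the gene's up-regulation probability in the center sample (∈ [0, 1]),
β defaults to the edge sign (+1/−1; a per-edge override is accepted), and
N_ds is the upstream gene's out-degree **within the core network being
scored** — PF is a property of the reported network, not of the full
pathway collection. Acyclic networks are solved by forward propagation in
topological order; cyclic ones by the dense linear solve (I − A)PF = ΔE,
falling back to damped relaxation (factor 0.9, same fixed point, ≤ 10⁴
iterations) when the system is near-singular; non-convergence raises and
names the offending strongly connected component. On DAGs all solvers
agree to 10⁻⁹. Genes present in every subgroup's network are ranked by
mean PF across subgroups, ties by name.

## Drug mapping

A drug maps iff ≥ 1 catalog target is a network gene (names matched
case-insensitively after trimming; no synonym resolution). Combination
records are order-normalized on load, so (A, B) and (B, A) compare equal.
A combination is validated iff **both** members are mapped and its score
is **strictly** greater than 8. Combination targets are ranked by
occurrence across validated rows, each row contributing every target it
lists once per listing.

## Synthetic data

The generator emulates the structure the analysis assumes: gene-level
(μ, σ) drawn from hyper-ranges (μ ∈ [2, 10], σ ∈ [0.5, 2], spanning weak
to strong expression without degenerate variance, scaled by a global
`noise_sd`); Gaussian controls; tumor samples assigned to subgroups
multinomially (equal proportions by default, resampled until every group
is populated); each subgroup driven by its own active TFs — plus an
optional shared core active in all subgroups (`shared_active_tfs`),
mirroring the common-TF overlap real cohorts show — whose disjoint target
blocks are shifted to `planted_fold` × the control mean (default 4, above
the fold-2 gate by design); `tf_flip_noise` drops a planted TF per sample
with the given probability. TF symbols appear as expression rows (shifted
where active) so every cascade node carries a probability. Pathways
contain exactly one planted start → TF path built through the TF's own
targets, with decoy leaves and a dead-end decoy arm that never create a
second start → TF route, so top-1 recovery at zero noise is well defined.
~70% of drugs target planted cascade genes; all pairwise combinations of
those drugs are screened, each synergistic (score ~ U(9, 40)) with
probability `synergy_fraction`, otherwise U(0, 7). Everything is a
deterministic function of (config, seed); per-component substreams keep
each generator operation independently reproducible.

What the generator does **not** emulate: RNA-seq count over-dispersion,
batch effects, correlated co-expression, copy-number or methylation
layers, overlapping TF regulons with shared targets, and pathway
cross-talk. Passing recovery tests therefore demonstrates correctness of
the inference machinery under the model's own assumptions, not
performance on real cohorts.

## Problem sizes

The bundled study and the test suite run at desk scale by choice: 88
controls (the design's control cohort size), 60 tumor samples, ~160 genes,
12 TFs, 8 pathways, 20 drugs. All statistical guarantees checked at this
scale (oracle agreement, calibration, recovery) are scale-free or improve
with size; the implementation is vectorized across genes, so cohort-scale
matrices raise runtime roughly linearly in gene count.

## Known limitations

* The doubled-variable rule is intentionally conservative; genes with
  modest but real shifts (< 2-fold) are invisible to it.
* k-modes is a local optimizer; with few restarts on near-tied data the
  partition can depend on the seed. The elbow table is descriptive, not a
  selection criterion.
* Simple-path enumeration is exponential in the worst case; the length
  cap and path budget bound work but can truncate genuinely long
  cascades.
* PF on cyclic networks depends on the linear system being well-posed;
  strongly amplifying feedback loops (spectral radius of A near 1) are
  reported as failures rather than silently damped.
* Drug mapping is name-based; catalogs with synonyms or salt forms need
  pre-normalization.
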