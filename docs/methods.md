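# Methods

## Substitution model

State order is A, C, G, T everywhere.  The T92 model has stationary
distribution `π_A = π_T = (1−θ)/2`, `π_C = π_G = θ/2` with θ the
equilibrium G+C content; off-diagonal rates are `κ·π_j` for transitions
(A↔G, C↔T) and `π_j` for transversions.  Each rate matrix is scaled so the
expected substitution rate at its own equilibrium is 1, i.e. branch
lengths keep their substitutions/site meaning branch by branch (a
convention the branch-wise model needs because each branch has its own θ).

Transition probabilities use the closed form obtained from the TN93
spectral decomposition under the T92 constraint `π_R = π_Y = 1/2`: with
unscaled time `d = t·r / (κθ(1−θ) + 1/2)`,

```
e2 = exp(−d)             (transversion mode)
e3 = exp(−d (κ+1)/2)     (transition mode)
```

and the matrix entries are linear combinations of 1, e2, e3.  A numerical
`expm` route exists as a cross-check and agrees to ~1e−12 (tested).

The branch-wise (GG-style) model assigns one θ per branch plus a free
`θ_root` for the root state distribution; κ and the gamma shape α are
shared across branches.  Whether the original formulation shared κ across
branches is ambiguous in parts of the literature; sharing is adopted here
as the identifiable, parsimonious choice.

### Discrete gamma

Among-site rate variation uses K equiprobable categories (default K = 8)
of a unit-mean gamma.  Category rates are the conditional means over the
quantile intervals — computed exactly via the regularized incomplete gamma
identity `E[X·1{X≤q}] = P(α+1, αq)` — then renormalized to unit mean.  A
median-of-interval variant is available for sensitivity checks
(`representation="median"`).  Rates are floored at 1e−10 so that extreme
shapes cannot produce an exactly-frozen category (an exact identity matrix
would make mismatching columns impossible *within* that category, which is
legal, but a floor keeps the optimizer's line searches smooth).

## Likelihood, fitting, gradients

Felsenstein pruning runs on pattern-compressed columns with per-node
rescaling of partial likelihoods; gaps and N are missing data (all-ones
partials).  Site likelihoods mix the K categories with equal prior weight.
A site whose likelihood is zero in every category (possible only with
data that contradict a zero-length branch) raises an error naming the
site.

Fitting maximizes the log-likelihood over all `θ_b` (logit scale), θ_root
(logit), κ and α (log scale) with L-BFGS-B; branch lengths are fixed by
default (trees come from an external estimation step) and can be
co-optimized with `FitOptions(optimize_branch_lengths=True)`.  Because the
likelihood is multilinear in the set of per-edge transition matrices, the
derivative with respect to any parameter is a contraction of a per-edge
"flow" tensor (outer product of the downward partial, the sibling
message, and the upward partial, accumulated over sites and categories)
with `dP_edge/dparameter`; the latter is a central finite difference of
the closed form (step 1e−6), which is exact enough for an optimizer
gradient (verified against full finite differences to ~1e−7 relative).
One gradient evaluation therefore costs about three likelihood
evaluations regardless of the number of branches.

Convergence requires the relative objective change below
`loglik_tol` (default 1e−6 absolute on the log-likelihood) and the max
transformed-scale gradient below `grad_tol` (default 1e−3).
Non-convergence returns a result flagged `converged=False` with a warning,
never silently.  Multi-start (default 3 starts: the "auto" initialization
— every θ at the observed global GC, κ=2, α=0.5 — plus perturbed starts)
guards against local optima; the orchestrated pipeline and the replicated
experiments use a single start, which on the synthetic studies reaches the
same optimum (checked by the fixed-point test).

## Ancestral reconstruction

Marginal posteriors per node/site come from the up–down (inside–outside)
algorithm; rate categories are marginalized with their site-specific
posterior weight (joint normalization over state × category), and the root
prior is π(θ_root).  Ancestral sequences are drawn *marginally* — an
independent categorical draw per site from each node's posterior (100
draws per node by default), which is the literal reading of drawing from
per-site posterior distributions; joint stochastic traceback is not
implemented.  Ancestral composition is the G+C fraction of each draw over
the analysed (masked) sites.

## Thermometry

The thermometer is an OLS regression of tip OGT on tip stem-GC (Spearman's
ρ and Pearson's r reported as diagnostics; ≥3 matched taxa and
non-constant composition required).  Tips without an OGT (e.g. Eukaryotes
in real datasets) stay in the tree for likelihood and reconstruction and
are simply excluded from the regression.  Phylogenetically independent
contrasts (Felsenstein's recursion, with branch lengths floored at 1e−8)
provide a phylogeny-corrected correlation test: correlation of the two
contrast sets through the origin, t-test with (n_contrasts − 1) df.  The
contrasts are validated against the defining generalized-least-squares
property — the contrast weight matrix whitens the Brownian tip covariance
(W C Wᵀ = I).

Ancestral OGT estimates push each sampled composition through the
regression.  The 95% interval is the empirical 2.5–97.5 percentile range
of the per-sample predictions, by default convolved with a Gaussian draw
at the regression's residual SD so the interval reflects thermometer
calibration scatter as well as reconstruction uncertainty.  This interval
recipe is this package's own definition.  Node *comparisons* (two-sample
Wilcoxon rank-sum, with direction) use the unconvolved sample sets: the
test asks whether two nodes' reconstructed compositions differ, the
thermometer is the same monotone map for both nodes, and iid calibration
noise would only dilute (and can even invert) an otherwise clear
compositional ordering.

Correspondence analysis (for amino-acid-style thermometers on composition
tables) is the SVD of the standardized residual matrix
`(P − rcᵀ)/√(rcᵀ)`; row scores in principal coordinates are `UΣ/√r`, and
the squared singular values sum to χ²/N (tested identities).

## Site partitioning

Sites are ranked by posterior-mean rate (not MAP category — smoother) and
split at an empirical quantile, default the median, giving equal-sized
slow/fast halves; ties break by site index so the split is deterministic
and exhaustive.  The original analyses do not state their split rule, so
the median is a declared default (`--rate-quantile`), not an inference
from the source.  Each partition is re-analysed from scratch: all
substitution-model parameters are refitted on the sub-alignment.  By
default the partition compositions are mapped through the thermometer
calibrated on the *complete* masked dataset, keeping one temperature scale
across site sets; recalibrating per partition is available
(`partition_thermometer="refit"`) but degenerates when a partition's
compositional spread collapses (slow sites in a uniformly thermophilic tip
sample), in which case its predictions collapse to the tip-mean OGT.

## Synthetic-study generator

`make_synthetic_study` emulates the structure of a universal rRNA study:

- a balanced rooted tree split into a Bacteria-like and an Archaea-like
  clade (default 24 taxa); the two deep root branches are 0.25
  substitutions/site, inner branches 0.08, terminal branches 0.12 —
  magnitudes typical of deep rRNA phylogenies;
- a cool, GC-poor root (`θ_root = 0.45`) and two independently GC-enriched
  clades (targets 0.68 / 0.64).  The θ transition happens *on the two deep
  root branches* and the clade target holds within each clade — the
  mesophilic-root / hyperthermophilic-domain-ancestors scenario — with a
  ±0.05 uniform per-tip jitter on terminal-branch θ so tip compositions
  spread for the regression;
- gamma rate variation (α = 0.5, K = 8) and κ = 2;
- tip OGTs from a known linear thermometer (slope 150 °C per GC unit,
  intercept −20 °C, Gaussian noise SD 5 °C) applied to each tip's lineage
  GC target; a stem mask covering half the sites (the real stem fraction
  is ≈ 0.47).

Every truth (per-branch θ, per-node lineage targets, thermometer
coefficients, true ancestral OGTs) is recorded for recovery tests.  Note
the distinction the generator deliberately preserves: θ is the
*adaptation target* of a lineage, and realized compositions lag it —
after 0.25 subs/site with α = 0.5 the clade-ancestor state distribution
sits near GC ≈ 0.50, between the root (0.45) and the target (0.68).
Reconstruction therefore recovers the *ordering* and the branch-θ truths,
while node-composition-based temperature estimates are attenuated toward
the root value, exactly as slow sites attenuate real reconstructions.

What the generator does **not** emulate: alignment error, secondary
structure (the "stem mask" is a random column subset), base-compositional
covariation between paired sites, lineage-specific rate variation
(covarion effects), a broad mesophile-to-hyperthermophile spread of tip
OGTs within clades, and realistic taxon sampling (125+ taxa).  Passing
tests therefore demonstrate internal correctness and recoverability of
the generative signal, not real-data performance.

## Bias-control experiment

`bias_experiment` reproduces the classic rate/composition confound check:
fit a stationary T92+gamma model, assign each site its MAP rate category
(the assignment rule is configurable; MAP is the default), measure each
category's observed GC, re-simulate each category under a homogeneous T92
with θ pinned to that GC and branch lengths multiplied by the category
rate (so each category's simulation matches its empirical divergence),
concatenate, refit the branch-wise model, and record `θ_root` and the θ of
the root's two child branches; 100 replicates by default.  Character
evolution is sampled directly from the closed-form P(t) (exact in
distribution, no Gillespie stepping).

When slow categories are GC-rich (as in rRNA stems), the refitted θ_root
is pulled above both child-lineage θs — across-site composition
heterogeneity masquerading as a GC-rich root.  With no rate–GC
correlation there is no directional pull.  In the replicated tests a
"directional excess" means the median θ_root exceeds both child medians
by more than 0.05; the experiment's input is 16 taxa × 1200 sites (8
categories × 150 sites), the smallest scale-down from the original
125-taxon × 2239-site alignment at which the sampling noise of
per-category observed compositions (a frozen slow category's GC is an
average over only its own columns) stays safely below that margin.

## Problem sizes and numerical choices

Replicated experiments in the test suite run at reduced but honest sizes:
parameter recovery at 16 taxa × 2000 sites × 20 replicates, the
end-to-end study at the generator defaults (24 taxa × 1500 sites,
100 posterior draws) × 20 replicates, the bias experiment at 20
resimulation replicates (down from 100).  Likelihood exactness is checked
against brute-force enumeration on every rooted topology with ≤ 5 leaves.
Seeds are explicit everywhere; all simulators are reproducible from
(spec, seed).

Known limitations: branch-θ estimates for single deep branches carry
large sampling variance (information about a branch's equilibrium comes
only from the composition shift across that branch); K = 1 disables the
rate-partitioning stage; the CLI supports only binary rooted input trees;
and no attempt is made to model selection on paired stem sites jointly.
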