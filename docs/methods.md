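# Methods

## Substitution process

The state space is the 61 sense codons of the standard genetic code,
ordered lexicographically over (A, C, G, T) with stops removed; this
ordering is frozen so serialized matrices and frequency vectors are
portable. The GY94 generator sets q_ij = 0 for multi-nucleotide changes and
q_ij = π_j · κ^[transition] · ω^[nonsynonymous] otherwise. Codon
equilibrium frequencies come from the data (`equal`, `F1x4`, `F3x4`,
`empirical`; F3x4 — position-specific nucleotide frequencies renormalized
over sense codons — is the default), with a 1e-10 floor on empirical
frequencies so likelihoods stay finite. κ is a free maximum-likelihood
parameter (start 2.0, bounds [0.01, 100]).

**Scaling convention.** A standalone `build_rate_matrix` is normalized to
one expected substitution per unit time at its own ω (the natural invariant
for a single matrix). Inside a site-class *mixture*, all classes share one
scale — the neutral rate at ω = 1 for the current κ — so a class with
ω > 1 evolves genuinely faster than a purifying class. Branch lengths are
therefore expressed in expected substitutions per codon at neutrality; the
free tree-scale parameter absorbs the overall factor, making the fit
equivalent (up to reparameterization) to the common convention of scaling
by the mixture-average rate. Normalizing each class separately would
equalize rates across classes and discard most of the signal that
distinguishes positively selected sites; the simulator and the likelihood
use the shared-reference convention consistently.

Matrix exponentials use the symmetric eigendecomposition of
B = Π^{1/2} Q Π^{-1/2} (exact for a reversible generator), computed once
per (κ, ω) and reused across branches. The four structural components of B
(synonymous/nonsynonymous × transition/transversion) are precomputed per
frequency vector, so each parameter vector costs one 61×61 `eigh` per
distinct ω.

## Likelihood

Felsenstein pruning over codon-site patterns (unique columns, weighted).
Partial likelihoods are rescaled to a per-pattern maximum of 1 at every
internal node with log factors accumulated separately, so deep trees cannot
underflow. Codons containing a gap or N are missing data: their tips carry
all-ones partials, i.e. they are marginalized rather than dropped, matching
the retain-all-sites treatment of alignment gaps. A fully specified
in-frame stop codon is a validation error. The mixture
lnL = Σ_s log Σ_k p_k L_s(ω_k); the per-site per-class log-likelihood
matrix is cached on the results object because the posterior computations
reuse it.

## Fitting

`CodonSiteModel.fit()` maximizes over the ω-structure parameters plus κ and
a single tree-scale factor (default; `branch_mode="full"` optimizes every
branch length, `"fixed"` holds them, and `np` counts whichever is used).
Mixture proportions are not part of the quasi-Newton search: for a fixed
class-likelihood matrix the mixture log-likelihood is concave in the
weights, so an inner EM loop (tolerance 1e-10) profiles them out exactly.
Outer optimization is L-BFGS-B on transformed coordinates (logit for
ω0 ∈ [1e-4, 0.999]; log for beta shapes [0.005, 99], κ, and scale
[1e-4, 100]; ω2/ω_s raw in [1, 50]) with a finite-difference step of 1e-5,
chosen large enough that the inner-EM tolerance cannot corrupt the
gradient. Multi-start defaults: ω0 ∈ {0.1, 0.5} (M1a/M2a), ω_s ∈
{1.5, 3, 5} (M2a/M8), two beta-shape starts for M7/M8a; `starts="fast"` is
a single-start profile for bulk simulation experiments. A fit of an
alternative model can be warm-started from its null (`init_from`), which
evaluates the null's optimum inside the alternative's parameter space and
thereby guarantees lnL(alt) ≥ lnL(null) regardless of optimizer luck; the
boundary point can also be supplied as a one-shot `eval_points` candidate.
If every L-BFGS-B run fails, a Nelder-Mead polish runs from the best point
seen and the results object carries `converged=False` rather than raising.

Beta discretization uses K = 10 equal-probability categories whose values
are the conditional means of the Beta(p, q) on each quantile interval
(computed in closed form from the regularized incomplete beta). `np`
counting: model free parameters (M1a 2, M2a 4, M7 2, M8a 3, M8 4) + 1 for
κ (unless fixed) + branch parameters (1 in scale mode). Frequency counts
are estimated by counting and not included in `np`; they cancel in every
LRT the package performs.

## Tests and FDR

LRT = 2(lnL_alt − lnL_null) with df = Δnp, referred to plain χ²_df
(negative statistics → P = 1.00, never an error). For the boundary M8a–M8
comparison the 50:50 χ²₀:χ²₁ mixture is available
(`null_distribution="mixture"`); plain χ²₁ is the default and is
conservative at the boundary, which the null-calibration experiment
verifies. Storey q-values: π0 estimated on the λ grid 0.05…0.95 (step
0.05) with B = 100 bootstrap resamples choosing the λ that minimizes the
estimated MSE around the plug-in minimum; q_(i) = min_{j≥i} π0·m·p_(j)/j.
Pinning π0 = 1 reduces exactly to Benjamini–Hochberg. Grouped correction
(`lrt_table`) defaults to per-clade, with a joint option.

## Site posteriors

NEB plugs the MLE weights into Bayes' rule per site. BEB averages the
per-site class posteriors over a uniform prior grid on the mixture
parameters, each grid point weighted by its full-data likelihood: for M8
the grid is 10 p0 midpoints × 10 ω_s midpoints on (1, 11) with the beta
shapes held at their MLEs; for M2a a triangular (p0, p1) midpoint grid ×
10 ω0 midpoints on (0, 1) × 10 ω2 midpoints on (1, 11). A degenerate grid
at the MLE reproduces NEB exactly (tested). Three-way aggregation for
beta-based models labels a beta category "neutral" when its ω ≥ 0.95,
"negative" below, and the ω_s class "positive"; for M2a the three classes
map directly. This mapping only affects the aggregate curves, never the
positive-site calls. Site reports are 1-based over the analyzed alignment
columns; `map_alignment_to_reference` converts to ungapped residue numbers
of a reference taxon for joining with mutation tables.

## Pre-analysis QC

Sequences with strictly more than 1% N over their non-gap positions are
removed (the low-complexity criterion of the original curation is not
recoverable from its description; the filter counts ambiguous bases).
Tree pruning collapses degree-2 nodes and sums their branch lengths. The
conserved-block filter is a deliberate simplification of Gblocks-style
trimming: a codon column is conserved when its most frequent fully
resolved codon exceeds 50% of rows and at most half the rows are gapped;
surviving columns are kept in runs of ≥ 4 codons. It is codon-granular,
idempotent, and reports a 1-based column map; bit-exact Gblocks fidelity
is a non-goal and the report says so.

## Mutation and stability integration

The regression of selection on disease burden defaults to binned mode —
sites grouped by mutation count, aggregate posteriors averaged per group,
Pearson r and a least-squares line of mean posterior against count —
because the relationship of interest is between the *average* selection
probability and the count; per-site Pearson is available. Sites absent
from the mutation table count 0 by default (optionally dropped). Constant
inputs yield a flagged "undefined" correlation rather than NaN. ΔΔG
summaries are exact medians/quartiles per substitution class; a display
clip at 10 kcal/mol exists for plotting only and never feeds the
statistics.

## Synthetic data

`simulate_alignment` draws, in a fixed documented order from one seeded
generator (site classes, then root codons from π, then branch transitions
parents-before-children), evolving each site under its class's generator;
stop codons cannot be emitted because the state space excludes them.
`coalescent_tree` builds random bifurcating topologies with exponential
coalescence depths rescaled to a requested mean branch length.
`simulate_mutation_counts` draws Poisson counts with rate
mean_count · exp(coupling · (P(negative) − 0.5)) — a monotone, positive
link chosen as a modeling convenience for the qualitative inverse
relationship between positive selection and disease burden.
`simulate_ddg_table` draws ΔΔG = (median − 1) + exp(spread · Z), a shifted
log-normal whose median is exactly the requested one and whose right skew
mimics empirical stability scans.

What the generators do *not* emulate: indels and alignment error,
among-site rate variation beyond the ω mixture, codon-usage bias (the
default simulations use uniform π), non-binary trees, and real
mutation-database ascertainment. Passing the simulation experiments
demonstrates internal statistical correctness of the estimators and tests,
not fidelity to any particular empirical data set; the published
coefficients that depend on the original alignments and databases are
correspondingly out of scope.

## Study-condition experiments (`codonsel.experiments`)

Null calibration: 100 replicates of M8a data (p0 = 0.85, Beta(0.4, 1.6),
κ = 2.5, 8 taxa, 300 codons, mean branch 0.15 — a conserved vertebrate
coding gene in miniature), fit with the fast protocol (null single-start;
alternative warm-started from the null with the boundary point evaluated
explicitly). The χ²₁ rejection rate at 0.05 must stay ≤ 0.10. Nesting:
ten 6-taxon × 200-codon null datasets, checking lnL(M8) ≥ lnL(M8a) and
lnL(M2a) ≥ lnL(M1a) within 1e-4. Recovery: M2a data with ω2 = 3,
p2 = 0.15 (12 taxa, 600 codons); ω̂2 must land in [2.0, 4.5].
Discrimination: M8 data with ω_s = 4 at 10% of sites (12 taxa, 600
codons); the AUC of BEB P(positive) for truly positive vs other sites
must exceed 0.70. Problem sizes are the package's chosen study
conditions; the bulk experiments use the fast fitting profile, one-off
fits the full multi-start.

## Known limitations

* Branch lengths are optimized through a single scale factor by default;
  full per-branch optimization is available but slow.
* The M8a–M8 test is conservative under plain χ²₁; power at small trees
  (≤ 8 taxa, short branches) is limited and ω_s can run to its bound with
  a tiny weight on information-poor datasets — the LRT remains valid.
* BEB grids follow the published 10-point scheme; ω_s estimates above the
  grid ceiling (11) are handled by the likelihood weighting but the grid
  does not extend to them.
* Only the standard genetic code ships, though the code table is
  pluggable.
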