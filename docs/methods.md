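# Methods

`radiate` implements the macroevolutionary toolkit used to ask whether a
clade radiated adaptively (ecologically driven, "niche-filling") or
non-adaptively (speciation with niche conservatism): lineage-accumulation
statistics, diversification-model selection with a missing-species
correction, Gaussian trait-evolution model selection, disparity-through-time,
and a stepwise multi-optimum Ornstein–Uhlenbeck search for adaptive peaks.
This note records the models, conventions, numerical choices, and the design
decisions taken where the design was genuinely open.

## Trees and time

A `Phylogeny` is a rooted binary ultrametric tree with branch lengths in
millions of years (My).  Ages run backward from the present (tips at age 0);
heights from the root are derived.  Polytomies are resolved to binary with
zero-length branches on load (with a warning), because the γ statistic and
the birth–death likelihoods assume binary trees and dated consensus trees
occasionally carry soft polytomies.  Dated trees also carry rounding noise:
tip depths within a relative 1e-6 of the crown age count as ultrametric;
deviations up to 1e-3 are repaired by extending terminal branches; anything
larger is refused rather than silently fixed.  NEXUS input accepts
TRANSLATE blocks, quoted labels and bracketed comments (the conventions of
BEAST/TreeAnnotator output); labels are preserved verbatim, including
underscores.

Pruning returns the induced subtree crowned at the MRCA of the kept tips,
with degree-2 nodes suppressed and branch lengths summed, so the crown age
of a pruned tree can be younger than the original.

The offset-lognormal calibration prior has quantile
`offset + exp(meanlog + sdlog·Φ⁻¹(p))`; with the stem calibration
(offset 18.5 My, meanlog 1.0, sdlog 1.5) this gives a median of 21.22 My and
a 95% bound of 50.55 My.

## Lineage accumulation: γ and the MCCR test

γ standardizes where branching events sit in time; under complete-sampling
constant-rate pure birth it is asymptotically standard normal, and negative
values indicate an early burst.  Because incomplete sampling biases γ
negative, the Monte-Carlo constant-rate (MCCR) test recalibrates the null:
simulate pure-birth trees at the assumed true clade size, delete tips
uniformly down to the sample size, and take the one-tailed probability that
a null γ falls at or below the observed one.

The null simulator does not build explicit topologies.  A pure-birth tree's
node ages are sums of independent Exp(kλ) internode durations, and its
topology law is uniform pair coalescence backward in time; tracking which
backward lineages subtend sampled tips yields the pruned tree's branching
times directly.  This is mathematically identical to simulating the full
tree and deleting tips, but it vectorizes across all replicates, so the
default 10,000 replicates run in well under a second.  The equivalence is
verified in the test suite against the forward Gillespie simulator
(p-values of forward-simulated pruned trees are uniform against the
backward null, Kolmogorov–Smirnov distance < 0.05 over 2,000 trials).

## Diversification likelihoods

Four models of per-lineage rates as functions of standing diversity N:

| model | speciation λ_N | extinction μ_N | k |
|-------|----------------|-----------------|---|
| Yule  | λ0             | 0               | 1 |
| crBD  | λ0             | μ               | 2 |
| DDL+E | max(0, λ0 − (λ0−μ)·N/K) | μ      | 3 |
| DDE+E | λ0·(μ/λ0)^(N/K)         | μ      | 3 |

The DDE+E form declines exponentially with N and equals μ at N = K; it
degenerates at μ = 0, so μ is bounded below by 1e-6 for that model.

**Master equation.**  The likelihood of the branching times carries a
probability vector Q_n(t) over the number n of *hidden* species — species
alive at t that are not ancestral to the sampled tree.  With k reconstructed
lineages and N = n + k:

    dQ_n/dt = (n−1+2k)·λ_{N−1}·Q_{n−1} + (n+1)·μ_{N+1}·Q_{n+1}
              − N·(λ_N + μ_N)·Q_n

The 2k term sums over which daughter of a split of an observed lineage
continues the observed line.  At each observed node the vector is multiplied
by k·λ_N and k increments; at the present the likelihood reads out the state
holding exactly the assumed number of unsampled extant species
(missing species are carried as hidden-state mass, not as a binomial
ρ-thinning).  The likelihood is conditioned on the crown age and on survival
of both crown lineages.  With this convention the complete-sampling
constant-rate case has the closed form

    log L = log (n−1)! + 2·log(1−u(x₂)) + Σ_{i=3..n} [log λ + log p₁(x_i)]

with u(t) = λ(1−e^{−rt})/(λ−μe^{−rt}) and p₁(t) = r²e^{−rt}/(λ−μe^{−rt})²,
r = λ−μ.  The two routes agree to ~1e-10 on 5–20-tip trees, which is the
package's primary correctness anchor (the pure-birth case is also checked
against the interval-product density analytically).

**Conditioning.**  P(both crown lineages survive) uses the constant-rate
closed form (r/(λ−μe^{−rT}))² with (λ0, μ).  This is exact for Yule and
crBD.  For the diversity-dependent models it is an approximation: the exact
quantity couples the descendant counts of the two crown lineages through the
shared diversity and would require a two-dimensional master equation at
every optimizer step.  The approximation makes the K→∞ limit of the DD
models reproduce crBD exactly (a property the test suite asserts) and only
affects a slowly-varying multiplicative term.

**Numerics.**  Between nodes the generator is a time-invariant tridiagonal
birth–death chain; it is symmetrized by a diagonal similarity and
propagated exactly through `eigh_tridiagonal`, so there is no stiffness
limit and the cost is independent of the rate magnitudes.  When the
similarity scaling would overflow (extreme λ/μ) or when μ = 0, the chain is
an upward cascade and a small dense matrix exponential on a truncated block
is used instead; for μ = 0 truncation at the number of missing species is
exact because hidden lineages never die.  The state space is truncated at
max(100, 4·m+40) hidden species (m = assumed missing), capped at
max(10·K, 1000); the vector is renormalized each interval with the log-scale
accumulated, preventing underflow.  Truncation loses probability mass, so
strongly supercritical corners (μ close to λ at high rates on deep trees)
are *under*-scored, never inflated; the truncation is stability-checked in
the tests.

**Fitting.**  λ0 is optimized in log space, extinction as the ratio
μ/λ0 ∈ [1e-8, 0.999], and K as log(K − n_total) with an upper bound of
1e8 + n_total so the DD models strictly nest crBD.  Each model runs bounded
L-BFGS-B from 5 seeded multi-starts spanning λ0 ∈ [0.1, 50],
μ/λ0 ∈ [0.05, 0.95], K ∈ (1.5·n_total, 20·n_total], plus a warm start at the
nested simpler model's MLE (Yule→crBD, crBD→DD), which guarantees the
maximized log-likelihoods respect model nesting up to local-polish
tolerance.  Non-convergence is flagged on the returned fit, never silent.
AICc uses the number of *tips* as the sample size (the convention that
exactly reproduces the published AICc values from their printed
log-likelihoods), and ΔAICc is relative to the best model.

## Trait evolution: BM, OU, EB, Delta

All four models are Gaussian on the pruned tree of measured species, so the
likelihood is a phylogenetic GLS.  With shared times s_ij and height T:

* BM: V_ij = σ²·s_ij (k = 2: σ², root state z0)
* OU: V_ij = (σ²/2α)·e^{−2α(T−s_ij)}·(1−e^{−2α·s_ij}) — the
  *non-stationary* form with the root state fixed and variance growing from
  zero.  This is the convention required to reproduce the published OU
  log-likelihood scale; a stationary-root OU is a different model.
* EB: V_ij = σ²·(e^{a·s_ij}−1)/a, a ∈ [−10/T, 0]
* Delta: V_ij = σ²·T·(s_ij/T)^δ, δ ∈ (0, 3] — height-preserving time-warp.
  The upper bound of 3 is the conventional default of comparative fitting
  tools; a δ̂ of 3 is a boundary estimate meaning "at least this
  late-accelerated".

z0 is profiled by GLS and σ² analytically, so each fit is a deterministic
1-D bounded optimization of the shape parameter (α ∈ [1e-8, 50/T]);
boundary-pinned estimates are flagged.  AICc uses the number of species with
trait data; the parameter counts (2, 3, 3, 3) and that convention
reconstruct the published AICc column from its printed log-likelihoods.
Maximum likelihood (not REML) is used throughout.  Measurement error is not
modeled: the species values are treated as known means.

Species values from specimen data follow the documented size rule: within
each sex, specimens in the upper two-thirds of the observed SVL range are
averaged (intermediate upper quantiles estimate asymptotic size better than
maxima); the species value is the mean of the sex means, ln-transformed.

Ancestral states under BM are GLS conditional expectations; the root equals
the GLS root state, and each internal node is verified in the tests against
an independent re-rooted GLS computed purely from path distances.

## Disparity through time and MDI

Disparity is the average squared pairwise difference.  The DTT curve starts
at 1 at the root (the clade against itself) and, at each internal-node age
from root to tips, averages the relative disparity of the lineages crossing
just after that node.  The Brownian null simulates datasets at the BM ML
rate (MDI is invariant to the rate, which only shapes the envelope), takes
the pointwise median and 2.5%/97.5% envelope, and MDI integrates
(observed − null median) over relative time by right-continuous steps,
including the terminal segment to the present.  Null curves are evaluated
with closed-form subclade sums vectorized across simulations, so the default
10,000 simulations cost about a second.  A constant trait makes relative
disparity 0/0; the curve is returned as zeros with a warning.

## Adaptive-peak search

The multi-optimum OU (Hansen) model paints branches with regimes; a shift on
a branch starts a regime inherited until overridden, the root belongs to
regime 0, and the root state equals the root regime's optimum (the root
weight e^{−αT} is folded into regime 0, avoiding an unidentifiable extra
parameter).  Tip means are W·θ with the exponentially-discounted occupancy
weights; θ is profiled by GLS (regimes merged onto shared optima sum their
weight columns), σ² analytically, and α numerically — one bounded 1-D search
per candidate model.  AICc charges 2 + (number of distinct regimes)
parameters; shift locations are not charged.

The stepwise search adds, in the forward phase, the shift that most lowers
AICc, and in the backward phase merges regime pairs onto shared optima
(detecting convergence) while AICc improves.  **Acceptance threshold:** a
forward shift must improve AICc by more than 2·ln(C), where C is the number
of candidate branches.  A bare "any improvement" rule is not usable with
best-of-all-branches selection: the maximum of C approximately-χ²₁ deviance
gains under a shift-free model is about 2·ln C ≈ 9, far above the ~2.6
per-parameter AICc penalty, so an uncorrected search accepts around a dozen
spurious shifts on *any* single-regime dataset (verified empirically against
brute-force joint optimization to rule out a likelihood artifact).  The
2·ln C correction is the Bonferroni-style allowance for that selection; with
it, single-peak data yield no shift in the majority of runs while
clade-level shifts of realistic size are still found.  Backward merges keep
the plain strict-improvement rule, since merging only removes parameters.
Ties break toward the branch closest to the root, then by smallest
descendant tip label; the search is fully deterministic and the trace
records every accepted step.

## Synthetic data and the study emulator

`sim_tree` draws trees by forward Gillespie simulation with the same rate
functions as the likelihoods (pure birth conditioned on n uses the exact
internode-exponential construction).  Conditioning on a tip count alone
stops at first passage to n (plus the final exponential wait); conditioning
on both a duration and a count observes the clade at the fixed horizon and
rejects until the extant count matches, which is the cleaner emulation of
"a clade of known age and known diversity".  Extinct lineages are pruned and
the crown tree of the extant tips returned.  `sim_traits` draws from the
exact multivariate normal of the requested model (including the multi-peak
Hansen mean) and deletes a uniform fraction of species.

`make_study_fixture` emulates the study inputs: a constant-rate birth–death
clade with a true diversity of 65 species at the fitted rate scale
(λ = 8, μ = 4.4 per lineage-time, i.e. ε = 0.55), of which 58 are sampled
into the tree; two crown subclades of at least 15 sampled species; two-peak
OU ln-SVL (optima 4.46 and 4.57 ln-mm, α = 0.4375/My) on 41 of the 58
species.  Two calibrations reconcile internally inconsistent published
scales:

* **Crown age 15 My.**  The fitted birth–death rates imply a tree only ~1
  time-unit deep, while the trait analyses demand a dated tree an order of
  magnitude deeper.  The published BM fit pins the real tree's scale: its
  log-likelihood and σ̂² jointly imply ln|S| ≈ 51.3 for the 41-species
  shared-time matrix, which matches birth–death-shaped subtrees at a crown
  age near 15 My.  The simulated tree is therefore rescaled to a 15-My
  crown (tree *shape* is unaffected; rescaling a constant-rate tree is
  equivalent to rescaling its rates).
* **Within-regime σ² = 0.00175.**  The published single-optimum OU σ̂² was
  estimated on two-peak data, so its stationary variance (≈ 0.0050)
  already contains the between-peak component ((0.11/2)² ≈ 0.0030).  The
  generator uses the remainder as within-regime stationary variance so the
  total matches the published fit; reusing the published σ̂² directly would
  double-count the peak separation.

What the emulator reproduces: the sampling design (58 of 65; 41 of 58
measured), the two-subclade structure, constant-rate lineage accumulation,
the scale of the published BM/OU fits, and a two-peak body-size landscape
with the published optima.  What it does not: the true topology and node
ages, any non-uniform pattern in which species lack measurements, intra-
specific sampling error, and the exact single-OU (α̂, σ̂²) signature — a
single-optimum fit to simulated two-peak data recovers a smaller α̂ than the
published value, a known confounding of unmodeled mean structure with weaker
pull.  Tests passing on the emulator therefore validate the machinery and
the qualitative study conclusions (constant-rate accumulation, OU-governed
size evolution, two adaptive peaks), not the study's exact numbers.

## Problem sizes in tests and the acceptance script

Simulation-based checks use: 2,000 replicates for γ normality and for MCCR
p-value uniformity (399 null replicates per test), 200 replicates for λ, α
and σ² recovery, 100 trials for MDI null self-consistency, 30 for envelope
coverage, and 9 runs each for the stepwise search's false-positive and
two-regime recovery rates (each run is a full search).  The acceptance
script runs the complete pipeline on one emulator draw at the full published
depths (10,000 MCCR replicates, 10,000 DTT simulations, three total-
diversity assumptions).

## Known limitations

* Crown-survival conditioning under diversity dependence is approximate
  (constant-rate form); rankings among DD models are insensitive to it, but
  absolute DD log-likelihoods near small K carry the approximation.
* The master-equation truncation under-scores strongly supercritical,
  near-critical corners (μ/λ → 1 at high absolute rates on deep trees).
* Extinction rates estimated from reconstructed trees are weakly identified
  (μ̂ frequently near 0 on constant-rate data); this is a property of the
  data, not the optimizer.
* The stepwise peak search is greedy: it explores single-shift additions and
  pairwise merges only, and its selection-corrected threshold trades a
  small loss of power for calibrated false-positive behavior.
* Time-varying (non-diversity) rate models, trait-dependent diversification,
  multivariate traits and measurement-error models are out of scope.
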