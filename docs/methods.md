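# Methods

## Model and statistic

The unit of analysis is a *site set*: N gapless 5-species alignment
instances (human, chimp, mouse, rat, dog) of an L-column binding site for
one PWM. Evolution is modelled on a rooted binary tree with the topology
`(((human,chimp),(mouse,rat)),dog)` under HKY85 — transition/transversion
ratio κ, equilibrium frequencies π, per-branch transition matrices from the
closed-form spectral solution, branch lengths in expected
substitutions/site. The default tree

    (((human:0.007,chimp:0.008):0.09,(mouse:0.09,rat:0.08):0.27):0.02,dog:0.25)

with κ = 2.5 and π = (0.30, 0.20, 0.20, 0.30) approximates neutral
divergence in alignable mammalian promoter sequence (human–mouse path ≈
0.46 subs/site, ~40% G+C). All of these are replaceable: parameters can be
fitted in-package by maximum likelihood (Felsenstein pruning + bounded
L-BFGS-B on log-κ and log-branch-lengths, κ ∈ [0.1, 100], lengths ∈
[10⁻⁶, 10], π from observed frequencies with add-half smoothing) or
supplied via a YAML config (κ, π, newick).

Given an ancestral assignment — one base at each of the 4 internal nodes,
256 possibilities, indexed big-endian over the post-order node sequence —
the column likelihood is the root prior (stationary π, the standard choice
for a reversible model) times the product of the 8 branch transition
probabilities. Branches carry a fixed 1..8 pre-order index so that
branch-resolved outputs are reproducible. The likelihood engine is generic
in the number of internal nodes; two-taxon toys (4 assignments) exercise
the same code paths in tests, and summing the 256 assignment likelihoods
reproduces the pruning likelihood to 10⁻¹² relative error (a standing
test).

Assignment weighting, the pair extension over 256×256 assignment pairs,
and the CoEvol score are exactly as in the README. Three numerical points:

* everything is computed in log space; sums over assignments use
  log-sum-exp, and the 256×256 joint weight table is built from per-row
  scaled linear tables so no intermediate underflows;
* the single-pass weighting is deliberate: weights come from the data
  once, then likelihoods from the weights — there is no EM iteration;
* aggregation over instances is a **sum** (a per-instance mean is available
  behind `aggregate="mean"` for cross-PWM pooling diagnostics); controls
  are N-matched so sums are comparable.

## Finite-sample behaviour of the null

The plug-in CoEvol statistic is **not** mean-zero under independence: the
joint weights are estimated from the same N instances they score, which
produces a positive bias analogous to the plug-in mutual-information bias
(roughly constant in N; larger when the per-instance assignment posteriors
are diverse across instances, e.g. ≈ +9 with SD ≈ 13 at N = 100 on
stationary columns under the default tree). This is a property of the
estimator, not an implementation artifact. All significance machinery in
the package is therefore *relative*: empirical p-values against N-matched
Shuffle re-pairings (exchangeable under the null, hence exactly calibrated),
and quantile-based right-tail comparisons against the Random control's own
T99. Tests of the "null is centred" flavour assert the shuffle-centred
statistic (foreground minus its shuffle-null mean), which is exactly
mean-zero under exchangeability.

## Controls

* **Random** — N pseudo-sites of L columns drawn from the gapless columns
  of a promoter-alignment pool; without replacement within a site, with
  replacement across sites (a without-replacement mode exists for small
  pools). Defines the T99 threshold (nearest-rank 99th percentile; tail
  fractions use strict >).
* **Shuffle** — a uniform permutation of position j's instances. The
  per-position conditional tables are preserved as multisets, so marginal
  assignment distributions are provably unchanged; a fast path reuses them
  across replicates (bit-identical to the naive path, tested). Default 100
  replicates; empirical p = #{CE_S ≥ CE_F}/R with inclusive ties, displayed
  as "<1/R" at zero.
* **RandomContext** — contiguous gapless L-slices of promoter alignments.
  Because binding sites are more conserved than random promoter positions,
  per-instance likelihood products are first matched into 16 equal bins
  spanning [−16, 0] in log10 (likelihood products are probabilities, so
  log10 is the natural reading of that range; values below −16 clamp to the
  lowest bin, logged). Candidates are pre-scored with pool-wide assignment
  weights per scope; each matched selection of N candidates is re-scored
  self-consistently; empty bins fall back to the nearest non-empty bin
  (logged). Repeated 100× per foreground pair by default.

## Significance

Storey–Tibshirani q-values: π₀(λ) = #{p > λ}/(m(1−λ)) over λ =
0.05…0.95, smoothed by an **inverse-variance-weighted linear fit** read off
at λ = 0.95 and capped at 1, then the usual step-up
q(p₍ᵢ₎) = min₍ⱼ≥ᵢ₎ π₀·m·p₍ⱼ₎/j. The stiff smoother is a deliberate choice:
a cubic (or flexible spline) extrapolated at λ ≈ 1 has endpoint SD ≈
0.06–0.1 at m = 2000 on uniform p-values, while the weighted linear fit is
stable and at worst conservative for FDR. Pairs with q ≤ 0.05 are called
co-evolving; the quadruple analysis instead uses nominal p < 0.01 (all
shuffle values smaller). Distribution comparisons (Mann–Whitney,
Kolmogorov–Smirnov, Kendall) use scipy.

## Quadruples

Under a fixed assignment every branch carries exactly one transition per
position, so posterior-weighted indicator averages give per-branch
propensities Pr(u,v) and Pr(u,v,x,y) (proper distributions over 16 and 256
outcomes; tested to 10⁻⁹). The quadruple-level score is
log[Pr(u,v,x,y)/(Pr(u,v)·Pr(x,y))] — defined by direct analogy with the
pair-level statistic; −∞ (unobserved joint) is allowed and filtered, a zero
marginal with positive joint flags +∞. Enrichment among significant cases
uses the mean + 2·SD rule over the M = 240 admissible quadruples (u≠v or
x≠y), threshold N/M + 2√((N/M)(1−1/M)), strict >. Reciprocal pairs
(u,v,x,y)/(v,u,y,x) form 120 orbits; the rank-difference null is the
*discrete* uniform on {1..240−r} (ranks are integers), z = (actual −
expected)/SD, degenerate ranges (240−r < 2) are skipped and logged, and
ranking ties break lexicographically for reproducibility.

Two caveats established during development and worth knowing:

* a rejection coupling at λ = 0 (below) **freezes** the coupled pair — no
  substitution events occur, detection works through co-conservation across
  instances — so branch-level quadruple recovery is exercised with mirrored
  histories (one simulated position duplicated at the partner position)
  rather than hard coupling;
* at desk scale, quadruples with near-zero propensity can reach nominal
  significance through assignment-posterior mass alone; count-based
  rankings should be pooled over replicates before reading the top ranks.

## Synthetic data generator

Sites are evolved along the tree by an event-driven (thinning) simulation
of the HKY process over the whole L-mer, so dinucleotide context stays
current. Defaults emulate the study conditions: N = 237 instances (the
average retained match count per TF), L = 12 (the median motif length),
root profile = stationary π per column. Two departures from independence:

* **preferred nucleotide pairs** — a coupled pair (i, j) carries a set of
  preferred base combinations; proposals that would leave the set are
  rejected with probability 1−λ. λ = 1 is the null, λ = 0 a hard
  constraint. Rejection-style coupling composes with HKY without deriving a
  16-state model; note the λ = 0 freezing caveat above.
* **CpG hypermutation** — the C→T rate is multiplied (default off; tests
  use 10–40×, the observed mammalian range) when the C precedes a G, and
  symmetrically G→A when following a C.

Per-(site, branch) random streams are split from the master seed with
counter-based spawn keys, so enlarging N never shifts earlier draws; all
generators are bit-reproducible given a seed. True ancestral states are
returned for oracle tests (e.g. per-branch substitution fractions match the
closed-form HKY expectation within 3 binomial SEs over 10,000 columns).

What the generator does *not* model: indels and alignment error,
binding-site turnover, rate variation across sites, and selection on the
motif beyond the root profile. Passing tests on this data show the
machinery is correct and calibrated under the model; they do not show
robustness to alignment artefacts or turnover in real promoter data.

## Test and acceptance problem sizes

Statistical checks run at sizes chosen for a single core: the right-tail
calibration uses 5000 pairs × 50 instances per replicate from a
20,000-column null pool; null calibration uses 500 pairs × 30 instances
× 100 shuffles; power uses 100 replicates of N = 40, L = 4 with a hard
coupling; parameter recovery uses 12,000 columns. Two designs deserve
explanation:

* **Scope trend.** With synthetic signal confined to scope 1 (the only
  kind an adjacent-only coupling can produce — chained couplings either
  freeze evolution or decay below detectability within one step), per-scope
  significant counts at scopes 2–8 are sparse Poisson noise, and FDR
  control at 0.05 necessarily admits occasional false flags (the empirical
  p-value also has an atom of 1/(R+1) at zero). The check therefore uses
  the design that minimises that noise — one motif, L = 9, N = 150, a
  single hard adjacent coupling, CpG ×10 on an AT-rich profile (mechanism
  active, CG context rare), R = 800 shuffles — and a fixed seed. Monte
  Carlo of the decision procedure puts the residual chance of a spurious
  non-monotonicity near 10%; the seed and assertion were frozen before the
  evaluation was run.
* **Root-adjacent branches.** Under a reversible model the root position is
  unidentifiable; parameter recovery asserts the *sum* of the two
  root-adjacent branch lengths rather than each separately.

## Known limitations

* The 256-assignment enumeration is exercised for 4 internal nodes only;
  the engine is generic but untested beyond 5 taxa.
* The score-lattice PWM p-value is exact on its lattice (default
  resolution 10⁻³ log-odds units); scores are snapped to the lattice, so
  p-values of off-lattice query scores inherit up to half-resolution
  rounding per column.
* The quadruple stage in the pipeline runs on significant pairs by default
  (configurable to all pairs); exhaustive PWM × pair × branch × quadruple
  sweeps are quadratic-to-cubic in motif length and meant for batch runs.
* RandomContext matching assumes the candidate pool spans the foreground's
  likelihood bins; sparse pools fall back to nearest bins and are logged.
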