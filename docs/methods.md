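# Methods

## The protogenome model

A protogenome is modelled as an ensemble of single-stranded DNA 150-mers
(50 codons) assembled by uniform, independent, frame-aligned concatenation
of the trimers currently available to a proto-lifeform.  Codons come in
reverse-complement pairs — a trimer and its partner are assumed to
co-occur because templated replication links them — and the 64 trimers
form exactly 32 such pairs (no odd-length DNA sequence is its own reverse
complement).  A chronology is an ordered incorporation of the 32 pairs
over steps M = 1..32.  Each step is characterised solely by its accessible
sequence patterns: pools are resampled fresh at every step, no strands,
damage states, time scales or replication dynamics carry over.  Junction
dimers between concatenated codons are ordinary dimers and are damaged
like any others.

Per step, a pool of n = 10⁴ strands is irradiated in silico at a fixed
dose of 2 photons per base (PpB; on the unshielded early Earth this dose
arrives within minutes) and χ_M is the fraction of strands with zero
lesions.  The accumulated UV stability χ_acc,N = ∏_{M≤N} χ_M ranks
chronologies; because it is a product, a single UV-susceptible early step
suppresses it by orders of magnitude, which is why chronology choice
matters most while few codons are available.

## Photon-to-lesion mechanism

Photon absorption is taken as uniform across bases: per-base photon
counts are iid Poisson(dose).  Each absorbed photon triggers an
independent Bernoulli(μ/2) lesion trial on each of the two dimers
flanking the absorbing base (terminal bases have one flanking dimer,
still at weight μ/2), so the expected lesion count at every dimer is
μ·dose — the operational meaning of a rate measured in damages per
photon-per-base.  By Poisson thinning, the per-dimer lesion counts under
this two-stage mechanism are exactly independent Poisson(μ·dose); the
package implements both the explicit photon mechanism and the per-dimer
Poisson shortcut, and additionally a χ-only sampler that draws each
strand's undamaged indicator directly as Bernoulli(exp(−dose·Σμ)) — the
exact marginal — for the chronology-tracing and search hot paths.  All
three are cross-checked against each other and against the analytic
per-strand average (1/n)·Σ exp(−dose·Σμ) in the test suite.  A lesion is
a lesion: no distinction between CPD and 6–4 photoproduct chemistry is
made, since the readout (polymerase stalling) responds to both.

## Rate measurement model

The damage rates are estimated from an irradiated randomer library
d(ACAC-N₈-ACAC): survival of sequence j at dose D is its depth-normalised
read frequency divided by the unexposed control's.  Two estimators for
the per-sequence rate μ_j are provided:

- `fit_initial_slope` — least-squares line through (D, S) restricted to
  the low-dose regime D ≤ 2 PpB with intercept fixed at 1 (S(j,0) = 1 by
  construction), μ = −slope, negative estimates clamped to zero with a
  warning.  This is the classical initial-slope read-out; its bias is
  second order (≈ μ·D_eff/2 relative).
- the model default (`DamageRateModel.fit(method="log")`) — count-weighted
  regression of −log S on D over all doses, with a first-order
  small-count bias correction (E[log c] ≈ log λ − 1/(2λ)).  Under the
  Poisson-lesion model S = exp(−μD)/Z(D) holds exactly at every dose, so
  all doses are informative and the log fit is the lower-variance choice
  at finite depth.

Depth normalisation can only measure rates **relative to the
library-average survival**: resampling a fixed sequencing depth at each
dose divides every survival by Z(D) = mean library survival, shifting all
fitted μ_j down by roughly the mean strand rate.  The deconvolution
therefore carries a free, sign-unconstrained intercept (implemented by
centering the equations); without it the common negative shift would be
forced into the non-negative context rates and distort them severely.

## Deconvolution and identifiability

The additive model μ_j = Σ_positions μ(left, dimer, right) over the full
tagged 16-mer is fitted by non-negative least squares across all 65536
randomer equations.  The solver forms the 400×400 Gram matrix, takes its
eigendecomposition square-root factor and runs Lawson–Hanson NNLS on the
factor — exact (active-set) and fast, which matters because the noiseless
round trip must close to machine precision.

The model carries a structural **gauge freedom**: adding
f(L,X,Y) − f(X,Y,R) to μ(L, XY, R) for an arbitrary trimer function f
telescopes out of every full-strand sum, leaving only boundary terms that
are constant because the tags are fixed.  Consequently no individual
context rate is identifiable — the design has rank 192 (with intercept)
out of 400 — and only the row-space component of the context vector is
determined by the data.  `DeconvolutionResult` exposes that projector
(`project_identifiable`), the rank, and a strict per-context mask (empty
for the standard design, as it must be).  Parameter-recovery statements
in the tests are made on the identifiable projection, where the noiseless
round trip is exact to ~1e-13 and recovery from counts at depth 10⁷ reads
per dose lands below 10% relative RMSE.  Downstream predictions are
essentially gauge-invariant: interior strand sums telescope, leaving only
the two terminal dimers (2 of 149) exposed to the gauge, so pool-survival
simulations are insensitive to it.  Marginal k-mer tables (k = 2, 3, 4)
are derived from the fitted table by summing the dimers inside each k-mer
with flanks outside it averaged uniformly over A/C/G/T; being linear
images of a particular NNLS representative they inherit some gauge
arbitrariness and are reported for inspection, not as identified
parameters.

k-mer survival aggregation counts a matching strand once regardless of
how many times the k-mer occurs (sequencing reports strand survival, not
per-site damage), and by default matches anywhere in the full 16-mer
including tag/core junctions — a lesion at a junction stalls the
polymerase just as well; `include_tags=False` restricts matching to the
random core.

## Synthetic data generator

The generator provides the statistical structure the analysis assumes,
with defaults anchored to the measured facts about ssDNA photodamage:
dipyrimidines dominate (base dimer rates μ₀: TT = 0.030/PpB — so that
TT-containing trimer rates land in the measured few×10⁻² range — then
TC = 0.022, CT = 0.018, CC = 0.012; purine-containing dimers ≤ 0.002),
each flanking guanine masks a dimer 5-fold (so a doubly G-flanked TT is
reduced 25-fold), each flanking adenine enhances mildly (×1.3, reflecting
the measured TTA > TTG ordering), strand-end flanks are neutral, and
optional relative Gaussian jitter (default off) stresses the pipeline.
With these defaults 78% of generated trimer rates fall below
20×10⁻³/PpB, close to the measured 84% quantile for real ssDNA.  Read counts follow the forward model of the measurement:
survival exp(−μ_j·D) thinning a per-dose multinomial of fixed depth, with
uniform library abundance by default and a log-normal option to
stress-test the normalisation.

The dose grid is a dose-0 control plus 16 regular intervals of 0.25 PpB
up to 4 PpB, placing 8 points inside the low-dose fit window.

What the generator does **not** emulate — and hence what passing tests do
not show about real libraries: sequencing errors, adapter artifacts,
polymerase read-through past lesions (stalling is assumed complete),
PCR/ligation sequence bias beyond a static abundance skew, and any
correlation structure in rates beyond nearest-neighbour context.

## Numerical choices

- RNG: one `numpy` generator per pool; chronology tracing derives a
  generator per step from `SeedSequence(seed, spawn_key=(M,))`, so all
  candidate evaluations at a step share a common stream (variance
  reduction for comparisons) and any witness path re-evaluates
  bit-identically.
- Greedy search ties break lexicographically by pair label (candidates
  are scanned in canonical order and must strictly improve).
- Ambiguous chronologies are enumerated exhaustively when the number of
  valid completions fits the budget (default 10⁴ paths; χ evaluations are
  memoised on the available-trimer set, so shared prefixes are free), and
  bounded by greedy per-step min/max selection otherwise; infeasible
  prefixes (that cannot complete without pair reuse) are pruned.
- Accumulated-stability histograms use geometric bins with constant
  factor 1.5 anchored at the maximum value (anchor configurable); exact
  zeros are reported in a separate underflow bucket.
- Rank decisions use a relative eigenvalue tolerance of 1e-12; strict
  per-context identifiability requires row-space mass > 1 − 1e-8.
- Negative fitted rates are clamped to zero (rates are physical
  quantities); the raw per-randomer estimates are kept unclamped inside
  the model pipeline so that the NNLS stage sees unbiased equations.
- Coordinates are 0-based half-open; a dimer is named by its left base
  index; all sequences are stored 5'→3'.

## Problem sizes

Pools of 10⁴ strands are used for headline numbers (the acceptance
script and the Monte-Carlo-versus-closed-form checks); the greedy-search
and convergence tests run at 2×10³ strands, and toy oracle comparisons at
500 strands with 30-mers, which leaves the statistical assertions
well-powered at 3σ tolerances.  The random-chronology ensemble in the
acceptance script is 250 chronologies; parameter recovery runs at the
full measurement scale (65536 randomers, 17 dose columns, 10⁷ reads per
dose).

## Limitations

- Single-stranded DNA only; RNA and duplex DNA have different
  photophysics and would need their own context-rate tables.
- Rates are relative (see the intercept discussion): absolute damage
  rates require an external anchor such as spike-ins.
- The greedy chronology search is a heuristic; with 32! orderings no
  exhaustive certificate is possible beyond the first step, where greedy
  provably coincides with brute force.
- The model contains no replication dynamics, fitness, mutation or
  repair; χ_acc is a relative photostability metric, not a survival
  probability.
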