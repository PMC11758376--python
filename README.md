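# uvchron

UV photodamage as a selection pressure on early genetic codes.

Before enzymatic repair existed, intense sub-300 nm sunlight on the early
Earth was a direct threat to any surface-exposed genetic polymer: adjacent
pyrimidines form dimeric photolesions (CPDs, 6–4 photoproducts) that stall
replication.  If early life used only a restricted set of codons, the
sequence bias of its "protogenome" determined how quickly lesions
accumulated — and UV light therefore ranked the possible orders in which
codons could have been adopted.  `uvchron` is a toolkit for quantifying
that ranking: it estimates sequence-context-dependent UV damage rates from
irradiated randomer sequencing libraries, irradiates pools of
codon-restricted DNA strands in silico, and scores codon chronologies by
their accumulated UV stability.  It is aimed at origins-of-life and
molecular-evolution researchers who want to test codon-order hypotheses
against photochemical constraints.

## Model

**Damage rates.** A library d(ACAC-N₈-ACAC) (4⁸ = 65536 random cores)
is irradiated at 266 nm; damaged strands drop out of sequencing because
high-fidelity polymerases stall at dimeric lesions.  For each sequence *j*
and dose *D* (photons per base, PpB), survival is the depth-normalised
ratio against the unexposed control,

    S(j, D) = [c(j,D)/total(D)] / [c(j,0)/total(0)]  ≈  exp(−μ_j · D) / Z(D),

with *Z(D)* the library-average survival (depth normalisation only
measures rates relative to the library mean; the deconvolution carries a
free intercept for this).  The per-strand rate is additive over dimers
with nearest-neighbour context,

    μ_j = Σ_i μ(left_i, dimer_i, right_i),

and the 16 × 25 context table μ(L, d, R) is recovered by non-negative
least squares over all 65536 randomer equations
(`DamageRateModel(counts).fit()`).

**Irradiation.** Photons are distributed over every base as independent
Poisson draws with mean = dose; each photon converts into a lesion at
either adjacent dimer with probability μ/2, so lesion counts per dimer are
exactly Poisson(μ·D).  A strand is damaged if it carries one or more
lesions; χ is the fraction of lesion-free strands in a pool of 10⁴
150-mers.

**Chronologies.** The 64 trimers form 32 reverse-complement codon pairs
(a codon and its partner co-occur under templated replication).  A
chronology *C* adds one pair per developmental step *M* = 1..32; at each
step a fresh pool is assembled by uniform random codon concatenation and
irradiated at a fixed 2 PpB, giving χ_M.  The accumulated UV stability

    χ_acc,N(C) = ∏_{M=1..N} χ_M

ranks chronologies: one severely damaged early step suppresses the whole
product.  Greedy stepwise search finds the most/least UV-stable
chronologies; ambiguous literature chronologies (several interchangeable
pairs at a step) are evaluated exhaustively or by greedy bounds into a
min–max stability band.

## Worked example

```python
import numpy as np
import uvchron as uv

table = uv.make_synthetic_context_rates()          # context-dependent rates
settings = uv.IrradiationSettings(dose=2.0, seed=7, n_strands=10_000)

fix = uv.make_fixture_chronologies()
trace = uv.chi_trace(fix["most_stable"], table, settings)
print(f"chi_1  = {trace.chi[0]:.3f}")              # chi_1  = 0.899
print(f"chi_32 = {trace.chi[-1]:.3f}")             # chi_32 = 0.272
print(f"chi_acc,32 = {trace.accumulated().final:.3e}")   # 1.727e-09

worst = uv.chi_trace(fix["most_susceptible"], table, settings)
print(f"worst chi_1 = {worst.chi[0]:.3f}")         # worst chi_1 = 0.014
```

A pool built only from the G/C-rich pair GCG/CGC keeps 90% of its strands
lesion-free at 2 PpB, while a TTT/AAA pool — a dipyrimidine worst case —
keeps 1.4%; starting a chronology with the wrong pair costs 23 orders of
magnitude in accumulated stability (1.7e-9 vs 1.9e-32).

Fitting rates from (simulated) sequencing counts:

```python
counts = uv.simulate_randomer_counts(table, depth=10_000_000,
                                     rng=np.random.default_rng(0))
res = uv.DamageRateModel(counts).fit()
print(res.summary())
# rate estimator:    log
# identifiable:      192/400 rate combinations
# most UV-susceptible trimers: ... TTC 5.36e-02, TTT 5.76e-02
# trimers below 20e-3/PpB: 78.1%
```

The same pipeline runs from the shell: `uvchron synth rates`,
`uvchron rates --counts counts.tsv`, `uvchron trace`, `uvchron search`,
`uvchron ambiguous`, `uvchron hist` (see `uvchron --help`).  Every run
writes a JSON summary with its configuration, seed and output hashes, and
re-running with the same seed reproduces χ values bit-exactly.

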