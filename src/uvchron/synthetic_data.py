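"""Synthetic rate tables and randomer read-count tables.

The generator reproduces the statistical structure the analysis assumes,
so every pipeline stage is testable without the deposited sequencing
data: dipyrimidine dimers (TT highest, then TC/CT/CC) dominate lesion
formation, flanking guanines mask a dipyrimidine roughly five-fold per
flank, flanking adenines mildly enhance it, and purine-containing dimers
damage at near-zero rates.  Read counts follow the forward model of the
measurement: per-strand survival exp(-mu_j * D) thinning a multinomial
sequencing depth across the 4^8 randomers, with an unexposed control.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, DIMERS
from .chronology import Chronology
from .chronology_search import AmbiguousChronology
from .damage_rates import ContextRateTable, RandomerDesign, ReadCountTable

__all__ = [
    "SyntheticRateModel",
    "make_synthetic_context_rates",
    "simulate_randomer_counts",
    "make_fixture_chronologies",
]

#: base dimer rates mu0 in damages per photon-per-base, anchored so the
#: resulting trimer-rate distribution sits near the measured magnitudes
#: (TT-containing trimers in the few-1e-2 range, ~84% of trimers below
#: 20e-3, purine-rich dimers nearly inert)
DEFAULT_BASE_RATES = {
    "TT": 0.030,
    "TC": 0.022,
    "CT": 0.018,
    "CC": 0.012,
    "TA": 0.002,
    "AT": 0.002,
    "CA": 0.001,
    "AC": 0.001,
    "TG": 0.001,
    "GT": 0.001,
    "CG": 0.001,
    "GC": 0.001,
    "AA": 0.001,
    "AG": 0.0008,
    "GA": 0.0008,
    "GG": 0.0005,
}


@dataclass
class SyntheticRateModel:
    """Parameters of the synthetic context-rate generator.

    g_masking divides the rate once per flanking G (so a doubly
    G-flanked TT is masked g^2-fold); a_enhancement multiplies once per
    flanking A.  Strand-end flanks are neutral.  noise_sd adds relative
    Gaussian jitter (rate * N(0, sd)), clamped at zero.
    """

    base_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RATES)
    )
    g_masking: float = 5.0
    a_enhancement: float = 1.3
    noise_sd: float = 0.0

    def __post_init__(self):
        if set(self.base_rates) != set(DIMERS):
            raise ValueError("base_rates must cover all 16 dimers")
        if any(v < 0 for v in self.base_rates.values()):
            raise ValueError("base rates must be non-negative")
        if self.g_masking < 1:
            raise ValueError("g_masking must be >= 1")
        if self.a_enhancement < 1:
            raise ValueError("a_enhancement must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_synthetic_context_rates(
    model: SyntheticRateModel | None = None,
    rng: np.random.Generator | None = None,
) -> ContextRateTable:
    """Context table mu(L, d, R) = mu0(d) / g^#G * a^#A (+ jitter, >= 0)."""
    if model is None:
        model = SyntheticRateModel()
    rates = np.zeros((5, 16, 5))
    g_idx = BASES.index("G")
    a_idx = BASES.index("A")
    for d, dimer in enumerate(DIMERS):
        mu0 = model.base_rates[dimer]
        for l in range(5):
            for r in range(5):
                n_g = int(l == g_idx) + int(r == g_idx)
                n_a = int(l == a_idx) + int(r == a_idx)
                rates[l, d, r] = (
                    mu0 / model.g_masking**n_g * model.a_enhancement**n_a
                )
    if model.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        rates = rates * (1.0 + model.noise_sd * rng.standard_normal(rates.shape))
        rates = np.clip(rates, 0.0, None)
    return ContextRateTable(rates)


def simulate_randomer_counts(
    rates: ContextRateTable,
    design: RandomerDesign | None = None,
    depth: int = 10_000_000,
    rng: np.random.Generator | None = None,
    abundance=None,
) -> ReadCountTable:
    """Forward-simulate the irradiated randomer sequencing measurement.

    Per randomer j the survival at dose D is exp(-mu_j * D) with mu_j
    the additive context rate of the full tagged strand; each dose
    column draws ``depth`` reads multinomially with weights proportional
    to library abundance times survival.  ``abundance`` is None
    (uniform), "lognormal" (sigma = 1, a skewed-library stress test for
    the normalisation), or an explicit weight vector.
    """
    if design is None:
        design = RandomerDesign()
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    mu = design.full_strand_rates(rates)
    n = design.n_randomers
    if abundance is None:
        ab = np.ones(n)
    elif isinstance(abundance, str):
        if abundance != "lognormal":
            raise ValueError("abundance must be None, 'lognormal', or a vector")
        ab = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    else:
        ab = np.asarray(abundance, dtype=float)
        if ab.shape != (n,) or (ab < 0).any() or ab.sum() == 0:
            raise ValueError("abundance vector must be non-negative, length 4^k")
    counts = np.empty((n, design.n_doses), dtype=np.int64)
    for col, dose in enumerate(design.doses):
        w = ab * np.exp(-mu * dose)
        counts[:, col] = rng.multinomial(depth, w / w.sum())
    return ReadCountTable(design=design, counts=counts)


def _data_path(name: str):
    return importlib.resources.files("uvchron.data").joinpath(name)


def make_fixture_chronologies(seed: int = 2025) -> dict[str, object]:
    """Bundled chronology fixtures.

    Returns the packaged most-UV-stable and most-UV-susceptible
    orderings, one fixed-seed random chronology, and two ambiguous
    exemplars (interchangeable pairs concentrated in the earliest or the
    latest steps).
    """
    from .chronology_search import sample_random_chronologies
    from .cli_io import read_chronology

    best = read_chronology(_data_path("best_chronology.tsv"))
    worst = read_chronology(_data_path("worst_chronology.tsv"))
    early = read_chronology(_data_path("early_ambiguity.tsv"))
    late = read_chronology(_data_path("late_ambiguity.tsv"))
    best.label, best.provenance = "most-stable", "fixture"
    worst.label, worst.provenance = "most-susceptible", "fixture"
    early.label, early.provenance = "early-ambiguity", "fixture"
    late.label, late.provenance = "late-ambiguity", "fixture"
    rng = np.random.default_rng(seed)
    random_fix = sample_random_chronologies(1, rng)[0]
    random_fix.label, random_fix.provenance = "random-fixture", f"random(seed={seed})"
    return {
        "most_stable": best,
        "most_susceptible": worst,
        "random": random_fix,
        "early_ambiguity": early,
        "late_ambiguity": late,
    }
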