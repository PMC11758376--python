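"""Codon-pair bookkeeping, pool construction, and chronology stability.

A codon pair is a trimer and its reverse complement, assumed to co-occur
because templated replication links them; the 64 trimers form exactly 32
such pairs (no odd-length DNA is its own reverse complement).  A
chronology is an ordered incorporation of all 32 pairs over developmental
steps M = 1..32.  At each step a fresh pool of strands is assembled by
uniform random concatenation of the currently available codons,
irradiated at the fixed dose, and the fraction chi_M of lesion-free
strands recorded.  The accumulated UV stability chi_acc,N is the product
of chi_M over the first N steps and is the metric by which chronologies
are ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode_sequence, reverse_complement as _revcomp_str, enumerate_kmers
from .damage_rates import ContextRateTable
from .photodamage_mc import IrradiationSettings, pool_chi

__all__ = [
    "reverse_complement",
    "CodonPair",
    "Chronology",
    "SurvivalTrace",
    "AccumulatedStability",
    "LogHistogram",
    "enumerate_codon_pairs",
    "build_pool",
    "chi_trace",
    "accumulated_stability",
    "log_histogram",
    "validate_chronology",
    "step_rng",
]

N_STEPS = 32


def reverse_complement(trimer: str) -> str:
    """Watson–Crick reverse complement of a codon trimer (5'->3')."""
    if len(trimer) != 3:
        raise ValueError(f"expected a trimer, got {trimer!r}")
    return _revcomp_str(trimer)


@dataclass(frozen=True)
class CodonPair:
    """A codon and its reverse complement, added to the genome together."""

    codon: str
    partner: str

    def __post_init__(self):
        object.__setattr__(self, "codon", self.codon.upper())
        object.__setattr__(self, "partner", self.partner.upper())
        if reverse_complement(self.codon) != self.partner:
            raise ValueError(
                f"{self.partner} is not the reverse complement of {self.codon}"
            )

    @classmethod
    def from_codon(cls, codon: str) -> "CodonPair":
        return cls(codon=codon.upper(), partner=reverse_complement(codon))

    @property
    def label(self) -> str:
        return f"{self.codon}/{self.partner}"

    @property
    def trimers(self) -> tuple[str, str]:
        return (self.codon, self.partner)

    def canonical(self) -> "CodonPair":
        """Lexicographically smaller member first."""
        a, b = sorted(self.trimers)
        return CodonPair(codon=a, partner=b)

    def __str__(self) -> str:
        return self.label


def enumerate_codon_pairs() -> list[CodonPair]:
    """The 32 canonical reverse-complement codon pairs.

    Canonical form puts the lexicographically smaller trimer first; the
    list is sorted by that member.  The 32 pairs partition all 64
    trimers.
    """
    pairs = {}
    for trimer in enumerate_kmers(3):
        pair = CodonPair.from_codon(trimer).canonical()
        pairs[pair.codon] = pair
    return [pairs[c] for c in sorted(pairs)]


def validate_chronology(steps: list[CodonPair], complete: bool = True) -> None:
    """Reject duplicate pairs, non-complementary pairs, incomplete partitions.

    CodonPair construction already enforces complementarity; this checks
    the step list: no trimer may appear twice, and with ``complete`` the
    32 steps must partition all 64 trimers.
    """
    seen: set[str] = set()
    for i, pair in enumerate(steps):
        if not isinstance(pair, CodonPair):
            raise ValueError(f"step {i + 1} is not a CodonPair")
        for t in pair.trimers:
            if t in seen:
                raise ValueError(f"trimer {t} appears more than once (step {i + 1})")
            seen.add(t)
    if complete:
        if len(steps) != N_STEPS:
            raise ValueError(f"chronology must have {N_STEPS} steps, has {len(steps)}")
        if len(seen) != 64:
            raise ValueError("chronology does not partition the 64 trimers")


@dataclass
class Chronology:
    """An ordered incorporation of the 32 codon pairs."""

    steps: list[CodonPair]
    label: str = "chronology"
    provenance: str = "unspecified"

    def __post_init__(self):
        validate_chronology(self.steps)

    def available_trimers(self, M: int) -> list[str]:
        """Sorted trimers available at step M (1-based, inclusive)."""
        if not 1 <= M <= len(self.steps):
            raise ValueError(f"step M must be in 1..{len(self.steps)}")
        out: list[str] = []
        for pair in self.steps[:M]:
            out.extend(pair.trimers)
        return sorted(out)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class SurvivalTrace:
    """chi_M for M = 1..32 at a fixed dose, with full provenance."""

    label: str
    chi: np.ndarray
    dose: float
    n_strands: int
    seed: int

    def __post_init__(self):
        self.chi = np.asarray(self.chi, dtype=float)
        if self.chi.ndim != 1 or len(self.chi) != N_STEPS:
            raise ValueError(f"trace must hold {N_STEPS} chi values")
        if ((self.chi < 0) | (self.chi > 1)).any():
            raise ValueError("chi values must lie in [0, 1]")

    def accumulated(self, N: int = N_STEPS) -> "AccumulatedStability":
        return accumulated_stability(self, N)


@dataclass
class AccumulatedStability:
    """Prefix products chi_acc,N = prod_{M<=N} chi_M."""

    label: str
    chi_acc: np.ndarray  # (N,) prefix products for N = 1..len

    def __post_init__(self):
        self.chi_acc = np.asarray(self.chi_acc, dtype=float)

    @property
    def final(self) -> float:
        return float(self.chi_acc[-1])

    def at(self, N: int) -> float:
        if not 1 <= N <= len(self.chi_acc):
            raise ValueError(f"N must be in 1..{len(self.chi_acc)}")
        return float(self.chi_acc[N - 1])


def _trimer_codes(trimers: list[str]) -> np.ndarray:
    return np.stack([encode_sequence(t) for t in trimers])


def build_pool_codes(
    trimers: list[str],
    n_strands: int,
    strand_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Encoded pool (n, L): frame-aligned concatenation of uniform codons."""
    if not trimers:
        raise ValueError("no codons available to build a pool")
    if strand_length % 3:
        raise ValueError("strand_length must be a multiple of 3")
    table = _trimer_codes(trimers)
    n_codons = strand_length // 3
    picks = rng.integers(0, len(trimers), size=(n_strands, n_codons))
    return table[picks].reshape(n_strands, strand_length)


def build_pool(
    available_pairs: list[CodonPair],
    settings: IrradiationSettings,
    rng: np.random.Generator,
) -> list[str]:
    """Pool of strands randomly assembled from the available codon pairs.

    Each strand concatenates strand_length/3 trimers drawn uniformly and
    independently from the union of both members of every available
    pair.  Junction dimers between codons are real dimers and are
    damaged like any others.
    """
    if not available_pairs:
        raise ValueError("available_pairs is empty")
    trimers = sorted(t for p in available_pairs for t in p.trimers)
    codes = build_pool_codes(trimers, settings.n_strands, settings.strand_length, rng)
    from ._seq import decode_sequence

    return [decode_sequence(row) for row in codes]


def step_rng(seed: int, M: int) -> np.random.Generator:
    """Deterministic per-step generator derived from (seed, step M).

    All candidate evaluations at a given step share this stream (common
    random numbers), and witness paths re-evaluate bit-identically.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(M,)))


def step_chi(
    trimers: list[str],
    M: int,
    rates: ContextRateTable,
    settings: IrradiationSettings,
) -> float:
    """chi of a fresh pool built from ``trimers`` at step M."""
    rng = step_rng(settings.seed, M)
    codes = build_pool_codes(trimers, settings.n_strands, settings.strand_length, rng)
    return pool_chi(codes, settings.dose, rates, rng)


def chi_trace(
    chronology: Chronology,
    rates: ContextRateTable,
    settings: IrradiationSettings,
) -> SurvivalTrace:
    """chi_M for every step of a chronology.

    Each step builds and irradiates a fresh, independent pool from the
    first M pairs; strands and damage states are never carried between
    steps (the pool's sequence bias is the only thing that evolves).
    """
    chi = np.empty(len(chronology))
    for M in range(1, len(chronology) + 1):
        chi[M - 1] = step_chi(chronology.available_trimers(M), M, rates, settings)
    return SurvivalTrace(
        label=chronology.label,
        chi=chi,
        dose=settings.dose,
        n_strands=settings.n_strands,
        seed=settings.seed,
    )


def accumulated_stability(trace, N: int | None = None) -> AccumulatedStability:
    """Accumulated UV stability: prefix products of chi_M up to N.

    ``trace`` is a SurvivalTrace or a plain chi sequence.  Low-chi steps
    dominate the product, so an early UV-susceptible step suppresses the
    whole chronology's accumulated stability.
    """
    if isinstance(trace, SurvivalTrace):
        chi = trace.chi
        label = trace.label
    else:
        chi = np.asarray(trace, dtype=float)
        label = "trace"
    if N is None:
        N = len(chi)
    if not 1 <= N <= len(chi):
        raise ValueError(f"N must be in 1..{len(chi)}, got {N}")
    return AccumulatedStability(label=label, chi_acc=np.cumprod(chi[:N]))


@dataclass
class LogHistogram:
    """Histogram on geometric bins (constant factor in log scale).

    ``edges`` is descending, anchored at the largest value; bin k covers
    (edges[k+1], edges[k]].  Exact zeros (numerical underflow of a
    product of chi values) are counted in ``n_underflow`` instead of a
    bin.
    """

    edges: np.ndarray
    counts: np.ndarray
    factor: float
    n_underflow: int = 0

    @property
    def n(self) -> int:
        return int(self.counts.sum()) + self.n_underflow


def log_histogram(
    values, factor: float = 1.5, anchor: float | None = None
) -> LogHistogram:
    """Collate values into bins of constant width factor on a log scale.

    Used for distributions of accumulated stabilities, which span many
    orders of magnitude.  Edges descend from ``anchor`` (default: the
    maximum value) by the given factor; negative values are an error,
    zeros go to the underflow bucket.
    """
    values = np.asarray(values, dtype=float)
    if factor <= 1:
        raise ValueError("factor must be > 1")
    if (values < 0).any():
        raise ValueError("values must be non-negative (chi products)")
    n_underflow = int((values == 0).sum())
    pos = values[values > 0]
    if pos.size == 0:
        return LogHistogram(
            edges=np.array([]), counts=np.array([], dtype=int),
            factor=factor, n_underflow=n_underflow,
        )
    top = float(pos.max()) if anchor is None else float(anchor)
    if top < pos.max():
        raise ValueError("anchor must be >= the largest value")
    logf = np.log(factor)
    # smallest k with top/factor^k strictly below the minimum value
    k_min = np.log(top / pos.min()) / logf
    n_bins = max(1, int(np.floor(k_min + 1e-9)) + 1)
    edges = top / factor ** np.arange(n_bins + 1)
    # bin index: value v in (edges[k+1], edges[k]]  <=>  k = floor(log(top/v)/logf), clipped
    with np.errstate(divide="ignore"):
        k = np.floor(np.log(top / pos) / logf + 1e-9).astype(int)
    k = np.clip(k, 0, n_bins - 1)
    counts = np.bincount(k, minlength=n_bins)
    return LogHistogram(
        edges=edges, counts=counts, factor=factor, n_underflow=n_underflow
    )
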