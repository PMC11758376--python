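"""Extreme, random, and ambiguous codon chronologies.

The space of chronologies (32! ~ 2.6e35 orderings) cannot be exhausted,
so the most/least UV-stable chronologies are found by greedy stepwise
optimisation: at each step every unused candidate pair is appended to
the current prefix, a fresh pool is scored with a common per-step random
stream, and the best (or worst) candidate is kept.  Literature amino
acid chronologies often allow several codon pairs interchangeably at a
step; such ambiguous chronologies are evaluated either by exhaustive
enumeration of all completions (when the path count fits a budget) or
by greedy per-step bounds, yielding a min/max band of accumulated
stabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chronology import (
    Chronology,
    CodonPair,
    N_STEPS,
    accumulated_stability,
    enumerate_codon_pairs,
    step_chi,
)
from .damage_rates import ContextRateTable
from .photodamage_mc import IrradiationSettings

__all__ = [
    "AmbiguousChronology",
    "StabilityRange",
    "greedy_extreme_chronology",
    "sample_random_chronologies",
    "evaluate_ambiguous",
]


@dataclass
class AmbiguousChronology:
    """A chronology whose steps may each offer several candidate pairs.

    Every selectable path must use each pair at most once, and at least
    one completion into a full 32-pair partition must exist.
    """

    steps: list[list[CodonPair]]
    label: str = "ambiguous"
    provenance: str = "unspecified"

    def __post_init__(self):
        if any(len(opts) == 0 for opts in self.steps):
            raise ValueError("every step must offer at least one codon pair")
        for opts in self.steps:
            labels = [p.canonical().label for p in opts]
            if len(set(labels)) != len(labels):
                raise ValueError("duplicate candidate pair within a step")
        if not self._has_completion():
            raise ValueError("ambiguous chronology admits no valid completion")

    def _has_completion(self) -> bool:
        return _feasible(self.steps, 0, frozenset())

    @property
    def is_ambiguous(self) -> bool:
        return any(len(opts) > 1 for opts in self.steps)

    def n_paths(self, cap: int = 10_000_000) -> int:
        """Number of valid completions, counted up to ``cap``."""
        count = 0

        def rec(i: int, used: frozenset) -> None:
            nonlocal count
            if count > cap:
                return
            if i == len(self.steps):
                count += 1
                return
            for pair in self.steps[i]:
                key = pair.canonical().label
                if key not in used:
                    rec(i + 1, used | {key})

        rec(0, frozenset())
        return count


def _feasible(steps, i: int, used: frozenset, _memo=None) -> bool:
    """Can steps[i:] still be completed without re-using a pair?"""
    if _memo is None:
        _memo = {}
    if i == len(steps):
        return True
    key = (i, used)
    if key in _memo:
        return _memo[key]
    ok = False
    for pair in steps[i]:
        lab = pair.canonical().label
        if lab not in used and _feasible(steps, i + 1, used | {lab}, _memo):
            ok = True
            break
    _memo[key] = ok
    return ok


@dataclass
class StabilityRange:
    """Per-prefix min/max accumulated stability with witness paths."""

    label: str
    min_acc: np.ndarray
    max_acc: np.ndarray
    min_witness: list[tuple[str, ...]]  # per N: pair labels of the minimising path prefix
    max_witness: list[tuple[str, ...]]
    method: str  # "exhaustive" or "greedy"
    n_paths: int

    def __post_init__(self):
        self.min_acc = np.asarray(self.min_acc, dtype=float)
        self.max_acc = np.asarray(self.max_acc, dtype=float)
        if (self.min_acc > self.max_acc + 1e-15).any():
            raise ValueError("min accumulated stability exceeds max")

    def width(self, N: int) -> float:
        return float(self.max_acc[N - 1] - self.min_acc[N - 1])


class _StepChiCache:
    """Memoised chi_M keyed by (step, available trimer set).

    chi depends only on the set of available trimers and the per-step
    stream, not on the order in which pairs were added, so completions
    sharing a prefix set re-use the same pool evaluation.
    """

    def __init__(self, rates: ContextRateTable, settings: IrradiationSettings):
        self.rates = rates
        self.settings = settings
        self._cache: dict[tuple[int, tuple[str, ...]], float] = {}

    def chi(self, M: int, trimers: tuple[str, ...]) -> float:
        key = (M, trimers)
        if key not in self._cache:
            self._cache[key] = step_chi(list(trimers), M, self.rates, self.settings)
        return self._cache[key]


def _trimer_key(pairs: list[CodonPair]) -> tuple[str, ...]:
    return tuple(sorted(t for p in pairs for t in p.trimers))


def greedy_extreme_chronology(
    rates: ContextRateTable,
    settings: IrradiationSettings,
    objective: str = "max",
) -> Chronology:
    """Most (objective="max") or least ("min") UV-stable chronology.

    Stepwise greedy: at each step M every unused candidate pair is
    appended to the prefix, chi_M of a fresh pool is evaluated with the
    common per-step stream, and the extreme candidate is kept.  Ties
    break lexicographically by pair label (candidates are scanned in
    label order with strict improvement required).
    """
    if objective not in ("max", "min"):
        raise ValueError("objective must be 'max' or 'min'")
    better = (lambda a, b: a > b) if objective == "max" else (lambda a, b: a < b)
    cache = _StepChiCache(rates, settings)
    remaining = enumerate_codon_pairs()  # sorted by label already
    chosen: list[CodonPair] = []
    for M in range(1, N_STEPS + 1):
        best_pair = None
        best_chi = None
        for pair in remaining:
            chi = cache.chi(M, _trimer_key(chosen + [pair]))
            if best_chi is None or better(chi, best_chi):
                best_pair, best_chi = pair, chi
        chosen.append(best_pair)
        remaining = [p for p in remaining if p != best_pair]
    return Chronology(
        steps=chosen,
        label=f"greedy-{objective}",
        provenance="greedy",
    )


def sample_random_chronologies(
    n: int = 10_000, rng: np.random.Generator | None = None
) -> list[Chronology]:
    """Uniformly random permutations of the 32 canonical codon pairs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    pairs = enumerate_codon_pairs()
    out = []
    for i in range(n):
        perm = rng.permutation(len(pairs))
        out.append(
            Chronology(
                steps=[pairs[j] for j in perm],
                label=f"random-{i}",
                provenance="random",
            )
        )
    return out


def evaluate_ambiguous(
    amb: AmbiguousChronology,
    rates: ContextRateTable,
    settings: IrradiationSettings,
    budget: int = 10_000,
) -> StabilityRange:
    """Min/max accumulated stability over the completions of ``amb``.

    If the number of valid completions is within ``budget`` they are
    enumerated exhaustively (chi evaluations are memoised on the
    available-trimer set, so shared prefixes cost nothing); otherwise
    greedy per-step min/max selection provides bounds.  The method used
    is recorded on the result, and each reported extreme carries the
    witness path that realises it under the same per-step streams.
    """
    n_paths = amb.n_paths(cap=budget)
    cache = _StepChiCache(rates, settings)
    n_steps = len(amb.steps)
    if n_paths <= budget:
        method = "exhaustive"
        min_acc = np.full(n_steps, np.inf)
        max_acc = np.full(n_steps, -np.inf)
        min_wit: list[tuple[str, ...] | None] = [None] * n_steps
        max_wit: list[tuple[str, ...] | None] = [None] * n_steps

        def rec(i: int, chosen: list[CodonPair], acc: float):
            if i == n_steps:
                return
            for pair in amb.steps[i]:
                lab = pair.canonical().label
                if any(p.canonical().label == lab for p in chosen):
                    continue
                path = chosen + [pair]
                chi = cache.chi(i + 1, _trimer_key(path))
                new_acc = acc * chi
                # only record prefixes that can still be completed
                if not _feasible(amb.steps, i + 1, frozenset(
                    p.canonical().label for p in path
                )):
                    continue
                labels = tuple(p.label for p in path)
                if new_acc < min_acc[i]:
                    min_acc[i] = new_acc
                    min_wit[i] = labels
                if new_acc > max_acc[i]:
                    max_acc[i] = new_acc
                    max_wit[i] = labels
                rec(i + 1, path, new_acc)

        rec(0, [], 1.0)
        return StabilityRange(
            label=amb.label,
            min_acc=min_acc,
            max_acc=max_acc,
            min_witness=[w for w in min_wit],
            max_witness=[w for w in max_wit],
            method=method,
            n_paths=n_paths,
        )

    # greedy bounds: pick the extreme feasible candidate at each step
    def greedy(objective: str):
        better = (lambda a, b: a > b) if objective == "max" else (lambda a, b: a < b)
        chosen: list[CodonPair] = []
        acc = 1.0
        accs, wits = [], []
        for i in range(n_steps):
            best = None
            best_chi = None
            for pair in amb.steps[i]:
                lab = pair.canonical().label
                if any(p.canonical().label == lab for p in chosen):
                    continue
                if not _feasible(
                    amb.steps, i + 1,
                    frozenset(p.canonical().label for p in chosen) | {lab},
                ):
                    continue
                chi = cache.chi(i + 1, _trimer_key(chosen + [pair]))
                if best_chi is None or better(chi, best_chi):
                    best, best_chi = pair, chi
            chosen.append(best)
            acc *= best_chi
            accs.append(acc)
            wits.append(tuple(p.label for p in chosen))
        return np.array(accs), wits

    min_acc, min_wit = greedy("min")
    max_acc, max_wit = greedy("max")
    return StabilityRange(
        label=amb.label,
        min_acc=min_acc,
        max_acc=max_acc,
        min_witness=min_wit,
        max_witness=max_wit,
        method="greedy",
        n_paths=n_paths,
    )
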