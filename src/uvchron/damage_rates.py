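"""Sequence-context-dependent UV damage rates from randomer sequencing counts.

The measurement this module models: a library of short single-stranded DNA
oligomers with a fixed 5'/3' tag and a fully randomised core (default
d(ACAC-N8-ACAC), 65536 distinct cores) is irradiated at 266 nm and sampled
at a series of doses D (in photons per base, PpB).  Library preparation uses
polymerases that stall at dimeric photolesions, so damaged strands drop out
of the read counts.  Dividing each sequence's depth-normalised count by its
unexposed control gives the survival S(j, D) of sequence j, which under
independent Poisson lesion formation decays as exp(-mu_j * D).

The per-sequence rates mu_j are additive over the dimers of the strand,
with each dimer's contribution depending on its immediate left/right
neighbours.  Deconvolving the 4^8 per-sequence rates into the 16 x 25
context-resolved dimer rates mu(left, dimer, right) is a sparse linear
problem solved here by non-negative least squares.

The statsmodels-style entry point is :class:`DamageRateModel`; the
individual pipeline stages (:func:`compute_survival`,
:func:`aggregate_kmer_survival`, :func:`fit_initial_slope`,
:func:`deconvolve_context_rates`) are also public.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse

from ._seq import (
    BASES,
    DIMERS,
    END_CODE,
    END_SYMBOL,
    decode_sequence,
    dimer_context_codes,
    encode_sequence,
    enumerate_kmers,
    kmer_code_matrix,
)

__all__ = [
    "ContextRateTable",
    "KmerRateTable",
    "RandomerDesign",
    "ReadCountTable",
    "SurvivalCurve",
    "SurvivalTable",
    "compute_survival",
    "aggregate_kmer_survival",
    "fit_initial_slope",
    "deconvolve_context_rates",
    "DeconvolutionResult",
    "DamageRateModel",
    "DamageRateResults",
]

#: flank alphabet used in context keys; "-" is a strand end (no neighbour)
FLANKS = tuple(BASES) + (END_SYMBOL,)

N_CONTEXTS = 5 * 16 * 5  # left x dimer x right = 400


def _flank_code(symbol: str) -> int:
    if symbol in (END_SYMBOL, "", None):
        return END_CODE
    if symbol in BASES:
        return BASES.index(symbol)
    raise ValueError(f"invalid flank symbol {symbol!r} (expected A/C/G/T or '-')")


def context_index(left: str, dimer: str, right: str) -> int:
    """Flat 0..399 index of a (left, dimer, right) context."""
    if dimer not in DIMERS:
        raise ValueError(f"invalid dimer {dimer!r}")
    return _flank_code(left) * 80 + DIMERS.index(dimer) * 5 + _flank_code(right)


def context_label(flat: int) -> tuple[str, str, str]:
    """Inverse of :func:`context_index`."""
    left, rest = divmod(flat, 80)
    dimer, right = divmod(rest, 5)
    return FLANKS[left], DIMERS[dimer], FLANKS[right]


class ContextRateTable:
    """Damage rates mu(left, dimer, right) in damages per photon-per-base.

    Internally a (5, 16, 5) array indexed by (left flank, dimer, right
    flank) with flank code 4 = strand end.  All 400 entries are always
    present; rates are non-negative and finite.
    """

    def __init__(self, rates: np.ndarray):
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (5, 16, 5):
            raise ValueError(f"rates must have shape (5, 16, 5), got {rates.shape}")
        if not np.all(np.isfinite(rates)):
            raise ValueError("rates must be finite")
        if (rates < 0).any():
            raise ValueError("rates must be non-negative")
        self.rates = rates

    # -- construction -------------------------------------------------
    @classmethod
    def zeros(cls) -> "ContextRateTable":
        return cls(np.zeros((5, 16, 5)))

    @classmethod
    def from_flat(cls, flat: np.ndarray) -> "ContextRateTable":
        return cls(np.asarray(flat, dtype=float).reshape(5, 16, 5))

    @classmethod
    def from_mapping(cls, mapping) -> "ContextRateTable":
        """Build from {(left, dimer, right): rate}; all 400 keys required."""
        rates = np.full((5, 16, 5), np.nan)
        for (left, dimer, right), mu in mapping.items():
            rates[_flank_code(left), DIMERS.index(dimer), _flank_code(right)] = mu
        missing = np.argwhere(np.isnan(rates))
        if len(missing):
            names = ", ".join(
                f"({FLANKS[l]},{DIMERS[d]},{FLANKS[r]})" for l, d, r in missing[:5]
            )
            raise ValueError(
                f"rate table incomplete: {len(missing)} of 400 contexts missing "
                f"(first: {names})"
            )
        return cls(rates)

    @classmethod
    def homogeneous(cls, mu: float) -> "ContextRateTable":
        """Every dimer in every context damaged at the same rate ``mu``."""
        return cls(np.full((5, 16, 5), float(mu)))

    # -- accessors ----------------------------------------------------
    def __getitem__(self, key) -> float:
        left, dimer, right = key
        return float(self.rates[_flank_code(left), DIMERS.index(dimer), _flank_code(right)])

    def to_frame(self) -> pd.DataFrame:
        """Long-form table with columns left, dimer, right, rate ('-' = end)."""
        rows = [
            (FLANKS[l], DIMERS[d], FLANKS[r], self.rates[l, d, r])
            for l in range(5)
            for d in range(16)
            for r in range(5)
        ]
        return pd.DataFrame(rows, columns=["left", "dimer", "right", "rate"])

    @property
    def flat(self) -> np.ndarray:
        """(400,) view in context_index order."""
        return self.rates.reshape(-1)

    @property
    def max_rate(self) -> float:
        return float(self.rates.max())

    # -- strand arithmetic --------------------------------------------
    def pool_dimer_rates(self, codes: np.ndarray) -> np.ndarray:
        """Per-dimer rates for encoded strands; shape (n, L-1)."""
        left, dimer, right = dimer_context_codes(codes)
        return self.rates[left, dimer, right]

    def strand_total_rates(self, codes: np.ndarray) -> np.ndarray:
        """Total additive rate sum_dimers mu(context) per strand."""
        return self.pool_dimer_rates(codes).sum(axis=1)

    def sequence_rate(self, seq: str) -> float:
        """Total rate of one ACGT sequence (strand ends use '-' contexts)."""
        return float(self.strand_total_rates(encode_sequence(seq)[None, :])[0])

    def kmer_rates(self, k: int) -> "KmerRateTable":
        """Marginal k-mer rates (k = 2, 3 or 4).

        The rate of a k-mer sums the context rates of the dimers it
        contains; flanks falling outside the k-mer are marginalised by a
        uniform average over A/C/G/T (interior positions of a long
        random strand, not strand ends).
        """
        if k not in (2, 3, 4):
            raise ValueError("k must be 2, 3 or 4")
        inner = self.rates[:4, :, :4]  # exclude strand-end flanks
        marg_l = inner.mean(axis=0)  # (16, 4): left flank averaged out
        marg_r = inner.mean(axis=2)  # (4, 16)
        marg_lr = inner.mean(axis=(0, 2))  # (16,)
        codes = kmer_code_matrix(k)
        out: dict[str, float] = {}
        for row in codes:
            mu = 0.0
            for i in range(k - 1):
                d = 4 * row[i] + row[i + 1]
                has_l, has_r = i > 0, i + 2 < k
                if has_l and has_r:
                    mu += self.rates[row[i - 1], d, row[i + 2]]
                elif has_r:
                    mu += marg_l[d, row[i + 2]]
                elif has_l:
                    mu += marg_r[row[i - 1], d]
                else:
                    mu += marg_lr[d]
            out[decode_sequence(row)] = float(mu)
        return KmerRateTable(k=k, rates=out)


@dataclass
class KmerRateTable:
    """Damage rates per k-mer (damages per photon-per-base)."""

    k: int
    rates: dict[str, float]

    def __post_init__(self):
        if self.k not in (2, 3, 4):
            raise ValueError("k must be 2, 3 or 4")
        expected = set(enumerate_kmers(self.k))
        if set(self.rates) != expected:
            raise ValueError(f"rate table must cover all {len(expected)} {self.k}-mers")
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("k-mer rates must be non-negative")

    def __getitem__(self, kmer: str) -> float:
        return self.rates[kmer.upper()]

    def as_series(self) -> pd.Series:
        return pd.Series(self.rates, name=f"{self.k}mer_rate").sort_index()

    def quantile_below(self, threshold: float) -> float:
        """Fraction of k-mers with rate below ``threshold``."""
        vals = np.fromiter(self.rates.values(), dtype=float)
        return float((vals < threshold).mean())


@dataclass(frozen=True)
class RandomerDesign:
    """Layout of the randomer strand and the irradiation dose series.

    Defaults mirror a d(ACAC-N8-ACAC) 16-mer probed at a dose-0 control
    plus 16 regular intervals of 0.25 PpB up to 4 PpB.
    """

    tag5: str = "ACAC"
    tag3: str = "ACAC"
    random_length: int = 8
    doses: tuple[float, ...] = (0.0,) + tuple(0.25 * k for k in range(1, 17))

    def __post_init__(self):
        encode_sequence(self.tag5) if self.tag5 else None
        encode_sequence(self.tag3) if self.tag3 else None
        if self.random_length < 1:
            raise ValueError("random_length must be >= 1")
        d = np.asarray(self.doses, dtype=float)
        if len(d) < 2 or d[0] != 0.0:
            raise ValueError("doses must start with the 0-dose control")
        if not np.all(np.diff(d) > 0):
            raise ValueError("doses must be strictly increasing")

    @property
    def n_randomers(self) -> int:
        return 4**self.random_length

    @property
    def strand_length(self) -> int:
        return len(self.tag5) + self.random_length + len(self.tag3)

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    def randomer_codes(self) -> np.ndarray:
        """(4^k, k) encoded random cores in lexicographic order."""
        return kmer_code_matrix(self.random_length)

    def full_codes(self) -> np.ndarray:
        """(4^k, strand_length) encoded full strands including tags."""
        n = self.n_randomers
        core = self.randomer_codes()
        parts = []
        if self.tag5:
            parts.append(np.tile(encode_sequence(self.tag5), (n, 1)))
        parts.append(core)
        if self.tag3:
            parts.append(np.tile(encode_sequence(self.tag3), (n, 1)))
        return np.concatenate(parts, axis=1)

    def randomer_sequences(self) -> np.ndarray:
        return _randomer_sequences_cached(self.random_length)

    def sequence_index(self, seq: str) -> int:
        """Lexicographic index of a random-core sequence."""
        codes = encode_sequence(seq)
        if len(codes) != self.random_length:
            raise ValueError(
                f"expected a {self.random_length}-mer core sequence, got {seq!r}"
            )
        return int(np.dot(codes, 4 ** np.arange(self.random_length - 1, -1, -1)))

    def design_matrix(self) -> scipy.sparse.csr_matrix:
        """Sparse (4^k, 400) matrix mapping context rates to full-strand rates.

        Row j counts, for randomer j's full strand (tags included), how
        often each (left, dimer, right) context occurs, so that
        ``A @ table.flat`` gives the additive strand rates mu_j.
        """
        left, dimer, right = dimer_context_codes(self.full_codes())
        cols = (left.astype(np.intp) * 80 + dimer * 5 + right).ravel()
        rows = np.repeat(np.arange(self.n_randomers), left.shape[1])
        data = np.ones(cols.size)
        return scipy.sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_randomers, N_CONTEXTS)
        )

    def full_strand_rates(self, table: ContextRateTable) -> np.ndarray:
        """Additive rates mu_j of all randomer full strands under ``table``."""
        return table.strand_total_rates(self.full_codes())


@functools.lru_cache(maxsize=4)
def _randomer_sequences_cached(k: int) -> np.ndarray:
    return np.array(enumerate_kmers(k))


@dataclass
class ReadCountTable:
    """Read counts indexed by (randomer core sequence, dose).

    ``counts`` has one row per randomer in lexicographic order and one
    column per dose in ``design.doses`` (column 0 = unexposed control).
    """

    design: RandomerDesign
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        expected = (self.design.n_randomers, self.design.n_doses)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts must have shape {expected} (randomers x doses), "
                f"got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def sequences(self) -> np.ndarray:
        return self.design.randomer_sequences()

    @property
    def totals(self) -> np.ndarray:
        """Total reads per dose column."""
        return self.counts.sum(axis=0)

    def to_frame(self, form: str = "wide") -> pd.DataFrame:
        doses = list(self.design.doses)
        if form == "wide":
            df = pd.DataFrame(self.counts, columns=[f"{d:g}" for d in doses])
            df.insert(0, "sequence", self.sequences)
            return df
        if form == "long":
            wide = self.to_frame("wide")
            long = wide.melt(id_vars="sequence", var_name="dose", value_name="count")
            long["dose"] = long["dose"].astype(float)
            return long.sort_values(["sequence", "dose"], ignore_index=True)
        raise ValueError("form must be 'wide' or 'long'")


@dataclass
class SurvivalCurve:
    """Survival S(D) of one sequence or k-mer aggregate across doses."""

    label: str
    doses: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.doses.shape != self.survival.shape:
            raise ValueError("doses and survival must have equal length")

    def values(self) -> list[tuple[float, float]]:
        return list(zip(self.doses.tolist(), self.survival.tolist()))


@dataclass
class SurvivalTable:
    """Per-randomer survival curves S(j, D) with a usability mask.

    Sequences with zero control reads cannot be normalised; their rows
    are NaN and ``usable`` is False, and they are excluded downstream.
    """

    design: RandomerDesign
    survival: np.ndarray  # (n_randomers, n_doses)
    usable: np.ndarray  # (n_randomers,) bool

    @property
    def doses(self) -> np.ndarray:
        return np.asarray(self.design.doses)

    @property
    def sequences(self) -> np.ndarray:
        return self.design.randomer_sequences()

    def curve(self, seq: str) -> SurvivalCurve:
        j = self.design.sequence_index(seq)
        if not self.usable[j]:
            raise ValueError(
                f"sequence {seq!r} has zero control reads; survival undefined"
            )
        return SurvivalCurve(label=seq, doses=self.doses, survival=self.survival[j])

    def __len__(self) -> int:
        return self.design.n_randomers


def compute_survival(counts: ReadCountTable) -> SurvivalTable:
    """Normalised survival S(j,D) = (c(j,D)/total(D)) / (c(j,0)/total(0)).

    S(j, 0) is exactly 1.  A dose column with zero total reads is an
    error; a sequence with zero control reads is flagged unusable.
    """
    totals = counts.totals.astype(float)
    zero_cols = np.flatnonzero(totals == 0)
    if zero_cols.size:
        dose = counts.design.doses[zero_cols[0]]
        raise ValueError(f"no reads at dose {dose:g} PpB; cannot normalize")
    c = counts.counts.astype(float)
    control = c[:, 0]
    usable = control > 0
    freq = c / totals
    S = np.full_like(freq, np.nan)
    S[usable] = freq[usable] / freq[usable, 0:1]
    S[usable, 0] = 1.0
    return SurvivalTable(design=counts.design, survival=S, usable=usable)


def aggregate_kmer_survival(
    counts: ReadCountTable, kmer: str, include_tags: bool = True
) -> SurvivalCurve:
    """Survival of all strands containing ``kmer``, summed before normalising.

    Each matching randomer contributes its reads once regardless of how
    many times the k-mer occurs (sequencing reports strand survival, not
    per-site damage).  With ``include_tags`` the k-mer is matched
    anywhere in the full strand including the tag/core junctions, since
    junction lesions also stall the polymerase; set False to restrict
    matching to the random core.
    """
    kmer = kmer.upper()
    encode_sequence(kmer)
    if not 2 <= len(kmer) <= 4:
        raise ValueError("kmer length must be between 2 and 4")
    design = counts.design
    if include_tags:
        haystacks = (
            design.tag5 + s + design.tag3 for s in design.randomer_sequences()
        )
    else:
        haystacks = iter(design.randomer_sequences())
    mask = np.fromiter((kmer in s for s in haystacks), dtype=bool, count=design.n_randomers)
    if not mask.any():
        raise ValueError(f"no randomer strand contains k-mer {kmer!r}")
    totals = counts.totals.astype(float)
    zero_cols = np.flatnonzero(totals == 0)
    if zero_cols.size:
        raise ValueError(
            f"no reads at dose {design.doses[zero_cols[0]]:g} PpB; cannot normalize"
        )
    num = counts.counts[mask].sum(axis=0).astype(float)
    if num[0] == 0:
        raise ValueError(f"k-mer {kmer!r} has zero control reads; survival undefined")
    freq = num / totals
    S = freq / freq[0]
    S[0] = 1.0
    return SurvivalCurve(label=kmer, doses=np.asarray(design.doses), survival=S)


def fit_initial_slope(curve: SurvivalCurve, max_dose: float = 2.0) -> float:
    """Damage rate from the initial linear drop of a survival curve.

    Least-squares line through (D, S) for D <= ``max_dose`` with the
    intercept fixed at 1 (S(0) = 1 by construction); mu is the negative
    slope.  Restricting to the low-dose regime keeps crosstalk between
    multiple lesions on one strand small.  Negative estimates are
    clamped to 0 with a warning (rates are physical, non-negative).
    """
    mask = curve.doses <= max_dose + 1e-12
    mask &= np.isfinite(curve.survival)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 dose points with D <= {max_dose:g}, have {int(mask.sum())}"
        )
    D = curve.doses[mask]
    S = curve.survival[mask]
    denom = float(np.dot(D, D))
    if denom == 0:
        raise ValueError("all usable dose points are at D = 0; slope undefined")
    mu = -float(np.dot(D, S - 1.0)) / denom
    if mu < 0:
        warnings.warn(
            f"negative fitted rate {mu:.3g} for {curve.label!r} clamped to 0",
            stacklevel=2,
        )
        mu = 0.0
    return mu


def _fit_rates_linear(
    S: np.ndarray, doses: np.ndarray, max_dose: float = 2.0
) -> np.ndarray:
    """Vectorised low-dose linear slope fit (intercept fixed at 1)."""
    mask = doses <= max_dose + 1e-12
    D = doses[mask]
    Sm = S[:, mask]
    valid = np.isfinite(Sm)
    Dm = np.broadcast_to(D, Sm.shape)
    num = np.where(valid, Dm * (Sm - 1.0), 0.0).sum(axis=1)
    den = np.where(valid, Dm * Dm, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, -num / den, np.nan)


def _fit_rates_log(
    S: np.ndarray,
    doses: np.ndarray,
    counts: np.ndarray,
    max_dose: float | None = None,
) -> np.ndarray:
    """Vectorised count-weighted regression of -log S on dose.

    Under the exponential survival model -log S(j,D) = mu_j * D at every
    dose, so all doses are informative.  Points are weighted by the
    inverse sampling variance of log S, 1/(1/c_D + 1/c_0), and a
    first-order small-count bias correction (E[log c] ~ log(lambda) -
    1/(2*lambda)) is applied.  Zero-count points carry no weight.
    """
    nz = doses > 0
    if max_dose is not None:
        nz &= doses <= max_dose + 1e-12
    D = doses[nz]
    Sm = S[:, nz].astype(float)
    cD = counts[:, nz].astype(float)
    c0 = counts[:, 0:1].astype(float)
    valid = (cD > 0) & (c0 > 0) & np.isfinite(Sm) & (Sm > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = -np.log(Sm) - 1.0 / (2.0 * cD) + 1.0 / (2.0 * c0)
        w = 1.0 / (1.0 / cD + 1.0 / c0)
    y = np.where(valid, y, 0.0)
    w = np.where(valid, w, 0.0)
    Dm = np.broadcast_to(D, y.shape)
    num = (w * Dm * y).sum(axis=1)
    den = (w * Dm * Dm).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


@dataclass
class DeconvolutionResult:
    """Context-rate deconvolution output with identifiability diagnostics.

    The additive context model carries a gauge freedom: adding
    f(L, X, Y) - f(X, Y, R) to mu(L, XY, R) for any trimer function f
    telescopes out of every full-strand sum (the boundary terms are
    constant because the tags are fixed), so individual context rates
    are determined only up to the row space of the design.  ``rank``
    identifiable linear combinations of the 400 rates are pinned down
    exactly; :meth:`project_identifiable` extracts that gauge-invariant
    part of any context vector for like-with-like comparisons.
    Downstream pool survival depends on interior strand sums, which are
    gauge-invariant up to the two terminal dimers.
    """

    context_rates: ContextRateTable
    identifiable: np.ndarray  # (400,) bool: strictly identifiable single contexts
    rank: int
    row_space: np.ndarray  # (400, rank) orthonormal basis of identifiable combinations
    residual_norm: float
    n_equations: int
    intercept: float = 0.0
    kmer_tables: dict[int, KmerRateTable] = field(default_factory=dict)

    @property
    def unidentifiable_contexts(self) -> list[tuple[str, str, str]]:
        return [context_label(i) for i in np.flatnonzero(~self.identifiable)]

    @property
    def identifiable_contexts(self) -> list[tuple[str, str, str]]:
        return [context_label(i) for i in np.flatnonzero(self.identifiable)]

    def project_identifiable(self, table_or_flat) -> np.ndarray:
        """Project a context-rate vector onto the identifiable subspace."""
        if isinstance(table_or_flat, ContextRateTable):
            x = table_or_flat.flat
        else:
            x = np.asarray(table_or_flat, dtype=float).reshape(-1)
        return self.row_space @ (self.row_space.T @ x)


def _nnls_via_gram(G: np.ndarray, c: np.ndarray, rank_tol: float = 1e-12):
    """Non-negative least squares given the Gram matrix G = A'A and c = A'b.

    Factorises G = B'B through its eigendecomposition and runs
    Lawson–Hanson NNLS on the square factor; exact for rank-deficient
    systems (minimises ||Ax - b|| over x >= 0 up to the projection onto
    range(A')).  Returns (x, orthonormal row-space basis, columns).
    """
    w, V = np.linalg.eigh(G)
    wmax = w.max() if w.size else 0.0
    keep = w > rank_tol * max(wmax, 1.0)
    B = np.sqrt(w[keep])[:, None] * V[:, keep].T
    y = (V[:, keep].T @ c) / np.sqrt(w[keep])
    x, _ = scipy.optimize.nnls(B, y)
    return x, V[:, keep]


def deconvolve_context_rates(
    full_rates,
    design: RandomerDesign,
    intercept: bool = True,
) -> DeconvolutionResult:
    """Deconvolve full-strand rates into context-dependent dimer rates.

    Fits the additive model mu_j = sum over dimer positions of
    mu(left, dimer, right) across all randomer equations by non-negative
    least squares, then derives marginal dimer/trimer/tetramer tables.

    ``full_rates`` is a mapping {core sequence: mu}, a pandas Series so
    indexed, or an array covering all randomers in lexicographic order
    (NaN rows are dropped).  Contexts the design cannot pin down (the
    constant tag and strand-end contexts, plus one gauge direction per
    trimer — see :class:`DeconvolutionResult`) are resolved by the NNLS
    solution but flagged through ``rank`` / ``identifiable``; a random
    core shorter than 4 cannot expose any dimer to variation in both
    flanks and is rejected.

    With ``intercept`` (default) a free additive offset is fitted
    alongside the non-negative context rates.  Depth-normalised survival
    only measures rates relative to the library-average survival at each
    dose (the per-dose renormalisation subtracts roughly the mean strand
    rate from every mu_j), and without a sign-free offset that common
    shift would be forced into the non-negative rates and distort them.
    """
    if design.random_length < 4:
        raise ValueError(
            "randomer design is rank-deficient: with random_length "
            f"{design.random_length} < 4 no dimer sees free variation in both "
            "flanks, so no (left, dimer, right) context is identifiable"
        )
    n = design.n_randomers
    b = np.full(n, np.nan)
    if isinstance(full_rates, dict):
        for seq, mu in full_rates.items():
            b[design.sequence_index(seq)] = mu
    elif isinstance(full_rates, pd.Series):
        for seq, mu in full_rates.items():
            b[design.sequence_index(str(seq))] = mu
    else:
        arr = np.asarray(full_rates, dtype=float)
        if arr.shape != (n,):
            raise ValueError(
                f"full_rates array must have length {n} (one entry per randomer)"
            )
        b = arr
    rows = np.flatnonzero(np.isfinite(b))
    if rows.size == 0:
        raise ValueError("full_rates contains no usable entries")
    A = design.design_matrix()[rows]
    bv = b[rows]

    if intercept:
        # centering the equations is equivalent to a free offset column
        m = np.asarray(A.mean(axis=0)).ravel()
        b_mean = bv.mean()
        nrows = rows.size
        G = np.asarray((A.T @ A).todense()) - nrows * np.outer(m, m)
        c = A.T @ bv - nrows * m * b_mean
    else:
        G = np.asarray((A.T @ A).todense())
        c = A.T @ bv
    x, row_space = _nnls_via_gram(G, c)
    # a single context is strictly identifiable iff its unit vector lies
    # entirely in the row space
    row_mass = np.linalg.norm(row_space, axis=1)
    identifiable = row_mass > 1.0 - 1e-8
    fitted = A @ x
    offset = float(b_mean - m @ x) if intercept else 0.0
    residual = float(np.linalg.norm(fitted + offset - bv))
    table = ContextRateTable.from_flat(np.maximum(x, 0.0))
    kmers = {k: table.kmer_rates(k) for k in (2, 3, 4)}
    return DeconvolutionResult(
        context_rates=table,
        identifiable=identifiable,
        rank=row_space.shape[1],
        row_space=row_space,
        residual_norm=residual,
        n_equations=int(rows.size),
        intercept=offset,
        kmer_tables=kmers,
    )


class DamageRateModel:
    """Context-dependent damage-rate model for a randomer count table.

    Parameters
    ----------
    counts
        Read counts per (randomer core, dose) with an unexposed control.

    ``fit`` runs the full pipeline — survival normalisation, per-sequence
    rate estimation, additive NNLS deconvolution — and returns a
    :class:`DamageRateResults`.
    """

    def __init__(self, counts: ReadCountTable):
        self.counts = counts
        self.design = counts.design

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, design: RandomerDesign | None = None
    ) -> "DamageRateModel":
        """Build from a long-form DataFrame (sequence, dose, count)."""
        from .cli_io import counts_from_frame  # late import; IO lives in cli_io

        return cls(counts_from_frame(frame, design=design))

    def fit(self, method: str = "log", max_dose: float | None = None) -> "DamageRateResults":
        """Estimate per-sequence and context-dependent damage rates.

        method="log" (default) regresses -log S on dose with count
        weights over all doses (exact under exponential survival);
        method="linear" uses the low-dose linear slope with intercept
        fixed at 1 (``max_dose`` defaults to 2 PpB in that case).
        """
        survival = compute_survival(self.counts)
        if method == "log":
            mu = _fit_rates_log(
                survival.survival, survival.doses, self.counts.counts, max_dose
            )
        elif method == "linear":
            mu = _fit_rates_linear(
                survival.survival, survival.doses, 2.0 if max_dose is None else max_dose
            )
        else:
            raise ValueError("method must be 'log' or 'linear'")
        mu = np.where(survival.usable, mu, np.nan)
        deconv = deconvolve_context_rates(mu, self.design)
        return DamageRateResults(
            model=self, survival=survival, full_rates=mu, deconvolution=deconv,
            method=method,
        )


class DamageRateResults:
    """Fitted damage rates with diagnostics and a text summary."""

    def __init__(self, model, survival, full_rates, deconvolution, method):
        self.model = model
        self.survival = survival
        self.full_rates = full_rates  # raw per-randomer estimates (may be <0 from noise)
        self.deconvolution = deconvolution
        self.method = method

    @property
    def context_rates(self) -> ContextRateTable:
        return self.deconvolution.context_rates

    @property
    def params(self) -> pd.Series:
        """Context rates as a Series indexed by (left, dimer, right)."""
        df = self.context_rates.to_frame()
        return df.set_index(["left", "dimer", "right"])["rate"]

    def kmer_rates(self, k: int) -> KmerRateTable:
        return self.deconvolution.kmer_tables[k]

    @property
    def fittedvalues(self) -> np.ndarray:
        """Full-strand rates reconstructed from the fitted context table."""
        return self.model.design.full_strand_rates(self.context_rates)

    @property
    def resid(self) -> np.ndarray:
        return self.full_rates - self.fittedvalues

    @property
    def residual_norm(self) -> float:
        return self.deconvolution.residual_norm

    def predict_sequence_rate(self, seq: str) -> float:
        """Additive damage rate of an arbitrary ACGT strand."""
        return self.context_rates.sequence_rate(seq)

    def summary(self) -> str:
        design = self.model.design
        trimers = self.kmer_rates(3).as_series().sort_values()
        lines = [
            "Context-dependent UV damage rates",
            "=" * 48,
            f"design:            {design.tag5}-N{design.random_length}-{design.tag3}, "
            f"{design.n_doses - 1} doses + control",
            f"randomers:         {design.n_randomers}",
            f"usable curves:     {int(self.survival.usable.sum())}",
            f"rate estimator:    {self.method}",
            f"identifiable:      {self.deconvolution.rank}/400 rate combinations",
            f"residual norm:     {self.residual_norm:.4g}",
            "-" * 48,
            "most UV-stable trimers (damages/PpB):",
        ]
        lines += [f"    {s}  {v: .4e}" for s, v in trimers.head(5).items()]
        lines.append("most UV-susceptible trimers (damages/PpB):")
        lines += [f"    {s}  {v: .4e}" for s, v in trimers.tail(5).items()]
        lines.append(
            f"trimers below 20e-3/PpB: {100 * self.kmer_rates(3).quantile_below(0.020):.1f}%"
        )
        return "\n".join(lines)
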