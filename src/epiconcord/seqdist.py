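"""Alignment-free k-mer sequence comparison and closed-form F84 distances.

Promoter-scale sequences are compared without alignment: overlapping k-mer
frequency profiles (k chosen from the sequence length), optional removal of
high-frequency k-mers defined on a reference collection, then Pearson or
Jensen-Shannon distance between profiles. Coding sequences supplied as
pairwise alignments get the F84 substitution-model distance in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np

DNA = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(DNA)}

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class KmerConfig:
    """Parameters of the k-mer profiling step."""

    k: int
    alphabet_size: int = 4
    removal_quantile: float = 0.95

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alphabet_size < 2:
            raise ValueError("alphabet size must be >= 2")
        if not 0 <= self.removal_quantile < 1 and self.removal_quantile != 1:
            raise ValueError("removal_quantile must lie in [0, 1]")


@dataclass
class KmerProfile:
    """Normalized k-mer frequency vector with filtering metadata.

    ``frequencies`` has length 4**k; removed k-mers carry frequency 0 and the
    remaining entries sum to 1 (renormalized after removal).
    """

    k: int
    frequencies: np.ndarray
    removed_kmers: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (4**self.k,):
            raise ValueError("frequency vector length must be 4**k")
        if (self.frequencies < 0).any():
            raise ValueError("negative k-mer frequency")

    @property
    def retained(self) -> np.ndarray:
        mask = np.ones(4**self.k, dtype=bool)
        mask[list(self.removed_kmers)] = False
        return mask


@dataclass(frozen=True)
class DistancePair:
    pearson_distance: float
    js_divergence: float


@dataclass
class AlignedPairSummary:
    """Site-pattern summary of a gapless pairwise alignment."""

    L: int
    P: float  # transition proportion
    Q: float  # transversion proportion
    base_freqs: dict[str, float]
    ts_tv_ratio: float = 2.0
    A: float = field(init=False, default=float("nan"))
    B: float = field(init=False, default=float("nan"))
    C: float = field(init=False, default=float("nan"))

    def __post_init__(self) -> None:
        pi = self.base_freqs
        pi_r = pi["A"] + pi["G"]
        pi_y = pi["C"] + pi["T"]
        self.A = pi["A"] * pi["G"] / pi_r + pi["C"] * pi["T"] / pi_y
        self.B = pi["A"] * pi["G"] + pi["C"] * pi["T"]
        self.C = pi_r * pi_y


class SaturationError(ValueError):
    """Distance undefined: observed divergence at or beyond model saturation."""


# ---------------------------------------------------------------------------
# k-mer profiles
# ---------------------------------------------------------------------------


def select_k(N: int, c: int = 4) -> int:
    """Minimum k-mer length guaranteeing the longest vocabulary for a
    sequence of length ``N`` over ``c`` characters: floor(log_c N)."""
    if N < c:
        raise ValueError(f"sequence length {N} shorter than alphabet size {c}")
    return max(1, math.floor(math.log(N) / math.log(c) + 1e-9))


def kmer_index(kmer: str) -> int:
    idx = 0
    for base in kmer:
        idx = idx * 4 + _BASE_INDEX[base]
    return idx


def index_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(DNA[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product(DNA, repeat=k)]


def kmer_counts(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer counts; windows containing N (or any non-ACGT
    character) are skipped so results are seed-free."""
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    counts = np.zeros(4**k, dtype=float)
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if any(b not in _BASE_INDEX for b in window):
            continue
        counts[kmer_index(window)] += 1
    return counts


def high_frequency_kmers(
    seqs: Iterable[str], k: int, quantile: float = 0.95
) -> frozenset[int]:
    """K-mers whose pooled frequency over a reference collection lies strictly
    above the given quantile of pooled k-mer frequencies.

    The removal set is defined at the collection level so every profile in an
    analysis is filtered identically.
    """
    pooled = np.zeros(4**k, dtype=float)
    for seq in seqs:
        pooled += kmer_counts(seq, k)
    total = pooled.sum()
    if total == 0:
        return frozenset()
    freqs = pooled / total
    cutoff = np.quantile(freqs, quantile)
    return frozenset(int(i) for i in np.nonzero(freqs > cutoff)[0])


def kmer_profile(
    seq: str, config: KmerConfig, removed: frozenset[int] = frozenset()
) -> KmerProfile:
    """Normalized overlapping k-mer frequency profile of one sequence.

    ``removed`` is the collection-level high-frequency set (see
    :func:`high_frequency_kmers`); retained frequencies are renormalized to
    sum to 1.
    """
    counts = kmer_counts(seq, config.k)
    counts[list(removed)] = 0.0
    total = counts.sum()
    if total > 0:
        counts /= total
    return KmerProfile(config.k, counts, frozenset(removed))


def _common_retained(p: KmerProfile, q: KmerProfile) -> np.ndarray:
    if p.k != q.k:
        raise ValueError("profiles have different k")
    return p.retained & q.retained


def pearson_distance(p: KmerProfile, q: KmerProfile) -> float:
    """1 - Pearson correlation over retained k-mers common to both profiles."""
    mask = _common_retained(p, q)
    x, y = p.frequencies[mask], q.frequencies[mask]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (constant) profile: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def js_divergence(p: KmerProfile, q: KmerProfile) -> float:
    """Jensen-Shannon divergence (log base 2, hence bounded in [0, 1])
    between two profiles, restricted to their common retained k-mers and
    renormalized; 0*log(0) := 0."""
    mask = _common_retained(p, q)
    x, y = p.frequencies[mask], q.frequencies[mask]
    return js_divergence_vectors(x, y)


def js_divergence_vectors(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("empty profile")
    x = x / x.sum()
    y = y / y.sum()
    m = 0.5 * (x + y)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_x = np.where(x > 0, x * np.log2(x / m), 0.0)
        kl_y = np.where(y > 0, y * np.log2(y / m), 0.0)
    jsd = 0.5 * float(kl_x.sum()) + 0.5 * float(kl_y.sum())
    return float(min(max(jsd, 0.0), 1.0))


def profile_entropy(p: KmerProfile | np.ndarray) -> float:
    """Shannon entropy (bits) of the retained frequency vector."""
    freqs = p.frequencies if isinstance(p, KmerProfile) else np.asarray(p, float)
    freqs = freqs[freqs > 0]
    return float(-(freqs * np.log2(freqs)).sum())


def distance_pair(p: KmerProfile, q: KmerProfile) -> DistancePair:
    return DistancePair(pearson_distance(p, q), js_divergence(p, q))


# ---------------------------------------------------------------------------
# F84 distance on supplied pairwise alignments
# ---------------------------------------------------------------------------


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def pair_summary(
    seq1: str, seq2: str, ts_tv_ratio: float = 2.0
) -> AlignedPairSummary:
    """Summarize a pairwise alignment into (L, P, Q, base frequencies).

    Gap columns and columns with ambiguous bases are dropped pairwise; base
    frequencies are empirical over the concatenated pair.
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    seq1, seq2 = seq1.upper(), seq2.upper()
    n_ts = n_tv = L = 0
    base_counts = {b: 0 for b in DNA}
    for a, b in zip(seq1, seq2):
        if a not in _BASE_INDEX or b not in _BASE_INDEX:
            continue
        L += 1
        base_counts[a] += 1
        base_counts[b] += 1
        if a != b:
            if _is_transition(a, b):
                n_ts += 1
            else:
                n_tv += 1
    if L == 0:
        raise ValueError("no usable (gap-free, unambiguous) aligned columns")
    total = 2 * L
    freqs = {b: base_counts[b] / total for b in DNA}
    return AlignedPairSummary(L, n_ts / L, n_tv / L, freqs, ts_tv_ratio)


def f84_distance_from_summary(s: AlignedPairSummary) -> float:
    """Closed-form F84 distance from a site-pattern summary.

    d = -2A ln(1 - P/(2A) - (A-B)Q/(2AC)) + 2(A-B-C) ln(1 - Q/(2C))
    with A, B, C derived from the empirical base frequencies.
    """
    A, B, C = s.A, s.B, s.C
    arg1 = 1.0 - s.P / (2.0 * A) - (A - B) * s.Q / (2.0 * A * C)
    arg2 = 1.0 - s.Q / (2.0 * C)
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(
            f"F84 distance undefined at P={s.P:.4f}, Q={s.Q:.4f} (saturated)"
        )
    return -2.0 * A * math.log(arg1) + 2.0 * (A - B - C) * math.log(arg2)


def f84_distance(seq1: str, seq2: str, ts_tv_ratio: float = 2.0) -> float:
    """F84 nucleotide-substitution distance of an aligned sequence pair.

    The closed form is moment-based: it inverts the model's expected
    transition/transversion proportions, so the supplied expected
    ``ts_tv_ratio`` is recorded in the summary but does not alter the
    estimate (base frequencies and P, Q are empirical).
    """
    summary = pair_summary(seq1, seq2, ts_tv_ratio)
    if summary.P == 0 and summary.Q == 0:
        return 0.0
    return f84_distance_from_summary(summary)
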