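"""Independent brute-force / numeric oracles used by the test suite.

These deliberately avoid the code paths they check: the F84 oracle goes
through a rate-matrix exponential and numeric likelihood maximization; the
binomial and Fisher oracles enumerate point masses with ``math.comb``; the
ANOVA oracle projects onto explicit design matrices with ``numpy.lstsq``.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, root

BASES = "ACGT"
PURINES = {"A", "G"}


# ---------------------------------------------------------------------------
# F84 numeric maximum-likelihood oracle
# ---------------------------------------------------------------------------


def _f84_rate_matrix(pi: dict[str, float], a: float, b: float) -> np.ndarray:
    pi_r = pi["A"] + pi["G"]
    pi_y = pi["C"] + pi["T"]
    Q = np.zeros((4, 4))
    for i, bi in enumerate(BASES):
        for j, bj in enumerate(BASES):
            if i == j:
                continue
            q = b * pi[bj]
            if (bi in PURINES) == (bj in PURINES):
                q += a * pi[bj] / (pi_r if bj in PURINES else pi_y)
            Q[i, j] = q
        Q[i, i] = -Q[i].sum()
    return Q


def _expected_pq(pi, a, b):
    Q = _f84_rate_matrix(pi, a, b)
    M = expm(Q)
    pivec = np.array([pi[x] for x in BASES])
    p_ts = p_tv = 0.0
    for i, bi in enumerate(BASES):
        for j, bj in enumerate(BASES):
            if i == j:
                continue
            pr = pivec[i] * M[i, j]
            if (bi in PURINES) == (bj in PURINES):
                p_ts += pr
            else:
                p_tv += pr
    return p_ts, p_tv, Q, pivec


def f84_ml_oracle(P_obs: float, Q_obs: float, pi: dict[str, float], L: int) -> float:
    """ML F84 distance by numeric maximization of the collapsed
    same/transition/transversion trinomial likelihood over the two rate
    parameters (matrix-exponential transition probabilities)."""
    n_ts, n_tv = P_obs * L, Q_obs * L
    n_same = L - n_ts - n_tv

    def nll(x):
        a, b = np.exp(x)
        p_ts, p_tv, _, _ = _expected_pq(pi, a, b)
        s = 1.0 - p_ts - p_tv
        if p_ts <= 0 or p_tv <= 0 or s <= 0:
            return 1e9
        return -(n_same * np.log(s) + n_ts * np.log(p_ts) + n_tv * np.log(p_tv))

    res = minimize(
        nll,
        [np.log(0.1), np.log(0.05)],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
    )

    # polish: at the trinomial ML the expected (P, Q) equal the observed ones
    def residuals(x):
        a, b = np.exp(x)
        p_ts, p_tv, _, _ = _expected_pq(pi, a, b)
        return [p_ts - P_obs, p_tv - Q_obs]

    sol = root(residuals, res.x, method="hybr", tol=1e-14)
    x = sol.x if sol.success else res.x
    a, b = np.exp(x)
    _, _, Q, pivec = _expected_pq(pi, a, b)
    return float(-(pivec * np.diag(Q)).sum())


# ---------------------------------------------------------------------------
# Exact binomial upper-tail oracle
# ---------------------------------------------------------------------------


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(K >= k) for K ~ Binomial(n, p) by direct point-mass summation."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


# ---------------------------------------------------------------------------
# Fisher two-sided oracle by hypergeometric enumeration
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _hypergeom_pmf_vector(N: int, r1: int, c1: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    lo = max(0, r1 + c1 - N)
    hi = min(r1, c1)
    denom = math.comb(N, c1)
    support = tuple(range(lo, hi + 1))
    pmf = tuple(
        math.comb(r1, x) * math.comb(N - r1, c1 - x) / denom for x in support
    )
    return support, pmf


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of all margins-fixed tables whose
    hypergeometric probability does not exceed the observed one."""
    N = a + b + c + d
    r1, c1 = a + b, a + c
    support, pmf = _hypergeom_pmf_vector(N, r1, c1)
    p_obs = pmf[support.index(a)]
    # scipy-compatible tolerance for ties
    return min(1.0, sum(p for p in pmf if p <= p_obs * (1 + 1e-7)))


# ---------------------------------------------------------------------------
# Two-way ANOVA design-matrix projection oracle (Type II)
# ---------------------------------------------------------------------------


def _dummy(levels) -> np.ndarray:
    cats = sorted(set(levels))
    out = np.zeros((len(levels), len(cats) - 1))
    for i, v in enumerate(levels):
        j = cats.index(v)
        if j > 0:
            out[i, j - 1] = 1.0
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def anova_type2_ss(y, factor_a, factor_b) -> dict[str, float]:
    """Type II sums of squares for y ~ A + B via nested-model projections."""
    y = np.asarray(y, dtype=float)
    ones = np.ones((len(y), 1))
    Xa, Xb = _dummy(list(factor_a)), _dummy(list(factor_b))
    X_ab = np.hstack([ones, Xa, Xb])
    X_a = np.hstack([ones, Xa])
    X_b = np.hstack([ones, Xb])
    rss_full = _rss(X_ab, y)
    return {
        "concordance": _rss(X_b, y) - rss_full,
        "uniqueness": _rss(X_a, y) - rss_full,
        "Residual": rss_full,
    }
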