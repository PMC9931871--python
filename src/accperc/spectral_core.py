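"""Spectral quantities of an accessibility setup.

Everything in this module derives from the log matrix-exponential entry

    Gamma_{vw}(t) = ln( (e^{tA})_{vw} ),

the exponential growth rate (in the number of loci L) of the expected
number of quasi-accessible walks between genotypes whose per-locus allele
pairs are (v, w).  The divergence-weighted mean of Gamma over allele pairs
is strictly increasing in t, so it has a unique root beta*: the critical
fitness difference below which accessible paths asymptotically do not
exist.  Its derivatives at beta* give the expected length of critical
accessible walks (beta* Gamma'* steps per locus) and their fluctuations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .allele_graphs import (
    AccessibilitySetup,
    AlleleGraph,
    GenotypePair,
    counting_matrix,
)

__all__ = [
    "GammaEvaluation",
    "ThresholdResult",
    "WalkLengthMoments",
    "gamma",
    "gamma_matrices",
    "mean_gamma",
    "solve_beta_star",
    "beta_star_complete_poly",
    "beta_star_no_return",
    "threshold_c_L",
    "walk_length_moments",
    "expected_quasi_accessible",
    "enumerate_walk_expectation_oracle",
    "enumeration_tail_bound",
    "product_adjacency",
    "genotype_index",
]

#: Absolute entry tolerance contract for the matrix exponential.
EXPM_ATOL = 1e-13

#: Bracket expansion cap for the root search (design contract).
_BRACKET_CAP = 2.0**60


# ---------------------------------------------------------------------------
# Gamma and its derivatives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaEvaluation:
    """Gamma_{vw}(t) together with its first two t-derivatives.

    ``reachable`` is False when no walk v -> w exists (the matrix
    exponential entry is exactly zero and Gamma is formally -inf); in that
    case ``value`` and the derivatives are NaN and e^Gamma contributions
    must be treated as exactly zero.
    """

    value: float
    first_deriv: float
    second_deriv: float
    reachable: bool


def gamma_matrices(
    graph: AlleleGraph, t: float, max_order: int = 2
) -> tuple[np.ndarray, ...]:
    """Return (e^{tA}, A e^{tA}, A^2 e^{tA}) up to ``max_order``, with
    structurally-unreachable entries forced to exactly zero."""
    if t <= 0:
        raise ValueError("t must be positive")
    A = graph.adjacency.astype(float)
    E = expm(t * A)
    # Structural zeros: (e^{tA})_{vw} = 0 iff no walk v->w (off-diagonal)
    # -- enforce exactly, independent of floating-point round-off.
    mask = graph.reachable() | np.eye(graph.n_alleles, dtype=bool)
    E = np.where(mask, E, 0.0)
    out = [E]
    if max_order >= 1:
        out.append(A @ E)
    if max_order >= 2:
        out.append(A @ A @ E)
    return tuple(out)


def gamma(
    graph: AlleleGraph, v: str, w: str, t: float, max_order: int = 2
) -> GammaEvaluation:
    """Evaluate Gamma_{vw}(t) = ln((e^{tA})_{vw}) and its derivatives.

    The first derivative is (A e^{tA})_{vw} / (e^{tA})_{vw}; the second is
    (A^2 e^{tA})_{vw} / (e^{tA})_{vw} minus the square of the first.  For a
    diagonal pair with no returning cycle the entry is identically 1, so
    Gamma is 0 with vanishing derivatives.
    """
    i, j = graph.index(v), graph.index(w)
    mats = gamma_matrices(graph, t, max_order=max_order)
    E = mats[0]
    if E[i, j] == 0.0:
        return GammaEvaluation(math.nan, math.nan, math.nan, reachable=False)
    value = math.log(E[i, j])
    d1 = d2 = 0.0
    if max_order >= 1:
        d1 = mats[1][i, j] / E[i, j]
    if max_order >= 2:
        d2 = mats[2][i, j] / E[i, j] - d1 * d1
    return GammaEvaluation(value, d1, d2, reachable=True)


def _weights(setup: AccessibilitySetup, use_finite_L: bool) -> np.ndarray:
    if use_finite_L:
        if setup.M is None:
            raise ValueError("setup has no counting matrix for finite-L weights")
        return setup.M / setup.L
    return setup.p


def mean_gamma(
    setup: AccessibilitySetup,
    t: float,
    order: int = 0,
    use_finite_L: bool = False,
) -> float:
    """Divergence-weighted mean of Gamma (order 0) or one of its first two
    derivatives over allele pairs.

    Weights are the divergence matrix p, or M/L when ``use_finite_L``.  A
    positively-weighted pair that is unreachable makes the mean undefined
    and raises.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    W = _weights(setup, use_finite_L)
    mats = gamma_matrices(setup.graph, t, max_order=order)
    E = mats[0]
    sel = W > 0
    if (E[sel] == 0.0).any():
        bad = np.argwhere(sel & (E == 0.0))
        labels = [(setup.graph.labels[v], setup.graph.labels[w]) for v, w in bad]
        raise ValueError(f"weighted allele pairs are unreachable: {labels}")
    total = 0.0
    idx_v, idx_w = np.nonzero(sel)
    for v, w in zip(idx_v, idx_w):
        e = E[v, w]
        if order == 0:
            x = math.log(e)
        elif order == 1:
            x = mats[1][v, w] / e
        else:
            d1 = mats[1][v, w] / e
            x = mats[2][v, w] / e - d1 * d1
        total += W[v, w] * x
    return total


# ---------------------------------------------------------------------------
# Critical point
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdResult:
    """Critical fitness difference and walk-length rates of a setup.

    ``beta_star`` is the unique root of the divergence-weighted mean Gamma;
    ``gamma_prime_star`` / ``gamma_double_prime_star`` are the mean first
    and second derivatives there; ``walk_length_factor`` is the expected
    number of mutational steps per locus along critical accessible walks,
    beta* Gamma'*.  ``beta_hat`` is the finite-L root (weights M/L) when a
    counting matrix is available, else None.  ``accessible`` records
    whether beta* <= 1: since beta is a difference of fitness quantiles it
    cannot exceed 1, so beta* > 1 means the endpoint pair can never be
    asymptotically accessible (the value itself is not clamped).
    """

    beta_star: float
    gamma_prime_star: float
    gamma_double_prime_star: float
    walk_length_factor: float
    beta_hat: float | None = None
    residual: float = 0.0

    @property
    def accessible(self) -> bool:
        return self.beta_star <= 1.0


def _solve_root(setup: AccessibilitySetup, use_finite_L: bool) -> float:
    f = lambda t: mean_gamma(setup, t, order=0, use_finite_L=use_finite_L)
    lo = hi = 1.0
    flo = f(lo)
    while flo > 0.0:
        lo /= 2.0
        if lo < 1.0 / _BRACKET_CAP:
            raise RuntimeError("root bracket expansion failed (lower bound)")
        flo = f(lo)
    fhi = f(hi)
    while fhi < 0.0:
        hi *= 2.0
        if hi > _BRACKET_CAP:
            raise RuntimeError("root bracket expansion failed (upper bound)")
        fhi = f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    # mean Gamma is strictly increasing, so the bracketed root is unique
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200))


def solve_beta_star(
    setup: AccessibilitySetup, use_finite_L: bool = False
) -> ThresholdResult:
    """Solve the critical fitness difference beta* of an accessibility setup
    as the root of the divergence-weighted mean Gamma, then evaluate the
    starred derivative quantities there.

    With ``use_finite_L`` (requires a counting matrix M) the finite-L root
    beta-hat of the M/L-weighted mean is solved as well and reported in
    ``beta_hat``; the starred quantities always refer to the asymptotic
    (p-weighted) root.
    """
    beta_star = _solve_root(setup, use_finite_L=False)
    g1 = mean_gamma(setup, beta_star, order=1)
    g2 = mean_gamma(setup, beta_star, order=2)
    beta_hat = _solve_root(setup, use_finite_L=True) if use_finite_L else None
    residual = mean_gamma(setup, beta_star, order=0)
    return ThresholdResult(
        beta_star=beta_star,
        gamma_prime_star=g1,
        gamma_double_prime_star=g2,
        walk_length_factor=beta_star * g1,
        beta_hat=beta_hat,
        residual=residual,
    )


def beta_star_complete_poly(n: int) -> float:
    """beta* for the complete graph on ``n`` alleles at full distance, as
    the log of the unique root x > 1 of x^n - n x - 1 = 0."""
    if n < 2:
        raise ValueError("need at least 2 alleles")
    f = lambda x: x**n - n * x - 1.0
    hi = 2.0
    while f(hi) < 0.0:
        hi *= 2.0
    x = brentq(f, 1.0, hi, xtol=1e-15, rtol=8.9e-16)
    return float(math.log(x))


def beta_star_no_return(n: int) -> tuple[float, float]:
    """Closed-form (beta*, Gamma'*) for the complete graph with arrows into
    the wild type removed: beta* = ln(n-1)/(n-2), Gamma'* = n-1.  The
    biallelic case (the directed hypercube) is the limit (1, 1)."""
    if n < 2:
        raise ValueError("need at least 2 alleles")
    if n == 2:
        return 1.0, 1.0
    return math.log(n - 1) / (n - 2), float(n - 1)


def threshold_c_L(setup: AccessibilitySetup, L: int) -> float:
    """Finite-L location of the accessibility transition,

        c_L = beta_hat - ln(L) / (L * Gamma'(beta_hat)),

    using the finite-L root beta_hat when the setup carries a counting
    matrix and the asymptotic beta* otherwise."""
    if L < 2:
        raise ValueError("L must be at least 2")
    finite = setup.M is not None
    root = _solve_root(setup, use_finite_L=finite)
    g1 = mean_gamma(setup, root, order=1, use_finite_L=finite)
    return root - math.log(L) / (L * g1)


# ---------------------------------------------------------------------------
# Walk-length statistics and expected walk counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WalkLengthMoments:
    """Per-locus mean and variance of the length of quasi-accessible walks
    at fitness difference beta: mu = beta Gamma'(beta) and
    sigma^2 = beta Gamma'(beta) + beta^2 Gamma''(beta)."""

    mu_per_locus: float
    sigma2_per_locus: float


def walk_length_moments(setup: AccessibilitySetup, beta: float) -> WalkLengthMoments:
    if beta <= 0:
        raise ValueError("beta must be positive")
    g1 = mean_gamma(setup, beta, order=1)
    g2 = mean_gamma(setup, beta, order=2)
    return WalkLengthMoments(beta * g1, beta * g1 + beta * beta * g2)


def expected_quasi_accessible(
    setup: AccessibilitySetup,
    L: int,
    beta: float,
    pair: GenotypePair | None = None,
) -> float:
    """Exact expected number of quasi-accessible walks between the
    endpoints at fitness difference beta:

        E[Z] = L * Gamma'(beta) * exp(L * Gamma(beta)),

    where Gamma is the per-locus mean (weighted by the pair's counting
    matrix / L when a concrete pair is given, by the divergence matrix
    otherwise)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if pair is not None:
        M = counting_matrix(pair, setup.graph)
        work = AccessibilitySetup(setup.graph, M / pair.L, M=M)
        L = pair.L
        g0 = mean_gamma(work, beta, order=0, use_finite_L=True)
        g1 = mean_gamma(work, beta, order=1, use_finite_L=True)
    else:
        g0 = mean_gamma(setup, beta, order=0)
        g1 = mean_gamma(setup, beta, order=1)
    return L * g1 * math.exp(L * g0)


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle on the product graph
# ---------------------------------------------------------------------------


def genotype_index(genotype: tuple[str, ...], graph: AlleleGraph) -> int:
    """Mixed-radix code of a genotype; locus 0 is the least significant."""
    code = 0
    for lab in reversed(genotype):
        code = code * graph.n_alleles + graph.index(lab)
    return code


def product_adjacency(graph: AlleleGraph, L: int) -> np.ndarray:
    """Dense adjacency matrix of the genotype space (Cartesian power):
    arrows change exactly one locus along an allele-graph arrow."""
    n = graph.n_alleles
    size = n**L
    if size > 10**4:
        raise ValueError("product graph too large for dense enumeration")
    P = np.zeros((size, size), dtype=np.int64)
    A = graph.adjacency
    for g in range(size):
        rem = g
        for locus in range(L):
            allele = rem % n
            rem //= n
            for to in range(n):
                if A[allele, to]:
                    h = g + (to - allele) * n**locus
                    P[g, h] = 1
    return P


def enumerate_walk_expectation_oracle(
    graph: AlleleGraph,
    pair: GenotypePair,
    beta: float,
    n_max: int = 40,
) -> float:
    """Partial sum of the expected quasi-accessible walk count by explicit
    walk counting on the product graph: a walk of length N is
    quasi-accessible with probability beta^{N-1}/(N-1)!, and the number of
    walks of length N is the (a, b) entry of the N-th power of the product
    adjacency matrix.  Converges monotonically from below to the closed
    form as n_max grows."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    P = product_adjacency(graph, pair.L)
    ia = genotype_index(pair.a, graph)
    ib = genotype_index(pair.b, graph)
    vec = np.zeros(P.shape[0])
    vec[ia] = 1.0
    total = 0.0
    fact = 1.0  # (N-1)! running value
    for N in range(1, n_max + 1):
        vec = vec @ P
        if N > 1:
            fact *= N - 1
        total += vec[ib] * beta ** (N - 1) / fact
    return total


def enumeration_tail_bound(
    graph: AlleleGraph, L: int, beta: float, n_max: int
) -> float:
    """Upper bound on the truncation error of the enumeration oracle: walk
    counts of length N are at most D^N with D the product-graph degree
    bound L * Delta, so the tail beyond n_max is at most
    D * e^{beta D} * (beta D)^{n_max} / n_max!."""
    D = L * graph.max_degree
    return D * math.exp(beta * D) * (beta * D) ** n_max / math.factorial(n_max)
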