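"""Martinsson-function evaluation and regularity classification.

The first-moment threshold for accessibility percolation is sharp only
when accessible walks are not clustered around a few shared initial and
final segments.  Martinsson's function M*(s, r, beta) quantifies this:
walks are cut into three segments spanning fitness fractions
beta*(1-s)*r, beta*s and beta*(1-s)*(1-r), and the expected growth rate of
the middle segment is averaged with weights proportional to the number of
ways the segment can be reached from the endpoints.  On the boundary
M*(0, r, beta) = 0 and M*(1, r, beta) equals the mean Gamma at beta, so it
vanishes at the critical point.  A setup is

* semi-regular  if M*(s, r, beta*) <= 0 on the whole domain,
* regular       if additionally M* < 0 strictly in the interior and the
                 s-derivative at s = 1 is non-zero (then the first-moment
                 threshold c_L is a genuine 1/L-threshold function),
* irregular     otherwise (the true critical value exceeds beta*).

The classification here is numerical, on a lattice of (s, r) values with a
sign tolerance; it mirrors how such regularity checks are done in practice
and can in principle miss sign changes finer than the lattice.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .allele_graphs import AccessibilitySetup, AlleleGraph
from .spectral_core import ThresholdResult, solve_beta_star

__all__ = [
    "MartinssonEval",
    "SearchResult",
    "martinsson",
    "classify",
    "search_irregular",
]


def _masked_expm(graph: AlleleGraph, t: float) -> np.ndarray:
    """e^{tA} with structurally-zero entries forced to exactly 0; exact
    identity at t = 0."""
    n = graph.n_alleles
    if t == 0.0:
        return np.eye(n)
    E = expm(t * graph.adjacency.astype(float))
    mask = graph.reachable() | np.eye(n, dtype=bool)
    return np.where(mask, E, 0.0)


def martinsson(
    setup: AccessibilitySetup, s: float, r: float, beta: float
) -> float:
    """Evaluate Martinsson's function M*(s, r, beta) of the setup.

    For each weighted endpoint pair (a, b) the value is the mean of
    Gamma_{xy}(beta*s) over intermediate allele pairs (x, y), weighted by
    exp(Gamma_{ax}(beta*(1-s)*r) + Gamma_{xy}(beta*s) +
    Gamma_{yb}(beta*(1-s)*(1-r))); pairs whose middle segment is
    unreachable contribute zero to both numerator and denominator
    (the Gamma * e^Gamma = 0 convention).  The outer mean is weighted by
    the divergence matrix.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (0.0 <= s <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError("s and r must lie in [0, 1]")
    g = setup.graph
    sbar, rbar = 1.0 - s, 1.0 - r
    E1 = _masked_expm(g, beta * sbar * r)
    E2 = _masked_expm(g, beta * s)
    E3 = _masked_expm(g, beta * sbar * rbar)
    with np.errstate(divide="ignore"):
        lnE2 = np.where(E2 > 0.0, np.log(np.where(E2 > 0.0, E2, 1.0)), 0.0)

    total = 0.0
    for a, b in zip(*np.nonzero(setup.p > 0)):
        W = np.outer(E1[a, :], E3[:, b]) * E2  # W[x, y]
        denom = W.sum()
        if denom == 0.0:
            pair = (g.labels[a], g.labels[b])
            raise ValueError(f"all three-segment weights vanish for pair {pair}")
        total += setup.p[a, b] * float((lnE2 * W).sum() / denom)
    return total


@dataclass(frozen=True)
class MartinssonEval:
    """Lattice evaluation of M*(s, r, beta) and the resulting type."""

    s_values: np.ndarray
    r_values: np.ndarray
    grid: np.ndarray  # shape (len(s_values), len(r_values)), interior lattice
    beta: float
    max_interior: float
    ds_at_1: float
    classification: str  # "regular" | "semi_regular" | "irregular"
    tol: float


#: Geometrically refined lattice lines appended near the domain boundary:
#: the positive region of an irregular setup can be a thin sliver hugging
#: s -> 1 (observed for the order-4 irregular family), which a uniform
#: lattice of moderate resolution would miss.
_BOUNDARY_LINES = (0.001, 0.005, 0.01, 0.05, 0.95, 0.99, 0.995, 0.999)


def _lattice(grid_n: int) -> np.ndarray:
    vals = set(np.arange(1, grid_n) / grid_n) | set(_BOUNDARY_LINES)
    return np.array(sorted(vals))


def classify(
    setup: AccessibilitySetup,
    grid_n: int = 200,
    tol: float = 1e-9,
    beta: float | None = None,
    threshold: ThresholdResult | None = None,
) -> MartinssonEval:
    """Classify a setup as regular / semi-regular / irregular from the sign
    pattern of Martinsson's function at the critical point.

    ``beta`` defaults to the setup's beta* (solved on the fly or taken from
    a precomputed ``threshold``).  The function is evaluated on an open
    (grid_n - 1)^2 lattice of interior (s, r) points, augmented with
    geometrically refined boundary lines; the setup is irregular iff the
    interior maximum exceeds ``tol``, regular iff every interior value is
    below ``-tol`` and the one-sided s-derivative at s = 1 exceeds ``tol``
    in magnitude, and semi-regular otherwise.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be at least 2")
    if beta is None:
        if threshold is None:
            threshold = solve_beta_star(setup)
        beta = threshold.beta_star

    s_values = _lattice(grid_n)
    r_values = _lattice(grid_n)
    grid = np.empty((len(s_values), len(r_values)))
    for i, s in enumerate(s_values):
        for j, r in enumerate(r_values):
            grid[i, j] = martinsson(setup, s, r, beta)
    max_interior = float(grid.max())

    h = 1e-5
    r_mid = 0.5
    ds_at_1 = (
        martinsson(setup, 1.0, r_mid, beta)
        - martinsson(setup, 1.0 - h, r_mid, beta)
    ) / h

    if max_interior > tol:
        label = "irregular"
    elif bool((grid < -tol).all()) and abs(ds_at_1) > tol:
        label = "regular"
    else:
        label = "semi_regular"
    return MartinssonEval(
        s_values=s_values,
        r_values=r_values,
        grid=grid,
        beta=float(beta),
        max_interior=max_interior,
        ds_at_1=float(ds_at_1),
        classification=label,
        tol=tol,
    )


@dataclass(frozen=True)
class SearchResult:
    """Outcome of a search for irregular allele graphs."""

    found: tuple[tuple[AlleleGraph, float, MartinssonEval], ...]
    examined: int
    complete: bool


def _digraphs_of_order(n: int):
    """All simple digraphs on n labelled vertices as adjacency matrices."""
    slots = [(i, j) for i in range(n) for j in range(n) if i != j]
    for bits in itertools.product((0, 1), repeat=len(slots)):
        A = np.zeros((n, n), dtype=np.int64)
        for (i, j), bit in zip(slots, bits):
            A[i, j] = bit
        yield A


def _canonical_under_interior_relabelling(A: np.ndarray) -> bool:
    """True iff A is the lexicographically largest representative among all
    permutations of the interior vertices (endpoints 0 and n-1 fixed);
    used to skip setups equivalent up to relabelling."""
    n = A.shape[0]
    key = tuple(A.flat)
    for perm in itertools.permutations(range(1, n - 1)):
        order = (0, *perm, n - 1)
        other = tuple(A[np.ix_(order, order)].flat)
        if other > key:
            return False
    return True


def search_irregular(
    max_vertices: int,
    beta_cap: float = math.inf,
    budget: int | None = None,
    grid_n: int = 8,
    tol: float = 1e-9,
    rng_seed: int = 0,
    n_samples: int = 500,
) -> SearchResult:
    """Best-effort search for allele graphs whose homopolymer setup
    (divergence weight 1 on the pair (first vertex, last vertex)) is of
    irregular type with beta* <= beta_cap.

    Graph orders up to 4 are enumerated exhaustively (one representative
    per relabelling class of the interior vertices); order 5 is sampled
    (``n_samples`` seeded draws), larger orders are refused.  ``budget``
    caps the number of classified graphs; when it is exhausted the partial
    result is returned with ``complete=False``.  Irregularity is decided
    on a coarse screening lattice -- the ``grid_n`` uniform grid plus the
    refined boundary lines -- which is sound for inclusion (a positive
    lattice value survives any refinement) but, being best-effort, may
    miss setups whose positive region avoids the lattice entirely.
    """
    if max_vertices > 5:
        raise ValueError("search supports at most 5 vertices")
    rng = np.random.default_rng(rng_seed)
    found: list[tuple[AlleleGraph, float, MartinssonEval]] = []
    examined = 0

    def candidates(n: int):
        if n <= 4:
            for A in _digraphs_of_order(n):
                if _canonical_under_interior_relabelling(A):
                    yield A
        else:
            slots = [(i, j) for i in range(n) for j in range(n) if i != j]
            for _ in range(n_samples):
                A = np.zeros((n, n), dtype=np.int64)
                for (i, j), bit in zip(slots, rng.integers(0, 2, len(slots))):
                    A[i, j] = bit
                yield A

    for n in range(2, max_vertices + 1):
        labels = tuple(str(i) for i in range(n))
        for A in candidates(n):
            graph = AlleleGraph(labels, A)
            reach = graph.reachable()
            if not reach[0, n - 1]:
                continue
            if budget is not None and examined >= budget:
                return SearchResult(tuple(found), examined, complete=False)
            examined += 1
            setup = AccessibilitySetup.homopolymer(graph, labels[0], labels[-1])
            res = solve_beta_star(setup)
            ev = classify(setup, grid_n=grid_n, tol=tol, threshold=res)
            if ev.classification == "irregular" and res.beta_star <= beta_cap:
                found.append((graph, res.beta_star, ev))
    return SearchResult(tuple(found), examined, complete=True)
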