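"""House-of-Cards simulation on Cartesian power genotype spaces.

Fitness values are i.i.d. standard uniform; a path is accessible if its
fitness values increase at every step.  Conditioning on the fitness
difference beta between the endpoints is applied by pinning the initial
genotype at fitness 0 and the final genotype at beta (shifting all values
modulo 1 leaves the i.i.d. uniform law invariant, so this is the same
event).  Accessibility then depends only on the rank order of the
remaining values, which also yields the equivalent Bernoulli site
percolation picture: each interior genotype survives with probability
beta and only the order of the survivors matters.

Genotypes are encoded as mixed-radix integers (locus 0 least significant),
so neighbours are enumerated per locus without materialising the product
graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .allele_graphs import AlleleGraph, GenotypePair, counting_matrix

__all__ = [
    "LandscapeRealization",
    "SimSummary",
    "draw_landscape",
    "is_accessible",
    "estimate_accessibility",
    "estimate_accessibility_thinning",
    "exact_accessibility_small",
    "threshold_scan",
]

#: Refuse to materialise genotype spaces larger than this.
DEFAULT_GENOTYPE_CAP = 10**6

_UNREACHED = np.iinfo(np.int32).max


# ---------------------------------------------------------------------------
# Genotype-space plumbing
# ---------------------------------------------------------------------------


def _encode(genotype: tuple[str, ...], graph: AlleleGraph) -> int:
    code = 0
    for lab in reversed(genotype):
        code = code * graph.n_alleles + graph.index(lab)
    return code


def _decode(code: int, graph: AlleleGraph, L: int) -> tuple[str, ...]:
    out = []
    for _ in range(L):
        out.append(graph.labels[code % graph.n_alleles])
        code //= graph.n_alleles
    return tuple(out)


def _edge_arrays(graph: AlleleGraph, L: int) -> tuple[np.ndarray, np.ndarray]:
    """All arrows of the genotype space as (src, dst) index arrays."""
    n = graph.n_alleles
    size = n**L
    out_nbrs = [np.nonzero(graph.adjacency[v])[0] for v in range(n)]
    src: list[np.ndarray] = []
    dst: list[np.ndarray] = []
    codes = np.arange(size, dtype=np.int64)
    rem = codes.copy()
    for locus in range(L):
        allele = rem % n
        rem //= n
        stride = n**locus
        for v in range(n):
            here = codes[allele == v]
            for w in out_nbrs[v]:
                src.append(here)
                dst.append(here + (int(w) - v) * stride)
    if not src:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(src), np.concatenate(dst)


def _in_neighbour_lists(graph: AlleleGraph, L: int, size: int):
    """Per-genotype in-neighbour generator data: for each locus, alleles
    that may mutate into the current one."""
    n = graph.n_alleles
    in_nbrs = [np.nonzero(graph.adjacency[:, w])[0] for w in range(n)]
    return n, in_nbrs


# ---------------------------------------------------------------------------
# Landscape realisations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandscapeRealization:
    """One conditioned House-of-Cards draw on a genotype space."""

    graph: AlleleGraph
    L: int
    pair: GenotypePair
    beta: float
    seed: int | tuple
    fitness: np.ndarray = field(repr=False)

    @property
    def a_index(self) -> int:
        return _encode(self.pair.a, self.graph)

    @property
    def b_index(self) -> int:
        return _encode(self.pair.b, self.graph)


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    # independent, order-invariant stream per (master seed, replicate)
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep)]))


def draw_landscape(
    graph: AlleleGraph,
    L: int,
    pair: GenotypePair,
    beta: float,
    seed: int,
    rep: int = 0,
    cap: int = DEFAULT_GENOTYPE_CAP,
) -> LandscapeRealization:
    """Draw one HoC landscape conditioned on the endpoint fitness values
    (initial genotype at 0, final at beta); interior values i.i.d. uniform
    on [0, 1].  Reproducible given (seed, rep)."""
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    if pair.L != L:
        raise ValueError("pair length does not match L")
    size = graph.n_alleles**L
    if size > cap:
        raise ValueError(f"genotype space of size {size} exceeds cap {cap}")
    rng = _replicate_rng(seed, rep)
    fitness = rng.random(size)
    fitness[_encode(pair.a, graph)] = 0.0
    fitness[_encode(pair.b, graph)] = beta
    return LandscapeRealization(graph, L, pair, beta, (seed, rep), fitness)


# ---------------------------------------------------------------------------
# Accessibility checking
# ---------------------------------------------------------------------------


def is_accessible(
    landscape: LandscapeRealization,
) -> tuple[bool, list[tuple[str, ...]] | None]:
    """Decide whether the final genotype is accessible from the initial one
    and return a witness path if so.

    Single pass over genotypes sorted by fitness (ties broken by genotype
    index, a probability-zero event): a genotype is reachable iff some
    in-neighbour with strictly smaller fitness is reachable; predecessor
    pointers reconstruct a fitness-monotonic witness path.  The witness is
    always simple because fitness strictly increases along it.
    """
    g = landscape.graph
    F = landscape.fitness
    n, in_nbrs = _in_neighbour_lists(g, landscape.L, F.size)
    ia, ib = landscape.a_index, landscape.b_index
    order = np.argsort(F, kind="stable")
    reachable = np.zeros(F.size, dtype=bool)
    pred = np.full(F.size, -1, dtype=np.int64)
    reachable[ia] = True
    for code in order:
        if reachable[code] or code == ia:
            continue
        rem = int(code)
        fg = F[code]
        for locus in range(landscape.L):
            allele = rem % n
            rem //= n
            stride = n**locus
            for u_allele in in_nbrs[allele]:
                u = code + (int(u_allele) - allele) * stride
                if reachable[u] and (F[u], u) < (fg, code):
                    reachable[code] = True
                    pred[code] = u
                    break
            if reachable[code]:
                break
    if not reachable[ib]:
        return False, None
    path = [int(ib)]
    while path[-1] != ia:
        path.append(int(pred[path[-1]]))
    path.reverse()
    return True, [_decode(c, g, landscape.L) for c in path]


def _propagate_hops(
    F: np.ndarray, src: np.ndarray, dst: np.ndarray, ia: int, size: int
) -> np.ndarray:
    """Vectorised reachability with hop counts for a batch of landscapes.

    ``F`` has shape (batch, size).  Returns D of the same shape: the
    minimum number of fitness-increasing steps from the initial genotype,
    _UNREACHED where no monotonic path exists.  Equivalent to the sorted
    single-pass checker (tested against it); edges are relaxed in rounds
    until a fixed point, which terminates because hop counts only shrink.
    """
    # group edges by destination once for segment-wise minimum reduction
    order = np.argsort(dst, kind="stable")
    src_s, dst_s = src[order], dst[order]
    seg_starts = np.flatnonzero(np.r_[True, dst_s[1:] != dst_s[:-1]])
    seg_dst = dst_s[seg_starts]

    batch = F.shape[0]
    D = np.full((batch, size), _UNREACHED, dtype=np.int32)
    D[:, ia] = 0
    if src_s.size == 0:
        return D
    allowed = F[:, src_s] < F[:, dst_s]
    while True:
        cand = D[:, src_s]
        cand = np.where(allowed & (cand < _UNREACHED), cand + 1, _UNREACHED)
        seg_min = np.minimum.reduceat(cand, seg_starts, axis=1)
        new_D = D.copy()
        new_D[:, seg_dst] = np.minimum(new_D[:, seg_dst], seg_min)
        if np.array_equal(new_D, D):
            return D
        D = new_D


@dataclass(frozen=True)
class SimSummary:
    """Monte-Carlo accessibility estimate with a Wilson 95% interval."""

    reps: int
    hits: int
    p_hat: float
    ci_low: float
    ci_high: float
    path_length_samples: np.ndarray = field(repr=False)

    @property
    def mean_witness_length(self) -> float:
        if self.path_length_samples.size == 0:
            return math.nan
        return float(self.path_length_samples.mean())


def _wilson_summary(hits: int, reps: int, lengths: np.ndarray) -> SimSummary:
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(hits, reps, alpha=0.05, method="wilson")
    return SimSummary(reps, hits, hits / reps, float(lo), float(hi), lengths)


def _batched_estimate(
    graph: AlleleGraph,
    L: int,
    pair: GenotypePair,
    reps: int,
    seed: int,
    fill_fitness,
    cap: int,
    batch_size: int | None = None,
) -> SimSummary:
    size = graph.n_alleles**L
    if size > cap:
        raise ValueError(f"genotype space of size {size} exceeds cap {cap}")
    src, dst = _edge_arrays(graph, L)
    ia, ib = _encode(pair.a, graph), _encode(pair.b, graph)
    if batch_size is None:
        # keep the per-round working set (batch x edges) around ~10^7 entries
        batch_size = 10**7 // max(1, src.size)
    batch_size = max(1, min(batch_size, reps))
    hits = 0
    lengths: list[np.ndarray] = []
    done = 0
    while done < reps:
        b = min(batch_size, reps - done)
        F = np.empty((b, size))
        for i in range(b):
            fill_fitness(F[i], _replicate_rng(seed, done + i))
        F[:, ia] = 0.0
        D = _propagate_hops(F, src, dst, ia, size)
        reached = D[:, ib] < _UNREACHED
        hits += int(reached.sum())
        if reached.any():
            lengths.append(D[reached, ib].astype(np.int64))
        done += b
    all_lengths = (
        np.concatenate(lengths) if lengths else np.empty(0, dtype=np.int64)
    )
    return _wilson_summary(hits, reps, all_lengths)


def estimate_accessibility(
    graph: AlleleGraph,
    L: int,
    pair: GenotypePair,
    beta: float,
    reps: int,
    seed: int,
    cap: int = DEFAULT_GENOTYPE_CAP,
) -> SimSummary:
    """Monte-Carlo estimate of beta-accessibility by conditioned-uniform
    draws: endpoints pinned at 0 and beta, interior i.i.d. uniform on
    [0, 1].  Witness lengths are the minimum number of steps of a
    fitness-monotonic path in each accessible replicate."""
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if pair.L != L:
        raise ValueError("pair length does not match L")
    ib = _encode(pair.b, graph)

    def fill(row: np.ndarray, rng: np.random.Generator) -> None:
        row[:] = rng.random(row.size)
        row[ib] = beta

    return _batched_estimate(graph, L, pair, reps, seed, fill, cap)


def estimate_accessibility_thinning(
    graph: AlleleGraph,
    L: int,
    pair: GenotypePair,
    beta: float,
    reps: int,
    seed: int,
    cap: int = DEFAULT_GENOTYPE_CAP,
) -> SimSummary:
    """Equivalent estimator through the Bernoulli site-percolation picture:
    each interior genotype is kept with probability beta (one uniform
    draw) and the kept genotypes receive an independent rank order (a
    second draw); accessibility uses only those ranks.  Distribution-equal
    to the conditioned-uniform estimator and used as a cross-check."""
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    if pair.L != L:
        raise ValueError("pair length does not match L")
    ib = _encode(pair.b, graph)

    def fill(row: np.ndarray, rng: np.random.Generator) -> None:
        keep = rng.random(row.size) < beta
        ranks = rng.random(row.size)
        # removed genotypes get +inf: never on a monotonic path to b
        row[:] = np.where(keep, beta * ranks, np.inf)
        row[ib] = beta

    return _batched_estimate(graph, L, pair, reps, seed, fill, cap)


# ---------------------------------------------------------------------------
# Exact small-instance probability (inclusion-exclusion over paths)
# ---------------------------------------------------------------------------


def _linear_extensions(preds: list[int], m: int) -> int:
    """Number of linear extensions of a poset on m elements given as
    predecessor bitmasks (0 if the relation is cyclic)."""
    dp = np.zeros(1 << m, dtype=np.int64)
    dp[0] = 1
    for mask in range(1 << m):
        if dp[mask] == 0:
            continue
        for v in range(m):
            bit = 1 << v
            if mask & bit:
                continue
            if preds[v] & ~mask:
                continue
            dp[mask | bit] += dp[mask]
    return int(dp[(1 << m) - 1])


def exact_accessibility_small(
    graph: AlleleGraph,
    L: int,
    pair: GenotypePair,
    beta: float,
    max_paths: int = 12,
    max_interior: int = 10,
) -> float:
    """Exact beta-accessibility by inclusion-exclusion over the simple
    paths of the genotype space.

    A set S of paths is simultaneously accessible iff the m interior
    genotypes of its union all fall in (0, beta) (probability beta^m) and
    their uniform rank order extends the union of the paths' chain orders
    (probability e/m!, with e the number of linear extensions; e = 0 when
    two paths order shared interiors inconsistently).  Feasible only for
    few paths / interiors; raises when the caps are exceeded so callers
    can fall back to Monte Carlo.
    """
    import networkx as nx

    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    if pair.L != L:
        raise ValueError("pair length does not match L")
    size = graph.n_alleles**L
    if size > 10**4:
        raise ValueError("genotype space too large for path enumeration")
    src, dst = _edge_arrays(graph, L)
    G = nx.DiGraph()
    G.add_nodes_from(range(size))
    G.add_edges_from(zip(src.tolist(), dst.tolist()))
    ia, ib = _encode(pair.a, graph), _encode(pair.b, graph)

    paths: list[list[int]] = []
    for path in nx.all_simple_paths(G, ia, ib):
        paths.append(path)
        if len(paths) > max_paths:
            raise ValueError(f"more than {max_paths} simple paths; cap exceeded")
    if not paths:
        return 0.0

    interiors = sorted({v for path in paths for v in path[1:-1]})
    if len(interiors) > max_interior:
        raise ValueError(
            f"{len(interiors)} interior genotypes on the path union; cap exceeded"
        )
    vid = {v: i for i, v in enumerate(interiors)}

    total = 0.0
    k = len(paths)
    for subset in range(1, 1 << k):
        chosen = [paths[i] for i in range(k) if subset >> i & 1]
        union: set[int] = set()
        rel: set[tuple[int, int]] = set()
        for path in chosen:
            inner = [vid[v] for v in path[1:-1]]
            union.update(inner)
            rel.update(
                (inner[i], inner[j])
                for i in range(len(inner))
                for j in range(i + 1, len(inner))
            )
        elems = sorted(union)
        local = {v: i for i, v in enumerate(elems)}
        m = len(elems)
        preds = [0] * m
        for u, v in rel:
            preds[local[v]] |= 1 << local[u]
        e = _linear_extensions(preds, m)
        prob = beta**m * e / math.factorial(m)
        total += prob if bin(subset).count("1") % 2 == 1 else -prob
    return total


# ---------------------------------------------------------------------------
# Threshold scans
# ---------------------------------------------------------------------------


def threshold_scan(
    graph: AlleleGraph,
    L_list,
    pair_family,
    beta_grid,
    reps: int,
    seed: int,
    cap: int = DEFAULT_GENOTYPE_CAP,
):
    """Tabulate Monte-Carlo accessibility over an (L, beta) grid.

    ``pair_family`` maps L to a GenotypePair (or is a pair of allele
    labels (a, b), meaning the homopolymer endpoints a^L -> b^L).  Returns
    a long-format DataFrame; for regular setups the empirical crossing of
    p_hat sharpens around the threshold c_L as L grows.
    """
    import pandas as pd

    if not callable(pair_family):
        a_lab, b_lab = pair_family
        pair_family = lambda L: GenotypePair((a_lab,) * L, (b_lab,) * L)
    rows = []
    for L in L_list:
        pair = pair_family(L)
        for beta in beta_grid:
            summary = estimate_accessibility(
                graph, L, pair, float(beta), reps, seed, cap=cap
            )
            rows.append(
                {
                    "L": L,
                    "beta": float(beta),
                    "reps": summary.reps,
                    "hits": summary.hits,
                    "p_hat": summary.p_hat,
                    "ci_low": summary.ci_low,
                    "ci_high": summary.ci_high,
                    "mean_witness_length": summary.mean_witness_length,
                }
            )
    return pd.DataFrame(rows)
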