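"""Allele graphs and accessibility setups.

An allele graph is a finite simple directed graph whose vertices are the
possible allelic states of one genetic locus and whose arrows are the
permitted single-step mutations.  The L-fold Cartesian power of an allele
graph is the genotype space: genotypes are length-L allele sequences and a
mutation changes exactly one locus along an allele-graph arrow.

A pair of endpoint genotypes is summarised, up to the irrelevant permutation
symmetry of loci, by its allele counting matrix M (how many loci must move
from allele v to allele w) and, asymptotically in L, by the divergence
matrix p = lim M/L.  A graph together with a divergence matrix forms an
accessibility setup, the object on which critical fitness differences are
computed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlleleGraph",
    "GenotypePair",
    "AccessibilitySetup",
    "SetupReport",
    "build_complete",
    "build_complete_no_return",
    "build_path",
    "build_amino_acid_graph",
    "counting_matrix",
    "validate_setup",
    "standard_genetic_code",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleGraph:
    """A finite simple directed graph of alleles.

    Parameters
    ----------
    labels
        Ordered vertex names.  All matrices produced by this package use
        this order.
    adjacency
        Square 0/1 matrix ``A`` with ``A[v, w] = 1`` iff there is an arrow
        from ``labels[v]`` to ``labels[w]``.  The diagonal must be zero
        (no self-loops).
    """

    labels: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if A.shape[0] != len(self.labels):
            raise ValueError("label count does not match adjacency size")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate vertex labels")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.diag(A).any():
            raise ValueError("self-loops are not allowed on an allele graph")
        object.__setattr__(self, "adjacency", A.astype(np.int64))
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    # -- basic attributes ---------------------------------------------------

    @property
    def n_alleles(self) -> int:
        return len(self.labels)

    @property
    def max_degree(self) -> int:
        """Largest out- or in-degree of any vertex."""
        A = self.adjacency
        return int(max(A.sum(axis=1).max(), A.sum(axis=0).max()))

    def index(self, label: str) -> int:
        try:
            return self.labels.index(str(label))
        except ValueError:
            raise KeyError(f"unknown allele label {label!r}") from None

    # -- derived structure --------------------------------------------------

    def reachable(self) -> np.ndarray:
        """Boolean matrix: entry (v, w) is True iff a walk of length >= 1
        from v to w exists.  Diagonal entries require a genuine cycle."""
        A = self.adjacency.astype(bool)
        R = A.copy()
        for _ in range(self.n_alleles):
            R_new = R | (R @ A)
            if (R_new == R).all():
                break
            R = R_new
        return R

    def distance(self, source: str, target: str) -> float:
        """Directed graph distance between two alleles (inf if unreachable)."""
        import networkx as nx

        G = self.to_networkx()
        try:
            return float(nx.shortest_path_length(G, str(source), str(target)))
        except nx.NetworkXNoPath:
            return float("inf")

    def to_networkx(self):
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(self.labels)
        v_idx, w_idx = np.nonzero(self.adjacency)
        G.add_edges_from((self.labels[v], self.labels[w]) for v, w in zip(v_idx, w_idx))
        return G

    def permuted(self, order: Sequence[int]) -> "AlleleGraph":
        """Relabelled copy with vertices reordered by ``order``."""
        order = list(order)
        A = self.adjacency[np.ix_(order, order)]
        return AlleleGraph(tuple(self.labels[i] for i in order), A)

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        v_idx, w_idx = np.nonzero(self.adjacency)
        edges = [[self.labels[v], self.labels[w]] for v, w in zip(v_idx, w_idx)]
        return json.dumps({"labels": list(self.labels), "edges": edges})

    @classmethod
    def from_json(cls, text: str) -> "AlleleGraph":
        data = json.loads(text)
        labels = [str(x) for x in data["labels"]]
        edges = [(str(u), str(v)) for u, v in data.get("edges", [])]
        undirected = [(str(u), str(v)) for u, v in data.get("undirected_edges", [])]
        return cls.from_edges(labels, edges, undirected)

    @classmethod
    def from_edges(
        cls,
        labels: Iterable[str],
        edges: Iterable[tuple[str, str]] = (),
        undirected_edges: Iterable[tuple[str, str]] = (),
    ) -> "AlleleGraph":
        labels = tuple(str(x) for x in labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        A = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for u, v in edges:
            A[idx[u], idx[v]] = 1
        for u, v in undirected_edges:
            A[idx[u], idx[v]] = 1
            A[idx[v], idx[u]] = 1
        return cls(labels, A)

    @classmethod
    def from_edgelist_tsv(cls, path) -> "AlleleGraph":
        """Read a two-column (source, target) TSV; an optional third column
        equal to ``both`` makes the edge bidirectional.  Vertices are ordered
        lexicographically by label."""
        directed: list[tuple[str, str]] = []
        undirected: list[tuple[str, str]] = []
        seen: set[str] = set()
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                u, v = row[0].strip(), row[1].strip()
                seen.update((u, v))
                if len(row) > 2 and row[2].strip().lower() == "both":
                    undirected.append((u, v))
                else:
                    directed.append((u, v))
        return cls.from_edges(sorted(seen), directed, undirected)


@dataclass(frozen=True)
class GenotypePair:
    """Endpoint genotypes as equal-length allele-label sequences."""

    a: tuple[str, ...]
    b: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", tuple(str(x) for x in self.a))
        object.__setattr__(self, "b", tuple(str(x) for x in self.b))
        if len(self.a) != len(self.b):
            raise ValueError("endpoint genotypes must have equal length")
        if len(self.a) == 0:
            raise ValueError("genotypes must have at least one locus")

    @property
    def L(self) -> int:
        return len(self.a)


def counting_matrix(pair: GenotypePair, graph: AlleleGraph) -> np.ndarray:
    """Allele counting matrix: entry (v, w) counts loci with a_l = v and
    b_l = w.  Entries sum to the number of loci."""
    M = np.zeros((graph.n_alleles, graph.n_alleles), dtype=np.int64)
    for av, bw in zip(pair.a, pair.b):
        M[graph.index(av), graph.index(bw)] += 1
    return M


@dataclass(frozen=True)
class AccessibilitySetup:
    """An allele graph together with the asymptotic direction between the
    endpoint genotypes.

    ``p`` is the divergence matrix: nonnegative, summing to one, entry
    (v, w) the asymptotic fraction of loci required to move from allele v
    to allele w.  ``M`` optionally pins a concrete finite-L counting matrix
    (then ``L = M.sum()`` and the remainder is ``R = M - L p``).
    """

    graph: AlleleGraph
    p: np.ndarray
    M: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        n = self.graph.n_alleles
        if p.shape != (n, n):
            raise ValueError("divergence matrix has wrong shape")
        object.__setattr__(self, "p", p)
        if self.M is not None:
            M = np.asarray(self.M)
            if M.shape != (n, n):
                raise ValueError("counting matrix has wrong shape")
            object.__setattr__(self, "M", M.astype(np.int64))

    @property
    def L(self) -> int | None:
        return None if self.M is None else int(self.M.sum())

    @property
    def delta(self) -> float:
        """Relative distance: total off-diagonal divergence weight."""
        return float(self.p.sum() - np.trace(self.p))

    @property
    def remainder(self) -> np.ndarray | None:
        """Finite-L remainder matrix R = M - L p (None without M)."""
        if self.M is None:
            return None
        return self.M - self.L * self.p

    # -- constructors -------------------------------------------------------

    @classmethod
    def homopolymer(cls, graph: AlleleGraph, a: str, b: str) -> "AccessibilitySetup":
        """All loci move from allele ``a`` to allele ``b`` (p_{ab} = 1)."""
        p = np.zeros((graph.n_alleles, graph.n_alleles))
        p[graph.index(a), graph.index(b)] = 1.0
        return cls(graph, p)

    @classmethod
    def from_delta(
        cls, graph: AlleleGraph, a: str, b: str, delta: float
    ) -> "AccessibilitySetup":
        """A fraction ``delta`` of loci move a -> b, the rest stay at ``a``."""
        if not 0.0 < delta <= 1.0:
            raise ValueError("relative distance delta must lie in (0, 1]")
        p = np.zeros((graph.n_alleles, graph.n_alleles))
        p[graph.index(a), graph.index(b)] = delta
        p[graph.index(a), graph.index(a)] = 1.0 - delta
        return cls(graph, p)

    @classmethod
    def from_pair(cls, graph: AlleleGraph, pair: GenotypePair) -> "AccessibilitySetup":
        """Finite-L setup in which the divergence matrix is taken to be the
        pair's own counting matrix divided by L (zero remainder)."""
        M = counting_matrix(pair, graph)
        return cls(graph, M / pair.L, M=M)

    @classmethod
    def from_divergence_csv(cls, graph: AlleleGraph, path) -> "AccessibilitySetup":
        """Divergence matrix CSV: header row and first column are labels."""
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        df.index = df.index.map(str)
        df.columns = df.columns.map(str)
        p = np.zeros((graph.n_alleles, graph.n_alleles))
        for v in df.index:
            for w in df.columns:
                p[graph.index(v), graph.index(w)] = float(df.loc[v, w])
        return cls(graph, p)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _numeric_labels(n: int) -> tuple[str, ...]:
    # zero-padded so lexicographic label order equals numeric order
    width = len(str(n - 1))
    return tuple(str(i).zfill(width) for i in range(n))


def build_complete(n: int) -> AlleleGraph:
    """Complete directed graph on ``n`` alleles (all mutations allowed)."""
    if n < 2:
        raise ValueError("a complete allele graph needs at least 2 alleles")
    A = np.ones((n, n), dtype=np.int64) - np.eye(n, dtype=np.int64)
    return AlleleGraph(_numeric_labels(n), A)


def build_complete_no_return(n: int, wildtype: int | str = 0) -> AlleleGraph:
    """Complete graph with all arrows into the wild-type allele removed,
    modelling irreversible loss of the initial allelic state."""
    if n < 2:
        raise ValueError("a complete allele graph needs at least 2 alleles")
    labels = _numeric_labels(n)
    if isinstance(wildtype, str):
        if wildtype not in labels:
            raise ValueError(f"invalid wildtype label {wildtype!r}")
        wt = labels.index(wildtype)
    else:
        wt = int(wildtype)
        if not 0 <= wt < n:
            raise ValueError(f"invalid wildtype index {wildtype}")
    A = np.ones((n, n), dtype=np.int64) - np.eye(n, dtype=np.int64)
    A[:, wt] = 0
    return AlleleGraph(labels, A)


def build_path(n: int) -> AlleleGraph:
    """Path graph 0 - 1 - ... - (n-1) with bidirectional arrows; mutations
    must pass through every intermediate allele in order."""
    if n < 2:
        raise ValueError("a path allele graph needs at least 2 alleles")
    A = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        A[i, i + 1] = 1
        A[i + 1, i] = 1
    return AlleleGraph(_numeric_labels(n), A)


_BASES = "ACGU"


def standard_genetic_code() -> dict[str, str]:
    """Codon (RNA) -> three-letter amino-acid code under the standard
    nuclear genetic code; stop codons map to ``Stop``."""
    from Bio.Data import CodonTable
    from Bio.SeqUtils import seq3

    table = CodonTable.unambiguous_rna_by_id[1]
    code = {codon: seq3(aa) for codon, aa in table.forward_table.items()}
    for codon in table.stop_codons:
        code[codon] = "Stop"
    return code


def build_amino_acid_graph(
    include_stop: bool = True,
    codon_table: Mapping[str, str] | None = None,
) -> AlleleGraph:
    """Amino-acid allele graph induced by single-nucleotide substitutions.

    Vertices are amino acids (three-letter codes); an arrow joins X to Y iff
    some codon translating to X can be changed into a codon translating to Y
    by substituting a single nucleotide.  The graph is symmetric because
    single-nucleotide substitutions are reversible.

    By default the stop signal is treated as a 21st allele with its own
    arrows, which matches the published critical values for this graph;
    with ``include_stop=False`` codons involving stop are ignored, i.e.
    mutations into or through stop are considered absent (a 20-vertex
    graph, the variant appropriate when premature termination is lethal).
    """
    code = dict(codon_table) if codon_table is not None else standard_genetic_code()
    vertices = sorted(set(code.values()) - ({"Stop"} if not include_stop else set()))
    idx = {aa: i for i, aa in enumerate(vertices)}
    A = np.zeros((len(vertices), len(vertices)), dtype=np.int64)
    for codon, aa_x in code.items():
        if aa_x not in idx:
            continue
        for pos in range(3):
            for base in _BASES:
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                aa_y = code.get(mutant)
                if aa_y is None or aa_y == aa_x or aa_y not in idx:
                    continue
                A[idx[aa_x], idx[aa_y]] = 1
    return AlleleGraph(tuple(vertices), A)


# ---------------------------------------------------------------------------
# Setup validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SetupReport:
    """Per-condition validation report for an accessibility setup."""

    conditions: tuple[tuple[str, bool, str], ...]
    delta: float

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.conditions)

    def __str__(self) -> str:
        lines = [
            f"[{'PASS' if ok else 'FAIL'}] {name}" + (f": {detail}" if detail else "")
            for name, ok, detail in self.conditions
        ]
        lines.append(f"relative distance delta = {self.delta:g}")
        return "\n".join(lines)


def validate_setup(setup: AccessibilitySetup) -> SetupReport:
    """Check the defining conditions of a well-behaved accessibility setup:

    1. weight only on allele pairs joined by a walk of non-zero length,
    2. endpoints differ (checkable when a counting matrix is given),
    3. the divergence matrix is a proper probability matrix,
    4. the relative distance delta is positive,
    plus consistency of the counting matrix when one is supplied.
    """
    g, p = setup.graph, setup.p
    reach = g.reachable()
    conditions: list[tuple[str, bool, str]] = []

    bad = [
        (g.labels[v], g.labels[w])
        for v, w in zip(*np.nonzero((p > 0) & ~reach))
    ]
    conditions.append(
        (
            "weights only on pairs joined by a non-zero-length walk",
            not bad,
            f"offending pairs: {bad}" if bad else "",
        )
    )

    if setup.M is not None:
        off = setup.M.sum() - np.trace(setup.M)
        conditions.append(
            ("endpoint genotypes differ", off > 0, "" if off > 0 else "a_L == b_L")
        )

    finite = bool(np.isfinite(p).all())
    nonneg = finite and bool((p >= 0).all())
    norm = finite and abs(p.sum() - 1.0) <= 1e-9
    conditions.append(
        (
            "divergence matrix is nonnegative and sums to 1",
            nonneg and norm,
            "" if nonneg and norm else f"sum = {p.sum()!r}",
        )
    )

    delta = setup.delta
    conditions.append(
        ("relative distance delta > 0", delta > 0, f"delta = {delta:g}")
    )

    if setup.M is not None:
        M = setup.M
        ok_m = bool((M >= 0).all())
        conditions.append(
            ("counting matrix entries are nonnegative integers", ok_m, "")
        )

    return SetupReport(tuple(conditions), delta)
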