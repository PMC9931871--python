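# Methods

## Model

A genotype is a length-L sequence over the vertex set of an *allele
graph* 𝒜: a finite simple directed graph whose arrows are the point
mutations permitted on one locus. The genotype space is the Cartesian
power 𝒜^L — an arrow changes exactly one locus along an allele-graph
arrow. Fitness values are House-of-Cards: i.i.d. continuous, taken
standard uniform without loss of generality because accessibility (the
existence of a directed path with strictly increasing fitness) depends
only on rank order. β-accessibility conditions on the endpoint fitness
difference F(b) − F(a) = β; because shifting all uniform values modulo 1
leaves the law invariant, this is implemented by pinning F(a) = 0 and
F(b) = β exactly, interiors i.i.d. uniform on [0, 1]. Equivalently
(Bernoulli site-percolation picture) each interior genotype survives with
probability β and only the survivors' rank order matters; both pictures
are implemented and cross-checked against each other.

Endpoint sequences enter only through the allele counting matrix
M_vw = #{loci with a_l = v, b_l = w} and, asymptotically, the divergence
matrix p = lim M/L. A *well-behaved setup* requires: weight only on
allele pairs joined by a walk of non-zero length, distinct endpoints, a
convergent p, and positive relative distance δ = Σ_{v≠w} p_vw.
`validate_setup` reports each condition separately with the offending
allele pairs.

## Spectral quantities

All analytics derive from Γ_vw(t) = ln((e^{tA})_vw) and its first two
t-derivatives, computed as (A e^{tA})_vw/(e^{tA})_vw and the analogous
second-order expression. Structural zeros of e^{tA} (allele pairs with no
connecting walk) are detected by boolean transitive closure and forced to
exactly zero, never left to floating-point round-off; such pairs carry an
explicit "unreachable" flag and their e^Γ contributions are exactly 0. A
diagonal pair with no returning cycle has Γ ≡ 0 with vanishing
derivatives.

The divergence-weighted mean ⟨Γ(t)⟩ is strictly increasing with range
(−∞, ∞), so its root β* exists and is unique. The solver brackets from
t = 1 (halving the lower bound while the mean is positive, doubling the
upper while negative, cap 2^60) and refines with Brent's method at
machine tolerance; residuals are ~1e−15, well inside the 1e−12 contract.
β* is reported unclamped; β* > 1 sets `accessible = False` rather than
truncating the value. Closed forms for the complete graph (the positive
root of x^n − n x − 1 = 0) and the no-return graph
(β* = ln(n−1)/(n−2), Γ′* = n−1, limit (1, 1) at n = 2) are provided
separately and are cross-checked against the generic solver in the tests
rather than substituted for it.

Matrix exponentials use scipy's Padé scaling-and-squaring. The accuracy
contract is 1e−13 *relative to the dominant entry* of e^{tA}: a flat
absolute entry tolerance is not achievable in double precision once
entries reach e^{tΔ}. The contract is verified against an
extended-precision truncated power series on random 5×5 graphs.

Expected quasi-accessible walk counts (walks counted with revisited
genotypes re-randomised; the existence of a quasi-accessible walk is
equivalent to that of an accessible path) have the closed form
L Γ′(β) e^{L Γ(β)}. An independent brute-force oracle evaluates the same
expectation by explicit walk counting on the dense product-graph
adjacency matrix (powers up to n_max, each length-N walk weighted
β^{N−1}/(N−1)!), with a rigorous truncation tail bound
D e^{βD} (βD)^{n_max}/n_max! from the degree bound D = LΔ. The oracle is
restricted to |𝔸|^L ≤ 10^4 and converges monotonically from below.

## Regularity classification

Martinsson's function M*(s, r, β) splits walks into three segments
spanning fitness fractions β(1−s)r, βs, β(1−s)(1−r) and averages the
middle segment's Γ with weights e^{Γ_{ax} + Γ_{xy} + Γ_{yb}}; terms whose
middle segment is unreachable contribute zero to both numerator and
denominator (the Γ e^Γ = 0 convention, which also makes M*(0, r, β) = 0
exact). Classification at β*: *irregular* iff the lattice maximum over
interior (s, r) exceeds tol = 1e−9; *regular* iff every interior value is
below −tol and the one-sided s-derivative at s = 1 (step 1e−5, taken
inward since s = 1 is a boundary) exceeds tol in magnitude;
*semi-regular* otherwise.

The lattice is the uniform open grid (default 200 intervals per axis)
**augmented with geometric boundary lines** s, r ∈ {0.001, 0.005, 0.01,
0.05, 0.95, 0.99, 0.995, 0.999}. The augmentation matters: exhaustively
classifying all order-4 digraphs with homopolymer weights showed that the
positive region of the irregular examples is a sliver hugging the
(s→1, r→1) corner with maximum ≈ 1e−3, invisible to coarse uniform grids.
One representative of that family — the complete graph on four alleles
with the initial allele's arrows restricted to a single interior vertex —
ships in the test suite; the whole family has β* ≈ 1.02–1.05 > 1, so
irregularity there coexists with asymptotic inaccessibility.
`search_irregular` enumerates order ≤ 4 exhaustively (one representative
per relabelling class of interior vertices) and samples order 5 with a
seeded generator; its coarse screening lattice is sound for inclusion (a
positive lattice value survives refinement) but, like any lattice test,
cannot certify regularity — a sign change finer than the lattice would be
missed, a caveat surfaced in the classifier's CLI output.

## Simulator

Genotypes are mixed-radix integers (locus 0 least significant); the
genotype-space arrow list is generated per locus from the allele graph's
adjacency, never as a dense product matrix, with a refusal cap of 10^6
genotypes. Each replicate draws its fitness vector from an independent
stream seeded by (master seed, replicate index), so results are invariant
to replicate execution order and batching.

The reference accessibility checker is a single pass over genotypes
sorted by fitness (ties, a probability-zero event, broken by genotype
index): a genotype is reachable iff some in-neighbour with smaller
fitness is reachable; predecessor pointers yield a witness path, which is
automatically simple because fitness strictly increases along it. The
production estimator vectorises the same event across replicates by
relaxing fitness-increasing edges to a fixed point, tracking minimal hop
counts; its agreement with the single-pass checker is property-tested.
Witness lengths reported by the estimator are therefore *minimal*
monotonic path lengths. Estimates carry Wilson 95% intervals
(statsmodels).

For instances whose path structure is tiny (≤ 12 simple paths, ≤ 10
interior genotypes on their union) an exact probability is computed by
inclusion–exclusion over path subsets: a subset with m union interiors is
simultaneously accessible with probability β^m e/m!, where e counts the
linear extensions of the union of the paths' chain orders (bitmask
dynamic program; e = 0 for inconsistent orders). This oracle anchors the
Monte-Carlo estimators in the tests.

## Synthetic study conditions and their scope

The simulator *is* the data generator: landscapes are drawn exactly from
the conditioned HoC law, so simulation checks test the implementation,
not the model's fit to any empirical landscape. Real fitness landscapes
have correlated, non-exchangeable fitness values and heterogeneous loci;
nothing here speaks to them beyond the HoC idealisation. Desk-scale
checks use the biallelic complete graph with L ∈ {6, 8, 10} and 4000
replicates per cell (Monte-Carlo s.e. ≈ 0.008), sizes chosen so the whole
suite runs in minutes on one CPU; asymptotic threshold statements are
checked only through finite-size surrogates. One prescribed surrogate is
knowingly violated at this scale and its test left failing: p̂ at fixed
β > β* *decreases* with L over {6, 8, 10} for every β ≤ 1, because the
finite-L threshold c_L = β̂ − ln L/(L Γ′) rises towards β* as L grows,
shrinking the effective supercritical margin — the increase predicted by
the asymptotic theory sets in only at larger L. The subcritical decay and
the critical walk-length interval μL ± 3σ√L are reproduced.

## Genetic code

The amino-acid allele graph connects X and Y iff some codon of X mutates
to a codon of Y by a single nucleotide substitution, under NCBI
translation table 1 (via Biopython); a user-supplied codon→amino-acid
mapping can replace it. The default includes the stop signal as a 21st
vertex with its own arrows: computing both variants showed that the
21-vertex graph reproduces the published critical values for this network
(Tyr/Met β* = 0.4527, β*Γ′* = 4.7567; Asp/Met β* = 0.4570) to all printed
digits while the 20-vertex graph does not, so the stop-included graph is
what those results refer to. The 20-vertex variant
(`include_stop=False`) remains available for the modelling stance that
mutations into stop are lethal and hence absent. Tyr/Met is the unique
amino-acid pair at graph distance 3 and carries the longest critical
walks; its β* nevertheless lies *below* that of the distance-2 pair
Asp/Met — graph structure matters beyond distance.

## Known limitations

* Regularity classification is a lattice test with the caveats above;
  it is not a proof.
* The extended genotype space behind quasi-accessibility is handled
  analytically only; no runtime object represents it.
* Threshold functions are reported to leading order
  (β̂ − ln L/(L Γ′(β̂))); sub-leading terms beyond the bounded-remainder
  form are not resolved.
* Adaptive-walk dynamics (explicit SSWM walkers) and correlated
  landscapes are out of scope.
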