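# accperc — accessibility percolation on Cartesian power genotype spaces

Under strong-selection weak-mutation dynamics a population moves through
genotype space along *accessible paths*: mutational paths whose fitness
increases at every step. On a House-of-Cards (HoC) landscape — i.i.d.
uniform fitness values, so only rank order matters — whether the final
genotype **b** is accessible from the initial genotype **a** undergoes a
percolation-like transition in the conditioned fitness difference
β = F(**b**) − F(**a**) as the number of loci L grows.

`accperc` computes this transition analytically for genotype spaces built
as the L-fold Cartesian power 𝒜^L of an arbitrary finite simple directed
*allele graph* 𝒜 (vertices = allelic states of one locus, arrows =
permitted point mutations), and validates the analytics with a seeded HoC
simulator and exact small-instance oracles. It is aimed at researchers in
fitness-landscape theory and molecular evolution who want threshold
values, critical walk lengths, or simulation baselines for mutational
structures beyond the biallelic hypercube — including the amino-acid
mutation network induced by the standard genetic code.

## The model in brief

For alleles v, w and the adjacency matrix A of 𝒜, define

    Γ_vw(t) = ln ( (e^{tA})_vw ),

the exponential growth rate of expected quasi-accessible walk counts.
An endpoint sequence is summarised by its divergence matrix
p_vw = lim M_vw / L (the asymptotic fraction of loci that must move from
allele v to w). The divergence-weighted mean ⟨Γ(β)⟩_p is strictly
increasing in β, and its unique root is the **critical fitness
difference β\***:

    ⟨Γ_{a_l b_l}(β*)⟩_p = 0 .

Since β is a difference of fitness quantiles, β\* > 1 means the endpoints
can never be asymptotically accessible. The derivatives at the root give
the expected number of mutational steps per locus along critical
accessible walks, μ = β\*Γ′\* (the excess over 1 being reversions and
sideways steps), with per-locus variance σ² = β\*Γ′\* + β\*²Γ″\*. The
finite-L transition is located at c_L = β̂ − ln L / (L Γ′(β̂)). Whether
the first-moment threshold is sharp is decided by the sign pattern of
Martinsson's function M\*(s, r, β\*) (regular / semi-regular / irregular
setups), which `accperc` evaluates on a lattice.

## Worked example

Critical values for complete allele graphs at full Hamming distance
(`accperc table1`):

```
alleles beta_star       gamma_prime_star        walk_length_factor
2       0.8814  1.414   1.246
3       0.6309  2.532   1.598
4       0.5088  3.601   1.832
21      0.1542  20.86   3.217
```

Read: on the biallelic hypercube an accessible path between antipodal
genotypes exists (for large L) only when the endpoint fitness difference
exceeds β\* = ln(1+√2) ≈ 0.881, and critical paths take ≈ 1.246 L steps —
about 25% of steps are reversions or sideways moves. With more alleles the
required fitness difference drops and walks lengthen.

The path graph on three alleles, traversed end to end on every locus, is
a different story (`accperc beta-star --graph builder:path:3 --divergence
delta:1.0 --pair 0,2`):

```
{"beta_star": 1.246450480280461, "gamma_prime_star": 1.9999999999999996,
 "gamma_double_prime_star": -0.9999999999999991,
 "walk_length_factor": 2.4929009605609216, "accessible": false}
```

β\* = ln(3+2√2)/√2 ≈ 1.25 exceeds 1: no fitness difference makes this
setup asymptotically accessible.

Monte-Carlo simulation near the threshold (`accperc simulate --graph
builder:complete:2 --l 8 --a 00000000 --b 11111111 --beta 0.85
--reps 20000 --seed 42`):

```
{"p_hat": 0.45145, "ci_low": 0.44456320471152944,
 "ci_high": 0.4583554419895184, "reps": 20000,
 "mean_witness_length": 8.055155609702071}
```

At L = 8 and β = 0.85 (just below β\*) accessibility is still appreciable
— the finite-L threshold c_8 ≈ 0.70 sits well below β\*; witness paths
average ≈ 8 steps.

Other entry points: `accperc aatable` (all amino-acid homopolymer pairs
on the genetic-code graph), `accperc fig4` (β\* versus relative distance),
`accperc classify` (regularity type), `accperc scan` (p̂ over an (L, β)
grid). The same functionality is available from Python via
`accperc.solve_beta_star`, `accperc.classify`,
`accperc.estimate_accessibility`, etc.

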