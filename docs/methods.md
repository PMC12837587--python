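# Methods

## The calculus

The package treats one evolutionary step as a map between two probability
distributions over types and assigns it an informational fold, the Jeffreys
divergence

    J(q′, q) = Σ_i (q′_i − q_i) ln(q′_i / q_i),

the symmetrized Kullback–Leibler divergence, in nats. Three equivalent
routes to J are implemented and cross-checked in the tests: direct
summation; the change in the population mean of the log-ratio character
Z_i = ln(q′_i/q_i); and, for replicator-type updates q′ = q·ω with
ω = w/w̄, the Price covariance cov_q(ω, ln ω). The fold depends only on the
pair (q, q′), so it is also defined for non-multiplicative maps (migration
is affine), where the log-ratio is read as a frequency reweighting rather
than a fitness multiplier.

Units are always nats. Reported values are exact up to floating point; the
algebraic identities (fold = Price covariance; T1+T2+T3+T4 = J_total;
partition components summing to the total) hold to 1e-10–1e-12 and are
asserted at those tolerances.

## Levels

**Lineage selection and transmission** (`replicator`). One generation is
selection, p′ = p·w/w̄, optionally followed by transmission through a
column-stochastic kernel T (p″ = T·p′). This order — selection first — is
the standard selection–mutation recursion; the fold definitions do not fix
it, so it is a package choice. Two folds per step: J_r = J(p′, p)
(selection) and J_rt = J(p″, p) (selection plus transmission). The residual
J_rt − J_r is reported without a sign claim: full mixing, for example,
restores the pre-selection state and makes the residual −J_r. Fitness
schedules may be constant, per-step, or frequency-dependent callables
evaluated at the pre-selection state. Monomorphic states without a kernel
are fixed points by definition; lost types are never resurrected implicitly.
Equilibria are states whose one-step fold falls below a tolerance (default
1e-9 nats).

**Mating** (`mating`). Pair-formation tables are reweighted by mating
propensities m, normalized by the mean propensity so both arguments of the
reproductive fold J_repr are probability distributions (the unnormalized
product q·m is not). J_repr splits additively into intra- and inter-lineage
term sums. Fecundity aggregation rules combine parental rates x, y:
G_L = x, G_R = y, G_mean = (x+y)/2, G_geom = √(xy), G_λ = λx + (1−λ)y
(the convex combination; λ = 1, 0, ½ recover G_L, G_R, G_mean), and
G_hybrid = I_xy(x+y)/2 with isolation factor I_xy ≥ 0 (0 = complete
isolation). The full mating partition J = J_S1 + J_S2 + J_PSI + E is the
holobiont partition with the axes read as the two sexes.

**Group selection** (`group_selection`). Frank-style tragedy of the
commons: within a group, type 1 (competitiveness x1) at frequency q updates
to q′ = q·x1/y with y = q·x1 + (1−q)·x2; the within-group fold J_q is the
binary Jeffreys divergence. Across an ensemble of groups with weights p_q,
the mean intra-group information J̄_x = Σ p_q J_q is computed before
between-group selection. Between groups, fitness k − y·s (s = intensity,
k > max(y)·s a positivity offset) reweights p_q, normalized by its ensemble
mean so p′_q stays on the simplex — the normalizer is left implicit in the
model and fixed here by conservation of probability. J_G is invariant to
the rescaling (k, s) → (ck, cs). A full cycle runs the within-group update
(of q and hence y) first, then the between-group reweighting at the updated
competitiveness; groups persist across cycles (a single two-stage episode
repeated), with re-initialization left to the caller. The ensemble's grid
of initial q and its weights are user-supplied; the synthetic module offers
uniform and binomial-founder modes on an interior grid (boundaries excluded
because J_q is undefined at fixation). Equal competitiveness short-circuits
to q′ = q exactly, so neutral ensembles generate exactly zero information.

**Migration** (`migration`). Island–continent: q_I(t+1) = (1−m)·q_I + m·q_C.
Each allele approaches the continent frequency geometrically,
p(t) = P + (1−m)^t (p0 − P), the fold vanishes exactly at the fixed point,
and per-step folds decrease monotonically without selection. Composition
with selection defaults to selection-then-migration within a generation
(the standard island-model recursion) and is configurable.

**Holobiont** (`holobiont`). The joint table q over (host, K microbiome
components) updates by q′ = q·W/w̄. Fitness decomposes multiplicatively as
W = W_H · Π_k W_Mk · a. Because this factorization is not identifiable
from W alone, `decompose_fitness` fixes a gauge: a log-linear (ANOVA-style)
split of ln W into grand mean + mean-centred main effects + interaction
residual, with the grand mean folded into the host factor and
a = exp(residual); the round trip is exact. The partition measures J_total
on the flattened tables, J_H and J_Mk on axis marginals, and splits the
remainder against the independence reference r = outer product of the
*post*-selection marginals:

    T1 = Σ(r−q)ln(r/q)   T2 = Σ(r−q)ln(q′/r)
    T3 = Σ(q′−r)ln(r/q)  T4 = Σ(q′−r)ln(q′/r)

with T1+…+T4 = J_total exactly and T3 = 0 whenever the initial q is a
product of its own marginals. J_assoc := T4 ≥ 0 always. Two candidate
definitions of the interaction residual coexist: the algebraic term T2, and
the closure residual E := J_total − J_H − ΣJ_Mk − J_assoc. They agree on
the independence manifold (where T1 = J_H + ΣJ_Mk) and differ off it; the
package defines E as the residual — so the partition always sums to the
total — and reports T2 alongside as a diagnostic. I_assoc = J_assoc + E may
be slightly negative when marginal reorganization erodes specific pairing.
A direct gauge-dependent association measure Σ(q′−q)·ln a is also provided
for comparison; it is not asserted equal to I_assoc since it depends on the
chosen fitness gauge (the prime in some presentations of this quantity is
read here as the static association factor, with no within-step update
of a).

## Association permutation test

For integer count tables, the association statistic is the Jeffreys
divergence between the observed joint frequencies and the product of their
own marginals, computed after adding a 0.5 pseudocount per cell
(Haldane–Anscombe style) so zero cells stay finite. The null re-pairs host
labels against microbiome configurations uniformly at random, preserving
both marginal count vectors exactly and thereby isolating association from
marginal structure; the identical pseudocounted statistic is applied to
observed and null tables, so the adjustment does not bias the test.
p = (1 + #{null ≥ observed})/(n_perm + 1). Degenerate margins (a single
category on either axis) return p = 1 with a warning. Calibration checks
use 200 product-distributed tables of 500 individuals (empirical type-I
error at α = 0.05 within [0.02, 0.09]) and 100 strongly diagonal 2×2
tables of 400 individuals for power (p ≤ 0.01 in ≥ 95% of replicates),
with 199 permutations per table.

## Numerical conventions

- Natural logarithm everywhere; all information values in nats.
- Distributions validate on input (non-negative, unit mass within 1e-9,
  unique labels) and renormalize exactly; updates renormalize after each
  step, so trajectories stay on the simplex to 1e-12 over hundreds of
  generations.
- Zero frequencies are an error wherever a log-ratio is required, never
  silently patched; an explicit `smoothing=True` adds a 1e-9
  pseudo-probability floor and renormalizes. Identical distributions give a
  fold of exactly 0 even on the simplex boundary (degenerate fixed points).
- Jeffreys terms are evaluated as (max−min)·ln(max/min) per component, so
  each term is non-negative and J(p, q) == J(q, p) bit-for-bit.
- Synthetic randomness flows from one integer seed through numpy
  `SeedSequence` spawning onto per-purpose PCG64 substreams, so adding a
  generator call for one purpose never perturbs draws for another, and
  outputs are reproducible across platforms; generator metadata records the
  seed and algorithm.

## Synthetic data

The generators emulate the calculus's study conditions, not real data:
symmetric-Dirichlet simplex draws (concentration 1 by default; → uniform as
concentration grows), log-normal fitness effects centred on 1 with separate
spreads for host (0.2), microbiome components (0.2) and association (0.2) —
σ_A = 0 yields a ≡ 1 exactly — and multinomial count sampling. Real
microbiome data differ in ways these generators do not model: compositional
sparsity, many rare taxa, overdispersion beyond multinomial sampling, and
temporal autocorrelation. Passing tests therefore demonstrate the
correctness and internal consistency of the calculus and its estimators
under multinomial sampling, not robustness to those real-data features.

Consistency checks sample the worked example's post-state at
n = 10², 10³, 10⁴, 10⁵ with 100 replicates per size; component-wise median
absolute errors decrease in n and fall below 0.01 at n = 10⁵. These sizes
keep the whole default suite fast while spanning three decades of sampling
noise.

## Known limitations

- The J_rt − J_r transmission residual is reported without a canonical
  sign decomposition.
- E vs T2 off the independence manifold: both reported, residual E is the
  closing definition (see above).
- No continuous-time dynamics, no genetic drift (Wright–Fisher sampling)
  beyond multinomial count generation, no explicit Mendelian offspring
  formation, no multi-deme migration, and no real microbiome (ASV)
  processing pipeline.
- The permutation test conditions on total sample size and both margins;
  it tests association only, not marginal selection.
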