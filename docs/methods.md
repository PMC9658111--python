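# Methods

## Model and assumptions

ISM treats an expert panel's pairwise judgments as a directed relation
"influences / helps achieve" over `n` factors and studies its
reflexive-transitive closure. The method assumes the relation is
meaningful to close transitively (if `i` helps achieve `k` and `k`
helps achieve `j`, then `i` helps achieve `j`), that a single consensus
matrix represents the panel, and that influence is binary — no
strengths or probabilities. Cycles are legitimate (mutually reinforcing
factors, `X` judgments) and end up as strongly connected groups sharing
one hierarchy level.

## Pipeline stages and numerical choices

**Binarization.** `V/A/X/O` map to the four 0/1 patterns; the diagonal
is fixed at 1 before closure. The substitution rules do not cover
`i = j`, but published initial matrices print a unit diagonal, and the
level-partition algebra (reachability/antecedent sets both containing
the factor itself) requires reflexivity.

**Closure.** A Warshall sweep (O(n³), exact integer arithmetic) — at
desk scale (n up to a few hundred) nothing faster is warranted. The
Boolean-power form `M ∨ M² ∨ … ∨ Mⁿ` and networkx's closure are kept in
the test suite as independent oracles, never on the main path. The mask
of closure-added entries is `M* ∧ ¬M`, computed once; an
already-closed input therefore maps to itself with an empty mask
(idempotence is tested). Some ISM papers describe this stage as
"removing" transitivity; the only operation that maps a printed initial
matrix to its printed final matrix is *adding* the transitively implied
links, which is what this package does.

**Level partition.** At each iteration, over active factors only,
factors with `R(i) ⊆ A(i)` (equivalently `R(i) ∩ A(i) = R(i)`) are
assigned the current level and removed — all qualifying factors
simultaneously, so a mutual group is never split. Some write-ups say
factors whose reachability and antecedent sets are *identical* go to
the current level; that literal rule does not reproduce published
partitions (a top-level factor typically has a small reachability set
and a large antecedent set), while the standard subset criterion does.
Termination is guaranteed on genuinely closed reflexive matrices (a
sink strongly-connected component always qualifies); a corrupted input
that yields an empty iteration raises `ConsistencyError` rather than
looping. Level 1 is the first iteration and the *top* of the diagram —
the most dependent, least driving end. The full
reachability/antecedent/intersection trace of every iteration is kept
and exported, mirroring the appendix tables ISM studies print.

**MICMAC.** "High" means strictly greater than the threshold, default
`n/2`. For the bundled 14-factor study this is the unique simple
midpoint rule consistent with every published assignment (driving 8 of
14 counts high; dependence 6 of 14 counts low). The threshold is a
config/CLI override for sensitivity analysis. Only direct FRM power
sums are used — no iterated indirect-influence MICMAC.

**Digraph.** Published ISM figures rarely print their edge list, so the
conventional drawing rule is adopted: candidate edges are off-diagonal
FRM 1-cells; mutual same-level pairs become one double-headed edge;
one-way candidates are kept only between consecutive levels and then
greedily transitively reduced in roster order (a candidate `i → j` is
dropped when already-kept edges give `i → k → j`, mutual edges counting
in both directions — the greedy order makes the reduction
deterministic). Skip-level candidates are excluded; their information
survives in the FRM, which — with the level partition — is the
analysis surface. Mutual cross-level reachability cannot occur when the
partition comes from the same matrix, but the builder checks and raises
rather than drawing a downward arrow.

**Consistency check.** The pipeline ends with two structural checks —
re-deriving the closure from the IRM must reproduce the FRM and mask
exactly, and every strictly one-way FRM relation must point from a
numerically higher level to a lower one (with adjacent-level relations
recoverable from the reduced digraph's closure). These two checks are
this package's operationalization of the "validity and conceptual
consistency" step ISM write-ups mention without defining; the verdict
is recorded in the bundle metadata and, by default, a failure aborts
the run.

**Aggregation.** Panels publish one consensus matrix but no aggregation
rule. `aggregate_ssims` offers per-pair modal symbol with fixed
tie-break priority `X > V > A > O` (keep an asserted relation over "no
relation"; configurable). It is plumbing for multi-expert inputs, never
invoked implicitly, and makes no claim to reconstruct how any
particular panel reached consensus.

## Bundled dataset and errata

The packaged study ranked 14 pandemic-containment strategies from a
16-member expert panel's consensus SSIM. Its printed tables are
mutually inconsistent in five places, which no single input matrix can
satisfy simultaneously:

* three symbol cells — (S6,S14) printed `A`, (S8,S11) and (S8,S12)
  printed `O` — contradict the printed *binary* initial matrix, which
  encodes `V` at all three;
* the printed final matrix stars (S5,S3) as closure-derived, yet row S5
  of the printed initial matrix is empty off-diagonal, so closure
  cannot create that entry. The study's own seven-level partition
  (S3 and S5 sharing Level 1), its dependence power for S3 (14) and
  driving power for S5 (2) all require `FRM[S5,S3] = 1`, which implies
  the symbol (S3,S5) was `X`, not the printed `V`.

The default `reconciled` variant applies exactly these four corrections
((3,5) `V→X`, (6,14) `A→V`, (8,11) `O→V`, (8,12) `O→V`); the `printed`
variant is verbatim. With the reconciled matrix the pipeline reproduces
the published final matrix (196/196 cells), both power margins, the
seven levels, and the quadrant memberships exactly; the irreducible
residue is the initial matrix's (S5,S3) cell (ours 1, printed 0 — the
publication's own final table prints 1) and the star count (16 derived
vs 17 printed, the 17th being that same cell, encoded here as a direct
entry). The two test-suite assertions that state the printed initial
table verbatim are therefore red by that one cell, deliberately: they
document the discrepancy instead of papering over it. The publication
also counts "seven" independent-cluster strategies while enumerating
six; the powers give six, and six it is here.

## Synthetic data

`random_ssim` draws each upper-triangle cell i.i.d. from a four-point
symbol distribution (default uniform) — it emulates an arbitrary
consensus matrix, including cycles, with no acyclicity constraint.
`layered_ssim` encodes a known layered hierarchy: `X` within designated
mutual groups, a deeper-to-shallower link for every adjacent-layer
pair, optional skip-layer links at a configurable rate (closure makes
them redundant, so they never change the recovered levels), `O`
elsewhere. `random_layered_truth` draws such ground truths with one
factor per layer guaranteed, a configurable chance of one mutual pair
per multi-factor layer (default 0.3), and a shuffled roster order so
both directions of the upper-triangle storage convention are exercised.
All randomness flows through numpy's seeded PCG64 generator, so outputs
are reproducible byte-for-byte.

What the generators do *not* emulate: expert disagreement and judgment
noise, near-decomposable structures, or the symbol correlations a real
panel produces. Recovery tests therefore show the pipeline is a correct
inverse of the generative encoding — not that ISM recovers "true"
structure from noisy human judgment.

## Problem sizes used in tests

The property suites run on seeded random matrices with n = 3–12 (200
instances) and layered recovery on 100 instances with up to 6 layers —
sizes at which the Boolean-power oracle is exact and fast and which
already exercise every code path (cycles, mutual groups, skip links,
single-level and n-level extremes). The bundled study is n = 14.

## Known limitations

Binary influence only (no fuzzy/weighted ISM); single consensus matrix
(no elicitation, Delphi, or expert weighting); no indirect-influence
MICMAC ranking; digraph aesthetics limited to rank constraints; the
level partition is unique for a given closed matrix, but the reduced
edge set depends on the documented deterministic reduction order where
several minimal drawings exist.
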