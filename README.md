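# ismkit

Interpretive structural modeling (ISM) with MICMAC analysis, as a tested
Python library and command-line tool.

ISM is a multi-criteria decision-analysis technique that turns a panel's
pairwise judgments about a set of factors into a layered influence
hierarchy. It is aimed at analysts — in policy, operations, management
research — who have an expert-judgment matrix and want the standard ISM
outputs: reachability matrices, hierarchy levels, driving/dependence
powers, quadrant classification, and the leveled digraph.

## The method

The input is a *structural self-interaction matrix* (SSIM): for each
unordered pair of factors `(i, j)` with `i < j`, one symbol —

| symbol | meaning |
|--------|-------------------------------|
| `V`    | `i` influences `j`            |
| `A`    | `j` influences `i`            |
| `X`    | mutual influence              |
| `O`    | no relation                   |

The pipeline then computes:

1. **Initial reachability matrix (IRM)** — the binary form of the SSIM
   (`V → m[i,j]=1`, `A → m[j,i]=1`, `X → both`, `O → neither`), with a
   unit diagonal.
2. **Final reachability matrix (FRM)** — the reflexive-transitive
   closure `M* = M ∨ M² ∨ … ∨ Mⁿ`, computed with a Warshall sweep;
   entries created by closure are tracked in a mask (the entries ISM
   papers print with a star).
3. **Power profile** — driving power `drv(i) = Σⱼ M*[i,j]` (row sum) and
   dependence power `dep(j) = Σᵢ M*[i,j]` (column sum).
4. **Level partition** — iterative peeling: over the still-active
   factors, with reachability set `R(i)`, antecedent set `A(i)` and
   intersection `R(i) ∩ A(i)`, every factor with `R(i) ⊆ A(i)` receives
   the current level and is removed. Level 1 is the top of the diagram
   (most dependent); the last level is the bottom (most driving).
5. **MICMAC classification** — quadrants around the `n/2` midpoint:
   autonomous (low/low), dependent (low driving, high dependence),
   linkage (high/high), independent (high driving, low dependence).
6. **Hierarchy digraph** — adjacent-level edges from the FRM, mutual
   pairs joined on their shared level, transitively reduced for display,
   exported as DOT/CSV/JSON.

A seeded synthetic-data module generates both unconstrained random SSIMs
and SSIMs encoding a known layered ground truth, so every stage is
testable end to end without external data.

## Bundled dataset

The package ships the consensus SSIM of a published ISM–MICMAC study
that ranked 14 strategies (S1–S14: smart lockdown, travel limitations,
online purchase promotion, social distancing, online education, …,
strong leadership, social-media awareness) for containing the
socio-economic and health fallout of the COVID-19 pandemic in a
developing-country setting. `ismkit.pandemic_ssim()` returns it; see
`docs/methods.md` for the four documented errata cells that distinguish
the default `reconciled` variant from the `printed` one.

## Worked example

```python
import ismkit

bundle = ismkit.run_pipeline(ismkit.pandemic_ssim())
for k, lvl in enumerate(bundle.partition.levels, start=1):
    print(f"Level {k}: {', '.join(lvl)}")
print("driving  :", bundle.powers.driving)
print("dependence:", bundle.powers.dependence)
for q in ("independent", "linkage", "dependent", "autonomous"):
    print(f"{q:12s}", ", ".join(bundle.micmac.members(q)) or "(none)")
```

prints

```
Level 1: S3, S5
Level 2: S4, S13, S14
Level 3: S6, S11, S12
Level 4: S7
Level 5: S8
Level 6: S1, S2
Level 7: S9, S10
driving  : (12, 12, 2, 5, 2, 8, 9, 10, 14, 14, 8, 8, 5, 5)
dependence: (4, 4, 14, 12, 14, 9, 6, 5, 2, 2, 9, 9, 12, 12)
independent  S1, S2, S7, S8, S9, S10
linkage      S6, S11, S12
dependent    S3, S4, S5, S13, S14
autonomous   (none)
```

Read bottom-up: strong leadership and government control (S9) and
social-media awareness (S10) sit at Level 7 with maximal driving power
(14) — they influence every other strategy and are the root levers.
Online purchase promotion (S3) and online education (S5) sit at Level 1
with maximal dependence (14): outcomes of the rest of the system, not
levers. The independent quadrant holds the six high-driving strategies,
the dependent quadrant the five outcome-like ones, and no strategy is
autonomous (disconnected).

The same run from a shell:

```sh
ism reproduce-paper --out out/          # bundled dataset
ism run --ssim my_matrix.csv --out out/ # your own matrix
ism synth layered --n 10 --layers 4 --seed 1 --out demo.csv
ism validate --ssim demo.csv
```

`ism run` writes the full result bundle (IRM/FRM with transitivity mask,
powers, levels, iteration trace, MICMAC table, DOT digraph, JSON report,
SHA-256 manifest); re-running on the same input is byte-identical.

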