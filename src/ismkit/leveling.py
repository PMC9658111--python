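"""Iterative level partition of a final reachability matrix.

The hierarchy levels of an ISM model are peeled off the closed matrix one
iteration at a time. Over the factors still unassigned, each factor ``i``
gets

* a reachability set ``R(i)`` — active factors it reaches,
* an antecedent set ``A(i)`` — active factors that reach it,
* the intersection ``I(i) = R(i) & A(i)``.

Every factor with ``I(i) = R(i)`` (equivalently ``R(i) ⊆ A(i)``: it
reaches nothing that does not reach it back) is assigned the current
level and removed; the process repeats until no factor remains. Level 1
is the first iteration and sits at the *top* of the ISM diagram — the
most dependent, least driving end of the hierarchy. Mutually reachable
factors always land on the same level, and a strictly one-way relation
always points from a numerically higher level to a lower one.

On a genuinely closed reflexive matrix every iteration assigns at least
one factor (a sink strongly-connected component always qualifies), so the
procedure terminates in at most ``n`` iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConsistencyError, ContractError
from .reachability import ReachabilityMatrix
from .ssim import FactorSet


@dataclass(frozen=True)
class IterationRecord:
    """One factor's sets at one iteration of the partition."""

    iteration: int
    factor_id: str
    reachability: tuple[str, ...]
    antecedent: tuple[str, ...]
    intersection: tuple[str, ...]
    assigned: bool


@dataclass(frozen=True)
class LevelPartition:
    """Result of the level partition: ``levels[0]`` is Level 1 (top of the
    diagram), plus the full per-iteration trace."""

    factor_set: FactorSet
    levels: tuple[tuple[str, ...], ...]
    iterations: tuple[IterationRecord, ...]

    def __post_init__(self) -> None:
        flat = [f for lvl in self.levels for f in lvl]
        if sorted(flat) != sorted(self.factor_set.ids) or len(flat) != len(set(flat)):
            raise ContractError("levels must partition the factor set")
        if any(len(lvl) == 0 for lvl in self.levels):
            raise ContractError("levels must be non-empty")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_of(self, factor_id: str) -> int:
        """1-based level of a factor (1 = top of the diagram)."""
        for k, lvl in enumerate(self.levels, start=1):
            if factor_id in lvl:
                return k
        raise KeyError(factor_id)

    def to_frame(self) -> pd.DataFrame:
        labels = {f.id: f.label for f in self.factor_set.factors}
        rows = [
            {"factor": fid, "label": labels[fid], "level": self.level_of(fid)}
            for fid in self.factor_set.ids
        ]
        return pd.DataFrame(rows)

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False, lineterminator="\n")

    def trace_frame(self) -> pd.DataFrame:
        """The iteration trace in the tabular layout ISM studies print:
        one row per (iteration, factor) with comma-joined sets and the
        level assigned (blank until assignment)."""
        rows = []
        for rec in self.iterations:
            rows.append(
                {
                    "iteration": rec.iteration,
                    "factor": rec.factor_id,
                    "reachability_set": ",".join(rec.reachability),
                    "antecedent_set": ",".join(rec.antecedent),
                    "intersection_set": ",".join(rec.intersection),
                    "level": rec.iteration if rec.assigned else "",
                }
            )
        return pd.DataFrame(rows)

    def trace_to_csv(self) -> str:
        return self.trace_frame().to_csv(index=False, lineterminator="\n")


def partition_levels(r: ReachabilityMatrix) -> LevelPartition:
    """Partition the factors of a final reachability matrix into levels.

    Deterministic: factors are scanned in roster order and all factors
    qualifying in an iteration are assigned simultaneously (so a mutual
    group is never split).
    """
    if r.stage != "final":
        raise ContractError("partition_levels expects a stage='final' matrix")
    ids = r.factor_set.ids
    cells = r.cells
    active = list(range(r.n))
    levels: list[tuple[str, ...]] = []
    records: list[IterationRecord] = []
    iteration = 0
    while active:
        iteration += 1
        reach = {i: [j for j in active if cells[i, j]] for i in active}
        antec = {i: [j for j in active if cells[j, i]] for i in active}
        assigned: list[int] = []
        for i in active:
            inter = [j for j in reach[i] if j in set(antec[i])]
            hit = inter == reach[i]
            records.append(
                IterationRecord(
                    iteration=iteration,
                    factor_id=ids[i],
                    reachability=tuple(ids[j] for j in reach[i]),
                    antecedent=tuple(ids[j] for j in antec[i]),
                    intersection=tuple(ids[j] for j in inter),
                    assigned=hit,
                )
            )
            if hit:
                assigned.append(i)
        if not assigned:
            raise ConsistencyError(
                f"iteration {iteration} assigned no factor; the input matrix "
                "is not a genuine reflexive-transitive closure"
            )
        levels.append(tuple(ids[i] for i in assigned))
        active = [i for i in active if i not in set(assigned)]
    return LevelPartition(
        factor_set=r.factor_set, levels=tuple(levels), iterations=tuple(records)
    )
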