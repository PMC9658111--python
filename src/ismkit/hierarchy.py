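"""Leveled ISM digraph: construction, transitive reduction, export.

The final diagram of an ISM study places every factor on its level
(level 1 drawn topmost) and draws arrows pointing *up* the hierarchy:
from a factor on level ``L+1`` to a factor on level ``L``. Edges come
from the final reachability matrix:

* a mutually reachable pair on the same level becomes one ``mutual``
  edge (drawn double-headed);
* a strictly one-way 1-cell becomes a ``one_way`` candidate edge, kept
  only between consecutive levels and then transitively reduced — a
  candidate ``i -> j`` is dropped when some already-kept ``k`` gives
  ``i -> k -> j`` (mutual edges count in both directions).

The matrix and the level partition — not the drawing — carry the
analysis; the digraph is the conventional presentation of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import ConsistencyError, ContractError
from .leveling import LevelPartition
from .reachability import ReachabilityMatrix
from .ssim import FactorSet

EdgeKind = str  # "one_way" | "mutual"


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    kind: EdgeKind


@dataclass(frozen=True)
class HierarchyDigraph:
    """Factor nodes annotated with levels plus the reduced edge set.

    ``mutual`` edges are stored once, oriented by roster order (source
    precedes target); they connect same-level nodes only. Every
    ``one_way`` edge points from level ``L+1`` to level ``L``.
    """

    factor_set: FactorSet
    levels: tuple[tuple[str, ...], ...]
    edges: tuple[Edge, ...]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_of(self, factor_id: str) -> int:
        for k, lvl in enumerate(self.levels, start=1):
            if factor_id in lvl:
                return k
        raise KeyError(factor_id)

    def to_networkx(self) -> nx.DiGraph:
        """The digraph as a :class:`networkx.DiGraph`; mutual edges are
        expanded into both directions, ``kind`` kept as an edge attribute
        and ``level`` as a node attribute."""
        g = nx.DiGraph()
        for fid in self.factor_set.ids:
            g.add_node(fid, level=self.level_of(fid))
        for e in self.edges:
            g.add_edge(e.source, e.target, kind=e.kind)
            if e.kind == "mutual":
                g.add_edge(e.target, e.source, kind="mutual")
        return g

    def edges_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"source": e.source, "target": e.target, "kind": e.kind}
             for e in self.edges],
            columns=["source", "target", "kind"],
        )

    def edges_to_csv(self) -> str:
        return self.edges_to_frame().to_csv(index=False, lineterminator="\n")

    def to_json_obj(self) -> dict:
        return {
            "nodes": [
                {"id": f.id, "label": f.label, "level": self.level_of(f.id)}
                for f in self.factor_set.factors
            ],
            "edges": [
                {"source": e.source, "target": e.target, "kind": e.kind}
                for e in self.edges
            ],
        }


def build_digraph(r: ReachabilityMatrix, p: LevelPartition) -> HierarchyDigraph:
    """Build the reduced, leveled ISM digraph from a final reachability
    matrix and its level partition.

    Deterministic: candidate edges are scanned in roster order, and the
    greedy reduction drops a candidate only when it is implied by edges
    kept earlier, so re-running yields identical output.
    """
    if r.stage != "final":
        raise ContractError("build_digraph expects a stage='final' matrix")
    if r.factor_set.ids != p.factor_set.ids:
        raise ContractError("matrix and partition describe different factor sets")
    ids = r.factor_set.ids
    idx = {f: i for i, f in enumerate(ids)}
    cells = r.cells
    level = {f: p.level_of(f) for f in ids}

    mutual: list[Edge] = []
    candidates: list[Edge] = []
    for i, fi in enumerate(ids):
        for j, fj in enumerate(ids):
            if i == j or not cells[i, j]:
                continue
            if cells[j, i]:
                if i < j:  # store each mutual pair once
                    if level[fi] != level[fj]:
                        raise ConsistencyError(
                            f"mutually reachable pair ({fi}, {fj}) spans levels "
                            f"{level[fi]} and {level[fj]}; partition does not "
                            "match the matrix"
                        )
                    mutual.append(Edge(fi, fj, "mutual"))
            elif level[fi] == level[fj] + 1:
                candidates.append(Edge(fi, fj, "one_way"))
            elif level[fi] <= level[fj]:
                raise ConsistencyError(
                    f"one-way relation {fi} -> {fj} does not point up the "
                    f"hierarchy (levels {level[fi]} -> {level[fj]})"
                )
            # else: skip-level candidate, excluded by the drawing rule

    # adjacency of kept edges; mutual edges participate in both directions
    kept = nx.DiGraph()
    kept.add_nodes_from(ids)
    for e in mutual:
        kept.add_edge(e.source, e.target)
        kept.add_edge(e.target, e.source)
    kept_one_way: list[Edge] = []
    for e in sorted(candidates, key=lambda e: (idx[e.source], idx[e.target])):
        implied = any(
            kept.has_edge(e.source, k) and kept.has_edge(k, e.target)
            for k in ids
        )
        if not implied:
            kept.add_edge(e.source, e.target)
            kept_one_way.append(e)

    edges = tuple(
        sorted(
            mutual + kept_one_way,
            key=lambda e: (idx[e.source], idx[e.target], e.kind),
        )
    )
    return HierarchyDigraph(factor_set=r.factor_set, levels=p.levels, edges=edges)


def to_dot(g: HierarchyDigraph) -> str:
    """Render the digraph as DOT text, one rank per level (level 1 on
    top), mutual edges double-headed. Byte-deterministic."""
    lines = [
        "digraph ism {",
        "  rankdir=TB;",
        '  node [shape=box, fontsize=10];',
    ]
    for k, lvl in enumerate(g.levels, start=1):
        members = "; ".join(f'"{f}"' for f in lvl)
        lines.append(f"  {{ rank=same; /* level {k} */ {members}; }}")
    # invisible spine pins level 1 at the top of the drawing
    spine = [lvl[0] for lvl in g.levels]
    for a, b in zip(spine, spine[1:]):
        lines.append(f'  "{a}" -> "{b}" [style=invis];')
    for e in g.edges:
        if e.kind == "mutual":
            lines.append(f'  "{e.source}" -> "{e.target}" [dir=both];')
        else:
            lines.append(f'  "{e.source}" -> "{e.target}" [constraint=false];')
    lines.append("}")
    return "\n".join(lines) + "\n"
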