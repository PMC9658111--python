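"""End-to-end orchestration: SSIM in, full ISM-MICMAC result bundle out.

``run_pipeline`` chains the stages — binarization, transitive closure,
power profile, level partition, MICMAC classification, digraph
construction — and then runs two structural consistency checks (the
package's operationalization of "validity and conceptual consistency"):

1. *closure consistency* — recomputing the closure of the IRM reproduces
   the FRM and its transitive mask exactly;
2. *orientation consistency* — every strictly one-way FRM relation
   points from a numerically higher level to a lower one, mutual pairs
   are co-leveled, and every adjacent-level FRM relation is recoverable
   from the reduced digraph's closure.

No stage after parsing consumes randomness, so a bundle re-written from
the same input is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from . import __version__
from .errors import ConsistencyError
from .hierarchy import HierarchyDigraph, build_digraph, to_dot
from .leveling import LevelPartition, partition_levels
from .micmac import MicmacClassification, classify
from .reachability import (
    PowerProfile,
    ReachabilityMatrix,
    initial_reachability,
    power_profile,
    transitive_closure,
)
from .ssim import SSIMatrix, write_ssim


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of a pipeline run. ``micmac_threshold`` overrides the
    default n/2 quadrant midpoint."""

    micmac_threshold: float | None = None

    def to_obj(self) -> dict:
        return {"micmac_threshold": self.micmac_threshold}


@dataclass(frozen=True)
class ConsistencyReport:
    """Verdicts of the structural consistency checks."""

    closure_consistent: bool
    orientation_consistent: bool
    digraph_covers_adjacent_relations: bool

    @property
    def ok(self) -> bool:
        return (
            self.closure_consistent
            and self.orientation_consistent
            and self.digraph_covers_adjacent_relations
        )

    def to_obj(self) -> dict:
        return {
            "closure_consistent": self.closure_consistent,
            "orientation_consistent": self.orientation_consistent,
            "digraph_covers_adjacent_relations": self.digraph_covers_adjacent_relations,
            "ok": self.ok,
        }


@dataclass(frozen=True)
class ResultBundle:
    """Everything one ISM-MICMAC run produces, over a single factor set."""

    ssim: SSIMatrix
    irm: ReachabilityMatrix
    frm: ReachabilityMatrix
    powers: PowerProfile
    partition: LevelPartition
    micmac: MicmacClassification
    digraph: HierarchyDigraph
    consistency: ConsistencyReport
    config: PipelineConfig
    metadata: dict


def check_consistency(
    ssim: SSIMatrix,
    irm: ReachabilityMatrix,
    frm: ReachabilityMatrix,
    partition: LevelPartition,
    digraph: HierarchyDigraph,
) -> ConsistencyReport:
    """Run the structural consistency checks on a completed run."""
    reclosed = transitive_closure(irm)
    closure_ok = bool(
        np.array_equal(reclosed.cells, frm.cells)
        and np.array_equal(reclosed.transitive_mask, frm.transitive_mask)
    )

    ids = frm.factor_set.ids
    level = {f: partition.level_of(f) for f in ids}
    orientation_ok = True
    for i, fi in enumerate(ids):
        for j, fj in enumerate(ids):
            if i == j or not frm.cells[i, j]:
                continue
            if frm.cells[j, i]:
                if level[fi] != level[fj]:
                    orientation_ok = False
            elif level[fi] <= level[fj]:
                orientation_ok = False

    g = digraph.to_networkx()
    cover_ok = True
    for i, fi in enumerate(ids):
        for j, fj in enumerate(ids):
            if i == j or not frm.cells[i, j]:
                continue
            if level[fi] == level[fj] + 1 and not nx.has_path(g, fi, fj):
                cover_ok = False
    return ConsistencyReport(
        closure_consistent=closure_ok,
        orientation_consistent=orientation_ok,
        digraph_covers_adjacent_relations=cover_ok,
    )


def run_pipeline(
    ssim: SSIMatrix, config: PipelineConfig | None = None,
    strict: bool = True,
) -> ResultBundle:
    """Execute the full ISM-MICMAC pipeline on a validated SSIM.

    With ``strict=True`` (default) a failed consistency check raises
    :class:`ConsistencyError`; otherwise the verdict is only recorded in
    the bundle metadata.
    """
    config = config or PipelineConfig()
    irm = initial_reachability(ssim)
    frm = transitive_closure(irm)
    powers = power_profile(frm)
    partition = partition_levels(frm)
    micmac = classify(powers, threshold=config.micmac_threshold)
    digraph = build_digraph(frm, partition)
    consistency = check_consistency(ssim, irm, frm, partition, digraph)
    if strict and not consistency.ok:
        raise ConsistencyError(
            f"consistency check failed: {consistency.to_obj()}"
        )
    ssim_csv = write_ssim(ssim)
    metadata = {
        "ismkit_version": __version__,
        "n_factors": ssim.n,
        "config": config.to_obj(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_obj(), sort_keys=True).encode()
        ).hexdigest(),
        "ssim_sha256": hashlib.sha256(ssim_csv.encode()).hexdigest(),
        "consistency": consistency.to_obj(),
    }
    return ResultBundle(
        ssim=ssim,
        irm=irm,
        frm=frm,
        powers=powers,
        partition=partition,
        micmac=micmac,
        digraph=digraph,
        consistency=consistency,
        config=config,
        metadata=metadata,
    )


def _report_obj(b: ResultBundle) -> dict:
    return {
        "metadata": b.metadata,
        "n_factors": b.ssim.n,
        "n_levels": b.partition.n_levels,
        "levels": [list(lvl) for lvl in b.partition.levels],
        "driving_power": {f: d for f, d in zip(b.powers.factor_set.ids, b.powers.driving)},
        "dependence_power": {
            f: d for f, d in zip(b.powers.factor_set.ids, b.powers.dependence)
        },
        "micmac_threshold": b.micmac.threshold,
        "micmac": {q: list(b.micmac.members(q)) for q in
                   ("autonomous", "dependent", "linkage", "independent")},
        "n_transitive_entries": int(np.asarray(b.frm.transitive_mask).sum()),
        "consistency": b.consistency.to_obj(),
    }


def write_bundle(b: ResultBundle, out_dir) -> dict[str, str]:
    """Write the bundle's ten artifact files plus a manifest.

    Returns the manifest: file name -> SHA-256 of its content. Identical
    bundles produce identical bytes, hence identical manifests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "irm.csv": b.irm.to_csv(),
        "frm.csv": b.frm.to_csv(),
        "frm_transitive.csv": b.frm.mask_to_csv(),
        "powers.csv": b.powers.to_csv(),
        "levels.csv": b.partition.to_csv(),
        "iterations.csv": b.partition.trace_to_csv(),
        "micmac.csv": b.micmac.to_csv(),
        "model.dot": to_dot(b.digraph),
        "graph.json": json.dumps(b.digraph.to_json_obj(), indent=2, sort_keys=True)
        + "\n",
    }
    files["report.json"] = json.dumps(_report_obj(b), indent=2, sort_keys=True) + "\n"
    manifest: dict[str, str] = {}
    for name, content in sorted(files.items()):
        (out / name).write_text(content, encoding="utf-8")
        manifest[name] = hashlib.sha256(content.encode()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
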