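"""Binary reachability matrices: SSIM substitution, transitive closure,
and driving/dependence power profiles.

The symbolic SSIM is first binarized into the *initial reachability
matrix* (IRM) by the standard substitution rules — for each judged pair
``(i, j)`` with ``i < j``::

    V  ->  cell(i, j) = 1, cell(j, i) = 0
    A  ->  cell(i, j) = 0, cell(j, i) = 1
    X  ->  both 1
    O  ->  both 0

with every diagonal cell fixed at 1 (each factor reaches itself). The
*final reachability matrix* (FRM) is the reflexive-transitive closure of
the IRM; entries turned on by closure ("transitive" entries, starred in
printed ISM tables) are tracked in a parallel mask. Row sums of the FRM
are a factor's *driving power* (how many factors it reaches, itself
included); column sums are its *dependence power*.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ContractError, SSIMParseError
from .ssim import FactorSet, SSIMatrix

Stage = Literal["initial", "final"]


@dataclass(frozen=True)
class ReachabilityMatrix:
    """An n x n binary reachability matrix over an ordered factor set.

    ``stage`` is ``"initial"`` (straight from the SSIM) or ``"final"``
    (transitively closed); for a final matrix ``transitive_mask`` flags
    exactly the cells that closure turned on.
    """

    factor_set: FactorSet
    cells: np.ndarray = field(hash=False)
    stage: Stage = "initial"
    transitive_mask: np.ndarray | None = field(default=None, hash=False)

    def __post_init__(self) -> None:
        n = self.factor_set.n
        cells = np.array(self.cells, dtype=np.int8, copy=True)
        if cells.shape != (n, n):
            raise ContractError(f"cells must be {n}x{n}, got {cells.shape}")
        if not np.isin(cells, (0, 1)).all():
            raise ContractError("cells must be binary")
        if not (np.diag(cells) == 1).all():
            raise ContractError("all diagonal cells must be 1")
        cells.flags.writeable = False
        object.__setattr__(self, "cells", cells)
        if self.stage == "final":
            mask = self.transitive_mask
            mask = np.zeros((n, n), np.int8) if mask is None else np.array(
                mask, dtype=np.int8, copy=True
            )
            if mask.shape != (n, n):
                raise ContractError("transitive_mask shape mismatch")
            if (mask & ~cells).any():
                raise ContractError("transitive_mask set outside 1-cells")
            sq = cells.astype(np.int64) @ cells.astype(np.int64)
            closed = (cells | (sq > 0)).astype(np.int8)
            if not np.array_equal(closed, cells):
                raise ContractError("stage='final' matrix is not transitively closed")
            mask.flags.writeable = False
            object.__setattr__(self, "transitive_mask", mask)
        elif self.transitive_mask is not None and np.asarray(self.transitive_mask).any():
            raise ContractError("initial matrix cannot carry transitive entries")

    @property
    def n(self) -> int:
        return self.factor_set.n

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.factor_set.ids)
        return pd.DataFrame(np.asarray(self.cells, dtype=int), index=ids, columns=ids)

    def to_csv(self) -> str:
        df = self.to_frame()
        df.index.name = "factor"
        return df.to_csv(lineterminator="\n")

    def mask_to_csv(self) -> str:
        if self.stage != "final":
            raise ContractError("transitive mask exists only on final matrices")
        ids = list(self.factor_set.ids)
        df = pd.DataFrame(np.asarray(self.transitive_mask, dtype=int),
                          index=ids, columns=ids)
        df.index.name = "factor"
        return df.to_csv(lineterminator="\n")


@dataclass(frozen=True)
class PowerProfile:
    """Per-factor driving (row-sum) and dependence (column-sum) powers of
    a final reachability matrix. Both sums count the factor itself, so
    every power lies in [1, n], and the two vectors have equal totals
    (each equals the number of 1-cells in the FRM)."""

    factor_set: FactorSet
    driving: tuple[int, ...]
    dependence: tuple[int, ...]

    def __post_init__(self) -> None:
        n = self.factor_set.n
        for name, vec in (("driving", self.driving), ("dependence", self.dependence)):
            if len(vec) != n:
                raise ContractError(f"{name} must have length {n}")
            if any(not 1 <= v <= n for v in vec):
                raise ContractError(f"{name} powers must lie in [1, {n}]")
        if sum(self.driving) != sum(self.dependence):
            raise ContractError("driving and dependence totals must agree")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"driving": list(self.driving), "dependence": list(self.dependence)},
            index=list(self.factor_set.ids),
        )

    def to_csv(self) -> str:
        df = self.to_frame()
        df.index.name = "factor"
        return df.to_csv(lineterminator="\n")


def initial_reachability(m: SSIMatrix) -> ReachabilityMatrix:
    """Binarize a SSIM into the initial reachability matrix (unit diagonal,
    V/A/X/O substitution on every judged pair)."""
    n = m.n
    cells = np.eye(n, dtype=np.int8)
    for (i, j), sym in m.judgments.items():
        if sym == "V":
            cells[i, j] = 1
        elif sym == "A":
            cells[j, i] = 1
        elif sym == "X":
            cells[i, j] = cells[j, i] = 1
        # O: both stay 0
    return ReachabilityMatrix(factor_set=m.factor_set, cells=cells, stage="initial")


def transitive_closure(r: ReachabilityMatrix) -> ReachabilityMatrix:
    """Reflexive-transitive closure of an initial reachability matrix.

    Uses the Warshall update (for each pivot k, any i that reaches k
    inherits everything k reaches); the input is left untouched and the
    returned matrix's ``transitive_mask`` marks exactly the entries the
    closure added.
    """
    if r.stage != "initial":
        raise ContractError("transitive_closure expects a stage='initial' matrix")
    closed = np.array(r.cells, dtype=np.int8)
    n = r.n
    for k in range(n):
        # rows that reach k pick up row k
        reach_k = closed[:, k] == 1
        closed[reach_k] |= closed[k]
    mask = (closed & ~np.asarray(r.cells)).astype(np.int8)
    return ReachabilityMatrix(
        factor_set=r.factor_set, cells=closed, stage="final", transitive_mask=mask
    )


def power_profile(r: ReachabilityMatrix) -> PowerProfile:
    """Driving (row-sum) and dependence (column-sum) powers of a FRM."""
    if r.stage != "final":
        raise ContractError("power profiles are defined on the final matrix only")
    cells = np.asarray(r.cells, dtype=int)
    return PowerProfile(
        factor_set=r.factor_set,
        driving=tuple(int(x) for x in cells.sum(axis=1)),
        dependence=tuple(int(x) for x in cells.sum(axis=0)),
    )


def read_reachability(text: str, stage: Stage = "initial",
                      mask_text: str | None = None) -> ReachabilityMatrix:
    """Parse a reachability matrix from the CSV written by ``to_csv``."""
    df = pd.read_csv(io.StringIO(text), index_col=0)
    ids = [str(c) for c in df.columns]
    if ids != [str(r) for r in df.index]:
        raise SSIMParseError("reachability CSV header/row ids disagree")
    mask = None
    if mask_text is not None:
        mask = pd.read_csv(io.StringIO(mask_text), index_col=0).to_numpy(dtype=np.int8)
    return ReachabilityMatrix(
        factor_set=FactorSet.from_ids(ids),
        cells=df.to_numpy(dtype=np.int8),
        stage=stage,
        transitive_mask=mask,
    )
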