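"""Structural self-interaction matrix (SSIM): types, validation and I/O.

An ISM study starts from an upper-triangular symbolic matrix of pairwise
expert judgments over ``n`` factors. For each ordered pair ``(i, j)`` with
``i < j`` (indices into the factor order) exactly one symbol records the
contextual relation:

====== =============================================
symbol meaning
====== =============================================
``V``  factor *i* influences (helps achieve) factor *j*
``A``  factor *j* influences factor *i*
``X``  *i* and *j* influence each other
``O``  *i* and *j* are unrelated
====== =============================================

The CSV dialect mirrors how such matrices are printed: a header row of
factor ids, one row per factor, symbols in the upper triangle, and ``-``
(or an empty cell) on the diagonal and lower triangle.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CompletenessError, RosterError, SSIMParseError

#: The four admissible judgment symbols, in canonical order.
SYMBOLS: tuple[str, ...] = ("V", "A", "X", "O")

#: Tie-break priority used by :func:`aggregate_ssims` (first wins).
DEFAULT_TIE_PRIORITY: tuple[str, ...] = ("X", "V", "A", "O")

#: Marker written on diagonal / lower-triangle cells.
IGNORE_MARKER = "-"


@dataclass(frozen=True)
class Factor:
    """One factor (strategy/variable) of the system under study."""

    id: str
    label: str = ""
    description: str = ""


@dataclass(frozen=True)
class FactorSet:
    """Ordered roster of factors; order is significant and preserved
    through every downstream stage (matrices, levels, digraph)."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        if len(self.factors) < 2:
            raise RosterError(f"need at least 2 factors, got {len(self.factors)}")
        ids = [f.id for f in self.factors]
        if any(not i for i in ids):
            raise RosterError("factor ids must be non-empty")
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise RosterError(f"duplicate factor id(s): {', '.join(sorted(dupes))}")

    @classmethod
    def from_ids(cls, ids: Sequence[str]) -> "FactorSet":
        return cls(tuple(Factor(id=i) for i in ids))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.factors)

    @property
    def n(self) -> int:
        return len(self.factors)

    def index(self, factor_id: str) -> int:
        return self.ids.index(factor_id)

    def __len__(self) -> int:
        return len(self.factors)


def _validate_judgments(
    n: int, judgments: Mapping[tuple[int, int], str]
) -> dict[tuple[int, int], str]:
    expected = {(i, j) for i in range(n) for j in range(i + 1, n)}
    clean: dict[tuple[int, int], str] = {}
    for (i, j), sym in judgments.items():
        if (i, j) not in expected:
            raise SSIMParseError(
                f"judgment at ({i}, {j}) is not an upper-triangle pair"
            )
        s = str(sym).strip().upper()
        if s not in SYMBOLS:
            raise SSIMParseError(
                f"unknown symbol {sym!r} for pair ({i}, {j}); expected one of "
                + "/".join(SYMBOLS)
            )
        clean[(i, j)] = s
    missing = expected - clean.keys()
    if missing:
        raise CompletenessError(
            f"missing {len(missing)} upper-triangle judgment(s), e.g. "
            f"{sorted(missing)[:3]}"
        )
    return clean


@dataclass(frozen=True)
class SSIMatrix:
    """A validated SSIM: a factor roster plus one symbol per pair i < j."""

    factor_set: FactorSet
    judgments: Mapping[tuple[int, int], str] = field(hash=False)

    def __post_init__(self) -> None:
        clean = _validate_judgments(self.factor_set.n, self.judgments)
        object.__setattr__(self, "judgments", clean)

    @property
    def n(self) -> int:
        return self.factor_set.n

    def symbol(self, id_i: str, id_j: str) -> str:
        """Judgment for the pair given by two factor *ids* (order-free:
        asking for (j, i) returns the mirrored symbol, V <-> A)."""
        i, j = self.factor_set.index(id_i), self.factor_set.index(id_j)
        if i == j:
            raise KeyError("no diagonal judgments in a SSIM")
        if i < j:
            return self.judgments[(i, j)]
        sym = self.judgments[(j, i)]
        return {"V": "A", "A": "V"}.get(sym, sym)

    def equals(self, other: "SSIMatrix") -> bool:
        """Structural equality: same factor ids in the same order, same
        judgments (labels/descriptions ignored)."""
        return (
            self.factor_set.ids == other.factor_set.ids
            and dict(self.judgments) == dict(other.judgments)
        )


def parse_ssim(text: str) -> SSIMatrix:
    """Parse SSIM CSV content into a validated :class:`SSIMatrix`.

    Factor order equals file order. Symbols are case-insensitive on input.
    Diagonal and lower-triangle cells must be empty or ``-``; anything in
    the upper triangle must be one of V/A/X/O.
    """
    try:
        df = pd.read_csv(io.StringIO(text), index_col=0, dtype=str,
                         keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise SSIMParseError(f"cannot read SSIM CSV: {exc}") from None
    header_ids = [str(c) for c in df.columns]
    row_ids = [str(r) for r in df.index]
    if header_ids != row_ids:
        raise RosterError(
            f"header ids {header_ids} do not match row ids {row_ids}"
        )
    factor_set = FactorSet.from_ids(row_ids)
    n = factor_set.n
    judgments: dict[tuple[int, int], str] = {}
    for i, rid in enumerate(row_ids):
        for j, cid in enumerate(header_ids):
            cell = str(df.iat[i, j]).strip()
            if i < j:
                if cell == "" or cell == IGNORE_MARKER:
                    raise CompletenessError(
                        f"missing judgment for pair ({rid}, {cid})"
                    )
                if cell.upper() not in SYMBOLS:
                    raise SSIMParseError(
                        f"unknown symbol {cell!r} at row {rid}, column {cid}"
                    )
                judgments[(i, j)] = cell.upper()
            elif cell not in ("", IGNORE_MARKER):
                raise SSIMParseError(
                    f"unexpected content {cell!r} at row {rid}, column {cid} "
                    "(diagonal/lower triangle must be empty or '-')"
                )
    return SSIMatrix(factor_set=factor_set, judgments=judgments)


def write_ssim(m: SSIMatrix) -> str:
    """Serialize a SSIM to the CSV dialect accepted by :func:`parse_ssim`.

    Output is byte-deterministic for a given matrix.
    """
    ids = m.factor_set.ids
    n = m.n
    grid = [[IGNORE_MARKER] * n for _ in range(n)]
    for (i, j), sym in m.judgments.items():
        grid[i][j] = sym
    df = pd.DataFrame(grid, index=list(ids), columns=list(ids))
    df.index.name = "factor"
    return df.to_csv(lineterminator="\n")


def read_ssim(path) -> SSIMatrix:
    """Read a SSIM from a CSV file on disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_ssim(fh.read())


def aggregate_ssims(
    matrices: Iterable[SSIMatrix],
    tie_priority: Sequence[str] = DEFAULT_TIE_PRIORITY,
) -> SSIMatrix:
    """Combine several experts' SSIMs over the same roster into one.

    The per-pair rule is the modal (most frequent) symbol; ties are broken
    by a fixed priority (default X > V > A > O, i.e. a tie between an
    asserted relation and "unrelated" keeps the relation). This is an
    optional pre-processing step and is never applied implicitly: the
    pipeline always consumes a single consensus matrix.
    """
    mats = list(matrices)
    if not mats:
        raise RosterError("nothing to aggregate")
    if sorted(tie_priority) != sorted(SYMBOLS):
        raise RosterError(f"tie_priority must permute {SYMBOLS}")
    base = mats[0].factor_set
    for m in mats[1:]:
        if m.factor_set.ids != base.ids:
            raise RosterError(
                f"mismatched factor sets: {base.ids} vs {m.factor_set.ids}"
            )
    rank = {s: k for k, s in enumerate(tie_priority)}
    judgments: dict[tuple[int, int], str] = {}
    for pair in mats[0].judgments:
        counts = Counter(m.judgments[pair] for m in mats)
        best = max(counts.items(), key=lambda kv: (kv[1], -rank[kv[0]]))
        judgments[pair] = best[0]
    return SSIMatrix(factor_set=base, judgments=judgments)
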