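"""Seeded synthetic SSIM generators.

Two generators make every pipeline stage testable without external data:

* :func:`random_ssim` draws each upper-triangle judgment independently
  from a four-point symbol distribution — unconstrained matrices,
  including cycles (``X`` pairs), which are legitimate ISM inputs.
* :func:`layered_ssim` encodes a *known* layered hierarchy (the kind of
  structure an ISM study recovers: ordered levels, optional mutually
  reinforcing pairs within a level) so that level-partition recovery can
  be checked against ground truth.

All randomness flows through :class:`numpy.random.Generator` seeded by
the caller (PCG64), so a given ``(arguments, seed)`` pair reproduces the
same matrix byte-for-byte on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .ssim import FactorSet, SSIMatrix

_TOL = 1e-9


@dataclass(frozen=True)
class SymbolDistribution:
    """Probabilities for drawing V, A, X, O (must sum to 1)."""

    v: float
    a: float
    x: float
    o: float

    def __post_init__(self) -> None:
        probs = (self.v, self.a, self.x, self.o)
        if any(p < 0 for p in probs):
            raise ContractError("symbol probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > _TOL:
            raise ContractError(f"symbol probabilities must sum to 1, got {sum(probs)}")

    @property
    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.v, self.a, self.x, self.o)

    @classmethod
    def uniform(cls) -> "SymbolDistribution":
        return cls(0.25, 0.25, 0.25, 0.25)


def random_ssim(n: int, dist: SymbolDistribution, seed: int) -> SSIMatrix:
    """Random SSIM: each of the n(n-1)/2 upper-triangle cells drawn
    independently from ``dist``; same (n, dist, seed) gives the identical
    matrix."""
    if n < 2:
        raise ContractError("need n >= 2 factors")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(dist.as_tuple)
    symbols = "VAXO"
    judgments: dict[tuple[int, int], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            u = rng.random()
            judgments[(i, j)] = symbols[int(np.searchsorted(cum, u, side="right"))]
    return SSIMatrix(
        factor_set=FactorSet.from_ids([f"F{k + 1}" for k in range(n)]),
        judgments=judgments,
    )


@dataclass(frozen=True)
class LayeredTruth:
    """Ground-truth hierarchy for recovery tests.

    ``layers[0]`` is layer 1, the *top* of the diagram (least driving);
    factors in deeper layers influence factors in shallower ones.
    ``mutual_groups`` lists sets of mutually reinforcing factors; each
    group must sit inside one layer. ``order`` is the roster (storage)
    order of the factors, defaulting to layer concatenation; shuffling it
    exercises both directions of the upper-triangle symbol convention.
    """

    layers: tuple[tuple[str, ...], ...]
    mutual_groups: tuple[tuple[str, ...], ...] = ()
    order: tuple[str, ...] = field(default=())
    seed: int = 0

    def __post_init__(self) -> None:
        flat = [f for layer in self.layers for f in layer]
        if not self.layers or any(not layer for layer in self.layers):
            raise ContractError("layers must be non-empty")
        if len(flat) != len(set(flat)):
            raise ContractError("each factor belongs to exactly one layer")
        layer_of = self.layer_assignment()
        seen: set[str] = set()
        for grp in self.mutual_groups:
            if len(grp) < 2:
                raise ContractError("mutual groups need at least 2 members")
            if len({layer_of[f] for f in grp}) != 1:
                raise ContractError(f"mutual group {grp} spans layers")
            if seen & set(grp):
                raise ContractError("mutual groups must be disjoint")
            seen |= set(grp)
        order = self.order or tuple(flat)
        if sorted(order) != sorted(flat):
            raise ContractError("order must permute the layered factors")
        object.__setattr__(self, "order", tuple(order))

    @property
    def n(self) -> int:
        return sum(len(layer) for layer in self.layers)

    def layer_assignment(self) -> dict[str, int]:
        """factor id -> 1-based layer number (1 = top)."""
        return {
            f: k for k, layer in enumerate(self.layers, start=1) for f in layer
        }

    def group_of(self) -> dict[str, int]:
        g = {}
        for k, grp in enumerate(self.mutual_groups):
            for f in grp:
                g[f] = k
        return g


def layered_ssim(truth: LayeredTruth, skip_rate: float = 0.0,
                 seed: int | None = None) -> SSIMatrix:
    """Encode a layered ground truth as a SSIM.

    Same mutual group -> ``X``; a pair spanning adjacent layers always
    gets the symbol making the deeper factor reach the shallower one;
    pairs spanning two or more layers get that symbol with probability
    ``skip_rate`` (such skip links are already implied by closure, so
    they never change the recovered levels); everything else is ``O``.
    """
    if not 0.0 <= skip_rate <= 1.0:
        raise ContractError("skip_rate must lie in [0, 1]")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    layer_of = truth.layer_assignment()
    group_of = truth.group_of()
    order = truth.order
    judgments: dict[tuple[int, int], str] = {}
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            fi, fj = order[i], order[j]
            li, lj = layer_of[fi], layer_of[fj]
            if group_of.get(fi, -1) == group_of.get(fj, -2):
                sym = "X"
            elif li == lj:
                sym = "O"
            else:
                # deeper (larger layer number) reaches shallower
                deeper_is_i = li > lj
                gap = abs(li - lj)
                present = gap == 1 or rng.random() < skip_rate
                if not present:
                    sym = "O"
                else:
                    sym = "V" if deeper_is_i else "A"
            judgments[(i, j)] = sym
    return SSIMatrix(
        factor_set=FactorSet.from_ids(list(order)), judgments=judgments
    )


def random_layered_truth(
    n: int,
    n_layers: int,
    seed: int,
    mutual_rate: float = 0.3,
    shuffle_order: bool = True,
) -> LayeredTruth:
    """Draw a random ground truth: ``n`` factors spread over ``n_layers``
    non-empty layers, with roughly ``mutual_rate`` of multi-factor layers
    containing one mutual pair, and (optionally) a shuffled roster order."""
    if not 2 <= n_layers <= n:
        raise ContractError("need 2 <= n_layers <= n")
    rng = np.random.default_rng(seed)
    ids = [f"F{k + 1}" for k in range(n)]
    # every layer gets one factor, the rest are spread at random
    sizes = np.ones(n_layers, dtype=int)
    for _ in range(n - n_layers):
        sizes[rng.integers(n_layers)] += 1
    layers: list[tuple[str, ...]] = []
    pos = 0
    for s in sizes:
        layers.append(tuple(ids[pos:pos + int(s)]))
        pos += int(s)
    groups: list[tuple[str, ...]] = []
    for layer in layers:
        if len(layer) >= 2 and rng.random() < mutual_rate:
            pick = rng.choice(len(layer), size=2, replace=False)
            groups.append(tuple(layer[int(k)] for k in sorted(pick)))
    order = list(ids)
    if shuffle_order:
        rng.shuffle(order)
    return LayeredTruth(
        layers=tuple(layers),
        mutual_groups=tuple(groups),
        order=tuple(order),
        seed=int(rng.integers(2**31)),
    )
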