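"""MICMAC classification: driving/dependence quadrants.

Cross-impact (MICMAC) analysis places each factor on a plane with
dependence power on the x-axis and driving power on the y-axis, split
into four quadrants around the midpoint ``n/2``:

* **autonomous** — low driving, low dependence: weakly connected to the
  system;
* **dependent** — low driving, high dependence: outcomes, top of the
  hierarchy;
* **linkage** — high driving, high dependence: unstable relays in the
  middle of the hierarchy;
* **independent** — high driving, low dependence: root causes, bottom of
  the hierarchy.

"High" means strictly greater than the threshold (default ``n/2``); this
is the unique simple midpoint rule consistent with the packaged study's
printed cluster memberships (a factor with dependence 6 of 14 is low, one
with driving 8 of 14 is high). The threshold is exposed for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ContractError
from .reachability import PowerProfile
from .ssim import FactorSet

QUADRANTS = ("autonomous", "dependent", "linkage", "independent")


@dataclass(frozen=True)
class MicmacClassification:
    """Per-factor quadrant assignment plus the threshold that produced it."""

    factor_set: FactorSet
    threshold: float
    driving: tuple[int, ...]
    dependence: tuple[int, ...]
    quadrants: tuple[str, ...]

    def members(self, quadrant: str) -> tuple[str, ...]:
        if quadrant not in QUADRANTS:
            raise KeyError(quadrant)
        return tuple(
            fid
            for fid, q in zip(self.factor_set.ids, self.quadrants)
            if q == quadrant
        )

    def counts(self) -> dict[str, int]:
        return {q: len(self.members(q)) for q in QUADRANTS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": list(self.factor_set.ids),
                "driving": list(self.driving),
                "dependence": list(self.dependence),
                "quadrant": list(self.quadrants),
            }
        )

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False, lineterminator="\n")


def _quadrant(driving: int, dependence: int, threshold: float) -> str:
    hi_drive = driving > threshold
    hi_dep = dependence > threshold
    if hi_drive and hi_dep:
        return "linkage"
    if hi_drive:
        return "independent"
    if hi_dep:
        return "dependent"
    return "autonomous"


def classify(p: PowerProfile, threshold: float | None = None) -> MicmacClassification:
    """Classify every factor of a power profile into its MICMAC quadrant.

    ``threshold`` defaults to ``n/2``; a power is "high" iff strictly
    greater than the threshold.
    """
    n = p.factor_set.n
    thr = n / 2 if threshold is None else float(threshold)
    for vec in (p.driving, p.dependence):
        if any(not 1 <= v <= n for v in vec):
            raise ContractError(f"powers must lie in [1, {n}]")
    quadrants = tuple(
        _quadrant(d, e, thr) for d, e in zip(p.driving, p.dependence)
    )
    return MicmacClassification(
        factor_set=p.factor_set,
        threshold=thr,
        driving=p.driving,
        dependence=p.dependence,
        quadrants=quadrants,
    )


def quadrant_coordinates(c: MicmacClassification) -> pd.DataFrame:
    """Scatter-plot table: one (dependence, driving, quadrant, label) row
    per factor, in roster order."""
    labels = {f.id: f.label for f in c.factor_set.factors}
    return pd.DataFrame(
        {
            "factor": list(c.factor_set.ids),
            "dependence": list(c.dependence),
            "driving": list(c.driving),
            "quadrant": list(c.quadrants),
            "label": [labels[f] for f in c.factor_set.ids],
        }
    )


def plot_quadrants(c: MicmacClassification, ax=None):
    """Draw the MICMAC driving/dependence scatter with quadrant midlines.

    Returns the matplotlib axes. Import of matplotlib is deferred so the
    numeric pipeline stays usable in minimal environments.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    coords = quadrant_coordinates(c)
    markers = {"autonomous": "s", "dependent": "v", "linkage": "D",
               "independent": "^"}
    for quad, sub in coords.groupby("quadrant", sort=True):
        ax.scatter(sub["dependence"], sub["driving"], marker=markers[quad],
                   label=quad)
    for _, row in coords.iterrows():
        ax.annotate(row["factor"], (row["dependence"], row["driving"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    n = c.factor_set.n
    ax.axvline(c.threshold, color="grey", lw=0.8)
    ax.axhline(c.threshold, color="grey", lw=0.8)
    ax.set_xlim(0, n + 1)
    ax.set_ylim(0, n + 1)
    ax.set_xlabel("dependence power")
    ax.set_ylabel("driving power")
    ax.legend(loc="upper right", fontsize=8)
    return ax
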