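"""Packaged study data: the 14-strategy pandemic-containment SSIM.

The study this package reproduces ranked 14 strategies for containing the
socio-economic and health fallout of the COVID-19 pandemic in a
resource-limited setting, from a consensus expert judgment matrix. That
matrix ships here in two variants:

``printed``
    The upper-triangle symbol matrix exactly as published.

``reconciled`` (default)
    The published matrix with four cell-level errata corrected
    (:data:`ERRATA`). The published symbolic matrix, its published binary
    (initial reachability) form, and its published closed (final
    reachability) form are mutually inconsistent at these four pairs; the
    corrections are the unique minimal edit under which the pipeline
    reproduces the published final reachability matrix (all 196 cells),
    both power margins, the seven hierarchy levels, and the four MICMAC
    clusters. One residual disagreement is irreducible: the published
    *initial* matrix prints 0 where its own *final* matrix prints 1 for
    the (online education -> online purchase) cell, so the reconciled
    initial matrix has a 1 there (195/196 agreement with the printed
    initial matrix).
"""

from __future__ import annotations

import csv
from importlib import resources

from .errors import ISMError
from .ssim import Factor, FactorSet, SSIMatrix, parse_ssim

#: Errata corrections applied in the ``reconciled`` variant, keyed by
#: (row id, column id) of the upper-triangle pair: printed -> corrected.
ERRATA: dict[tuple[str, str], tuple[str, str]] = {
    ("S3", "S5"): ("V", "X"),
    ("S6", "S14"): ("A", "V"),
    ("S8", "S11"): ("O", "V"),
    ("S8", "S12"): ("O", "V"),
}

_VARIANT_FILES = {
    "reconciled": "pandemic_ssim_reconciled.csv",
    "printed": "pandemic_ssim_printed.csv",
}


def _read_data_text(name: str) -> str:
    return (resources.files("ismkit") / "data" / name).read_text(encoding="utf-8")


def pandemic_factors() -> FactorSet:
    """The roster of the 14 pandemic-containment strategies (S1..S14)."""
    reader = csv.DictReader(_read_data_text("pandemic_strategies.csv").splitlines())
    factors = tuple(
        Factor(id=row["id"], label=row["label"], description=row["description"])
        for row in reader
    )
    return FactorSet(factors)


def pandemic_ssim(variant: str = "reconciled") -> SSIMatrix:
    """The study's 14x14 consensus SSIM (91 judgments), with labels.

    Parameters
    ----------
    variant
        ``"reconciled"`` (default) or ``"printed"``; see the module
        docstring for what distinguishes them.
    """
    try:
        fname = _VARIANT_FILES[variant]
    except KeyError:
        raise ISMError(
            f"unknown variant {variant!r}; choose from {sorted(_VARIANT_FILES)}"
        ) from None
    bare = parse_ssim(_read_data_text(fname))
    roster = pandemic_factors()
    if bare.factor_set.ids != roster.ids:
        raise ISMError("packaged SSIM and roster disagree on factor ids")
    return SSIMatrix(factor_set=roster, judgments=bare.judgments)


def builtin_fixture(variant: str = "reconciled") -> SSIMatrix:
    """Alias for :func:`pandemic_ssim` (the package's built-in example)."""
    return pandemic_ssim(variant)
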