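"""Shared fixtures: the study's printed matrices, frozen as text.

``PRINTED_IRM`` and ``PRINTED_FRM`` are the published initial and final
reachability matrices of the 14-strategy pandemic-containment study;
``*`` marks the entries the publication flags as transitivity-derived.
They are the golden references the reachability tests compare against.
"""

import numpy as np
import pytest

import ismkit

PRINTED_IRM_TEXT = """\
1 1 1 1 1 0 1 1 0 0 1 0 1 1
1 1 1 1 0 1 1 0 0 0 1 1 1 1
0 0 1 0 1 0 0 0 0 0 0 0 0 0
0 0 1 1 1 0 0 0 0 0 0 0 1 1
0 0 0 0 1 0 0 0 0 0 0 0 0 0
0 0 1 1 0 1 0 0 0 0 1 0 1 1
0 0 1 1 1 1 1 0 0 0 0 1 1 1
0 0 0 1 1 1 1 1 0 0 1 1 0 1
1 1 1 1 1 1 1 1 1 1 1 0 1 1
1 1 1 0 1 1 0 1 1 1 1 1 1 0
0 0 1 1 1 1 0 0 0 0 1 1 1 1
0 0 1 1 1 1 0 0 0 0 1 1 1 1
0 0 1 1 1 0 0 0 0 0 0 0 1 0
0 0 1 0 0 0 0 0 0 0 0 0 1 1
"""

PRINTED_FRM_TEXT = """\
1 1 1 1 1 *1 1 1 0 0 1 *1 1 1
1 1 1 1 *1 1 1 *1 0 0 1 1 1 1
0 0 1 0 1 0 0 0 0 0 0 0 0 0
0 0 1 1 1 0 0 0 0 0 0 0 1 1
0 0 *1 0 1 0 0 0 0 0 0 0 0 0
0 0 1 1 *1 1 0 0 0 0 1 *1 1 1
0 0 1 1 1 1 1 0 0 0 *1 1 1 1
0 0 *1 1 1 1 1 1 0 0 1 1 *1 1
1 1 1 1 1 1 1 1 1 1 1 *1 1 1
1 1 1 *1 1 1 *1 1 1 1 1 1 1 *1
0 0 1 1 1 1 0 0 0 0 1 1 1 1
0 0 1 1 1 1 0 0 0 0 1 1 1 1
0 0 1 1 1 0 0 0 0 0 0 0 1 *1
0 0 1 *1 *1 0 0 0 0 0 0 0 1 1
"""

PAPER_DRIVING = (12, 12, 2, 5, 2, 8, 9, 10, 14, 14, 8, 8, 5, 5)
PAPER_DEPENDENCE = (4, 4, 14, 12, 14, 9, 6, 5, 2, 2, 9, 9, 12, 12)

PAPER_LEVELS = (
    ("S3", "S5"),
    ("S4", "S13", "S14"),
    ("S6", "S11", "S12"),
    ("S7",),
    ("S8",),
    ("S1", "S2"),
    ("S9", "S10"),
)

PAPER_MICMAC = {
    "autonomous": (),
    "dependent": ("S3", "S4", "S5", "S13", "S14"),
    "linkage": ("S6", "S11", "S12"),
    "independent": ("S1", "S2", "S7", "S8", "S9", "S10"),
}


def _parse_grid(text):
    cells, stars = [], []
    for line in text.strip().splitlines():
        row, srow = [], []
        for tok in line.split():
            srow.append(1 if tok.startswith("*") else 0)
            row.append(int(tok.lstrip("*")))
        cells.append(row)
        stars.append(srow)
    return np.array(cells, dtype=np.int8), np.array(stars, dtype=np.int8)


@pytest.fixture(scope="session")
def printed_irm():
    cells, _ = _parse_grid(PRINTED_IRM_TEXT)
    return cells


@pytest.fixture(scope="session")
def printed_frm():
    cells, _ = _parse_grid(PRINTED_FRM_TEXT)
    return cells


@pytest.fixture(scope="session")
def printed_star_mask():
    _, stars = _parse_grid(PRINTED_FRM_TEXT)
    return stars


@pytest.fixture(scope="session")
def study_ssim():
    return ismkit.pandemic_ssim()


@pytest.fixture(scope="session")
def study_bundle(study_ssim):
    return ismkit.run_pipeline(study_ssim)
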