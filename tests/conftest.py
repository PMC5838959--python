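"""Shared fixtures: a hand-traced 12-TSS consolidation fixture and small
helpers used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from promoterome.io_formats import ExpressionMatrix, GenomicRegion
from promoterome.tss_processing import RawTss

# ---------------------------------------------------------------------------
# 12-TSS hand fixture
#
# Sample space: 12 tissues (brain x5, liver x4, testis x3), 2 primary
# cells, 2 cell lines.  Genes exercise every consolidation branch:
#   GENEA (chr1,+): a1/a2 identical profiles 80 bp apart (merge, r=1);
#     a3 exactly anti-correlated 80 bp further (reject on r); a4 same
#     profile as a1 but 240 bp away (reject on distance).
#   GENEB (chr2,+): b1/b2/b3 identical profiles at points 0/80/160 — the
#     chain case: 160 is within 100 bp of member 80, so all three merge.
#   GENEC (chr3,+): filter boundaries — c1 discarded (tissue 0.5, best
#     rescue 4.9), c2 rescued by cell line 6.0, c3 kept at tissue exactly 1.
#   GENED (chr4,-): strand-aware TSS points; d1 testis-specific, d2 low.

_TISSUE_ORGANS = ["brain"] * 5 + ["liver"] * 4 + ["testis"] * 3

BASE = np.array(
    [10, 12, 14, 8, 9, 6, 7, 8, 9, 20, 22, 24, 3, 3, 2, 2], dtype=float
)
ANTI = np.concatenate([(30 - BASE[:12]) / 10, [0.5, 0.5, 0.5, 0.5]])
BRAIN = np.array(
    [20, 25, 30, 22, 21] + [0.5] * 7 + [1, 1, 1, 1], dtype=float
)
C1 = np.array([0.5] * 12 + [4.9, 4.9, 4.9, 4.9], dtype=float)
C2 = np.array([0.5] * 12 + [1.0, 1.0, 6.0, 1.0], dtype=float)
C3 = np.array([1.0] + [0.4] * 11 + [0.5, 0.5, 0.5, 0.5], dtype=float)
D1 = np.array([0.2] * 9 + [30, 28, 26] + [1, 1, 1, 1], dtype=float)
D2 = np.array([3, 2.5, 2] + [0.3] * 9 + [0.5, 0.5, 0.5, 0.5], dtype=float)


def _meta() -> pd.DataFrame:
    rows = []
    for i, organ in enumerate(_TISSUE_ORGANS):
        rows.append(dict(sample_id=f"ts{i + 1}", category="tissue",
                         tissue_label=f"{organ}_{i + 1}", organ=organ))
    for i in range(2):
        rows.append(dict(sample_id=f"pc{i + 1}", category="primary_cell",
                         tissue_label="pc", organ="cell"))
    for i in range(2):
        rows.append(dict(sample_id=f"cl{i + 1}", category="cell_line",
                         tissue_label="cl", organ="cell"))
    return pd.DataFrame(rows)


_FIXTURE_SPEC = [
    # (tss_id, gene, chrom, start, end, strand, profile)
    ("a1", "GENEA", "chr1", 100, 120, "+", BASE),
    ("a2", "GENEA", "chr1", 180, 200, "+", BASE),
    ("a3", "GENEA", "chr1", 260, 280, "+", ANTI),
    ("a4", "GENEA", "chr1", 500, 520, "+", BASE),
    ("b1", "GENEB", "chr2", 0, 10, "+", BRAIN),
    ("b2", "GENEB", "chr2", 80, 90, "+", BRAIN),
    ("b3", "GENEB", "chr2", 160, 170, "+", BRAIN),
    ("c1", "GENEC", "chr3", 100, 120, "+", C1),
    ("c2", "GENEC", "chr3", 5000, 5020, "+", C2),
    ("c3", "GENEC", "chr3", 10000, 10020, "+", C3),
    ("d1", "GENED", "chr4", 1000, 1020, "-", D1),
    ("d2", "GENED", "chr4", 5000, 5020, "-", D2),
]

# hand-traced expectations
EXPECTED_CLUSTERS = [
    {"a1", "a2"}, {"a3"}, {"a4"}, {"b1", "b2", "b3"},
    {"c1"}, {"c2"}, {"c3"}, {"d1"}, {"d2"},
]
EXPECTED_DISCARDED = [{"c1"}]
EXPECTED_NAMES = {
    "pA@GENEA": {"a1", "a2"}, "pB@GENEA": {"a4"}, "pC@GENEA": {"a3"},
    "pA@GENEB": {"b1", "b2", "b3"},
    "pA@GENEC": {"c2"}, "pB@GENEC": {"c3"},
    "pA@GENED": {"d1"}, "pB@GENED": {"d2"},
}
EXPECTED_LABELS = {
    "pA@GENEA": "broad", "pB@GENEA": "broad", "pC@GENEA": "low",
    "pA@GENEB": "specific", "pA@GENEC": "noise", "pB@GENEC": "low",
    "pA@GENED": "specific", "pB@GENED": "low",
}
EXPECTED_DOMINANT = {"pA@GENEB": "brain", "pA@GENED": "testis"}


@pytest.fixture(scope="session")
def tss_fixture():
    meta = _meta()
    values = pd.DataFrame(
        {tid: prof for tid, _, _, _, _, _, prof in _FIXTURE_SPEC},
        index=meta["sample_id"],
    ).T
    expr = ExpressionMatrix(values, meta)
    raw = [
        RawTss(GenomicRegion(chrom, start, end, strand, tid), gene,
               np.asarray(prof, dtype=float))
        for tid, gene, chrom, start, end, strand, prof in _FIXTURE_SPEC
    ]
    return expr, raw


@pytest.fixture
def rng():
    return np.random.default_rng(0)
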