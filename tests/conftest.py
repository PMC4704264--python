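"""Shared fixtures: reference totals and count-matrix builders.

The reference per-replicate spectral totals come from the published
two-strain GFP benchmark experiment the default thresholds were derived
on: two expression levels (High/Low) sampled at two growth phases, three
biological replicates each.
"""

from __future__ import annotations

import numpy as np
import pytest

from sccomp import CountMatrix, DEFAULT_INTERNAL_STANDARDS

# Per-replicate SpC_total of the benchmark experiment's twelve runs.
REFERENCE_TOTALS = {
    "High-1": {"A": 2406, "B": 2878, "C": 4150},
    "High-2": {"A": 4492, "B": 4362, "C": 4347},
    "Low-1": {"A": 3226, "B": 2522, "C": 4514},
    "Low-2": {"A": 3810, "B": 4339, "C": 4259},
}

# R_TS (2 d.p.) printed for replicate pairs within each sample.
WITHIN_SAMPLE_RTS = {
    ("High-1:A", "High-1:B"): 1.20,
    ("High-1:A", "High-1:C"): 1.72,
    ("High-1:B", "High-1:C"): 1.44,
    ("High-2:A", "High-2:B"): 1.03,
    ("High-2:A", "High-2:C"): 1.03,
    ("High-2:B", "High-2:C"): 1.00,
    ("Low-1:A", "Low-1:B"): 1.28,
    ("Low-1:A", "Low-1:C"): 1.40,
    ("Low-1:B", "Low-1:C"): 1.79,
    ("Low-2:A", "Low-2:B"): 1.14,
    ("Low-2:A", "Low-2:C"): 1.12,
    ("Low-2:B", "Low-2:C"): 1.02,
}

# R_TS (2 d.p.) printed for the cross-sample comparisons.
CROSS_SAMPLE_RTS = {
    ("High-1:A", "Low-1:A"): 1.34,
    ("High-1:B", "Low-1:A"): 1.12,
    ("High-1:C", "Low-1:A"): 1.29,
    ("High-1:A", "Low-1:B"): 1.05,
    ("High-1:B", "Low-1:B"): 1.14,
    ("High-1:C", "Low-1:B"): 1.65,
    ("High-1:A", "Low-1:C"): 1.88,
    ("High-1:B", "Low-1:C"): 1.57,
    ("High-1:C", "Low-1:C"): 1.09,
    ("High-2:A", "Low-2:A"): 1.18,
    ("High-2:B", "Low-2:A"): 1.14,
    ("High-2:C", "Low-2:A"): 1.14,
    ("High-2:A", "Low-2:B"): 1.04,
    ("High-2:B", "Low-2:B"): 1.01,
    ("High-2:C", "Low-2:B"): 1.00,
    ("High-2:A", "Low-2:C"): 1.05,
    ("High-2:B", "Low-2:C"): 1.02,
    ("High-2:C", "Low-2:C"): 1.02,
}


def matrix_with_totals(totals: dict[str, dict[str, int]]) -> CountMatrix:
    """A count matrix with the internal standards present whose column
    sums equal the given per-replicate totals exactly."""
    protein_ids = ["gfp", *DEFAULT_INTERNAL_STANDARDS, "filler"]
    labels = [(s, r) for s, reps in totals.items() for r in reps]
    columns = []
    for s, reps in totals.items():
        for r in reps:
            total = totals[s][r]
            std = [50] * len(DEFAULT_INTERNAL_STANDARDS)
            gfp = 30
            filler = total - gfp - sum(std)
            assert filler >= 0
            columns.append([gfp, *std, filler])
    counts = np.array(columns).T
    return CountMatrix(protein_ids, labels, counts)


@pytest.fixture
def reference_matrix() -> CountMatrix:
    return matrix_with_totals(REFERENCE_TOTALS)


@pytest.fixture
def write_tsv(tmp_path):
    """Write text to a temporary TSV file and return its path."""
    def _write(text: str, name: str = "data.tsv"):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path
    return _write
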