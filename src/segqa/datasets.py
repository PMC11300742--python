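"""Published score tables from a 97-case adult diffuse-glioma cohort.

These are the printed ordinal-score distributions from a published
clinical study that rated deep-learning and manual glioma segmentations
on the two-step 5-point scale (no score of 1 occurred in that cohort).
They serve as fixed numeric inputs for reproducing the cohort-level
statistics; the underlying MRI data are not public.
"""

from __future__ import annotations

import numpy as np

from .cohort_stats import CrossTab, ScoreTable

#: Score levels that occurred in the cohort.
COHORT_SCORE_LEVELS = (2, 3, 4, 5)

#: DL (rows) x manual (columns) score cross-tabulation, n = 97.
_DL_MANUAL_CELLS = np.array(
    [
        [0, 1, 5, 0],
        [0, 23, 17, 2],
        [2, 15, 13, 7],
        [0, 3, 7, 2],
    ]
)

#: Subgroup score counts per method and factor level.
_SUBGROUP_COUNTS = {
    "deep_learning": {
        "focality": {"unifocal": [3, 31, 30, 10], "multifocal": [3, 11, 7, 2]},
        "status": {"newly_diagnosed": [0, 5, 8, 3], "recurrent": [6, 37, 29, 9]},
    },
    "manual": {
        "focality": {"unifocal": [0, 30, 33, 11], "multifocal": [2, 12, 9, 0]},
        "status": {"newly_diagnosed": [0, 4, 9, 3], "recurrent": [2, 38, 33, 8]},
    },
}


def dl_manual_crosstab() -> CrossTab:
    """The 4x4 DL-vs-manual score cross-tabulation (97 cases)."""
    return CrossTab(
        rows=COHORT_SCORE_LEVELS, cols=COHORT_SCORE_LEVELS, cells=_DL_MANUAL_CELLS
    )


def dl_score_table() -> ScoreTable:
    """Marginal DL score distribution: {2: 6, 3: 42, 4: 37, 5: 12}."""
    return dl_manual_crosstab().row_table()


def manual_score_table() -> ScoreTable:
    """Marginal manual score distribution: {2: 2, 3: 42, 4: 42, 5: 11}."""
    return dl_manual_crosstab().col_table()


def subgroup_crosstab(method: str, factor: str) -> CrossTab:
    """Score x factor-level table for one method ('deep_learning' or
    'manual') and one factor ('focality' or 'status')."""
    counts = _SUBGROUP_COUNTS[method][factor]
    levels = tuple(counts)
    cells = np.column_stack([counts[lv] for lv in levels])
    return CrossTab(rows=COHORT_SCORE_LEVELS, cols=levels, cells=cells)
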