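"""Cohort-level statistics for ordinal quality scores and Dice values.

Covers score-distribution summaries, cross-tabulation with Pearson
chi-square (no continuity correction, all-zero rows/columns dropped),
Mann-Whitney U subgroup comparisons (exact enumeration for small untied
samples, tie-corrected normal approximation otherwise, two-sided), and
the single-rater two-way-mixed consistency intraclass correlation
ICC(3,1) for inter-rater reliability of the ordinal ratings.

No multiple-testing correction is applied; each comparison is reported
at two-sided alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SCORE_LEVELS = (1, 2, 3, 4, 5)

__all__ = [
    "ScoreTable",
    "CrossTab",
    "score_summary",
    "cross_tabulate",
    "chi_square_test",
    "mann_whitney_test",
    "icc_consistency",
    "subgroup_compare",
]


class DegenerateTableError(ValueError):
    """Contingency table has fewer than two non-empty rows or columns."""


@dataclass(frozen=True)
class ScoreTable:
    """Frequency distribution of ordinal scores on the 1-5 scale."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        for level, c in self.counts.items():
            if level not in SCORE_LEVELS:
                raise ValueError(f"score level {level} outside 1..5")
            if c < 0:
                raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(sum(self.counts.values()))

    @classmethod
    def from_scores(cls, scores: Sequence[int]) -> "ScoreTable":
        vals, cnts = np.unique(np.asarray(scores, dtype=int), return_counts=True)
        return cls({int(v): int(c) for v, c in zip(vals, cnts)})

    def expand(self) -> np.ndarray:
        """The underlying per-case score vector implied by the counts."""
        return np.repeat(
            [lv for lv in sorted(self.counts)],
            [self.counts[lv] for lv in sorted(self.counts)],
        ).astype(float)


@dataclass(frozen=True)
class CrossTab:
    """Cross-tabulation of ordinal scores between two methods (or a score
    distribution split by a two-level factor)."""

    rows: tuple
    cols: tuple
    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.shape != (len(self.rows), len(self.cols)):
            raise ValueError("cells shape does not match row/col labels")
        if np.any(cells < 0):
            raise ValueError("cell counts must be non-negative")
        object.__setattr__(self, "cells", cells.astype(int))

    @property
    def n(self) -> int:
        return int(self.cells.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    def row_table(self) -> ScoreTable:
        return ScoreTable({int(r): int(t) for r, t in zip(self.rows, self.row_totals)})

    def col_table(self) -> ScoreTable:
        return ScoreTable({int(c): int(t) for c, t in zip(self.cols, self.col_totals)})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(self.rows), columns=list(self.cols))


def score_summary(table: ScoreTable) -> Dict[str, float]:
    """Mean, sample SD (denominator n-1) and fraction of scores >= 3."""
    n = table.n
    if n < 2:
        raise ValueError("need at least 2 observations for a summary with SD")
    x = table.expand()
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "fraction_ge3": float((x >= 3).mean()),
    }


def cross_tabulate(scores_a: Sequence, scores_b: Sequence) -> CrossTab:
    """Count cases by (score_a, score_b), aligned by position."""
    a = np.asarray(scores_a)
    b = np.asarray(scores_b)
    if a.size == 0:
        raise ValueError("empty score vectors")
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    tab = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    return CrossTab(
        rows=tuple(tab.index), cols=tuple(tab.columns), cells=tab.to_numpy()
    )


def chi_square_test(table: CrossTab | np.ndarray) -> Dict[str, float]:
    """Pearson chi-square of independence, no continuity correction.

    All-zero rows/columns are dropped before testing; a table with fewer
    than two non-empty rows or columns is degenerate.
    """
    cells = table.cells if isinstance(table, CrossTab) else np.asarray(table)
    cells = cells[cells.sum(axis=1) > 0][:, cells.sum(axis=0) > 0]
    if cells.shape[0] < 2 or cells.shape[1] < 2:
        raise DegenerateTableError(
            f"contingency table degenerate after dropping zeros: {cells.shape}"
        )
    res = stats.chi2_contingency(cells, correction=False)
    return {"statistic": float(res[0]), "df": int(res[2]), "p": float(res[1])}


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    combined = np.concatenate([a, b])
    return np.unique(combined).size < combined.size


def mann_whitney_test(
    group_a: Sequence, group_b: Sequence, method: str = "auto"
) -> Dict[str, float]:
    """Two-sided Mann-Whitney U test.

    ``method='auto'`` uses exact enumeration of the U distribution when
    the product of group sizes is at most 400 and the pooled sample has
    no ties, otherwise the normal approximation with tie-corrected
    variance and continuity correction. ``'exact'`` / ``'asymptotic'``
    force one path.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = (
            "exact" if a.size * b.size <= 400 and not _has_ties(a, b) else "asymptotic"
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p_two_sided": float(res.pvalue),
        "method": method,
    }


def icc_consistency(ratings: np.ndarray) -> float:
    """ICC(3,1): single-rater, two-way mixed-effects, consistency type.

    ``ratings`` is an n-cases x 2-raters matrix of ordinal scores with no
    missing cells. Computed via pingouin's two-way ANOVA decomposition,
    (MS_rows - MS_error) / (MS_rows + (k-1) * MS_error).
    """
    import pingouin as pg  # deferred: heavy import

    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] != 2:
        raise ValueError("ratings must be an n x 2 matrix")
    n, k = r.shape
    if n < 3:
        raise ValueError("need at least 3 cases")
    if np.any(~np.isfinite(r)):
        raise ValueError("ratings must have no missing cells")
    if np.allclose(np.var(r.mean(axis=1)), 0.0):
        raise ValueError("zero between-case variance: ICC undefined")
    # degenerate perfect agreement (zero error mean square): residual after
    # removing case and rater effects vanishes and the ANOVA ratio is 0/0
    resid = r - r.mean(axis=1, keepdims=True) - r.mean(axis=0) + r.mean()
    if np.allclose(resid, 0.0):
        return 1.0
    long = pd.DataFrame(
        {
            "case": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": r.ravel(),
        }
    )
    res = pg.intraclass_corr(
        data=long, targets="case", raters="rater", ratings="score"
    )
    mask = res["Type"].isin(["ICC3", "ICC(C,1)"])
    return float(res.loc[mask, "ICC"].iloc[0])


def subgroup_compare(
    cohort: pd.DataFrame, factor: str, measure: str
) -> Dict[str, object]:
    """Compare a measure between the two levels of a subgroup factor.

    ``cohort`` needs columns ``factor`` plus ``wt_dice`` (continuous) or
    ``score`` (ordinal 1-5). Continuous measures get a Mann-Whitney test
    with median and P25-P75 per level; ordinal scores get a Pearson
    chi-square on the score x level table.
    """
    from .mask_model import FOCALITIES, STATUSES

    level_order = {"status": STATUSES, "focality": FOCALITIES}
    if factor not in level_order:
        raise ValueError(f"factor must be 'status' or 'focality', got {factor!r}")
    levels = level_order[factor]
    groups = {lv: cohort.loc[cohort[factor] == lv] for lv in levels}
    for lv, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"factor level {lv!r} absent from cohort")

    if measure == "dsc":
        vals = {lv: g["wt_dice"].to_numpy(float) for lv, g in groups.items()}
        test = mann_whitney_test(vals[levels[0]], vals[levels[1]])
        summaries = {
            lv: {
                "n": int(v.size),
                "median": float(np.median(v)),
                "p25": float(np.percentile(v, 25)),
                "p75": float(np.percentile(v, 75)),
            }
            for lv, v in vals.items()
        }
        return {"factor": factor, "measure": measure, "levels": summaries, **test}

    if measure == "semiquant":
        observed_levels = sorted(set(cohort["score"].astype(int)))
        cells = np.array(
            [
                [
                    int((groups[lv]["score"].astype(int) == s).sum())
                    for lv in levels
                ]
                for s in observed_levels
            ]
        )
        ct = CrossTab(rows=tuple(observed_levels), cols=tuple(levels), cells=cells)
        test = chi_square_test(ct)
        return {"factor": factor, "measure": measure, "table": ct, **test}

    raise ValueError(f"measure must be 'dsc' or 'semiquant', got {measure!r}")
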