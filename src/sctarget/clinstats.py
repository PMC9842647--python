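"""Cohort-level 2x2 statistics, the IHC H-score and ROC cutoff selection.

Fisher's exact test is two-sided by point-probability summation over the
hypergeometric distribution with fixed margins; the chi-square test is the
plain Pearson form (Yates correction behind a flag).  Cohort tables choose
Fisher when any expected count is below 5, chi-square otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "IHCFractions",
    "RocResult",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "h_score",
    "roc_cutoff",
    "cohort_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b / c, d): rows are category levels, columns the two groups."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d)
        if any(v < 0 or v != int(v) for v in vals):
            raise ValueError("counts must be non-negative integers")
        if sum(vals) == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class IHCFractions:
    """Four-class IHC staining percentages; must sum to 100 (+/- 0.01)."""

    negative: float
    low_positive: float
    positive: float
    high_positive: float

    def __post_init__(self) -> None:
        vals = (self.negative, self.low_positive, self.positive, self.high_positive)
        if any(not 0.0 <= v <= 100.0 for v in vals):
            raise ValueError("percentages must lie in [0, 100]")
        if abs(sum(vals) - 100.0) > 0.01:
            raise ValueError(f"percentages sum to {sum(vals)}, expected 100")


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by hypergeometric point-probability summation.

    With margins fixed, all tables whose point probability is at most the
    observed one (within a 1e-7 relative slack) contribute; p is clipped to
    [0, 1].  A zero margin gives p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, a + b + c + d
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(max(p, 0.0), 1.0)


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (1 df); optional Yates correction."""
    obs = table.as_array()
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (exp == 0).any():
        raise ValueError("zero expected count; use fisher_exact_2x2")
    diff = np.abs(obs - exp)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def h_score(fractions: IHCFractions) -> float:
    """Weighted IHC H-score in [0, 300]:
    0*negative% + 1*low_positive% + 2*positive% + 3*high_positive%."""
    return (
        0.0 * fractions.negative
        + 1.0 * fractions.low_positive
        + 2.0 * fractions.positive
        + 3.0 * fractions.high_positive
    )


def roc_cutoff(scores, binary_outcome) -> RocResult:
    """AUC (rank statistic with tie correction) and the Youden-J cutoff.

    Candidate cutoffs are midpoints between adjacent distinct scores; the
    cutoff maximizing sensitivity + specificity - 1 is returned (ties to the
    lowest cutoff), with predicted-positive meaning score > cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_outcome, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must align")
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    distinct = np.unique(s)
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for cut in cuts:  # ascending, so ties keep the lowest cutoff
        pred = s > cut
        sens = (pred & (y == 1)).sum() / n1
        spec = (~pred & (y == 0)).sum() / n0
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(cut), float(sens), float(spec))
    if best is None:  # all scores identical
        best = (0.0, float(distinct[0]), 1.0, 0.0)
    return RocResult(auc=float(auc), cutoff=best[1], sensitivity=best[2], specificity=best[3])


@dataclass
class CohortTestResult:
    table: ContingencyTable2x2
    test: str
    statistic: float | None
    p: float


def cohort_table(records, category_column: str, group_column: str) -> CohortTestResult:
    """Tabulate two 2-level columns and test association.

    Fisher's exact test is chosen when any expected count is below 5,
    Pearson chi-square otherwise.  More than two levels in either column is
    an error: pre-bin first.
    """
    import pandas as pd

    df = pd.DataFrame(records)
    cats = sorted(df[category_column].unique())
    grps = sorted(df[group_column].unique())
    if len(cats) != 2 or len(grps) != 2:
        raise ValueError("category and group must each have exactly 2 levels; pre-bin first")
    ct = pd.crosstab(df[category_column], df[group_column]).loc[cats, grps]
    table = ContingencyTable2x2(*(int(v) for v in ct.to_numpy().ravel()))
    obs = table.as_array()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if (exp < 5).any():
        return CohortTestResult(table=table, test="fisher", statistic=None, p=fisher_exact_2x2(table))
    chi2, p = chi_square_2x2(table)
    return CohortTestResult(table=table, test="chi-square", statistic=chi2, p=p)
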