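"""Agreement statistics for cross-tabulated category assignments.

Everything operates on a labeled :class:`ContingencyTable` (reference
source on the rows, EHR source on the columns): raw concordance, Cohen's
kappa with optional linear or quadratic (Fleiss–Cohen) disagreement
weights, asymptotic confidence intervals, category collapsing/restriction,
two-by-two screening metrics (PPV/NPV/sensitivity/specificity), and the
product-moment correlation for paired continuous values.

Weighted kappa, for a k×k table with cell proportions p_ij, row and column
marginals r_i and c_j, and weights w_ij = 1 − (|i−j|/(k−1))^q (q = 1
linear, q = 2 quadratic; unweighted = identity on the diagonal):

    kappa_w = (sum w_ij p_ij − sum w_ij r_i c_j) / (1 − sum w_ij r_i c_j)

The confidence interval uses the large-sample standard error of the
weighted kappa (Fleiss–Cohen–Everitt form) with normal quantiles, clipped
to [−1, 1]; other interval constructions exist, so printed intervals from
other software may differ slightly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "WeightScheme",
    "AgreementResult",
    "ScreeningMetrics",
    "concordance",
    "cohens_kappa",
    "kappa_ci",
    "collapse_table",
    "screening_metrics",
    "pearson_correlation",
]


class WeightScheme(enum.Enum):
    NONE = "none"
    LINEAR = "linear"
    QUADRATIC = "quadratic"


@dataclass(frozen=True)
class ContingencyTable:
    """Labeled cross-tabulation; rows = reference source, cols = EHR source."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.row_labels)) != len(self.row_labels) or len(
            set(self.col_labels)
        ) != len(self.col_labels):
            raise ValueError("labels must be unique")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[tuple[str, str]],
        row_labels: Sequence[str],
        col_labels: Sequence[str],
    ) -> "ContingencyTable":
        """Tabulate (reference label, EHR label) pairs onto a fixed grid."""
        ri = {l: i for i, l in enumerate(row_labels)}
        ci = {l: i for i, l in enumerate(col_labels)}
        counts = np.zeros((len(row_labels), len(col_labels)))
        for r, c in pairs:
            counts[ri[r], ci[c]] += 1
        return cls(tuple(row_labels), tuple(col_labels), counts)


@dataclass(frozen=True)
class AgreementResult:
    statistic: float
    weight_scheme: WeightScheme
    n: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass(frozen=True)
class ScreeningMetrics:
    ppv: Optional[float]
    npv: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    tp: int
    fp: int
    fn: int
    tn: int


def concordance(
    table: ContingencyTable,
    pairing: Optional[Mapping[str, str]] = None,
) -> AgreementResult:
    """Fraction of records assigned matching categories by the two sources.

    ``pairing`` maps row labels to the column label they agree with; by
    default identical labels are paired.
    """
    if table.n == 0:
        raise ValueError("empty table")
    if pairing is None:
        pairing = {l: l for l in table.row_labels if l in table.col_labels}
    agree = 0.0
    ci = {l: i for i, l in enumerate(table.col_labels)}
    for r, c in pairing.items():
        if r not in table.row_labels or c not in ci:
            raise ValueError(f"pairing refers to missing label: {r!r}->{c!r}")
        agree += table.counts[table.row_labels.index(r), ci[c]]
    return AgreementResult(float(agree / table.n), WeightScheme.NONE, int(table.n))


def _weight_matrix(k: int, scheme: WeightScheme) -> np.ndarray:
    idx = np.arange(k)
    dist = np.abs(np.subtract.outer(idx, idx))
    if scheme is WeightScheme.NONE:
        return (dist == 0).astype(float)
    q = 1 if scheme is WeightScheme.LINEAR else 2
    return 1.0 - (dist / (k - 1)) ** q


def _aligned_counts(table: ContingencyTable, ordering: Sequence[str]) -> np.ndarray:
    if set(ordering) != set(table.row_labels) or set(ordering) != set(table.col_labels):
        raise ValueError("kappa requires a square table over one ordered category set")
    r = [table.row_labels.index(l) for l in ordering]
    c = [table.col_labels.index(l) for l in ordering]
    return table.counts[np.ix_(r, c)]


def cohens_kappa(
    table: ContingencyTable,
    weights: WeightScheme = WeightScheme.NONE,
    ordering: Optional[Sequence[str]] = None,
) -> AgreementResult:
    """Chance-corrected agreement on a square table.

    ``ordering`` fixes the shared category order (required for weighted
    schemes to be meaningful); it defaults to the row-label order.
    """
    ordering = tuple(ordering or table.row_labels)
    counts = _aligned_counts(table, ordering)
    k = len(ordering)
    if k < 2:
        raise ValueError("kappa requires at least two categories")
    n = counts.sum()
    if n == 0:
        raise ValueError("empty table")
    w = _weight_matrix(k, weights)
    p = counts / n
    r, c = p.sum(axis=1), p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(r, c)).sum())
    if pe >= 1.0:
        raise ValueError("degenerate marginals: chance agreement is total")
    return AgreementResult((po - pe) / (1.0 - pe), weights, int(n))


def kappa_ci(
    table: ContingencyTable,
    result: AgreementResult,
    alpha: float = 0.05,
    ordering: Optional[Sequence[str]] = None,
) -> tuple[float, float]:
    """Large-sample normal interval for (weighted) kappa, clipped to [-1, 1]."""
    ordering = tuple(ordering or table.row_labels)
    counts = _aligned_counts(table, ordering)
    n = counts.sum()
    if n < 2:
        raise ValueError("interval requires n >= 2")
    k = len(ordering)
    w = _weight_matrix(k, result.weight_scheme)
    p = counts / n
    r, c = p.sum(axis=1), p.sum(axis=0)
    pe = float((w * np.outer(r, c)).sum())
    kap = result.statistic
    wbar_row = w @ c  # row-conditional expected weight
    wbar_col = w.T @ r
    term = (w - (wbar_row[:, None] + wbar_col[None, :]) * (1 - kap)) ** 2
    var = ((p * term).sum() - (kap - pe * (1 - kap)) ** 2) / (n * (1 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    z = float(stats.norm.ppf(1 - alpha / 2))
    return (float(max(kap - z * se, -1.0)), float(min(kap + z * se, 1.0)))


def collapse_table(
    table: ContingencyTable,
    row_groups: Mapping[str, Sequence[str]],
    col_groups: Mapping[str, Sequence[str]],
) -> ContingencyTable:
    """Sum counts within label groups; ungrouped labels are dropped.

    ``row_groups`` / ``col_groups`` map each new label to the old labels it
    absorbs. Groups must not overlap; the total count over retained labels
    is conserved.
    """

    def check(groups: Mapping[str, Sequence[str]], labels: Sequence[str], axis: str):
        seen: set[str] = set()
        for new, olds in groups.items():
            for old in olds:
                if old not in labels:
                    raise ValueError(f"unknown {axis} label {old!r}")
                if old in seen:
                    raise ValueError(f"overlapping groups at {axis} label {old!r}")
                seen.add(old)

    check(row_groups, table.row_labels, "row")
    check(col_groups, table.col_labels, "column")
    new_rows = tuple(row_groups)
    new_cols = tuple(col_groups)
    counts = np.zeros((len(new_rows), len(new_cols)))
    for i, nr in enumerate(new_rows):
        ri = [table.row_labels.index(l) for l in row_groups[nr]]
        for j, nc in enumerate(new_cols):
            ci = [table.col_labels.index(l) for l in col_groups[nc]]
            counts[i, j] = table.counts[np.ix_(ri, ci)].sum()
    return ContingencyTable(new_rows, new_cols, counts)


def restrict_table(table: ContingencyTable, labels: Sequence[str]) -> ContingencyTable:
    """Keep only the given labels on both axes (identity grouping)."""
    groups = {l: (l,) for l in labels}
    return collapse_table(table, groups, groups)


def screening_metrics(table: ContingencyTable) -> ScreeningMetrics:
    """PPV/NPV/sensitivity/specificity from a 2×2 eligibility table.

    Rows are the reference verdicts (eligible first), columns the EHR
    verdicts. A zero denominator flags that metric as undefined (None)
    rather than raising.
    """
    if table.counts.shape != (2, 2):
        raise ValueError("screening metrics require a 2x2 table")
    tp = int(table.counts[0, 0])
    fn = int(table.counts[0, 1])
    fp = int(table.counts[1, 0])
    tn = int(table.counts[1, 1])

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return ScreeningMetrics(
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def pearson_correlation(pairs: Sequence[tuple[float, float]]) -> Optional[float]:
    """Product-moment correlation; None when a coordinate has no variance."""
    if len(pairs) < 2:
        raise ValueError("correlation requires at least two pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)
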