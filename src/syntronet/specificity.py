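"""Partnership-specificity statistics on sorted-consortium tables.

Single ANME-SRB consortia sorted by flow cytometry yield one (ANME clade,
SRB clade) pair per sort. Cross-tabulating sorts gives a contingency table on
which a chi-squared test of independence asks whether the SRB partner found in
a sort depends on the ANME subtype present; conditional partner fractions
(e.g. 8/9 of SEEP-SRB1g sorts paired with ANME-2b) quantify the specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Nonnegative integer counts indexed by (ANME clade rows, SRB clade cols)."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ParameterError("contingency counts must be 2-D")
        if np.any(counts < 0):
            raise ParameterError("contingency counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ParameterError("label lengths must match counts shape")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))

    def drop_empty(self) -> "ContingencyTable":
        """Remove rows/columns with zero marginal total."""
        rows = self.counts.sum(axis=1) > 0
        cols = self.counts.sum(axis=0) > 0
        return ContingencyTable(
            counts=self.counts[np.ix_(rows, cols)],
            row_labels=tuple(l for l, m in zip(self.row_labels, rows) if m),
            col_labels=tuple(l for l, m in zip(self.col_labels, cols) if m),
        )


def contingency_from_sorts(sorts, drop_empty: bool = False) -> ContingencyTable:
    """Cross-tabulate a consortium sort table into (ANME x SRB) counts."""
    if sorts.n == 0:
        raise ParameterError("empty sort table")
    rows = sorted(set(sorts.anme_clade))
    cols = sorted(set(sorts.srb_clade))
    ri = {l: i for i, l in enumerate(rows)}
    ci = {l: i for i, l in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for a, s in zip(sorts.anme_clade, sorts.srb_clade):
        counts[ri[a], ci[s]] += 1
    table = ContingencyTable(counts=counts, row_labels=tuple(rows), col_labels=tuple(cols))
    return table.drop_empty() if drop_empty else table


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    low_expected: bool  # any expected count < 5


def chi2_independence(table: ContingencyTable) -> Chi2Result:
    """Pearson chi-squared test of independence, no continuity correction.

    chi^2 = sum (O - E)^2 / E with E = row total x column total / n;
    df = (r - 1)(c - 1). Zero-marginal categories must be dropped first
    (``ContingencyTable.drop_empty``); a warning flag is set when any expected
    count falls below 5.
    """
    obs = table.counts.astype(float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateDataError(
            "zero row/column marginal: drop empty categories before testing"
        )
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateDataError("need at least 2 rows and 2 columns")
    n = obs.sum()
    expected = np.outer(row, col) / n
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    low = bool((expected < 5).any())
    if low:
        logger.warning("chi2_independence: expected count < 5 in some cell")
    return Chi2Result(statistic=statistic, df=df, p_value=p, low_expected=low)


def partner_fractions(
    table: ContingencyTable, focal_axis: str, focal_clade: str
) -> pd.DataFrame:
    """Conditional partner distribution given a focal clade.

    ``focal_axis="anme"`` conditions on a row (ANME subtype), returning the
    distribution over SRB partners; ``"srb"`` conditions on a column. Output
    has columns partner / count / fraction / percent.
    """
    if focal_axis == "anme":
        if focal_clade not in table.row_labels:
            raise ParameterError(f"unknown ANME clade {focal_clade!r}")
        vec = table.counts[table.row_labels.index(focal_clade), :]
        partners = table.col_labels
    elif focal_axis == "srb":
        if focal_clade not in table.col_labels:
            raise ParameterError(f"unknown SRB clade {focal_clade!r}")
        vec = table.counts[:, table.col_labels.index(focal_clade)]
        partners = table.row_labels
    else:
        raise ParameterError("focal_axis must be 'anme' or 'srb'")
    total = int(vec.sum())
    if total == 0:
        raise DegenerateDataError(f"focal clade {focal_clade!r} has zero total")
    frac = vec / total
    return pd.DataFrame(
        {
            "partner": list(partners),
            "count": vec.astype(int),
            "fraction": frac,
            "percent": 100.0 * frac,
        }
    )


def specificity_power(
    spec_matrix,
    anme_marginal,
    n_sorts: int,
    alpha: float = 0.001,
    reps: int = 1000,
    seed: int = 0,
    anme_clades=None,
    srb_clades=None,
) -> float:
    """Fraction of simulated sort tables in which the chi-squared test rejects.

    Calibration harness: under uniform conditional rows (no specificity) the
    rejection rate estimates the type-I error; under a specific partnership
    matrix it estimates power.
    """
    from .synthetic import gen_sorted_consortia

    if reps < 1:
        raise ParameterError("reps must be >= 1")
    root = np.random.SeedSequence(seed)
    rejections = 0
    tested = 0
    for child in root.spawn(reps):
        sorts = gen_sorted_consortia(
            spec_matrix,
            anme_marginal,
            n_sorts,
            seed=child,
            anme_clades=anme_clades,
            srb_clades=srb_clades,
        )
        table = contingency_from_sorts(sorts, drop_empty=True)
        if table.counts.shape[0] < 2 or table.counts.shape[1] < 2:
            continue  # degenerate draw: no testable variation
        result = chi2_independence(table)
        tested += 1
        if result.p_value < alpha:
            rejections += 1
    if tested == 0:
        raise DegenerateDataError("no replicate produced a testable table")
    return rejections / tested
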