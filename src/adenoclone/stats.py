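"""Cohort-level inferential statistics.

Categorical patient characteristics (pretreatment, co-occurring disease,
receptor status, ...) are compared against mutation status with Fisher's
exact test on 2x2 tables; continuous measures (VAF vectors, methylation
frequencies, expression fold changes) with Welch's unequal-variance
t-test.  Relative expression from qPCR uses the comparative threshold
cycle method (fold change ``2**-ddCt`` against a housekeeping reference
and a control condition).

The Fisher p-value is two-sided via the point-probability method — the
sum over all tables with the observed margins whose probability does not
exceed that of the observed table — and the reported odds ratio is the
sample (cross-product) estimate ``(a*d)/(b*c)``.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
import scipy.stats


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]`` with optional row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("exposed", "unexposed")
    col_labels: tuple[str, str] = ("case", "control")

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not float(v).is_integer():
                raise ValueError(f"non-integer count {name}={v}")
            if v < 0:
                raise ValueError(f"negative count {name}={v}")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p_two_sided)``; the odds ratio is the sample
    estimate ``(a*d)/(b*c)`` (inf when ``b*c == 0`` and ``a*d > 0``, NaN
    when both products vanish).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    arr = table.as_array()
    res = scipy.stats.fisher_exact(arr, alternative="two-sided")
    ad, bc = table.a * table.d, table.b * table.c
    if bc > 0:
        oddsratio = ad / bc
    elif ad > 0:
        oddsratio = float("inf")
    else:
        oddsratio = float("nan")
    return oddsratio, float(res.pvalue)


def welch_t(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Returns ``(t, df, p_two_sided)``; each vector needs at least two
    finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each vector needs length >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite value in input")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclasses.dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR well pair: target and housekeeping-reference Ct values."""

    sample_id: str
    ct_target: float
    ct_reference: float
    condition: str

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")


def qpcr_fold_change(
    measurements: Sequence[QpcrMeasurement], control_condition: str
) -> pd.DataFrame:
    """Comparative threshold cycle (ddCt) relative expression.

    ``dCt = Ct_target - Ct_reference``; ``ddCt`` subtracts the mean dCt of
    the control condition; ``fold = 2**-ddCt``.  Returns one row per
    measurement.
    """
    if not measurements:
        raise ValueError("no measurements")
    dct = [m.ct_target - m.ct_reference for m in measurements]
    control = [
        v for m, v in zip(measurements, dct) if m.condition == control_condition
    ]
    if not control:
        raise ValueError(f"no measurements in control condition {control_condition!r}")
    baseline = float(np.mean(control))
    rows = []
    for m, v in zip(measurements, dct):
        ddct = v - baseline
        rows.append(
            {
                "sample_id": m.sample_id,
                "condition": m.condition,
                "delta_ct": v,
                "delta_delta_ct": ddct,
                "fold_change": 2.0 ** (-ddct),
            }
        )
    return pd.DataFrame(rows)


def table1_battery(
    patients: pd.DataFrame,
    *,
    status_column: str = "kras_mutated",
    characteristics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fisher tests of every boolean characteristic against mutation status.

    ``patients`` holds one row per patient with a boolean status column
    and boolean characteristic columns.  Returns a tidy table with the
    2x2 counts, the sample odds ratio (NaN-flagged when undefined) and
    the two-sided Fisher p per characteristic.
    """
    if status_column not in patients.columns:
        raise ValueError(f"missing status column {status_column!r}")
    if patients[status_column].isna().any():
        bad = patients.index[patients[status_column].isna()].tolist()
        raise ValueError(f"missing mutation status for rows: {bad}")
    status = patients[status_column].astype(bool)
    if characteristics is None:
        characteristics = [
            c
            for c in patients.columns
            if c != status_column and patients[c].dropna().isin([0, 1, True, False]).all()
        ]
    rows = []
    for char in characteristics:
        flag = patients[char].astype(bool)
        a = int((flag & status).sum())  # characteristic & mutated
        b = int((flag & ~status).sum())
        c = int((~flag & status).sum())
        d = int((~flag & ~status).sum())
        oddsratio, p = fisher_exact(ContingencyTable2x2(a, b, c, d))
        rows.append(
            {
                "characteristic": char,
                "mutated_with": a,
                "wildtype_with": b,
                "mutated_without": c,
                "wildtype_without": d,
                "odds_ratio": oddsratio,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
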