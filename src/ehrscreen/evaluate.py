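"""Contingency-table evaluation statistics with statistical disclosure control.

For each binary feature set, the coincidence of feature presence and
caseness is summarised as a 2x2 table (TP, FP, FN, TN) and evaluated with
the statistics suited to a heavily imbalanced target:

* prevalence of the feature per 1,000 records;
* class balance accuracy (CBA) — the lower bound of average sensitivity
  and average positive predictive value,
  ``0.5 * (TP / min(TP+FN, TP+FP) + TN / min(TN+FP, TN+FN))``;
* odds ratio ``(TP * TN) / (FP * FN)``;
* positive and negative predictive values.

Disclosure control follows the small-cell convention for published counts:
a raw count of seven or fewer is suppressed outright, anything larger is
rounded to the nearest ten (half up) *before* any statistic is computed.
A statistic needing a suppressed cell is reported unavailable, never
imputed. Statistics on the raw cells can be requested for internal use and
are labelled as such.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

SUPPRESSION_THRESHOLD = 7


def disclosure_control(count: int) -> int | None:
    """Suppress counts <= 7 (returns None); otherwise round to nearest 10.

    Rounding is half-up: 14 -> 10, 15 -> 20. Negative counts are a logic
    error upstream and raise.
    """
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count!r}")
    if count <= SUPPRESSION_THRESHOLD:
        return None
    return int(math.floor(count / 10 + 0.5)) * 10


@dataclass(frozen=True)
class ContingencyTable:
    """Feature presence x caseness cell counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def controlled(self) -> "ContingencyTable | None":
        """Disclosure-controlled copy, or None if any cell is suppressed."""
        cells = [disclosure_control(c) for c in (self.tp, self.fp, self.fn, self.tn)]
        if any(c is None for c in cells):
            return None
        return ContingencyTable(*cells)

    @classmethod
    def from_columns(cls, feature: np.ndarray, caseness: np.ndarray) -> "ContingencyTable":
        f = np.asarray(feature).astype(bool)
        y = np.asarray(caseness).astype(bool)
        if f.shape != y.shape:
            raise ValueError("feature and caseness must have equal length")
        return cls(
            tp=int((f & y).sum()),
            fp=int((f & ~y).sum()),
            fn=int((~f & y).sum()),
            tn=int((~f & ~y).sum()),
        )


def class_balance_accuracy(table: ContingencyTable) -> float | None:
    """CBA; None when a needed denominator is zero."""
    d1 = min(table.tp + table.fn, table.tp + table.fp)
    d2 = min(table.tn + table.fp, table.tn + table.fn)
    if d1 == 0 or d2 == 0:
        return None
    return 0.5 * (table.tp / d1 + table.tn / d2)


def odds_ratio(table: ContingencyTable, continuity_correction: bool = False) -> float | None:
    """(TP*TN)/(FP*FN); None (unavailable/infinite) on a zero off-diagonal.

    With ``continuity_correction`` each cell gets +0.5 (Haldane-Anscombe),
    which keeps the ratio finite.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    if continuity_correction:
        tp, fp, fn, tn = (c + 0.5 for c in (tp, fp, fn, tn))
    if fp * fn == 0:
        return None
    return (tp * tn) / (fp * fn)


def ppv_npv_prevalence(
    table: ContingencyTable,
) -> tuple[float | None, float | None, float]:
    """(PPV, NPV, prevalence of the feature per 1,000 records)."""
    ppv = table.tp / (table.tp + table.fp) if table.tp + table.fp else None
    npv = table.tn / (table.tn + table.fn) if table.tn + table.fn else None
    prevalence = 1000.0 * (table.tp + table.fp) / table.total
    return ppv, npv, prevalence


def evaluation_row(
    feature_id: str,
    table: ContingencyTable,
    use_controlled: bool = True,
    continuity_correction: bool = False,
) -> dict:
    """All Table-style statistics for one binary feature set.

    With ``use_controlled`` (the publication default) the cells pass
    through disclosure control before any calculation; if a cell is
    suppressed every statistic is unavailable (NaN) and the row is
    flagged.
    """
    t: ContingencyTable | None = table.controlled() if use_controlled else table
    row: dict = {
        "feature_id": feature_id,
        "cells_basis": "disclosure_controlled" if use_controlled else "raw",
        "suppressed": t is None,
    }
    if t is None:
        row.update(
            dict.fromkeys(
                ["tp", "fp", "fn", "tn", "prevalence_per_1000", "cba", "odds_ratio",
                 "ppv", "npv"],
                np.nan,
            )
        )
        return row
    ppv, npv, prev = ppv_npv_prevalence(t)
    cba = class_balance_accuracy(t)
    orr = odds_ratio(t, continuity_correction)
    row.update(
        tp=t.tp, fp=t.fp, fn=t.fn, tn=t.tn,
        prevalence_per_1000=prev,
        cba=np.nan if cba is None else cba,
        odds_ratio=np.nan if orr is None else orr,
        ppv=np.nan if ppv is None else ppv,
        npv=np.nan if npv is None else npv,
    )
    return row


def evaluation_table(
    feature_columns: pd.DataFrame,
    caseness: np.ndarray,
    use_controlled: bool = True,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Evaluation statistics for every 0/1 column of ``feature_columns``."""
    y = np.asarray(caseness).astype(bool)
    rows = []
    for col in feature_columns.columns:
        table = ContingencyTable.from_columns(feature_columns[col].to_numpy(), y)
        rows.append(
            evaluation_row(col, table, use_controlled, continuity_correction)
        )
    return pd.DataFrame(rows)
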