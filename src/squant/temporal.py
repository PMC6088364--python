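"""Burstiness and memory of inter-event-interval sequences.

Burstiness  B = (sigma - mu) / (sigma + mu)  with the sample SD and mean of
the IEIs: -1 for a perfectly regular train, 0 for a Poisson process, and
values approaching 1 for bursty trains.  Memory M is the Spearman rank
autocorrelation of the IEI series at lag 1: positive when long intervals
follow long intervals.  Cells are placed in the (B, M) plane per event
class (all/small/large).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["burstiness", "memory", "bm_table"]


def burstiness(ieis) -> float:
    """B = (sigma - mu)/(sigma + mu) of an IEI sequence (sample SD, ddof=1).

    Requires at least two intervals.  B is scale invariant and lies in
    [-1, 1) for any finite positive sequence; a zero-variance sequence gives
    exactly -1 and a Poisson train gives ~0.
    """
    ieis = np.asarray(ieis, dtype=float)
    if ieis.size < 2:
        raise ValueError("burstiness requires at least 2 IEIs")
    if np.any(ieis <= 0):
        raise ValueError("IEIs must be positive")
    if np.ptp(ieis) == 0:  # zero-variance limiting case, exactly -1
        return -1.0
    mu = float(np.mean(ieis))
    sigma = float(np.std(ieis, ddof=1))
    return (sigma - mu) / (sigma + mu)


def memory(ieis) -> float:
    """M = Spearman rank correlation of (IEI_1..IEI_{n-1}) vs (IEI_2..IEI_n).

    Ties are handled with average ranks.  Returns NaN (reported missing)
    when either lagged subsequence is constant, which makes ranks
    degenerate — e.g. a perfectly regular train.
    """
    ieis = np.asarray(ieis, dtype=float)
    if ieis.size < 4:
        raise ValueError("memory requires at least 4 IEIs (3 lag-1 pairs)")
    a, b = ieis[:-1], ieis[1:]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("degenerate (constant) IEI subsequence; memory undefined")
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def bm_table(cells: dict) -> pd.DataFrame:
    """(B, M) points for a collection of cells.

    Parameters
    ----------
    cells : dict
        ``{cell_id: {event_class: iei_sequence}}`` with event classes such
        as ``all``, ``small``, ``large``.

    Returns
    -------
    DataFrame with columns ``cell_id, event_class, n_ieis, b, m``; cells
    whose sequences fail the preconditions are skipped with a warning.
    """
    rows = []
    for cell_id, by_class in cells.items():
        for event_class, ieis in by_class.items():
            ieis = np.asarray(ieis, dtype=float)
            try:
                b = burstiness(ieis)
            except ValueError as exc:
                warnings.warn(f"cell {cell_id}/{event_class} skipped: {exc}")
                continue
            try:
                m = memory(ieis) if ieis.size >= 4 else float("nan")
            except ValueError:
                m = float("nan")
            rows.append(
                {
                    "cell_id": cell_id,
                    "event_class": event_class,
                    "n_ieis": int(ieis.size),
                    "b": b,
                    "m": m,
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "event_class", "n_ieis", "b", "m"])


def bm_group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of B and M per event class."""
    def sem(x):
        x = x.dropna()
        return x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else float("nan")

    return table.groupby("event_class").agg(
        n=("b", "size"),
        b_mean=("b", "mean"),
        b_sem=("b", sem),
        m_mean=("m", "mean"),
        m_sem=("m", sem),
    )
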