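"""Descriptive daily phenotypic correlations between SCS and yield traits.

A data-level (model-free) view of how the SCS-yield relationship changes
over lactation: records are adjusted for their contemporary group, binned
into days-in-milk windows, and the Pearson correlation between SCS and each
yield trait is computed per window.  The adjustment is a design choice --
subtracting the herd-year-month (HYM) group mean per trait -- since shared
management environment would otherwise dominate the raw correlations; a raw
mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotypes import ClassAssignment, DIM_MIN, DIM_MAX

log = logging.getLogger(__name__)

#: Default SCS-yield trait pairs.
DEFAULT_PAIRS = (("scs", "milk"), ("scs", "fat_kg"), ("scs", "protein_kg"))


@dataclass(frozen=True)
class DailyCorrelation:
    """Pearson correlation of one trait pair within one DIM window."""

    dim_lo: float
    dim_hi: float
    pair: tuple[str, str]
    r: float
    n: int


def precorrect(records: pd.DataFrame, classes: ClassAssignment, traits=None) -> pd.DataFrame:
    """Subtract the HYM contemporary-group mean from each trait.

    Adjusted traits have exactly zero mean within every group; a
    single-record group therefore adjusts to zero.
    """
    traits = traits or ["scs", "milk", "fat_kg", "protein_kg"]
    out = records.copy()
    hym = pd.Series(classes.hym, index=out.index)
    for t in traits:
        out[t] = out[t] - out.groupby(hym)[t].transform("mean")
    return out


def daily_correlations(
    records: pd.DataFrame,
    window_days: int = 15,
    pairs=DEFAULT_PAIRS,
    min_n: int = 30,
) -> list[DailyCorrelation]:
    """Windowed Pearson correlations over days in milk.

    Windows of ``window_days`` tile [5, 305].  Windows with fewer than
    ``min_n`` records are suppressed; a window in which either trait is
    constant yields ``r = nan`` (logged).
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    dim = records["dim"].to_numpy(dtype=float)
    edges = np.arange(DIM_MIN, DIM_MAX + window_days, window_days, dtype=float)
    edges[-1] = max(edges[-1], DIM_MAX)
    out: list[DailyCorrelation] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        # half-open windows except the last, so each record lands in one
        mask = (dim >= lo) & ((dim < hi) | ((hi >= DIM_MAX) & (dim <= DIM_MAX)))
        n = int(mask.sum())
        if n < min_n:
            continue
        sub = records.loc[mask]
        for a, b in pairs:
            x = sub[a].to_numpy(dtype=float)
            y = sub[b].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                log.warning("degenerate variance for %s-%s in window [%g, %g)", a, b, lo, hi)
                r = float("nan")
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            out.append(DailyCorrelation(lo, hi, (a, b), r, n))
    return out


def average_daily_correlation(corrs: list[DailyCorrelation]) -> dict[tuple[str, str], float]:
    """Record-count-weighted mean window correlation, per trait pair."""
    if not corrs:
        raise ValueError("no populated windows")
    out: dict[tuple[str, str], float] = {}
    for pair in {c.pair for c in corrs}:
        sub = [c for c in corrs if c.pair == pair and np.isfinite(c.r)]
        if not sub:
            continue
        w = np.array([c.n for c in sub], dtype=float)
        r = np.array([c.r for c in sub])
        out[pair] = float(np.sum(w * r) / np.sum(w))
    return out


def correlation_table(corrs: list[DailyCorrelation]) -> pd.DataFrame:
    """Delimited-text-ready table: window bounds, pair, r, n."""
    return pd.DataFrame(
        {
            "dim_lo": [c.dim_lo for c in corrs],
            "dim_hi": [c.dim_hi for c in corrs],
            "pair": ["-".join(c.pair) for c in corrs],
            "r": [c.r for c in corrs],
            "n": [c.n for c in corrs],
        }
    )
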