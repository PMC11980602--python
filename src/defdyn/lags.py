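"""Time-shift correlation between defense-system and phage abundance.

For monthly series of total DS abundance and total phage abundance, the
table of Pearson correlations over shifted windows identifies the lag at
which the DS response best tracks phage fluctuations.  The public sign
convention is ``lag_of_ds``: the number of months the DS series trails
the phage series, positive when DS follows phage (phage(t) is correlated
with DS(t + lag_of_ds)).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, InputError

log = logging.getLogger(__name__)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("series must have equal length")
    if len(x) < 3:
        raise InputError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("correlation undefined for a constant series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def time_shift_correlation(ds_total, phage_total,
                           max_shift: int) -> pd.DataFrame:
    """Correlate phage(t) with DS(t + lag) for lag in [-max_shift, max_shift].

    Positive ``lag_of_ds`` means the DS series is taken later in time than
    the phage series (DS trails phage).  Rows with fewer than 3
    overlapping points or a constant window are omitted with a warning.
    """
    ds = np.asarray(ds_total, dtype=float)
    ph = np.asarray(phage_total, dtype=float)
    if ds.shape != ph.shape:
        raise InputError("series must be aligned and of equal length")
    n = len(ds)
    if max_shift >= n / 2:
        raise InputError(f"max_shift must be < length/2 ({max_shift} >= {n / 2})")
    rows = []
    for lag in range(-max_shift, max_shift + 1):
        if lag >= 0:
            x, y = ph[:n - lag] if lag else ph, ds[lag:]
        else:
            x, y = ph[-lag:], ds[:n + lag]
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            log.warning("shift %d skipped: insufficient overlap or "
                        "constant window", lag)
            continue
        r, p = pearson(x, y)
        rows.append((lag, r, len(x), p))
    return pd.DataFrame(rows, columns=["lag_of_ds", "r", "n_overlap", "p"])


def best_lag(table: pd.DataFrame) -> int:
    """Shift with maximal r; exact ties broken toward zero."""
    if table.empty:
        raise InputError("empty shift-correlation table")
    ranked = sorted(table.itertuples(index=False),
                    key=lambda row: (-row.r, abs(row.lag_of_ds),
                                     row.lag_of_ds))
    return int(ranked[0].lag_of_ds)


def env_correlations(ds_total, env: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson of DS abundance vs each environmental
    variable, with Benjamini-Hochberg q-values alongside the raw p."""
    ds = np.asarray(ds_total, dtype=float)
    if len(ds) != len(env):
        raise InputError("env table must be aligned to the DS series")
    rows = []
    for var in env.columns:
        vals = env[var].to_numpy(dtype=float)
        ok = ~(np.isnan(vals) | np.isnan(ds))
        if ok.sum() < 3:
            log.warning("variable '%s' skipped: <3 complete pairs", var)
            continue
        if np.ptp(vals[ok]) == 0 or np.ptp(ds[ok]) == 0:
            log.warning("variable '%s' skipped: constant series", var)
            continue
        r, p = pearson(ds[ok], vals[ok])
        rows.append((var, r, p, int(ok.sum())))
    out = pd.DataFrame(rows, columns=["variable", "r", "p", "n"])
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    return out.sort_values("r", ascending=False).reset_index(drop=True)
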