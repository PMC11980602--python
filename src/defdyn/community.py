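"""Community temporal dynamics: similarity decay and core/unique species.

Bray-Curtis similarity (1 - dissimilarity) between all sample pairs is
tabulated against the time lag in months between the pair; a stable
community keeps high similarity at every lag while a high-turnover one
decays with lag.  Species are classified as *core* (yearly mean relative
abundance above a threshold in every year), *unique* (above the threshold
in exactly one year) or *other*.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .errors import AnalysisError, InputError


def bray_curtis_similarity(x, y) -> float:
    """1 - sum|x_i - y_i| / sum(x_i + y_i); symmetric, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("vectors must have the same length")
    if (x < 0).any() or (y < 0).any():
        raise InputError("abundance vectors must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise AnalysisError(
            "Bray-Curtis similarity undefined: both vectors are all-zero")
    return float(1.0 - braycurtis(x, y))


def _normalize_rows(m: pd.DataFrame) -> pd.DataFrame:
    sums = m.sum(axis=1)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise InputError(f"sample '{bad}' has zero total abundance")
    return m.div(sums, axis=0)


def lag_similarity_curve(m: pd.DataFrame, timeline: pd.DataFrame
                         ) -> pd.DataFrame:
    """Bray-Curtis similarity of all unordered sample pairs vs month lag.

    Rows are (sample_a, sample_b, lag_months, bray_curtis_similarity), one
    per unordered pair (n(n-1)/2 rows); abundances are row-normalized
    before comparison so RPKM and relative tables are treated alike.
    """
    missing = [s for s in m.index if s not in timeline.index]
    if missing:
        raise InputError(f"sample '{missing[0]}' missing from timeline")
    rel = _normalize_rows(m)
    months = timeline["month_index"]
    rows = []
    for a, b in combinations(m.index, 2):
        lag = int(abs(months[a] - months[b]))
        sim = bray_curtis_similarity(rel.loc[a].to_numpy(),
                                     rel.loc[b].to_numpy())
        rows.append((a, b, lag, sim))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "lag_months",
                                       "bray_curtis_similarity"])


def classify_core_unique(m: pd.DataFrame, timeline: pd.DataFrame,
                         threshold: float = 0.001) -> pd.DataFrame:
    """Core/unique/other classification from per-year mean relative abundance.

    A species is *core* if its yearly mean relative abundance strictly
    exceeds ``threshold`` in every calendar year spanned by the timeline,
    *unique* if it exceeds it in exactly one year, *other* otherwise.
    Returns a table indexed by species with per-year means and a label.
    """
    missing = [s for s in m.index if s not in timeline.index]
    if missing:
        raise InputError(f"sample '{missing[0]}' missing from timeline")
    rel = _normalize_rows(m)
    years = timeline.loc[rel.index, "date"].astype(str).str[:4].astype(int)
    if years.nunique() < 2:
        raise InputError("timeline must span at least 2 calendar years")
    yearly = rel.groupby(years).mean()  # years x species
    exceeds = yearly > threshold
    n_years_above = exceeds.sum(axis=0)
    label = pd.Series("other", index=m.columns, name="label")
    label[n_years_above == len(yearly)] = "core"
    label[n_years_above == 1] = "unique"
    out = yearly.T
    out.columns = [f"year_{y}" for y in yearly.index]
    out.index.name = "species"
    out["label"] = label
    return out
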