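"""Pan-immunity analysis of near-identical genomes.

MAGs are clustered at ANI >= 95% (single-linkage connected components,
the species-level convention), and the defense-system composition of
every qualifying within-threshold pair is compared by the symmetric
difference of their DS subtype sets.  Pairs in which either MAG carries
no DS are excluded.  The headline summaries are the fraction of pairs
with identical DS composition and the fraction differing in three or
more DSs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)


@dataclass
class MAGPanel:
    """DS subtype sets per MAG plus their pairwise ANI table."""
    ds_sets: dict[str, frozenset[str]]
    ani: pd.DataFrame  # columns mag_a, mag_b, ani (percent)
    clusters: dict[str, str] = field(default_factory=dict)


def cluster_mags(ani: pd.DataFrame, threshold: float = 95.0,
                 mag_ids=None, symmetry_tol: float = 0.5) -> dict[str, str]:
    """Single-linkage ANI clustering: connected components of the graph
    with an edge wherever ANI >= threshold.

    Cluster labels are deterministic (the smallest member ID).  If the
    table lists both orientations of a pair, they must agree within
    ``symmetry_tol`` percent.
    """
    seen: dict[tuple[str, str], float] = {}
    nodes = set(mag_ids) if mag_ids is not None else set()
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # keep the lexicographically smaller root for determinism
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    for row in ani.itertuples(index=False):
        a, b, val = str(row.mag_a), str(row.mag_b), float(row.ani)
        if not (0.0 <= val <= 100.0):
            raise InputError(f"ANI out of range for pair ({a}, {b}): {val}")
        nodes.update((a, b))
        key = (a, b) if a <= b else (b, a)
        if key in seen and abs(seen[key] - val) > symmetry_tol:
            raise InputError(
                f"asymmetric ANI for pair {key}: {seen[key]} vs {val}")
        seen[key] = val
    for n in sorted(nodes):
        parent[n] = n
    for (a, b), val in sorted(seen.items()):
        if val >= threshold:
            union(a, b)
    return {n: find(n) for n in sorted(nodes)}


def ds_difference(set_a, set_b) -> int:
    """Number of DSs differing between two genomes: |A symmetric-diff B|."""
    return len(frozenset(set_a) ^ frozenset(set_b))


def _subtype_to_type(subtype: str) -> str:
    return subtype.rsplit("_", 1)[0] if "_" in subtype else subtype


def pair_difference_distribution(panel: MAGPanel, threshold: float = 95.0,
                                 level: str = "subtype") -> tuple[pd.DataFrame,
                                                                  dict]:
    """DS differences across all ANI >= threshold MAG pairs.

    Pairs where either MAG carries no DS are excluded.  ``level`` counts
    differences over subtype sets (default) or over type sets (subtypes
    collapsed by their type prefix).  Returns the per-pair table and a
    summary with the 0-difference and >=3-difference fractions.
    """
    if level not in ("subtype", "type"):
        raise InputError(f"unknown level '{level}'")

    def effective(mag: str) -> frozenset[str]:
        s = panel.ds_sets.get(mag, frozenset())
        if level == "type":
            return frozenset(_subtype_to_type(x) for x in s)
        return frozenset(s)

    rows = []
    for row in panel.ani.itertuples(index=False):
        a, b, val = str(row.mag_a), str(row.mag_b), float(row.ani)
        if val < threshold:
            continue
        sa, sb = panel.ds_sets.get(a, frozenset()), panel.ds_sets.get(b, frozenset())
        if not sa or not sb:
            continue
        rows.append((a, b, val, ds_difference(effective(a), effective(b))))
    table = pd.DataFrame(rows, columns=["mag_a", "mag_b", "ani", "n_ds_diff"])
    if table.empty:
        log.warning("no qualifying MAG pairs at ANI >= %s", threshold)
        summary = {"n_pairs": 0, "fraction_zero_diff": float("nan"),
                   "fraction_ge3_diff": float("nan")}
        return table, summary
    summary = {
        "n_pairs": int(len(table)),
        "fraction_zero_diff": float((table["n_ds_diff"] == 0).mean()),
        "fraction_ge3_diff": float((table["n_ds_diff"] >= 3).mean()),
    }
    return table, summary
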