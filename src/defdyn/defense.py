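"""Defense-system (DS) quantification.

Only *complete* DSs (all required components on one carrier) count.  The
abundance of a DS type in a sample is the summed abundance (RPKM) of the
contigs carrying at least one complete DS of that type; a contig carrying
two different types contributes its full abundance to both types, while
the total-DS series counts each DS-carrying contig once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["carrier_id", "ds_type", "ds_subtype", "is_complete",
                      "n_orfs"]


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise InputError(f"annotation table is missing columns: {missing}")
    if ann["is_complete"].isna().any():
        raise InputError("is_complete must be defined for every annotation row")
    return ann


def filter_complete(ann: pd.DataFrame) -> pd.DataFrame:
    """Keep only annotations of complete defense systems."""
    validate_annotations(ann)
    return ann[ann["is_complete"].astype(bool)].reset_index(drop=True)


@dataclass
class DSAbundanceSeries:
    """Per-type DS abundance matrix plus the per-contig-once total series."""
    per_type: pd.DataFrame  # samples x DS types
    total: pd.Series        # per-sample abundance of DS-carrying contigs


def ds_abundance_series(ann: pd.DataFrame, contig_abundance: pd.DataFrame
                        ) -> DSAbundanceSeries:
    """DS-type abundance = summed abundance of complete-DS-carrying contigs.

    Contigs annotated but absent from the abundance table are skipped with
    a warning.  A contig with two complete DSs of the same type contributes
    once to that type; a contig with two different types contributes fully
    to each, but only once to the total.
    """
    complete = filter_complete(ann)
    if complete.empty:
        log.warning("no complete DS annotations; returning empty series")
        return DSAbundanceSeries(
            per_type=pd.DataFrame(index=contig_abundance.index),
            total=pd.Series(0.0, index=contig_abundance.index, name="total_ds"))
    known = set(contig_abundance.columns)
    missing = sorted(set(complete["carrier_id"]) - known)
    if missing:
        log.warning("skipping %d annotated contig(s) absent from the "
                    "abundance table: %s", len(missing), missing[:5])
        complete = complete[complete["carrier_id"].isin(known)]
    pairs = complete[["carrier_id", "ds_type"]].drop_duplicates()
    types = sorted(pairs["ds_type"].unique())
    per_type = pd.DataFrame(0.0, index=contig_abundance.index, columns=types)
    for ds_type, group in pairs.groupby("ds_type"):
        per_type[ds_type] = contig_abundance[group["carrier_id"]].sum(axis=1)
    carriers = sorted(pairs["carrier_id"].unique())
    total = contig_abundance[carriers].sum(axis=1)
    total.name = "total_ds"
    return DSAbundanceSeries(per_type=per_type, total=total)


def mag_ds_stats(ann: pd.DataFrame, mag_ids: list[str],
                 clusters: dict[str, str] | None = None) -> dict:
    """Per-MAG complete-DS counts and panel-level summaries.

    Returns fraction of MAGs carrying >= 1 complete DS, the mean DS count,
    a histogram of counts, and per-cluster mean +- sd when cluster labels
    are supplied.
    """
    complete = filter_complete(ann)
    counts = pd.Series(0, index=pd.Index(sorted(mag_ids), name="mag_id"))
    observed = complete[complete["carrier_id"].isin(counts.index)]
    per_mag = observed.groupby("carrier_id").size()
    counts.loc[per_mag.index] = per_mag
    summary = {
        "per_mag_counts": counts,
        "fraction_with_ds": float((counts >= 1).mean()) if len(counts) else 0.0,
        "mean_ds_per_mag": float(counts.mean()) if len(counts) else 0.0,
        "histogram": counts.value_counts().sort_index().to_dict(),
    }
    if clusters is not None:
        labels = counts.index.map(clusters)
        grouped = counts.groupby(labels)
        summary["per_cluster"] = pd.DataFrame(
            {"mean": grouped.mean(), "sd": grouped.std(ddof=1),
             "n": grouped.size()})
    return summary
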