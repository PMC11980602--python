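"""CRISPR spacer repertoire statistics.

Spacers are dereplicated at 100% identity and 100% coverage of the
shorter sequence (exact duplicates and perfect substrings collapse into
the longest representative).  A spacer targets a vOTU if it aligns
full-length, ungapped, on either strand with at most one mismatch and at
least 95% identity (for spacers shorter than 20 nt a single mismatch
already violates 95%, so only exact matches qualify).  Repertoire
turnover is summarized by the retention ratio: the fraction of an earlier
sample's spacers still present in a later sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError, InputError
from .simulate import SpacerRepertoire

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_acgt(seq: str, label: str) -> None:
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise InputError(f"{label}: non-ACGT character(s) {bad}")


def dereplicate_spacers(seqs) -> set[str]:
    """Collapse duplicates and perfect substrings of longer spacers.

    The representative of a collapsed group is the longest sequence (ties
    broken lexicographically); deterministic and idempotent.
    """
    unique = set()
    for i, s in enumerate(seqs):
        _check_acgt(s, f"spacer record {i} ({s[:12]}...)")
        unique.add(s)
    kept: list[str] = []
    for s in sorted(unique, key=lambda x: (-len(x), x)):
        if not any(s in longer for longer in kept):
            kept.append(s)
    return set(kept)


def spacer_density(n_unique_spacers: int, total_reads: int) -> float:
    """Unique spacers per million reads."""
    if total_reads <= 0:
        raise InputError(f"total_reads must be positive (got {total_reads})")
    return n_unique_spacers / (total_reads / 1e6)


@dataclass(frozen=True)
class TargetHit:
    spacer: str
    votu_id: str
    mismatches: int
    strand: str   # '+' or '-'
    position: int  # 0-based start on the vOTU forward strand


def _allowed_mismatches(length: int, max_mismatches: int,
                        min_identity: float) -> int:
    # identity (L - m)/L * 100 >= min_identity  =>  m <= L*(1 - id/100)
    return min(max_mismatches, floor(length * (1.0 - min_identity / 100.0)
                                     + 1e-9))


class VotuWindowIndex:
    """Exact-match index of every length-L window of a vOTU sequence set.

    Built lazily per spacer length; lets spacer matching run as O(1)
    dictionary lookups (1-mismatch hits are found by enumerating the 3L
    single-substitution variants of the query).
    """

    def __init__(self, votus: dict[str, str]):
        for name, seq in votus.items():
            _check_acgt(seq, f"vOTU {name}")
        self.votus = votus
        self._by_len: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def windows(self, length: int) -> dict[str, list[tuple[str, int]]]:
        if length not in self._by_len:
            index: dict[str, list[tuple[str, int]]] = {}
            for vid in sorted(self.votus):
                seq = self.votus[vid]
                for pos in range(len(seq) - length + 1):
                    index.setdefault(seq[pos:pos + length], []).append(
                        (vid, pos))
            self._by_len[length] = index
        return self._by_len[length]


def _one_mismatch_variants(seq: str):
    for pos, base in enumerate(seq):
        for alt in "ACGT":
            if alt != base:
                yield seq[:pos] + alt + seq[pos + 1:]


def match_spacers(repertoire, votus: dict[str, str],
                  max_mismatches: int = 1,
                  min_identity: float = 95.0,
                  index: VotuWindowIndex | None = None) -> list[TargetHit]:
    """Full-length ungapped matches of each spacer (either strand) to vOTUs.

    ``repertoire`` is an iterable of spacer sequences or a
    :class:`SpacerRepertoire`.  All qualifying hit positions are reported;
    positions refer to the vOTU forward strand.  A prebuilt
    :class:`VotuWindowIndex` can be supplied to amortize indexing across
    many repertoires.
    """
    if max_mismatches > 1:
        raise InputError("max_mismatches > 1 is not supported "
                         "(spacer-protospacer matching allows at most 1)")
    if isinstance(repertoire, SpacerRepertoire):
        spacers = sorted(repertoire.spacers)
    else:
        spacers = sorted(set(repertoire))
    if index is None:
        index = VotuWindowIndex(votus)
    hits: list[TargetHit] = []
    for spacer in spacers:
        _check_acgt(spacer, f"spacer {spacer[:12]}...")
        L = len(spacer)
        allowed = _allowed_mismatches(L, max_mismatches, min_identity)
        windows = index.windows(L)
        for qseq, strand in ((spacer, "+"), (reverse_complement(spacer), "-")):
            for vid, pos in windows.get(qseq, ()):
                hits.append(TargetHit(spacer, vid, 0, strand, pos))
            if allowed >= 1:
                for variant in _one_mismatch_variants(qseq):
                    for vid, pos in windows.get(variant, ()):
                        hits.append(TargetHit(spacer, vid, 1, strand, pos))
    hits.sort(key=lambda h: (h.spacer, h.votu_id, h.position, h.strand,
                             h.mismatches))
    return hits


def retention_ratio(rep_i: SpacerRepertoire, rep_j: SpacerRepertoire) -> float:
    """Fraction of the earlier repertoire still present in the later one."""
    earlier = set(rep_i.spacers)
    if not earlier:
        raise AnalysisError(
            f"retention undefined: earlier repertoire '{rep_i.sample_id}' "
            "is empty")
    return len(earlier & set(rep_j.spacers)) / len(earlier)


def retention_lag_curve(reps: list[SpacerRepertoire],
                        timeline: pd.DataFrame) -> pd.DataFrame:
    """Retention ratio of every ordered earlier->later repertoire pair.

    Emits the forward ratio (earlier-repertoire denominator) and, for
    transparency, the reverse ratio with the later repertoire as
    denominator.
    """
    if len(reps) < 2:
        raise InputError("need at least 2 repertoires")
    months = timeline["month_index"]
    ordered = sorted(reps, key=lambda r: months[r.sample_id])
    rows = []
    for i, ri in enumerate(ordered):
        for rj in ordered[i + 1:]:
            lag = int(months[rj.sample_id] - months[ri.sample_id])
            shared = len(set(ri.spacers) & set(rj.spacers))
            fwd = shared / len(ri.spacers) if ri.spacers else np.nan
            rev = shared / len(rj.spacers) if rj.spacers else np.nan
            rows.append((ri.sample_id, rj.sample_id, lag, fwd, rev))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "lag_months",
                                       "retention", "retention_rev"])


def targeting_rate(votu_ids, hits: list[TargetHit]) -> float:
    """Fraction of vOTUs with at least one spacer hit."""
    votu_ids = list(votu_ids)
    if not votu_ids:
        raise InputError("empty vOTU set")
    targeted = {h.votu_id for h in hits}
    return sum(1 for v in votu_ids if v in targeted) / len(votu_ids)


DEFAULT_BINS = [(0.0, 0.5), (0.5, 1.0), (1.0, 2.0), (2.0, 4.0),
                (4.0, float("inf"))]


def _bin_label(lo: float, hi: float) -> str:
    return f"({lo}, {hi}]" if np.isfinite(hi) else f"> {lo}"


def cooccurrence_by_bin(phages: pd.DataFrame,
                        hits_per_sample: dict[str, set[str]],
                        bins=None) -> pd.DataFrame:
    """Spacer/vOTU co-occurrence frequency per vOTU-abundance bin.

    Each (vOTU, sample) observation with abundance > 0 falls in exactly one
    bin (first bin closed at its lower edge, others half-open (lo, hi]);
    the observation co-occurs if that sample's repertoire has >= 1 target
    hit on the vOTU.  Frequency per bin is the mean over its observations.
    """
    if bins is None:
        bins = DEFAULT_BINS
    for (lo, hi), (lo2, _hi2) in zip(bins, bins[1:]):
        if lo >= hi or hi != lo2:
            raise ConfigError(
                "bins: must be disjoint, ordered and contiguous "
                f"(offending pair ({lo}, {hi}) / ({lo2}, ...))")
    if bins[0][0] != 0.0 or np.isfinite(bins[-1][1]):
        raise ConfigError("bins: must cover [0, inf)")
    edges = [hi for _lo, hi in bins[:-1]]
    n_obs = np.zeros(len(bins), dtype=int)
    n_co = np.zeros(len(bins), dtype=int)
    for sample in phages.index:
        targeted = hits_per_sample.get(sample, set())
        row = phages.loc[sample]
        for votu, ab in row.items():
            if ab <= 0:
                continue
            b = int(np.searchsorted(edges, ab, side="left"))
            n_obs[b] += 1
            if votu in targeted:
                n_co[b] += 1
    freq = np.where(n_obs > 0, n_co / np.maximum(n_obs, 1), np.nan)
    return pd.DataFrame({
        "bin": [_bin_label(lo, hi) for lo, hi in bins],
        "bin_low": [lo for lo, _ in bins],
        "bin_high": [hi for _, hi in bins],
        "n_obs": n_obs,
        "frequency": freq,
    })


def hits_by_sample(reps: list[SpacerRepertoire], votus: dict[str, str],
                   **kwargs) -> dict[str, set[str]]:
    """Map each sample to the set of vOTUs its repertoire targets."""
    index = VotuWindowIndex(votus)
    out = {}
    for rep in reps:
        hits = match_spacers(rep, votus, index=index, **kwargs)
        out[rep.sample_id] = {h.votu_id for h in hits}
    return out
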