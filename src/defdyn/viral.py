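"""Viral-contig screening, quality filtering, vOTU clustering and RPKM.

The acceptance cascade combines two virus-prediction scores: a primary
score in [0, 1] (VirSorter2-style), a hallmark-gene flag, and a secondary
confirmation flag (VIBRANT-style).  A contig of at least ``min_len`` bp is
accepted if

* primary score >= 0.9, or
* primary score >= 0.7 and it carries a hallmark gene, or
* primary score >= 0.5 and the secondary tool confirms it.

Quality filtering keeps contigs with completeness >= 50% whose gene
content satisfies ``viral_genes - 5 * host_genes > 0`` (strict).  Accepted
contigs are clustered into species-level vOTUs greedily, longest first, at
>= 95% identity and >= 85% alignment coverage of the shorter sequence.
Abundances are reads per kilobase per million mapped reads (RPKM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

REQUIRED_COLUMNS = ["contig_id", "length_bp", "score_primary", "has_hallmark",
                    "validated_secondary", "completeness_pct", "viral_genes",
                    "host_genes"]


@dataclass(frozen=True)
class ViralContigRecord:
    contig_id: str
    length_bp: int
    score_primary: float
    has_hallmark: bool
    validated_secondary: bool
    completeness_pct: float
    viral_genes: int
    host_genes: int

    def validate(self) -> None:
        if self.length_bp < 0:
            raise InputError(f"{self.contig_id}: negative length_bp")
        if not (0.0 <= self.score_primary <= 1.0):
            raise InputError(f"{self.contig_id}: score_primary outside [0, 1]")
        if not (0.0 <= self.completeness_pct <= 100.0):
            raise InputError(
                f"{self.contig_id}: completeness_pct outside [0, 100]")
        if self.viral_genes < 0 or self.host_genes < 0:
            raise InputError(f"{self.contig_id}: negative gene count")


def records_from_table(df: pd.DataFrame) -> list[ViralContigRecord]:
    """Build validated records from a contig feature table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"contig table is missing columns: {missing}")
    recs = []
    for row in df.itertuples(index=False):
        rec = ViralContigRecord(
            contig_id=str(row.contig_id), length_bp=int(row.length_bp),
            score_primary=float(row.score_primary),
            has_hallmark=bool(row.has_hallmark),
            validated_secondary=bool(row.validated_secondary),
            completeness_pct=float(row.completeness_pct),
            viral_genes=int(row.viral_genes), host_genes=int(row.host_genes))
        rec.validate()
        recs.append(rec)
    return recs


def screen_candidates(records: list[ViralContigRecord],
                      min_len: int = 5000,
                      score_high: float = 0.9,
                      score_hallmark: float = 0.7,
                      score_validated: float = 0.5) -> set[str]:
    """Apply the three-branch acceptance cascade; all thresholds inclusive."""
    accepted = set()
    for rec in records:
        rec.validate()
        if rec.length_bp < min_len:
            continue
        if (rec.score_primary >= score_high
                or (rec.score_primary >= score_hallmark and rec.has_hallmark)
                or (rec.score_primary >= score_validated
                    and rec.validated_secondary)):
            accepted.add(rec.contig_id)
    return accepted


def quality_filter(records: list[ViralContigRecord],
                   min_completeness: float = 50.0,
                   host_gene_factor: int = 5) -> set[str]:
    """Completeness >= 50% and viral_genes - 5*host_genes strictly positive."""
    return {rec.contig_id for rec in records
            if rec.completeness_pct >= min_completeness
            and rec.viral_genes - host_gene_factor * rec.host_genes > 0}


@dataclass
class VOTUCluster:
    representative_id: str
    member_ids: list[str]
    identity_to_rep: dict[str, float]


def cluster_votus(identities: pd.DataFrame, lengths: dict[str, int],
                  min_identity: float = 95.0,
                  min_coverage: float = 85.0) -> list[VOTUCluster]:
    """Greedy longest-first clustering with CD-HIT semantics.

    ``identities`` has columns id_a, id_b, identity, coverage_shorter
    (percent, symmetric or symmetrizable).  Sequences are visited longest
    first (ties by ID); each joins the first representative it matches at
    >= ``min_identity`` identity and >= ``min_coverage`` coverage of the
    shorter sequence, else founds a new cluster.
    """
    pair: dict[tuple[str, str], tuple[float, float]] = {}
    ids_seen = set()
    for row in identities.itertuples(index=False):
        a, b = str(row.id_a), str(row.id_b)
        ids_seen.update((a, b))
        key = (a, b) if a <= b else (b, a)
        pair[key] = (float(row.identity), float(row.coverage_shorter))
    for i in ids_seen:
        if i not in lengths:
            raise InputError(f"no length provided for sequence '{i}'")
    order = sorted(lengths, key=lambda i: (-lengths[i], i))
    clusters: list[VOTUCluster] = []
    for seq_id in order:
        placed = False
        for cl in clusters:
            rep = cl.representative_id
            key = (seq_id, rep) if seq_id <= rep else (rep, seq_id)
            if key not in pair:
                continue
            ident, cov = pair[key]
            if ident >= min_identity and cov >= min_coverage:
                cl.member_ids.append(seq_id)
                cl.identity_to_rep[seq_id] = ident
                placed = True
                break
        if not placed:
            clusters.append(VOTUCluster(representative_id=seq_id,
                                        member_ids=[seq_id],
                                        identity_to_rep={seq_id: 100.0}))
    return clusters


def cluster_labels(clusters: list[VOTUCluster]) -> dict[str, str]:
    """Map each member to its representative's ID."""
    return {m: cl.representative_id for cl in clusters for m in cl.member_ids}


def identity_table_from_fasta(seqs: dict[str, str]) -> pd.DataFrame:
    """Approximate pairwise identity/coverage from sequences (toy inputs).

    Aligns the shorter sequence into the longer one (infix edit-distance
    alignment via edlib); identity is reported relative to the shorter
    sequence and coverage of the shorter is taken as 100%.  Intended for
    small test inputs, not production-scale dereplication.
    """
    import edlib

    ids = sorted(seqs)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            short, long_ = (a, b) if len(seqs[a]) <= len(seqs[b]) else (b, a)
            res = edlib.align(seqs[short], seqs[long_], mode="HW", task="distance")
            ident = 100.0 * (1.0 - res["editDistance"] / len(seqs[short]))
            rows.append((a, b, max(ident, 0.0), 100.0))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "identity",
                                       "coverage_shorter"])


def compute_rpkm(counts: pd.DataFrame, totals: pd.Series,
                 lengths: dict[str, int]) -> pd.DataFrame:
    """RPKM[s, c] = count[s, c] / (length_c / 1e3) / (total_s / 1e6)."""
    for cid in counts.columns:
        if cid not in lengths:
            raise InputError(f"no length provided for contig '{cid}'")
        if lengths[cid] <= 0:
            raise InputError(f"non-positive length for contig '{cid}'")
    for sample in counts.index:
        if sample not in totals.index:
            raise InputError(f"no total read count for sample '{sample}'")
        if totals[sample] <= 0:
            raise InputError(f"zero total mapped reads in sample '{sample}'")
    kb = np.array([lengths[c] / 1e3 for c in counts.columns])
    per_million = totals.loc[counts.index].to_numpy(dtype=float) / 1e6
    rpkm = counts.to_numpy(dtype=float) / kb[None, :] / per_million[:, None]
    return pd.DataFrame(rpkm, index=counts.index, columns=counts.columns)
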