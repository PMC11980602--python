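"""Screen viral contigs, cluster them into vOTUs, and compute RPKM.

Applies the two-tool acceptance cascade (primary score >= 0.9, or >= 0.7
with hallmark genes, or >= 0.5 with secondary confirmation; contigs
>= 5 kb), the completeness/gene-content quality filter, then greedy
longest-first clustering at 95% identity / 85% coverage of the shorter
sequence.
"""

import os

import pandas as pd

from defdyn import io as dio
from defdyn import viral

SIM = "results/sim"
OUT = "results/viral"


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    features = dio.read_table_tsv(f"{SIM}/contigs.tsv")
    records = viral.records_from_table(features)
    screened = viral.screen_candidates(records)
    high = screened & viral.quality_filter(
        [r for r in records if r.contig_id in screened])
    print(f"{len(records)} contigs -> {len(screened)} pass the cascade -> "
          f"{len(high)} high-confidence viral contigs")

    lengths = dict(zip(features["contig_id"], features["length_bp"]))
    identity = dio.read_table_tsv(f"{SIM}/votu_identity.tsv")
    keep = identity["id_a"].isin(high) & identity["id_b"].isin(high)
    clusters = viral.cluster_votus(identity[keep],
                                   {c: lengths[c] for c in sorted(high)})
    print(f"{len(high)} contigs cluster into {len(clusters)} vOTUs")

    counts = dio.read_abundance_tsv(f"{SIM}/contig_counts.tsv")
    totals = dio.read_table_tsv(f"{SIM}/contig_totals.tsv") \
        .set_index("sample_id")["total_reads"]
    rpkm = viral.compute_rpkm(counts[sorted(high)], totals, lengths)

    dio.write_table_tsv(pd.DataFrame({"contig_id": sorted(high)}),
                        f"{OUT}/accepted_contigs.tsv")
    dio.write_table_tsv(
        pd.DataFrame([(c.representative_id, m, c.identity_to_rep[m])
                      for c in clusters for m in c.member_ids],
                     columns=["representative_id", "member_id",
                              "identity_to_rep"]),
        f"{OUT}/votu_clusters.tsv")
    dio.write_abundance_tsv(rpkm, f"{OUT}/contig_rpkm.tsv")
    print(f"outputs -> {OUT}/")


if __name__ == "__main__":
    main()
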