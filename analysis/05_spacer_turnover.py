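"""CRISPR spacer turnover and protospacer targeting.

Dereplicates each sample's spacers, maps them to vOTU sequences
(full-length, both strands, at most one mismatch at >= 95% identity),
and summarizes repertoire turnover: retention ratio vs lag, spacer
density, targeting rate, and co-occurrence frequency by vOTU abundance
bin.
"""

import glob
import os

import pandas as pd

from defdyn import io as dio, spacers
from defdyn.simulate import SpacerRepertoire

SIM = "results/sim"
OUT = "results/spacers"


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    timeline = dio.read_timeline_tsv(f"{SIM}/timeline.tsv")
    phages = dio.read_abundance_tsv(f"{SIM}/phages.tsv")
    votus = dio.read_fasta(f"{SIM}/votus.fasta")
    reads = dio.read_table_tsv(f"{SIM}/spacer_reads.tsv") \
        .set_index("sample_id")["total_reads"]

    reps = []
    for path in sorted(glob.glob(f"{SIM}/spacers_*.fasta")):
        sample = os.path.basename(path)[len("spacers_"):-len(".fasta")]
        unique = spacers.dereplicate_spacers(dio.read_fasta(path).values())
        reps.append(SpacerRepertoire(sample, frozenset(unique),
                                     int(reads[sample])))
    print(f"{len(reps)} monthly repertoires, "
          f"median size {int(pd.Series([len(r.spacers) for r in reps]).median())}")

    retention = spacers.retention_lag_curve(reps, timeline)
    lag1 = retention.loc[retention.lag_months == 1, "retention"].dropna()
    print(f"mean lag-1 retention ratio: {lag1.mean():.3f} "
          "(rapid repertoire turnover)")

    index = spacers.VotuWindowIndex(votus)
    hits_per_sample = {}
    all_hits = []
    for rep in reps:
        hits = spacers.match_spacers(rep, votus, index=index)
        hits_per_sample[rep.sample_id] = {h.votu_id for h in hits}
        all_hits.extend(hits)
    rate = spacers.targeting_rate(phages.columns, all_hits)
    print(f"spacers target {100 * rate:.1f}% of vOTUs")

    cooc = spacers.cooccurrence_by_bin(phages, hits_per_sample)
    lo, hi = cooc["frequency"].iloc[0], cooc["frequency"].iloc[-1]
    print(f"co-occurrence frequency rises from {100 * lo:.1f}% in the "
          f"lowest abundance bin to {100 * hi:.1f}% in the highest")

    density = pd.DataFrame(
        {"sample_id": [r.sample_id for r in reps],
         "n_spacers": [len(r.spacers) for r in reps],
         "density_per_million": [
             spacers.spacer_density(len(r.spacers), r.total_reads)
             for r in reps]})

    dio.write_table_tsv(retention, f"{OUT}/retention.tsv")
    dio.write_table_tsv(cooc, f"{OUT}/cooccurrence.tsv")
    dio.write_table_tsv(density, f"{OUT}/density.tsv")
    dio.write_table_tsv(
        pd.DataFrame([(h.spacer, h.votu_id, h.mismatches, h.strand,
                       h.position) for h in all_hits],
                     columns=["spacer", "votu_id", "mismatches", "strand",
                              "position"]),
        f"{OUT}/hits.tsv")
    print(f"outputs -> {OUT}/")


if __name__ == "__main__":
    main()
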