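"""Pan-immunity: do near-identical genomes carry different defenses?

Clusters MAGs at ANI >= 95% (single linkage) and counts defense-system
differences (symmetric difference of DS subtype sets) across every
qualifying MAG pair, excluding MAGs without DSs.
"""

import json
import os

from defdyn import io as dio, panimmunity

SIM = "results/sim"
OUT = "results/pan"


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    mags = dio.read_table_tsv(f"{SIM}/mags_ds.tsv")
    ani = dio.read_table_tsv(f"{SIM}/ani.tsv").rename(
        columns={"ani_percent": "ani"})
    ds_sets = {m: frozenset(g["ds_subtype"]) for m, g in mags.groupby("mag_id")}
    clusters = panimmunity.cluster_mags(ani, mag_ids=ds_sets.keys())
    print(f"{len(clusters)} MAGs form "
          f"{len(set(clusters.values()))} ANI>=95% clusters")

    panel = panimmunity.MAGPanel(ds_sets, ani, clusters)
    pairs, summary = panimmunity.pair_difference_distribution(panel)
    print(f"{summary['n_pairs']} qualifying MAG pairs: "
          f"{100 * summary['fraction_zero_diff']:.1f}% share an identical DS "
          f"composition; {100 * summary['fraction_ge3_diff']:.1f}% differ in "
          "three or more DSs")

    dio.write_table_tsv(pairs, f"{OUT}/mag_pair_differences.tsv")
    with open(f"{OUT}/summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"outputs -> {OUT}/")


if __name__ == "__main__":
    main()
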