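"""Quantify the defense-system response to phage fluctuations.

Builds the DS-type abundance series from complete-DS-carrying contig
RPKM, then asks at which time shift total DS abundance best correlates
with total phage abundance, and which environmental variable tracks DS
abundance after Benjamini-Hochberg correction.
"""

import os

from defdyn import defense, io as dio, lags

SIM = "results/sim"
OUT = "results/lag"


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    ann = dio.read_table_tsv(f"{SIM}/ds_annotations.tsv")
    rpkm = dio.read_abundance_tsv("results/viral/contig_rpkm.tsv")
    series = defense.ds_abundance_series(ann, rpkm)
    dio.write_abundance_tsv(series.per_type, f"{OUT}/ds_type_abundance.tsv")
    print(f"DS abundance series built for {series.per_type.shape[1]} types "
          f"from {len(defense.filter_complete(ann))} complete annotations")

    ds_total = dio.read_abundance_tsv(f"{SIM}/ds.tsv").sum(axis=1)
    phage_total = dio.read_abundance_tsv(f"{SIM}/phages.tsv").sum(axis=1)
    table = lags.time_shift_correlation(ds_total.to_numpy(),
                                        phage_total.to_numpy(), max_shift=6)
    best = lags.best_lag(table)
    r_best = table.set_index("lag_of_ds").loc[best, "r"]
    r0 = table.set_index("lag_of_ds").loc[0, "r"]
    print(f"DS abundance trails phage abundance by {best} month(s): "
          f"r = {r_best:.3f} at the best shift vs r = {r0:.3f} at shift 0")

    env = dio.read_matrix_tsv(f"{SIM}/env.tsv")
    env_table = lags.env_correlations(ds_total.to_numpy(), env)
    top = env_table.iloc[0]
    print(f"top environmental correlate: {top['variable']} "
          f"(r = {top['r']:.3f}, q = {top['q']:.2g})")

    dio.write_table_tsv(table, f"{OUT}/shift_correlation.tsv")
    dio.write_table_tsv(env_table, f"{OUT}/env_correlation.tsv")
    print(f"outputs -> {OUT}/")


if __name__ == "__main__":
    main()
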