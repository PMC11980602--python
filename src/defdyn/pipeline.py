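"""End-to-end pipeline: simulate -> screen -> quantify -> correlate ->
spacer statistics -> pan-immunity.

One YAML config drives all stages; every screening/clustering threshold is
surfaced as a named key with its standard default.  Each TSV output starts
with a ``# defdyn config=<hash>`` metadata line, and a machine-readable
JSON run report records per-stage counts.  Rerunning with the same config
and seed reproduces byte-identical outputs (wall times live only in the
report).
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from . import community, defense, io as dio, lags, panimmunity, spacers, viral
from .config import SimConfig
from .errors import ConfigError, DefdynError
from .simulate import SpacerRepertoire, simulate, write_sim_output

log = logging.getLogger(__name__)

STAGES = ["simulate", "viral_screen", "community_dynamics", "defense_quant",
          "lag_analysis", "spacer_dynamics", "pan_immunity"]

DEFAULT_THRESHOLDS = {
    "vc_score_high": 0.9,
    "vc_score_hallmark": 0.7,
    "vc_score_validated": 0.5,
    "min_contig_len": 5000,
    "checkv_completeness": 50.0,
    "viral_host_gene_factor": 5,
    "votu_identity": 95.0,
    "votu_coverage": 85.0,
    "core_threshold": 0.001,
    "ani_threshold": 95.0,
    "spacer_max_mismatch": 1,
    "spacer_min_identity": 95.0,
    "max_shift": 6,
}


@dataclass
class PipelineConfig:
    out_dir: str = "defdyn_out"
    seed: int = 0
    sim: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        cfg.out_dir = raw.get("out_dir", cfg.out_dir)
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.sim = dict(raw.get("sim", {}))
        cfg.thresholds.update(raw.get("thresholds", {}))
        for stage, flag in raw.get("stages", {}).items():
            if stage not in STAGES:
                raise ConfigError(f"stages: unknown stage '{stage}'")
            cfg.stages[stage] = bool(flag)
        return cfg

    def sim_config(self) -> SimConfig:
        return SimConfig(**self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        return {"out_dir": self.out_dir, "seed": self.seed, "sim": self.sim,
                "thresholds": self.thresholds, "stages": self.stages}

    def hash(self) -> str:
        # out_dir is excluded: the hash identifies the scientific
        # parameters, not where the results land
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    t = config.thresholds
    ranges = {
        "vc_score_high": (0.0, 1.0), "vc_score_hallmark": (0.0, 1.0),
        "vc_score_validated": (0.0, 1.0),
        "checkv_completeness": (0.0, 100.0),
        "votu_identity": (0.0, 100.0), "votu_coverage": (0.0, 100.0),
        "core_threshold": (0.0, 1.0), "ani_threshold": (0.0, 100.0),
        "spacer_min_identity": (0.0, 100.0),
    }
    for key, (lo, hi) in ranges.items():
        val = t.get(key)
        if val is None or not (lo <= float(val) <= hi):
            problems.append(f"{key}: must be within [{lo}, {hi}] (got {val})")
    for key in ("min_contig_len", "viral_host_gene_factor", "max_shift"):
        if int(t.get(key, -1)) < 0:
            problems.append(f"{key}: must be >= 0 (got {t.get(key)})")
    if int(t.get("spacer_max_mismatch", 0)) not in (0, 1):
        problems.append("spacer_max_mismatch: must be 0 or 1 "
                        f"(got {t.get('spacer_max_mismatch')})")
    for stage in config.stages:
        if stage not in STAGES:
            problems.append(f"stages: unknown stage '{stage}'")
    try:
        config.sim_config().validate()
    except (ConfigError, TypeError) as exc:
        problems.append(f"sim: {exc}")
    return problems


class PipelineError(DefdynError):
    """A stage failed or a required input is missing."""


def _require(stage: str, *paths: str) -> None:
    for p in paths:
        if not os.path.exists(p):
            raise PipelineError(f"stage '{stage}': missing input file {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the report."""
    problems = validate_config(config)
    if problems:
        raise ConfigError("invalid pipeline config: " + "; ".join(problems))
    t = config.thresholds
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    header = (f"defdyn config={config.hash()}",)
    sim_dir = os.path.join(out, "sim")
    report: dict = {"software_version": __version__,
                    "config_hash": config.hash(), "seed": config.seed,
                    "stages": {}}
    started = time.time()

    def record(stage: str, **stats) -> None:
        report["stages"][stage] = dict(stats)

    j = os.path.join

    if config.stages.get("simulate", True):
        t0 = time.time()
        sim = simulate(config.sim_config())
        write_sim_output(sim, sim_dir, header)
        record("simulate", n_samples=int(len(sim.timeline)),
               n_bacteria=int(sim.bacteria.shape[1]),
               n_votus=int(sim.phages.shape[1]),
               n_ds_types=int(sim.ds.shape[1]),
               n_mags=int(len(sim.mag_panel.ds_sets)),
               wall_time_s=round(time.time() - t0, 3))

    if config.stages.get("viral_screen", True):
        t0 = time.time()
        _require("viral_screen", j(sim_dir, "contigs.tsv"),
                 j(sim_dir, "contig_counts.tsv"),
                 j(sim_dir, "contig_totals.tsv"),
                 j(sim_dir, "votu_identity.tsv"))
        stage_dir = j(out, "viral_screen")
        os.makedirs(stage_dir, exist_ok=True)
        features = dio.read_table_tsv(j(sim_dir, "contigs.tsv"))
        records = viral.records_from_table(features)
        screened = viral.screen_candidates(
            records, min_len=int(t["min_contig_len"]),
            score_high=t["vc_score_high"],
            score_hallmark=t["vc_score_hallmark"],
            score_validated=t["vc_score_validated"])
        high_conf = screened & viral.quality_filter(
            [r for r in records if r.contig_id in screened],
            min_completeness=t["checkv_completeness"],
            host_gene_factor=int(t["viral_host_gene_factor"]))
        log.info("viral_screen: %d/%d contigs pass the cascade, %d "
                 "high-confidence", len(screened), len(records),
                 len(high_conf))
        lengths = dict(zip(features["contig_id"], features["length_bp"]))
        identity = dio.read_table_tsv(j(sim_dir, "votu_identity.tsv"))
        keep = identity["id_a"].isin(high_conf) & identity["id_b"].isin(high_conf)
        clusters = viral.cluster_votus(
            identity[keep], {c: lengths[c] for c in sorted(high_conf)},
            min_identity=t["votu_identity"], min_coverage=t["votu_coverage"])
        counts = dio.read_abundance_tsv(j(sim_dir, "contig_counts.tsv"))
        totals = dio.read_table_tsv(j(sim_dir, "contig_totals.tsv")) \
            .set_index("sample_id")["total_reads"]
        rpkm = viral.compute_rpkm(counts[sorted(high_conf)], totals, lengths)
        dio.write_table_tsv(
            pd.DataFrame({"contig_id": sorted(high_conf)}),
            j(stage_dir, "accepted_contigs.tsv"), header)
        dio.write_table_tsv(
            pd.DataFrame([(cl.representative_id, m, cl.identity_to_rep[m])
                          for cl in clusters for m in cl.member_ids],
                         columns=["representative_id", "member_id",
                                  "identity_to_rep"]),
            j(stage_dir, "votu_clusters.tsv"), header)
        dio.write_abundance_tsv(rpkm, j(stage_dir, "contig_rpkm.tsv"), header)
        record("viral_screen", n_input=len(records), n_screened=len(screened),
               n_high_confidence=len(high_conf), n_votus=len(clusters),
               wall_time_s=round(time.time() - t0, 3))

    if config.stages.get("community_dynamics", True):
        t0 = time.time()
        _require("community_dynamics", j(sim_dir, "bacteria.tsv"),
                 j(sim_dir, "phages.tsv"), j(sim_dir, "timeline.tsv"))
        stage_dir = j(out, "community_dynamics")
        os.makedirs(stage_dir, exist_ok=True)
        timeline = dio.read_timeline_tsv(j(sim_dir, "timeline.tsv"))
        bacteria = dio.read_abundance_tsv(j(sim_dir, "bacteria.tsv"))
        phages = dio.read_abundance_tsv(j(sim_dir, "phages.tsv"))
        curve_b = community.lag_similarity_curve(bacteria, timeline)
        phage_nonzero = phages.loc[phages.sum(axis=1) > 0]
        curve_p = community.lag_similarity_curve(phage_nonzero, timeline)
        classes = community.classify_core_unique(
            bacteria, timeline, threshold=t["core_threshold"])
        dio.write_table_tsv(curve_b, j(stage_dir, "lag_similarity_bacteria.tsv"),
                            header)
        dio.write_table_tsv(curve_p, j(stage_dir, "lag_similarity_phages.tsv"),
                            header)
        dio.write_table_tsv(classes.reset_index(),
                            j(stage_dir, "core_unique_bacteria.tsv"), header)
        labels = classes["label"]
        record("community_dynamics", n_pairs_bacteria=len(curve_b),
               n_pairs_phage=len(curve_p),
               n_core=int((labels == "core").sum()),
               n_unique=int((labels == "unique").sum()),
               mean_lag1_similarity_bacteria=float(
                   curve_b.loc[curve_b.lag_months == 1,
                               "bray_curtis_similarity"].mean()),
               wall_time_s=round(time.time() - t0, 3))

    if config.stages.get("defense_quant", True):
        t0 = time.time()
        rpkm_path = j(out, "viral_screen", "contig_rpkm.tsv")
        _require("defense_quant", j(sim_dir, "ds_annotations.tsv"),
                 j(sim_dir, "mags_ds.tsv"), j(sim_dir, "ani.tsv"), rpkm_path)
        stage_dir = j(out, "defense_quant")
        os.makedirs(stage_dir, exist_ok=True)
        ann = dio.read_table_tsv(j(sim_dir, "ds_annotations.tsv"))
        rpkm = dio.read_abundance_tsv(rpkm_path)
        series = defense.ds_abundance_series(ann, rpkm)
        mags = dio.read_table_tsv(j(sim_dir, "mags_ds.tsv"))
        # the ANI table lists every MAG, including those without any DS
        ani_pairs = dio.read_table_tsv(j(sim_dir, "ani.tsv"))
        mag_ids = sorted(set(ani_pairs["mag_a"]) | set(ani_pairs["mag_b"])
                         | set(mags["mag_id"]))
        mag_ann = pd.DataFrame({
            "carrier_id": mags["mag_id"],
            "ds_type": mags["ds_subtype"].str.rsplit("_", n=1).str[0],
            "ds_subtype": mags["ds_subtype"], "is_complete": True,
            "n_orfs": 1})
        stats = defense.mag_ds_stats(mag_ann, mag_ids)
        dio.write_abundance_tsv(series.per_type,
                                j(stage_dir, "ds_type_abundance.tsv"), header)
        dio.write_table_tsv(series.total.rename_axis("sample_id").reset_index(),
                            j(stage_dir, "ds_total_abundance.tsv"), header)
        dio.write_table_tsv(
            stats["per_mag_counts"].rename("n_complete_ds")
            .rename_axis("mag_id").reset_index(),
            j(stage_dir, "mag_ds_counts.tsv"), header)
        record("defense_quant",
               n_annotations=len(ann),
               n_complete=int(len(defense.filter_complete(ann))),
               n_mags=len(mag_ids),
               fraction_mags_with_ds=stats["fraction_with_ds"],
               mean_ds_per_mag=stats["mean_ds_per_mag"],
               wall_time_s=round(time.time() - t0, 3))

    if config.stages.get("lag_analysis", True):
        t0 = time.time()
        _require("lag_analysis", j(sim_dir, "ds.tsv"),
                 j(sim_dir, "phages.tsv"), j(sim_dir, "env.tsv"))
        stage_dir = j(out, "lag_analysis")
        os.makedirs(stage_dir, exist_ok=True)
        ds_total = dio.read_abundance_tsv(j(sim_dir, "ds.tsv")).sum(axis=1)
        phage_total = dio.read_abundance_tsv(j(sim_dir, "phages.tsv")).sum(axis=1)
        table = lags.time_shift_correlation(ds_total.to_numpy(),
                                            phage_total.to_numpy(),
                                            max_shift=int(t["max_shift"]))
        best = lags.best_lag(table)
        env = dio.read_matrix_tsv(j(sim_dir, "env.tsv"))
        env_table = lags.env_correlations(ds_total.to_numpy(), env)
        dio.write_table_tsv(table, j(stage_dir, "shift_correlation.tsv"), header)
        dio.write_table_tsv(env_table, j(stage_dir, "env_correlation.tsv"),
                            header)
        record("lag_analysis", best_lag_months=int(best),
               r_at_best=float(table.loc[table.lag_of_ds == best, "r"].iloc[0]),
               r_at_zero=float(table.loc[table.lag_of_ds == 0, "r"].iloc[0]),
               top_env_variable=str(env_table["variable"].iloc[0]),
               wall_time_s=round(time.time() - t0, 3))

    if config.stages.get("spacer_dynamics", True):
        t0 = time.time()
        _require("spacer_dynamics", j(sim_dir, "votus.fasta"),
                 j(sim_dir, "phages.tsv"), j(sim_dir, "timeline.tsv"),
                 j(sim_dir, "spacer_reads.tsv"))
        stage_dir = j(out, "spacer_dynamics")
        os.makedirs(stage_dir, exist_ok=True)
        timeline = dio.read_timeline_tsv(j(sim_dir, "timeline.tsv"))
        phages = dio.read_abundance_tsv(j(sim_dir, "phages.tsv"))
        votus = dio.read_fasta(j(sim_dir, "votus.fasta"))
        reads = dio.read_table_tsv(j(sim_dir, "spacer_reads.tsv")) \
            .set_index("sample_id")["total_reads"]
        reps = []
        for path in sorted(glob.glob(j(sim_dir, "spacers_*.fasta"))):
            sample = os.path.basename(path)[len("spacers_"):-len(".fasta")]
            seqs = spacers.dereplicate_spacers(dio.read_fasta(path).values())
            reps.append(SpacerRepertoire(sample, frozenset(seqs),
                                         int(reads[sample])))
        if len(reps) < 2:
            raise PipelineError("stage 'spacer_dynamics': found fewer than 2 "
                                "spacer FASTA files")
        density = pd.DataFrame(
            {"sample_id": [r.sample_id for r in reps],
             "n_spacers": [len(r.spacers) for r in reps],
             "density_per_million": [
                 spacers.spacer_density(len(r.spacers), r.total_reads)
                 for r in reps]})
        retention = spacers.retention_lag_curve(reps, timeline)
        index = spacers.VotuWindowIndex(votus)
        all_hits = []
        hits_per_sample: dict[str, set[str]] = {}
        for rep in reps:
            hits = spacers.match_spacers(
                rep, votus, max_mismatches=int(t["spacer_max_mismatch"]),
                min_identity=t["spacer_min_identity"], index=index)
            hits_per_sample[rep.sample_id] = {h.votu_id for h in hits}
            all_hits.extend((rep.sample_id, h.spacer, h.votu_id, h.mismatches,
                             h.strand, h.position) for h in hits)
        cooc = spacers.cooccurrence_by_bin(phages, hits_per_sample)
        rate = spacers.targeting_rate(phages.columns, [
            spacers.TargetHit(s, v, m, st, p)
            for (_sid, s, v, m, st, p) in all_hits])
        dio.write_table_tsv(density, j(stage_dir, "spacer_density.tsv"), header)
        dio.write_table_tsv(retention, j(stage_dir, "spacer_retention.tsv"),
                            header)
        dio.write_table_tsv(
            pd.DataFrame(all_hits, columns=["sample_id", "spacer", "votu_id",
                                            "mismatches", "strand", "position"]),
            j(stage_dir, "spacer_hits.tsv"), header)
        dio.write_table_tsv(cooc, j(stage_dir, "spacer_cooccurrence.tsv"),
                            header)
        lag1 = retention.loc[retention.lag_months == 1, "retention"]
        record("spacer_dynamics", n_samples=len(reps),
               n_hits=len(all_hits),
               targeting_rate=float(rate),
               mean_lag1_retention=float(lag1.mean()),
               wall_time_s=round(time.time() - t0, 3))

    if config.stages.get("pan_immunity", True):
        t0 = time.time()
        _require("pan_immunity", j(sim_dir, "mags_ds.tsv"),
                 j(sim_dir, "ani.tsv"))
        stage_dir = j(out, "pan_immunity")
        os.makedirs(stage_dir, exist_ok=True)
        mags = dio.read_table_tsv(j(sim_dir, "mags_ds.tsv"))
        ani = dio.read_table_tsv(j(sim_dir, "ani.tsv")).rename(
            columns={"ani_percent": "ani"})
        ds_sets = {m: frozenset(g["ds_subtype"])
                   for m, g in mags.groupby("mag_id")}
        clusters = panimmunity.cluster_mags(
            ani, threshold=t["ani_threshold"], mag_ids=ds_sets.keys())
        panel = panimmunity.MAGPanel(ds_sets=ds_sets, ani=ani,
                                     clusters=clusters)
        pairs, summary = panimmunity.pair_difference_distribution(
            panel, threshold=t["ani_threshold"])
        dio.write_table_tsv(pairs, j(stage_dir, "mag_pair_differences.tsv"),
                            header)
        with open(j(stage_dir, "pan_immunity_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        record("pan_immunity", n_clusters=len(set(clusters.values())),
               **summary, wall_time_s=round(time.time() - t0, 3))

    report["wall_time_s"] = round(time.time() - started, 3)
    with open(j(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
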