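"""Synthetic activated-sludge community generator.

Emulates the statistical structure of a 6-year monthly metagenomic time
series of a wastewater-treatment-plant community:

* a temporally stable bacterial community with a persistent high-abundance
  core (relative abundances),
* a high-turnover phage community in which vOTUs arrive by a memoryless
  process, rise logistically, decay geometrically past their peak and are
  modulated by a 12-month seasonal sinusoid (RPKM-like units),
* defense-system (DS) abundance that follows total phage abundance with a
  planted integer lag of 0-3 months,
* CRISPR spacer repertoires that acquire protospacer-derived spacers when
  a vOTU is abundant and lose spacers memorylessly each month,
* a MAG panel of ANI>=95% species clusters whose members share a core DS
  set but differ in accessory DSs (pan-immunity).

All planted quantities (lag, loss rate, cluster labels, protospacer
positions, targeted vOTUs) are recorded in ``truth`` so downstream
statistics can be tested by parameter recovery.  The whole simulation is
deterministic given ``SimConfig.seed``: one master ``SeedSequence`` is
spawned into a fixed set of per-component streams.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import ConfigError
from . import io as dio

SPACER_LEN = 30
_BASES = np.array(list("ACGT"))

#: order of per-component RNG streams spawned from the master seed
_STREAMS = ("bacteria", "phages", "ds", "spacers", "mags", "contigs", "env")

ENV_VARIABLES = ["T", "DO", "pH", "COD", "BOD", "SS", "NH4-N", "NO3-N",
                 "TN", "TP", "SSV", "SVI", "HRT", "SRT"]


def component_rngs(cfg: SimConfig) -> dict[str, np.random.Generator]:
    """Deterministic per-component RNG streams derived from the master seed."""
    children = np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_STREAMS, children)}


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_timeline(n_months: int, start_year: int = 2013) -> pd.DataFrame:
    """Monthly sample timeline starting January of ``start_year``."""
    idx = [f"S{i + 1:03d}" for i in range(n_months)]
    dates = [f"{start_year + i // 12:04d}-{i % 12 + 1:02d}-01"
             for i in range(n_months)]
    return pd.DataFrame({"month_index": range(n_months), "date": dates},
                        index=pd.Index(idx, name="sample_id"))


# ---------------------------------------------------------------------------
# bacteria

def _bacteria(cfg: SimConfig, rng: np.random.Generator
              ) -> tuple[pd.DataFrame, dict]:
    n_core = max(1, cfg.n_bacteria // 5)
    species = [f"sp_{i:03d}" for i in range(cfg.n_bacteria)]
    # log-normal baselines: a designated core with high baselines, a tail of
    # rare species; month-to-month variation is small multiplicative noise
    log_base = np.empty(cfg.n_bacteria)
    log_base[:n_core] = rng.normal(0.0, 0.5, n_core)
    log_base[n_core:] = rng.normal(-3.0, 1.0, cfg.n_bacteria - n_core)
    base = np.exp(log_base)
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_months, cfg.n_bacteria))
    ab = base[None, :] * np.exp(noise)
    ab /= ab.sum(axis=1, keepdims=True)
    timeline = make_timeline(cfg.n_months)
    df = pd.DataFrame(ab, index=timeline.index, columns=species)
    truth = {"core_bacteria": species[:n_core]}
    return df, truth


def simulate_bacterial_series(cfg: SimConfig,
                              rng: np.random.Generator | None = None
                              ) -> pd.DataFrame:
    """Stable bacterial community; rows are relative abundances summing to 1."""
    cfg.validate()
    if rng is None:
        rng = component_rngs(cfg)["bacteria"]
    return _bacteria(cfg, rng)[0]


# ---------------------------------------------------------------------------
# phages

def _phage_trajectory(t: np.ndarray, arrival: int, peak: float,
                      decay: float, rise_months: int = 6,
                      floor: float = 1e-3) -> np.ndarray:
    """Logistic rise to ``peak`` then geometric decay; extinct stays 0."""
    tau = t - arrival
    rise = peak / (1.0 + np.exp(-1.2 * (tau - rise_months / 2.0)))
    n_decay = np.maximum(tau - rise_months + 1, 0)
    vals = np.where(tau < rise_months, rise,
                    peak / (1.0 + np.exp(-1.2 * (rise_months / 2.0 - 1)))
                    * (1.0 - decay) ** n_decay)
    vals = np.where(tau < 0, 0.0, vals)
    # extinction: once below the floor after the rise, stay at zero
    dead = (tau >= rise_months) & (vals < floor)
    if dead.any():
        vals[np.argmax(dead):] = 0.0
    return vals


def _phages(cfg: SimConfig, rng: np.random.Generator
            ) -> tuple[pd.DataFrame, dict]:
    t = np.arange(cfg.n_months)
    # initial pool: vOTUs mid-rise at month 0 (arrived within the last
    # rise window), so "extant at start" holds for any decay rate
    arrivals: list[int] = [int(a) for a in rng.integers(-5, 1, cfg.n_phages)]
    for month in range(cfg.n_months):
        arrivals.extend([month] * int(rng.poisson(cfg.phage_arrival_rate)))
    n_votu = len(arrivals)
    peaks = np.exp(rng.normal(0.5, 0.8, n_votu))
    phase = rng.uniform(0, 12)
    season = np.maximum(
        0.0, 1.0 + cfg.season_amp * np.sin(2 * np.pi * (t + phase) / 12.0))
    mat = np.zeros((cfg.n_months, n_votu))
    for j, (a, k) in enumerate(zip(arrivals, peaks)):
        mat[:, j] = _phage_trajectory(t, a, k, cfg.phage_decay_rate) * season
    cols = [f"vOTU_{j + 1}" for j in range(n_votu)]
    timeline = make_timeline(cfg.n_months)
    df = pd.DataFrame(mat, index=timeline.index, columns=cols)
    truth = {"phage_arrivals": {c: a for c, a in zip(cols, arrivals)},
             "season_phase": float(phase)}
    return df, truth


def simulate_phage_series(cfg: SimConfig,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """High-turnover seasonal phage community in RPKM-like units."""
    cfg.validate()
    if rng is None:
        rng = component_rngs(cfg)["phages"]
    return _phages(cfg, rng)[0]


# ---------------------------------------------------------------------------
# defense systems

def _defense(phages: pd.DataFrame, cfg: SimConfig,
             rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    n = len(phages)
    if cfg.lag_months >= n:
        raise ConfigError(
            f"lag_months: must be < series length ({cfg.lag_months} >= {n})")
    total = phages.sum(axis=1).to_numpy()
    baselines = np.exp(rng.normal(1.0, 0.3, len(cfg.ds_types)))
    betas = cfg.coupling_beta * rng.uniform(0.5, 1.5, len(cfg.ds_types))
    mat = np.empty((n, len(cfg.ds_types)))
    for j, (b, beta) in enumerate(zip(baselines, betas)):
        series = np.full(n, b)
        if cfg.lag_months == 0:
            series = b + beta * total
        else:
            series[cfg.lag_months:] = b + beta * total[:-cfg.lag_months]
        series = series + rng.normal(0.0, cfg.noise_sd, n)
        mat[:, j] = np.maximum(series, 0.0)
    df = pd.DataFrame(mat, index=phages.index, columns=list(cfg.ds_types))
    truth = {"lag_months": cfg.lag_months,
             "ds_baselines": dict(zip(cfg.ds_types, baselines.tolist())),
             "ds_betas": dict(zip(cfg.ds_types, betas.tolist()))}
    return df, truth


def simulate_defense_series(phages: pd.DataFrame, cfg: SimConfig,
                            rng: np.random.Generator | None = None
                            ) -> pd.DataFrame:
    """DS-type abundances trailing total phage abundance by the planted lag.

    Each type d follows ``baseline_d + beta_d * total_phage(t - lag)`` with
    additive Gaussian noise, truncated at zero; the first ``lag_months``
    entries carry the baseline only.
    """
    cfg.validate()
    if rng is None:
        rng = component_rngs(cfg)["ds"]
    return _defense(phages, cfg, rng)[0]


# ---------------------------------------------------------------------------
# spacer repertoires

@dataclass(frozen=True)
class SpacerRepertoire:
    """Dereplicated spacer set of one sample plus its sequencing depth."""
    sample_id: str
    spacers: frozenset[str]
    total_reads: int


def _mutate_one(seq: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(seq)))
    alt = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + alt[int(rng.integers(0, 3))] + seq[pos + 1:]


def _spacers(phages: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator,
             initial_spacers=None
             ) -> tuple[list[SpacerRepertoire], dict[str, str], dict]:
    votu_seqs = {v: random_dna(rng, cfg.votu_seq_len) for v in phages.columns}
    state: set[str] = set(initial_spacers) if initial_spacers else set()
    reps: list[SpacerRepertoire] = []
    acquisitions: list[dict] = []
    abund = phages.to_numpy()
    samples = list(phages.index)
    max_start = cfg.votu_seq_len - SPACER_LEN
    for t, sample in enumerate(samples):
        if t > 0 and cfg.spacer_loss_prob > 0 and state:
            kept = rng.random(len(state)) >= cfg.spacer_loss_prob
            state = {s for s, k in zip(sorted(state), kept) if k}
        for j, votu in enumerate(phages.columns):
            ab = abund[t, j]
            if ab <= 0:
                continue
            if rng.random() < min(1.0, cfg.spacer_acq_slope * ab):
                start = int(rng.integers(0, max_start + 1))
                spacer = votu_seqs[votu][start:start + SPACER_LEN]
                mism = 0
                if cfg.spacer_mismatch_prob > 0 and \
                        rng.random() < cfg.spacer_mismatch_prob:
                    spacer = _mutate_one(spacer, rng)
                    mism = 1
                state.add(spacer)
                acquisitions.append({"sample_id": sample, "votu": votu,
                                     "position": start, "spacer": spacer,
                                     "mismatches": mism})
        n_bg = int(rng.poisson(cfg.spacer_background_rate))
        for _ in range(n_bg):
            state.add(random_dna(rng, SPACER_LEN))
        total_reads = int(rng.integers(8_000_000, 20_000_000))
        reps.append(SpacerRepertoire(sample, frozenset(state), total_reads))
    truth = {"spacer_loss_prob": cfg.spacer_loss_prob,
             "acquisitions": acquisitions,
             "targeted_votus": sorted({a["votu"] for a in acquisitions})}
    return reps, votu_seqs, truth


def simulate_spacer_repertoires(phages: pd.DataFrame, cfg: SimConfig,
                                rng: np.random.Generator | None = None,
                                initial_spacers=None
                                ) -> tuple[list[SpacerRepertoire],
                                           dict[str, str]]:
    """Monthly spacer repertoires and the vOTU sequences they target.

    Per month, each extant vOTU donates a 30-mer spacer copied from a
    random protospacer locus of its sequence with probability
    ``min(1, spacer_acq_slope * abundance)``; every existing spacer is lost
    independently with ``spacer_loss_prob`` at each month transition;
    background non-targeting spacers arrive at ``spacer_background_rate``.
    """
    cfg.validate()
    if rng is None:
        rng = component_rngs(cfg)["spacers"]
    reps, seqs, _ = _spacers(phages, cfg, rng, initial_spacers)
    return reps, seqs


# ---------------------------------------------------------------------------
# MAG panel

def subtype_universe(ds_types: list[str]) -> list[str]:
    return [f"{t}_{suffix}" for t in ds_types for suffix in ("I", "II", "III")]


def _mag_panel(cfg: SimConfig, rng: np.random.Generator):
    from .panimmunity import MAGPanel  # avoid import cycle at module load

    universe = np.array(subtype_universe(cfg.ds_types))
    lo, hi = cfg.mag_cluster_size
    sizes = rng.integers(lo, hi + 1, cfg.n_mag_clusters)
    ds_sets: dict[str, frozenset[str]] = {}
    clusters: dict[str, str] = {}
    mag_counter = 0
    dlo, dhi = cfg.mag_accessory_draw
    for c in range(cfg.n_mag_clusters):
        core = rng.choice(universe, size=min(cfg.mag_core_ds, len(universe)),
                          replace=False)
        rest = np.array([s for s in universe if s not in set(core)])
        pool = rng.choice(rest, size=min(cfg.mag_accessory_pool, len(rest)),
                          replace=False)
        cluster_id = f"cluster_{c + 1}"
        for _ in range(sizes[c]):
            mag_counter += 1
            mag = f"MAG_{mag_counter:03d}"
            clusters[mag] = cluster_id
            if rng.random() < cfg.mag_frac_no_ds:
                ds_sets[mag] = frozenset()
                continue
            k = int(rng.integers(dlo, dhi + 1)) if len(pool) else 0
            k = min(k, len(pool))
            acc = rng.choice(pool, size=k, replace=False) if k else []
            ds_sets[mag] = frozenset(core) | frozenset(acc)
    mags = sorted(ds_sets)
    rows = []
    for i, a in enumerate(mags):
        for b in mags[i + 1:]:
            same = clusters[a] == clusters[b]
            ani = rng.uniform(95.5, 99.9) if same else rng.uniform(75.0, 90.0)
            rows.append((a, b, float(ani)))
    ani_df = pd.DataFrame(rows, columns=["mag_a", "mag_b", "ani"])
    panel = MAGPanel(ds_sets=ds_sets, ani=ani_df)
    pair_diffs = {f"{a}|{b}": len(ds_sets[a] ^ ds_sets[b])
                  for i, a in enumerate(mags) for b in mags[i + 1:]
                  if clusters[a] == clusters[b]}
    truth = {"mag_clusters": clusters,
             "mag_ds_sets": {m: sorted(s) for m, s in ds_sets.items()},
             "within_cluster_pair_diffs": pair_diffs}
    return panel, truth


def simulate_mag_panel(cfg: SimConfig,
                       rng: np.random.Generator | None = None):
    """Pan-immune MAG panel: ANI>=95% clusters sharing a core DS set but
    differing in accessory DSs; planted differences recorded in truth."""
    cfg.validate()
    if rng is None:
        rng = component_rngs(cfg)["mags"]
    return _mag_panel(cfg, rng)[0]


# ---------------------------------------------------------------------------
# viral-contig screening inputs (pipeline plumbing)

def _contigs(cfg: SimConfig, rng: np.random.Generator, n_contigs: int = 60):
    """Synthetic contig feature/count tables for the screening stage."""
    ids = [f"contig_{i + 1:03d}" for i in range(n_contigs)]
    viral_like = rng.random(n_contigs) < 0.5
    rows = []
    for cid, viral in zip(ids, viral_like):
        length = int(rng.integers(3000, 60000))
        if viral:
            score = float(rng.uniform(0.5, 1.0))
            hallmark = bool(rng.random() < 0.6)
            validated = bool(rng.random() < 0.6)
            completeness = float(rng.uniform(30, 100))
            viral_genes = int(rng.integers(5, 40))
            host_genes = int(rng.integers(0, 3))
        else:
            score = float(rng.uniform(0.0, 0.7))
            hallmark = bool(rng.random() < 0.1)
            validated = bool(rng.random() < 0.1)
            completeness = float(rng.uniform(0, 60))
            viral_genes = int(rng.integers(0, 5))
            host_genes = int(rng.integers(1, 10))
        rows.append((cid, length, score, hallmark, validated, completeness,
                     viral_genes, host_genes))
    features = pd.DataFrame(rows, columns=[
        "contig_id", "length_bp", "score_primary", "has_hallmark",
        "validated_secondary", "completeness_pct", "viral_genes",
        "host_genes"])
    timeline = make_timeline(cfg.n_months)
    counts = pd.DataFrame(rng.poisson(200, size=(cfg.n_months, n_contigs)),
                          index=timeline.index, columns=ids)
    totals = pd.Series(rng.integers(900_000, 1_100_000, cfg.n_months),
                       index=timeline.index, name="total_reads")
    # planted identity groups among the contigs, for vOTU clustering
    group_of = {cid: i // 3 for i, cid in enumerate(ids)}
    pair_rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if group_of[a] == group_of[b]:
                ident = float(rng.uniform(96.0, 99.9))
                cov = float(rng.uniform(90.0, 100.0))
            else:
                ident = float(rng.uniform(60.0, 90.0))
                cov = float(rng.uniform(60.0, 100.0))
            pair_rows.append((a, b, ident, cov))
    identity = pd.DataFrame(
        pair_rows, columns=["id_a", "id_b", "identity", "coverage_shorter"])
    # DefenseFinder-like annotations: some contigs carry 1-2 DSs, complete
    # or partial
    ann_rows = []
    for cid in ids:
        if rng.random() < 0.3:
            for _ in range(int(rng.integers(1, 3))):
                ds_type = cfg.ds_types[int(rng.integers(0, len(cfg.ds_types)))]
                suffix = ("I", "II", "III")[int(rng.integers(0, 3))]
                ann_rows.append((cid, ds_type, f"{ds_type}_{suffix}",
                                 bool(rng.random() < 0.7),
                                 int(rng.integers(2, 9))))
    annotations = pd.DataFrame(ann_rows, columns=[
        "carrier_id", "ds_type", "ds_subtype", "is_complete", "n_orfs"])
    truth = {"contig_groups": group_of}
    return features, counts, totals, identity, annotations, truth


# ---------------------------------------------------------------------------
# environmental variables

def _env(ds_total: np.ndarray, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """14 AR(1) environmental series; BOD carries a planted DS signal."""
    n = len(ds_total)
    data = {}
    for name in ENV_VARIABLES:
        x = np.empty(n)
        x[0] = rng.normal()
        for t in range(1, n):
            x[t] = 0.6 * x[t - 1] + rng.normal()
        data[name] = x
    z = (ds_total - ds_total.mean()) / (ds_total.std() or 1.0)
    data["BOD"] = 0.8 * z + 0.6 * rng.normal(size=n)
    df = pd.DataFrame(data)
    return df, {"env_planted_variable": "BOD"}


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SimOutput:
    """Everything the downstream pipeline consumes, plus planted truth."""
    config: SimConfig
    timeline: pd.DataFrame
    bacteria: pd.DataFrame
    phages: pd.DataFrame
    ds: pd.DataFrame
    repertoires: list[SpacerRepertoire]
    votu_seqs: dict[str, str]
    mag_panel: object
    env: pd.DataFrame
    contig_features: pd.DataFrame
    contig_counts: pd.DataFrame
    contig_totals: pd.Series
    contig_identity: pd.DataFrame
    contig_ds_annotations: pd.DataFrame
    truth: dict = field(default_factory=dict)


def simulate(cfg: SimConfig) -> SimOutput:
    """Run every generator under per-component streams of the master seed."""
    cfg.validate()
    rngs = component_rngs(cfg)
    truth: dict = {"seed": cfg.seed}
    timeline = make_timeline(cfg.n_months)
    bacteria, t_b = _bacteria(cfg, rngs["bacteria"])
    phages, t_p = _phages(cfg, rngs["phages"])
    ds, t_d = _defense(phages, cfg, rngs["ds"])
    reps, votu_seqs, t_s = _spacers(phages, cfg, rngs["spacers"])
    panel, t_m = _mag_panel(cfg, rngs["mags"])
    features, counts, totals, identity, annotations, t_c = _contigs(
        cfg, rngs["contigs"])
    env, t_e = _env(ds.sum(axis=1).to_numpy(), rngs["env"])
    env.index = timeline.index
    for part in (t_b, t_p, t_d, t_s, t_m, t_c, t_e):
        truth.update(part)
    return SimOutput(config=cfg, timeline=timeline, bacteria=bacteria,
                     phages=phages, ds=ds, repertoires=reps,
                     votu_seqs=votu_seqs, mag_panel=panel, env=env,
                     contig_features=features, contig_counts=counts,
                     contig_totals=totals, contig_identity=identity,
                     contig_ds_annotations=annotations, truth=truth)


def write_sim_output(out: SimOutput, outdir: str | os.PathLike,
                     header_lines: tuple[str, ...] = ()) -> None:
    """Serialize a SimOutput as the pipeline's plain-text input files."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    j = os.path.join
    dio.write_abundance_tsv(out.bacteria, j(outdir, "bacteria.tsv"), header_lines)
    dio.write_abundance_tsv(out.phages, j(outdir, "phages.tsv"), header_lines)
    dio.write_abundance_tsv(out.ds, j(outdir, "ds.tsv"), header_lines)
    dio.write_timeline_tsv(out.timeline, j(outdir, "timeline.tsv"), header_lines)
    dio.write_abundance_tsv(out.env, j(outdir, "env.tsv"), header_lines)
    dio.write_fasta(out.votu_seqs, j(outdir, "votus.fasta"))
    for rep in out.repertoires:
        seqs = {f"spacer_{i + 1:04d}": s
                for i, s in enumerate(sorted(rep.spacers))}
        dio.write_fasta(seqs, j(outdir, f"spacers_{rep.sample_id}.fasta"))
    reads = pd.DataFrame(
        {"sample_id": [r.sample_id for r in out.repertoires],
         "total_reads": [r.total_reads for r in out.repertoires]})
    dio.write_table_tsv(reads, j(outdir, "spacer_reads.tsv"), header_lines)
    mag_rows = [(m, s) for m, subset in sorted(out.mag_panel.ds_sets.items())
                for s in sorted(subset)]
    dio.write_table_tsv(pd.DataFrame(mag_rows, columns=["mag_id", "ds_subtype"]),
                        j(outdir, "mags_ds.tsv"), header_lines)
    ani = out.mag_panel.ani.rename(
        columns={"mag_a": "mag_a", "mag_b": "mag_b", "ani": "ani_percent"})
    dio.write_table_tsv(ani, j(outdir, "ani.tsv"), header_lines)
    dio.write_table_tsv(out.contig_features, j(outdir, "contigs.tsv"), header_lines)
    dio.write_abundance_tsv(out.contig_counts, j(outdir, "contig_counts.tsv"),
                            header_lines)
    dio.write_table_tsv(out.contig_totals.rename_axis("sample_id").reset_index(),
                        j(outdir, "contig_totals.tsv"), header_lines)
    dio.write_table_tsv(out.contig_identity, j(outdir, "votu_identity.tsv"),
                        header_lines)
    dio.write_table_tsv(out.contig_ds_annotations,
                        j(outdir, "ds_annotations.tsv"), header_lines)
    with open(j(outdir, "truth.json"), "w") as fh:
        json.dump(out.truth, fh, indent=1, sort_keys=True, default=str)
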