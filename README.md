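# defdyn

Statistics for phage–bacteria–defense-system eco-dynamics in long-term
metagenomic time series, built around the activated-sludge setting:
monthly samples of an engineered microbial community in which the
bacterial community stays stable while the phage community turns over,
and prokaryotic antiviral defense systems (DSs) track phage pressure.

For microbial ecologists and bioinformaticians who already have the
table-level products of a metagenomic workflow (abundance tables,
viral-contig feature tables, DefenseFinder-style annotations, CRISPR
spacer sets, MAG ANI tables) and want the downstream ecology:

- **Viral screening & vOTUs** — the two-tool acceptance cascade
  (score ≥ 0.9, or ≥ 0.7 with hallmark genes, or ≥ 0.5 with secondary
  confirmation; contigs ≥ 5 kb), completeness/gene-content quality
  filtering, greedy longest-first clustering at 95% identity / 85%
  coverage of the shorter sequence, and RPKM quantification.
- **Community dynamics** — Bray–Curtis similarity
  `S(x, y) = 1 − Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)` of all sample pairs against time
  lag, and core/unique species classification (> 0.1% mean relative
  abundance in every year vs in exactly one year).
- **Defense quantification** — complete-DS filtering and DS-type
  abundance as the summed RPKM of complete-DS-carrying contigs.
- **Time-shift correlation** — Pearson r between phage(t) and
  DS(t + s) across shifts, with `best_lag` recovering the months by
  which the DS response trails phage fluctuations; environmental
  correlations with Benjamini–Hochberg correction.
- **Spacer turnover** — CRISPR spacer dereplication, density per
  million reads, protospacer matching (full-length, both strands,
  ≤ 1 mismatch at ≥ 95% identity), retention ratio
  `|Sᵢ ∩ Sⱼ| / |Sᵢ|` vs lag, and spacer/vOTU co-occurrence by
  abundance bin.
- **Pan-immunity** — single-linkage ANI ≥ 95% MAG clustering and the
  distribution of DS-set symmetric differences |A △ B| across
  near-identical MAG pairs.
- **Synthetic community simulator** — generates all of the above
  inputs with planted ground truth (true lag, spacer loss rate,
  cluster labels, protospacer positions) so every statistic is tested
  by parameter recovery. See `docs/methods.md` for the models.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic community (each step writes its tables under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_screen_votus.py
python analysis/03_community_dynamics.py
python analysis/04_defense_lag.py
python analysis/05_spacer_turnover.py
python analysis/06_pan_immunity.py
```

which prints, among other things:

```
planted DS lag: 2 months; planted spacer loss: 0.9/month
2556 bacterial sample pairs; mean similarity lag 1: 0.973, lag 6: 0.973 (stable)
2556 phage sample pairs;     mean similarity lag 1: 0.849, lag 6: 0.341 (high turnover)
DS abundance trails phage abundance by 2 month(s): r = 1.000 at the best shift vs r = 0.753 at shift 0
top environmental correlate: BOD (r = 0.817, q = 3e-17)
mean lag-1 retention ratio: 0.106 (rapid repertoire turnover)
co-occurrence frequency rises from 2.0% in the lowest abundance bin to 85.7% in the highest
107 qualifying MAG pairs: 0.9% share an identical DS composition; 62.6% differ in three or more DSs
```

Read against the planted truth: the bacterial community is stable while
phage similarity decays with lag; the time-shift analysis recovers the
planted 2-month DS lag and the planted BOD signal; lag-1 spacer
retention recovers 1 − loss = 0.10; co-occurrence rises with vOTU
abundance because acquisition probability does; and near-identical MAGs
almost never share a DS repertoire — the pan-immunity signature.

The same stages are exposed as a CLI (`defdyn run --config
pipeline.yaml --out DIR --seed N`, plus per-stage subcommands such as
`defdyn screen`, `defdyn lagcorr`, `defdyn pan-immunity`) for use on
externally produced tables; see `defdyn --help`.

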