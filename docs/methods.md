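# Methods

`defdyn` implements the ecological-statistics layer of a long-term
(multi-year, monthly) metagenomic study of phage–bacteria–defense-system
dynamics in activated sludge, together with a synthetic community
simulator whose planted parameters make every statistic testable by
recovery. This note describes the models, the defaults and why, the
numerical choices, and what the synthetic data does and does not show.

## The synthetic community

Real inputs for this kind of study are terabytes of raw reads processed
by an external tool chain (assembly, binning, viral prediction, defense
annotation, CRISPR detection). `defdyn` consumes only the resulting
tables and sequence sets, and its simulator generates those products
directly, one component per deterministic RNG stream spawned from a
single master seed (`SimConfig.seed`), so identical configs give
bit-identical output.

**Bacteria** (relative abundance). Species receive log-normal baseline
abundances — a designated core (one fifth of species) with high
baselines, a rare tail — and each month multiplies the baseline by
`exp(N(0, noise_sd))` before row renormalization. With the default
`noise_sd = 0.05` the month-to-month Bray–Curtis similarity stays above
0.9 at every lag: a temporally stable community with a persistent core,
the pattern engineered treatment communities show. At `noise_sd = 0` the
composition is exactly constant (a tested closed form).

**Phages** (RPKM-like units). vOTUs arrive by a Poisson process
(`phage_arrival_rate` per month, default 1.0) on top of an initial pool
of `n_phages` vOTUs mid-rise at month 0. Each trajectory rises
logistically over ~6 months to a log-normal peak, then decays
geometrically at `phage_decay_rate` (default 0.25/month) and is set to
zero permanently once below an extinction floor (10⁻³); all columns are
modulated by a shared 12-month sinusoid of amplitude `season_amp`
(default 0.3). This reproduces the qualitative phage pattern the
analyses assume: boom–bust vOTU trajectories, community similarity that
decays with lag, and a seasonal signature. The "RPKM-like" units are
arbitrary: the statistics consume abundance tables, never read mappings.

**Defense systems.** Each DS type *d* follows
`baseline_d + beta_d * P(t − lag_months) + N(0, noise_sd)`, truncated at
zero, where `P` is total phage abundance and `beta_d` is
`coupling_beta` scaled by a per-type factor in [0.5, 1.5]. The first
`lag_months` entries carry the baseline only. This additive lagged
response is a deliberately simple stand-in — the field has no agreed
mechanistic model of community-level DS–phage coupling — chosen because
it makes the lag identifiable and the noiseless case exactly solvable
(Pearson r = 1 at the true shift). `lag_months` is the planted
ground truth the time-shift analysis has to recover.

**Spacer repertoires.** Per month, each extant vOTU donates a 30-mer
spacer with probability `min(1, spacer_acq_slope × abundance)`; the
spacer is copied from a random position of the vOTU sequence (the
protospacer locus, recorded in truth), optionally with exactly one
substitution (`spacer_mismatch_prob`). Every existing spacer is lost
independently with `spacer_loss_prob` at each month transition, and
non-targeting background 30-mers arrive at `spacer_background_rate` per
month. Copying from a random locus (rather than one fixed locus per
vOTU) matters: re-acquisition then produces a *different* sequence, so
the planted memoryless loss rate is identifiable from the retention
ratio (expected lag-1 retention = 1 − loss). The default
`spacer_loss_prob = 0.9` encodes the rapid monthly turnover reported
for activated-sludge CRISPR repertoires (single-digit-percent lag-1
retention). Spacers are 30-mers over {A,C,G,T}; at 4³⁰ sequences,
background collisions are negligible.

**MAG panel.** `n_mag_clusters` species-level clusters with within-
cluster ANI drawn uniformly from [95.5, 99.9]% and between-cluster ANI
from [75, 90]%, leaving a deliberate margin around the 95% threshold.
Cluster members share a core DS subtype set and draw accessory subtypes
from a cluster-specific pool; a configurable fraction of MAGs carries no
DS at all (these are excluded from pan-immunity pair counting, as the
analysis prescribes). All planted pairwise DS differences and cluster
labels are recorded in truth.

**Environmental table.** Fourteen AR(1) series named after standard
wastewater process parameters; BOD is constructed as standardized total
DS abundance plus noise, planting a known top correlate for the
environmental-correlation analysis to find.

## The analyses

**Viral screening.** A contig of ≥ `min_contig_len` (default 5000 bp)
is accepted iff primary score ≥ 0.9, or ≥ 0.7 with hallmark genes, or
≥ 0.5 with secondary-tool confirmation; quality filtering keeps
completeness ≥ 50% and `viral_genes − 5·host_genes > 0`. All `≥`
thresholds are inclusive and the gene rule strictly exclusive, exactly
as printed in the protocols these rules come from; boundary tests pin
each edge. Scores are inputs: the package does not emulate the
prediction tools.

**vOTU clustering** follows CD-HIT semantics: sequences sorted by length
descending (ties by ID for determinism); each joins the first existing
representative it matches at ≥ 95% identity and ≥ 85% coverage of the
shorter sequence, else founds a cluster. Identity/coverage arrive as a
precomputed pair table; a toy edlib-based helper can derive one from
FASTA for small inputs, but production alignment is out of scope.

**RPKM** is `count / (length/10³) / (total/10⁶)`; linear in counts and
invariant to joint scaling of counts and totals.

**Community dynamics.** Bray–Curtis similarity (1 − dissimilarity, via
scipy) on row-normalized abundances for all n(n−1)/2 sample pairs versus
month lag. Normalizing both bacterial (relative) and phage (RPKM)
tables makes the two curves comparable compositional quantities.
Core/unique classification uses the yearly mean of monthly relative
abundances with a strict `>` at the 0.1% threshold; calendar years come
from the timeline dates, and partial years count as years.

**Defense quantification.** Only complete DSs count. A DS type's
abundance in a sample is the summed RPKM of contigs carrying ≥ 1
complete DS of that type. A multi-type contig contributes its full RPKM
to each of its types but only once to the total-DS series, so the total
literally equals "abundance of DS-carrying contigs" while per-type
series stay type-faithful; consequently the per-type sum can exceed the
total, which is intended and tested.

**Time-shift correlation.** For shifts s ∈ [−K, K], Pearson r between
phage(t) and DS(t+s) over the overlapping window. The public sign
convention is `lag_of_ds`: months DS *trails* phage, positive when DS
follows — an unambiguous name chosen because axis conventions in
time-shift plots are easy to misread. `best_lag` takes the maximal r
with exact ties broken toward zero (sort key (−r, |lag|, lag)).
Pearson is used (not Spearman) because the companion analysis is a
linear regression of DS on phage abundance. Significance is the plain
two-sided t-test p; no autocorrelation correction is applied (a known
limitation — monthly ecological series are autocorrelated, so shift
p-values are optimistic; the null-simulation test therefore applies a
Bonferroni family-wise check across shifts).

**Spacer statistics.** Dereplication collapses exact duplicates and
perfect substrings into the longest representative (ties
lexicographic) — 100% identity at 100% coverage of the shorter sequence
forces the substring collapse; the operation is idempotent. Matching
reports every full-length ungapped alignment of a spacer or its reverse
complement with ≤ 1 mismatch and ≥ 95% identity (for spacers under
20 nt a single mismatch violates 95%, so only exact matches qualify).
The implementation indexes every length-L vOTU window exactly and finds
1-mismatch hits by enumerating the 3L single-substitution variants of
the query; tests verify exact hit-set equality against a brute-force
sliding-window oracle. The retention ratio divides the intersection by
the *earlier* repertoire (the "retained rather than discarded"
reading); the reverse-denominator ratio is emitted alongside for
transparency, and intersection uses exact sequence equality after
per-sample dereplication. Co-occurrence bins each (vOTU, sample)
observation with positive abundance by abundance — default edges 0.5,
1, 2, 4 (the first bin closed, the rest half-open (lo, hi]); the exact
published bin edges beyond 0.5 and 4.0 are not printed, so bins are
configurable.

**Pan-immunity.** MAGs are clustered by single-linkage connected
components of the ANI ≥ 95% graph (the minimal reading of "cluster at
ANI ≥ 95%", matching dereplication conventions); labels are the
smallest member ID. DS differences are the symmetric-difference
cardinality of DS *subtype* sets (presence/absence, not multisets —
duplicate subtypes within a MAG are not counted twice); type-level
counting is available via a flag. Pairs with either member lacking DSs
are excluded before the 0-difference and ≥ 3-difference fractions are
computed.

## Problem sizes and defaults

The simulator's default study shape is 72 monthly samples (6 years),
100 bacterial species, an initial pool of 40 vOTUs growing by ~1
arrival/month, 12 DS types, and a ~50-MAG panel in 8 ANI clusters. The
acceptance checks run: 25 seeds per planted lag ℓ ∈ {0..3} at
`coupling_beta = 2`, `noise_sd = 5` (noise on the order of half the
phage-signal SD); a 60-month retention run at loss 0.9; three pooled
72-month runs for co-occurrence; and oracle comparisons at 1000 random
vector pairs and 50 vOTUs × 200 spacers. These sizes are chosen so the
statistics are well past their law-of-large-numbers regime while the
whole suite stays interactive.

## What passing tests do and do not show

The simulator reproduces the *statistical structure* the analyses
assume — stable bacteria, bursty seasonal phages, lagged additive DS
response, memoryless spacer loss, pan-immune MAG clusters — not real
sequencing: no read-level noise, no assembly or binning artifacts, no
compositional coupling between phage and bacterial tables, no
phylogenetic structure in DS assignment, and protospacers are planted
in otherwise random DNA. Passing recovery tests therefore demonstrates
that the statistics are implemented correctly and identify their target
quantities under the stated model; they do not validate the upstream
bioinformatics or the biological claims on real data.

## Known limitations

- Shift-correlation significance ignores temporal autocorrelation.
- The additive lagged DS model is a testability device, not a
  mechanistic claim.
- Dereplication substring-collapse is same-strand only.
- The toy FASTA identity helper approximates identity via edit distance
  of an infix alignment and reports 100% coverage of the shorter
  sequence; use a real aligner for production pair tables.
- `best_lag` with an exactly tied maximum at ±k deterministically
  prefers −k after the |lag| tie-break; only the symmetric-table case
  is contractually pinned to 0.
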