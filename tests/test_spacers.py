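"""Spacer dereplication, density, protospacer matching, retention and
co-occurrence statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from defdyn.config import SimConfig
from defdyn.errors import AnalysisError, ConfigError, InputError
from defdyn.simulate import (SpacerRepertoire, make_timeline, random_dna,
                             simulate, simulate_phage_series,
                             simulate_spacer_repertoires)
from defdyn.spacers import (cooccurrence_by_bin, dereplicate_spacers,
                            hits_by_sample, match_spacers, retention_lag_curve,
                            retention_ratio, reverse_complement,
                            spacer_density, targeting_rate)
from oracles import brute_force_match, revcomp

dna = st.text(alphabet="ACGT", min_size=20, max_size=45)


class TestDereplicate:
    def test_exact_duplicates_collapse(self):
        s = "ACGTACGTACGTACGTACGTACGTACGTAC"
        assert dereplicate_spacers([s, s, s, s]) == {s}

    def test_substring_collapses_into_longer(self):
        long = "ACGTACGTACGTACGTACGTACGTACGTAC"
        short = long[2:28]
        assert dereplicate_spacers([long, short]) == {long}

    def test_one_mismatch_keeps_both(self):
        a = "ACGTACGTACGTACGTACGTACGTACGTAC"
        b = a[:10] + "A" + a[11:]
        assert a[10] != "A"
        assert dereplicate_spacers([a, b]) == {a, b}

    def test_non_acgt_named(self):
        with pytest.raises(InputError, match="N"):
            dereplicate_spacers(["ACGTN" * 6])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(dna, max_size=20))
    def test_idempotent(self, seqs):
        once = dereplicate_spacers(seqs)
        assert dereplicate_spacers(once) == once


class TestDensity:
    def test_hand_computed(self):
        assert spacer_density(50, 10_000_000) == pytest.approx(5.0)

    def test_zero_spacers(self):
        assert spacer_density(0, 1_000_000) == 0.0

    def test_ratio_invariance(self):
        assert spacer_density(80, 4_000_000) == \
            pytest.approx(spacer_density(160, 8_000_000))

    def test_nonpositive_reads_rejected(self):
        with pytest.raises(InputError):
            spacer_density(5, 0)


class TestMatching:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.votus = {f"v{i}": random_dna(rng, 500) for i in range(3)}
        self.rng = rng

    def test_verbatim_protospacer_found(self):
        spacer = self.votus["v1"][100:130]
        hits = match_spacers([spacer], self.votus)
        assert any(h.votu_id == "v1" and h.position == 100
                   and h.mismatches == 0 and h.strand == "+" for h in hits)

    def test_one_substitution_counts_one_mismatch(self):
        spacer = self.votus["v1"][100:130]
        mutated = spacer[:5] + ("A" if spacer[5] != "A" else "C") + spacer[6:]
        hits = match_spacers([mutated], self.votus)
        assert any(h.votu_id == "v1" and h.position == 100
                   and h.mismatches == 1 for h in hits)

    def test_two_substitutions_rejected(self):
        spacer = self.votus["v2"][50:80]
        mutated = ("A" if spacer[0] != "A" else "C") + spacer[1:29] + \
            ("A" if spacer[29] != "A" else "C")
        hits = match_spacers([mutated], self.votus)
        assert not any(h.votu_id == "v2" and h.position == 50 for h in hits)

    def test_reverse_complement_strand_reported(self):
        spacer = reverse_complement(self.votus["v0"][200:230])
        hits = match_spacers([spacer], self.votus)
        assert any(h.votu_id == "v0" and h.position == 200
                   and h.strand == "-" for h in hits)

    def test_short_spacer_requires_exact_match(self):
        # 19-mer: one mismatch gives 18/19 = 94.7% identity < 95%
        spacer = self.votus["v1"][40:59]
        mutated = spacer[:3] + ("A" if spacer[3] != "A" else "C") + spacer[4:]
        exact_hits = match_spacers([spacer], self.votus)
        mism_hits = match_spacers([mutated], self.votus)
        assert any(h.position == 40 for h in exact_hits)
        assert not any(h.votu_id == "v1" and h.position == 40
                       for h in mism_hits)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        votus = {f"v{i}": random_dna(rng, 400) for i in range(8)}
        spacers = [random_dna(rng, 30) for _ in range(15)]
        for vid in votus:  # plant exact, 1-sub and revcomp spacers
            seq = votus[vid]
            start = int(rng.integers(0, 370))
            spacers.append(seq[start:start + 30])
            sub = seq[start:start + 30]
            pos = int(rng.integers(0, 30))
            alt = "ACGT"[("ACGT".index(sub[pos]) + 1) % 4]
            spacers.append(sub[:pos] + alt + sub[pos + 1:])
            spacers.append(revcomp(seq[start:start + 30]))
        got = {(h.spacer, h.votu_id, h.position, h.strand, h.mismatches)
               for h in match_spacers(spacers, votus)}
        assert got == brute_force_match(spacers, votus)


class TestRetention:
    def _rep(self, sid, seqs):
        return SpacerRepertoire(sid, frozenset(seqs), 1_000_000)

    def test_identical_repertoires(self):
        r = self._rep("S001", {"A" * 30, "C" * 30})
        assert retention_ratio(r, self._rep("S002", {"A" * 30, "C" * 30})) == 1.0

    def test_disjoint_repertoires(self):
        a = self._rep("S001", {"A" * 30})
        b = self._rep("S002", {"G" * 30})
        assert retention_ratio(a, b) == 0.0

    def test_half_retained(self):
        a = self._rep("S001", {"A" * 30, "C" * 30, "G" * 30, "T" * 30})
        b = self._rep("S002", {"A" * 30, "C" * 30, "AC" * 15})
        assert retention_ratio(a, b) == 0.5

    def test_empty_earlier_undefined(self):
        with pytest.raises(AnalysisError, match="S001"):
            retention_ratio(self._rep("S001", set()),
                            self._rep("S002", {"A" * 30}))

    def test_equals_one_iff_earlier_subset(self, rng):
        pool = [random_dna(rng, 30) for _ in range(12)]
        earlier = self._rep("S001", set(pool[:5]))
        later_super = self._rep("S002", set(pool[:8]))
        later_partial = self._rep("S003", set(pool[3:8]))
        assert retention_ratio(earlier, later_super) == 1.0
        assert retention_ratio(earlier, later_partial) < 1.0

    def test_lag_curve_counts_ordered_pairs(self):
        reps = [self._rep(f"S{i + 1:03d}", {random_dna(np.random.default_rng(i), 30)})
                for i in range(5)]
        curve = retention_lag_curve(reps, make_timeline(5))
        assert len(curve) == 10
        assert (curve["lag_months"] > 0).all()
        assert curve["retention"].between(0, 1).all()

    def test_mean_retention_nonincreasing_with_lag(self):
        means = []
        for seed in (3, 4, 5):
            cfg = SimConfig(n_months=48, spacer_loss_prob=0.9, seed=seed)
            phages = simulate_phage_series(cfg)
            reps, _ = simulate_spacer_repertoires(phages, cfg)
            curve = retention_lag_curve(reps, make_timeline(48))
            sub = curve[curve.lag_months.between(1, 6)]
            means.append(sub.groupby("lag_months")["retention"].mean())
        mean_by_lag = pd.concat(means, axis=1).mean(axis=1)
        assert (mean_by_lag.diff().dropna() <= 1e-12).all()


class TestTargetingAndCooccurrence:
    def test_all_targeted(self, sim_out):
        hits = match_spacers(
            {a["spacer"] for a in sim_out.truth["acquisitions"]},
            sim_out.votu_seqs)
        rate = targeting_rate(sorted(sim_out.truth["targeted_votus"]), hits)
        assert rate == 1.0

    def test_no_spacers_rate_zero_and_empty_set_rejected(self):
        assert targeting_rate(["v1", "v2"], []) == 0.0
        with pytest.raises(InputError):
            targeting_rate([], [])

    def test_rate_matches_planted_fraction(self, sim_out):
        hits = hits_by_sample(sim_out.repertoires, sim_out.votu_seqs)
        targeted = set().union(*hits.values()) if hits else set()
        planted = set(sim_out.truth["targeted_votus"])
        assert targeted == planted
        rate = targeting_rate(list(sim_out.phages.columns), [
            h for rep in sim_out.repertoires
            for h in match_spacers(rep, sim_out.votu_seqs)])
        assert rate == pytest.approx(len(planted) / sim_out.phages.shape[1])

    def test_certain_acquisition_fills_every_bin(self):
        cfg = SimConfig(n_months=24, spacer_acq_slope=1e6,
                        spacer_background_rate=0.0, spacer_loss_prob=0.5,
                        seed=9)
        phages = simulate_phage_series(cfg)
        reps, votus = simulate_spacer_repertoires(phages, cfg)
        hits = hits_by_sample(reps, votus)
        table = cooccurrence_by_bin(phages, hits)
        observed = table[table.n_obs > 0]
        assert (observed["frequency"] == 1.0).all()

    def test_no_spacers_all_zero(self):
        cfg = SimConfig(n_months=24, spacer_acq_slope=0.0,
                        spacer_background_rate=0.0, seed=9)
        phages = simulate_phage_series(cfg)
        table = cooccurrence_by_bin(phages, {})
        observed = table[table.n_obs > 0]
        assert (observed["frequency"] == 0.0).all()

    def test_overlapping_bins_rejected(self, sim_out):
        with pytest.raises(ConfigError, match="bins"):
            cooccurrence_by_bin(sim_out.phages, {},
                                bins=[(0.0, 1.0), (0.5, float("inf"))])
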