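"""Generator contracts: determinism, conservation laws, zero-noise limits
and identifiability of the planted parameters."""

import json

import numpy as np
import pytest

from defdyn.community import bray_curtis_similarity, lag_similarity_curve
from defdyn.config import SimConfig
from defdyn.errors import ConfigError
from defdyn.simulate import (SPACER_LEN, make_timeline, simulate,
                             simulate_bacterial_series,
                             simulate_defense_series, simulate_mag_panel,
                             simulate_phage_series,
                             simulate_spacer_repertoires)
from defdyn.spacers import retention_lag_curve


def _mean_similarity_at_lag(matrix, lag):
    curve = lag_similarity_curve(matrix, make_timeline(len(matrix)))
    return curve.loc[curve.lag_months == lag, "bray_curtis_similarity"].mean()


class TestBacteria:
    def test_rows_are_compositions(self):
        m = simulate_bacterial_series(SimConfig(n_months=24, seed=4))
        assert (m.values >= 0).all()
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_noise_community_is_static(self):
        m = simulate_bacterial_series(SimConfig(n_months=24, noise_sd=0.0,
                                                seed=4))
        first = m.iloc[0].to_numpy()
        assert (m.to_numpy() == first[None, :]).all()
        assert bray_curtis_similarity(first, m.iloc[-1]) == 1.0

    def test_high_temporal_stability_at_default_noise(self):
        cfg = SimConfig(n_months=36, n_bacteria=100, noise_sd=0.05, seed=1)
        m = simulate_bacterial_series(cfg)
        assert _mean_similarity_at_lag(m, 1) > 0.9

    def test_core_species_stay_above_floor(self):
        out = simulate(SimConfig(n_months=36, seed=11))
        core = out.truth["core_bacteria"]
        years = out.timeline["date"].str[:4]
        yearly = out.bacteria.groupby(years.values).mean()
        assert (yearly[core] > 0.001).all().all()


class TestPhages:
    def test_no_arrivals_no_pool_is_all_zero(self):
        m = simulate_phage_series(SimConfig(n_months=24, n_phages=0,
                                            phage_arrival_rate=0.0, seed=2))
        assert (m.to_numpy() == 0).all()

    def test_full_decay_kills_after_one_step(self):
        cfg = SimConfig(n_months=24, n_phages=1, phage_arrival_rate=0.0,
                        phage_decay_rate=1.0, season_amp=0.0, seed=2)
        m = simulate_phage_series(cfg)
        col = m.iloc[:, 0].to_numpy()
        assert col.max() > 0
        last_nonzero = np.nonzero(col)[0].max()
        assert (col[last_nonzero + 1:] == 0).all()

    def test_turnover_decays_similarity_with_lag(self):
        cfg = SimConfig(n_months=48, phage_arrival_rate=1.0,
                        phage_decay_rate=0.3, seed=7)
        m = simulate_phage_series(cfg)
        m = m.loc[m.sum(axis=1) > 0]
        assert _mean_similarity_at_lag(m, 6) < _mean_similarity_at_lag(m, 1)

    def test_extinct_votus_stay_extinct(self):
        m = simulate_phage_series(SimConfig(n_months=48, seed=9))
        for col in m.columns:
            v = m[col].to_numpy()
            nz = np.nonzero(v)[0]
            if len(nz) and nz.max() < len(v) - 1:
                assert (v[nz.max() + 1:] == 0).all()


class TestDefense:
    def test_decoupled_series_uncorrelated(self):
        cfg = SimConfig(n_months=120, coupling_beta=0.0, noise_sd=1.0, seed=3)
        phages = simulate_phage_series(cfg)
        ds = simulate_defense_series(phages, cfg)
        total_p = phages.sum(axis=1).to_numpy()
        total_d = ds.sum(axis=1).to_numpy()
        r = np.corrcoef(total_p, total_d)[0, 1]
        assert abs(r) < 0.3

    def test_noiseless_shift_is_perfectly_correlated(self):
        cfg = SimConfig(n_months=48, lag_months=2, noise_sd=0.0, seed=3)
        phages = simulate_phage_series(cfg)
        ds = simulate_defense_series(phages, cfg)
        p = phages.sum(axis=1).to_numpy()
        d = ds.sum(axis=1).to_numpy()
        r_shifted = np.corrcoef(p[:-2], d[2:])[0, 1]
        r_zero = np.corrcoef(p, d)[0, 1]
        assert r_shifted == pytest.approx(1.0, abs=1e-12)
        assert r_zero < r_shifted

    def test_lag_must_fit_series(self):
        cfg = SimConfig(n_months=40, lag_months=2, seed=3)
        phages = simulate_phage_series(cfg).iloc[:1]
        with pytest.raises(ConfigError, match="lag_months"):
            simulate_defense_series(phages, cfg)


class TestSpacers:
    def test_total_loss_empties_repertoire_overlap(self):
        cfg = SimConfig(n_months=12, lag_months=0, spacer_loss_prob=1.0,
                        spacer_acq_slope=0.0, spacer_background_rate=3.0,
                        seed=5)
        phages = simulate_phage_series(cfg)
        reps, _ = simulate_spacer_repertoires(phages, cfg)
        curve = retention_lag_curve(reps, make_timeline(12))
        lag1 = curve.loc[curve.lag_months == 1, "retention"].dropna()
        assert (lag1 == 0.0).all()

    def test_no_loss_no_gain_keeps_repertoire_constant(self):
        cfg = SimConfig(n_months=12, lag_months=0, spacer_loss_prob=0.0,
                        spacer_acq_slope=0.0, spacer_background_rate=0.0,
                        seed=5)
        phages = simulate_phage_series(cfg)
        initial = {"ACGT" * 7 + "AC", "TTGA" * 7 + "CA"}
        reps, _ = simulate_spacer_repertoires(phages, cfg,
                                              initial_spacers=initial)
        assert all(set(r.spacers) == initial for r in reps)
        curve = retention_lag_curve(reps, make_timeline(12))
        assert (curve["retention"] == 1.0).all()

    def test_planted_loss_rate_recovered_at_lag_one(self):
        cfg = SimConfig(n_months=60, spacer_loss_prob=0.9, seed=3)
        phages = simulate_phage_series(cfg)
        reps, _ = simulate_spacer_repertoires(phages, cfg)
        curve = retention_lag_curve(reps, make_timeline(60))
        lag1 = curve.loc[curve.lag_months == 1, "retention"].dropna()
        assert lag1.mean() == pytest.approx(0.10, abs=0.03)

    def test_acquired_spacers_are_verbatim_protospacers(self):
        cfg = SimConfig(n_months=24, spacer_mismatch_prob=0.5, seed=8)
        out = simulate(cfg)
        votus = out.votu_seqs
        for acq in out.truth["acquisitions"]:
            window = votus[acq["votu"]][acq["position"]:
                                        acq["position"] + SPACER_LEN]
            n_diff = sum(a != b for a, b in zip(acq["spacer"], window))
            assert n_diff == acq["mismatches"]


class TestMagPanel:
    def test_empty_accessory_pool_gives_identical_members(self):
        cfg = SimConfig(n_months=24, mag_accessory_pool=0,
                        mag_accessory_draw=(0, 0), mag_frac_no_ds=0.0, seed=6)
        panel = simulate_mag_panel(cfg)
        by_cluster = {}
        out = simulate(cfg)
        for mag, cl in out.truth["mag_clusters"].items():
            by_cluster.setdefault(cl, []).append(out.mag_panel.ds_sets[mag])
        for sets in by_cluster.values():
            assert all(s == sets[0] for s in sets)
        assert panel.ani["ani"].between(75, 100).all()

    def test_large_cluster_mostly_distinct_repertoires(self):
        cfg = SimConfig(n_months=24, n_mag_clusters=1,
                        mag_cluster_size=(15, 15), mag_core_ds=0,
                        mag_accessory_pool=11, mag_accessory_draw=(4, 4),
                        mag_frac_no_ds=0.0, seed=6)
        out = simulate(cfg)
        diffs = list(out.truth["within_cluster_pair_diffs"].values())
        assert len(diffs) == 15 * 14 // 2
        assert np.mean([d > 0 for d in diffs]) > 0.8

    def test_ani_separates_within_and_between(self, sim_out):
        panel = sim_out.mag_panel
        clusters = sim_out.truth["mag_clusters"]
        for row in panel.ani.itertuples(index=False):
            if clusters[row.mag_a] == clusters[row.mag_b]:
                assert row.ani >= 95.5
            else:
                assert row.ani <= 90.0


class TestDeterminismAndValidation:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_months=24, spacer_mismatch_prob=0.2, seed=13)
        a, b = simulate(cfg), simulate(cfg)
        assert a.bacteria.equals(b.bacteria)
        assert a.phages.equals(b.phages)
        assert a.ds.equals(b.ds)
        assert a.repertoires == b.repertoires
        assert a.votu_seqs == b.votu_seqs
        assert a.mag_panel.ani.equals(b.mag_panel.ani)
        assert json.dumps(a.truth, sort_keys=True, default=str) == \
            json.dumps(b.truth, sort_keys=True, default=str)

    def test_different_seed_differs(self):
        a = simulate(SimConfig(n_months=24, seed=1))
        b = simulate(SimConfig(n_months=24, seed=2))
        assert not a.bacteria.equals(b.bacteria)

    @pytest.mark.parametrize("field,value", [
        ("phage_decay_rate", 0.0),
        ("spacer_loss_prob", 1.5),
        ("coupling_beta", -1.0),
        ("noise_sd", -0.1),
        ("n_months", 10),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            cfg.validate()
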