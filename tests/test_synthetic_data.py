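"""Ground-truth cohort generator: planted structure and couplings."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from plaquetopics import (
    ConfigError,
    SimulationConfig,
    simulate_cohort,
    simulate_counts,
    simulate_metadata,
    simulate_topics,
)


class TestConfigValidation:
    def test_k_true_lower_bound(self):
        with pytest.raises(ConfigError):
            SimulationConfig(k_true=1).validate()

    def test_planted_index_in_range(self):
        with pytest.raises(ConfigError):
            SimulationConfig(k_true=4, planted_topic_index=4).validate()

    def test_infeasible_dominant_share(self):
        with pytest.raises(ConfigError, match="simplex"):
            SimulationConfig(dominant_share=0.5, dominant_jitter=0.1).validate()


class TestSimulateTopics:
    def test_planted_row_structure(self):
        cfg = SimulationConfig(n_genera=10, k_true=3, rng_seed=1)
        phi = simulate_topics(cfg)
        assert phi.shape == (3, 10)
        assert np.allclose(phi.sum(axis=1), 1.0, atol=1e-9)
        planted = phi[cfg.planted_topic_index]
        dom = planted[list(cfg.dominant_genus_indices)]
        assert ((dom >= 0.35) & (dom <= 0.45)).all()

    def test_small_eta_gives_near_deterministic_topics(self):
        cfg = SimulationConfig(n_genera=30, k_true=4, topic_concentration=1e-3, rng_seed=2)
        phi = simulate_topics(cfg)
        others = np.delete(phi, cfg.planted_topic_index, axis=0)
        assert (others.max(axis=1) > 0.95).all()

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(rng_seed=5)
        assert np.array_equal(simulate_topics(cfg), simulate_topics(cfg))


class TestSimulateMetadata:
    def test_null_coupling_gives_no_correlation(self):
        cfg = SimulationConfig(
            n_subjects=2000, n_placebo=1000, beta_bop=0.0, ab_bop_suppression=1.0,
            rng_seed=3,
        )
        meta = simulate_metadata(cfg)
        base = meta[meta["visit"] == "V2"]
        r = np.corrcoef(base["oleary_pct"], base["bop_pct"])[0, 1]
        assert abs(r) < 0.05

    def test_bop_slope_recovered(self):
        cfg = SimulationConfig(n_subjects=2000, n_placebo=1000, rng_seed=4)
        meta = simulate_metadata(cfg)
        base = meta[meta["visit"] == "V2"]
        fit = stats.linregress(base["oleary_pct"], base["bop_pct"])
        assert abs(fit.slope - cfg.beta_bop) < 2 * fit.stderr

    def test_pretreatment_center_direction(self):
        cfg = SimulationConfig(n_subjects=800, n_placebo=400, rng_seed=5)
        meta = simulate_metadata(cfg)
        base = meta[meta["visit"] == "V2"]
        heavy = base[base["pretreatment_count"] == 5]["oleary_pct"].median()
        none = base[base["pretreatment_count"] == 0]["oleary_pct"].median()
        assert heavy < none

    def test_antibiotic_bop_suppressed_after_baseline(self):
        cfg = SimulationConfig(n_subjects=400, n_placebo=200, rng_seed=6)
        meta = simulate_metadata(cfg)
        v4 = meta[meta["visit"] == "V4"]
        ab = v4[v4["arm"] == "antibiotic"]["bop_pct"]
        pl = v4[v4["arm"] == "placebo"]["bop_pct"]
        assert ab.median() < pl.median()
        assert (ab < 25).mean() > 0.8

    def test_subject_constant_design(self):
        meta = simulate_metadata(SimulationConfig(n_subjects=50, n_placebo=25, rng_seed=7))
        per_subj = meta.groupby("subject_id")[["arm", "center_id"]].nunique()
        assert (per_subj == 1).all().all()
        assert meta.groupby("subject_id").size().eq(5).all()


class TestSimulateCounts:
    def test_fixed_library_size(self):
        cfg = SimulationConfig(
            n_subjects=20, n_genera=30, k_true=3, library_size_median=5000,
            library_size_sigma=0.0, rng_seed=8,
        )
        ds, truth = simulate_cohort(cfg)
        assert (ds.counts.counts.sum(axis=1) == 5000).all()
        assert np.array_equal(ds.counts.counts.sum(axis=1), truth.library_sizes)

    def test_simplex_invariants(self, small_cohort):
        _, _, truth = small_cohort
        assert np.abs(truth.phi_true.sum(axis=1) - 1).max() < 1e-9
        assert np.abs(truth.theta_true.sum(axis=1) - 1).max() < 1e-9

    def test_bit_reproducible(self):
        cfg = SimulationConfig(n_subjects=25, n_genera=25, k_true=3, rng_seed=9)
        ds1, t1 = simulate_cohort(cfg)
        ds2, t2 = simulate_cohort(cfg)
        assert np.array_equal(ds1.counts.counts, ds2.counts.counts)
        assert np.array_equal(t1.theta_true, t2.theta_true)
        assert ds1.metadata.equals(ds2.metadata)

    def test_marginal_frequencies_converge(self):
        cfg = SimulationConfig(
            n_subjects=5, visits=("V2",), n_genera=40, k_true=3,
            library_size_median=1e6, library_size_sigma=0.0, rng_seed=10,
        )
        ds, truth = simulate_cohort(cfg)
        freq = ds.counts.counts / ds.counts.counts.sum(axis=1, keepdims=True)
        expected = truth.theta_true @ truth.phi_true
        assert np.abs(freq - expected).sum(axis=1).max() < 0.02

    def test_null_effect_or_covers_one(self):
        cfg = SimulationConfig(
            n_subjects=400, n_placebo=200, beta_plaque=0.0, n_genera=30, k_true=4,
            library_size_median=2000, rng_seed=11,
        )
        ds, truth = simulate_cohort(cfg)
        assert truth.tilt_by_arm == {"placebo": 0.0, "antibiotic": 0.0}
        x = ds.metadata["oleary_pct"].to_numpy() / 10
        fit = sm.Logit(truth.high_state.astype(int), sm.add_constant(x)).fit(disp=0)
        lo, hi = fit.conf_int()[1]
        assert lo < 0.0 < hi

    def test_planted_or_recovered(self):
        """Logistic fit on ground-truth shares recovers OR 1.2 within [1.1, 1.3]."""
        cfg = SimulationConfig(
            n_subjects=800, n_placebo=400, n_genera=30, k_true=4,
            library_size_median=2000, rng_seed=12,
        )
        ds, truth = simulate_cohort(cfg)
        x = ds.metadata["oleary_pct"].to_numpy() / 10
        fit = sm.Logit(truth.high_state.astype(int), sm.add_constant(x)).fit(disp=0)
        assert 1.1 < math.exp(fit.params[1]) < 1.3

    def test_phi_shape_mismatch_rejected(self):
        cfg = SimulationConfig(n_subjects=10, rng_seed=13)
        meta = simulate_metadata(cfg)
        with pytest.raises(ConfigError):
            simulate_counts(cfg, np.ones((2, 2)) / 2, meta)
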