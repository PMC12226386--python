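"""Synthetic experiment generator: determinism, calibration to the
configured effect profiles, stream independence, and couplings."""

import numpy as np
import pytest

from nirtrs.autonomic import lf_hf, mean_hr_per_period
from nirtrs.design import ExperimentDesign
from nirtrs.pipeline import invert_tpsf_stream
from nirtrs.simulate import (
    CHANNEL_WAVELENGTHS,
    OXY_TARGETS,
    SimulationConfig,
    simulate_experiment,
    simulate_period_matrix,
    simulate_rr,
    simulate_subject_hb,
    simulate_tpsf_stream,
    simulate_vas,
    subject_z,
)
from nirtrs.stats import normalize_baseline, paired_t, segment_periods


def period_means(hb, design, channel="ch1", chrom="oxy"):
    s = hb[channel]
    vals = s.oxy_um if chrom == "oxy" else s.deoxy_um
    return segment_periods(normalize_baseline(vals, design), design)


class TestSubjectHb:
    def test_noiseless_flat_null(self, design):
        """Zero effects and zero noise: every period mean is exactly 1."""
        cfg = SimulationConfig.noiseless()
        for chan in ("ch1", "ch2"):
            cfg.oxy_targets[("creative", chan)] = np.ones(13)
            cfg.deoxy_targets[("creative", chan)] = np.ones(13)
        hb = simulate_subject_hb(cfg, 0, "creative", design)
        np.testing.assert_allclose(hb["ch1"].oxy_um, 25.0, rtol=1e-12)
        np.testing.assert_allclose(period_means(hb, design), 1.0, rtol=1e-12)

    def test_noiseless_reproduces_configured_targets_exactly(self, design):
        """With noise off the kinetics-smoothed series has period means
        equal to the per-period targets by construction."""
        cfg = SimulationConfig.noiseless()
        hb = simulate_subject_hb(cfg, 3, "creative", design)
        np.testing.assert_allclose(
            period_means(hb, design, "ch1", "oxy"),
            OXY_TARGETS[("creative", "ch1")],
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            period_means(hb, design, "ch2", "oxy"),
            OXY_TARGETS[("creative", "ch2")],
            rtol=1e-9,
        )

    def test_monte_carlo_grand_mean_matches_calibration(self, design):
        """200 subjects: the grand mean of the first post-task period in
        channel 1 lies within 2 SE of the configured 1.014 target."""
        cfg = SimulationConfig(seed=5)
        vals = [
            period_means(simulate_subject_hb(cfg, i, "creative", design), design)[10]
            for i in range(200)
        ]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(200)
        assert abs(vals.mean() - 1.014) <= 2 * se

    def test_seed_determinism(self, design):
        a = simulate_subject_hb(SimulationConfig(seed=9), 2, "simple", design)
        b = simulate_subject_hb(SimulationConfig(seed=9), 2, "simple", design)
        np.testing.assert_array_equal(a["ch1"].oxy_um, b["ch1"].oxy_um)
        np.testing.assert_array_equal(a["ch2"].deoxy_um, b["ch2"].deoxy_um)

    def test_stream_independence_across_conditions(self, design):
        """Changing only the creative profile leaves the simple-condition
        draws bit-identical under the same seed."""
        cfg_a = SimulationConfig(seed=4)
        cfg_b = SimulationConfig(seed=4)
        cfg_b.oxy_targets[("creative", "ch1")] = (
            cfg_b.oxy_targets[("creative", "ch1")] + 0.05
        )
        a = simulate_subject_hb(cfg_a, 1, "simple", design)
        b = simulate_subject_hb(cfg_b, 1, "simple", design)
        np.testing.assert_array_equal(a["ch1"].oxy_um, b["ch1"].oxy_um)
        np.testing.assert_array_equal(a["ch2"].oxy_um, b["ch2"].oxy_um)


class TestPeriodMatrixFastPath:
    def test_shapes_and_determinism(self):
        pm = simulate_period_matrix(SimulationConfig(seed=1))
        assert pm["oxy"].shape == (23, 2, 2, 13)
        pm2 = simulate_period_matrix(SimulationConfig(seed=1))
        np.testing.assert_array_equal(pm["oxy"], pm2["oxy"])

    def test_null_config_has_no_condition_effect(self):
        """Under the null configuration the paired t at the first post-task
        period is calibrated: over 300 replicates the rejection rate at
        alpha = 0.05 stays near alpha."""
        rej = 0
        for seed in range(300):
            pm = simulate_period_matrix(SimulationConfig.null(seed=seed))["oxy"]
            res = paired_t(pm[:, 0, 0, 10], pm[:, 1, 0, 10])
            rej += res.p < 0.05
        assert 0.02 <= rej / 300 <= 0.09


class TestRr:
    def test_flat_when_unmodulated(self, design):
        cfg = SimulationConfig(
            lf_mod_amp=0.0, hf_mod_amp=0.0, rr_jitter_s=0.0,
            hr_coupling_bpm=0.0, hr_between_sd_bpm=0.0,
        )
        rr = simulate_rr(cfg, 0, "simple", 0.0, design)
        np.testing.assert_allclose(rr.intervals, rr.intervals[0], rtol=1e-12)
        hr = mean_hr_per_period(rr, design)
        np.testing.assert_allclose(hr, 60.0 / rr.intervals[0], rtol=1e-12)

    def test_negative_post_task_hr_coupling(self, design):
        """Across 200 subjects, post-task HR correlates negatively with the
        responder z-score, detectable at alpha = 0.05."""
        cfg = SimulationConfig(seed=8)
        zs, hrs = [], []
        for i in range(200):
            z = subject_z(cfg, i)
            rr = simulate_rr(cfg, i, "creative", z, design)
            zs.append(z)
            hrs.append(np.nanmean(mean_hr_per_period(rr, design)[10:]))
        r = np.corrcoef(zs, hrs)[0, 1]
        t = r * np.sqrt(198) / np.sqrt(1 - r * r)
        assert r < 0 and abs(t) > 1.97

    def test_lf_hf_modulation_ratio(self, design):
        cfg = SimulationConfig(
            lf_mod_amp=0.08, hf_mod_amp=0.04, rr_jitter_s=0.0,
            hr_between_sd_bpm=0.0,
        )
        rr = simulate_rr(cfg, 0, "simple", 0.0, design)
        assert lf_hf(rr).lf_hf == pytest.approx(4.0, rel=0.20)

    def test_seed_determinism(self, design):
        a = simulate_rr(SimulationConfig(seed=3), 1, "creative", 0.5, design)
        b = simulate_rr(SimulationConfig(seed=3), 1, "creative", 0.5, design)
        np.testing.assert_array_equal(a.event_times, b.event_times)


class TestVas:
    def test_zero_sd_zero_coupling_returns_means(self):
        cfg = SimulationConfig(vas_coupling=0.0)
        cfg.vas_params = {
            k: (v[0], 0.0, v[2], 0.0, v[4]) for k, v in cfg.vas_params.items()
        }
        scores = simulate_vas(cfg, 0, "creative", 1.3)
        assert scores["enjoyment"] == pytest.approx(83.57)
        scores_s = simulate_vas(cfg, 0, "simple", 1.3)
        assert scores_s["enjoyment"] == pytest.approx(39.61)

    def test_clipping_to_scale_bounds(self):
        cfg = SimulationConfig()
        cfg.vas_params = {
            k: (95.0, 20.0, 95.0, 20.0, v[4]) for k, v in cfg.vas_params.items()
        }
        for i in range(50):
            for cond in ("simple", "creative"):
                scores = simulate_vas(cfg, i, cond)
                assert all(0.0 <= s <= 100.0 for s in scores.values())

    def test_pooled_enjoyment_oxy_correlation_near_target(self):
        """Pooling both conditions over 500 subjects, the enjoyment score
        correlates with the post-task oxy response in the configured
        0.5-0.6 band (within +-0.1)."""
        cfg = SimulationConfig(seed=2)
        pm = simulate_period_matrix(cfg, n_subjects=500)["oxy"]
        oxy, scores = [], []
        for i in range(500):
            z = subject_z(cfg, i)
            for ci, cond in enumerate(("simple", "creative")):
                oxy.append(pm[i, ci, 0, 10])
                scores.append(simulate_vas(cfg, i, cond, z)["enjoyment"])
        r = np.corrcoef(oxy, scores)[0, 1]
        assert 0.4 <= r <= 0.7


class TestTpsfStream:
    def test_noiseless_round_trip(self, design):
        """Expectation-curve TPSFs invert back to the concentrations to
        better than 0.1%."""
        cfg = SimulationConfig.noiseless()
        hb = simulate_subject_hb(cfg, 0, "creative", design)
        series = hb["ch1"]
        sub = type(series)(
            times=series.times[:3], oxy_um=series.oxy_um[:3], deoxy_um=series.deoxy_um[:3]
        )
        stream = simulate_tpsf_stream(
            sub, cfg, CHANNEL_WAVELENGTHS["ch1"], noiseless=True
        )
        oxy, deoxy = invert_tpsf_stream(stream)
        np.testing.assert_allclose(oxy, sub.oxy_um, rtol=1e-3)
        np.testing.assert_allclose(deoxy, sub.deoxy_um, rtol=1e-3)

    def test_photon_budget_round_trip_rmse(self, design):
        """At 1e6 photons per sample the recovered oxy series has RMSE
        below 2% of the true concentration."""
        cfg = SimulationConfig.noiseless(photons_per_sample=1_000_000)
        hb = simulate_subject_hb(cfg, 0, "creative", design)
        series = hb["ch1"]
        sub = type(series)(
            times=series.times[:6], oxy_um=series.oxy_um[:6], deoxy_um=series.deoxy_um[:6]
        )
        rng = np.random.default_rng(0)
        stream = simulate_tpsf_stream(sub, cfg, CHANNEL_WAVELENGTHS["ch1"], rng=rng)
        oxy, _ = invert_tpsf_stream(stream)
        rmse = np.sqrt(np.mean((oxy / sub.oxy_um - 1.0) ** 2))
        assert rmse <= 0.02

    def test_seeded_stream_identical(self, design):
        cfg = SimulationConfig()
        hb = simulate_subject_hb(SimulationConfig.noiseless(), 0, "simple", design)
        series = hb["ch1"]
        sub = type(series)(
            times=series.times[:2], oxy_um=series.oxy_um[:2], deoxy_um=series.deoxy_um[:2]
        )
        a = simulate_tpsf_stream(sub, cfg, CHANNEL_WAVELENGTHS["ch1"],
                                 rng=np.random.default_rng(11))
        b = simulate_tpsf_stream(sub, cfg, CHANNEL_WAVELENGTHS["ch1"],
                                 rng=np.random.default_rng(11))
        for (ta, tb) in zip(a, b):
            for x, y in zip(ta, tb):
                np.testing.assert_array_equal(x.counts, y.counts)


class TestFullExperiment:
    def test_same_seed_identical_bundle(self):
        cfg = SimulationConfig(seed=6, n_subjects=4)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        for key in a.hb:
            np.testing.assert_array_equal(
                a.hb[key]["ch1"].oxy_um, b.hb[key]["ch1"].oxy_um
            )
            np.testing.assert_array_equal(
                a.rr[key].event_times, b.rr[key].event_times
            )
        assert a.vas.equals(b.vas)
        assert a.manifest == b.manifest

    def test_power_self_consistency_at_post_task(self, design):
        """Default study, n = 23: the paired-t rejection frequency at the
        first post-task period tracks the power computed at the realized
        effect size (scaled replicate count)."""
        from nirtrs.stats import posthoc_power

        rej, dzs = 0, []
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed)
            pm_c = np.empty(23)
            pm_s = np.empty(23)
            for i in range(23):
                for cond, arr in (("creative", pm_c), ("simple", pm_s)):
                    hb = simulate_subject_hb(cfg, i, cond, design)
                    arr[i] = period_means(hb, design)[10]
            res = paired_t(pm_s, pm_c)
            rej += res.p < 0.05
            dzs.append(abs(res.d_z))
        predicted = posthoc_power(float(np.mean(dzs)), 23, 0.05)
        assert abs(rej / n_seeds - predicted) <= 0.15
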