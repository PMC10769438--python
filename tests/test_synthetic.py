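import numpy as np
import pytest
from scipy import stats

from bitescape import (
    CalibrationScale,
    GeneratorConfig,
    SurfaceParams,
    calibrate_track,
    generate_dataset,
    sample_kinematics,
    summarize_dataset,
    summarize_strike,
    true_performance,
)
from bitescape.errors import ValidationError
from bitescape.synthetic import simulate_strike


class TestPerformanceSurface:
    def test_value_at_bump_centers(self):
        p = SurfaceParams()
        for (cg, cj), amp in zip(p.centers, p.amplitudes):
            v = true_performance(cg, cj, p)
            # the other bump contributes a tiny positive tail
            assert p.baseline + amp <= v <= p.baseline + amp + 0.05

    def test_decays_to_baseline(self):
        p = SurfaceParams()
        assert true_performance(100.0, 100.0, p) == pytest.approx(
            p.baseline, abs=1e-6
        )

    def test_valley_between_peaks(self):
        p = SurfaceParams()
        (g1, j1), (g2, j2) = p.centers
        mid = true_performance((g1 + g2) / 2, (j1 + j2) / 2, p)
        assert mid < true_performance(g1, j1, p)
        assert mid < true_performance(g2, j2, p)


class TestConfigValidation:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(
                strike_type_probs={"edge": 0.5, "corner": 0.2, "scrape": 0.2, "miss": 0.2}
            )

    def test_scale_eater_protrusion_regime_enforced(self):
        means = {
            sp: dict(v) for sp, v in GeneratorConfig().kinematic_means.items()
        }
        means["scale_eater"]["jp"] = 5.0
        with pytest.raises(ValidationError):
            GeneratorConfig(kinematic_means=means)

    def test_strikes_capped_at_sixteen(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(strikes_per_individual=17)


class TestGeneration:
    def test_counts_match_config(self, default_dataset):
        assert len(default_dataset.tracks) == 4 * 5 * 8
        assert len(default_dataset.bites) == 160
        assert len(default_dataset.ground_truth) == 160

    def test_determinism_under_fixed_seed(self):
        cfg = GeneratorConfig(n_individuals=2, strikes_per_individual=3)
        a = generate_dataset(cfg, seed=9)
        b = generate_dataset(cfg, seed=9)
        for ta, tb in zip(a.tracks, b.tracks):
            np.testing.assert_array_equal(ta.coords, tb.coords)
        assert a.ground_truth.equals(b.ground_truth)

    def test_miss_rows_have_zero_dimensions(self, default_dataset):
        gt = default_dataset.ground_truth
        misses = gt[gt.strike_type == "miss"]
        assert len(misses) > 0
        assert (misses[["length_mm", "width_mm", "depth_mm"]] == 0).all().all()

    def test_emitted_length_tracks_true_performance(self):
        cfg = GeneratorConfig(n_individuals=10)
        ds = generate_dataset(cfg, seed=21, render_tracks=False)
        gt = ds.ground_truth
        hits = gt[gt.strike_type != "miss"]
        # remove the known offsets; the residual is performance + noise
        adj = (
            hits.length_mm
            - hits.individual_intercept
            - hits.species.map(cfg.species_length_offsets)
            - hits.strike_type.map(cfg.strike_type_length_offsets)
        )
        perf = true_performance(hits.g, hits.jp, cfg.surface)
        slope, _, _, _, se = stats.linregress(perf, adj)[:5]
        assert abs(slope - 1.0) < 3 * se

    def test_outputs_readable_via_io(self, tmp_path):
        from bitescape import load_bite_table, read_track

        cfg = GeneratorConfig(n_individuals=1, strikes_per_individual=2)
        ds = generate_dataset(cfg, seed=4, out_dir=tmp_path)
        tracks = sorted((tmp_path / "tracks").glob("*.h5"))
        assert len(tracks) == 8
        back = read_track(tracks[0])
        assert back.coords.shape[1] == 5
        assert len(load_bite_table(tmp_path / "bites.csv")) == 8


class TestKinematicMarginals:
    def test_sampled_gape_matches_config_distribution(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(77)
        draw = sample_kinematics(cfg, "generalist", 1000, rng)
        mu = cfg.kinematic_means["generalist"]["g"]
        sd = cfg.kinematic_sds["generalist"]["g"]
        _, p = stats.kstest((draw["g"] - mu) / sd, "norm")
        assert p > 0.01
        r = np.corrcoef(draw["g"], draw["jp"])[0, 1]
        assert abs(r - cfg.g_jp_corr) < 0.1


class TestRoundTrip:
    def test_same_seed_same_track(self):
        cfg = GeneratorConfig(landmark_jitter_px=2.0)
        row = {
            "strike_id": "s",
            "individual_id": "f",
            "species": "generalist",
            "strike_type": "edge",
            "g": 3.5,
            "jp": 3.0,
            "ja": 28.0,
            "ttpg": 6.36,
            "rs": 0.6,
        }
        t1, r1 = simulate_strike(row, cfg, np.random.default_rng(5))
        t2, r2 = simulate_strike(row, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(t1.coords, t2.coords)
        assert r1 == r2

    def test_noiseless_recovery_exact_to_frame(self, noiseless_dataset, scale):
        mpf = 1000.0 / 1100.0
        for track, (_, gt) in zip(
            noiseless_dataset.tracks, noiseless_dataset.ground_truth.iterrows()
        ):
            s = summarize_strike(calibrate_track(track, scale))
            assert s.peak_gape_mm == pytest.approx(gt.g, abs=1e-9)
            assert s.peak_protrusion_mm == pytest.approx(gt.jp, abs=1e-9)
            assert s.min_jaw_angle_deg == pytest.approx(gt.ja, abs=1e-9)
            assert abs(s.ttpg_ms - gt.ttpg) <= mpf + 1e-9
            assert s.ram_speed_m_s == pytest.approx(gt.rs, rel=1e-6)

    def test_jittered_recovery_unbiased(self):
        # default 5 px jitter at 10 px/mm
        cfg = GeneratorConfig(n_individuals=3, dropout_rate=0.0)
        ds = generate_dataset(cfg, seed=13)
        kin = summarize_dataset(
            (calibrate_track(t, CalibrationScale(cfg.px_per_mm)) for t in ds.tracks),
            smooth_window=21,
        )
        m = kin.merge(
            ds.ground_truth[["strike_id", "g", "jp"]],
            on="strike_id",
            suffixes=("_rec", "_true"),
        )
        assert abs((m.g_rec - m.g_true).mean()) < 0.2
        assert abs((m.jp_rec - m.jp_true).mean()) < 0.2

    def test_dropout_tracks_still_summarized(self, scale):
        cfg = GeneratorConfig(
            n_individuals=1, strikes_per_individual=4, dropout_rate=0.05
        )
        ds = generate_dataset(cfg, seed=6)
        kin = summarize_dataset(
            (calibrate_track(t, scale) for t in ds.tracks), smooth_window=21
        )
        assert len(kin) == len(ds.tracks)
        assert kin[["g", "jp"]].notna().all().all()
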