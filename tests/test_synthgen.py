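"""Generator: determinism, calibration of latent draws, render invariants."""

import numpy as np
import pytest
from scipy.stats import binom, truncnorm

from micropassage.errors import ConfigError
from micropassage.microdevice import ChannelGeometry
from micropassage.synthgen import (BeadParams, ColumnShape, NoiseParams,
                                   SynthConfig, default_geometry,
                                   render_bead_transit, render_lamina_panel,
                                   render_movie, sample_cohort,
                                   speed_law_parent_params)


def binomial_ok(count, n, p, conf=0.999):
    """Count lies inside the central binomial interval around p."""
    lo = binom.ppf((1 - conf) / 2, n, p)
    hi = binom.ppf(1 - (1 - conf) / 2, n, p)
    return lo <= count <= hi


class TestSpeedLaw:
    def test_moment_matched_parent(self):
        a, loc, scale = speed_law_parent_params(4.48, 3.93, 0.5)
        m, v = truncnorm.stats(a, np.inf, loc=loc, scale=scale, moments="mv")
        assert m == pytest.approx(4.48, abs=1e-6)
        assert np.sqrt(v) == pytest.approx(3.93, abs=1e-6)

    def test_draws_respect_floor_and_moments(self):
        cfg = SynthConfig(n_cells=20000, seed=9)
        speeds = np.array([c.v_free_um_min for c in sample_cohort(cfg)])
        assert speeds.min() >= cfg.speed_floor_um_min
        assert speeds.mean() == pytest.approx(4.48, abs=0.12)
        assert speeds.std(ddof=1) == pytest.approx(3.93, abs=0.15)

    def test_unmatchable_sd_rejected(self):
        with pytest.raises(ConfigError):
            speed_law_parent_params(4.0, 4.5, 0.5)


class TestSampleCohort:
    def test_same_seed_identical_latents(self):
        cfg = SynthConfig(n_cells=30, seed=12)
        a, b = sample_cohort(cfg), sample_cohort(cfg)
        assert all(x == y for x, y in zip(a, b))

    def test_forced_passage_probability_one(self):
        cfg = SynthConfig(n_cells=50, seed=13,
                          passage_prob_by_width={1.5: 1.0},
                          geometry=default_geometry(1.5))
        assert all(c.intended_outcome == "passed" for c in sample_cohort(cfg))

    def test_passage_calibration_at_large_n(self):
        # calibrated width response at W=1.5 -> 40% of draws pass
        cfg = SynthConfig(n_cells=10000, seed=14,
                          geometry=default_geometry(1.5))
        n_pass = sum(c.intended_outcome == "passed" for c in sample_cohort(cfg))
        assert binomial_ok(n_pass, 10000, 0.40)

    def test_enrichment_flags_conditioned_on_outcome(self):
        cfg = SynthConfig(n_cells=10000, seed=15,
                          geometry=default_geometry(1.5))
        cells = sample_cohort(cfg)
        passers = [c for c in cells if c.intended_outcome == "passed"]
        nonpass = [c for c in cells if c.nuclear_entry
                   and c.intended_outcome == "reversed"]
        assert binomial_ok(sum(c.enriched for c in passers), len(passers), 0.93)
        assert binomial_ok(sum(c.enriched for c in nonpass), len(nonpass), 0.25)

    def test_width_missing_and_interpolation_disabled(self):
        with pytest.raises(ConfigError):
            SynthConfig(geometry=default_geometry(1.75),
                        allow_width_interpolation=False).passage_prob()

    def test_slowdown_heterogeneity_keeps_cohort_mean(self):
        cfg = SynthConfig(n_cells=20000, seed=16,
                          geometry=default_geometry(1.5))
        slows = np.array([c.slowdown_fraction for c in sample_cohort(cfg)])
        assert slows.mean() == pytest.approx(0.41, abs=0.005)
        assert slows.std() == pytest.approx(0.10, abs=0.01)


class TestColumnShape:
    @pytest.mark.parametrize("com", [10.0, 76.0, 80.0, 85.0, 92.0, 100.0, 115.0])
    def test_interval_conserves_area_and_centroid(self, com):
        shape = ColumnShape(default_geometry(1.5), 7.0, 210.0)
        b, f = shape.interval_from_com(com)
        xs = np.linspace(b, f, 40001)
        w = shape.width_at(xs)
        area = np.trapezoid(w, xs)
        centroid = np.trapezoid(w * xs, xs) / area
        assert area == pytest.approx(210.0, rel=1e-4)
        assert centroid == pytest.approx(com, abs=2e-3)

    def test_free_shape_far_from_constriction(self):
        shape = ColumnShape(default_geometry(1.5), 7.0, 210.0)
        b, f = shape.interval_from_com(20.0)
        assert (b, f) == pytest.approx((5.0, 35.0))


class TestRenderMovie:
    def test_bitwise_determinism(self):
        cfg = SynthConfig(n_cells=1, seed=17, geometry=default_geometry(1.5))
        lat = sample_cohort(cfg)[0]
        m1, _ = render_movie(lat, cfg)
        m2, _ = render_movie(lat, cfg)
        assert np.array_equal(m1.frames, m2.frames)

    def test_event_time_ordering(self):
        cfg = SynthConfig(n_cells=25, seed=18, geometry=default_geometry(1.5))
        for lat in sample_cohort(cfg):
            _, truth = render_movie(lat, cfg)
            times = [truth.t_cell_entry_min, truth.t_nuc_entry_min,
                     truth.t_nuc_exit_min, truth.t_cell_exit_min]
            defined = [t for t in times if t is not None]
            assert defined == sorted(defined)
            if truth.outcome == "passed":
                assert truth.t_cell_exit_min is not None
            if truth.outcome.startswith("reversed"):
                assert truth.t_cell_exit_min is None
                assert truth.t_reversal_min is not None

    def test_dna_signal_conserved_prenoise(self, quiet_noise):
        cfg = SynthConfig(n_cells=2, seed=19, geometry=default_geometry(1.5),
                          force_outcome="passed", noise=quiet_noise)
        lat = sample_cohort(cfg)[0]
        movie, truth = render_movie(lat, cfg)
        dna = movie.channel("dna").astype(float)
        bg = cfg.shape.background
        totals = []
        for k in range(movie.n_frames):
            if truth.nuc_back_um[k] > 3 and truth.nuc_front_um[k] < 124:
                totals.append(dna[k].sum() - bg * dna[k].size)
        totals = np.array(totals)
        assert np.all(np.abs(totals / np.median(totals) - 1) < 0.02)

    def test_nucleus_width_clamped_to_constriction(self, quiet_noise):
        cfg = SynthConfig(n_cells=2, seed=20, geometry=default_geometry(1.5),
                          force_outcome="passed", noise=quiet_noise)
        lat = sample_cohort(cfg)[0]
        movie, truth = render_movie(lat, cfg)
        from micropassage.microdevice import constriction_mask
        inside = constriction_mask(cfg.geometry, cfg.frame_shape)
        px = cfg.geometry.pixel_size_um
        for k in range(movie.n_frames):
            nm = truth.nucleus_mask(k) & inside
            if nm.any():
                width = nm.sum(axis=0).max() * px
                assert width <= cfg.geometry.constriction_width_um + 1e-9

    def test_nonnegative_pixels(self):
        cfg = SynthConfig(n_cells=1, seed=21, geometry=default_geometry(1.5))
        movie, _ = render_movie(sample_cohort(cfg)[0], cfg)
        assert movie.frames.min() >= 0


class TestLaminaPanel:
    def test_zero_rupture_probability(self):
        cfg = SynthConfig(n_cells=30, seed=22,
                          rupture_prob_by_condition={"straight_channel": 0.0})
        panel = render_lamina_panel(cfg, "straight_channel")
        assert all(not t.ruptured for _, t in panel)

    def test_rupture_calibration(self):
        cfg = SynthConfig(n_cells=2000, seed=23)
        panel = render_lamina_panel(cfg, "long_constriction")
        n_rupt = sum(t.ruptured for _, t in panel)
        assert binomial_ok(n_rupt, 2000, 0.87)

    def test_arc_length_formula(self):
        # 60 deg gap on a circle of diameter 10 um -> pi*10/6 ~ 5.24 um
        from micropassage.synthgen import LaminaTruth
        t = LaminaTruth(index=0, condition="straight_channel", ruptured=True,
                        gap_span_deg=60.0, gap_center_deg=0.0,
                        tip_localized=True, semi_axis_a_um=5.0,
                        semi_axis_b_um=5.0)
        assert t.rupture_perimeter_um == pytest.approx(np.pi * 10 / 6, rel=1e-3)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ConfigError):
            render_lamina_panel(SynthConfig(n_cells=1), "no_such_condition")


class TestBeadTransit:
    def test_unmatched_width_paints_no_ring(self):
        cfg = SynthConfig(n_cells=10, seed=24, geometry=default_geometry(3.5),
                          force_outcome="passed",
                          bead_params=BeadParams(p_peribead_accumulation=1.0))
        for lat in sample_cohort(cfg):
            _, truth = render_bead_transit(lat, cfg)
            assert not truth.bead_ring_active.any()

    def test_oversized_bead_stalls_at_entrance(self):
        cfg = SynthConfig(n_cells=5, seed=25, geometry=default_geometry(2.5),
                          force_outcome="passed", bead_params=BeadParams())
        for lat in sample_cohort(cfg):
            _, truth = render_bead_transit(lat, cfg)
            assert truth.bead_stalled
            bead_front = truth.bead_center_x_um + 1.5
            assert np.all(bead_front <= cfg.geometry.entrance_x_um + 1e-9)

    def test_matched_width_ring_every_inside_frame(self):
        cfg = SynthConfig(n_cells=5, seed=26, geometry=default_geometry(3.0),
                          force_outcome="passed",
                          bead_params=BeadParams(p_peribead_accumulation=1.0))
        lo, hi = cfg.geometry.inside_interval_um
        for lat in sample_cohort(cfg):
            _, truth = render_bead_transit(lat, cfg)
            inside = (truth.bead_center_x_um >= lo) & (truth.bead_center_x_um < hi)
            assert np.array_equal(truth.bead_ring_active, inside)

    def test_bead_wider_than_channel_rejected(self):
        cfg = SynthConfig(n_cells=1, seed=27, geometry=default_geometry(3.0),
                          bead_params=BeadParams(diameter_um=8.0))
        with pytest.raises(ConfigError):
            render_bead_transit(sample_cohort(cfg)[0], cfg)


class TestConfigValidation:
    def test_probability_out_of_range(self):
        with pytest.raises(ConfigError):
            SynthConfig(p_enrich_passer=1.4)

    def test_constriction_must_fit_in_frame(self):
        g = ChannelGeometry(7, 5, 2, 10, 400.0, 0.25)
        with pytest.raises(ConfigError):
            SynthConfig(geometry=g)
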