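"""Intensity normalization metrics, shape metrics and enrichment calls."""

import numpy as np
import pandas as pd
import pytest

from micropassage.actinquant import (EnrichmentParams, actin_around_bead,
                                     actin_vs_position_profile,
                                     dna_thickness_actin_relation,
                                     enrichment_flag,
                                     normalized_actin_in_constriction,
                                     normalized_perinuclear_actin,
                                     nuclear_circularity)
from micropassage.errors import (BeadOutsideCell, BorderTouchWarning,
                                 CellNotInConstriction, InsufficientColumns,
                                 NaNIntensity, UndefinedBaseline)
from micropassage.events import PassageEvent
from micropassage.microdevice import ChannelGeometry
from micropassage.segment import FrameMasks, cortex_mask, \
    perinuclear_cortex_mask
from .conftest import make_disk

GEOM = ChannelGeometry(channel_width_um=7.0, channel_height_um=5.0,
                       constriction_width_um=2.0, constriction_length_um=10.0,
                       constriction_center_x_um=20.0, pixel_size_um=0.5)
# inside interval [15, 25) um -> columns 30..49


def simple_masks(shape=(40, 100)):
    cell = np.zeros(shape, bool)
    cell[10:30, 10:70] = True
    nucleus = np.zeros(shape, bool)
    nucleus[14:26, 30:50] = True
    cortex = cortex_mask(cell)
    peri = perinuclear_cortex_mask(cortex, nucleus)
    return FrameMasks(cell=cell, nucleus=nucleus, cortex=cortex,
                      perinuclear_cortex=peri)


class TestNormalizedActinInConstriction:
    def test_uniform_cell_exactly_one(self):
        fm = simple_masks()
        frame = np.full(fm.cell.shape, 37.0)
        assert normalized_actin_in_constriction(frame, fm.cell, GEOM) == 1.0

    def test_pixel_sum_arithmetic(self):
        # 100-px cell: 20 px in constriction at 30, 80 px outside at 5
        g = ChannelGeometry(7, 5, 2, 5, 12.5, 1.0)   # columns 10..14 inside
        cell = np.zeros((10, 30), bool)
        cell[0:4, 10:15] = True                       # 20 px inside
        cell[0:8, 0:10] = True                        # 80 px outside
        frame = np.full((10, 30), 5.0)
        frame[0:4, 10:15] = 30.0
        val = normalized_actin_in_constriction(frame, cell, g)
        assert val == pytest.approx(30.0 / 10.0)

    def test_cell_outside_constriction(self):
        cell = np.zeros((40, 100), bool)
        cell[10:30, 60:90] = True
        with pytest.raises(CellNotInConstriction):
            normalized_actin_in_constriction(np.ones((40, 100)), cell, GEOM)

    def test_multiplicative_scaling_invariance(self):
        fm = simple_masks()
        rng = np.random.default_rng(0)
        frame = rng.uniform(1, 10, fm.cell.shape)
        v1 = normalized_actin_in_constriction(frame, fm.cell, GEOM)
        v2 = normalized_actin_in_constriction(7.3 * frame, fm.cell, GEOM)
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestNormalizedPerinuclearActin:
    def test_uniform_cell_exactly_one(self):
        fm = simple_masks()
        frame = np.full(fm.cell.shape, 12.0)
        assert normalized_perinuclear_actin(frame, fm) == 1.0

    def test_zero_intensity_degenerate(self):
        fm = simple_masks()
        with pytest.raises(NaNIntensity):
            normalized_perinuclear_actin(np.zeros(fm.cell.shape), fm)

    def test_ring_raises_ratio(self):
        fm = simple_masks()
        frame = np.full(fm.cell.shape, 10.0)
        frame[fm.perinuclear_cortex] = 30.0
        assert normalized_perinuclear_actin(frame, fm) > 1.5


class TestEnrichmentFlag:
    def _series(self, values):
        return pd.Series(values, index=range(len(values)), dtype=float)

    def _event(self, entry=10.0, exit_=16.0):
        return PassageEvent(t_cell_entry_min=4.0, t_nuc_entry_min=entry,
                            t_nuc_exit_min=exit_, t_cell_exit_min=20.0,
                            outcome="passed", nuclear_entry_flag=True)

    def test_flat_series_not_flagged(self):
        s = self._series([1.0] * 12)
        flag, peak = enrichment_flag(s, self._event(), 2.0)
        assert not flag and peak == 1.0

    def test_clear_peak_flagged(self):
        s = self._series([1.0, 1.02, 0.98, 1.0, 0.99, 2.0, 2.2, 2.1, 1.0,
                          1.0, 1.0, 1.0])
        flag, peak = enrichment_flag(s, self._event(), 2.0)
        assert flag and peak == pytest.approx(2.2)

    def test_peak_outside_window_ignored(self):
        s = self._series([1.0, 1.0, 1.0, 1.0, 3.0, 1.0, 1.0, 1.0, 1.0,
                          2.5, 1.0, 1.0])
        # peak at frame 4 (pre-entry) contaminates the baseline instead of
        # the window -> adaptive threshold rises, frame-9 peak must clear it
        flag, _ = enrichment_flag(s, self._event(), 2.0,
                                  EnrichmentParams(k_sd=2.0, floor=1.2))
        assert not flag

    def test_too_few_baseline_frames(self):
        s = self._series([1.0, 1.0, 2.0, 2.0])
        ev = PassageEvent(t_cell_entry_min=0.0, t_nuc_entry_min=4.0,
                          t_nuc_exit_min=6.0, t_cell_exit_min=None,
                          outcome="passed", nuclear_entry_flag=True)
        with pytest.raises(UndefinedBaseline):
            enrichment_flag(s, ev, 2.0)

    @pytest.mark.parametrize("p_enrich, bound, above", [
        (1.0, 0.95, True),    # detector recovers nearly all true rings
        (0.0, 0.05, False),   # and stays quiet on never-enriched cohorts
    ])
    def test_generator_truth_recovery(self, p_enrich, bound, above):
        from micropassage.pipeline import measure_enrichment
        from micropassage.synthgen import SynthConfig, default_geometry
        cfg = SynthConfig(n_cells=40, seed=71 + int(p_enrich),
                          geometry=default_geometry(2.0),
                          force_outcome="passed", p_enrich_passer=p_enrich)
        r = measure_enrichment(cfg)
        if above:
            assert r["fraction_enriched"] >= bound
        else:
            assert r["fraction_enriched"] <= bound


class TestActinVsPositionProfile:
    def test_uniform_cell_profile_one(self):
        pos = pd.Series(np.linspace(0, 40, 21))
        val = pd.Series(np.ones(21))
        prof = actin_vs_position_profile([(pos, val)], GEOM, bin_width_um=2.0)
        filled = prof[prof["n"] > 0]
        assert np.allclose(filled["mean_norm_actin"], 1.0)

    def test_empty_bins_reported(self):
        pos = pd.Series([0.0, 30.0])
        val = pd.Series([1.0, 2.0])
        prof = actin_vs_position_profile([(pos, val)], GEOM, bin_width_um=2.0)
        empty = prof[prof["n"] == 0]
        assert len(empty) > 0
        assert empty["mean_norm_actin"].isna().all()

    def test_peak_inside_constriction_on_synthetic_passers(self):
        from micropassage.pipeline import AnalysisParams, analyze_movie
        from micropassage.synthgen import (SynthConfig, default_geometry,
                                           render_movie, sample_cohort)
        cfg = SynthConfig(n_cells=10, seed=73, geometry=default_geometry(2.0),
                          force_outcome="passed", p_enrich_passer=1.0)
        records = []
        for lat in sample_cohort(cfg):
            movie, _ = render_movie(lat, cfg)
            res = analyze_movie(movie, cfg.geometry,
                                AnalysisParams(measure_actin=True))
            if res.perinuclear is not None:
                records.append((res.track["nuc_com_x_um"], res.perinuclear))
        prof = actin_vs_position_profile(records, cfg.geometry, 2.0)
        filled = prof[(prof["n"] >= 5)].dropna(subset=["mean_norm_actin"])
        peak_pos = filled.loc[filled["mean_norm_actin"].idxmax(),
                              "bin_center_um"]
        assert abs(peak_pos) <= cfg.geometry.constriction_length_um / 2 + 2.0


class TestNuclearCircularity:
    def test_disk_identity(self):
        assert nuclear_circularity(make_disk(20)) == pytest.approx(1.0,
                                                                   abs=0.02)

    def test_square_closed_form(self):
        sq = np.zeros((44, 44))
        sq[7:37, 7:37] = 1.0
        assert nuclear_circularity(sq) == pytest.approx(np.pi / 4, abs=0.02)

    def test_thin_line_low_circularity(self):
        line = np.zeros((40, 40))
        line[20, 2:38] = 1.0
        assert nuclear_circularity(line) < 0.1

    def test_isoperimetric_bound(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = np.zeros((50, 50))
            y, x = rng.integers(10, 30, 2)
            m[y:y + rng.integers(5, 18), x:x + rng.integers(5, 18)] = 1.0
            assert nuclear_circularity(m) <= 1.02

    def test_border_touch_warns(self):
        m = np.zeros((20, 20))
        m[0:10, 5:15] = 1.0
        with pytest.warns(BorderTouchWarning):
            nuclear_circularity(m)


class TestDnaThicknessActinRelation:
    # wide constriction (W=5) so the tapered nucleus has sub-W columns
    G5 = ChannelGeometry(channel_width_um=7.0, channel_height_um=5.0,
                         constriction_width_um=5.0,
                         constriction_length_um=10.0,
                         constriction_center_x_um=20.0, pixel_size_um=0.5)

    def _tapered_fixture(self, actin_vs_thickness):
        """Elliptical nucleus inside the constriction; actin painted on the
        cortex as a function of the local nucleus thickness."""
        shape = (40, 100)
        cell = np.zeros(shape, bool)
        cell[8:32, 20:80] = True
        nucleus = np.zeros(shape, bool)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        # ellipse centered at (20, 40): axial semi-axis 18 px, transverse 3
        ell = (((xx - 40) / 18.0) ** 2 + ((yy - 20) / 3.0) ** 2) <= 1.0
        nucleus[ell] = True
        cortex = cortex_mask(cell)
        dna = np.full(shape, 5.0)
        actin = np.full(shape, 10.0)
        thick = nucleus.sum(axis=0) * GEOM.pixel_size_um
        for j in np.flatnonzero(nucleus.any(axis=0)):
            dna[nucleus[:, j], j] = 100.0 / max(thick[j], 0.5)
            actin[cortex[:, j], j] = actin_vs_thickness(thick[j])
        return FrameMasks(cell=cell, nucleus=nucleus, cortex=cortex), dna, actin

    def test_anticorrelation_recovered(self):
        fm, dna, actin = self._tapered_fixture(lambda t: 10.0 + 30.0 * (2.0 - t))
        table, slope, _ = dna_thickness_actin_relation(fm, dna, actin, self.G5)
        assert slope < 0
        # thinner columns are denser by construction
        r = np.corrcoef(table["dna_thickness_um"],
                        table["dna_mean_intensity"])[0, 1]
        assert r < -0.5

    def test_uniform_actin_flat_slope(self):
        fm, dna, actin = self._tapered_fixture(lambda t: 10.0)
        _, slope, _ = dna_thickness_actin_relation(fm, dna, actin, self.G5)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_thick_nucleus_insufficient_columns(self):
        shape = (40, 100)
        cell = np.zeros(shape, bool)
        cell[8:32, 20:80] = True
        nucleus = np.zeros(shape, bool)
        nucleus[14:26, 30:50] = True    # 6 um thick everywhere >= W=2
        fm = FrameMasks(cell=cell, nucleus=nucleus, cortex=cortex_mask(cell))
        with pytest.raises(InsufficientColumns):
            dna_thickness_actin_relation(fm, np.ones(shape), np.ones(shape),
                                         GEOM)


class TestActinAroundBead:
    def _bead_setup(self):
        shape = (40, 100)
        cell = np.zeros(shape, bool)
        cell[5:35, 10:90] = True
        beads = np.zeros(shape, int)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        beads[(yy - 20) ** 2 + (xx - 50) ** 2 <= 36] = 1
        return cell, beads

    def test_uniform_cell_ratio_one(self):
        cell, beads = self._bead_setup()
        frame = np.full(cell.shape, 9.0)
        assert actin_around_bead(frame, beads, 1, cell) == pytest.approx(1.0)

    def test_ring_detected(self):
        cell, beads = self._bead_setup()
        frame = np.full(cell.shape, 10.0)
        yy, xx = np.mgrid[0:40, 0:100]
        ring = np.abs(np.hypot(yy - 20, xx - 50) - 6) < 2
        frame[ring] = 40.0
        assert actin_around_bead(frame, beads, 1, cell) > 1.5

    def test_bead_speed_uncorrelated_with_annulus_actin(self):
        # rigid-bead cohort: actin accumulation is confinement-driven, so
        # per-cell bead speed and peribead actin density are independent
        from scipy.stats import spearmanr
        from micropassage.errors import MicropassageError
        from micropassage.segment import segment_beads, segment_cell
        from micropassage.synthgen import (BeadParams, SynthConfig,
                                           default_geometry,
                                           render_bead_transit,
                                           sample_cohort)
        cfg = SynthConfig(n_cells=100, seed=79, geometry=default_geometry(3.0),
                          force_outcome="passed", bead_params=BeadParams())
        speeds, densities = [], []
        for lat in sample_cohort(cfg):
            movie, _ = render_bead_transit(lat, cfg)
            bead_ch = movie.channel("bead")
            actin_ch = movie.channel("actin")
            centers, vals = {}, {}
            for t in range(movie.n_frames):
                lab = segment_beads(bead_ch[t], 1.5, cfg.geometry)
                if lab.max() == 0:
                    continue
                ys, xs = np.nonzero(lab == 1)
                centers[t] = (xs.mean() + 0.5) * cfg.geometry.pixel_size_um
                try:
                    cell = segment_cell(actin_ch[t])
                    vals[t] = actin_around_bead(actin_ch[t], lab, 1, cell)
                except MicropassageError:
                    continue
            lo, hi = cfg.geometry.inside_interval_um
            inside = sorted(t for t in vals if lo <= centers[t] < hi)
            # speed over the constriction neighbourhood: fast beads cross
            # the constriction itself in fewer than two frames
            near = sorted(t for t in centers
                          if lo - 8.0 <= centers[t] < hi + 8.0)
            if not inside or len(near) < 2:
                continue
            dt = movie.frame_interval_min
            speeds.append((centers[near[-1]] - centers[near[0]])
                          / ((near[-1] - near[0]) * dt))
            densities.append(np.mean([vals[t] for t in inside]))
        rho = spearmanr(speeds, densities).statistic
        assert len(speeds) >= 80
        assert abs(rho) < 0.2

    def test_bead_outside_cell(self):
        cell, beads = self._bead_setup()
        cell[:, 40:] = False
        with pytest.raises(BeadOutsideCell):
            actin_around_bead(np.ones(cell.shape), beads, 1, cell)
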