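"""Heatmap pipeline: windows, phase-matched baselines, ROI recovery."""

import numpy as np
import pytest

from respigate.circular_stats import TWO_PI
from respigate.receptive_field_mapping import (
    BlockStimulus,
    build_heatmap,
    control_window,
    extract_roi,
    peristimulus_histogram,
    phase_conditioned_baseline,
    response_window,
    smooth_covered,
    stimuli_hitting_roi,
)
from respigate.synthetic_data import (
    PhaseLockSpec,
    PlantedResponseSpec,
    PlantedSite,
    synth_session,
)

from conftest import make_session


class TestWindows:
    @pytest.mark.parametrize("onset,duration,margin,expected", [
        (0.0, 200.0, 50.0, (0.0, 150.0)),
        (0.0, 100.0, 50.0, (0.0, 50.0)),
        (300.0, 200.0, 0.0, (300.0, 500.0)),
    ])
    def test_response_window(self, onset, duration, margin, expected):
        stim = BlockStimulus(0, 0, onset, duration)
        assert response_window(stim, margin) == expected

    def test_response_window_shorter_than_margin_errors(self):
        with pytest.raises(ValueError, match="non-positive"):
            response_window(BlockStimulus(0, 0, 0.0, 40.0), 50.0)

    def test_control_window_between_stimuli(self):
        stim = BlockStimulus(0, 0, 500.0, 100.0)
        assert control_window(stim, prev_offset=300.0, gap=50.0) == (350.0, 500.0)

    def test_control_window_skipped_when_too_tight(self):
        stim = BlockStimulus(0, 0, 340.0, 100.0)
        assert control_window(stim, prev_offset=300.0, gap=50.0) is None


class TestBaseline:
    def test_homogeneous_poisson_flat_profile(self):
        # no phase modulation: every bin's mean should sit near 8 Hz
        session, _ = synth_session(
            n_stimuli=500, baseline=PhaseLockSpec(baseline_rate=8.0,
                                                  peak_rate=8.0), seed=21)
        prof = phase_conditioned_baseline(session, n_bins=12)
        se = prof.sd_rate / np.sqrt(np.maximum(prof.n_windows, 1))
        ok = np.abs(prof.mean_rate - 8.0) <= 2 * se + 1.0
        assert ok.all()

    def test_zero_spikes_zero_baseline(self, tiny_session):
        tiny_session.spikes = np.empty(0)
        prof = phase_conditioned_baseline(tiny_session, n_bins=4)
        filled = prof.n_windows > 0
        assert np.all(prof.mean_rate[filled] == 0.0)
        assert np.all(prof.sd_rate[filled] == 0.0)

    def test_phase_locked_baseline_peaks_at_planted_angle(self):
        spec = PhaseLockSpec(center_angle=np.pi, width=0.4,
                             baseline_rate=2.0, peak_rate=60.0)
        session, _ = synth_session(n_stimuli=500, baseline=spec, seed=22)
        prof = phase_conditioned_baseline(session, n_bins=12)
        hot = int(np.nanargmax(prof.mean_rate))
        center = (hot + 0.5) * TWO_PI / 12
        assert abs(center - np.pi) < TWO_PI / 12 + 1e-9


class TestBuildHeatmap:
    def _one_block_session(self, simple_map, spikes):
        rows = [(300.0, 300.0, 100.0, 1000.0, 200.0, np.nan)]
        return make_session(spikes, rows, simple_map)

    def test_single_block_deposit_counts(self, simple_phase_map):
        from respigate.receptive_field_mapping import BaselineProfile
        session = self._one_block_session(simple_phase_map,
                                          [1010.0, 1050.0, 1100.0])
        # baseline: expected 1 spike per 150 ms response window
        base = BaselineProfile(np.linspace(0, TWO_PI, 13),
                               np.full(12, 1 / 0.15), np.zeros(12),
                               np.ones(12, dtype=int))
        hmap = build_heatmap(session, base, k=0.0, sigma=0.0, units="counts")
        covered = hmap.grid[hmap.covered]
        np.testing.assert_allclose(covered, 2.0)
        assert np.isnan(hmap.grid[~hmap.covered]).all()
        assert hmap.coverage[~hmap.covered].sum() == 0

    def test_overlap_average(self, simple_phase_map):
        # two blocks sharing half their footprint, deposits 2 and 4
        rows = [(200.0, 200.0, 100.0, 1000.0, 200.0, np.nan),
                (250.0, 200.0, 100.0, 1400.0, 200.0, np.nan)]
        spikes = [1000.5, 1001.0,                      # 2 spikes in block 1
                  1400.5, 1401.0, 1401.5, 1402.0]      # 4 spikes in block 2
        session = make_session(spikes, rows, simple_phase_map)
        hmap = build_heatmap(session, None, sigma=0.0, units="counts")
        vals = np.unique(np.round(hmap.grid[hmap.covered], 9))
        np.testing.assert_allclose(vals, [2.0, 3.0, 4.0])

    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(30, 30))
        covered = rng.uniform(size=(30, 30)) > 0.4
        out = smooth_covered(grid, covered, 0.0)
        np.testing.assert_array_equal(out[covered], grid[covered])
        assert np.isnan(out[~covered]).all()

    def test_normalized_smoothing_ignores_uncovered(self):
        grid = np.zeros((40, 40))
        covered = np.zeros((40, 40), dtype=bool)
        covered[:, :20] = True
        grid[:, :20] = 5.0
        out = smooth_covered(grid, covered, 3.0)
        # a plain Gaussian would drag edge values toward 0
        np.testing.assert_allclose(out[covered], 5.0, rtol=1e-6)

    def test_empty_phase_selection_errors(self, tiny_session):
        with pytest.raises(ValueError, match="empty selection"):
            build_heatmap(tiny_session, None, phase_range=(2.0, 2.001))


class TestExtractRoi:
    def _map(self, grid, coverage=None):
        from respigate.receptive_field_mapping import Heatmap
        cov = np.ones_like(grid, dtype=int) if coverage is None else coverage
        return Heatmap(np.asarray(grid, dtype=float), cov, 0.0, 4.0)

    def test_gaussian_bump_single_roi(self):
        yy, xx = np.mgrid[0:50, 0:50]
        grid = 10 * np.exp(-((xx - 25) ** 2 + (yy - 25) ** 2) / 30.0)
        rois = extract_roi(self._map(grid), "excitatory", threshold=5.0,
                           min_pixels=10, min_coverage=1)
        assert len(rois) == 1
        cx, cy = rois[0].centroid_um
        assert abs(cx - 25.5 * 4) < 4 and abs(cy - 25.5 * 4) < 4

    def test_all_zero_map_empty(self):
        assert extract_roi(self._map(np.zeros((20, 20))), "excitatory", 5.0,
                           min_pixels=1, min_coverage=1) == []

    def test_inhibitory_dark_regions(self):
        grid = np.full((20, 20), 10.0)
        grid[5:10, 5:10] = 1.0   # quiet region on an unsubtracted map
        rois = extract_roi(self._map(grid), "inhibitory", threshold=8.0,
                           min_pixels=1, min_coverage=1)
        assert len(rois) == 1
        assert rois[0].n_pixels == 25
        assert rois[0].peak_value == 1.0


class TestPlantedRecovery:
    def test_excitatory_and_suppressive_sites_recovered(self):
        planted = PlantedResponseSpec(
            excitatory_sites=[PlantedSite(150.0, 450.0, gain=12.0)],
            inhibitory_sites=[PlantedSite(450.0, 150.0, suppression=0.95,
                                          diameter=120.0)])
        baseline = PhaseLockSpec(center_angle=0.0, width=0.6,
                                 baseline_rate=6.0, peak_rate=30.0)
        session, _ = synth_session(n_stimuli=700, field_size=(600.0, 600.0),
                                   planted=planted, baseline=baseline, seed=30)
        base = phase_conditioned_baseline(session)
        hot = build_heatmap(session, base, k=1.5, sigma=1.0)
        rois = extract_roi(hot, "excitatory", threshold=0.0, min_pixels=25)
        assert rois, "planted excitatory site not detected"
        cx, cy = rois[0].centroid_um
        assert np.hypot(cx - 150.0, cy - 450.0) < 100.0
        raw = build_heatmap(session, None, sigma=4.0)
        dark = extract_roi(raw, "inhibitory", threshold=8.0, min_pixels=25)
        # one dark region must contain the planted suppressive centre
        assert any(r.mask[int(150 / 4), int(450 / 4)] for r in dark)


class TestStimuliHittingRoi:
    def _roi_mask(self, session, x0, x1, y0, y1):
        from respigate.receptive_field_mapping import ROI
        mask = np.zeros(session.grid_shape, dtype=bool)
        px = session.pixel
        mask[int(y0 / px):int(y1 / px), int(x0 / px):int(x1 / px)] = True
        return ROI(mask, "excitatory", 0.0, 1.0)

    def test_exact_cover_fraction_one(self, tiny_session):
        # pixelised footprint of block 1 (48-152 um spans whole block)
        roi = self._roi_mask(tiny_session, 48, 152, 48, 152)
        hits = stimuli_hitting_roi(tiny_session, roi)
        assert len(hits) == 1
        assert hits.iloc[0]["overlap_fraction"] == pytest.approx(1.0)

    def test_disjoint_block_excluded(self, tiny_session):
        roi = self._roi_mask(tiny_session, 500, 560, 500, 560)
        assert len(stimuli_hitting_roi(tiny_session, roi)) == 0

    def test_half_overlap_fraction(self, tiny_session):
        # ROI covers the left half of block 1 (x up to its center at 100)
        roi = self._roi_mask(tiny_session, 48, 100, 48, 152)
        hits = stimuli_hitting_roi(tiny_session, roi)
        assert hits.iloc[0]["overlap_fraction"] == pytest.approx(0.5, abs=0.05)


class TestPeristimulus:
    def test_single_trial_counts(self, simple_phase_map):
        rows = [(100.0, 100.0, 100.0, 1000.0, 100.0, np.nan)]
        session = make_session([1010.0, 1030.0], rows, simple_phase_map)
        psth = peristimulus_histogram(session, bin_ms=25.0, t_max=100.0)
        np.testing.assert_allclose(psth["rate"][:2] * 0.025, [1.0, 1.0])
        assert psth["rate"][2:].sum() == 0

    def test_identical_trials_zero_se(self, simple_phase_map):
        rows = [(100.0, 100.0, 100.0, float(o), 100.0, np.nan)
                for o in (1000.0, 2000.0, 3000.0)]
        spikes = [o + d for o in (1000.0, 2000.0, 3000.0) for d in (10.0, 30.0)]
        session = make_session(spikes, rows, simple_phase_map)
        psth = peristimulus_histogram(session, bin_ms=25.0, t_max=100.0)
        np.testing.assert_allclose(psth["se"], 0.0)

    def test_poisson_rate_recovered(self):
        session, truth = synth_session(
            n_stimuli=400, baseline=PhaseLockSpec(baseline_rate=20.0,
                                                  peak_rate=20.0), seed=40)
        psth = peristimulus_histogram(session, bin_ms=25.0, t_max=100.0)
        se = psth["se"]
        assert np.all(np.abs(psth["rate"] - 20.0) < 2 * se + 2.0)

    def test_spike_conservation_against_interval_queries(self, tiny_session):
        psth = peristimulus_histogram(tiny_session, bin_ms=50.0, t_max=200.0)
        total = psth["rate"].sum() * 0.05 * psth["n_trials"]
        direct = sum(tiny_session.spike_count(o, o + 200.0)
                     for o in tiny_session.stimuli["onset"])
        assert total == pytest.approx(direct)
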