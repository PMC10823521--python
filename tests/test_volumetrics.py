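"""Background refill, volume integration, step detection and statistics."""

import numpy as np
import pytest

from nucleoafm import synthetic as syn, volumetrics as vol


def _disc_mask(shape=(40, 40), center=(20, 20), r=6):
    y, x = np.indices(shape)
    return np.hypot(y - center[0], x - center[1]) <= r


class TestBackground:
    @pytest.mark.parametrize("method", ["inpaint", "laplacian"])
    def test_flat_background_refilled_flat(self, method):
        frame = np.zeros((40, 40))
        mask = _disc_mask()
        frame[mask] += 5.0
        bg = vol.estimate_background(frame, mask, method=method)
        assert np.abs(bg[mask]).max() < 0.05
        assert np.array_equal(bg[~mask], frame[~mask])

    def test_empty_mask_returns_frame(self):
        frame = np.random.default_rng(0).normal(size=(20, 20))
        bg = vol.estimate_background(frame, np.zeros((20, 20), bool))
        assert np.array_equal(bg, frame)

    @pytest.mark.parametrize("method", ["inpaint", "laplacian"])
    def test_linear_ramp_reproduced(self, method):
        y, x = np.indices((40, 40), dtype=float)
        frame = 0.05 * x + 0.02 * y
        mask = _disc_mask()
        bumped = frame.copy()
        bumped[mask] += 4.0
        bg = vol.estimate_background(bumped, mask, method=method)
        assert np.abs(bg[mask] - frame[mask]).max() < 0.1

    def test_full_mask_rejected(self):
        with pytest.raises(ValueError):
            vol.estimate_background(np.zeros((10, 10)),
                                    np.ones((10, 10), bool))

    def test_laplacian_and_inpaint_volumes_agree(self, centered_nucleosome):
        frame, mask, _ = centered_nucleosome
        particle = mask == 1
        nonempty = mask > 0
        vs = {}
        for method in ("inpaint", "laplacian"):
            bg = vol.estimate_background(frame, nonempty, method=method)
            vs[method] = vol.particle_volume(frame, particle, bg, 1.9)
        assert vs["laplacian"] == pytest.approx(vs["inpaint"], rel=0.10)


class TestVolume:
    def test_particle_at_background_height_is_zero(self):
        frame = np.full((20, 20), 1.3)
        assert vol.particle_volume(frame, _disc_mask((20, 20), (10, 10), 4),
                                   frame, 1.9) == 0.0

    def test_rendered_cap_within_2pct_of_closed_form(self, centered_nucleosome):
        frame, mask, state = centered_nucleosome
        bg = np.zeros_like(frame)
        v = vol.particle_volume(frame, mask == 1, bg, 1.9)
        assert v == pytest.approx(state.nominal_volume, rel=0.02)

    def test_volume_additivity_disjoint_particles(self):
        frame = np.zeros((40, 80))
        m1 = _disc_mask((40, 80), (20, 20), 6)
        m2 = _disc_mask((40, 80), (20, 60), 8)
        frame[m1] = 3.0
        frame[m2] = 2.0
        bg = np.zeros_like(frame)
        v1 = vol.particle_volume(frame, m1, bg, 1.0)
        v2 = vol.particle_volume(frame, m2, bg, 1.0)
        assert vol.particle_volume(frame, m1 | m2, bg, 1.0) == \
            pytest.approx(v1 + v2)

    def test_pixel_size_convergence_monotone(self):
        from nucleoafm.benchmarks import cap_volume_error
        errs = [cap_volume_error(p) for p in (1.9, 1.0, 0.5)]
        assert errs[0] >= errs[1] >= errs[2] or max(errs) < 0.002

    def test_simulated_nucleosome_lands_in_band(self, small_movie):
        from nucleoafm import pipeline
        from nucleoafm.preprocess import RasterStack
        stack = RasterStack(small_movie.frames, small_movie.pixel_size,
                            small_movie.fps)
        tab = pipeline.measure_volumes(stack, small_movie.truth_masks)
        pre = tab[tab.frame < 10].V_nm3.mean()
        assert 594.8 - 116.3 < pre < 594.8 + 116.3


class TestSteps:
    def test_null_trace_no_events(self):
        rng = np.random.default_rng(0)
        V = 500.0 + rng.normal(0, 30.0, 100)
        assert vol.detect_steps(V, fps=1.0) == []

    def test_single_planted_step_recovered(self):
        rng = np.random.default_rng(1)
        V = np.full(100, 600.0)
        V[47:] -= 200.0
        V += rng.normal(0, 30.0, 100)
        events = vol.detect_steps(V, fps=1.0)
        assert len(events) == 1
        assert abs(events[0].frame - 47) <= 1
        assert -events[0].dV == pytest.approx(200.0, rel=0.15)
        assert events[0].mode == "sudden"

    def test_two_steps_recovered_in_order(self):
        rng = np.random.default_rng(2)
        V = np.full(120, 700.0)
        V[40:] -= 200.0
        V[80:] -= 120.0
        V += rng.normal(0, 20.0, 120)
        events = vol.detect_steps(V, fps=1.0, min_step=100.0)
        assert len(events) == 2
        assert events[0].frame < events[1].frame
        assert -events[0].dV == pytest.approx(200.0, rel=0.15)
        assert -events[1].dV == pytest.approx(120.0, rel=0.2)

    def test_gradual_drop_classified_gradual(self):
        V = np.full(60, 600.0)
        V[30:] = 400.0
        V[29] = 550.0
        V[30] = 480.0
        V[31] = 430.0
        events = vol.detect_steps(V, fps=2.0, sigma=10.0, min_step=100.0)
        assert len(events) == 1
        assert events[0].mode == "gradual"

    def test_short_trace_warns_no_detection(self):
        with pytest.warns(UserWarning):
            assert vol.detect_steps(np.arange(5.0)) == []


class TestStates:
    @pytest.mark.parametrize("v,expect", [
        (594.8, "nucleosome"),
        (351.7, "tetrasome"),
        (470.2, "hexasome"),
    ])
    def test_band_means_map_to_species(self, v, expect):
        assert vol.assign_state(v) == expect

    def test_tie_breaks_to_lower_volume_state(self):
        # construct equal standardized distances between two bands
        bands = vol.StateBands((("a", 500.0, 50.0), ("b", 400.0, 50.0)))
        assert vol.assign_state(450.0, bands) == "b"

    def test_far_outlier_unassigned(self):
        assert vol.assign_state(5000.0) == "unassigned"

    def test_state_sequence_on_segments(self):
        V = np.concatenate([np.full(20, 594.8), np.full(20, 470.2)])
        ev = vol.detect_steps(V, fps=1.0, sigma=5.0, min_step=80.0)
        assert vol.state_sequence(V, ev) == ["nucleosome", "hexasome"]


class TestLifetimes:
    def test_unit_step_cdf(self):
        records, t, F = vol.first_ejection_stats([10.0] * 5, [60.0] * 5)
        assert records.observed.all()
        assert F[-1] == 1.0
        assert np.all(t[1:] == 10.0)

    def test_cdf_monotone_bounded(self):
        rng = np.random.default_rng(0)
        times = list(rng.exponential(20, 30)) + [None] * 5
        _, t, F = vol.first_ejection_stats(times, [100.0] * 35)
        assert np.all(np.diff(F) >= 0)
        assert F[-1] <= 1.0

    def test_censoring_recorded(self):
        records, *_ = vol.first_ejection_stats([5.0, None], [60.0, 60.0])
        assert list(records.observed) == [True, False]
        assert records.time_s.iloc[1] == 60.0


class TestMixture:
    def test_unimodal_prefers_k1(self):
        rng = np.random.default_rng(0)
        fit = vol.fit_mixture_aic(rng.normal(500, 60, 500), seed=0)
        assert fit.k == 1

    def test_trimodal_prefers_k3(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(350, 20, 170),
                            rng.normal(470, 20, 170),
                            rng.normal(600, 20, 160)])
        fit = vol.fit_mixture_aic(x, seed=0)
        assert fit.k == 3

    def test_aic_definition(self):
        rng = np.random.default_rng(2)
        fit = vol.fit_mixture_aic(rng.normal(0, 1, 200), k_candidates=(1,),
                                  seed=0)
        # k=1: two free parameters (mean, variance) plus no free weights
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.log_likelihood,
                                        rel=1e-6)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            vol.fit_mixture_aic(np.full(50, 3.0))


class TestRms:
    def test_constant(self):
        assert vol.rms_of_trace([4.0] * 7) == pytest.approx(4.0)

    def test_two_samples(self):
        assert vol.rms_of_trace([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.normal(500, 80, 64)
        assert vol.rms_of_trace(x) == pytest.approx(
            float(np.sqrt(sum(v * v for v in x) / len(x))))
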