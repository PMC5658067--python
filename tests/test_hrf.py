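"""FIR design/extraction, leave-n-out HRF, gamma-variate fit, HR metrics."""

import numpy as np
import pytest

from swbold import glm as G
from swbold.hrf import (
    FIRConfig,
    assemble_leave_n_out_hrf,
    build_fir_design,
    canonical_hrf,
    extract_mean_hr,
    fit_fir,
    fit_gamma_variate,
    quantify_hr,
    select_top_voxels,
)
from swbold.simulate import (
    BoldSimConfig,
    default_hrf_params,
    sample_hrf_kernel,
    simulate_bold_session,
)
from swbold.types import (
    BoldSession,
    EventArray,
    GammaVariateParams,
    HemodynamicResponse,
    SlowWaveVector,
)


def sw_from_onsets(onsets, n_volumes, tr=1.0):
    bins = np.zeros(n_volumes, dtype=np.int8)
    bins[np.asarray(onsets, dtype=int)] = 1
    return SlowWaveVector(bins, tr)


class TestFirDesign:
    def test_single_onset_puts_one_indicator_per_column(self):
        sw = sw_from_onsets([25], 50)
        design = build_fir_design(sw)
        X = design.matrix
        assert X.shape == (50, 40)
        assert np.all(X.sum(axis=0) == 1)
        for j, t in enumerate(design.bin_times_s):
            assert X[25 + int(t), j] == 1

    def test_zero_vector_rejected(self):
        sw = SlowWaveVector(np.zeros(50, dtype=np.int8), 1.0)
        with pytest.raises(ValueError, match="no events"):
            build_fir_design(sw)

    def test_jittered_overlapping_onsets_remain_identifiable(self):
        rng = np.random.default_rng(0)
        onsets = np.unique(rng.integers(0, 280, 40))
        design = build_fir_design(sw_from_onsets(onsets, 300))
        assert np.linalg.matrix_rank(design.matrix) == 40

    def test_bin_width_must_match_tr(self):
        sw = sw_from_onsets([25], 50, tr=2.0)
        with pytest.raises(ValueError, match="TR"):
            build_fir_design(sw)


class TestFitFir:
    @staticmethod
    def _session_from_signal(sig_pct, n_vox=4):
        # voxel mean exactly 100 so % conversion is exact
        data = 100.0 + np.tile(sig_pct - sig_pct.mean(), (n_vox, 1))
        return BoldSession(data.reshape(2, 2, 1, -1), tr_s=1.0)

    def test_noiseless_nonoverlapping_events_recover_kernel_exactly(self):
        # kernel support restricted to the modeled FIR window (0-19 s)
        kernel = sample_hrf_kernel(default_hrf_params(), 1.0)[:20]
        onsets = np.array([30, 90, 150])
        neural = np.zeros(220)
        neural[onsets] = 1.0
        sig = np.convolve(neural, kernel)[:220]
        bold = self._session_from_signal(sig)
        design = build_fir_design(sw_from_onsets(onsets, 220))
        glm = fit_fir(bold, design, ar1=0.0)
        betas = glm.betas[1:41, 0]
        post = design.bin_times_s >= 0
        assert np.allclose(betas[post], kernel, atol=1e-9)
        assert np.allclose(betas[~post], 0.0, atol=1e-9)

    def test_overlapping_events_equal_pseudoinverse_solution(self):
        rng = np.random.default_rng(3)
        kernel = sample_hrf_kernel(default_hrf_params(), 1.0)
        onsets = np.sort(rng.choice(np.arange(25, 270), 35, replace=False))
        neural = np.zeros(300)
        neural[onsets] = 1.0
        sig = np.convolve(neural, kernel)[:300] + rng.normal(0, 0.1, 300)
        bold = self._session_from_signal(sig)
        design = build_fir_design(sw_from_onsets(onsets, 300))
        glm = fit_fir(bold, design, ar1=0.0)
        # independent normal-equations oracle on the same % data
        y = bold.masked_timeseries()[:, 0]
        y = 100.0 * (y - y.mean()) / y.mean()
        X = np.column_stack([np.ones(300), design.matrix])
        oracle = np.linalg.pinv(X) @ y
        assert np.allclose(glm.betas[:, 0], oracle, atol=1e-6)

    def test_pure_noise_voxel_not_significant(self):
        rng = np.random.default_rng(4)
        bold = self._session_from_signal(rng.normal(0, 1.0, 400))
        design = build_fir_design(sw_from_onsets([50, 120, 200, 300], 400))
        glm = fit_fir(bold, design, ar1=0.0)
        _, p_map = G.f_test(glm, np.arange(40))
        assert p_map[0, 0, 0] > 0.01


class TestSelectTopVoxels:
    @staticmethod
    def _toy_maps():
        f = np.random.default_rng(0).uniform(1, 2, (6, 6, 3))
        f[:, :, 1] += 10.0
        # slice 1 has the most suprathreshold voxels and anchors the pick
        p = np.full(f.shape, 0.5)
        p[:, :, 1] = 0.001
        p[:3, :, 0] = 0.001
        p[:3, :, 2] = 0.001
        return f, p

    def test_selects_highest_f_per_slice(self):
        f, p = self._toy_maps()
        picks = select_top_voxels(f, p, n_per_slice=10)
        assert picks.shape == (30, 3)
        assert sorted(np.unique(picks[:, 2])) == [0, 1, 2]
        for z in (0, 1, 2):
            sel = picks[picks[:, 2] == z]
            assert sel.shape[0] == 10
            eligible = f[:, :, z][p[:, :, z] < 0.05]
            f_sel = f[sel[:, 0], sel[:, 1], z]
            assert f_sel.min() >= np.sort(eligible)[-10]

    def test_excluded_voxel_replaced_by_next_ranked(self):
        f, p = self._toy_maps()
        top = np.unravel_index(np.argmax(f[:, :, 1]), (6, 6))
        excl = np.zeros(f.shape, dtype=bool)
        excl[top[0], top[1], 1] = True
        picks = select_top_voxels(f, p, n_per_slice=10, exclusion_mask=excl)
        assert not any((x, y, z) == (top[0], top[1], 1) for x, y, z in picks)

    def test_no_active_voxels_is_an_error(self):
        f = np.zeros((4, 4, 2))
        p = np.ones((4, 4, 2))
        with pytest.raises(ValueError, match="no active"):
            select_top_voxels(f, p)

    def test_sparse_slice_takes_all_with_warning(self):
        f, p = self._toy_maps()
        p[:, :, 0] = 0.5
        p[:3, 0, 0] = 0.001
        with pytest.warns(UserWarning, match="eligible"):
            picks = select_top_voxels(f, p, n_per_slice=10)
        assert (picks[:, 2] == 0).sum() == 3


class TestLeaveNOut:
    @staticmethod
    def _hrs():
        t = np.arange(-20.0, 20.0)
        return [HemodynamicResponse(t, np.roll(np.eye(1, 40, 26)[0] * (i + 1), 0))
                for i in range(3)]

    def test_average_excludes_held_out_session(self):
        hrs = self._hrs()
        # poison the held-out session: the result must not change
        hrs_poisoned = [hrs[0],
                        HemodynamicResponse(hrs[1].times_s, hrs[1].values),
                        hrs[2]]
        hrs_poisoned[1] = HemodynamicResponse(hrs[1].times_s,
                                              hrs[1].values * 1e6)
        t_a, k_a = assemble_leave_n_out_hrf(hrs, held_out=1)
        t_b, k_b = assemble_leave_n_out_hrf(hrs_poisoned, held_out=1)
        assert np.array_equal(k_a, k_b)

    def test_identical_sessions_give_that_hr_unit_peak(self):
        t = np.arange(-20.0, 20.0)
        v = np.exp(-0.5 * ((t - 6.5) / 2.5) ** 2) * 0.17
        hrs = [HemodynamicResponse(t, v)] * 3
        tk, k = assemble_leave_n_out_hrf(hrs, held_out=0)
        assert k.max() == pytest.approx(1.0)
        assert tk[0] >= 0.0 and tk[-1] <= 15.0

    def test_single_session_is_circular(self):
        with pytest.raises(ValueError, match="circular"):
            assemble_leave_n_out_hrf(self._hrs()[:1], held_out=0)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError, match="range"):
            assemble_leave_n_out_hrf(self._hrs(), held_out=5)


class TestCanonicalHrf:
    def test_peak_between_5_and_6_seconds(self):
        t, h = canonical_hrf(1.0)
        assert 5.0 <= t[np.argmax(h)] <= 6.0

    def test_starts_at_zero_with_positive_mass(self):
        t, h = canonical_hrf(0.5)
        assert h[0] == 0.0
        assert h.sum() > 0


class TestGammaVariateFit:
    def test_exact_samples_recovered_to_1e6(self):
        params = GammaVariateParams(t0_s=1.0, alpha=2.0, beta_s=1.5, amp=0.2)
        t = np.arange(-20.0, 20.0)
        hr = HemodynamicResponse(t, params(t))
        fit, r2 = fit_gamma_variate(hr)
        assert fit.t0_s == pytest.approx(1.0, abs=1e-6)
        assert fit.alpha == pytest.approx(2.0, abs=1e-5)
        assert fit.beta_s == pytest.approx(1.5, abs=1e-5)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        # peak location closed form: t0 + alpha*beta
        assert fit.time_to_peak_s == pytest.approx(4.0, abs=1e-5)

    def test_flat_zero_response_rejected(self):
        t = np.arange(-20.0, 20.0)
        with pytest.raises(ValueError):
            fit_gamma_variate(HemodynamicResponse(t, np.zeros(40)))


class TestQuantifyHr:
    def test_symmetric_triangle_geometry(self):
        t = np.arange(0.0, 11.0)
        v = 1.0 - np.abs(t - 5.0) / 5.0
        q = quantify_hr(hr=HemodynamicResponse(t, v))
        assert q.ttp_s == pytest.approx(5.0, abs=1e-9)
        assert q.dsa_pct == pytest.approx(1.0, abs=1e-9)
        assert q.hmd_s == pytest.approx(5.0, abs=1e-9)

    def test_all_zero_response_flagged_undefined(self):
        t = np.arange(0.0, 20.0)
        q = quantify_hr(hr=HemodynamicResponse(t, np.zeros(20)))
        assert not q.defined

    def test_published_hr_shape_recovered_from_coarse_samples(self):
        # gamma variate built to the published descriptors, sampled at TR
        from swbold.simulate import gamma_variate_from_shape

        params = gamma_variate_from_shape(6.5, 6.8, t0_s=0.7, amp=0.17)
        t = np.arange(-20.0, 20.0)
        q = quantify_hr(hr=HemodynamicResponse(t, params(t)))
        assert q.ttp_s == pytest.approx(6.5, abs=0.2)
        assert q.dsa_pct == pytest.approx(0.17, rel=0.02)
        assert q.hmd_s == pytest.approx(6.8, abs=0.2)

    def test_fit_based_quantification_matches_parameters(self):
        params = GammaVariateParams(t0_s=0.7, alpha=4.0, beta_s=1.45, amp=0.17)
        q = quantify_hr(fit=params)
        assert q.ttp_s == pytest.approx(params.time_to_peak_s, abs=1e-6)
        assert q.dsa_pct == pytest.approx(0.17)
        assert q.onset_latency_s == pytest.approx(0.7)


class TestFirRecoveryInvariant:
    def test_mean_extracted_hr_correlates_with_planted_kernel(self):
        # >=200 jittered events, noise at the default level
        rng = np.random.default_rng(6)
        onsets, t = [], 25.0
        while t < 1480.0:
            onsets.append(t)
            t += 3.0 + rng.exponential(2.5)
        events = EventArray(np.array(onsets), np.full(len(onsets), 1.3), 1500.0)
        assert len(onsets) >= 200
        cfg = BoldSimConfig(grid_shape=(6, 6, 2), n_volumes=1500, seed=7)
        res = simulate_bold_session(cfg, events)
        sw = sw_from_onsets(np.floor(events.onsets_s).astype(int), 1500)
        design = build_fir_design(sw)
        glm = fit_fir(res.session, design)
        voxels = np.argwhere(res.cortical_mask)
        hr = extract_mean_hr(glm, design, voxels)
        post = hr.times_s >= 0
        r = np.corrcoef(hr.values[post], res.kernel[:20])[0, 1]
        assert r >= 0.95

    def test_thirty_identical_voxels_average_to_single_voxel_hr(self):
        kernel = sample_hrf_kernel(default_hrf_params(), 1.0)
        neural = np.zeros(200)
        neural[[30, 90, 150]] = 1.0
        sig = np.convolve(neural, kernel)[:200]
        data = 100.0 + np.tile(sig - sig.mean(), (30, 1)).reshape(5, 6, 1, 200)
        bold = BoldSession(data, tr_s=1.0)
        design = build_fir_design(sw_from_onsets([30, 90, 150], 200))
        glm = fit_fir(bold, design, ar1=0.0)
        all_vox = np.argwhere(np.ones((5, 6, 1), dtype=bool))
        hr_all = extract_mean_hr(glm, design, all_vox)
        hr_one = extract_mean_hr(glm, design, all_vox[:1])
        assert np.allclose(hr_all.values, hr_one.values, atol=1e-9)
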