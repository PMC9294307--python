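import numpy as np
import pytest
from scipy.special import eval_legendre

from cibalance.containers import Evoked, SourceMap
from cibalance.preprocess import preprocess_epochs
from cibalance.source_imaging import (LEFT_AC_ROI, RIGHT_AC_ROI, RoiSpec,
                                      _sphere_potentials, build_head_model,
                                      compute_leadfield,
                                      estimate_artifact_subspace,
                                      extract_roi_peak, omnibus_threshold,
                                      project_out_subspace, pseudo_z_map,
                                      source_timecourses, tracs_weights)
from cibalance.synthetic import (SimulationConfig, default_sources,
                                 simulate_epochs)


# --------------------------------------------------------------------------
# head model construction
# --------------------------------------------------------------------------

class TestHeadModel:
    def test_defaults_valid(self):
        m = build_head_model()
        assert m.radii == (80.0, 85.0, 92.0)

    def test_zero_conductivity_rejected(self):
        with pytest.raises(ValueError):
            build_head_model(conductivities=(0.33, 0.0, 0.33))

    def test_nonincreasing_radii_rejected(self):
        with pytest.raises(ValueError):
            build_head_model(radii=(85.0, 80.0, 92.0))


# --------------------------------------------------------------------------
# analytic forward solution against an independent series oracle
# --------------------------------------------------------------------------

def homogeneous_sphere_oracle(dip_pos, q, electrodes, R, sigma, n_terms=150):
    """Closed-form homogeneous-sphere surface potential.

    Independent implementation: analytic per-degree coefficient (2n+1)/n with
    scipy Legendre polynomials and numerically differentiated P'_n.
    """
    b = np.linalg.norm(dip_pos)
    zh = dip_pos / b if b > 0 else np.array([0.0, 0.0, 1.0])
    out = np.zeros(len(electrodes))
    R_m = R / 1000.0
    h = 1e-6
    for i, e in enumerate(electrodes):
        eh = e / np.linalg.norm(e)
        x = float(eh @ zh)
        u = eh - x * zh
        v = 0.0
        for n in range(1, n_terms + 1):
            coef = (2 * n + 1) / n * (b / R) ** (n - 1)
            dPn = (eval_legendre(n, x + h) - eval_legendre(n, x - h)) / (2 * h)
            v += coef * (n * eval_legendre(n, x) * (q @ zh) + dPn * (q @ u))
        out[i] = v * 1e-9 / (4 * np.pi * sigma * R_m ** 2) * 1e6
    return out


class TestSpherePotentials:
    R, SIGMA = 92.0, 0.33

    @pytest.fixture(scope="class")
    def electrodes(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=(24, 3))
        return e / np.linalg.norm(e, axis=1, keepdims=True) * self.R

    @pytest.fixture(scope="class")
    def homogeneous(self):
        return build_head_model(radii=(90.0, 91.0, self.R),
                                conductivities=(self.SIGMA,) * 3)

    @pytest.mark.parametrize("moment", [(30.0, 0.0, 0.0), (0.0, 0.0, 30.0),
                                        (10.0, -20.0, 15.0)])
    def test_matches_single_sphere_closed_form(self, electrodes, homogeneous,
                                               moment):
        c = np.array([0.0, 0.0, 50.0])
        q = np.array(moment)
        L = _sphere_potentials(c[None], electrodes, homogeneous, n_terms=120)
        v = L[:, 0, :] @ q
        oracle = homogeneous_sphere_oracle(c, q, electrodes, self.R, self.SIGMA)
        assert np.abs(v - oracle).max() <= 0.01 * np.abs(oracle).max()

    def test_centered_dipole_is_classic_cosine_pattern(self, electrodes,
                                                       homogeneous):
        # V = 3 q cos(theta) / (4 pi sigma R^2) for a dipole at the centre
        q = 20.0
        L = _sphere_potentials(np.zeros((1, 3)), electrodes, homogeneous)
        v = L[:, 0, :] @ np.array([0.0, 0.0, q])
        expected = (3 * q * 1e-9 * (electrodes[:, 2] / self.R)
                    / (4 * np.pi * self.SIGMA * (self.R / 1000.0) ** 2) * 1e6)
        assert np.allclose(v, expected, rtol=1e-10)

    def test_linearity_in_moment(self, electrodes, homogeneous):
        c = np.array([-30.0, 10.0, 40.0])
        L = _sphere_potentials(c[None], electrodes, homogeneous)
        q = np.array([5.0, -3.0, 8.0])
        assert np.allclose(L[:, 0, :] @ (2 * q), 2 * (L[:, 0, :] @ q))

    def test_dipole_outside_brain_rejected(self, electrodes):
        head = build_head_model()
        with pytest.raises(ValueError):
            _sphere_potentials(np.array([[0.0, 0.0, 85.0]]), electrodes, head)


class TestLeadfieldGrid:
    def test_grid_inside_brain_shell(self, leadfield10, head):
        assert (np.linalg.norm(leadfield10.grid, axis=1)
                <= head.brain_radius).all()
        assert leadfield10.n_excluded > 0

    def test_car_reference_zeroes_rows(self, head, montage62):
        _, chan_pos, _ = montage62
        lf = compute_leadfield(head, 25.0, chan_pos, reference="car")
        assert np.allclose(lf.matrix.mean(axis=0), 0.0, atol=1e-12)

    def test_invalid_spacing_rejected(self, head, montage62):
        _, chan_pos, _ = montage62
        with pytest.raises(ValueError):
            compute_leadfield(head, -5.0, chan_pos)


# --------------------------------------------------------------------------
# artifact subspace and beamformer constraints
# --------------------------------------------------------------------------

def simulated_ci2(head, n_epochs=50, seed=3, artifact=500.0):
    cfg = SimulationConfig(n_epochs=n_epochs, seed=seed, noise_sd=15.0,
                           artifact_amplitude=artifact)
    srcs = default_sources(cfg, amp_left=70.0, amp_right=45.0,
                           morphology="immature_NciPci")
    return cfg, simulate_epochs(cfg, srcs, head, artifact_sides=("left",),
                                condition="CI2")


class TestArtifactSubspace:
    def test_recovers_rank1_topography(self, head):
        from cibalance.synthetic import artifact_topography
        _, ep = simulated_ci2(head)
        evoked, clean, _ = preprocess_epochs(ep)
        A = estimate_artifact_subspace(evoked, rank=1)
        true = artifact_topography(ep.channel_positions, "left")
        true = true - true.mean()
        true /= np.linalg.norm(true)
        assert abs(float(A[:, 0] @ true)) >= 0.99

    def test_orthonormal_columns(self, head):
        _, ep = simulated_ci2(head)
        evoked, _, _ = preprocess_epochs(ep)
        A = estimate_artifact_subspace(evoked, rank=3)
        assert np.allclose(A.T @ A, np.eye(3), atol=1e-10)

    def test_rank_at_channel_count_rejected(self, head):
        _, ep = simulated_ci2(head, n_epochs=5)
        evoked, _, _ = preprocess_epochs(ep)
        with pytest.raises(ValueError):
            estimate_artifact_subspace(evoked, rank=62)

    def test_projection_removes_subspace(self, head):
        _, ep = simulated_ci2(head)
        evoked, _, _ = preprocess_epochs(ep)
        A = estimate_artifact_subspace(evoked, rank=1)
        cleaned = project_out_subspace(evoked, A)
        assert np.allclose(A.T @ cleaned.data[cleaned.good_mask()], 0.0,
                           atol=1e-9)


class TestBeamformerConstraints:
    def test_unit_gain_and_artifact_nulls(self, head, leadfield20):
        _, ep = simulated_ci2(head, n_epochs=30)
        evoked, clean, _ = preprocess_epochs(ep)
        A = estimate_artifact_subspace(evoked, rank=1)
        w = tracs_weights(clean, leadfield20, A)
        good = w.good_channels
        L = leadfield20.matrix[good]
        L = L - L.mean(axis=0, keepdims=True)
        for v in (0, w.weights.shape[0] // 2, w.weights.shape[0] - 1):
            gain = w.weights[v].T @ L[:, v, :]
            assert np.allclose(gain, np.eye(3), atol=1e-8)
            assert np.abs(w.weights[v].T @ A).max() <= 1e-8

    def test_scalar_mode_unit_gain(self, head, leadfield20):
        _, ep = simulated_ci2(head, n_epochs=30)
        _, clean, _ = preprocess_epochs(ep)
        w = tracs_weights(clean, leadfield20, None, orientation="scalar")
        assert w.weights.shape[2] == 1

    def test_negative_regularization_rejected(self, head, leadfield20):
        _, ep = simulated_ci2(head, n_epochs=5)
        _, clean, _ = preprocess_epochs(ep)
        with pytest.raises(ValueError):
            tracs_weights(clean, leadfield20, None, regularization=-1.0)


# --------------------------------------------------------------------------
# pseudo-Z statistic and omnibus threshold
# --------------------------------------------------------------------------

def toy_weights_and_evoked(signal_level, noise_sd, seed=0, n_base=1000):
    """One-voxel identity filter over a synthetic source time course."""
    from cibalance.source_imaging import BeamformerWeights

    rng = np.random.default_rng(seed)
    times = np.arange(-n_base, 200.0)
    data = rng.normal(0.0, noise_sd, (1, times.size))
    data[0, times >= 90] += signal_level
    pos = np.array([[0.0, 0.0, 92.0]])
    ev = Evoked(data=data, times=times, channel_positions=pos, fs=1000.0,
                reference="CAR")
    w = BeamformerWeights(weights=np.ones((1, 1, 1)),
                          grid=np.zeros((1, 3)), spacing=10.0,
                          good_channels=np.array([True]),
                          flagged=np.array([False]),
                          covariance_window=(36.0, 400.0), regularization=0.05)
    return w, ev


class TestPseudoZ:
    def test_signal_mean_equal_to_baseline_sd_gives_pz_one(self):
        w, ev = toy_weights_and_evoked(signal_level=0.0, noise_sd=1.0)
        bmask = ev.time_mask(-1000, -80)
        sd = ev.data[0, bmask].std(ddof=1)
        ev.data[0, ev.times >= 90] = sd
        smap = pseudo_z_map(w, ev, (95.0, 99.0), (-1000.0, -80.0))
        assert smap.pz[0] == pytest.approx(1.0, rel=0.05)

    def test_scale_invariance(self):
        w, ev = toy_weights_and_evoked(signal_level=5.0, noise_sd=1.0)
        a = pseudo_z_map(w, ev, (95.0, 99.0), (-1000.0, -80.0)).pz[0]
        ev.data *= 3.7
        b = pseudo_z_map(w, ev, (95.0, 99.0), (-1000.0, -80.0)).pz[0]
        assert b == pytest.approx(a, rel=1e-9)

    def test_five_sigma_signal_estimates_pz_five(self):
        # Monte-Carlo oracle: many long baselines, mean signal planted at 5 sd
        vals = [pseudo_z_map(*toy_weights_and_evoked(5.0, 1.0, seed=s,
                                                     n_base=4000),
                             (95.0, 120.0), (-4000.0, -80.0)).pz[0]
                for s in range(20)]
        assert np.mean(vals) == pytest.approx(5.0, rel=0.10)

    def test_overlapping_windows_rejected(self):
        w, ev = toy_weights_and_evoked(5.0, 1.0)
        with pytest.raises(ValueError):
            pseudo_z_map(w, ev, (-100.0, -90.0), (-1000.0, -80.0))

    def test_zero_baseline_sd_names_voxel(self):
        w, ev = toy_weights_and_evoked(5.0, 0.0)
        ev.data[:, ev.times < 0] = 0.0
        with pytest.raises(ZeroDivisionError, match="voxel 0"):
            pseudo_z_map(w, ev, (95.0, 99.0), (-1000.0, -80.0))


class TestOmnibus:
    def test_alpha_one_is_minimum_of_max_pz(self):
        w, ev = toy_weights_and_evoked(0.0, 1.0)
        t1 = omnibus_threshold(w, ev, (-1000.0, -80.0), alpha=1.0)
        t05 = omnibus_threshold(w, ev, (-1000.0, -80.0), alpha=0.05)
        assert t1 <= t05

    def test_short_baseline_rejected(self):
        w, ev = toy_weights_and_evoked(0.0, 1.0, n_base=100)
        with pytest.raises(ValueError):
            omnibus_threshold(w, ev, (-100.0, -95.0))

    def test_strong_planted_source_survives_threshold(self, head, leadfield20):
        # power companion to the type-I calibration: a strong source should
        # be flagged significant in (nearly) every run
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_epochs=60, seed=seed, noise_sd=15.0,
                                   artifact_amplitude=0.0)
            srcs = default_sources(cfg, amp_left=90.0, amp_right=60.0,
                                   morphology="immature_NciPci")
            ep = simulate_epochs(cfg, srcs, head, artifact_sides=(),
                                 condition="CI2")
            evoked, clean, _ = preprocess_epochs(ep)
            w = tracs_weights(clean, leadfield20, None)
            ts = source_timecourses(w, evoked)
            omni = omnibus_threshold(w, evoked, source_ts=ts)
            smap = pseudo_z_map(w, evoked, (94.5, 99.5), omnibus_value=omni,
                                source_ts=ts)
            hits += bool(extract_roi_peak(smap, LEFT_AC_ROI).significant)
        assert hits >= 9


# --------------------------------------------------------------------------
# ROI peak extraction
# --------------------------------------------------------------------------

def toy_map(grid, pz, omnibus=1.0):
    return SourceMap(grid=grid, pz=pz, omnibus_value=omnibus,
                     signal_window=(92.5, 97.5))


class TestRoiPeak:
    GRID = np.array([[-60.0, -20.0, 10.0], [-70.0, -10.0, 0.0],
                     [60.0, -20.0, 10.0], [0.0, 0.0, 50.0]])

    def test_argmax_inside_box(self):
        pz = np.array([5.0, 3.0, 4.0, 9.0])
        peak = extract_roi_peak(toy_map(self.GRID, pz), LEFT_AC_ROI)
        assert peak.voxel == (-60.0, -20.0, 10.0)
        assert peak.significant and peak.pz_corrected == pytest.approx(4.0)

    def test_subthreshold_map_not_significant(self):
        pz = np.array([0.5, 0.3, 0.4, 0.2])
        peak = extract_roi_peak(toy_map(self.GRID, pz), LEFT_AC_ROI)
        assert not peak.significant and peak.pz_corrected <= 0

    def test_uniform_map_lowest_index_tiebreak(self):
        pz = np.full(4, 2.0)
        peak = extract_roi_peak(toy_map(self.GRID, pz), LEFT_AC_ROI)
        assert peak.voxel == (-60.0, -20.0, 10.0)   # first matching voxel

    def test_invariant_to_values_outside_roi(self):
        pz = np.array([5.0, 3.0, 4.0, 9.0])
        a = extract_roi_peak(toy_map(self.GRID, pz), LEFT_AC_ROI)
        pz2 = pz.copy()
        pz2[2:] = [100.0, 200.0]
        b = extract_roi_peak(toy_map(self.GRID, pz2), LEFT_AC_ROI)
        assert a.voxel == b.voxel and a.pz == b.pz

    def test_corrected_equals_pz_minus_omnibus_everywhere(self):
        pz = np.array([5.0, 3.0, 4.0, 9.0])
        m = toy_map(self.GRID, pz, omnibus=2.5)
        assert np.allclose(m.pz_corrected, pz - 2.5)

    def test_empty_roi_rejected(self):
        roi = RoiSpec(hemisphere="left", x_bound=-500.0)
        with pytest.raises(ValueError):
            extract_roi_peak(toy_map(self.GRID, np.ones(4)), roi)
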