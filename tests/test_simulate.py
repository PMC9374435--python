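"""VAR machinery, closed-form oracles, task generator and forward model."""

import numpy as np
import pytest

from thetaflow.data import ENCODING, ValidationError, select_trials
from thetaflow.forward import (
    LeadField,
    fibonacci_sphere,
    project_sources,
    sphere_dipole_potential,
    spherical_leadfield,
)
from thetaflow.granger import csd, wilson_factorize
from thetaflow.simulate import (
    CouplingEntry,
    CouplingSchedule,
    StabilityError,
    SynthConfig,
    VarModel,
    simulate_participant,
    var_simulate,
    var_spectrum_closed_form,
)
from thetaflow.data import EpochWindow


# -- VAR simulation ---------------------------------------------------------

def test_ar1_lag1_autocorrelation_matches_coefficient():
    # closed form: rho(1) = a for AR(1)
    m = VarModel(A=np.array([[[0.9]]]), sigma=np.eye(1), fs=100.0)
    ts = var_simulate(m, n_samples=4000, n_trials=50, seed=11)
    x = ts.data[:, 0, :]
    x = x - x.mean(axis=1, keepdims=True)
    rho = np.sum(x[:, 1:] * x[:, :-1]) / np.sum(x[:, :-1] ** 2)
    assert abs(rho - 0.9) < 0.02


def test_zero_coefficients_give_white_noise():
    m = VarModel(A=np.zeros((1, 1, 1)), sigma=np.eye(1), fs=100.0)
    ts = var_simulate(m, n_samples=4000, n_trials=20, seed=2)
    x = ts.data[:, 0, :]
    rho = np.sum(x[:, 1:] * x[:, :-1]) / np.sum(x[:, :-1] ** 2)
    assert abs(rho) < 0.02


def test_var_simulate_deterministic_per_seed():
    m = VarModel(A=np.array([[[0.5]]]), sigma=np.eye(1), fs=100.0)
    a = var_simulate(m, 200, 3, seed=5).data
    b = var_simulate(m, 200, 3, seed=5).data
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, var_simulate(m, 200, 3, seed=6).data)


def test_unstable_model_raises_before_simulation():
    m = VarModel(A=np.array([[[1.01]]]), sigma=np.eye(1), fs=100.0)
    with pytest.raises(StabilityError):
        var_simulate(m, 100, 1, seed=0)


# -- closed-form spectra ----------------------------------------------------

def test_white_noise_spectrum_is_flat_identity():
    m = VarModel(A=np.zeros((1, 2, 2)), sigma=np.eye(2), fs=40.0)
    s = var_spectrum_closed_form(m, np.linspace(0, 20, 11))
    np.testing.assert_allclose(
        s.S, np.broadcast_to(np.eye(2) / 40.0, s.S.shape), atol=1e-15
    )


def test_univariate_ar1_spectrum_closed_form():
    a, fs = 0.9, 100.0
    m = VarModel(A=np.array([[[a]]]), sigma=np.eye(1), fs=fs)
    freqs = np.array([0.0, 5.0, 20.0, 50.0])
    s = var_spectrum_closed_form(m, freqs)
    expected = 1.0 / np.abs(1 - a * np.exp(-2j * np.pi * freqs / fs)) ** 2 / fs
    np.testing.assert_allclose(s.S[:, 0, 0].real, expected, rtol=1e-12)


def test_closed_form_spectrum_hermitian_psd(rng):
    from thetaflow.simulate import random_stable_var

    m = random_stable_var(seed=4)
    s = var_spectrum_closed_form(m, np.linspace(0, 20, 41))
    np.testing.assert_allclose(s.S, np.conj(np.swapaxes(s.S, -1, -2)), atol=1e-14)
    assert np.linalg.eigvalsh(s.S).min() >= -1e-14


def test_empirical_csd_matches_closed_form_in_band():
    # bivariate model with x -> y coupling, 200 trials
    from thetaflow.simulate import unidirectional_theta_var

    m = unidirectional_theta_var(coupling=0.5, fs=40.0)
    ts = var_simulate(m, n_samples=800, n_trials=200, seed=21)
    est = csd(ts, window=EpochWindow("c", ts.times[0], 0.0),
              n_tapers=8, padding_s=20.0)
    ref = var_spectrum_closed_form(m, est.freqs)
    band = (est.freqs >= 4) & (est.freqs <= 20)
    for i in range(2):
        for j in range(2):
            num = np.abs(est.S[band, i, j] - ref.S[band, i, j])
            den = np.abs(ref.S[band, i, i] * ref.S[band, j, j]) ** 0.5
            assert np.median(num / den) < 0.05


# -- task generator ---------------------------------------------------------

def test_task_dataset_structure(focus_participant, focus_pair_cfg):
    ts = focus_participant
    assert ts.n_trials == focus_pair_cfg.n_trials_per_participant
    assert ts.times[0] == pytest.approx(-6.0)
    assert ts.times[-1] == pytest.approx(0.0 - 1 / ts.fs)
    roles = {c.role for c in ts.channels}
    assert roles == {"hippocampal_lfp", "ecog_grid"}
    assert ts.channel_names[0] == "HIPP1"


def test_task_dataset_deterministic(focus_pair_cfg):
    a = simulate_participant(focus_pair_cfg, 1)
    b = simulate_participant(focus_pair_cfg, 1)
    np.testing.assert_array_equal(a.data, b.data)
    assert a.trials == b.trials


def test_perfect_accuracy_labels_all_correct():
    cfg = SynthConfig(
        accuracy_by_set_size={4: 1.0, 6: 1.0, 8: 1.0},
        grid_subset=[("C", 2)], n_trials_per_participant=40, seed=3,
    )
    ts = simulate_participant(cfg, 0)
    assert all(t.correct for t in ts.trials)


def test_label_rates_converge_to_accuracy_map():
    cfg = SynthConfig(grid_subset=[("C", 2)], n_trials_per_participant=3000,
                      coupling_gain_enc=0.0, coupling_gain_maint=0.0, seed=9)
    from thetaflow.simulate import _draw_labels

    labels = _draw_labels(cfg, np.random.default_rng(0))
    for ss, p in cfg.accuracy_by_set_size.items():
        sub = [t.correct for t in labels if t.set_size == ss]
        rate = np.mean(sub)
        se = np.sqrt(p * (1 - p) / len(sub))
        assert abs(rate - p) < 3 * se + 1e-9


def test_spatial_weights_peak_at_focus():
    cfg = SynthConfig(seed=0)
    w = cfg.spatial_weights()
    assert w["GRID_C2"] == pytest.approx(1.0)
    assert w["GRID_C3"] == pytest.approx(np.exp(-1.0))
    assert max(w.values()) == w["GRID_C2"]


def test_coupling_schedule_window_validation():
    with pytest.raises(ValidationError):
        CouplingSchedule([CouplingEntry(EpochWindow("bad", -7.0, -6.5),
                                        "a", "b", 0.1, 0.025)])


def test_theta_band_bursts_present(focus_correct_highload):
    """Gamma power rises >100 % on the cortical contact during late encoding."""
    ts = focus_correct_highload
    sl_burst = ts.window_slice(EpochWindow("g", -4.0, -3.0))
    sl_base = ts.window_slice(EpochWindow("f", -6.0, -5.0))
    ci = ts.channel_index("GRID_C2")

    def band_power(seg):
        w = np.hanning(seg.shape[-1])  # suppress theta-peak leakage
        spec = np.abs(np.fft.rfft(seg * w, axis=-1)) ** 2
        f = np.fft.rfftfreq(seg.shape[-1], 1 / ts.fs)
        return spec[..., (f >= 60) & (f <= 80)].mean()

    rel = band_power(ts.data[:, ci, sl_burst]) / band_power(ts.data[:, ci, sl_base])
    assert rel > 2.0


# -- spherical leadfield ----------------------------------------------------

def test_center_dipole_matches_analytic_pattern():
    sens = fibonacci_sphere(40)
    q = np.array([0.2, -0.4, 0.7])
    v = sphere_dipole_potential(sens, np.zeros(3), q)
    np.testing.assert_allclose(v, 3 * (sens @ q) / (4 * np.pi), atol=1e-14)


def test_dipole_potential_rotation_equivariant(rng):
    """Rotating sensors and source/moment together leaves potentials unchanged."""
    from scipy.spatial.transform import Rotation

    sens = fibonacci_sphere(30)
    r0 = np.array([0.3, -0.1, 0.4])
    q = rng.standard_normal(3)
    rot = Rotation.from_euler("zyx", [0.4, -1.1, 0.7]).as_matrix()
    v1 = sphere_dipole_potential(sens, r0, q)
    v2 = sphere_dipole_potential(sens @ rot.T, rot @ r0, rot @ q)
    np.testing.assert_allclose(v1, v2, atol=1e-12)


def test_dipole_gain_linearity_and_mirror_symmetry():
    sens = fibonacci_sphere(25)
    r0 = np.array([0.25, 0.15, -0.3])
    q = np.array([0.1, 0.6, -0.2])
    np.testing.assert_allclose(
        sphere_dipole_potential(sens, r0, 2 * q),
        2 * sphere_dipole_potential(sens, r0, q),
    )
    flip = np.array([-1.0, 1.0, 1.0])
    v1 = sphere_dipole_potential(sens, r0, q)
    v2 = sphere_dipole_potential(sens * flip, r0 * flip, q * flip)
    np.testing.assert_allclose(v1, v2, atol=1e-13)


def test_source_outside_sphere_rejected():
    sens = fibonacci_sphere(10)
    from thetaflow.data import ConfigurationError

    with pytest.raises(ConfigurationError):
        sphere_dipole_potential(sens, np.array([1.2, 0, 0]), np.ones(3))


def test_leadfield_grid_and_parcels():
    lf = spherical_leadfield(24, {"spacing": 0.4, "max_radius": 0.8})
    assert np.all(np.linalg.norm(lf.source_grid, axis=1) < 1.0)
    assert set(lf.hemisphere) <= {"left", "right"}
    left = lf.source_grid[:, 0] < 0
    assert np.all(np.char.startswith(lf.parcel_label[left].astype(str), "left"))


def test_project_sources_zero_and_rank_one(rng):
    lf = spherical_leadfield(16, {"spacing": 0.5, "max_radius": 0.8})
    zero = project_sources(np.zeros((2, 1, 50)), [0], np.eye(3)[:1], lf, 0.0)
    np.testing.assert_array_equal(zero.data, 0.0)
    act = rng.standard_normal((1, 1, 200))
    ts = project_sources(act, [1], np.array([[0.0, 1.0, 0.0]]), lf, 0.0)
    assert np.linalg.matrix_rank(ts.data[0], tol=1e-10) == 1
    with pytest.raises(ValidationError):
        project_sources(act, [lf.n_sources + 3], np.eye(3)[:1], lf, 0.0)
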