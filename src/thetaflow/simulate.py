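"""Synthetic trial generators with known directed-coupling ground truth.

Two layers:

* Generic vector-autoregressive (VAR) machinery — simulation, the
  closed-form spectral matrix S(f) = H(f) Sigma H(f)* / fs, and the
  parametric Geweke causality of a known model.  These are the analytic
  oracles against which the nonparametric estimators are validated.
* A task-structured generator emulating the statistical structure of a
  verbal working-memory experiment: every channel is a theta-resonant AR(2)
  oscillator; during the encoding window the cortical grid focus drives the
  hippocampal channel through a lagged linear term, during maintenance the
  coupling reverses; gamma bursts ([60 80] Hz) appear on cortical channels
  late in encoding and beta bursts ([12 24] Hz) on the hippocampus late in
  maintenance; behavioral labels follow set-size-dependent accuracies and a
  linear reaction-time workload slope.  Incorrect trials carry no directed
  coupling — a modeling choice that yields direction-free nulls, not a
  mechanistic claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .data import (
    ENCODING,
    GRID_COLUMNS,
    MAINTENANCE,
    ChannelInfo,
    ConfigurationError,
    EpochWindow,
    TrialInfo,
    TrialSet,
    ValidationError,
)
from .granger import CrossSpectralMatrix


class StabilityError(ValueError):
    """Raised when a (piecewise) autoregressive system is not stable."""


# --------------------------------------------------------------------------
# VAR models and oracles
# --------------------------------------------------------------------------

@dataclass
class VarModel:
    """VAR(p): x_t = sum_l A[l] x_{t-l} + e_t,  e ~ N(0, sigma)."""

    A: np.ndarray  # (p, k, k)
    sigma: np.ndarray  # (k, k)
    fs: float

    def __post_init__(self) -> None:
        self.A = np.atleast_3d(np.asarray(self.A, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise ValidationError(f"A must be (p, k, k), got {self.A.shape}")
        if self.sigma.shape != self.A.shape[1:]:
            raise ValidationError("sigma shape does not match A")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValidationError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise ValidationError("sigma must be positive definite")

    @property
    def order(self) -> int:
        return self.A.shape[0]

    @property
    def k(self) -> int:
        return self.A.shape[1]

    def companion(self) -> np.ndarray:
        p, k = self.order, self.k
        c = np.zeros((p * k, p * k))
        c[:k, :] = self.A.transpose(1, 0, 2).reshape(k, p * k)
        if p > 1:
            c[k:, :-k] = np.eye((p - 1) * k)
        return c

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0

    def transfer(self, freqs: np.ndarray) -> np.ndarray:
        """H(f) = (I - sum_l A_l e^{-i 2 pi f l / fs})^{-1}, (n_freqs, k, k)."""
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        l = np.arange(1, self.order + 1)
        phase = np.exp(-2j * np.pi * np.outer(freqs, l) / self.fs)  # (f, p)
        a_f = np.tensordot(phase, self.A, axes=([1], [0]))  # (f, k, k)
        m = np.eye(self.k) - a_f
        try:
            return np.linalg.inv(m)
        except np.linalg.LinAlgError as e:
            det = np.abs(np.linalg.det(m))
            f_bad = freqs[int(np.argmin(det))]
            raise ValidationError(
                f"singular characteristic matrix at {f_bad:.3f} Hz"
            ) from e


def var_simulate(
    model: VarModel,
    n_samples: int,
    n_trials: int,
    seed: int,
    burn_in: int = 500,
    t0_offset: float | None = None,
) -> TrialSet:
    """Simulate independent trials of a stationary VAR; deterministic per seed."""
    if not model.is_stable():
        raise StabilityError(
            f"companion spectral radius {model.spectral_radius():.4f} >= 1"
        )
    rng = np.random.default_rng(seed)
    p, k = model.order, model.k
    chol = np.linalg.cholesky(model.sigma)
    total = n_samples + burn_in
    eps = rng.standard_normal((n_trials, total, k)) @ chol.T
    x = np.zeros((n_trials, total, k))
    for t in range(total):
        acc = eps[:, t]
        for l in range(1, min(p, t) + 1):
            acc = acc + x[:, t - l] @ model.A[l - 1].T
        x[:, t] = acc
    data = x[:, burn_in:].transpose(0, 2, 1)
    channels = [ChannelInfo(name=f"ch{i}", role="scalp") for i in range(k)]
    trials = [
        TrialInfo(set_size=6, correct=True, probe_in=True, rt=1.0)
        for _ in range(n_trials)
    ]
    if t0_offset is None:
        t0_offset = -n_samples / model.fs
    return TrialSet(
        data=data, fs=model.fs, t0_offset=t0_offset,
        channels=channels, trials=trials,
    )


def var_spectrum_closed_form(model: VarModel, freqs: np.ndarray) -> CrossSpectralMatrix:
    """Analytic cross-spectral density S(f) = H(f) Sigma H(f)* / fs."""
    if not model.is_stable():
        raise StabilityError("model is not stationary")
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    h = model.transfer(freqs)
    s = h @ model.sigma @ np.conj(np.swapaxes(h, -1, -2)) / model.fs
    return CrossSpectralMatrix(
        S=s,
        freqs=freqs,
        fs=model.fs,
        n_trials=0,
        n_tapers=0,
        channel_names=[f"ch{i}" for i in range(model.k)],
    )


def var_spectrum_full_grid(model: VarModel, n_freqs: int = 513) -> CrossSpectralMatrix:
    """Closed-form spectrum on a regular [0, Nyquist] grid (factorization input)."""
    return var_spectrum_closed_form(model, np.linspace(0.0, model.fs / 2, n_freqs))


def var_gc_spectrum(
    model: VarModel, freqs: np.ndarray, source: int, target: int
) -> np.ndarray:
    """Parametric Geweke causality of a known bivariate VAR (analytic oracle).

    Written out from the model's own transfer function and innovation
    covariance, independent of the nonparametric estimation path.
    """
    if model.k != 2:
        raise ConfigurationError("parametric GC oracle is pairwise (k=2)")
    x, y = target, source
    h = model.transfer(freqs)
    sig = model.sigma
    s = h @ sig @ np.conj(np.swapaxes(h, -1, -2))
    sxx = s[:, x, x].real
    cond_var = sig[y, y] - sig[x, y] ** 2 / sig[x, x]
    intrinsic = sxx - cond_var * np.abs(h[:, x, y]) ** 2
    return np.log(sxx / intrinsic)


def random_stable_var(
    k: int = 2,
    order: int = 2,
    fs: float = 40.0,
    seed: int = 0,
    max_radius: float = 0.9,
) -> VarModel:
    """A random stationary VAR with companion spectral radius <= max_radius.

    Coefficients are drawn i.i.d. and the whole coefficient stack is shrunk
    geometrically until the companion radius is below the bound, which keeps
    the causal spectral factor short enough for accurate factorization on a
    finite grid.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(scale=0.5, size=(order, k, k))
    c = rng.normal(size=(k, k))
    sigma = c @ c.T + 0.5 * np.eye(k)
    for _ in range(200):
        model = VarModel(A=a, sigma=sigma, fs=fs)
        rho = model.spectral_radius()
        if rho <= max_radius:
            return model
        a = a * (0.95 * max_radius / rho) ** (1.0 / 1.0)
    raise StabilityError("could not stabilize the random model")


def ar2_coefficients(f0: float, radius: float, fs: float) -> tuple[float, float]:
    """AR(2) with complex poles radius*exp(+-i 2 pi f0 / fs): resonance at ~f0."""
    theta = 2 * np.pi * f0 / fs
    return 2 * radius * np.cos(theta), -(radius**2)


def unidirectional_theta_var(
    f0: float = 6.0,
    radius: float = 0.9,
    coupling: float = 0.5,
    lag: int = 1,
    fs: float = 40.0,
) -> VarModel:
    """Bivariate VAR: channel 0 is an AR(2) theta oscillator driving channel 1.

    There is no 1 -> 0 coefficient, so GC in that direction is analytically
    zero; GC 0 -> 1 peaks at the oscillator resonance.
    """
    a1, a2 = ar2_coefficients(f0, radius, fs)
    p = max(2, lag)
    A = np.zeros((p, 2, 2))
    A[0] = np.diag([a1, a1])
    A[1, 0, 0] += a2
    A[1, 1, 1] += a2
    A[lag - 1, 1, 0] += coupling
    return VarModel(A=A, sigma=np.eye(2), fs=fs)


# --------------------------------------------------------------------------
# task-structured generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingEntry:
    window: EpochWindow
    source: str
    target: str
    gain: float
    lag_s: float


@dataclass
class CouplingSchedule:
    entries: list[CouplingEntry]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.window.t_start < -6.0 - 1e-9 or e.window.t_end > 0.0 + 1e-9:
                raise ValidationError(
                    f"coupling window [{e.window.t_start}, {e.window.t_end}) "
                    "outside the trial span [-6, 0] s"
                )
            if e.lag_s < 0:
                raise ValidationError("coupling lag must be >= 0")


def _grid_name(col: str, row: int) -> str:
    return f"GRID_{col}{row}"


@dataclass
class SynthConfig:
    """Study conditions for the synthetic task dataset.

    Defaults follow the emulated experiment: 15 participants, trials
    spanning [-6, 0] s, accuracies 97/89/83 % for set sizes 4/6/8, a
    53 ms/item reaction-time slope, theta-band (6 Hz) oscillators with
    encoding-window cortex->hippocampus coupling and the reverse during
    maintenance, gamma bursts ([60 80] Hz) on cortical contacts late in
    encoding and beta bursts ([12 24] Hz) on the hippocampus late in
    maintenance.  Coupling gains are calibrated so the band-averaged net
    flow |Delta-Granger| of the generating model is on the order of 0.05,
    the scale of the per-participant values the analysis targets.
    """

    n_participants: int = 15
    n_trials_per_participant: int = 100
    fs: float = 200.0
    theta_f0: float = 6.0
    ar_pole_radius: float = 0.95
    coupling_gain_enc: float = 0.06
    coupling_gain_maint: float = 0.06
    coupling_lag_s: float = 0.025
    gamma_band: tuple[float, float] = (60.0, 80.0)
    gamma_window: tuple[float, float] = (-4.0, -3.0)
    gamma_amp: float = 4.0  # added in-band power, as a multiple of baseline
    beta_band: tuple[float, float] = (12.0, 24.0)
    beta_window: tuple[float, float] = (-1.0, 0.0)
    beta_amp: float = 4.0
    accuracy_by_set_size: dict = field(
        default_factory=lambda: {4: 0.97, 6: 0.89, 8: 0.83}
    )
    rt_base: float = 0.9
    rt_slope: float = 0.053
    rt_noise_sd: float = 0.3
    grid_focus: tuple[str, int] = ("C", 2)
    spatial_decay: float = 1.0  # e-folding of coupling gain, in contact spacings
    grid_subset: list[tuple[str, int]] | None = None
    n_scalp: int = 0
    amplitude_uv: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 4.0 <= self.theta_f0 <= 8.0:
            raise ConfigurationError("theta_f0 must lie in the [4, 8] Hz theta band")
        for ss, p in self.accuracy_by_set_size.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"accuracy for set size {ss} outside [0, 1]")
        if not 0 < self.ar_pole_radius < 1:
            raise ConfigurationError("ar_pole_radius must be in (0, 1)")
        col, row = self.grid_focus
        if col not in GRID_COLUMNS or row not in range(1, 9):
            raise ConfigurationError(f"grid focus {self.grid_focus} off the 8x8 grid")
        if self.grid_subset is not None and self.grid_focus not in [
            tuple(g) for g in self.grid_subset
        ]:
            raise ConfigurationError("grid_subset must contain the coupling focus")

    def grid_positions(self) -> list[tuple[str, int]]:
        if self.grid_subset is not None:
            return [tuple(g) for g in self.grid_subset]
        return [(c, r) for c in GRID_COLUMNS for r in range(1, 9)]

    def channels(self) -> list[ChannelInfo]:
        chans = [ChannelInfo(name="HIPP1", role="hippocampal_lfp", hemisphere="left")]
        for col, row in self.grid_positions():
            chans.append(
                ChannelInfo(
                    name=_grid_name(col, row),
                    role="ecog_grid",
                    grid_pos=(col, row),
                    hemisphere="left",
                )
            )
        for i in range(self.n_scalp):
            chans.append(ChannelInfo(name=f"EEG{i:02d}", role="scalp"))
        return chans

    def spatial_weights(self) -> dict[str, float]:
        """Coupling weight per grid channel: exp(-distance_to_focus / decay)."""
        fc, fr = self.grid_focus
        w = {}
        for col, row in self.grid_positions():
            d = np.hypot(GRID_COLUMNS.index(col) - GRID_COLUMNS.index(fc), row - fr)
            w[_grid_name(col, row)] = float(np.exp(-d / self.spatial_decay))
        return w

    def default_schedule(self) -> CouplingSchedule:
        w = self.spatial_weights()
        entries = []
        for name, wc in w.items():
            if self.coupling_gain_enc != 0:
                entries.append(
                    CouplingEntry(ENCODING, name, "HIPP1",
                                  self.coupling_gain_enc * wc, self.coupling_lag_s)
                )
            if self.coupling_gain_maint != 0:
                entries.append(
                    CouplingEntry(MAINTENANCE, "HIPP1", name,
                                  self.coupling_gain_maint * wc, self.coupling_lag_s)
                )
        return CouplingSchedule(entries)


def _bandpassed_burst(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    n: int,
    band: tuple[float, float],
    fs: float,
) -> np.ndarray:
    """Unit-variance band-limited noise with a Hann envelope, shape + (n,)."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[..., (f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1) * np.hanning(n)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)  # unit window-average power


def simulate_trials(
    cfg: SynthConfig,
    schedule: CouplingSchedule,
    trial_gain: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Piecewise-coupled AR(2) trial data, (n_trials, n_channels, n_samples).

    ``trial_gain`` multiplies every coupling gain per trial (0 disables the
    directed flow in that trial).
    """
    rng = np.random.default_rng(seed)
    chans = cfg.channels()
    names = [c.name for c in chans]
    n_ch = len(chans)
    n_trials = trial_gain.size
    fs = cfg.fs
    burn = int(round(2.0 * fs))
    n_task = int(round(6.0 * fs))
    total = burn + n_task
    a1, a2 = ar2_coefficients(cfg.theta_f0, cfg.ar_pole_radius, fs)

    # stationary sd of the uncoupled AR(2); coupling gains are expressed in
    # innovation-sd units, so the lagged source term is normalized by it
    comp = np.array([[a1, a2], [1.0, 0.0]])
    gam = sla.solve_discrete_lyapunov(comp, np.diag([1.0, 0.0]))
    base_sd = float(np.sqrt(gam[0, 0]))

    # compile the schedule into per-timestep operations
    ops = []
    for e in schedule.entries:
        si, ti = names.index(e.source), names.index(e.target)
        lag = max(1, int(round(e.lag_s * fs)))
        t_lo = burn + int(round((e.window.t_start + 6.0) * fs))
        t_hi = burn + int(round((e.window.t_end + 6.0) * fs))
        ops.append((t_lo, t_hi, si, ti, e.gain, lag))

    x = np.zeros((n_trials, n_ch, total))
    eps = rng.standard_normal((n_trials, n_ch, total))
    for t in range(total):
        xt = eps[:, :, t]
        if t >= 1:
            xt = xt + a1 * x[:, :, t - 1]
        if t >= 2:
            xt = xt + a2 * x[:, :, t - 2]
        for (t_lo, t_hi, si, ti, gain, lag) in ops:
            if t_lo <= t < t_hi and t >= lag:
                xt[:, ti] = xt[:, ti] + (gain / base_sd) * trial_gain * x[:, si, t - lag]
        x[:, :, t] = xt
    if not np.isfinite(x).all() or np.abs(x).max() > 1e6:
        raise StabilityError(
            "piecewise-coupled process diverged; reduce the coupling gains"
        )
    x = x[:, :, burn:]
    x *= cfg.amplitude_uv / base_sd

    def band_sd(band: tuple[float, float]) -> float:
        """SD of the baseline AR(2) content inside a band (scaled units)."""
        f = np.linspace(band[0], band[1], 64)
        z = np.exp(-2j * np.pi * f / fs)
        dens = 1.0 / np.abs(1 - a1 * z - a2 * z**2) ** 2 / fs
        power = 2.0 * np.trapezoid(dens, f)  # one-sided band power
        return float(np.sqrt(power)) * cfg.amplitude_uv / base_sd

    # epoch-locked band-limited bursts
    cortical = [i for i, c in enumerate(chans) if c.role in ("ecog_grid", "scalp")]
    if cortical and cfg.gamma_amp > 0:
        lo = int(round((cfg.gamma_window[0] + 6.0) * fs))
        hi = int(round((cfg.gamma_window[1] + 6.0) * fs))
        burst = _bandpassed_burst(
            rng, (n_trials, len(cortical)), hi - lo, cfg.gamma_band, fs
        )
        # burst adds gamma_amp x the baseline in-band power; the default is
        # chosen so the relative PSD increase stays > 100 % after the
        # 0.2 x f spectral smoothing of the time-frequency estimator
        x[:, cortical, lo:hi] += (
            np.sqrt(cfg.gamma_amp) * band_sd(cfg.gamma_band) * burst
        )
    hipp = [i for i, c in enumerate(chans) if c.role == "hippocampal_lfp"]
    if hipp and cfg.beta_amp > 0:
        lo = int(round((cfg.beta_window[0] + 6.0) * fs))
        hi = int(round((cfg.beta_window[1] + 6.0) * fs))
        burst = _bandpassed_burst(
            rng, (n_trials, len(hipp)), hi - lo, cfg.beta_band, fs
        )
        x[:, hipp, lo:hi] += (
            np.sqrt(cfg.beta_amp) * band_sd(cfg.beta_band) * burst
        )
    return x


def _draw_labels(cfg: SynthConfig, rng: np.random.Generator) -> list[TrialInfo]:
    sizes = np.asarray(sorted(cfg.accuracy_by_set_size))
    labels = []
    for _ in range(cfg.n_trials_per_participant):
        ss = int(rng.choice(sizes))
        correct = bool(rng.random() < cfg.accuracy_by_set_size[ss])
        probe_in = bool(rng.random() < 0.5)
        rt = cfg.rt_base + cfg.rt_slope * ss + rng.normal(0.0, cfg.rt_noise_sd)
        labels.append(
            TrialInfo(set_size=ss, correct=correct, probe_in=probe_in,
                      rt=float(max(rt, 0.05)))
        )
    return labels


def simulate_participant(cfg: SynthConfig, participant: int) -> TrialSet:
    """One synthetic participant's TrialSet; deterministic in (seed, participant)."""
    label_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, participant, 0])
    )
    labels = _draw_labels(cfg, label_rng)
    trial_gain = np.array([1.0 if t.correct else 0.0 for t in labels])
    data_seed = np.random.SeedSequence([cfg.seed, participant, 1])
    data = simulate_trials(
        cfg, cfg.default_schedule(), trial_gain,
        seed=data_seed,
    )
    return TrialSet(
        data=data, fs=cfg.fs, t0_offset=-6.0,
        channels=cfg.channels(), trials=labels,
    )


def simulate_task_dataset(cfg: SynthConfig) -> list[TrialSet]:
    """One TrialSet per synthetic participant."""
    return [simulate_participant(cfg, p) for p in range(cfg.n_participants)]
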