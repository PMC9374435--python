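"""Synthetic forward model: single-sphere leadfields and source projection.

The head is a homogeneous unit sphere (conductivity 1); sensors sit on its
surface and dipolar sources strictly inside.  The surface potential of a
dipole q at radius b = |r0| is the classical series solution

    V(r) = 1/(4 pi sigma) * sum_{n>=1} (2n+1)/n * b^(n-1)/R^(n+1)
           * [ n (q . r0_hat) P_n(x) + (q . (r_hat - x r0_hat)) P_n'(x) ],

with x = r_hat . r0_hat, truncated once the geometric factor (b/R)^n falls
below 1e-12.  Parcel labels are assigned by spatial octant — a synthetic
stand-in for an anatomical atlas — and the hemisphere of a source is the
sign of its x coordinate (x < 0 = left).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ChannelInfo, ConfigurationError, TrialInfo, TrialSet, ValidationError


@dataclass
class LeadField:
    """Sensor gains for dipolar sources: gain[n_sensors, n_sources, 3]."""

    gain: np.ndarray
    source_grid: np.ndarray  # (n_sources, 3), head coordinates (m)
    sensor_positions: np.ndarray  # (n_sensors, 3)
    parcel_label: np.ndarray  # (n_sources,) strings
    radius: float = 1.0

    def __post_init__(self) -> None:
        if self.gain.ndim != 3 or self.gain.shape[2] != 3:
            raise ValidationError(f"gain must be (sensors, sources, 3), got {self.gain.shape}")
        if np.any(np.all(self.gain == 0, axis=(1, 2))):
            raise ValidationError("leadfield has an all-zero sensor row")
        if np.any(np.linalg.norm(self.source_grid, axis=1) >= self.radius):
            raise ValidationError("source grid extends outside the head sphere")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    @property
    def hemisphere(self) -> np.ndarray:
        """'left' where x < 0, else 'right'."""
        return np.where(self.source_grid[:, 0] < 0, "left", "right")


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Near-uniform sensor layout on the sphere (golden-angle spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z * z)
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sphere_dipole_potential(
    sensors: np.ndarray,
    r0: np.ndarray,
    q: np.ndarray,
    radius: float = 1.0,
    sigma: float = 1.0,
    tol: float = 1e-12,
    n_max: int = 400,
) -> np.ndarray:
    """Surface potential of one dipole in a homogeneous sphere (series form)."""
    sensors = np.asarray(sensors, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    q = np.asarray(q, dtype=float)
    b = np.linalg.norm(r0)
    if b >= radius:
        raise ConfigurationError(f"dipole at radius {b:.3f} not inside the sphere")
    r_hat = sensors / np.linalg.norm(sensors, axis=1, keepdims=True)
    if b < 1e-12:
        r0_hat = np.array([0.0, 0.0, 1.0])  # formula is r0_hat-independent at b=0
    else:
        r0_hat = r0 / b
    x = r_hat @ r0_hat  # cos(gamma) per sensor
    q_r = q @ r0_hat
    q_t = r_hat @ q - x * q_r  # q . (r_hat - x r0_hat)

    # Legendre recurrences: P_n via Bonnet, P_n' via P_n' = n P_{n-1} + x P_{n-1}'
    coef = 1.0 / (4.0 * np.pi * sigma)
    p_prev = np.ones_like(x)  # P_0
    p_cur = x.copy()  # P_1
    dp_cur = np.ones_like(x)  # P_1'
    ratio = b / radius
    v = np.zeros_like(x)
    geom = 1.0 / radius**2  # b^(n-1) / R^(n+1) at n = 1
    for n in range(1, n_max + 1):
        if n > 1:
            p_next = ((2 * n - 1) * x * p_cur - (n - 1) * p_prev) / n
            dp_next = n * p_cur + x * dp_cur
            p_prev, p_cur, dp_cur = p_cur, p_next, dp_next
            geom *= ratio  # advances b^(n-1)/R^(n+1) by one order
        v += (2 * n + 1) / n * geom * (n * q_r * p_cur + q_t * dp_cur)
        if ratio**n < tol:
            break
    return coef * v


def spherical_leadfield(
    n_sensors: int,
    source_grid_spec: dict | None = None,
    seed: int = 0,
) -> LeadField:
    """Analytic single-sphere leadfield on a cubic source grid.

    ``source_grid_spec`` keys: ``spacing`` (default 0.25), ``max_radius``
    (default 0.85) and ``jitter`` (fraction of spacing, default 0 — the seed
    only matters when jitter > 0).
    """
    spec = {"spacing": 0.25, "max_radius": 0.85, "jitter": 0.0}
    spec.update(source_grid_spec or {})
    spacing = spec["spacing"]
    rmax = spec["max_radius"]
    if rmax >= 1.0:
        raise ConfigurationError("max_radius must be < 1 (sources inside the sphere)")
    ax = np.arange(-1.0 + spacing / 2, 1.0, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if spec["jitter"] > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.uniform(
            -spec["jitter"] * spacing / 2, spec["jitter"] * spacing / 2, grid.shape
        )
    grid = grid[np.linalg.norm(grid, axis=1) <= rmax]
    sensors = fibonacci_sphere(n_sensors)
    gain = np.empty((n_sensors, grid.shape[0], 3))
    eye = np.eye(3)
    for si, r0 in enumerate(grid):
        for d in range(3):
            gain[:, si, d] = sphere_dipole_potential(sensors, r0, eye[d])
    labels = np.array(
        [
            ("left" if p[0] < 0 else "right")
            + ("_anterior" if p[1] >= 0 else "_posterior")
            + ("_superior" if p[2] >= 0 else "_inferior")
            for p in grid
        ]
    )
    return LeadField(
        gain=gain, source_grid=grid, sensor_positions=sensors, parcel_label=labels
    )


def project_sources(
    source_activity: np.ndarray,
    active_indices: np.ndarray,
    moments: np.ndarray,
    lf: LeadField,
    sensor_noise_sd: float = 0.0,
    fs: float = 200.0,
    t0_offset: float = -6.0,
    seed: int = 0,
    trials: list[TrialInfo] | None = None,
) -> TrialSet:
    """Forward-project source activity to the sensors and add white noise.

    ``source_activity``: (n_trials, n_active, n_samples); ``moments``:
    (n_active, 3) dipole moments for the active sources.
    """
    act = np.asarray(source_activity, dtype=float)
    if act.ndim != 3:
        raise ValidationError("source_activity must be (trials, sources, samples)")
    active_indices = np.asarray(active_indices, dtype=int)
    moments = np.atleast_2d(np.asarray(moments, dtype=float))
    if np.any(active_indices < 0) or np.any(active_indices >= lf.n_sources):
        raise ValidationError("active source index outside the grid")
    if moments.shape != (act.shape[1], 3) or active_indices.size != act.shape[1]:
        raise ValidationError("active_indices / moments inconsistent with activity")
    # (sensors, active): gain for each active source collapsed on its moment
    g = np.einsum("csd,sd->cs", lf.gain[:, active_indices, :], moments)
    sensor = np.einsum("cs,tsn->tcn", g, act)
    if sensor_noise_sd > 0:
        rng = np.random.default_rng(seed)
        sensor = sensor + rng.normal(0.0, sensor_noise_sd, sensor.shape)
    channels = [ChannelInfo(name=f"EEG{i:03d}", role="scalp") for i in range(lf.n_sensors)]
    if trials is None:
        trials = [
            TrialInfo(set_size=6, correct=True, probe_in=True, rt=1.0)
            for _ in range(act.shape[0])
        ]
    return TrialSet(
        data=sensor, fs=fs, t0_offset=t0_offset, channels=channels, trials=trials
    )
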