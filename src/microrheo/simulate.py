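"""Ground-truth trajectory simulators for interfacial particle tracking.

Generates ensembles of 2-D probe trajectories under the dynamical regimes a
bacteria-laden oil–water interface can impose on a trapped colloid:

* ``brownian`` — thermal diffusion, i.i.d. Gaussian increments, MSD = 4Dt.
* ``fbm`` — fractional Brownian motion with Hurst exponent H per coordinate
  (Davies–Harte circulant embedding, Cholesky fallback); per-coordinate
  Var X(t) = scale·t^{2H}, so the 2-D MSD is 2·scale·t^{2H} ~ t^{2H}.
* ``prw`` — persistent random walk: Ornstein–Uhlenbeck velocity with 2-D rms
  speed v and persistence time τ_p, sampled with the exact joint OU /
  integrated-OU discretization; MSD = 2v²τ_p²(t/τ_p − 1 + e^{−t/τ_p}).
* ``arrested`` — probes bound in an elastic matrix: OU position fluctuations
  about fixed anchors with equilibrium std σ_eq per coordinate and relaxation
  time τ_r; for lags ≫ τ_r the MSD is flat at 4σ_eq².

Common-mode drift and i.i.d. Gaussian localization noise are layered on top
of the dynamics. All simulators work in μm and seconds; rendering to pixel
units happens only in :func:`render_video`.

Randomness: one master seed per config is split with
``numpy.random.SeedSequence(seed).spawn(3)`` into independent streams for
(initial positions, dynamics, localization noise), so e.g. a run with and
without noise shares its dynamics realization.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from .errors import ParameterError
from .tracking import FrameStack, Trajectory, TrajectoryEnsemble

logger = logging.getLogger("microrheo.simulate")

MODELS = ("brownian", "fbm", "prw", "arrested")


# ---------------------------------------------------------------------------
# Configuration and ground truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated movie.

    ``model_params`` by model:
      brownian: ``D`` (μm²/s);
      fbm: ``H`` in (0, 1), ``scale`` (μm²/s^{2H}, per coordinate);
      prw: ``v`` (2-D rms speed, μm/s), ``tau_p`` (s);
      arrested: ``sigma_eq`` (μm, per coordinate), ``tau_r`` (s).
    """

    model: str
    n_particles: int = 200
    n_frames: int = 2000
    fps: float = 60.0
    seed: int = 0
    box_size: float | None = None      # μm; None = unbounded plane
    boundary: str = "none"             # none | reflecting | periodic
    init: str = "uniform"              # uniform | grid | origin
    localization_noise_sigma: float = 0.0   # μm, i.i.d. per coordinate per frame
    drift_velocity: tuple[float, float] = (0.0, 0.0)   # μm/s common mode
    model_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ParameterError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.n_particles < 1:
            raise ParameterError("n_particles must be >= 1")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if not (self.fps > 0):
            raise ParameterError("fps must be positive")
        if self.boundary not in ("none", "reflecting", "periodic"):
            raise ParameterError("boundary must be none|reflecting|periodic")
        if self.boundary != "none" and self.box_size is None:
            raise ParameterError("boundary handling requires box_size")
        if self.init not in ("uniform", "grid", "origin"):
            raise ParameterError("init must be uniform|grid|origin")
        if self.localization_noise_sigma < 0:
            raise ParameterError("localization_noise_sigma must be >= 0")
        p = dict(self.model_params)
        if self.model == "brownian":
            D = p.get("D", 0.0)
            if not np.isfinite(D) or D < 0:
                raise ParameterError(f"D must be finite and >= 0, got {D}")
        elif self.model == "fbm":
            H = p.get("H")
            if H is None or not (0 < H < 1):
                raise ParameterError(f"Hurst exponent H must lie in (0, 1), got {H}")
            if p.get("scale", 1.0) < 0:
                raise ParameterError("fbm scale must be >= 0")
        elif self.model == "prw":
            if p.get("v", 0.0) < 0:
                raise ParameterError("prw speed v must be >= 0")
            if not (p.get("tau_p", 0.0) > 0):
                raise ParameterError("prw persistence time tau_p must be positive")
        elif self.model == "arrested":
            if p.get("sigma_eq", 0.0) < 0:
                raise ParameterError("sigma_eq must be >= 0")
            if not (p.get("tau_r", 1.0) > 0):
                raise ParameterError("tau_r must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "model", "n_particles", "n_frames", "fps", "seed", "box_size",
            "boundary", "init", "localization_noise_sigma")}
        d["drift_velocity"] = list(self.drift_velocity)
        d["model_params"] = dict(self.model_params)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "drift_velocity" in d:
            d["drift_velocity"] = tuple(d["drift_velocity"])
        return cls(**d)


@dataclass
class GroundTruthSet:
    """Simulated trajectories with their generating config and true labels."""

    positions: np.ndarray      # (n_particles, n_frames, 2), μm, (x, y)
    config: SimConfig
    regime: str                # true regime label of the dynamics
    drift: np.ndarray          # (n_frames, 2) cumulative common-mode displacement, μm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.drift = np.asarray(self.drift, dtype=float)
        n, m, _ = self.positions.shape
        if m != self.config.n_frames or n != self.config.n_particles:
            raise ParameterError("positions shape inconsistent with config")
        if self.drift.shape != (self.config.n_frames, 2):
            raise ParameterError("drift series must have shape (n_frames, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ParameterError("positions must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.config.n_frames) / self.config.fps

    def to_ensemble(self, surface_age: float | None = None) -> TrajectoryEnsemble:
        """View as a TrajectoryEnsemble (pixel_size 1 μm/px placeholder)."""
        frames = np.arange(self.config.n_frames)
        trajs = [Trajectory(i, frames, self.positions[i, :, 0], self.positions[i, :, 1])
                 for i in range(self.config.n_particles)]
        return TrajectoryEnsemble(trajs, fps=self.config.fps, pixel_size=1.0,
                                  surface_age=surface_age,
                                  metadata={"model": self.config.model,
                                            "regime": self.regime,
                                            "seed": self.config.seed})

    def to_dataframe(self) -> pd.DataFrame:
        n, m, _ = self.positions.shape
        return pd.DataFrame({
            "particle_id": np.repeat(np.arange(n), m),
            "frame": np.tile(np.arange(m), n),
            "x_um": self.positions[:, :, 0].ravel(),
            "y_um": self.positions[:, :, 1].ravel(),
        })


def _rngs(config: SimConfig):
    init_ss, dyn_ss, noise_ss = np.random.SeedSequence(config.seed).spawn(3)
    return (np.random.default_rng(init_ss), np.random.default_rng(dyn_ss),
            np.random.default_rng(noise_ss))


def _initial_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_particles
    if config.box_size is None or config.init == "origin":
        return np.zeros((n, 2))
    L = config.box_size
    lo, hi = 0.1 * L, 0.9 * L
    if config.init == "uniform":
        return rng.uniform(lo, hi, size=(n, 2))
    # jittered grid: avoids overlapping spots when rendering
    side = math.ceil(math.sqrt(n))
    g = np.linspace(lo, hi, side)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel()])[:n]
    spacing = (hi - lo) / max(side - 1, 1)
    return pts + rng.uniform(-0.05 * spacing, 0.05 * spacing, size=pts.shape)


def _apply_boundary(pos: np.ndarray, config: SimConfig) -> np.ndarray:
    if config.boundary == "none":
        return pos
    L = config.box_size
    if config.boundary == "periodic":
        return np.mod(pos, L)
    # reflecting: fold into [0, 2L) then mirror the upper half
    folded = np.mod(pos, 2 * L)
    return np.where(folded > L, 2 * L - folded, folded)


def _finalize(config: SimConfig, dyn: np.ndarray, regime: str,
              noise_rng: np.random.Generator) -> GroundTruthSet:
    dyn = _apply_boundary(dyn, config)
    t = np.arange(config.n_frames)[:, None] * config.dt
    drift = t * np.asarray(config.drift_velocity, dtype=float)[None, :]
    pos = dyn + drift[None, :, :]
    if config.localization_noise_sigma > 0:
        pos = pos + noise_rng.normal(0.0, config.localization_noise_sigma, size=pos.shape)
    return GroundTruthSet(pos, config, regime, drift)


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def simulate_brownian(config: SimConfig) -> GroundTruthSet:
    """Thermal diffusion: i.i.d. Gaussian steps, Var 2D·dt per coordinate."""
    if config.model != "brownian":
        raise ParameterError("config.model must be 'brownian'")
    D = float(config.model_params.get("D", 0.0))
    init_rng, dyn_rng, noise_rng = _rngs(config)
    x0 = _initial_positions(config, init_rng)
    steps = dyn_rng.normal(0.0, math.sqrt(2 * D * config.dt),
                           size=(config.n_particles, config.n_frames - 1, 2))
    pos = np.concatenate([np.zeros((config.n_particles, 1, 2)),
                          np.cumsum(steps, axis=1)], axis=1) + x0[:, None, :]
    return _finalize(config, pos, "diffusive", noise_rng)


def fgn_autocovariance(k: np.ndarray, H: float) -> np.ndarray:
    """Autocovariance of unit-variance fractional Gaussian noise at lag k."""
    k = np.abs(np.asarray(k, dtype=float))
    return 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))


def sample_fgn(n_steps: int, H: float, n_series: int,
               rng: np.random.Generator, method: str = "auto") -> np.ndarray:
    """Sample unit-variance fractional Gaussian noise series of length n_steps.

    ``method``: 'auto' uses the Davies–Harte circulant embedding and falls
    back to Cholesky factorization of the Toeplitz covariance if the
    embedding is not nonnegative-definite; 'cholesky' forces the fallback
    (used as an independent oracle in the test-suite).
    """
    if not (0 < H < 1):
        raise ParameterError("H must lie in (0, 1)")
    if method not in ("auto", "davies-harte", "cholesky"):
        raise ParameterError("method must be auto|davies-harte|cholesky")
    r = fgn_autocovariance(np.arange(n_steps + 1), H)
    if method != "cholesky":
        m = 2 * n_steps
        c = np.concatenate([r[:n_steps], [r[n_steps]], r[n_steps - 1:0:-1]])
        lam = np.fft.fft(c).real
        if np.min(lam) > -1e-10:
            lam = np.clip(lam, 0.0, None)
            z = rng.standard_normal((n_series, m))
            y = rng.standard_normal((n_series, m))
            w = np.empty((n_series, m), dtype=complex)
            w[:, 0] = math.sqrt(lam[0] / m) * z[:, 0]
            w[:, n_steps] = math.sqrt(lam[n_steps] / m) * z[:, n_steps]
            k = np.arange(1, n_steps)
            coef = np.sqrt(lam[k] / (2 * m))
            w[:, k] = coef * (z[:, k] + 1j * y[:, k])
            w[:, m - k] = np.conj(w[:, k])
            return np.fft.fft(w, axis=1).real[:, :n_steps]
        if method == "davies-harte":
            raise ParameterError("circulant embedding not nonnegative-definite")
        logger.info("circulant embedding indefinite for H=%.3f, n=%d; "
                    "falling back to Cholesky", H, n_steps)
    cov = toeplitz(r[:n_steps])
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n_steps))
    return rng.standard_normal((n_series, n_steps)) @ L.T


def simulate_fbm(config: SimConfig) -> GroundTruthSet:
    """Fractional Brownian motion per coordinate; 2-D MSD = 2·scale·t^{2H}."""
    if config.model != "fbm":
        raise ParameterError("config.model must be 'fbm'")
    H = float(config.model_params["H"])
    scale = float(config.model_params.get("scale", 1.0))
    init_rng, dyn_rng, noise_rng = _rngs(config)
    x0 = _initial_positions(config, init_rng)
    n, m = config.n_particles, config.n_frames
    step_sd = math.sqrt(scale) * config.dt ** H
    fgn = sample_fgn(m - 1, H, 2 * n, dyn_rng) * step_sd
    increments = fgn.reshape(n, 2, m - 1).transpose(0, 2, 1)
    pos = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(increments, axis=1)],
                         axis=1) + x0[:, None, :]
    regime = "subdiffusive" if H < 0.5 else ("diffusive" if H == 0.5 else "superdiffusive")
    return _finalize(config, pos, regime, noise_rng)


def simulate_prw(config: SimConfig) -> GroundTruthSet:
    """Persistent random walk (OU velocity), exact joint discretization.

    The per-coordinate stationary velocity variance is v²/2 so that v is the
    2-D rms speed and the ensemble MSD follows
    2v²τ_p²(t/τ_p − 1 + e^{−t/τ_p}).
    """
    if config.model != "prw":
        raise ParameterError("config.model must be 'prw'")
    v = float(config.model_params.get("v", 0.0))
    tau = float(config.model_params["tau_p"])
    init_rng, dyn_rng, noise_rng = _rngs(config)
    x0 = _initial_positions(config, init_rng)
    n, m, dt = config.n_particles, config.n_frames, config.dt

    sigma2 = v ** 2 / 2.0          # per-coordinate velocity variance
    a = dt / tau
    e = math.exp(-a)
    s_vv = sigma2 * (1 - e ** 2)
    s_xx = sigma2 * tau ** 2 * (2 * a - 3 + 4 * e - e ** 2)
    s_xv = sigma2 * tau * (1 - e) ** 2
    # 2x2 Cholesky of the (Δx, v') conditional covariance
    l11 = math.sqrt(max(s_xx, 0.0))
    l21 = s_xv / l11 if l11 > 0 else 0.0
    l22 = math.sqrt(max(s_vv - l21 ** 2, 0.0))

    vel = dyn_rng.normal(0.0, math.sqrt(sigma2), size=(n, 2))
    pos = np.empty((n, m, 2))
    pos[:, 0, :] = 0.0
    xi = dyn_rng.standard_normal((m - 1, n, 2))
    eta = dyn_rng.standard_normal((m - 1, n, 2))
    coast = tau * (1 - e)
    for k in range(m - 1):
        dx = vel * coast + l11 * xi[k]
        vel = vel * e + l21 * xi[k] + l22 * eta[k]
        pos[:, k + 1, :] = pos[:, k, :] + dx
    pos += x0[:, None, :]
    return _finalize(config, pos, "superdiffusive", noise_rng)


def simulate_arrested(config: SimConfig) -> GroundTruthSet:
    """Probes bound in an elastic matrix: stationary OU about fixed anchors."""
    if config.model != "arrested":
        raise ParameterError("config.model must be 'arrested'")
    sigma = float(config.model_params.get("sigma_eq", 0.0))
    tau = float(config.model_params.get("tau_r", 1e-3))
    init_rng, dyn_rng, noise_rng = _rngs(config)
    anchors = _initial_positions(config, init_rng)
    n, m = config.n_particles, config.n_frames
    e = math.exp(-config.dt / tau)
    q = sigma * math.sqrt(max(1 - e ** 2, 0.0))
    dev = np.empty((n, m, 2))
    dev[:, 0, :] = dyn_rng.normal(0.0, sigma, size=(n, 2)) if sigma > 0 else 0.0
    if sigma > 0:
        xi = dyn_rng.standard_normal((m - 1, n, 2))
        for k in range(m - 1):
            dev[:, k + 1, :] = dev[:, k, :] * e + q * xi[k]
    else:
        dev[:, 1:, :] = 0.0
    pos = anchors[:, None, :] + dev
    return _finalize(config, pos, "elastic", noise_rng)


_SIMULATORS = {"brownian": simulate_brownian, "fbm": simulate_fbm,
               "prw": simulate_prw, "arrested": simulate_arrested}


def simulate(config: SimConfig) -> GroundTruthSet:
    """Dispatch to the simulator selected by ``config.model``."""
    return _SIMULATORS[config.model](config)


# ---------------------------------------------------------------------------
# Closed-form ensemble MSDs (exported as oracles for tests and docs)
# ---------------------------------------------------------------------------

def brownian_msd(t, D: float) -> np.ndarray:
    """2-D thermal MSD, 4Dt (μm²)."""
    return 4.0 * D * np.asarray(t, dtype=float)


def fbm_msd(t, scale: float, H: float) -> np.ndarray:
    """2-D fBm MSD, 2·scale·t^{2H} (μm²)."""
    return 2.0 * scale * np.asarray(t, dtype=float) ** (2 * H)


def prw_msd(t, v: float, tau_p: float) -> np.ndarray:
    """2-D persistent-random-walk MSD, 2v²τ²(t/τ − 1 + e^{−t/τ}) (μm²)."""
    t = np.asarray(t, dtype=float)
    return 2.0 * v ** 2 * tau_p ** 2 * (t / tau_p - 1 + np.exp(-t / tau_p))


def arrested_msd(t, sigma_eq: float, tau_r: float) -> np.ndarray:
    """2-D OU-in-trap MSD, 4σ_eq²(1 − e^{−t/τ_r}); flat 4σ_eq² for t ≫ τ_r."""
    t = np.asarray(t, dtype=float)
    return 4.0 * sigma_eq ** 2 * (1 - np.exp(-t / tau_r))


# ---------------------------------------------------------------------------
# Drift injection
# ---------------------------------------------------------------------------

def drift_from_velocity(velocity, n_frames: int, fps: float) -> np.ndarray:
    """Cumulative drift displacement from a constant or per-frame velocity (μm/s)."""
    v = np.asarray(velocity, dtype=float)
    if v.ndim == 1:
        v = np.broadcast_to(v, (n_frames, 2))
    if v.shape != (n_frames, 2):
        raise ParameterError("velocity must be a 2-vector or an (n_frames, 2) series")
    incr = np.vstack([np.zeros((1, 2)), v[1:] / fps])
    return np.cumsum(incr, axis=0)


def apply_drift(truth: GroundTruthSet, drift) -> GroundTruthSet:
    """Add a common-mode displacement series to every trajectory.

    ``drift`` is the cumulative common-mode displacement (μm), shape
    (n_frames, 2). Per-particle relative motion is untouched; the frame-k
    common-mode displacement of every particle grows by
    ``drift[k] − drift[k−1]``.
    """
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (truth.config.n_frames, 2):
        raise ParameterError(
            f"drift series must have shape ({truth.config.n_frames}, 2), "
            f"got {drift.shape}")
    return GroundTruthSet(truth.positions + drift[None, :, :], truth.config,
                          truth.regime, truth.drift + drift)


# ---------------------------------------------------------------------------
# Rendering to microscopy-like image stacks
# ---------------------------------------------------------------------------

def render_video(truth: GroundTruthSet, psf_sigma: float = 1.5,
                 peak_intensity: float = 6000.0, background_level: float = 800.0,
                 noise_sigma: float = 0.0, image_shape: tuple[int, int] = (256, 256),
                 pixel_size: float = 0.1, spot_aspect: float = 1.0,
                 seed: int | None = None) -> FrameStack:
    """Render ground-truth trajectories as a 16-bit grayscale movie.

    Each particle becomes a 2-D Gaussian spot of width ``psf_sigma`` px
    (elongated along x by ``spot_aspect``, to exercise the eccentricity
    filter) on a constant background with additive Gaussian pixel noise.
    Particles outside the field are clipped with a logged warning.
    """
    if not (psf_sigma > 0):
        raise ParameterError("psf_sigma must be positive")
    if not (pixel_size > 0):
        raise ParameterError("pixel_size must be positive")
    if seed is None:
        seed = truth.config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    n, m, _ = truth.positions.shape
    nrows, ncols = image_shape
    pos_px = truth.positions / pixel_size   # (x=col, y=row)
    sig_x = psf_sigma * spot_aspect
    sig_y = psf_sigma
    half = int(math.ceil(4 * max(sig_x, sig_y)))
    clipped = 0
    frames = np.full((m, nrows, ncols), float(background_level))
    for k in range(m):
        img = frames[k]
        for i in range(n):
            cx, cy = pos_px[i, k]
            if not (0 <= cx < ncols and 0 <= cy < nrows):
                clipped += 1
            r0, r1 = int(math.floor(cy)) - half, int(math.floor(cy)) + half + 1
            c0, c1 = int(math.floor(cx)) - half, int(math.floor(cx)) + half + 1
            r0c, r1c = max(r0, 0), min(r1, nrows)
            c0c, c1c = max(c0, 0), min(c1, ncols)
            if r0c >= r1c or c0c >= c1c:
                continue
            yy = np.arange(r0c, r1c)[:, None] - cy
            xx = np.arange(c0c, c1c)[None, :] - cx
            img[r0c:r1c, c0c:c1c] += peak_intensity * np.exp(
                -(xx ** 2 / (2 * sig_x ** 2) + yy ** 2 / (2 * sig_y ** 2)))
    if clipped:
        warnings.warn(f"{clipped} particle-frames fell outside the field and "
                      "were clipped", stacklevel=2)
        logger.warning("%d particle-frames outside the rendered field", clipped)
    if noise_sigma > 0:
        frames += rng.normal(0.0, noise_sigma, size=frames.shape)
    frames = np.clip(frames, 0, 65535)
    return FrameStack(frames.astype(np.uint16), fps=truth.config.fps,
                      pixel_size=pixel_size, bit_depth=16)


# ---------------------------------------------------------------------------
# Aging scenarios (interface-age schedules)
# ---------------------------------------------------------------------------

@dataclass
class AgingScenario:
    """An ordered schedule of (surface_age, SimConfig) stanzas.

    Each stanza is an independent movie recorded at that interface age;
    consecutive stanzas share nothing but the schedule.
    """

    name: str
    stanzas: list[tuple[float, SimConfig]]

    def __post_init__(self) -> None:
        if len(self.stanzas) < 2:
            raise ParameterError("a scenario needs at least 2 stanzas")
        ages = [a for a, _ in self.stanzas]
        if np.any(np.diff(ages) <= 0):
            raise ParameterError("surface ages must be strictly increasing")

    @property
    def ages(self) -> list[float]:
        return [a for a, _ in self.stanzas]

    def simulate(self, seed: int | None = None) -> list[tuple[float, GroundTruthSet]]:
        """Simulate every stanza; per-stanza seeds derived from ``seed``."""
        out = []
        for k, (age, cfg) in enumerate(self.stanzas):
            if seed is not None:
                child = int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0]
                            % (2 ** 31))
                cfg = replace(cfg, seed=child)
            out.append((age, simulate(cfg)))
        return out


# Stanza schedules for the two packaged interface phenotypes. Trajectory
# counts (50) sit inside the experimentally typical 25–200 range; movies are
# 6 s at 60 fps, matching the span of the displayed experimental trajectories.
_SCENARIO_NAMES = ("PAO1_like", "PA14_like")

_PAO1_SCHEDULE = [
    (60.0,    "prw",      {"v": 2.0, "tau_p": 0.5}),
    (600.0,   "prw",      {"v": 1.5, "tau_p": 0.5}),
    (1500.0,  "prw",      {"v": 1.0, "tau_p": 0.4}),
    (3600.0,  "fbm",      {"H": 0.30, "scale": 0.05}),
    (6000.0,  "fbm",      {"H": 0.25, "scale": 0.03}),
    (10000.0, "arrested", {"sigma_eq": 0.05, "tau_r": 0.01}),
    (30000.0, "arrested", {"sigma_eq": 0.03, "tau_r": 0.01}),
    (80000.0, "arrested", {"sigma_eq": 0.02, "tau_r": 0.01}),
]

_PA14_SCHEDULE = [
    (60.0,    "prw",      {"v": 2.0, "tau_p": 0.5}),
    (600.0,   "prw",      {"v": 1.8, "tau_p": 0.5}),
    (3600.0,  "prw",      {"v": 1.2, "tau_p": 0.4}),
    (10000.0, "brownian", {"D": 0.6}),
    (30000.0, "brownian", {"D": 0.45}),
    (80000.0, "brownian", {"D": 0.35}),
]


def build_aging_scenario(name: str = "PAO1_like",
                         stanzas: Sequence[tuple[float, SimConfig]] | None = None,
                         n_particles: int = 50, n_frames: int = 360,
                         fps: float = 60.0, seed: int = 0,
                         localization_noise_sigma: float = 0.01) -> AgingScenario:
    """Build a packaged or custom interface-aging scenario.

    ``PAO1_like`` programs the film-forming phenotype: superdiffusive active
    motion at ages below 1800 s, an abrupt switch to subdiffusive fBm at
    3600 s, and elastic arrest from 1e4 s onward. ``PA14_like`` programs the
    persistently active phenotype: superdiffusive-to-diffusive motion with no
    elastic stanza through 8e4 s. Custom stanzas override both.
    """
    if stanzas is not None:
        return AgingScenario(name=name, stanzas=list(stanzas))
    if name not in _SCENARIO_NAMES:
        raise ParameterError(f"unknown scenario {name!r}; choose from "
                             f"{_SCENARIO_NAMES} or pass custom stanzas")
    schedule = _PAO1_SCHEDULE if name == "PAO1_like" else _PA14_SCHEDULE
    built = []
    for k, (age, model, params) in enumerate(schedule):
        built.append((age, SimConfig(
            model=model, n_particles=n_particles, n_frames=n_frames, fps=fps,
            seed=int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0]
                     % (2 ** 31)),
            localization_noise_sigma=localization_noise_sigma,
            model_params=params)))
    return AgingScenario(name=name, stanzas=built)
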