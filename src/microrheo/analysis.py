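"""Ensemble microrheology: drift correction, MSD, exponent fits, regimes.

The analysis chain applied per interface age: subtract common-mode drift,
compute the time-averaged mean-squared displacement ⟨Δr²(t)⟩ of each
trajectory, ensemble-average, fit a power law ⟨Δr²(t)⟩ ~ tⁿ on log–log axes
over the lag window 1.67×10⁻²–1.67 s, read off the RMS displacement
d = √⟨Δr²(1.67 s)⟩, and classify the interface regime from n:

    n > 1.1    superdiffusive (active transport by motile bacteria)
    0.9–1.1    diffusive (thermal, or an active bath with random forcing)
    0.1–0.9    subdiffusive (viscoelastic interface)
    n < 0.1    elastic (probe locked in a solid interfacial film)

A time course over surface ages reports the first age at which the film
turns subdiffusive and the first at which it arrests elastically.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.constants import Boltzmann, pi

from .errors import AnalysisError, ParameterError
from .tracking import Trajectory, TrajectoryEnsemble

logger = logging.getLogger("microrheo.analysis")

LAG_WINDOW = (1.67e-2, 1.67)   # s, the standard fit window on the 60 fps grid
REF_LAG = 1.67                 # s, reference lag for d
ELASTIC_MAX = 0.1
DIFFUSIVE_BAND = (0.9, 1.1)
MIN_TRAJ_LENGTH = 110          # frames; lag 100 then has >= 10 origins
_WINDOW_SLACK = 0.01           # relative; the printed window is the rounded grid


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class MSDCurve:
    """Mean-squared displacement vs lag time."""

    lag_s: np.ndarray
    msd: np.ndarray            # μm²
    n_traj: np.ndarray         # trajectories contributing per lag
    fps: float

    def __post_init__(self) -> None:
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_traj = np.asarray(self.n_traj, dtype=int)
        if np.any(np.diff(self.lag_s) <= 0):
            raise ParameterError("lag times must be strictly increasing")
        if np.any(self.msd < -1e-12):
            raise ParameterError("msd must be non-negative")


@dataclass(frozen=True)
class PowerLawFit:
    """Result of the log–log power-law fit ⟨Δr²⟩ = prefactor · tⁿ."""

    exponent: float            # n
    prefactor: float           # μm²/sⁿ
    window: tuple[float, float]
    r_squared: float
    d: float                   # μm, RMS displacement at the reference lag
    ref_lag: float             # s, grid lag actually used for d
    n_points: int


@dataclass(frozen=True)
class RegimeLabel:
    """A regime label together with the thresholds that produced it."""

    regime: str                # superdiffusive | diffusive | subdiffusive | elastic
    exponent: float
    elastic_max: float
    diffusive_band: tuple[float, float]


@dataclass
class AgePointSummary:
    """Per-interface-age analysis output (one point of the n/d time course)."""

    surface_age: float
    fit: PowerLawFit
    label: RegimeLabel
    n_trajectories: int
    apparent_diffusivity: float    # μm²/s at the reference lag


@dataclass
class TimecourseResult:
    """Regime evolution over surface age with transition detection."""

    summaries: list[AgePointSummary]
    transition_age: float | None           # first age labelled elastic
    subdiffusive_onset_age: float | None   # first age with n below the band
    skipped_ages: list[float] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def ages(self) -> list[float]:
        return [s.surface_age for s in self.summaries]


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------

def subtract_drift(ensemble: TrajectoryEnsemble) -> TrajectoryEnsemble:
    """Remove common-mode (advective) motion from an ensemble.

    For every consecutive frame pair the mean x and y displacement over the
    trajectories spanning both frames is taken as the drift increment; the
    cumulative drift is subtracted from every trajectory so that corrected
    positions rebuild from each trajectory's first frame. Frame pairs with no
    spanning trajectory contribute zero correction (logged).
    """
    if len(ensemble) == 0:
        raise AnalysisError("cannot drift-correct an empty ensemble")
    if len(ensemble) == 1:
        warnings.warn("drift correction with a single trajectory zeroes all of "
                      "its displacements", stacklevel=2)
    f0 = min(int(t.frames[0]) for t in ensemble.trajectories)
    f1 = max(int(t.frames[-1]) for t in ensemble.trajectories)
    n_pairs = f1 - f0
    sums = np.zeros((n_pairs, 2))
    counts = np.zeros(n_pairs, dtype=int)
    for t in ensemble.trajectories:
        consecutive = np.diff(t.frames) == 1
        k = t.frames[:-1][consecutive] - f0
        disp = np.diff(t.positions, axis=0)[consecutive]
        np.add.at(sums, k, disp)
        np.add.at(counts, k, 1)
    empty = counts == 0
    if np.any(empty):
        logger.info("%d frame pairs have no spanning trajectory; zero drift "
                    "applied there", int(empty.sum()))
    mean_incr = np.zeros_like(sums)
    mean_incr[~empty] = sums[~empty] / counts[~empty, None]
    cum = np.vstack([np.zeros((1, 2)), np.cumsum(mean_incr, axis=0)])  # at f0..f1

    corrected = []
    for t in ensemble.trajectories:
        offset = cum[t.frames - f0] - cum[t.frames[0] - f0]
        pos = t.positions - offset
        corrected.append(Trajectory(t.particle_id, t.frames, pos[:, 0], pos[:, 1],
                                    features=t.features))
    meta = dict(ensemble.metadata)
    meta["drift_um"] = cum
    meta["drift_corrected"] = True
    return TrajectoryEnsemble(corrected, fps=ensemble.fps,
                              pixel_size=ensemble.pixel_size,
                              surface_age=ensemble.surface_age, metadata=meta)


# ---------------------------------------------------------------------------
# Mean-squared displacement
# ---------------------------------------------------------------------------

def _msd_1traj(frames: np.ndarray, pos: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD with overlapping origins; NaN where undefined."""
    span = int(frames[-1] - frames[0]) + 1
    grid = np.full((span, 2), np.nan)
    grid[frames - frames[0]] = pos
    out = np.full(max_lag, np.nan)
    for k in range(1, min(max_lag, span - 1) + 1):
        d = grid[k:] - grid[:-k]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        valid = ~np.isnan(sq)
        if valid.any():
            out[k - 1] = sq[valid].mean()
    return out


def trajectory_msd(traj: Trajectory, max_lag_frames: int, fps: float | None = None,
                   ) -> MSDCurve:
    """Time-averaged MSD of a single trajectory over overlapping origins."""
    if len(traj) < 2:
        raise AnalysisError("trajectory needs at least 2 points")
    if fps is None:
        fps = 60.0
    span = int(traj.frames[-1] - traj.frames[0])
    if max_lag_frames > span:
        logger.info("max_lag_frames %d truncated to trajectory span %d",
                    max_lag_frames, span)
        max_lag_frames = span
    vals = _msd_1traj(traj.frames, traj.positions, max_lag_frames)
    lags = np.arange(1, max_lag_frames + 1) / fps
    keep = ~np.isnan(vals)
    return MSDCurve(lags[keep], vals[keep], np.ones(keep.sum(), dtype=int), fps)


def ensemble_msd(ensemble: TrajectoryEnsemble, max_lag_frames: int = 100,
                 min_traj_length: int = MIN_TRAJ_LENGTH) -> MSDCurve:
    """Unweighted mean of per-trajectory time-averaged MSDs at each lag.

    Only trajectories of at least ``min_traj_length`` points enter; at each
    lag, only those with a defined value there contribute, and the
    contributing count is recorded.
    """
    qualifying = [t for t in ensemble.trajectories if len(t) >= min_traj_length]
    if not qualifying:
        raise AnalysisError(
            f"no trajectory reaches min_traj_length={min_traj_length} "
            f"(longest has {max(ensemble.lengths(), default=0)} points)")
    per_traj = np.vstack([_msd_1traj(t.frames, t.positions, max_lag_frames)
                          for t in qualifying])
    counts = np.sum(~np.isnan(per_traj), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(per_traj, axis=0)
    lags = np.arange(1, max_lag_frames + 1) / ensemble.fps
    keep = counts > 0
    curve = MSDCurve(lags[keep], means[keep], counts[keep], ensemble.fps)
    # per-lag standard error of the ensemble mean, for oracle comparisons
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sem = np.nanstd(per_traj, axis=0, ddof=1) / np.sqrt(np.maximum(counts, 1))
    curve.sem = sem[keep]
    return curve


# ---------------------------------------------------------------------------
# Power-law fit and regime classification
# ---------------------------------------------------------------------------

def fit_power_law(msd: MSDCurve, window: tuple[float, float] = LAG_WINDOW,
                  ref_lag: float = REF_LAG) -> PowerLawFit:
    """Fit ⟨Δr²(t)⟩ = prefactor · tⁿ by least squares on log₁₀–log₁₀ axes.

    The window bounds are applied with 1% relative slack because the printed
    window endpoints (1.67×10⁻² and 1.67 s) are the rounded 60 fps grid lags
    1/60 and 100/60 s. d is the square root of the measured MSD at the
    in-window grid lag nearest ``ref_lag`` (not the fitted curve's value).
    Zero-valued MSD points are excluded and logged.
    """
    t_min, t_max = window
    if not t_min < t_max:
        raise ParameterError("fit window must satisfy t_min < t_max")
    sel = (msd.lag_s >= t_min * (1 - _WINDOW_SLACK)) & \
          (msd.lag_s <= t_max * (1 + _WINDOW_SLACK))
    lags = msd.lag_s[sel]
    vals = msd.msd[sel]
    positive = vals > 0
    if np.any(~positive):
        logger.info("excluding %d zero-valued MSD points from the log–log fit",
                    int((~positive).sum()))
    lags, vals = lags[positive], vals[positive]
    if len(lags) < 3:
        raise AnalysisError(
            f"need >= 3 positive MSD points inside the window {window}, "
            f"have {len(lags)}")
    lx, ly = np.log10(lags), np.log10(vals)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    i_ref = int(np.argmin(np.abs(lags - ref_lag)))
    return PowerLawFit(exponent=float(slope), prefactor=float(10 ** intercept),
                       window=(t_min, t_max), r_squared=float(r2),
                       d=float(np.sqrt(vals[i_ref])), ref_lag=float(lags[i_ref]),
                       n_points=len(lags))


def classify_regime(fit: PowerLawFit | float, elastic_max: float = ELASTIC_MAX,
                    diffusive_band: tuple[float, float] = DIFFUSIVE_BAND,
                    ) -> RegimeLabel:
    """Label the interface regime from the fitted exponent.

    The labels partition the n axis: n < ``elastic_max`` is an essentially
    solid elastic film; up to the diffusive band, subdiffusive; within the
    band (inclusive), diffusive; above it, superdiffusive.
    """
    n = fit.exponent if isinstance(fit, PowerLawFit) else float(fit)
    if not np.isfinite(n):
        raise ParameterError("exponent must be finite")
    lo, hi = diffusive_band
    if not (elastic_max <= lo < hi):
        raise ParameterError("require elastic_max <= band_lo < band_hi")
    if n < elastic_max:
        regime = "elastic"
    elif n < lo:
        regime = "subdiffusive"
    elif n <= hi:
        regime = "diffusive"
    else:
        regime = "superdiffusive"
    return RegimeLabel(regime, n, elastic_max, (lo, hi))


# ---------------------------------------------------------------------------
# Diffusivity references and trapping energy
# ---------------------------------------------------------------------------

def apparent_diffusivity(msd: MSDCurve, at_lag: float) -> float:
    """D_app = ⟨Δr²(t)⟩ / 4t at the measured lag nearest ``at_lag`` (μm²/s)."""
    if not (msd.lag_s[0] * (1 - _WINDOW_SLACK) <= at_lag
            <= msd.lag_s[-1] * (1 + _WINDOW_SLACK)):
        raise AnalysisError(f"lag {at_lag} s outside measured range "
                            f"[{msd.lag_s[0]:.4g}, {msd.lag_s[-1]:.4g}] s")
    i = int(np.argmin(np.abs(msd.lag_s - at_lag)))
    return float(msd.msd[i] / (4.0 * msd.lag_s[i]))


def activity_ratio(d_apparent: float, d_thermal: float) -> float:
    """D_app / D_thermal; values well above 1 indicate active forcing."""
    if not (d_thermal > 0):
        raise ParameterError("d_thermal must be positive")
    return float(d_apparent / d_thermal)


def thermal_diffusivity(probe_radius: float, viscosity: float,
                        temperature: float = 298.0) -> float:
    """Stokes–Einstein diffusivity k_B·T / (6πηR) in μm²/s.

    ``probe_radius`` in m, ``viscosity`` in Pa·s, ``temperature`` in K.
    """
    if probe_radius <= 0 or viscosity <= 0 or temperature <= 0:
        raise ParameterError("probe_radius, viscosity, temperature must be > 0")
    d_m2s = Boltzmann * temperature / (6 * pi * viscosity * probe_radius)
    return d_m2s * 1e12


@dataclass(frozen=True)
class TrappingEnergy:
    joules: float
    kT: float
    temperature: float


def trapping_energy(gamma: float, delta_area: float,
                    temperature: float = 298.0) -> TrappingEnergy:
    """Interfacial trapping energy E = γ·ΔA, also expressed in k_B·T units.

    ``gamma`` in N/m, ``delta_area`` in m². For a micron-scale object at an
    oil–water interface this is of order 10⁷ k_B·T, which is why interfacial
    attachment is effectively irreversible.
    """
    if gamma < 0 or delta_area < 0:
        raise ParameterError("gamma and delta_area must be >= 0")
    e = gamma * delta_area
    return TrappingEnergy(joules=e, kT=e / (Boltzmann * temperature),
                          temperature=temperature)


# ---------------------------------------------------------------------------
# Interface-age time course
# ---------------------------------------------------------------------------

def analyze_ensemble(ensemble: TrajectoryEnsemble, *,
                     max_lag_frames: int = 100,
                     min_traj_length: int = MIN_TRAJ_LENGTH,
                     window: tuple[float, float] = LAG_WINDOW,
                     ref_lag: float = REF_LAG,
                     elastic_max: float = ELASTIC_MAX,
                     diffusive_band: tuple[float, float] = DIFFUSIVE_BAND,
                     drift_correction: bool = True,
                     ) -> tuple[MSDCurve, PowerLawFit, RegimeLabel]:
    """Drift-correct, ensemble-MSD, fit, classify — the per-age chain."""
    if drift_correction:
        ensemble = subtract_drift(ensemble)
    curve = ensemble_msd(ensemble, max_lag_frames, min_traj_length)
    fit = fit_power_law(curve, window, ref_lag)
    label = classify_regime(fit, elastic_max, diffusive_band)
    return curve, fit, label


def analyze_timecourse(age_ensembles: Sequence[tuple[float, TrajectoryEnsemble]], *,
                       max_lag_frames: int = 100,
                       min_traj_length: int = MIN_TRAJ_LENGTH,
                       window: tuple[float, float] = LAG_WINDOW,
                       ref_lag: float = REF_LAG,
                       elastic_max: float = ELASTIC_MAX,
                       diffusive_band: tuple[float, float] = DIFFUSIVE_BAND,
                       min_traj_count: int = 10,
                       drift_correction: bool = True) -> TimecourseResult:
    """Run the per-age analysis chain over a surface-age series.

    Ages with fewer than ``min_traj_count`` trajectories are skipped with a
    warning and recorded. ``transition_age`` is the first age labelled
    elastic; ``subdiffusive_onset_age`` the first with n below the diffusive
    band (either may be absent).
    """
    if len(age_ensembles) < 2:
        raise AnalysisError("a time course needs at least 2 ages")
    ages = [a for a, _ in age_ensembles]
    if np.any(np.diff(ages) <= 0):
        raise ParameterError("surface ages must be strictly increasing")
    summaries: list[AgePointSummary] = []
    skipped: list[float] = []
    for age, ens in age_ensembles:
        if len(ens) < min_traj_count:
            warnings.warn(f"age {age} s skipped: {len(ens)} trajectories "
                          f"< min_traj_count={min_traj_count}", stacklevel=2)
            skipped.append(age)
            continue
        curve, fit, label = analyze_ensemble(
            ens, max_lag_frames=max_lag_frames, min_traj_length=min_traj_length,
            window=window, ref_lag=ref_lag, elastic_max=elastic_max,
            diffusive_band=diffusive_band, drift_correction=drift_correction)
        summaries.append(AgePointSummary(
            surface_age=age, fit=fit, label=label, n_trajectories=len(ens),
            apparent_diffusivity=apparent_diffusivity(curve, ref_lag)))
    transition = next((s.surface_age for s in summaries
                       if s.label.regime == "elastic"), None)
    onset = next((s.surface_age for s in summaries
                  if s.fit.exponent < diffusive_band[0]), None)
    return TimecourseResult(
        summaries=summaries, transition_age=transition,
        subdiffusive_onset_age=onset, skipped_ages=skipped,
        params={"window": window, "ref_lag": ref_lag, "elastic_max": elastic_max,
                "diffusive_band": diffusive_band, "min_traj_length": min_traj_length,
                "min_traj_count": min_traj_count,
                "drift_correction": drift_correction})


# ---------------------------------------------------------------------------
# Plotting (optional artifacts)
# ---------------------------------------------------------------------------

def plot_msd(curves: Sequence[tuple[str, MSDCurve]], path=None):
    """Log–log ensemble MSD curves; returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves:
        ax.loglog(c.lag_s, c.msd, "o-", ms=3, label=str(label))
    ax.set_xlabel("lag time (s)")
    ax.set_ylabel(r"$\langle \Delta r^2 \rangle$ ($\mu$m$^2$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig

def plot_timecourse(result: TimecourseResult, path=None):
    """Exponent n and RMS displacement d versus surface age."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    ages = result.ages
    ns = [s.fit.exponent for s in result.summaries]
    ds = [s.fit.d for s in result.summaries]
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.semilogx(ages, ns, "o-", color="C3", label="exponent n")
    ax.axhline(1.0, ls="--", c="gray", lw=0.8)
    ax.axhline(0.1, ls=":", c="gray", lw=0.8)
    ax.set_xlabel("surface age (s)")
    ax.set_ylabel("exponent n")
    ax2 = ax.twinx()
    ax2.semilogx(ages, ds, "s--", mfc="none", color="C0", label="d(1.67 s)")
    ax2.set_yscale("log")
    ax2.set_ylabel(r"d ($\mu$m)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
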