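"""Post-processing: MSD curves, effective diffusion, unbound fractions.

In free 3-D diffusion the ensemble mean squared displacement is
``<r^2(t)> = 6 D t``.  Obstacles make the MSD transiently sub-linear: the
short-lag slope still reflects the free coefficient D0 while the long-lag
slope gives the reduced effective coefficient D_eff.  Transient binding
reduces the long-time mobility further, proportionally to the unbound
fraction fu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import SpeciesSpec, Trajectories, run_tracers
from .geometry import CellGeometry


@dataclass
class MsdCurve:
    """Time-lag averaged mean squared displacement."""

    lags: np.ndarray     # s
    msd: np.ndarray      # um^2
    n_pairs: np.ndarray  # displacement samples per lag

    def __post_init__(self):
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")


def compute_msd(trajectories, lags=None,
                use_multiple_origins: bool = True,
                origin_stride: int | None = None) -> MsdCurve:
    """Ensemble (and optionally time-origin) averaged MSD.

    ``trajectories`` is a Trajectories object or a (T, N, 3) position array
    sampled at uniform intervals.  ``lags`` selects lag indices (defaults to
    every available lag); lags beyond the trajectory length are dropped with
    a warning.
    """
    if isinstance(trajectories, Trajectories):
        pos = trajectories.positions
        dt_rec = float(trajectories.times[1] - trajectories.times[0]) \
            if len(trajectories.times) > 1 else 1.0
    else:
        pos = np.asarray(trajectories)
        dt_rec = 1.0
    T = pos.shape[0]
    if lags is None:
        lag_idx = np.arange(1, T)
    else:
        lag_idx = np.asarray(lags, int)
        drop = lag_idx >= T
        if np.any(drop):
            warnings.warn(f"dropping {int(drop.sum())} lags beyond the "
                          "trajectory length", stacklevel=2)
            lag_idx = lag_idx[~drop]
    msd = np.empty(lag_idx.size)
    n_pairs = np.empty(lag_idx.size, int)
    for k, L in enumerate(lag_idx):
        if use_multiple_origins:
            stride = origin_stride or 1
            origins = np.arange(0, T - L, stride)
        else:
            origins = np.array([0])
        d = pos[origins + L] - pos[origins]
        sq = np.sum(d * d, axis=-1)
        msd[k] = sq.mean()
        n_pairs[k] = sq.size
    return MsdCurve(lag_idx * dt_rec, msd, n_pairs)


def estimate_Deff(curve: MsdCurve, fit_window=None):
    """Least-squares slope of the MSD over a lag window, divided by 6.

    Returns ``(Deff, ci)`` where ``ci`` is the 95 % half-width from the
    regression standard error.  An intercept is allowed so that the
    short-time transient does not bias a long-lag fit.
    """
    lags = curve.lags
    msd = curve.msd
    if fit_window is not None:
        lo, hi = fit_window
        sel = (lags >= lo) & (lags <= hi)
        lags, msd = lags[sel], msd[sel]
    if lags.size < 3:
        raise ValueError("need at least 3 lag points in the fit window")
    fit = stats.linregress(lags, msd)
    return fit.slope / 6.0, 1.96 * fit.stderr / 6.0


def unbound_fraction_series(trajectories_or_bound):
    """fu(t) = unbound molecules / total molecules, per observation time.

    Accepts a Trajectories object or a boolean (T, N) bound array.  Returns
    ``(fu, steady_mean, steady_se)`` with the steady state taken over the
    second half of the series (SE over per-time fractions, block-averaged).
    """
    if isinstance(trajectories_or_bound, Trajectories):
        bound = trajectories_or_bound.bound
    else:
        bound = np.asarray(trajectories_or_bound)
    fu = 1.0 - bound.mean(axis=1)
    tail = fu[fu.size // 2:]
    nb = max(min(16, tail.size // 2), 1)
    blocks = np.array_split(tail, nb)
    bm = np.array([b.mean() for b in blocks])
    se = bm.std(ddof=1) / np.sqrt(nb) if nb > 1 else 0.0
    return fu, float(tail.mean()), float(se)


def effective_diffusion(geometry: CellGeometry, radius: float = 0.0025,
                        D0: float = 1.0, n_tracers: int = 1000,
                        t_end: float = 0.05, dt: float = 1.0e-6,
                        record_every: int = 500, seed: int = 0,
                        fit_window=(0.008, 0.04),
                        short_window=None, **binding):
    """Measure D_eff/D0 from the long-lag MSD slope of inert tracers.

    Runs the rejection random walk for ``n_tracers`` tracers, computes the
    origin-averaged MSD and fits the window ``fit_window`` (chosen past the
    anomalous-transient crossover but well before membrane confinement
    matters).  Returns a dict with the long-lag and optional short-lag
    estimates and the trajectories.
    """
    spec = SpeciesSpec("tracer", radius=radius, D0=D0, init_count=n_tracers)
    traj = run_tracers(geometry, spec, n_tracers, t_end, dt, record_every,
                       seed, **binding)
    curve = compute_msd(traj)
    deff, ci = estimate_Deff(curve, fit_window)
    out = {"Deff": deff, "ci": ci, "curve": curve, "trajectories": traj}
    if short_window is not None:
        short = run_tracers(geometry, spec, n_tracers,
                            short_window[1] * 10, dt, 1, seed + 1,
                            **binding)
        s_curve = compute_msd(short)
        out["D_short"], out["D_short_ci"] = estimate_Deff(
            s_curve, short_window)
    return out
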