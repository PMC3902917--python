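"""Single-particle-tracking analysis: MSD curves, apparent diffusion
coefficients and confined-diffusion fitting.

A tracked plasmid focus in a rod-shaped cell is described by its position
along the cell's long axis (``x``, pole at 0) and short axis (``y``,
centerline at 0).  Free diffusion gives a linear mean-square displacement
MSD(t) = 2 q D t per axis; motion confined to a region of size ``L``
saturates, and we fit the single-exponential confined-diffusion form

    MSD(t) = (L^2 / 6) * (1 - exp(-12 D t / L^2))  [+ offset]

whose asymptote ``L^2/6`` measures the confinement length.  Apparent
diffusion coefficients follow D_app = MSD(tau) / (tau * q_i) with the
dimensionality factor q_i (2 per axis, 4 in two dimensions).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger("plasmidyn")

AXES = ("long", "short", "2d")


@dataclass
class Trajectory:
    """One tracked spot: time-ordered positions in the cell frame.

    times are seconds; x is the long-axis coordinate in µm with the pole at
    0; y is the short-axis coordinate in µm with the centerline at 0.
    Sampling must be uniform within 1%.
    """

    track_id: int
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cell_id: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x and y must have equal length")
        if len(self.times) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        if dts.max() - dts.min() > 0.01 * dts.mean():
            raise ValueError("sampling must be uniform within 1%")

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return float(np.mean(np.diff(self.times)))

    def __len__(self) -> int:
        return len(self.times)

    def positions(self, axis: str) -> np.ndarray:
        if axis == "long":
            return self.x[:, None]
        if axis == "short":
            return self.y[:, None]
        if axis == "2d":
            return np.column_stack([self.x, self.y])
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")


@dataclass
class MSDCurve:
    """Mean-square displacement vs lag time for one axis choice."""

    axis: str
    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")


@dataclass
class DiffusionEstimate:
    """Apparent diffusion coefficient D_app = MSD / (tau * q_i)."""

    d_app: float
    tau: float
    q_i: int


@dataclass
class ConfinementFit:
    """Result of the confined-diffusion fit on one axis.

    ``plateau_reached`` is False when the fitted confinement exceeds the
    cell dimension on that axis or the observation span is shorter than
    three relaxation times L^2/(12 D) — mirroring tracks whose MSD never
    levels off within the experiment.
    """

    axis: str
    L: float
    D_fit: float
    offset: float
    rss: float
    plateau_reached: bool
    converged: bool = True

    @property
    def asymptote(self) -> float:
        """MSD plateau L^2/6 + offset (µm^2)."""
        return self.L**2 / 6.0 + self.offset


# ---------------------------------------------------------------------------
# MSD computation


def compute_msd(
    traj: Trajectory,
    axis: str = "long",
    max_lag: float | None = None,
    mode: str = "time_avg",
) -> MSDCurve:
    """Mean-square displacement of one track on the native lag grid.

    ``time_avg`` averages the squared displacement over every pair of frames
    (i, i+k); ``ensemble`` uses only displacements from the first frame.
    Lags with fewer than two usable pairs are omitted in time-averaged mode
    (with a logged warning).

    Parameters
    ----------
    traj : Trajectory
    axis : {"long", "short", "2d"}
    max_lag : float, optional
        Largest lag in seconds; defaults to half the track span.
    mode : {"time_avg", "ensemble"}
    """
    if mode not in ("time_avg", "ensemble"):
        raise ValueError(f"mode must be 'time_avg' or 'ensemble', got {mode!r}")
    pos = traj.positions(axis)
    n = len(traj)
    dt = traj.dt
    span = traj.times[-1] - traj.times[0]
    if max_lag is None:
        max_lag = span / 2.0
    kmax = min(n - 1, int(round(max_lag / dt)))
    lags, msd, npairs = [], [], []
    omitted = 0
    for k in range(1, kmax + 1):
        if mode == "time_avg":
            d = pos[k:] - pos[:-k]
            m = d.shape[0]
            if m < 2:
                omitted += 1
                continue
            sq = np.sum(d * d, axis=1)
            lags.append(k * dt)
            msd.append(sq.mean())
            npairs.append(m)
        else:
            d = pos[k] - pos[0]
            lags.append(k * dt)
            msd.append(float(np.sum(d * d)))
            npairs.append(1)
    if omitted:
        logger.warning(
            "track %s: %d lag(s) omitted (<2 pairs)", traj.track_id, omitted
        )
    if not lags:
        raise ValueError("no usable lags; track too short for requested max_lag")
    return MSDCurve(axis=axis, lags=np.array(lags), msd=np.array(msd),
                    n_pairs=np.array(npairs))


def average_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Pair-count-weighted average of MSD curves sharing one lag grid.

    Curves may have different lengths; each lag is averaged over the curves
    that reach it, weighted by their pair counts.
    """
    if not curves:
        raise ValueError("need at least one curve")
    axis = curves[0].axis
    if any(c.axis != axis for c in curves):
        raise ValueError("curves mix axes")
    # align on the union grid by rounded lag
    grid: dict[float, list[tuple[float, int]]] = {}
    for c in curves:
        for lag, m, w in zip(c.lags, c.msd, c.n_pairs):
            grid.setdefault(round(float(lag), 9), []).append((m, int(w)))
    lags = np.array(sorted(grid))
    msd = np.empty_like(lags)
    npairs = np.empty(len(lags), dtype=int)
    for i, lag in enumerate(lags):
        vals = grid[round(float(lag), 9)]
        w = np.array([v[1] for v in vals], dtype=float)
        m = np.array([v[0] for v in vals])
        msd[i] = np.average(m, weights=w)
        npairs[i] = int(w.sum())
    return MSDCurve(axis=axis, lags=lags, msd=msd, n_pairs=npairs)


def compute_dapp(msd_at_tau: float, tau: float, q_i: int) -> DiffusionEstimate:
    """Apparent diffusion coefficient D_app = MSD/(tau*q_i).

    q_i is 2 for a single axis and 4 for two-dimensional displacements.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if q_i not in (2, 4):
        raise ValueError(f"q_i must be 2 (per axis) or 4 (2D), got {q_i}")
    if msd_at_tau < 0:
        raise ValueError("msd must be non-negative")
    return DiffusionEstimate(d_app=msd_at_tau / (tau * q_i), tau=tau, q_i=q_i)


def dapp_vs_lag(curve: MSDCurve, q_i: int | None = None) -> np.ndarray:
    """D_app at every lag of an MSD curve (drops with lag under confinement)."""
    if q_i is None:
        q_i = 4 if curve.axis == "2d" else 2
    return np.array([compute_dapp(m, t, q_i).d_app
                     for m, t in zip(curve.msd, curve.lags)])


# ---------------------------------------------------------------------------
# Confined-diffusion fit


def confinement_model(t: np.ndarray, L: float, D: float,
                      offset: float = 0.0) -> np.ndarray:
    """Single-exponential confined-diffusion MSD, asymptote L^2/6 + offset."""
    t = np.asarray(t, dtype=float)
    return L**2 / 6.0 * (1.0 - np.exp(-12.0 * D * t / L**2)) + offset


def fit_confinement(
    curve: MSDCurve,
    cell_dim: float | None = None,
    with_offset: bool = False,
) -> ConfinementFit:
    """Fit the confined-diffusion form to an MSD curve.

    Weighted least squares with weights sqrt(n_pairs); multi-start over a
    grid of initial (L, D) guesses.  ``cell_dim`` is the cell size on the
    fitted axis, used only for the plateau classification.
    """
    if len(curve.lags) < 4:
        raise ValueError("need at least 4 lag points to fit")
    t, y = curve.lags, curve.msd
    w = np.sqrt(curve.n_pairs.astype(float))

    def resid(p: np.ndarray) -> np.ndarray:
        off = p[2] if with_offset else 0.0
        return w * (confinement_model(t, p[0], p[1], off) - y)

    L0 = max(np.sqrt(6.0 * max(y.max(), 1e-12)), 1e-4)
    D0 = max(y[0] / (2.0 * t[0]), 1e-12)
    starts = [(L0 * a, D0 * b) for a in (1.0, 0.3, 3.0) for b in (1.0, 0.1, 10.0)]
    best = None
    for Ls, Ds in starts:
        p0 = [Ls, Ds] + ([0.0] if with_offset else [])
        lb = [1e-6, 1e-12] + ([0.0] if with_offset else [])
        ub = [np.inf] * len(p0)
        try:
            sol = least_squares(resid, p0, bounds=(lb, ub), max_nfev=2000)
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        return ConfinementFit(axis=curve.axis, L=float("nan"), D_fit=float("nan"),
                              offset=0.0, rss=float("inf"),
                              plateau_reached=False, converged=False)
    L, D = float(best.x[0]), float(best.x[1])
    offset = float(best.x[2]) if with_offset else 0.0
    rss = float(np.sum((confinement_model(t, L, D, offset) - y) ** 2))
    relax = L**2 / (12.0 * D)
    plateau = (cell_dim is None or L <= cell_dim) and (t[-1] >= 3.0 * relax)
    return ConfinementFit(axis=curve.axis, L=L, D_fit=D, offset=offset,
                          rss=rss, plateau_reached=bool(plateau),
                          converged=bool(best.success))


def step_size_stats(traj: Trajectory, interval: float) -> tuple[float, float]:
    """Mean and SD of the per-second Euclidean step length at ``interval``.

    ``interval`` must be an integer multiple of the frame time.
    """
    dt = traj.dt
    k = interval / dt
    if abs(k - round(k)) > 0.01:
        raise ValueError("interval must be a multiple of the frame time")
    k = int(round(k))
    if k < 1 or k >= len(traj):
        raise ValueError("interval out of range for this track")
    dx = traj.x[k:] - traj.x[:-k]
    dy = traj.y[k:] - traj.y[:-k]
    speed = np.hypot(dx, dy) / interval
    return float(speed.mean()), float(speed.std())
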