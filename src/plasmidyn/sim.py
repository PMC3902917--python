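"""Stochastic whole-cell model of high-copy plasmid dynamics.

One cell grows exponentially (length doubling over the generation time),
carries a central nucleoid that splits late in the cycle, and hosts point
plasmids that (i) hop-diffuse along the long axis with nucleoid edges as
partially permeable barriers, (ii) initiate replication stochastically,
completing after plasmid_bp / fork_speed seconds, and (iii) are partitioned
at division by position: each daughter inherits the plasmids in its half.

Replication modes:

* ``constant_rate`` — every non-replicating plasmid initiates with a fixed
  probability per unit time (per-plasmid rate ln 2 / tau_gen on average
  doubles the copy number per generation).  This is a critical branching
  process: the mean is maintained but fluctuations accumulate over
  generations.
* ``rnaI_feedback`` — initiation is inhibited hyperbolically by the total
  copy number, standing in for the well-mixed antisense RNA I pool of
  ColE1-type control: lambda(n) = lambda0 / (1 + R(n)/R_half) with
  R(n) = n * rnai_pool / k_ref molecules.  The default
  lambda0 = (ln 2 + n_birth/K) / tau_gen (K = R_half in plasmid
  equivalents) makes the deterministic cycle map n_birth -> 2 n_birth
  exactly, giving long-run copy-number homeostasis.

Replisome-marker observables are logged per initiation: an SSB-type spot
spanning [t, t_done] and a DnaN-type spot spanning
[t, t_done + dnan_retention_s].
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .profiles import CellGeometry
from .synth import hop_step, reflect

LN2 = math.log(2.0)

REP_MODES = ("constant_rate", "rnaI_feedback")


@dataclass
class SimConfig:
    """Whole-cell simulation parameters.

    Units: minutes for tau_gen, µm for geometry, µm²/s for D, seconds for
    dt and marker times, bases and bp/s for synthesis.  ``rep_rate`` is the
    per-plasmid initiation rate per minute; None selects the calibrated
    default for the chosen mode.  ``rnai_pool`` is the RNA I copy number at
    the reference plasmid load ``k_ref`` and ``rnai_half`` the pool size at
    half-maximal inhibition (feedback mode only).
    """

    tau_gen: float = 100.0
    birth_length: float = 2.0
    width: float = 0.8
    D: float = 2.5e-3
    p_hop: float = 0.1
    nucleoid_fraction: float = 0.6
    nucleoid_split_x: float = 0.75
    n_birth: int = 12
    rep_mode: str = "constant_rate"
    rep_rate: float | None = None
    rnai_pool: float = 400.0
    rnai_half: float = 47.0
    k_ref: float = 17.0
    plasmid_bp: float = 11300.0
    fork_speed: float = 600.0
    dnan_retention_s: float = 283.0
    dt: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rep_mode not in REP_MODES:
            raise ValueError(f"rep_mode must be one of {REP_MODES}")
        if not (0.0 <= self.p_hop <= 1.0):
            raise ValueError("p_hop must lie in [0, 1]")
        if not (0.0 <= self.nucleoid_fraction < 1.0):
            raise ValueError("nucleoid_fraction must lie in [0, 1)")
        if not (0.0 < self.nucleoid_split_x <= 1.0):
            raise ValueError("nucleoid_split_x must lie in (0, 1]")
        if min(self.tau_gen, self.birth_length, self.width, self.dt,
               self.fork_speed) <= 0:
            raise ValueError("tau_gen, geometry, dt and fork_speed must be positive")
        if self.n_birth < 1:
            raise ValueError("n_birth must be >= 1")
        if self.D < 0 or self.dnan_retention_s < 0 or self.plasmid_bp < 0:
            raise ValueError("D, plasmid_bp and dnan_retention_s must be >= 0")
        rate = self.base_rate()
        frac = rate * self.dt / 60.0
        if frac > 0.5:
            raise ValueError(
                f"dt too large: per-step initiation probability {frac:.2f} > 0.5"
            )
        if frac > 0.1:
            import warnings

            warnings.warn(
                f"per-step initiation probability {frac:.2f} > 0.1; "
                "consider a smaller dt", stacklevel=2)

    def base_rate(self) -> float:
        """Per-plasmid initiation rate lambda0 (per minute)."""
        if self.rep_rate is not None:
            return self.rep_rate
        if self.rep_mode == "constant_rate":
            return LN2 / self.tau_gen
        K = self.feedback_K()
        return (LN2 + self.n_birth / K) / self.tau_gen

    def feedback_K(self) -> float:
        """Half-inhibition point in plasmid-copy equivalents."""
        return self.rnai_half / (self.rnai_pool / self.k_ref)


@dataclass
class SimState:
    """Evolving cell state: geometry, plasmid positions and active forks."""

    t: float = 0.0  # seconds since birth of this cell
    cell_length: float = 2.0
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))
    replicating: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    t_done: np.ndarray = field(default_factory=lambda: np.empty(0))
    generation: int = 0

    @property
    def n_copies(self) -> int:
        return len(self.x)


@dataclass
class SimResult:
    """Observables from a lineage run."""

    birth_copies: list[int] = field(default_factory=list)
    division_copies: list[int] = field(default_factory=list)
    loss_events: int = 0
    n_divisions: int = 0
    initiations: list[tuple[float, float]] = field(default_factory=list)  # (t_abs_s, rel_pos)
    ssb_spots: list[tuple[float, float, float]] = field(default_factory=list)  # (t0, t1, rel_pos)
    dnan_spots: list[tuple[float, float, float]] = field(default_factory=list)
    trajectory: list[tuple[float, float, float, float]] = field(default_factory=list)  # (t_abs_s, rel_pos, y_um, length)
    density_edges: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 51))
    density_counts: np.ndarray = field(default_factory=lambda: np.zeros(50))

    @property
    def initiation_positions(self) -> np.ndarray:
        return np.array([p for _, p in self.initiations])

    def position_density(self) -> np.ndarray:
        total = self.density_counts.sum()
        return self.density_counts / total if total else self.density_counts


def initial_state(config: SimConfig, rng: np.random.Generator) -> SimState:
    """Newborn cell with n_birth plasmids placed in the nucleoid-free space."""
    L, w = config.birth_length, config.width
    cell = _geometry(config, L, stage=0.0)
    free = cell.free_intervals()
    widths = np.array([b - a for a, b in free])
    n = config.n_birth
    gaps = rng.choice(len(free), size=n, p=widths / widths.sum())
    x = np.array([rng.uniform(free[g][0], free[g][1]) * L for g in gaps])
    y = rng.uniform(-w / 2.0, w / 2.0, size=n)
    return SimState(t=0.0, cell_length=L, x=x, y=y,
                    replicating=np.zeros(n, dtype=bool),
                    t_done=np.full(n, np.inf))


def _geometry(config: SimConfig, length: float, stage: float) -> CellGeometry:
    """Nucleoid layout at a cell-cycle stage: one central block, splitting
    into two (midcell gap) at nucleoid_split_x."""
    f = config.nucleoid_fraction
    if f == 0:
        ivs: list[tuple[float, float]] = []
    elif stage < config.nucleoid_split_x:
        ivs = [(0.5 - f / 2.0, 0.5 + f / 2.0)]
    else:
        q = f / 4.0
        ivs = [(0.25 - q, 0.25 + q), (0.75 - q, 0.75 + q)]
    return CellGeometry(cell_id=0, length=length, width=config.width,
                        nucleoid_intervals=ivs)


def step(state: SimState, config: SimConfig, rng: np.random.Generator,
         result: SimResult | None = None, t_abs: float = 0.0) -> SimState:
    """Advance the cell by one time step dt.

    Growth rescales long-axis positions with the exponentially elongating
    cell; each plasmid then takes a hop-diffusion step; non-replicating
    plasmids initiate replication stochastically; finished forks deposit
    the new copy at the parent's position (small jitter, no cohesion).
    """
    dt_s = config.dt
    tau_s = config.tau_gen * 60.0
    growth = 2.0 ** (dt_s / tau_s)
    L = state.cell_length * growth
    x = state.x * growth
    y = state.y.copy()
    t = state.t + dt_s
    stage = t / tau_s
    cell = _geometry(config, L, stage)
    barriers = cell.barriers_um()

    # diffusion: vectorize the common no-barrier-crossing case
    sd = math.sqrt(2.0 * config.D * dt_s)
    n = len(x)
    if sd > 0 and n:
        dx = rng.normal(0.0, sd, size=n)
        dy = rng.normal(0.0, sd, size=n)
        if barriers.size and config.p_hop < 1.0:
            lo = np.minimum(x, x + dx)
            hi = np.maximum(x, x + dx)
            crosses = (
                np.searchsorted(barriers, hi) - np.searchsorted(barriers, lo)
            ) > 0
            crosses |= (x + dx < 0) | (x + dx > L)
        else:
            crosses = np.zeros(n, dtype=bool)
        easy = ~crosses
        x[easy] = reflect(x[easy] + dx[easy], 0.0, L)
        for i in np.flatnonzero(crosses):
            x[i] = hop_step(x[i], dx[i], barriers, 0.0, L, config.p_hop, rng)
        y = reflect(y + dy, -config.width / 2.0, config.width / 2.0)

    # replication completions
    replicating = state.replicating.copy()
    t_done = state.t_done.copy()
    done = replicating & (t_done <= t)
    if np.any(done):
        idx = np.flatnonzero(done)
        jitter = rng.normal(0.0, 0.01, size=(len(idx), 2))
        x = np.append(x, np.clip(x[idx] + jitter[:, 0], 0.0, L))
        y = np.append(y, np.clip(y[idx] + jitter[:, 1],
                                 -config.width / 2.0, config.width / 2.0))
        replicating[idx] = False
        t_done[idx] = np.inf
        replicating = np.append(replicating, np.zeros(len(idx), dtype=bool))
        t_done = np.append(t_done, np.full(len(idx), np.inf))

    # new initiations
    lam0 = config.base_rate()  # per minute
    if config.rep_mode == "rnaI_feedback":
        R = len(x) * config.rnai_pool / config.k_ref
        lam = lam0 / (1.0 + R / config.rnai_half)
    else:
        lam = lam0
    p_init = lam * dt_s / 60.0
    idle = np.flatnonzero(~replicating)
    if idle.size and p_init > 0:
        fire = idle[rng.random(idle.size) < p_init]
        if fire.size:
            synth_s = config.plasmid_bp / config.fork_speed
            replicating[fire] = True
            t_done[fire] = t + synth_s
            if result is not None:
                for i in fire:
                    rel = float(x[i] / L)
                    t0 = t_abs + dt_s
                    result.initiations.append((t0, rel))
                    result.ssb_spots.append((t0, t0 + synth_s, rel))
                    result.dnan_spots.append(
                        (t0, t0 + synth_s + config.dnan_retention_s, rel))

    return SimState(t=t, cell_length=L, x=x, y=y, replicating=replicating,
                    t_done=t_done, generation=state.generation)


def divide(state: SimState, config: SimConfig,
           rng: np.random.Generator) -> tuple[SimState, SimState]:
    """Split the cell at midcell; plasmids go with their half.

    A plasmid exactly at the septum is assigned by a fair coin.  Daughter
    coordinates are re-expressed relative to the new poles; active forks
    travel with their template.  Copy counts are conserved.
    """
    mid = state.cell_length / 2.0
    left = state.x < mid
    at_septum = state.x == mid
    if np.any(at_septum):
        left = left | (at_septum & (rng.random(len(state.x)) < 0.5))

    def daughter(mask: np.ndarray, flip: bool) -> SimState:
        # left daughter keeps its pole at 0; right daughter shifts down by mid
        x = state.x[mask] - (mid if flip else 0.0)
        return SimState(
            t=0.0,
            cell_length=mid,
            x=np.clip(x, 0.0, mid),
            y=state.y[mask].copy(),
            replicating=state.replicating[mask].copy(),
            t_done=np.where(state.replicating[mask],
                            state.t_done[mask] - state.t, np.inf),
            generation=state.generation + 1,
        )

    d_left = daughter(left, flip=False)
    d_right = daughter(~left, flip=True)
    assert d_left.n_copies + d_right.n_copies == state.n_copies
    return d_left, d_right


def run(config: SimConfig, n_generations: int,
        record_trajectory: bool = False,
        record_every: int = 1) -> SimResult:
    """Simulate a lineage for n_generations, following one random daughter.

    Deterministic under ``config.seed``.  Logs birth/division copy numbers,
    loss events (a daughter left with zero copies), initiation events with
    relative positions, SSB/DnaN-type marker spots, a long-axis position
    density histogram and (optionally) the trajectory of one tracked
    plasmid.
    """
    rng = np.random.default_rng(config.seed)
    result = SimResult()
    state = initial_state(config, rng)
    tau_s = config.tau_gen * 60.0
    steps_per_gen = max(1, int(round(tau_s / config.dt)))
    t_abs = 0.0
    nbins = len(result.density_counts)
    for gen in range(n_generations):
        result.birth_copies.append(state.n_copies)
        if state.n_copies == 0:
            break
        for k in range(steps_per_gen):
            state = step(state, config, rng, result=result, t_abs=t_abs)
            t_abs += config.dt
            if k % record_every == 0:
                rel = state.x / state.cell_length
                hist, _ = np.histogram(rel, bins=nbins, range=(0.0, 1.0))
                result.density_counts += hist
                if record_trajectory and state.n_copies:
                    result.trajectory.append(
                        (t_abs, float(rel[0]), float(state.y[0]),
                         state.cell_length))
        result.division_copies.append(state.n_copies)
        d1, d2 = divide(state, config, rng)
        result.n_divisions += 1
        if d1.n_copies == 0 or d2.n_copies == 0:
            result.loss_events += 1
        state = d1 if rng.random() < 0.5 else d2
    return result


def loss_probability(n_division: int) -> float:
    """Probability a daughter inherits zero copies under Binomial(n, 1/2).

    2 * (1/2)^n: either daughter may be the empty one.  With the measured
    ~24 copies at division this is ~1.2e-7 per division, consistent with
    no observed loss over 70 generations.
    """
    if n_division < 0:
        raise ValueError("copy number must be non-negative")
    return 2.0 * 0.5**n_division


def gyration_diameter(
    plasmid_bp: float,
    calibration: list[tuple[float, float]] | None = None,
    anchor: tuple[float, float] = (11300.0, 265.0),
    exponent: float = 0.5,
) -> float:
    """Gyration diameter (nm) of a supercoiled plasmid of given size.

    With a calibration table of >= 2 (bp, diameter) points, fits the
    power law d = A * bp^nu in log-log space and evaluates it.  Without a
    table, uses the single published anchor (265 nm at 11.3 kb) with an
    assumed exponent — a configuration default, not a derived value.
    """
    if plasmid_bp <= 0:
        raise ValueError("plasmid_bp must be positive")
    if calibration is None:
        bp0, d0 = anchor
        return d0 * (plasmid_bp / bp0) ** exponent
    if len(calibration) < 2:
        raise ValueError("calibration needs at least 2 points")
    pts = np.asarray(calibration, dtype=float)
    if np.any(pts <= 0):
        raise ValueError("calibration points must be positive")
    slope, intercept = np.polyfit(np.log(pts[:, 0]), np.log(pts[:, 1]), 1)
    return float(np.exp(intercept) * plasmid_bp**slope)
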