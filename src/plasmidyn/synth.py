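"""Seeded synthetic-data generators with known ground truth.

Every input class the analysis consumes can be generated here: confined /
hop-diffusion Brownian trajectories with camera localization noise, qPCR
threshold-cycle plates, Poisson EdU spot counts, and Gaussian-spot images
for the minimal localizer.  All randomness flows from one explicit integer
seed per call; identical spec + seed gives bit-identical output.

The trajectory model is Brownian motion in a reflecting box: per-axis
Gaussian increments of variance 2*D*dt, folded specularly at the walls,
which preserves the uniform stationary distribution (long-run positional
variance box^2/12 per axis).  Hop diffusion adds partially permeable
barriers at nucleoid edges, crossed with probability p_hop per attempt.
Localization noise is added to the observed positions only; it does not
propagate into the dynamics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .copynum import QPCRPlate
from .profiles import CellGeometry
from .tracking import Trajectory

__all__ = [
    "TrajectoryGenSpec", "QPCRGenSpec", "EdUGenSpec",
    "gen_confined_trajectory", "gen_hop_trajectory", "gen_qpcr_plate",
    "gen_edu_counts", "gen_spot_image", "reflect",
]

# Default camera localization error (µm, 1 SD per axis).  A config value,
# not a measurement: typical for fluorescent-repressor spots imaged on a
# CCD, and adjustable in every generator call.
DEFAULT_LOC_NOISE_SD = 0.02


def reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Specular (fold-back) reflection of positions into [lo, hi].

    Folding the free path is exact for reflecting Brownian motion and
    handles arbitrarily large excursions in one pass.
    """
    if hi <= lo:
        raise ValueError("need hi > lo")
    span = hi - lo
    y = np.mod(np.asarray(x, dtype=float) - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


@dataclass
class TrajectoryGenSpec:
    """Parameters of a confined-diffusion trajectory.

    D in µm²/s; box_long/box_short are the confinement lengths (µm) along
    the cell's long and short axes; dt the sampling interval (s);
    loc_noise_sd the localization error SD (µm) added per observed frame.
    """

    D: float
    box_long: float
    box_short: float
    dt: float
    n_steps: int
    loc_noise_sd: float = DEFAULT_LOC_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("diffusion coefficient D must be >= 0")
        if self.box_long <= 0 or self.box_short <= 0:
            raise ValueError("box lengths must be positive")
        if self.dt <= 0:
            raise ValueError("sampling interval dt must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        if self.loc_noise_sd < 0:
            raise ValueError("loc_noise_sd must be >= 0")


def gen_confined_trajectory(spec: TrajectoryGenSpec,
                            track_id: int = 0) -> Trajectory:
    """Brownian motion in a reflecting box, observed with localization noise.

    The long axis spans [0, box_long] (pole at 0); the short axis spans
    [-box_short/2, +box_short/2] (centerline at 0).  The start position is
    drawn from the stationary (uniform) distribution.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_steps
    sd = np.sqrt(2.0 * spec.D * spec.dt)
    x0 = rng.uniform(0.0, spec.box_long)
    y0 = rng.uniform(-spec.box_short / 2.0, spec.box_short / 2.0)
    steps = rng.normal(0.0, sd, size=(n - 1, 2)) if sd > 0 else np.zeros((n - 1, 2))
    free = np.concatenate([[[x0, y0]], steps]).cumsum(axis=0)
    x = reflect(free[:, 0], 0.0, spec.box_long)
    y = reflect(free[:, 1], -spec.box_short / 2.0, spec.box_short / 2.0)
    if spec.loc_noise_sd > 0:
        x = x + rng.normal(0.0, spec.loc_noise_sd, size=n)
        y = y + rng.normal(0.0, spec.loc_noise_sd, size=n)
    times = np.arange(n) * spec.dt
    return Trajectory(track_id=track_id, times=times, x=x, y=y)


# ---------------------------------------------------------------------------
# Hop diffusion across nucleoid barriers


def hop_step(x: float, dx: float, barriers: np.ndarray, lo: float, hi: float,
             p_hop: float, rng: np.random.Generator,
             max_events: int = 100) -> float:
    """Advance one particle by dx along the long axis with barrier hopping.

    ``barriers`` is the sorted array of nucleoid-interval edges; even/odd
    index parity marks left/right edges.  Cell walls at lo/hi always
    reflect.  A sub-step crossing an edge *into* a nucleoid interval
    succeeds with probability p_hop per attempt, otherwise the remainder of
    the step is folded back at that edge; crossings *out* of a nucleoid
    interval are always free.  This one-sided rule realizes nucleoid
    exclusion as an equilibrium property: the stationary density inside the
    nucleoid is suppressed by a factor p_hop, and p_hop=1 recovers plain
    reflecting diffusion in [lo, hi].  With p_hop=0 a particle starting in
    a nucleoid-free compartment can never leave it.
    """
    target = x + dx
    pos = x
    for _ in range(max_events):
        # wall reflection first: fold the target into the cell
        if target < lo or target > hi:
            target = float(reflect(np.array([target]), lo, hi)[0])
            continue
        if p_hop >= 1.0 or barriers.size == 0:
            return target
        a, b = (pos, target) if pos <= target else (target, pos)
        crossed = barriers[(barriers > a) & (barriers < b)]
        if crossed.size == 0:
            return target
        # nearest edge in the direction of travel
        rightward = target > pos
        bar = float(crossed.min() if rightward else crossed.max())
        j = int(np.searchsorted(barriers, bar))
        entering = (j % 2 == 0) if rightward else (j % 2 == 1)
        if (not entering) or (p_hop > 0 and rng.random() < p_hop):
            pos = np.nextafter(bar, target)  # passed; continue past this edge
            continue
        target = 2.0 * bar - target  # fold the remainder back
        pos = np.nextafter(bar, target)
    return pos


def gen_hop_trajectory(
    cell: CellGeometry,
    D: float,
    p_hop: float,
    dt: float,
    n_steps: int,
    seed: int = 0,
    loc_noise_sd: float = 0.0,
    track_id: int = 0,
) -> Trajectory:
    """Hop-diffusion trajectory in a cell with nucleoid barriers.

    The nucleoid edges (from ``cell.nucleoid_intervals``) act as partially
    permeable barriers along the long axis, crossed with probability
    ``p_hop`` per attempt; the short axis is plain reflecting diffusion in
    the cell width.  The start position is uniform over the nucleoid-free
    long-axis gaps.
    """
    if not (0.0 <= p_hop <= 1.0):
        raise ValueError("p_hop must lie in [0, 1]")
    if D < 0 or dt <= 0 or n_steps < 2:
        raise ValueError("need D >= 0, dt > 0, n_steps >= 2")
    rng = np.random.default_rng(seed)
    L, w = cell.length, cell.width
    barriers = cell.barriers_um()
    free = cell.free_intervals()
    if not free:
        raise ValueError("cell has no nucleoid-free space to start in")
    # pick a free gap proportional to its length, then uniform inside it
    widths = np.array([b - a for a, b in free])
    gap = free[rng.choice(len(free), p=widths / widths.sum())]
    x = np.empty(n_steps)
    y = np.empty(n_steps)
    x[0] = rng.uniform(gap[0] * L, gap[1] * L)
    y[0] = rng.uniform(-w / 2.0, w / 2.0)
    sd = np.sqrt(2.0 * D * dt)
    dxs = rng.normal(0.0, sd, size=n_steps - 1) if sd > 0 else np.zeros(n_steps - 1)
    dys = rng.normal(0.0, sd, size=n_steps - 1) if sd > 0 else np.zeros(n_steps - 1)
    for i in range(1, n_steps):
        x[i] = hop_step(x[i - 1], dxs[i - 1], barriers, 0.0, L, p_hop, rng)
        y[i] = float(reflect(np.array([y[i - 1] + dys[i - 1]]), -w / 2.0, w / 2.0)[0])
    if loc_noise_sd > 0:
        x = x + rng.normal(0.0, loc_noise_sd, size=n_steps)
        y = y + rng.normal(0.0, loc_noise_sd, size=n_steps)
    return Trajectory(track_id=track_id, times=np.arange(n_steps) * dt,
                      x=x, y=y, cell_id=cell.cell_id)


# ---------------------------------------------------------------------------
# qPCR plates


@dataclass
class QPCRGenSpec:
    """Ground truth and noise model for a synthetic qPCR plate."""

    true_ratio: float
    eff_chr: float = 2.0
    eff_pl: float = 2.0
    ct_noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    base_ct: float = 20.0

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be positive")
        for eff, name in ((self.eff_chr, "eff_chr"), (self.eff_pl, "eff_pl")):
            if not (1.0 < eff <= 2.0):
                raise ValueError(f"{name} must be in (1, 2], got {eff}")
        if self.ct_noise_sd < 0 or self.n_replicates < 1:
            raise ValueError("need ct_noise_sd >= 0 and n_replicates >= 1")


def gen_qpcr_plate(spec: QPCRGenSpec) -> QPCRPlate:
    """Synthesize Ct values for sample and calibrator wells.

    The calibrator carries equal chromosome and plasmid copies at the base
    Ct; the sample chromosome matches the calibrator and the sample plasmid
    comes up log_eff(true_ratio) cycles earlier.  Gaussian cycle noise is
    added per well.
    """
    rng = np.random.default_rng(spec.seed)
    clean = {
        "cal_chr": spec.base_ct,
        "cal_pl": spec.base_ct,
        "chr": spec.base_ct,
        "pl": spec.base_ct - np.log(spec.true_ratio) / np.log(spec.eff_pl),
    }
    wells = []
    for target, ct0 in clean.items():
        for i in range(spec.n_replicates):
            ct = ct0 + (rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0)
            wells.append((f"{target}_{i + 1}", target, float(ct)))
    return QPCRPlate(wells=wells, eff_chr=spec.eff_chr, eff_pl=spec.eff_pl)


# ---------------------------------------------------------------------------
# EdU spot counts


@dataclass
class EdUGenSpec:
    """Poisson model of per-cell replication-spot counts in a labelling window."""

    rate_per_min: float
    window_min: float
    n_cells: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_per_min < 0 or self.window_min < 0:
            raise ValueError("rate and window must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def gen_edu_counts(spec: EdUGenSpec) -> pd.DataFrame:
    """Per-cell spot counts ~ Poisson(rate * window); columns cell_id, n_spots."""
    rng = np.random.default_rng(spec.seed)
    lam = spec.rate_per_min * spec.window_min
    counts = rng.poisson(lam, size=spec.n_cells)
    return pd.DataFrame({"cell_id": np.arange(spec.n_cells), "n_spots": counts})


# ---------------------------------------------------------------------------
# Spot images (plumbing for the minimal localizer)


def gen_spot_image(
    positions: np.ndarray,
    amplitude: float = 1000.0,
    psf_sd: float = 1.5,
    noise_sd: float = 10.0,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    background: float = 100.0,
) -> np.ndarray:
    """Sum of Gaussian spots on a noisy background; deterministic under seed.

    ``positions`` is an (n, 2) array of (row, col) pixel coordinates inside
    the image.  Returns a float image; cast to uint16 when writing TIFF.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    if positions.size and (
        positions.min() < 0
        or positions[:, 0].max() >= shape[0]
        or positions[:, 1].max() >= shape[1]
    ):
        raise ValueError("spot positions must lie inside the image")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, background, dtype=float)
    for r0, c0 in positions:
        img += amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * psf_sd**2)
        )
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    return img
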