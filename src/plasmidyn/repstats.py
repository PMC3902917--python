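"""Replication-event statistics: initiation intervals, replisome-marker
lifetimes, and the Poisson model of EdU pulse-labelling.

With n plasmids at birth replicating once per generation on average, a new
initiation is expected every tau_gen / n minutes.  A replisome marker spot
lasts for the synthesis time plasmid_bp / fork_speed plus any
post-synthesis retention of the marker (the beta sliding clamp stays on
DNA for minutes after the fork finishes; SSB leaves with the fork).

EdU pulse labelling counts replication events per cell in a window t: if
events are independent per plasmid, counts are Poisson with rate t / t1
where t1 is the labelling time giving one spot per cell on average, and
the count ratios obey P(1)/P(2) = 2/lambda, P(1)/P(3) = 6/lambda^2.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def expected_interinitiation(tau_gen: float, n_birth: float) -> float:
    """Expected minutes between replication events: tau_gen / n_birth."""
    if tau_gen <= 0 or n_birth <= 0:
        raise ValueError("tau_gen and n_birth must be positive")
    return tau_gen / n_birth


@dataclass
class SpotEvent:
    """One replisome-marker spot: appearance/disappearance times and position."""

    cell_id: int
    t_start: float
    t_end: float
    rel_pos: float
    marker: str = "DnaN"

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")
        if not (0.0 <= self.rel_pos <= 1.0):
            raise ValueError("rel_pos must lie in [0, 1]")


def interval_by_length(
    events: list[SpotEvent],
    lengths: dict[int, float],
    bins: np.ndarray,
) -> pd.Series:
    """Mean inter-event time per cell-length bin.

    Intervals are differences between consecutive event *start* times within
    one cell (spot lifetime does not enter).  Cells contribute only with two
    or more events.  Bins with no intervals are reported as NaN, not zero.
    """
    bins = np.asarray(bins, dtype=float)
    by_cell: dict[int, list[float]] = {}
    for ev in events:
        by_cell.setdefault(ev.cell_id, []).append(ev.t_start)
    rows = []
    for cid, starts in by_cell.items():
        if len(starts) < 2 or cid not in lengths:
            continue
        ivals = np.diff(np.sort(starts))
        rows.extend((lengths[cid], iv) for iv in ivals)
    labels = pd.IntervalIndex.from_breaks(bins)
    if not rows:
        return pd.Series(np.nan, index=labels, name="mean_interval")
    df = pd.DataFrame(rows, columns=["length", "interval"])
    cats = pd.cut(df["length"], bins=bins)
    out = df.groupby(cats, observed=False)["interval"].mean()
    out.name = "mean_interval"
    return out


@dataclass
class ReplisomeModel:
    """Marker-lifetime model: synthesis time plus post-synthesis retention."""

    plasmid_bp: float
    fork_speed: float
    retention_s: float = 0.0

    def __post_init__(self) -> None:
        if self.plasmid_bp < 0 or self.retention_s < 0:
            raise ValueError("plasmid_bp and retention_s must be non-negative")
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be positive")


def marker_lifetime(model: ReplisomeModel) -> float:
    """Expected spot lifetime in seconds: plasmid_bp/fork_speed + retention."""
    return model.plasmid_bp / model.fork_speed + model.retention_s


@dataclass
class EdUModel:
    """Per-cell replication-event accumulation rate under EdU labelling."""

    rate_per_min: float

    def __post_init__(self) -> None:
        if self.rate_per_min <= 0:
            raise ValueError("rate_per_min must be positive")

    @property
    def t1_min(self) -> float:
        """Labelling time giving one spot per cell on average."""
        return 1.0 / self.rate_per_min


def edu_calibrate(table: pd.DataFrame) -> EdUModel:
    """Calibrate the spot-accumulation rate from mean spots vs labelling time.

    ``table`` needs columns time_min and mean_spots.  The rate is the
    least-squares slope through the origin, slope = sum(t*y)/sum(t^2); a
    single time point is sufficient.
    """
    if not {"time_min", "mean_spots"}.issubset(table.columns):
        raise ValueError("table must have columns 'time_min' and 'mean_spots'")
    t = table["time_min"].to_numpy(dtype=float)
    y = table["mean_spots"].to_numpy(dtype=float)
    if len(t) < 1:
        raise ValueError("need at least one time point")
    if np.any(t <= 0):
        raise ValueError("labelling times must be positive")
    slope = float(np.sum(t * y) / np.sum(t * t))
    if slope <= 0:
        raise ValueError("non-positive slope; counts do not accumulate")
    return EdUModel(rate_per_min=slope)


@dataclass
class EdUPrediction:
    """Poisson count distribution for one labelling window."""

    lam: float
    pmf: np.ndarray

    @property
    def r12(self) -> float:
        """P(1 event)/P(2 events) = 2/lambda."""
        return 2.0 / self.lam

    @property
    def r13(self) -> float:
        """P(1 event)/P(3 events) = 6/lambda^2."""
        return 6.0 / self.lam**2


def edu_predict_pmf(model: EdUModel, window_min: float,
                    max_count: int | None = None) -> EdUPrediction:
    """Poisson pmf of spot counts after a labelling window.

    lambda = window / t1.  The pmf is truncated at ``max_count`` (default:
    far into the tail so the truncated mass is < 1e-12) and reports exact
    Poisson probabilities, not renormalized ones.
    """
    if window_min < 0:
        raise ValueError("window must be non-negative")
    lam = window_min / model.t1_min
    if max_count is None:
        max_count = max(20, int(lam + 12.0 * np.sqrt(lam + 1.0)))
    pmf = stats.poisson.pmf(np.arange(max_count + 1), lam)
    return EdUPrediction(lam=lam, pmf=pmf)


def edu_gof(counts: np.ndarray, model: EdUModel,
            window_min: float) -> tuple[float, float]:
    """Chi-square goodness of fit of per-cell counts to the Poisson model.

    Counts are binned {0, 1, 2, >=3}; the rate is fixed by the external
    calibration, so no parameter is estimated from the data and the
    statistic has 3 degrees of freedom.  Returns (statistic, p-value).
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("no counts supplied")
    if counts.size < 20:
        raise ValueError("need at least 20 cells for the chi-square test")
    lam = window_min / model.t1_min
    edges = [0, 1, 2]
    probs = stats.poisson.pmf(edges, lam)
    probs = np.append(probs, 1.0 - probs.sum())  # tail >=3
    observed = np.array([
        np.sum(counts == 0), np.sum(counts == 1), np.sum(counts == 2),
        np.sum(counts >= 3),
    ], dtype=float)
    expected = probs * counts.size
    stat = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(stat, df=len(observed) - 1))
    return stat, p
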