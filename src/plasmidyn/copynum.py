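"""Plasmid copy-number quantification and the cell-cycle copy-number model.

Relative qPCR compares the plasmid amplicon with a chromosomal amplicon
near oriC: with per-cycle efficiencies E the copy ratio is
E_pl^(dCt_pl) / E_chr^(dCt_chr), each dCt taken against a calibrator of
known composition.  Multiplying by the mean number of oriC per cell in an
exponential culture, 2^((C+D)/tau), converts the ratio into plasmids per
cell.

Within the cell cycle the copy number of an exponentially amplifying
replicon is p(x) = m * 2^x with cell-cycle stage x in [0, 1].  Averaging
over the steady-state age distribution of an exponential culture,
f(x) = 2 ln2 * 2^(-x), fixes m = k / (2 ln 2) where k is the population-
average copy number: k = 17 plasmids/cell then implies ~12 copies at birth
and ~24 at division.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

LN2 = math.log(2.0)

TARGETS = ("chr", "pl", "cal_chr", "cal_pl")


@dataclass
class QPCRPlate:
    """Threshold-cycle values for sample and calibrator wells.

    ``wells`` holds (well, target, ct) tuples with target in
    {chr, pl, cal_chr, cal_pl}; efficiencies are fold-amplification per
    cycle, in (1, 2].
    """

    wells: list[tuple[str, str, float]]
    eff_chr: float = 2.0
    eff_pl: float = 2.0

    def __post_init__(self) -> None:
        for eff, name in ((self.eff_chr, "eff_chr"), (self.eff_pl, "eff_pl")):
            if not (1.0 < eff <= 2.0):
                raise ValueError(f"{name} must be in (1, 2], got {eff}")
        for w in self.wells:
            if w[1] not in TARGETS:
                raise ValueError(f"unknown target {w[1]!r} in well {w[0]!r}")

    def mean_ct(self, target: str) -> float:
        cts = [ct for _, tgt, ct in self.wells if tgt == target]
        if not cts:
            raise ValueError(f"plate has no wells for target {target!r}")
        return float(np.mean(cts))


def qpcr_ratio(plate: QPCRPlate, calibrator_ratio: float = 1.0) -> float:
    """Plasmid:oriC copy ratio by efficiency-corrected relative quantification.

    ratio = E_pl^(Ct_cal_pl - Ct_pl) / E_chr^(Ct_cal_chr - Ct_chr)
            * calibrator_ratio

    using the mean Ct per target class.
    """
    if calibrator_ratio <= 0:
        raise ValueError("calibrator_ratio must be positive")
    d_pl = plate.mean_ct("cal_pl") - plate.mean_ct("pl")
    d_chr = plate.mean_ct("cal_chr") - plate.mean_ct("chr")
    return plate.eff_pl**d_pl / plate.eff_chr**d_chr * calibrator_ratio


def plasmids_per_cell(ratio: float, oric_avg: float) -> float:
    """Plasmids per cell from the plasmid:oriC ratio and mean oriC per cell."""
    if ratio <= 0 or oric_avg <= 0:
        raise ValueError("ratio and oric_avg must be positive")
    return ratio * oric_avg


@dataclass
class CellCycleParams:
    """Generation time and chromosome C (replication) / D (division) periods, minutes."""

    tau_gen: float
    C: float
    D: float

    def __post_init__(self) -> None:
        if self.tau_gen <= 0 or self.C < 0 or self.D < 0:
            raise ValueError("tau_gen must be positive; C, D non-negative")


def oric_average(params: CellCycleParams) -> float:
    """Mean oriC per cell in an exponential culture: 2^((C+D)/tau_gen)."""
    return 2.0 ** ((params.C + params.D) / params.tau_gen)


@dataclass
class CopyNumberModel:
    """Cell-cycle copy-number model p(x) = (k / (2 ln 2)) * 2^x."""

    k: float
    tau_gen: float = 100.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("population-average copy number k must be positive")
        if self.tau_gen <= 0:
            raise ValueError("tau_gen must be positive")

    @property
    def p0(self) -> float:
        """Copies in a newborn cell (x = 0)."""
        return self.k / (2.0 * LN2)


def cycle_copy_number(model: CopyNumberModel, x: float | np.ndarray) -> float | np.ndarray:
    """Copies per cell at cell-cycle stage x in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("cell-cycle stage x must lie in [0, 1]")
    out = model.p0 * 2.0**x
    return float(out) if out.ndim == 0 else out


def population_average(p0: float) -> float:
    """Population-average copies k = p0 * 2 ln 2.

    Inverse of the closure: the mean of p0 * 2^x under the steady-state age
    density 2 ln2 * 2^(-x) on [0, 1] is exactly p0 * 2 ln 2.
    """
    if p0 <= 0:
        raise ValueError("p0 must be positive")
    return p0 * 2.0 * LN2
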