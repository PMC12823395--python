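"""Amide I secondary-structure band dictionary and second-derivative peaks.

Literature band ranges for the amide I region overlap (turns overlap both
the alpha-helix and high-frequency beta-sheet windows); assignments keep
every containing label rather than forcing a partition.  Peaks are local
minima of the second derivative, since absorption maxima invert under
double differentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ParameterError, StageError
from .io import Spectrum

__all__ = [
    "BandRange",
    "PeakAssignment",
    "default_band_table",
    "detect_peaks",
    "spectral_deviation",
]


@dataclass(frozen=True)
class BandRange:
    """A labeled wavenumber window [lo, hi] in cm^-1."""

    label: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ParameterError("band range needs lo < hi")

    def __contains__(self, wavenumber: float) -> bool:
        return self.lo <= wavenumber <= self.hi


@dataclass(frozen=True)
class PeakAssignment:
    """A detected peak with all band labels whose range contains it."""

    peak: float            # cm^-1, sub-grid position
    labels: tuple
    prominence: float


def default_band_table() -> list[BandRange]:
    """Standard amide I assignment windows.

    Alpha-helix 1,642-1,660; beta-sheet low 1,615-1,638 and high
    1,672-1,694; turns 1,653-1,691; plus the narrow intermolecular
    beta-sheet aggregation marker around 1,620 cm^-1.
    """
    return [
        BandRange("alpha-helix", 1642.0, 1660.0),
        BandRange("beta-sheet(low)", 1615.0, 1638.0),
        BandRange("beta-sheet(high)", 1672.0, 1694.0),
        BandRange("turns", 1653.0, 1691.0),
        BandRange("intermolecular beta-sheet marker", 1615.0, 1625.0),
    ]


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid extremum position via a parabola through 3 points."""
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return float(x[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    return float(x[i] + shift * (x[1] - x[0]))


def detect_peaks(second_deriv: Spectrum, min_prominence: float = 0.0,
                 band_table: list[BandRange] | None = None
                 ) -> list[PeakAssignment]:
    """Find absorption peaks as local minima of a second-derivative spectrum.

    Positions are refined by parabolic interpolation; each peak carries all
    band labels whose range contains it.  An empty list is a valid result.
    """
    if second_deriv.stage != "second_derivative":
        raise StageError(
            f"expected a second_derivative spectrum, got {second_deriv.stage!r}"
        )
    table = band_table if band_table is not None else default_band_table()
    y = -second_deriv.intensity  # minima -> maxima
    idx, props = signal.find_peaks(y, prominence=min_prominence or None)
    out = []
    proms = props.get("prominences",
                      np.zeros(len(idx)) if min_prominence == 0 else None)
    if proms is None or len(proms) != len(idx):
        proms = signal.peak_prominences(y, idx)[0]
    for i, prom in zip(idx, proms):
        pos = _parabolic_refine(second_deriv.grid.values, y, int(i))
        pos = float(np.clip(pos, second_deriv.grid.lo, second_deriv.grid.hi))
        labels = tuple(b.label for b in table if pos in b)
        out.append(PeakAssignment(pos, labels, float(prom)))
    return out


def spectral_deviation(peaks_per_cell: list[list[PeakAssignment]]
                       ) -> tuple[float, dict]:
    """Maximum spread of matched peak positions across cells.

    For each label seen in at least two cells, takes max - min of the peak
    positions assigned to that label (nearest peak per cell); returns the
    maximum over labels and the per-label spreads.  Labels present in fewer
    than two cells are skipped with a warning.
    """
    if len(peaks_per_cell) < 2:
        raise ParameterError("need peaks from at least two cells")
    positions: dict[str, list[float]] = {}
    for peaks in peaks_per_cell:
        per_label: dict[str, float] = {}
        for pk in sorted(peaks, key=lambda p: -p.prominence):
            for label in pk.labels:
                # keep the most prominent peak per label per cell
                if label not in per_label:
                    per_label[label] = pk.peak
        for label, pos in per_label.items():
            positions.setdefault(label, []).append(pos)
    spreads = {}
    for label, vals in positions.items():
        if len(vals) < 2:
            warnings.warn(f"label {label!r} matched in only one cell; skipped",
                          stacklevel=2)
            continue
        spreads[label] = float(max(vals) - min(vals))
    if not spreads:
        raise ParameterError("no label matched in two or more cells")
    return max(spreads.values()), spreads
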