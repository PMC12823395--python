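"""Spectral conditioning: reference division, Savitzky-Golay smoothing and
second derivatives, baseline correction, 0-1 normalization, and the
single-scale least-squares medium fit.

Default conditioning order for absorption spectra is

    divide_reference (optional) -> savgol(19, 5) -> baseline -> minmax

Second derivatives are taken with respect to wavenumber (cm^-1), so their
units are per cm^-2; absorption maxima appear as second-derivative minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .errors import ParameterError, StageError
from .io import Spectrum, SpectralDataset, WavenumberGrid

__all__ = [
    "SavGolParams",
    "MediumFit",
    "PreprocessConfig",
    "divide_reference",
    "savgol",
    "second_derivative",
    "baseline_correct",
    "minmax_normalize",
    "fit_medium",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class SavGolParams:
    """Savitzky-Golay filter parameters (window in grid points)."""

    window: int = 19
    polyorder: int = 5
    deriv: int = 0

    def __post_init__(self):
        if self.window % 2 == 0 or self.window < 3:
            raise ParameterError("window must be an odd integer >= 3")
        if self.polyorder < 0 or self.polyorder >= self.window:
            raise ParameterError("need 0 <= polyorder < window")
        if self.deriv not in (0, 2):
            raise ParameterError("deriv must be 0 or 2")


@dataclass
class MediumFit:
    """Scale-only least-squares fit of a medium spectrum to a cell spectrum."""

    scale: float
    residual: Spectrum


def _require_same_grid(a: Spectrum, b: Spectrum):
    if a.grid != b.grid:
        raise StageError("spectra are on different grids")


def divide_reference(spectrum: Spectrum, reference: Spectrum) -> Spectrum:
    """Pointwise division by a strictly positive reference/buffer spectrum."""
    _require_same_grid(spectrum, reference)
    if np.any(reference.intensity <= 0):
        raise StageError("reference spectrum must be strictly positive")
    out = spectrum.copy()
    out.intensity = spectrum.intensity / reference.intensity
    out.meta["referenced"] = True
    return out


def savgol(spectrum: Spectrum, params: SavGolParams = SavGolParams()
           ) -> Spectrum:
    """Savitzky-Golay smoothing (deriv 0) or second derivative (deriv 2).

    Edges are handled by a polynomial fit over the truncated window, so a
    polynomial of degree <= polyorder is reproduced exactly everywhere.
    """
    if params.window > len(spectrum.grid):
        raise ParameterError("window longer than the spectrum")
    out = signal.savgol_filter(
        spectrum.intensity, params.window, params.polyorder,
        deriv=params.deriv, delta=spectrum.grid.step, mode="interp",
    )
    stage = "second_derivative" if params.deriv == 2 else "smoothed"
    result = spectrum.copy(stage=stage)
    result.intensity = out
    return result


def second_derivative(spectrum: Spectrum, window: int = 9, polyorder: int = 3,
                      upsample: int = 1) -> Spectrum:
    """Second derivative vs wavenumber, optionally on a spline-upsampled grid.

    ``upsample`` > 1 first resamples by cubic spline onto a grid refined by
    that factor, then differentiates there (window measured on the fine
    grid).  Units of the output are input units per cm^-2.
    """
    if upsample < 1:
        raise ParameterError("upsample must be >= 1")
    spec = spectrum
    if upsample > 1:
        fine = np.linspace(spec.grid.lo, spec.grid.hi,
                           (len(spec.grid) - 1) * upsample + 1)
        spline = CubicSpline(spec.grid.values, spec.intensity)
        spec = Spectrum(WavenumberGrid(fine), spline(fine),
                        stage=spec.stage, meta=dict(spec.meta))
    return savgol(spec, SavGolParams(window, polyorder, deriv=2))


def baseline_correct(spectrum: Spectrum, n_anchor: int = 3) -> Spectrum:
    """Subtract the straight line through the means of the ``n_anchor``
    lowest- and highest-wavenumber points.

    Exactly-linear spectra map to zero and the operation is idempotent.
    """
    grid = spectrum.grid.values
    if len(grid) < 2 * n_anchor:
        raise ParameterError("spectrum too short for baseline anchors")
    y = spectrum.intensity
    x_lo, y_lo = grid[:n_anchor].mean(), y[:n_anchor].mean()
    x_hi, y_hi = grid[-n_anchor:].mean(), y[-n_anchor:].mean()
    slope = (y_hi - y_lo) / (x_hi - x_lo)
    baseline = y_lo + slope * (grid - x_lo)
    out = spectrum.copy(stage="baselined")
    out.intensity = y - baseline
    return out


def minmax_normalize(spectrum: Spectrum) -> Spectrum:
    """Affine rescale to min 0 / max 1 (idempotent, affine-invariant)."""
    lo, hi = spectrum.intensity.min(), spectrum.intensity.max()
    # numerically constant spectra (e.g. float dust after baselining a
    # constant trace) cannot be meaningfully rescaled either
    if hi - lo <= 1e-12 * max(abs(hi), abs(lo), 1.0):
        raise StageError("constant spectrum cannot be min-max normalized")
    out = spectrum.copy(stage="normalized")
    out.intensity = (spectrum.intensity - lo) / (hi - lo)
    return out


def fit_medium(spectrum: Spectrum, medium: Spectrum) -> MediumFit:
    """Closed-form scale c = sum(s*m)/sum(m*m) and residual s - c*m."""
    _require_same_grid(spectrum, medium)
    mm = float(np.dot(medium.intensity, medium.intensity))
    if mm == 0.0:
        raise StageError("medium spectrum is identically zero")
    c = float(np.dot(spectrum.intensity, medium.intensity)) / mm
    residual = spectrum.copy()
    residual.intensity = spectrum.intensity - c * medium.intensity
    residual.meta["medium_scale"] = c
    return MediumFit(scale=c, residual=residual)


@dataclass
class PreprocessConfig:
    """Stage selection and parameters for :func:`preprocess_pipeline`."""

    stages: tuple = ("reference", "savgol", "baseline", "normalize")
    savgol: SavGolParams = field(default_factory=SavGolParams)
    reference: Spectrum | None = None  # falls back to dataset.medium

    _KNOWN = frozenset({"reference", "savgol", "baseline", "normalize"})

    def __post_init__(self):
        unknown = set(self.stages) - self._KNOWN
        if unknown:
            raise ParameterError(f"unknown pipeline stages: {sorted(unknown)}")


def preprocess_pipeline(dataset: SpectralDataset,
                        config: PreprocessConfig | None = None
                        ) -> SpectralDataset:
    """Apply the configured conditioning stages to every record.

    Records that fail a stage (e.g. a constant spectrum at normalization)
    are kept with ``meta['failed']`` set to the error message; the others
    are processed normally.  A ``meta['stages']`` log lists what ran.
    The dataset medium, when present, is conditioned the same way (without
    reference division against itself).
    """
    config = config or PreprocessConfig()
    # reference division runs only when an independently measured buffer
    # spectrum is supplied; the cell-medium spectrum is kept for the medium
    # fit, not used as a division reference
    reference = config.reference

    def run(spec: Spectrum, allow_reference: bool) -> Spectrum:
        log = []
        for stage in config.stages:
            if stage == "reference":
                if reference is None or not allow_reference:
                    continue
                spec = divide_reference(spec, reference)
            elif stage == "savgol":
                spec = savgol(spec, config.savgol)
            elif stage == "baseline":
                spec = baseline_correct(spec)
            elif stage == "normalize":
                spec = minmax_normalize(spec)
            log.append(stage)
        spec.meta["stages"] = log
        return spec

    new_records = []
    for rec in dataset.records:
        try:
            spec = run(rec.spectrum, allow_reference=True)
        except (StageError, ParameterError) as exc:
            spec = rec.spectrum.copy()
            spec.meta["failed"] = f"{rec.cell_id}: {exc}"
        new_records.append(
            type(rec)(rec.cell_id, rec.arm, rec.time_h, spec, rec.position))
    medium = dataset.medium
    if medium is not None and config.stages:
        try:
            medium = run(medium, allow_reference=False)
        except (StageError, ParameterError):
            medium = dataset.medium
    return SpectralDataset(new_records, dataset.grid, medium=medium)
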