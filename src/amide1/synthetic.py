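"""Synthetic amide I cohorts and micrographs with planted ground truth.

The generator emulates the statistical structure of live-cell amide I
(1,700-1,600 cm^-1) optoacoustic spectra measured in D2O medium during
proteasome-inhibitor treatment:

* a dominant cell-medium band near 1,646 cm^-1;
* alpha-helix content (bands at 1,650/1,656 cm^-1) that slowly decays
  during treatment-induced unfolding;
* a turn/helix feature at 1,666 cm^-1 that decays with H->D exchange;
* a smooth laser-emission-profile nuisance component;
* in treatment-responding cells, growth of the intermolecular beta-sheet
  doublet -- a strong band at 1,620 cm^-1 paired with a weaker one at
  1,682 cm^-1 -- which is the spectroscopic hallmark of misfolded-protein
  aggregation and the biomarker the response classifier reads out;
* i.i.d. additive measurement noise.

Micrographs are disk-shaped cells of constant amplitude over a noisy
background, supporting the CNR/NOA image metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, PlacementError
from .io import (CellRecord, Micrograph, Spectrum, SpectralDataset,
                 WavenumberGrid, canonical_grid)

__all__ = [
    "BandSpec",
    "CohortDesign",
    "GroundTruth",
    "make_band",
    "planted_components",
    "simulate_cell_spectrum",
    "simulate_cohort",
    "simulate_micrograph",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class BandSpec:
    """One spectral band: center/width in cm^-1, unit-free amplitude."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"  # gaussian | lorentzian | pseudo_voigt
    eta: float = 0.5  # Lorentzian fraction for pseudo_voigt

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ParameterError("fwhm must be positive")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ParameterError("pseudo-Voigt eta must be in [0, 1]")
        if self.shape not in {"gaussian", "lorentzian", "pseudo_voigt"}:
            raise ParameterError(f"unknown line shape {self.shape!r}")


def _profile(shape: str, eta: float, delta: np.ndarray, fwhm: float
             ) -> np.ndarray:
    """Unit-peak line profile as a function of distance from center."""
    gauss = np.exp(-0.5 * (delta / (fwhm / _FWHM_TO_SIGMA)) ** 2)
    lorentz = 1.0 / (1.0 + (2.0 * delta / fwhm) ** 2)
    if shape == "gaussian":
        return gauss
    if shape == "lorentzian":
        return lorentz
    return eta * lorentz + (1.0 - eta) * gauss


def make_band(band: BandSpec, grid: WavenumberGrid) -> Spectrum:
    """Evaluate a band on a grid; the grid point nearest the center takes
    the value ``band.amplitude`` exactly."""
    if not (grid.lo - 50.0 <= band.center <= grid.hi + 50.0):
        raise ParameterError(
            f"band center {band.center} cm^-1 too far outside grid "
            f"[{grid.lo}, {grid.hi}]"
        )
    if band.amplitude == 0.0:
        return Spectrum(grid, np.zeros(len(grid)), stage="raw")
    delta = grid.values - band.center
    prof = _profile(band.shape, band.eta, delta, band.fwhm)
    nearest = prof[np.argmin(np.abs(delta))]
    return Spectrum(grid, band.amplitude * prof / nearest, stage="raw")


@dataclass
class CohortDesign:
    """Study design for a synthetic two-arm treatment cohort.

    Amplitudes are on the scale of the (unit-amplitude) medium band.
    Rates are per hour; decays act multiplicatively as exp(-rate * t).
    """

    n_cells: int = 50                       # per arm
    time_points_h: tuple = (0.0, 72.0, 78.0, 96.0)
    responder_fraction: float = 0.64
    beta_growth: float = 0.0028             # 1,620-band amplitude gain /h
    beta_base: float = 0.10                 # basal beta-sheet amplitude
    beta_ratio: float = 0.35                # 1,682 : 1,620 amplitude ratio
    alpha_decay: float = 0.01               # 1,650/1,656 decay rate /h
    hd_drift: float = 0.01                  # 1,666 decay rate /h (shared
                                            # unfolding/H->D-exchange rate)
    medium_amp: float = 1.0                 # medium band at background points
    cell_medium_frac: float = 0.5           # medium partial volume at a cell
    alpha_amp: float = 0.70                 # alpha-helix amplitude in cells
    turn_amp: float = 0.30                  # turn-band amplitude in cells
    laser_amp: float = 0.15
    amplitude_jitter: float = 0.10          # relative lognormal sd per cell
    noise_sd: float = 0.01                  # additive noise sd (of medium peak)
    n_medium_spectra: int = 40              # pure-medium measurement points
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ParameterError("responder_fraction must be in [0, 1]")
        if not 0.0 <= self.cell_medium_frac <= 1.0:
            raise ParameterError("cell_medium_frac must be in [0, 1]")
        for name in ("beta_growth", "beta_base", "medium_amp", "laser_amp",
                     "alpha_amp", "turn_amp", "noise_sd", "amplitude_jitter"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth for a simulated cohort."""

    responder: dict              # cell_id -> bool
    beta_amplitude: dict         # (cell_id, time_h) -> planted 1,620 amplitude
    components: dict = field(default_factory=dict)  # name -> np.ndarray


_COMPONENT_NAMES = ("medium", "beta_sheet", "laser", "alpha_helix", "turn")


def planted_components(grid: WavenumberGrid | None = None,
                       beta_ratio: float = 0.35) -> dict:
    """The five planted unit-scale component spectra, keyed by name.

    ``beta_sheet`` is the intermolecular doublet: unit band at 1,620 plus
    ``beta_ratio`` times a weaker band at 1,682 cm^-1.
    """
    grid = grid or canonical_grid()

    def bands(specs):
        out = np.zeros(len(grid))
        for spec in specs:
            out += make_band(spec, grid).intensity
        return out

    x = (grid.values - (grid.lo + grid.hi) / 2.0) / ((grid.hi - grid.lo) / 2.0)
    laser = 0.8 + 0.25 * x - 0.2 * x ** 2 + 0.1 * x ** 3
    laser /= laser.max()
    return {
        "medium": bands([BandSpec(1646.0, 45.0, 1.0)]),
        "beta_sheet": bands([BandSpec(1620.0, 14.0, 1.0),
                             BandSpec(1682.0, 12.0, beta_ratio)]),
        "laser": laser,
        "alpha_helix": bands([BandSpec(1650.0, 18.0, 1.0),
                              BandSpec(1656.0, 16.0, 0.6)]),
        "turn": bands([BandSpec(1666.0, 18.0, 1.0)]),
    }


def _component_amplitudes(design: CohortDesign, rng: np.random.Generator
                          ) -> dict:
    """Per-cell base amplitudes with lognormal jitter (mean-one)."""
    jit = design.amplitude_jitter
    sigma = np.sqrt(np.log(1.0 + jit ** 2)) if jit > 0 else 0.0

    def draw():
        return float(np.exp(rng.normal(-0.5 * sigma ** 2, sigma))) if jit > 0 \
            else 1.0

    return {
        "medium": design.medium_amp * draw(),
        "laser": design.laser_amp * draw(),
        "alpha_helix": design.alpha_amp * draw(),
        "turn": design.turn_amp * draw(),
        "beta_base": design.beta_base * draw(),
        "beta_gain": draw(),
    }


def _evaluate_cell(components: dict, amps: dict, design: CohortDesign,
                   responder: bool, time_h: float,
                   rng: np.random.Generator,
                   treated: bool = True) -> tuple[np.ndarray, float]:
    beta_amp = amps["beta_base"]
    if responder:
        beta_amp += design.beta_growth * time_h * amps["beta_gain"]
    # treatment dynamics (alpha-helix loss, exchange-enhanced turn decay)
    # act on the treated arm; untreated cells are spectrally stationary
    t_dyn = time_h if treated else 0.0
    intensity = (
        design.cell_medium_frac * amps["medium"] * components["medium"]
        + amps["laser"] * components["laser"]
        + amps["alpha_helix"] * np.exp(-design.alpha_decay * t_dyn)
        * components["alpha_helix"]
        + amps["turn"] * np.exp(-design.hd_drift * t_dyn)
        * components["turn"]
        + beta_amp * components["beta_sheet"]
    )
    if design.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, design.noise_sd,
                                           size=intensity.shape)
    n_clipped = int(np.sum(intensity < 0))
    if n_clipped:
        intensity = np.clip(intensity, 0.0, None)
        if n_clipped > 0.05 * intensity.size:
            warnings.warn(
                f"{n_clipped}/{intensity.size} intensities clipped at 0",
                stacklevel=3,
            )
    return intensity, beta_amp


def simulate_cell_spectrum(design: CohortDesign, responder: bool,
                           time_h: float, rng: np.random.Generator,
                           treated: bool = True) -> Spectrum:
    """One cell spectrum at one time point (strictly reproducible per rng).

    The spectrum is the planted component mixture of :func:`planted_components`
    with the design's treatment dynamics applied (``treated=False`` disables
    them, as in the untreated arm), plus i.i.d. Gaussian noise.
    """
    grid = canonical_grid()
    components = planted_components(grid, design.beta_ratio)
    amps = _component_amplitudes(design, rng)
    intensity, beta_amp = _evaluate_cell(components, amps, design, responder,
                                         time_h, rng, treated=treated)
    return Spectrum(grid, intensity, stage="raw",
                    meta={"responder": responder, "time_h": time_h,
                          "beta_amplitude": beta_amp})


def simulate_cohort(design: CohortDesign
                    ) -> tuple[SpectralDataset, GroundTruth]:
    """Simulate a two-arm cohort; treated cells include ``floor(p * n)``
    responders (flags recorded in the ground truth); the untreated arm has
    responder dynamics disabled.  A noise-free medium reference spectrum is
    attached to the dataset."""
    if design.n_cells <= 0:
        raise ParameterError("n_cells must be >= 1")
    if not design.time_points_h:
        raise ParameterError("at least one time point required")
    grid = canonical_grid()
    components = planted_components(grid, design.beta_ratio)
    n_resp = int(np.floor(design.responder_fraction * design.n_cells))
    root = np.random.default_rng(design.seed)
    # one child stream per (arm, cell) plus one for the medium points, so
    # records are individually stable
    streams = root.spawn(2 * design.n_cells + 1)

    records: list[CellRecord] = []
    truth = GroundTruth(responder={}, beta_amplitude={},
                        components={k: v.copy()
                                    for k, v in components.items()})
    for ai, arm in enumerate(("treated", "untreated")):
        for ci in range(design.n_cells):
            cell_id = f"{'T' if arm == 'treated' else 'U'}{ci:03d}"
            rng = streams[ai * design.n_cells + ci]
            responder = arm == "treated" and ci < n_resp
            truth.responder[cell_id] = responder
            amps = _component_amplitudes(design, rng)
            for time_h in design.time_points_h:
                intensity, beta_amp = _evaluate_cell(
                    components, amps, design, responder, float(time_h), rng,
                    treated=arm == "treated")
                truth.beta_amplitude[(cell_id, float(time_h))] = beta_amp
                records.append(CellRecord(
                    cell_id, arm, float(time_h),
                    Spectrum(grid, intensity, stage="raw",
                             meta={"responder": responder}),
                ))
    # pure-medium measurement points (background positions in the dish);
    # they anchor the medium and laser-profile components in the unmixing
    rng_m = streams[-1]
    for mi in range(design.n_medium_spectra):
        amps = _component_amplitudes(design, rng_m)
        intensity = (amps["medium"] * components["medium"]
                     + amps["laser"] * components["laser"])
        if design.noise_sd > 0:
            intensity = intensity + rng_m.normal(0.0, design.noise_sd,
                                                 size=intensity.shape)
        records.append(CellRecord(
            f"M{mi:03d}", "medium", float(design.time_points_h[0]),
            Spectrum(grid, np.clip(intensity, 0.0, None), stage="raw",
                     meta={"role": "medium_point"})))
    medium = Spectrum(grid, design.medium_amp * components["medium"],
                      stage="raw", meta={"role": "medium"})
    return SpectralDataset(records, grid, medium=medium), truth


def simulate_micrograph(n_cells: int, cell_radius_px: int = 12,
                        cell_amp: float = 50.0, bg_amp: float = 10.0,
                        noise_pkpk: float = 4.4, size_px: int = 250,
                        seed: int = 0,
                        pixel_size_um: float = 2.0,
                        wavenumber_cm1: float = 1650.0
                        ) -> tuple[Micrograph, np.ndarray]:
    """Disk-shaped cells of amplitude ``cell_amp`` over background ``bg_amp``
    with uniform noise in [-noise_pkpk/2, +noise_pkpk/2].

    Returns the micrograph and a boolean mask of the planted disks.
    Non-overlapping placement is attempted 100 times per disk.
    """
    if not cell_amp > bg_amp >= 0:
        raise ParameterError("need cell_amp > bg_amp >= 0")
    if noise_pkpk < 0:
        raise ParameterError("noise_pkpk must be >= 0")
    rng = np.random.default_rng(seed)
    img = np.full((size_px, size_px), bg_amp, dtype=float)
    mask = np.zeros((size_px, size_px), dtype=bool)
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    centers: list[tuple[int, int]] = []
    for _ in range(n_cells):
        for _attempt in range(100):
            cy, cx = rng.integers(cell_radius_px, size_px - cell_radius_px,
                                  size=2)
            if all(np.hypot(cy - py, cx - px) >= 2 * cell_radius_px + 1
                   for py, px in centers):
                break
        else:
            raise PlacementError(
                f"could not place disk {len(centers) + 1} of {n_cells} "
                "without overlap"
            )
        centers.append((int(cy), int(cx)))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius_px ** 2
        img[disk] = cell_amp
        mask |= disk
    if noise_pkpk > 0:
        img = img + rng.uniform(-noise_pkpk / 2.0, noise_pkpk / 2.0,
                                size=img.shape)
    return Micrograph(img, pixel_size_um, wavenumber_cm1), mask
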