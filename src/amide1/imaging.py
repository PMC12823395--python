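"""Micrograph contrast metrics: CNR and normalized optoacoustic profiles.

CNR compares a sample point against a background/medium point, scaled by
the peak-to-peak noise amplitude:

    CNR = |OA_S - OA_ref| / Noise_PkPk

The normalized optoacoustic contrast along a line profile uses the
lowest-contrast background point as reference:

    NOA = |OA - OA_ref| / OA_ref

CNR is invariant to a global intensity offset; NOA is invariant to a
global positive rescaling (but not to offsets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _bresenham_line

from .errors import ParameterError
from .io import Micrograph

__all__ = [
    "ContrastReport",
    "ProfileReport",
    "estimate_noise_pkpk",
    "compute_cnr",
    "cnr_enhancement",
    "contrast_profile",
    "contrast_report",
]


@dataclass(frozen=True)
class ContrastReport:
    """Inputs and value of one CNR evaluation (intensities in mV)."""

    oa_s: float
    oa_ref: float
    noise_pkpk: float
    cnr: float


@dataclass
class ProfileReport:
    """NOA values along a pixel path."""

    path: list            # [(row, col), ...]
    noa: np.ndarray
    oa_ref: float


def estimate_noise_pkpk(micrograph: Micrograph,
                        background_roi: tuple[int, int, int, int],
                        robust: bool = True) -> float:
    """Peak-to-peak noise amplitude over a background ROI.

    ``background_roi`` is (row0, row1, col0, col1), half-open.  The robust
    default uses the 0.5-99.5 percentile span, which tracks the true
    peak-to-peak of uniform noise while resisting outliers; ``robust=False``
    gives the literal max - min.
    """
    r0, r1, c0, c1 = background_roi
    h, w = micrograph.pixels.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ParameterError(f"ROI {background_roi} outside image {h}x{w}")
    roi = micrograph.pixels[r0:r1, c0:c1]
    if roi.size < 25:
        raise ParameterError(f"ROI has {roi.size} pixels; need >= 25")
    if robust:
        lo, hi = np.percentile(roi, [0.5, 99.5])
        return float(hi - lo)
    return float(roi.max() - roi.min())


def compute_cnr(oa_s: float, oa_ref: float, noise_pkpk: float) -> float:
    """|OA_S - OA_ref| / Noise_PkPk (symmetric in its two signal arguments)."""
    if noise_pkpk <= 0:
        raise ParameterError("noise_pkpk must be positive")
    return abs(oa_s - oa_ref) / noise_pkpk


def cnr_enhancement(cnr_a: float, cnr_b: float) -> float:
    """Ratio of two CNRs, reported to one decimal place."""
    if cnr_b <= 0:
        raise ParameterError("reference CNR must be positive")
    return round(cnr_a / cnr_b, 1)


def contrast_profile(micrograph: Micrograph,
                     start: tuple[int, int], end: tuple[int, int],
                     oa_ref: float) -> ProfileReport:
    """NOA along the Bresenham line from ``start`` to ``end`` (row, col).

    ``oa_ref`` is the lowest-contrast background value; it must be positive
    for the normalization to be defined.
    """
    if oa_ref <= 0:
        raise ParameterError("oa_ref must be positive")
    h, w = micrograph.pixels.shape
    for r, c in (start, end):
        if not (0 <= r < h and 0 <= c < w):
            raise ParameterError(f"profile endpoint ({r}, {c}) outside image")
    rr, cc = _bresenham_line(int(start[0]), int(start[1]),
                             int(end[0]), int(end[1]))
    vals = micrograph.pixels[rr, cc]
    noa = np.abs(vals - oa_ref) / oa_ref
    return ProfileReport(path=list(zip(rr.tolist(), cc.tolist())),
                         noa=noa, oa_ref=float(oa_ref))


def contrast_report(micrograph: Micrograph, sample_px: tuple[int, int],
                    reference_px: tuple[int, int],
                    background_roi: tuple[int, int, int, int],
                    robust: bool = True) -> ContrastReport:
    """Full CNR evaluation from pixel coordinates and a background ROI."""
    noise = estimate_noise_pkpk(micrograph, background_roi, robust=robust)
    oa_s = float(micrograph.pixels[sample_px])
    oa_ref = float(micrograph.pixels[reference_px])
    return ContrastReport(oa_s, oa_ref, noise,
                          compute_cnr(oa_s, oa_ref, noise))
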