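"""Extracted-ion-mobilogram processing: MobA, MassI and 2D m/z-DT maps.

Two data-extraction methods are implemented for a spot acquisition:

MobA
    Sum the centroid intensities inside an m/z extraction window per drift
    bin (the extracted ion mobilogram), detect the mobility peak nearest
    the expected drift time, and integrate its raw area — the IM analogue
    of integrating an LC-MRM chromatographic peak.

MassI
    Bin all centroids onto a fixed m/z comb summed over the full TIC and
    take the maximum binned intensity inside the window.

The peak detector is a deterministic reimplementation of a vendor-style
apex-tracking integrator: local-quadratic (Savitzky-Golay) smoothing,
apex = highest smoothed local maximum within a drift-time tolerance of
the expected value, boundaries extended until the smoothed trace returns
to baseline + k*noise or reaches a valley, area = trapezoidal integral of
the *raw* trace between the boundaries.  It is a functional stand-in for
the proprietary algorithm, not a clone; every constant is a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.signal import find_peaks, savgol_filter

from .simulate import MZ_GRID_STEP, Acquisition

__all__ = [
    "ExtractionWindow",
    "Mobilogram",
    "MobilityPeak",
    "ANALYTE_WINDOW",
    "IS_WINDOW",
    "extract_mobilogram",
    "combine_spectrum",
    "massi",
    "detect_mobility_peak",
    "moba",
    "dt_mz_map",
    "MobilityMap",
]


class ExtractionWindow(BaseModel):
    """m/z window and expected drift time for one compound."""

    model_config = ConfigDict(extra="forbid")

    mz_low: float
    mz_high: float
    expected_dt: float  # ms
    dt_tolerance: float = Field(0.2, gt=0)  # ms

    @model_validator(mode="after")
    def _check(self) -> "ExtractionWindow":
        if not self.mz_low < self.mz_high:
            raise ValueError("mz_low must be < mz_high")
        return self


#: Default analyte (osimertinib fragment) extraction window.
ANALYTE_WINDOW = ExtractionWindow(mz_low=185.094, mz_high=185.121, expected_dt=1.85)
#: Default internal-standard fragment extraction window.
IS_WINDOW = ExtractionWindow(mz_low=189.125, mz_high=189.140, expected_dt=1.86)


@dataclass
class Mobilogram:
    """Intensity versus drift time for one m/z extraction window."""

    dt_grid: np.ndarray  # ms, strictly increasing
    intensity: np.ndarray  # a.u., same length

    def __post_init__(self) -> None:
        if len(self.dt_grid) != len(self.intensity):
            raise ValueError("dt_grid and intensity must have equal length")
        if len(self.dt_grid) > 1 and not (np.diff(self.dt_grid) > 0).all():
            raise ValueError("dt_grid must be strictly increasing")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def total(self) -> float:
        return float(self.intensity.sum())


@dataclass
class MobilityPeak:
    apex_dt: float
    left_dt: float
    right_dt: float
    area: float  # a.u.*ms
    apex_intensity: float

    def __post_init__(self) -> None:
        if not (self.left_dt <= self.apex_dt <= self.right_dt):
            raise ValueError("peak bounds must bracket the apex")
        if self.area < 0:
            raise ValueError("area must be >= 0")


def extract_mobilogram(acq: Acquisition, window: ExtractionWindow) -> Mobilogram:
    """Sum centroid intensities with mz_low <= m/z <= mz_high per drift bin.

    Bins without matching centroids are zero; an empty acquisition yields
    an all-zero mobilogram.
    """
    n_bins = len(acq.dt_centers)
    if acq.n_centroids == 0:
        return Mobilogram(dt_grid=acq.dt_centers, intensity=np.zeros(n_bins))
    mask = (acq.mz >= window.mz_low) & (acq.mz <= window.mz_high)
    intensity = np.bincount(
        acq.drift_bins[mask], weights=acq.intensity[mask], minlength=n_bins
    )
    return Mobilogram(dt_grid=acq.dt_centers, intensity=intensity)


def combine_spectrum(
    acq: Acquisition,
    mz_step: float = MZ_GRID_STEP,
    mz_range: tuple[float, float] | None = None,
):
    """TIC-combined spectrum: all centroids binned onto a fixed m/z comb.

    Returns ``(mz_centers, intensity)`` for the occupied comb range (or
    the requested range).  Bin j covers [j*mz_step, (j+1)*mz_step).
    """
    if acq.n_centroids == 0:
        return np.empty(0), np.empty(0)
    mz, inten = acq.mz, acq.intensity
    if mz_range is not None:
        lo, hi = mz_range
        if not lo < hi:
            raise ValueError("mz_range must be increasing")
        m = (mz >= lo) & (mz <= hi)
        mz, inten = mz[m], inten[m]
        if len(mz) == 0:
            return np.empty(0), np.empty(0)
    j = np.floor(mz / mz_step).astype(np.int64)
    j0 = j.min()
    profile = np.bincount(j - j0, weights=inten)
    centers = (np.arange(j0, j0 + len(profile), dtype=float) + 0.5) * mz_step
    return centers, profile


def massi(acq: Acquisition, window: ExtractionWindow, mz_step: float = MZ_GRID_STEP) -> float:
    """Maximum of the combined-spectrum profile inside the window (0 for blanks)."""
    centers, profile = combine_spectrum(acq, mz_step=mz_step)
    if len(centers) == 0:
        return 0.0
    m = (centers >= window.mz_low) & (centers <= window.mz_high)
    return float(profile[m].max()) if m.any() else 0.0


def _baseline_and_noise(mob: Mobilogram, window: ExtractionWindow):
    """Robust baseline from the mobilogram away from the expected peak.

    Median (baseline) and scaled MAD (noise) over bins with
    |dt - expected| > 3 * dt_tolerance; zero when no such bins exist.
    """
    far = np.abs(mob.dt_grid - window.expected_dt) > 3.0 * window.dt_tolerance
    if not far.any():
        return 0.0, 0.0
    ref = mob.intensity[far]
    baseline = float(np.median(ref))
    noise = float(1.4826 * np.median(np.abs(ref - baseline)))
    return baseline, noise


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    width = min(width if width % 2 == 1 else width + 1, len(y) if len(y) % 2 == 1 else len(y) - 1)
    if width < 3 or len(y) < 3:
        return y.astype(float)
    return savgol_filter(y, window_length=width, polyorder=2, mode="interp")


def detect_mobility_peak(
    mob: Mobilogram,
    window: ExtractionWindow,
    smooth_width: int = 5,
    noise_k: float = 2.0,
) -> MobilityPeak:
    """Apex-tracking peak detection and integration on a mobilogram.

    Apex: highest smoothed local maximum with |apex_dt - expected_dt| <=
    dt_tolerance (ties: closer to the expected DT, then earlier DT).
    Boundaries walk downhill from the apex on the smoothed trace and stop
    at the first bin at/below baseline + noise_k*noise or at a valley.
    The area is the trapezoidal integral of the *raw* trace between the
    boundaries.  When no qualifying maximum exists, a zero-area peak at
    the expected DT is returned.
    """
    dt, raw = mob.dt_grid, np.asarray(mob.intensity, dtype=float)
    if len(dt) == 0:
        raise ValueError("mobilogram is empty")
    if window.dt_tolerance > (dt[-1] - dt[0]) and len(dt) > 1:
        raise ValueError("dt_tolerance exceeds the drift-time grid span")

    smoothed = _smooth(raw, smooth_width)
    baseline, noise = _baseline_and_noise(mob, window)
    threshold = baseline + noise_k * noise

    peaks, _ = find_peaks(smoothed)
    candidates = [p for p in peaks if abs(dt[p] - window.expected_dt) <= window.dt_tolerance]
    candidates = [p for p in candidates if smoothed[p] > threshold]
    if not candidates:
        return MobilityPeak(
            apex_dt=window.expected_dt, left_dt=window.expected_dt,
            right_dt=window.expected_dt, area=0.0, apex_intensity=0.0,
        )
    apex = min(
        candidates,
        key=lambda p: (-smoothed[p], abs(dt[p] - window.expected_dt), dt[p]),
    )

    # Walk downhill on the smoothed trace; plateaus (exact ties, e.g. a peak
    # centered on a bin edge) continue the walk, only a strict rise is a valley.
    left = apex
    while left > 0:
        if smoothed[left - 1] <= threshold:
            left -= 1  # include the first at/below-threshold bin (peak tail)
            break
        if smoothed[left - 1] > smoothed[left]:
            break  # valley
        left -= 1
    right = apex
    n = len(dt)
    while right < n - 1:
        if smoothed[right + 1] <= threshold:
            right += 1
            break
        if smoothed[right + 1] > smoothed[right]:
            break
        right += 1

    area = float(np.trapezoid(raw[left : right + 1], dt[left : right + 1])) if right > left else 0.0
    return MobilityPeak(
        apex_dt=float(dt[apex]),
        left_dt=float(dt[left]),
        right_dt=float(dt[right]),
        area=max(area, 0.0),
        apex_intensity=float(smoothed[apex]),
    )


def moba(acq: Acquisition, window: ExtractionWindow, **peak_kwargs) -> float:
    """MobA: extracted-ion-mobilogram peak area for one window (a.u.*ms)."""
    mob = extract_mobilogram(acq, window)
    return detect_mobility_peak(mob, window, **peak_kwargs).area


@dataclass
class MobilityMap:
    """2D intensity matrix on (m/z bin x drift bin) with axis vectors."""

    matrix: np.ndarray  # shape (n_mz, n_dt)
    mz_centers: np.ndarray
    dt_centers: np.ndarray

    @property
    def mz_marginal(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def dt_marginal(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def dt_mz_map(
    acq: Acquisition,
    mz_range: tuple[float, float],
    dt_range: tuple[float, float],
    mz_step: float = MZ_GRID_STEP,
) -> MobilityMap:
    """2D m/z vs drift-time map of summed centroid intensities.

    Row/column marginals agree with :func:`combine_spectrum` and with the
    total mobilogram restricted to the same ranges and binning.
    """
    mz_lo, mz_hi = mz_range
    dt_lo, dt_hi = dt_range
    if not (mz_lo < mz_hi and dt_lo < dt_hi):
        raise ValueError("mz_range and dt_range must be increasing")
    j_lo = int(np.floor(mz_lo / mz_step))
    j_hi = int(np.floor(mz_hi / mz_step))
    mz_centers = (np.arange(j_lo, j_hi + 1, dtype=float) + 0.5) * mz_step
    dt_mask = (acq.dt_centers >= dt_lo) & (acq.dt_centers <= dt_hi)
    dt_idx = np.flatnonzero(dt_mask)
    matrix = np.zeros((len(mz_centers), len(dt_idx)))
    if acq.n_centroids:
        sel = (
            (acq.mz >= mz_lo) & (acq.mz <= mz_hi)
            & dt_mask[acq.drift_bins]
        )
        if sel.any():
            j = np.floor(acq.mz[sel] / mz_step).astype(np.int64) - j_lo
            col = np.searchsorted(dt_idx, acq.drift_bins[sel])
            np.add.at(matrix, (j, col), acq.intensity[sel])
    return MobilityMap(matrix=matrix, mz_centers=mz_centers, dt_centers=acq.dt_centers[dt_idx])
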