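"""Six-stage spectral peak identification on envelope-normalized spectra.

The magnitude spectrum of an ultrafast-EPI time series rides on a decreasing
baseline floor that is a property of the acquisition, not of physiology.  The
algorithm implemented here removes that floor before thresholding:

1. smooth the raw magnitude spectrum with a Savitzky–Golay filter (order 2,
   window 0.133 Hz — the width of the normal adult respiratory range of
   12–20 breaths/min);
2. build the *lower envelope*: piecewise-linear interpolation through the
   local minima of the smoothed curve;
3. divide the smoothed spectrum by the envelope and subtract one — the
   *adjusted spectrum*, zero wherever the smoothed curve touches its floor;
4. detect *primary* peaks: local maxima above mean + std of the adjusted
   spectrum;
5. exclude a zone of total width 0.667 Hz (the normal adult cardiac range of
   60–100 beats/min) around each primary peak and compute baseline
   mean/std over the remaining bins;
6. detect *final* peaks: local maxima above baseline mean + std with
   topographic prominence of at least 1.5 dB measured on the envelope-ratio
   curve 20·log10(1 + adjusted).

All standard deviations use the sample (n−1) convention, and the DC bin is
excluded from every statistic and can never be a peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences, savgol_filter

from .spectra import FrequencyGrid, Spectrum

__all__ = [
    "PeakFindParams",
    "AdjustedSpectrum",
    "Peak",
    "rate_range_width_hz",
    "sg_window_samples",
    "smooth_spectrum",
    "lower_envelope",
    "adjust_spectrum",
    "detect_primary_peaks",
    "baseline_stats",
    "detect_final_peaks",
    "identify_peaks",
]

#: Normal adult respiratory rate range (breaths per minute); its width in Hz
#: sets the default Savitzky–Golay window.
RESPIRATORY_RATE_RANGE_BPM = (12.0, 20.0)
#: Normal adult cardiac rate range (beats per minute); its width in Hz sets
#: the default exclusion-zone width.
CARDIAC_RATE_RANGE_BPM = (60.0, 100.0)


def rate_range_width_hz(low_bpm: float, high_bpm: float) -> float:
    """Width in Hz of a physiological rate range given in events/minute."""
    if not (0 <= low_bpm < high_bpm):
        raise ValueError("need 0 <= low_bpm < high_bpm")
    return (high_bpm - low_bpm) / 60.0


@dataclass
class PeakFindParams:
    """Tunable parameters of the peak-identification algorithm.

    sg_window_hz
        Savitzky–Golay window expressed in Hz (default 0.133, the 12–20
        breaths/min span).  Converted to an odd sample count via the
        spectrum's Δf.
    sg_order
        Polynomial order of the smoother (default 2).
    sg_window_multiplier
        Multiplier on the window sample count; 2 for very short-TR
        acquisitions (TR ≤ 75 ms) whose grids are much wider, 1 otherwise.
    exclusion_zone_hz
        Width of the baseline exclusion zone around each primary peak
        (default 0.667, the 60–100 beats/min span).  Interpreted as *total*
        width unless ``exclusion_is_half_width`` is set.
    min_prominence_db
        Minimum topographic prominence of a final peak, in dB on the
        envelope-ratio curve (default 1.5).
    """

    sg_window_hz: float = 0.133
    sg_order: int = 2
    sg_window_multiplier: int = 1
    exclusion_zone_hz: float = 0.667
    exclusion_is_half_width: bool = False
    min_prominence_db: float = 1.5

    #: TR (s) at and below which the window sample count is doubled.
    SHORT_TR_THRESHOLD_S = 0.075

    def __post_init__(self) -> None:
        if self.sg_window_hz <= 0 or self.exclusion_zone_hz <= 0 or self.min_prominence_db <= 0:
            raise ValueError("all PeakFindParams lengths/thresholds must be positive")
        if self.sg_order < 1:
            raise ValueError("sg_order must be >= 1")
        if self.sg_window_multiplier < 1:
            raise ValueError("sg_window_multiplier must be >= 1")

    @classmethod
    def for_tr(cls, tr: float, **overrides) -> "PeakFindParams":
        """Defaults adapted to the repetition time (doubles the window for
        short-TR acquisitions)."""
        params = cls(**overrides)
        if "sg_window_multiplier" not in overrides and tr <= cls.SHORT_TR_THRESHOLD_S:
            params = replace(params, sg_window_multiplier=2)
        return params


@dataclass(frozen=True)
class Peak:
    """An identified spectral peak on the adjusted spectrum."""

    center_frequency: float
    height: float
    prominence_db: float = float("nan")
    index: int = -1


@dataclass
class AdjustedSpectrum:
    """The per-stage curves of the peak-identification algorithm."""

    grid: FrequencyGrid
    raw: np.ndarray
    smoothed: np.ndarray
    envelope: np.ndarray
    adjusted: np.ndarray
    provenance: str = ""

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frequency_hz": self.grid.frequencies,
            "raw": self.raw,
            "smoothed": self.smoothed,
            "envelope": self.envelope,
            "adjusted": self.adjusted,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def sg_window_samples(delta_f: float, params: PeakFindParams, n_bins: int) -> int:
    """Savitzky–Golay window length in samples for a grid of spacing Δf.

    round(window_hz · multiplier / Δf), forced odd, at least 5, capped at the
    spectrum length (forced odd).
    """
    w = int(round(params.sg_window_hz * params.sg_window_multiplier / delta_f))
    if w % 2 == 0:
        w += 1
    w = max(w, 5)
    if w > n_bins:
        w = n_bins if n_bins % 2 == 1 else n_bins - 1
    return w


def smooth_spectrum(spectrum: Spectrum, params: PeakFindParams | None = None,
                    skip_dc: bool = False) -> np.ndarray:
    """Savitzky–Golay smoothing of the magnitude spectrum.

    Edges are handled by fitting the polynomial on the truncated window
    (scipy's ``interp`` mode), so a spectrum that is itself a polynomial of
    degree ≤ ``sg_order`` is reproduced exactly.

    ``skip_dc`` smooths from bin 1 onward and carries bin 0 as a duplicate
    of bin 1: the demeaned DC bin is exactly zero, and letting that
    discontinuity into the edge fit would bend the smoothed curve into a
    spurious low-frequency bump.
    """
    params = params or PeakFindParams()
    mag = np.asarray(spectrum.magnitude, dtype=float)
    start = 1 if skip_dc else 0
    if len(mag) - start < 5:
        raise ValueError(f"spectrum has {len(mag)} bins; need at least {5 + start} to smooth")
    window = sg_window_samples(spectrum.grid.delta_f, params, len(mag) - start)
    if params.sg_order >= window:
        raise ValueError(f"sg_order {params.sg_order} must be < window length {window}")
    smoothed = savgol_filter(mag[start:], window_length=window,
                             polyorder=params.sg_order, mode="interp")
    if skip_dc:
        smoothed = np.concatenate(([smoothed[0]], smoothed))
    return smoothed


def lower_envelope(smoothed: np.ndarray, grid: FrequencyGrid,
                   skip_dc: bool = False) -> np.ndarray:
    """Piecewise-linear lower envelope through the local minima.

    Knots are the first bin, every strict local minimum of the smoothed
    curve, and the last bin; linear interpolation bridges between knots.
    The result is then clipped pointwise to lie at or below the smoothed
    curve and floored at a tiny positive value so later division is safe.

    ``skip_dc`` restricts the envelope to bins 1.. (the analyzed support
    when the DC bin is excluded) and carries bin 0 as a duplicate of bin 1.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    start = 1 if skip_dc else 0
    curve = smoothed[start:]
    freqs = grid.frequencies[start:]
    n = len(curve)
    if n < 2:
        raise ValueError("need at least 2 bins for an envelope")
    interior = np.arange(1, n - 1)
    is_min = (curve[interior] < curve[interior - 1]) & (curve[interior] < curve[interior + 1])
    knots = np.concatenate(([0], interior[is_min], [n - 1]))
    env = np.interp(freqs, freqs[knots], curve[knots])
    env = np.minimum(env, curve)
    floor = 1e-12 * max(float(np.max(curve)), 1e-300)
    env = np.maximum(env, floor)
    if skip_dc:
        env = np.concatenate(([env[0]], env))
    return env


def adjust_spectrum(smoothed: np.ndarray, envelope: np.ndarray) -> np.ndarray:
    """Envelope-normalized spectrum: smoothed/envelope − 1 (non-negative)."""
    smoothed = np.asarray(smoothed, dtype=float)
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope <= 0):
        raise ValueError("envelope must be strictly positive (violated contract)")
    adjusted = smoothed / envelope - 1.0
    # numerically the ratio can dip a hair below 1 where env == smoothed
    return np.maximum(adjusted, 0.0)


def _local_maxima(adjusted: np.ndarray) -> np.ndarray:
    """Indices of local maxima with plateau handling.

    A flat-topped run counts as one peak at its center bin, ties broken
    toward the lower frequency.  Endpoints (including DC) never qualify.
    """
    idx, props = find_peaks(adjusted, plateau_size=1)
    if len(idx) == 0:
        return idx
    centers = (props["left_edges"] + props["right_edges"]) // 2
    return centers.astype(int)


def _sample_std(x: np.ndarray) -> float:
    """Sample (n−1) standard deviation; 0 for fewer than 2 values."""
    return float(np.std(x, ddof=1)) if len(x) >= 2 else 0.0


def detect_primary_peaks(adjusted: np.ndarray, grid: FrequencyGrid) -> list[Peak]:
    """Local maxima with height ≥ mean + std of the adjusted spectrum.

    The DC bin is excluded from the statistics and cannot be a peak.
    """
    adjusted = np.asarray(adjusted, dtype=float)
    body = adjusted[1:]
    threshold = float(np.mean(body)) + _sample_std(body)
    peaks = []
    for i in _local_maxima(adjusted):
        if i == 0:
            continue
        if adjusted[i] >= threshold:
            peaks.append(Peak(center_frequency=float(grid.frequencies[i]),
                              height=float(adjusted[i]), index=int(i)))
    return peaks


def baseline_stats(adjusted: np.ndarray, grid: FrequencyGrid,
                   primary_peaks: list[Peak],
                   params: PeakFindParams | None = None) -> tuple[float, float]:
    """Baseline mean/std of the adjusted spectrum outside the exclusion zones.

    A zone of total width ``exclusion_zone_hz`` (half-width if the
    corresponding flag is set) is centered on each primary peak; the DC bin
    is always excluded.
    """
    params = params or PeakFindParams()
    adjusted = np.asarray(adjusted, dtype=float)
    half = params.exclusion_zone_hz if params.exclusion_is_half_width else params.exclusion_zone_hz / 2.0
    keep = np.ones(len(adjusted), dtype=bool)
    keep[0] = False
    f = grid.frequencies
    for peak in primary_peaks:
        keep &= np.abs(f - peak.center_frequency) > half
    if not keep.any():
        raise ValueError(
            "exclusion zones cover the entire spectrum; widen the spectrum "
            "or reduce the number of primary peaks")
    baseline = adjusted[keep]
    return float(np.mean(baseline)), _sample_std(baseline)


def ratio_db(adjusted: np.ndarray) -> np.ndarray:
    """Envelope-ratio curve in decibels: 20·log10(1 + adjusted)."""
    return 20.0 * np.log10(1.0 + np.asarray(adjusted, dtype=float))


def detect_final_peaks(adjusted: np.ndarray, grid: FrequencyGrid,
                       baseline: tuple[float, float],
                       params: PeakFindParams | None = None) -> list[Peak]:
    """Final peaks: above baseline mean + std and prominent enough.

    Prominence is the standard topographic prominence, measured on the
    envelope-ratio curve in dB, and must reach ``min_prominence_db``.
    Returned sorted by frequency.
    """
    params = params or PeakFindParams()
    adjusted = np.asarray(adjusted, dtype=float)
    baseline_mean, baseline_std = baseline
    height_threshold = baseline_mean + baseline_std
    candidates = np.array([i for i in _local_maxima(adjusted)
                           if i != 0 and adjusted[i] >= height_threshold], dtype=int)
    if len(candidates) == 0:
        return []
    db = ratio_db(adjusted)
    prominences, _, _ = peak_prominences(db, candidates)
    peaks = [Peak(center_frequency=float(grid.frequencies[i]), height=float(adjusted[i]),
                  prominence_db=float(p), index=int(i))
             for i, p in zip(candidates, prominences) if p >= params.min_prominence_db]
    return sorted(peaks, key=lambda pk: pk.center_frequency)


def identify_peaks(spectrum: Spectrum,
                   params: PeakFindParams | None = None) -> tuple[AdjustedSpectrum, list[Peak]]:
    """Run the full six-stage algorithm on one spectrum.

    Returns the per-stage curves and the final peaks, deterministically for a
    fixed input.
    """
    params = params or PeakFindParams.for_tr(spectrum.tr)
    skip_dc = spectrum.grid.frequencies[0] == 0.0
    smoothed = smooth_spectrum(spectrum, params, skip_dc=skip_dc)
    envelope = lower_envelope(smoothed, spectrum.grid, skip_dc=skip_dc)
    adjusted = adjust_spectrum(smoothed, envelope)
    if skip_dc:
        adjusted[0] = 0.0
    adj = AdjustedSpectrum(grid=spectrum.grid, raw=np.asarray(spectrum.magnitude, dtype=float),
                           smoothed=smoothed, envelope=envelope, adjusted=adjusted,
                           provenance=spectrum.provenance)
    primary = detect_primary_peaks(adjusted, spectrum.grid)
    baseline = baseline_stats(adjusted, spectrum.grid, primary, params)
    final = detect_final_peaks(adjusted, spectrum.grid, baseline, params)
    return adj, final


def peaks_to_frame(peaks: list[Peak], provenance: str = "") -> pd.DataFrame:
    rows = [{"frequency_hz": p.center_frequency, "height": p.height,
             "prominence_db": p.prominence_db, "provenance": provenance} for p in peaks]
    return pd.DataFrame(rows, columns=["frequency_hz", "height", "prominence_db", "provenance"])
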