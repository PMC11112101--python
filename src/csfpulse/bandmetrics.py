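"""Frequency-band biomarkers: 3 dB bandwidth, area, and cross-subject summaries.

A detected peak becomes a *band* by walking outward from the peak on the
adjusted spectrum until the curve first drops below √2/2 of the peak height
(the amplitude equivalent of a 3 dB drop).  Crossings are located by linear
interpolation between bins.  If the curve instead runs into the grid edge, or
rises toward an adjacent higher peak before crossing, the band is cut at the
edge/valley and flagged truncated.  The band's *area* is the trapezoidal
integral of the adjusted curve over [f_lo, f_hi]; since the adjusted spectrum
is dimensionless the area carries units of Hz.

Bands from several subjects are grouped by center frequency (single-linkage,
default tolerance 0.2 Hz) and each group is summarized by the mean and sample
(n−1) standard deviation of frequency, magnitude, area and bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peakfind import AdjustedSpectrum, Peak

__all__ = [
    "Band",
    "BandGroup",
    "BandSummary",
    "THREE_DB_AMPLITUDE_FACTOR",
    "band_from_peak",
    "bands_from_peaks",
    "group_bands",
    "summarize_bands",
    "bands_to_frame",
    "summaries_to_frame",
]

#: Amplitude factor of a 3 dB drop: sqrt(2)/2.
THREE_DB_AMPLITUDE_FACTOR = float(np.sqrt(2.0) / 2.0)

METRICS = ("frequency", "magnitude", "area", "bandwidth")


@dataclass
class Band:
    """A spectral band around one identified peak (Table-style biomarkers)."""

    center_frequency: float
    magnitude: float
    f_lo: float
    f_hi: float
    bandwidth: float
    area: float
    region: str = ""
    subject: str = ""
    truncated: bool = False

    def metric(self, name: str) -> float:
        if name == "frequency":
            return self.center_frequency
        return getattr(self, name)

    @property
    def interval(self) -> tuple[float, float]:
        return (self.f_lo, self.f_hi)


@dataclass
class BandGroup:
    label: str
    bands: list[Band]


@dataclass
class BandSummary:
    """Per-group mean ± sample std of each band metric across subjects."""

    band_label: str
    n_subjects: int
    mean: dict[str, float]
    std: dict[str, float | None]


def _walk(curve: np.ndarray, freqs: np.ndarray, peak_idx: int,
          threshold: float, height: float, step: int) -> tuple[float, bool]:
    """Walk from the peak in direction ``step`` (−1 left, +1 right) until the
    curve first drops below ``threshold``.

    Returns (edge frequency, truncated).  Truncation happens at the grid
    boundary, or at the running valley if the curve climbs above the peak
    height (an adjacent higher peak) before crossing the threshold.
    """
    n = len(curve)
    i = peak_idx + step
    valley_idx = peak_idx
    while 0 <= i < n:
        if curve[i] < threshold:
            # linear interpolation between i-step (>= thr) and i (< thr)
            f0, f1 = freqs[i - step], freqs[i]
            y0, y1 = curve[i - step], curve[i]
            frac = (y0 - threshold) / (y0 - y1)
            return float(f0 + frac * (f1 - f0)), False
        if curve[i] < curve[valley_idx]:
            valley_idx = i
        if curve[i] > height:
            return float(freqs[valley_idx]), True
        i += step
    return float(freqs[0] if step < 0 else freqs[-1]), True


def band_from_peak(adjusted: AdjustedSpectrum, peak: Peak,
                   region: str = "", subject: str = "",
                   use_smoothed: bool = False) -> Band:
    """Compute the 3 dB band of a final peak.

    By default the band is measured on the adjusted spectrum — the curve on
    which the peak was identified; ``use_smoothed`` measures it on the
    smoothed raw spectrum instead.
    """
    curve = adjusted.smoothed if use_smoothed else adjusted.adjusted
    freqs = adjusted.grid.frequencies
    p = peak.index if peak.index >= 0 else adjusted.grid.index_of(peak.center_frequency)
    if not np.isclose(freqs[p], peak.center_frequency, rtol=0, atol=1e-9 * max(1.0, freqs[-1])):
        raise ValueError(f"peak frequency {peak.center_frequency} is not on the grid")
    height = float(curve[p])
    threshold = height * THREE_DB_AMPLITUDE_FACTOR
    f_lo, trunc_lo = _walk(curve, freqs, p, threshold, height, -1)
    f_hi, trunc_hi = _walk(curve, freqs, p, threshold, height, +1)
    area = _band_area(curve, freqs, f_lo, f_hi, threshold, trunc_lo, trunc_hi)
    return Band(center_frequency=float(freqs[p]), magnitude=height,
                f_lo=f_lo, f_hi=f_hi, bandwidth=f_hi - f_lo, area=area,
                region=region, subject=subject, truncated=trunc_lo or trunc_hi)


def _band_area(curve: np.ndarray, freqs: np.ndarray, f_lo: float, f_hi: float,
               threshold: float, trunc_lo: bool, trunc_hi: bool) -> float:
    """Trapezoidal integral of the curve over [f_lo, f_hi].

    Interpolated 3 dB crossings contribute an endpoint at exactly the
    threshold value; truncated edges land on a grid bin.
    """
    inside = (freqs > f_lo) & (freqs < f_hi)
    xs = freqs[inside]
    ys = curve[inside]
    x = np.concatenate(([f_lo], xs, [f_hi]))
    y = np.concatenate((
        [curve[np.searchsorted(freqs, f_lo)] if trunc_lo else threshold],
        ys,
        [curve[np.searchsorted(freqs, f_hi)] if trunc_hi else threshold],
    ))
    return float(np.trapezoid(y, x))


def bands_from_peaks(adjusted: AdjustedSpectrum, peaks: list[Peak],
                     region: str = "", subject: str = "",
                     use_smoothed: bool = False) -> list[Band]:
    return [band_from_peak(adjusted, p, region=region, subject=subject,
                           use_smoothed=use_smoothed) for p in peaks]


def group_bands(bands: list[Band], tolerance_hz: float = 0.2) -> list[BandGroup]:
    """Single-linkage grouping of bands by center frequency.

    Two bands belong to the same group when a chain of bands connects them
    with successive center-frequency gaps ≤ ``tolerance_hz`` (in 1D this is
    simply splitting the sorted centers at gaps larger than the tolerance).
    Groups are labelled "Band 1", "Band 2", ... in increasing frequency.
    """
    if tolerance_hz <= 0:
        raise ValueError("tolerance_hz must be positive")
    if not bands:
        return []
    ordered = sorted(bands, key=lambda b: b.center_frequency)
    groups: list[list[Band]] = [[ordered[0]]]
    for band in ordered[1:]:
        if band.center_frequency - groups[-1][-1].center_frequency <= tolerance_hz:
            groups[-1].append(band)
        else:
            groups.append([band])
    return [BandGroup(label=f"Band {i + 1}", bands=g) for i, g in enumerate(groups)]


def summarize_bands(groups: list[BandGroup]) -> list[BandSummary]:
    """Mean and sample (n−1) std of each metric, per group, across subjects.

    Values are kept at full precision; rounding (e.g. to 3 decimals for
    presentation) is left to the caller.  The std is omitted (None) for
    single-subject groups.
    """
    summaries = []
    for group in groups:
        if not group.bands:
            raise ValueError(f"group {group.label!r} is empty")
        n = len(group.bands)
        mean: dict[str, float] = {}
        std: dict[str, float | None] = {}
        for metric in METRICS:
            values = np.array([b.metric(metric) for b in group.bands], dtype=float)
            mean[metric] = float(values.mean())
            std[metric] = float(values.std(ddof=1)) if n >= 2 else None
        summaries.append(BandSummary(band_label=group.label, n_subjects=n, mean=mean, std=std))
    return summaries


def bands_to_frame(bands: list[Band]) -> pd.DataFrame:
    rows = [{"region": b.region, "subject": b.subject,
             "frequency_hz": b.center_frequency, "magnitude_au": b.magnitude,
             "area_hz": b.area, "bandwidth_hz": b.bandwidth,
             "f_lo_hz": b.f_lo, "f_hi_hz": b.f_hi, "truncated": b.truncated}
            for b in bands]
    return pd.DataFrame(rows, columns=["region", "subject", "frequency_hz", "magnitude_au",
                                       "area_hz", "bandwidth_hz", "f_lo_hz", "f_hi_hz", "truncated"])


def summaries_to_frame(summaries: list[BandSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row: dict = {"band": s.band_label, "n_subjects": s.n_subjects}
        for metric in METRICS:
            row[f"{metric}_mean"] = s.mean[metric]
            row[f"{metric}_std"] = s.std[metric]
        rows.append(row)
    return pd.DataFrame(rows)
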