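"""Physiological traces (ECG, respiration belt) and their spectral comparison
with the MRI signal.

Traces are recorded continuously around the scan; a scanner trigger timestamp
marks the scan onset, and :func:`align_to_scan` crops the trace to the scan
window.  The cropped trace's magnitude spectrum lives on its own grid
(Δf = 1/duration) and is peak-identified with the same envelope-normalized
algorithm used for MRI spectra, so cardiac/respiratory bands can be compared
with MRI bands in frequency-interval space — no resampling onto the MRI grid
is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bandmetrics import Band, bands_from_peaks
from .peakfind import PeakFindParams, identify_peaks
from .spectra import Spectrum, voxel_spectrum

__all__ = [
    "PhysioTrace",
    "OverlapPair",
    "BandOverlapReport",
    "read_physio_csv",
    "write_physio_csv",
    "align_to_scan",
    "trace_spectrum",
    "physio_bands",
    "band_overlap",
]


@dataclass
class PhysioTrace:
    """A physiological recording with its scanner-trigger timestamp."""

    samples: np.ndarray
    sampling_rate: float
    channel: str
    trigger_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be a 1D vector")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not (0 <= self.trigger_time <= self.duration):
            raise ValueError(f"trigger_time {self.trigger_time}s outside the "
                             f"{self.duration:.3f}s recording")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass(frozen=True)
class OverlapPair:
    """One MRI/physio band pair with a non-empty frequency overlap."""

    mri_band: Band
    physio_band: Band
    overlap_lo: float
    overlap_hi: float
    overlap_fraction: float  # |intersection| / |union|, in [0, 1]
    channel: str


@dataclass
class BandOverlapReport:
    pairs: list[OverlapPair]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"channel": p.channel,
                 "mri_center_hz": p.mri_band.center_frequency,
                 "physio_center_hz": p.physio_band.center_frequency,
                 "overlap_lo_hz": p.overlap_lo, "overlap_hi_hz": p.overlap_hi,
                 "overlap_fraction": p.overlap_fraction} for p in self.pairs]
        return pd.DataFrame(rows, columns=["channel", "mri_center_hz", "physio_center_hz",
                                           "overlap_lo_hz", "overlap_hi_hz", "overlap_fraction"])


def write_physio_csv(trace: PhysioTrace, path) -> None:
    """Write a trace as CSV: a metadata header row, then one sample per line."""
    with open(path, "w") as fh:
        fh.write("sampling_rate_hz,channel,trigger_time_s\n")
        fh.write(f"{trace.sampling_rate!r},{trace.channel},{trace.trigger_time!r}\n")
        fh.write("sample\n")
        np.savetxt(fh, trace.samples, fmt="%.10g")


def read_physio_csv(path) -> PhysioTrace:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        values = fh.readline().strip().split(",")
        meta = dict(zip(header, values))
        column = fh.readline().strip()
        if column != "sample":
            raise ValueError(f"{path}: expected a 'sample' column header, got {column!r}")
        samples = np.loadtxt(fh, dtype=float, ndmin=1)
    return PhysioTrace(samples=samples,
                       sampling_rate=float(meta["sampling_rate_hz"]),
                       channel=meta["channel"],
                       trigger_time=float(meta.get("trigger_time_s", 0.0)))


def align_to_scan(trace: PhysioTrace, scan_duration: float) -> PhysioTrace:
    """Crop the trace to [trigger_time, trigger_time + scan_duration]."""
    if trace.trigger_time + scan_duration > trace.duration + 0.5 / trace.sampling_rate:
        raise ValueError(
            f"scan window of {scan_duration:.3f}s starting at trigger "
            f"{trace.trigger_time:.3f}s exceeds the {trace.duration:.3f}s recording")
    i0 = int(round(trace.trigger_time * trace.sampling_rate))
    n = int(round(scan_duration * trace.sampling_rate))
    return replace(trace, samples=trace.samples[i0:i0 + n], trigger_time=0.0)


def trace_spectrum(trace: PhysioTrace) -> Spectrum:
    """Demeaned one-sided magnitude spectrum of the trace on its own grid."""
    return voxel_spectrum(trace.samples, tr=1.0 / trace.sampling_rate,
                          provenance=trace.channel)


def physio_bands(trace: PhysioTrace, params: PeakFindParams | None = None,
                 f_max: float | None = None) -> list[Band]:
    """Identify bands in a physio trace with the standard peak algorithm.

    ``f_max`` optionally restricts the analyzed spectrum (physio sampling
    rates put the Nyquist far above physiological interest; the default 10 Hz
    keeps the Savitzky–Golay window meaningful).
    """
    spec = trace_spectrum(trace)
    f_max = 10.0 if f_max is None else f_max
    keep = spec.grid.frequencies <= f_max
    if keep.sum() >= 5 and keep.sum() < len(spec.grid):
        from .spectra import FrequencyGrid
        grid = FrequencyGrid(delta_f=spec.grid.delta_f,
                             f_max=float(spec.grid.frequencies[keep][-1]),
                             frequencies=spec.grid.frequencies[keep])
        spec = Spectrum(grid=grid, magnitude=spec.magnitude[keep],
                        provenance=spec.provenance, n_samples=spec.n_samples, tr=spec.tr)
    params = params or PeakFindParams()
    adjusted, peaks = identify_peaks(spec, params)
    return bands_from_peaks(adjusted, peaks, region=trace.channel)


def band_overlap(mri_bands: list[Band], physio_bands_: list[Band],
                 channel: str = "") -> BandOverlapReport:
    """Cross all MRI/physio band pairs and keep those whose [f_lo, f_hi]
    intervals intersect.

    overlap_fraction is the Jaccard ratio |intersection| / |union| of the two
    intervals.
    """
    pairs = []
    for mb in mri_bands:
        for pb in physio_bands_:
            lo = max(mb.f_lo, pb.f_lo)
            hi = min(mb.f_hi, pb.f_hi)
            if hi <= lo:
                continue
            union = max(mb.f_hi, pb.f_hi) - min(mb.f_lo, pb.f_lo)
            frac = (hi - lo) / union if union > 0 else 1.0
            pairs.append(OverlapPair(mri_band=mb, physio_band=pb, overlap_lo=lo,
                                     overlap_hi=hi, overlap_fraction=frac,
                                     channel=channel or pb.region))
    return BandOverlapReport(pairs=pairs)
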