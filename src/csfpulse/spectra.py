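"""One-sided magnitude spectra of EPI voxel and ROI time series.

Each voxel's time series (T volumes sampled every TR seconds) is demeaned and
Fourier transformed; the one-sided magnitude spectrum lives on the grid
0, Δf, 2Δf, ..., f_max with Δf = 1/(T·TR) and f_max = 1/(2·TR) (for even T;
the largest grid frequency for odd T).  Magnitudes use the amplitude
convention: an on-grid sinusoid of amplitude A contributes magnitude A at its
bin (interior bins scaled by 2/T, DC and Nyquist by 1/T).  ROI spectra average
per-voxel *magnitudes* per frequency — not complex values — so components with
incoherent phases across voxels still add up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image import Image4D, LabelMap

__all__ = [
    "FrequencyGrid",
    "Spectrum",
    "make_frequency_grid",
    "voxel_spectrum",
    "roi_spectrum",
    "region_spectra",
    "magnitude_spectra",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyGrid:
    """One-sided DFT frequency grid: k·Δf for k = 0..⌊T/2⌋."""

    delta_f: float
    f_max: float
    frequencies: np.ndarray

    def __len__(self) -> int:
        return len(self.frequencies)

    def index_of(self, frequency: float, tol: float = 1e-6) -> int:
        """Index of the grid bin at ``frequency``; error if off-grid."""
        k = int(round(frequency / self.delta_f))
        if k < 0 or k >= len(self.frequencies) or abs(self.frequencies[k] - frequency) > tol * max(1.0, self.f_max):
            raise ValueError(f"frequency {frequency} Hz is not on the grid (Δf={self.delta_f})")
        return k


@dataclass
class Spectrum:
    """One-sided magnitude spectrum with provenance.

    ``magnitude`` is non-negative, one value per grid frequency, in the same
    arbitrary units as the time series (amplitude convention).  ``provenance``
    records where the spectrum came from: a voxel index, an ROI/region name,
    ``"whole-brain"``, or a physiological channel.
    """

    grid: FrequencyGrid
    magnitude: np.ndarray
    provenance: str
    n_samples: int
    tr: float

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if len(self.magnitude) != len(self.grid):
            raise ValueError("magnitude length does not match frequency grid")

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frequency_hz": self.grid.frequencies,
            "magnitude": self.magnitude,
            "provenance": self.provenance,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Spectrum":
        """Read a spectrum written by :meth:`to_tsv`.

        The one-sided grid alone cannot distinguish an even from an odd
        original sample count; an even count ``T = 2·(n_bins − 1)`` is
        assumed, which only affects the reported ``n_samples``/``tr``.
        """
        df = pd.read_csv(path, sep="\t")
        f = df["frequency_hz"].to_numpy(dtype=float)
        if len(f) < 2:
            raise ValueError(f"{path}: spectrum needs at least 2 bins")
        delta_f = float(f[1] - f[0])
        n_samples = 2 * (len(f) - 1)
        tr = 1.0 / (delta_f * n_samples)
        grid = FrequencyGrid(delta_f=delta_f, f_max=float(f[-1]), frequencies=f)
        return cls(grid=grid, magnitude=df["magnitude"].to_numpy(dtype=float),
                   provenance=str(df["provenance"].iloc[0]) if "provenance" in df else "file",
                   n_samples=n_samples, tr=tr)


def make_frequency_grid(n_volumes: int, tr: float) -> FrequencyGrid:
    """Frequency grid of a length-``n_volumes`` series sampled every ``tr`` s.

    Δf = 1/(n·TR); f_max = 1/(2·TR) for even n, else the largest grid
    frequency ⌊n/2⌋·Δf.  For 600 volumes at TR 155 ms this gives
    Δf ≈ 0.0108 Hz and f_max ≈ 3.226 Hz.
    """
    if n_volumes < 2:
        raise ValueError(f"need at least 2 volumes, got {n_volumes}")
    if not tr > 0:
        raise ValueError(f"TR must be positive, got {tr}")
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    return FrequencyGrid(delta_f=1.0 / (n_volumes * tr), f_max=float(freqs[-1]), frequencies=freqs)


def _one_sided_magnitude(series: np.ndarray, axis: int = -1,
                         detrend: bool = False) -> np.ndarray:
    """Demeaned one-sided amplitude spectrum along ``axis``.

    Interior bins scaled by 2/T, DC and (even-T) Nyquist by 1/T, so an
    on-grid sinusoid of amplitude A shows magnitude A at its bin.
    ``detrend`` removes a linear trend instead of just the mean.
    """
    series = np.asarray(series, dtype=float)
    t = series.shape[axis]
    if detrend:
        from scipy.signal import detrend as _detrend
        demeaned = _detrend(series, axis=axis, type="linear")
    else:
        demeaned = series - series.mean(axis=axis, keepdims=True)
    mag = np.abs(np.fft.rfft(demeaned, axis=axis)) * (2.0 / t)
    # undo the factor 2 at DC and, for even T, at Nyquist
    sl = [slice(None)] * mag.ndim
    sl[axis] = 0
    mag[tuple(sl)] *= 0.5
    if t % 2 == 0:
        sl[axis] = -1
        mag[tuple(sl)] *= 0.5
    return mag


def magnitude_spectra(series_2d: np.ndarray) -> np.ndarray:
    """Per-row one-sided magnitude spectra of a (n_series, T) array."""
    return _one_sided_magnitude(np.atleast_2d(series_2d), axis=-1)


def voxel_spectrum(series: np.ndarray, tr: float, provenance: str = "voxel",
                   detrend: bool = False) -> Spectrum:
    """Magnitude spectrum of a single time series.

    The temporal mean is removed first, so the DC bin is exactly zero and a
    constant series yields an all-zero spectrum.  ``detrend`` removes a
    linear trend as well (off by default; scanner drift mostly leaks below
    the physiological bands).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError(f"series must be 1D, got shape {series.shape}")
    if len(series) < 2:
        raise ValueError("series needs at least 2 samples")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    grid = make_frequency_grid(len(series), tr)
    mag = _one_sided_magnitude(series, detrend=detrend)
    return Spectrum(grid=grid, magnitude=mag, provenance=provenance,
                    n_samples=len(series), tr=tr)


def roi_spectrum(image: Image4D, mask: np.ndarray, roi_name: str = "roi",
                 detrend: bool = False) -> Spectrum:
    """Per-frequency arithmetic mean of the per-voxel magnitude spectra.

    Averaging magnitudes (not complex coefficients) keeps components whose
    phase varies across voxels from cancelling.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.spatial_shape:
        raise ValueError(f"mask shape {mask.shape} does not match image {image.spatial_shape}")
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError(f"ROI {roi_name!r} selects no voxels")
    series = image.data[mask]  # (n_vox, T)
    mag = _one_sided_magnitude(series, detrend=detrend).mean(axis=0)
    grid = make_frequency_grid(image.n_volumes, image.tr)
    return Spectrum(grid=grid, magnitude=mag, provenance=roi_name,
                    n_samples=image.n_volumes, tr=image.tr)


def region_spectra(image: Image4D, labels: LabelMap) -> dict[str, Spectrum]:
    """One spectrum per labelled region plus a whole-brain spectrum.

    Regions with no voxels are omitted with a logged warning.  The
    whole-brain spectrum averages over all non-background voxels.
    """
    if labels.labels.shape != image.spatial_shape:
        raise ValueError(f"label map shape {labels.labels.shape} does not match image {image.spatial_shape}")
    out: dict[str, Spectrum] = {}
    for region in dict.fromkeys(labels.scheme.values()):  # preserve order, dedupe
        mask = labels.region_mask(region)
        if not mask.any():
            logger.warning("region %r has no voxels; omitted", region)
            continue
        out[region] = roi_spectrum(image, mask, roi_name=region)
    brain = labels.brain_mask()
    if brain.any():
        out["whole-brain"] = roi_spectrum(image, brain, roi_name="whole-brain")
    else:
        logger.warning("label map has no non-background voxels; no whole-brain spectrum")
    return out
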