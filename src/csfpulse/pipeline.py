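"""End-to-end workflow: slab merging and the full analysis run.

``run_pipeline`` composes the modules the way a whole-brain acquisition is
analyzed: region spectra → envelope-normalized peak identification → band
biomarkers → spatial band masks, writing TSV/NIfTI/JSON artifacts plus a run
manifest that suffices to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bandmetrics import bands_from_peaks, bands_to_frame, group_bands, summaries_to_frame, summarize_bands
from .config import PipelineConfig
from .image import Image4D, LabelMap
from .peakfind import PeakFindParams, identify_peaks, peaks_to_frame
from .spatialmaps import band_mask, export_masks
from .spectra import region_spectra, roi_spectrum

__all__ = ["merge_slabs", "run_pipeline"]

logger = logging.getLogger(__name__)


def merge_slabs(slabs: list[Image4D]) -> Image4D:
    """Concatenate axial slabs along the slice axis.

    Slabs must agree in in-plane shape, number of volumes and TR; the merged
    affine is taken from the first slab.  Each slab is acquired in its own
    sequence run, so the merged series is only consistent in the frequency
    domain — per-voxel FFT magnitudes are unaffected by the slab start times.
    """
    if not slabs:
        raise ValueError("no slabs to merge")
    first = slabs[0]
    for i, slab in enumerate(slabs[1:], start=2):
        if slab.data.shape[:2] != first.data.shape[:2] or slab.n_volumes != first.n_volumes:
            raise ValueError(f"slab {i} shape {slab.data.shape} does not match "
                             f"slab 1 shape {first.data.shape}")
        if not np.isclose(slab.tr, first.tr):
            raise ValueError(f"slab {i} TR {slab.tr} does not match slab 1 TR {first.tr}")
    merged = np.concatenate([s.data for s in slabs], axis=2)
    boundaries = np.cumsum([s.data.shape[2] for s in slabs])[:-1]
    logger.info("merged %d slabs into %s; slab boundaries at slices %s",
                len(slabs), merged.shape, list(boundaries))
    return Image4D(data=merged, tr=first.tr, voxel_size=first.voxel_size,
                   affine=first.affine)


def _digest(array: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(array).tobytes()).hexdigest()[:16]


def run_pipeline(image: Image4D, labels: LabelMap | None, config: PipelineConfig,
                 out_dir) -> dict:
    """Run the full spectral analysis and write its artifacts.

    Outputs under ``out_dir``: per-region spectra and per-stage curves
    (TSV), peak and band tables (TSV), cross-region band summaries (TSV),
    band masks (NIfTI, from the whole-volume analysis region), and
    ``manifest.json``.  Deterministic for fixed inputs and config.

    Returns the manifest dictionary (with in-memory results under
    ``"results"``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tr = config.tr or image.tr
    if tr != image.tr:
        image = Image4D(data=image.data, tr=tr, voxel_size=image.voxel_size,
                        affine=image.affine)
    params = config.peakfind if config.peakfind else PeakFindParams.for_tr(tr)

    if labels is not None:
        spectra = region_spectra(image, labels)
    else:
        logger.info("no label map given; analyzing the whole volume only")
        whole = np.ones(image.spatial_shape, dtype=bool)
        spectra = {"whole-volume": roi_spectrum(image, whole, roi_name="whole-volume")}

    all_bands = []
    peak_frames = []
    adjusted_by_region = {}
    for region, spectrum in spectra.items():
        spectrum.to_tsv(out_dir / f"spectrum_{region}.tsv")
        adj, peaks = identify_peaks(spectrum, params)
        adj.to_tsv(out_dir / f"stages_{region}.tsv")
        adjusted_by_region[region] = (adj, peaks)
        peak_frames.append(peaks_to_frame(peaks, provenance=region))
        bands = bands_from_peaks(adj, peaks, region=region,
                                 use_smoothed=config.bands_on_smoothed)
        for band in bands:
            if band.truncated:
                logger.warning("band at %.3f Hz in %s is truncated", band.center_frequency, region)
        all_bands.extend(bands)
        logger.info("region %s: %d final peaks", region, len(peaks))

    peaks_df = pd.concat(peak_frames, ignore_index=True) if peak_frames else peaks_to_frame([])
    peaks_df.to_csv(out_dir / "peaks.tsv", sep="\t", index=False)
    bands_to_frame(all_bands).to_csv(out_dir / "bands.tsv", sep="\t", index=False)

    groups = group_bands(all_bands, tolerance_hz=config.grouping_tolerance_hz)
    summaries = summarize_bands(groups) if groups else []
    summaries_to_frame(summaries).to_csv(out_dir / "band_summaries.tsv", sep="\t", index=False)

    # spatial masks for the bands of the most informative region available
    mask_region = next((r for r in ("csf", "whole-brain", "whole-volume") if r in adjusted_by_region), None)
    masks = []
    if mask_region is not None:
        adj, peaks = adjusted_by_region[mask_region]
        bands = bands_from_peaks(adj, peaks, region=mask_region,
                                 use_smoothed=config.bands_on_smoothed)
        for b in bands:
            masks.append(band_mask(image, b, fraction=config.map_fraction,
                                   sigma=config.map_sigma, power=config.use_power_maps,
                                   mode_2d=config.map_2d))
        export_masks(masks, out_dir / "masks", reference=image)

    manifest = {
        "csfpulse_version": __version__,
        "config": config.to_dict(),
        "tr": tr,
        "n_volumes": image.n_volumes,
        "image_digest": _digest(image.data),
        "labels_digest": _digest(labels.labels) if labels is not None else None,
        "regions": {r: int(len(p[1])) for r, p in adjusted_by_region.items()},
        "n_bands": len(all_bands),
        "mask_region": mask_region,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["results"] = {
        "spectra": spectra,
        "adjusted": adjusted_by_region,
        "bands": all_bands,
        "groups": groups,
        "summaries": summaries,
        "masks": masks,
    }
    return manifest
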