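"""Published per-volunteer CSF band biomarkers used as a worked example.

These are the CSF-region band values (center frequency in Hz, adjusted-peak
magnitude in a.u., area in Hz, 3 dB bandwidth in Hz) reported per volunteer
in the whole-brain 7 T ultrafast-EPI study this method reproduces, grouped by
the study's four frequency bands.  They serve as input data for validating
:func:`csfpulse.bandmetrics.summarize_bands` against the study's printed
cross-volunteer means and standard deviations.
"""

from __future__ import annotations

from .bandmetrics import Band, BandGroup

__all__ = ["reference_csf_band_groups"]

# band label -> list of (subject, frequency_hz, magnitude_au, area_hz, bandwidth_hz)
_CSF_ROWS = {
    "Band 1": [
        ("volunteer-2", 0.318, 0.565, 0.026, 0.056),
        ("volunteer-3", 0.269, 0.597, 0.028, 0.056),
        ("volunteer-4", 0.387, 1.197, 0.054, 0.057),
        ("volunteer-5", 0.333, 0.162, 0.006, 0.043),
        ("volunteer-6", 0.247, 0.450, 0.021, 0.053),
    ],
    "Band 2": [
        ("volunteer-3", 0.516, 0.082, 0.003, 0.043),
        ("volunteer-6", 0.484, 0.073, 0.005, 0.070),
    ],
    "Band 3": [
        ("volunteer-2", 0.822, 0.206, 0.012, 0.065),
        ("volunteer-4", 0.763, 0.496, 0.039, 0.080),
        ("volunteer-5", 0.806, 0.119, 0.006, 0.072),
        ("volunteer-6", 0.914, 0.128, 0.008, 0.074),
    ],
    "Band 4": [
        ("volunteer-2", 1.151, 2.435, 0.142, 0.066),
        ("volunteer-3", 1.312, 1.507, 0.115, 0.085),
        ("volunteer-4", 1.151, 2.048, 0.169, 0.103),
        ("volunteer-5", 1.129, 1.374, 0.095, 0.068),
        ("volunteer-6", 1.226, 1.369, 0.075, 0.068),
    ],
}


def reference_csf_band_groups() -> list[BandGroup]:
    """The reference CSF bands as :class:`BandGroup` objects.

    A half-bandwidth interval is reconstructed around each center frequency;
    only the four tabulated metrics matter for summarization.
    """
    groups = []
    for label, rows in _CSF_ROWS.items():
        bands = [Band(center_frequency=f, magnitude=m, f_lo=f - bw / 2, f_hi=f + bw / 2,
                      bandwidth=bw, area=a, region="csf", subject=subj)
                 for subj, f, m, a, bw in rows]
        groups.append(BandGroup(label=label, bands=bands))
    return groups
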