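"""Seeded synthetic 4D EPI phantom with matched physiological traces.

The phantom emulates the statistical structure the analysis pipeline assumes
in real ultrafast-EPI data:

* three concentric ellipsoidal compartments — a bright CSF core (the
  ventricles), cerebral white matter around it, and a cortical grey-matter
  rim — on a zero background;
* region-dependent sinusoidal pulsation components near the respiratory
  (~0.3 Hz), cardiac (~1.2 Hz) and first cardiac-harmonic (~2.4 Hz)
  frequencies, strongest in CSF, weaker in cGM, weakest in cWM;
* a slow linear drift per region;
* per-voxel colored (1/f^α) noise whose magnitude-spectrum floor decreases
  with frequency, reproducing the acquisition-characteristic decreasing
  lower envelope seen in real spectra;
* Rician magnitude noise: observed = sqrt((S + ε₁)² + ε₂²) with independent
  zero-mean Gaussian ε of standard deviation ``rician_sigma``.

Everything is deterministic for a fixed seed.  Component frequencies are
snapped to the FFT grid by default so that ground-truth recovery is defined
to within one frequency bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import Image4D, LabelMap, DEFAULT_LABEL_SCHEME
from .physio import PhysioTrace

__all__ = ["PulsationComponent", "PhantomSpec", "PhantomTruth",
           "make_phantom", "make_physio_traces"]

REGIONS = ("csf", "cgm", "cwm")


@dataclass(frozen=True)
class PulsationComponent:
    """One sinusoidal pulsation: frequency, per-region amplitude fraction of
    the regional baseline, phase, and physiological rate variability.

    ``linewidth_hz`` is the standard deviation of the slow wander of the
    instantaneous frequency (heart-rate / breathing-rate variability).  It
    spreads the spectral line over a few bins — matching the finite 3 dB
    bandwidths seen in vivo — instead of an unphysical single-bin spike.
    Zero gives a pure sinusoid.
    """

    name: str
    frequency: float
    amplitudes: dict[str, float]  # region -> fraction of baseline
    phase: float = 0.0
    linewidth_hz: float = 0.0


def _default_components() -> list[PulsationComponent]:
    # CSF-dominant amplitudes; harmonic one third of the cardiac fraction.
    # Linewidths approximate in-vivo rate variability (bands of ~0.05-0.08 Hz).
    return [
        PulsationComponent("respiratory", 0.3,
                           {"csf": 0.015, "cgm": 0.008, "cwm": 0.004},
                           phase=0.0, linewidth_hz=0.045),
        PulsationComponent("cardiac", 1.2,
                           {"csf": 0.030, "cgm": 0.010, "cwm": 0.004},
                           phase=1.0, linewidth_hz=0.050),
        PulsationComponent("harmonic", 2.4,
                           {"csf": 0.010, "cgm": 0.0033, "cwm": 0.0013},
                           phase=2.0, linewidth_hz=0.070),
    ]


@dataclass
class PhantomSpec:
    """Ground-truth description of one synthetic dataset.

    Geometry: CSF ellipsoid semi-axes as fractions of the field of view,
    inside a white-matter compartment, ringed by a grey-matter shell; the
    outer "brain" ellipsoid spans ``brain_fraction`` of each dimension.
    """

    shape: tuple[int, int, int, int] = (64, 64, 20, 600)
    tr: float = 0.155
    components: list[PulsationComponent] = field(default_factory=_default_components)
    baselines: dict[str, float] = field(default_factory=lambda: {"csf": 1400.0, "cgm": 900.0, "cwm": 700.0})
    drift_slope: dict[str, float] = field(default_factory=lambda: {"csf": -0.05, "cgm": -0.04, "cwm": -0.03})
    rician_sigma: float = 2.5
    colored_noise_sigma: float = 2.0
    envelope_exponent: float = 0.6
    csf_fraction: tuple[float, float, float] = (0.35, 0.45, 0.50)
    gm_shell_fraction: float = 0.80  # inner edge of the cGM rim, rel. to brain
    brain_fraction: float = 0.90
    snap_to_grid: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr)
        for c in self.components:
            if c.frequency >= nyquist:
                raise ValueError(f"component {c.name!r} at {c.frequency} Hz is at or above "
                                 f"the Nyquist frequency {nyquist:.3f} Hz")
            if any(a < 0 for a in c.amplitudes.values()):
                raise ValueError(f"component {c.name!r} has a negative amplitude fraction")
        if self.rician_sigma < 0 or self.colored_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")

    def component(self, name: str) -> PulsationComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass
class PhantomTruth:
    """What the generator actually put into the data."""

    frequencies: dict[str, float]          # component name -> (snapped) frequency
    amplitudes: dict[str, dict[str, float]]  # component name -> region -> absolute amplitude (a.u.)
    region_masks: dict[str, np.ndarray]
    spec: PhantomSpec


def _ellipsoid(shape3, semi_axes) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape3]
    grids = np.ogrid[tuple(slice(0, s) for s in shape3)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def _geometry(spec: PhantomSpec) -> dict[str, np.ndarray]:
    shape3 = spec.shape[:3]
    brain_axes = [spec.brain_fraction * s / 2.0 for s in shape3]
    gm_inner_axes = [spec.gm_shell_fraction * a for a in brain_axes]
    csf_axes = [f * s / 2.0 for f, s in zip(spec.csf_fraction, shape3)]
    brain = _ellipsoid(shape3, brain_axes)
    gm_inner = _ellipsoid(shape3, gm_inner_axes)
    csf = _ellipsoid(shape3, csf_axes)
    return {"csf": csf, "cwm": gm_inner & ~csf, "cgm": brain & ~gm_inner}


def _snapped_frequency(freq: float, n: int, tr: float) -> float:
    delta_f = 1.0 / (n * tr)
    return round(freq / delta_f) * delta_f


def _colored_noise(rng: np.random.Generator, n_series: int, n_t: int, tr: float,
                   sigma: float, exponent: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit-free std ``sigma``."""
    white = rng.standard_normal((n_series, n_t))
    if sigma == 0:
        return np.zeros((n_series, n_t))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_t, d=tr)
    shaping = np.ones_like(f)
    nonzero = f > 0
    shaping[nonzero] = f[nonzero] ** (-exponent / 2.0)
    shaping[0] = shaping[1]  # keep DC finite; removed later by demeaning anyway
    spec *= shaping
    colored = np.fft.irfft(spec, n=n_t, axis=-1)
    colored_std = colored.std()
    if colored_std > 0:
        colored *= sigma / colored_std
    return colored


def _component_waveform(c: PulsationComponent, center: float, tvec: np.ndarray,
                        delta_f: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude narrowband waveform of one pulsation component.

    A zero linewidth gives the pure sinusoid sin(2π·center·t + φ).  A
    positive linewidth models physiological rate variability as a comb of
    sub-lines at center + j·Δf with Gaussian weights of standard deviation
    ``linewidth_hz`` and random (seeded) phases: a stationary narrowband
    process whose magnitude spectrum is a smooth unimodal line peaking
    exactly at the center bin.  Weights sum to one, so the line integrates
    to the same total magnitude as the pure sinusoid.
    """
    if c.linewidth_hz == 0:
        return np.sin(2 * np.pi * center * tvec + c.phase)
    k = int(np.ceil(3.0 * c.linewidth_hz / delta_f))
    offsets = np.arange(-k, k + 1)
    weights = np.exp(-0.5 * (offsets * delta_f / c.linewidth_hz) ** 2)
    # keep sub-lines at positive frequencies
    valid = (center + offsets * delta_f) > 0
    offsets, weights = offsets[valid], weights[valid]
    weights /= weights.sum()
    phases = rng.uniform(0, 2 * np.pi, size=len(offsets))
    phases[offsets == 0] = c.phase
    wave = np.zeros_like(tvec)
    for off, w, ph in zip(offsets, weights, phases):
        wave += w * np.sin(2 * np.pi * (center + off * delta_f) * tvec + ph)
    return wave


def make_phantom(spec: PhantomSpec) -> tuple[Image4D, LabelMap, PhantomTruth]:
    """Generate the 4D image, its label map, and the ground-truth record.

    The noiseless signal of a voxel in region r is
    ``S(t) = B_r · [1 + Σ_k a_{k,r} · w_k(t)] + d_r · t`` where w_k is the
    component's unit-amplitude narrowband waveform (shared across regions —
    one heart, one pair of lungs).  Per-voxel colored noise is added before
    the Rician magnitude transformation.
    """
    x, y, z, t = spec.shape
    tvec = np.arange(t) * spec.tr
    delta_f = 1.0 / (t * spec.tr)
    masks = _geometry(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2024]))

    frequencies = {}
    amplitudes: dict[str, dict[str, float]] = {}
    waveforms: dict[str, np.ndarray] = {}
    for c in spec.components:
        f_k = _snapped_frequency(c.frequency, t, spec.tr) if spec.snap_to_grid else c.frequency
        frequencies[c.name] = f_k
        amplitudes[c.name] = {r: spec.baselines[r] * c.amplitudes.get(r, 0.0) for r in REGIONS}
        waveforms[c.name] = _component_waveform(c, f_k, tvec, delta_f, rng)

    # regional time courses (everything except per-voxel noise is region-wide)
    regional = {}
    for r in REGIONS:
        course = np.full(t, spec.baselines[r])
        for c in spec.components:
            course = course + spec.baselines[r] * c.amplitudes.get(r, 0.0) * waveforms[c.name]
        course = course + spec.drift_slope.get(r, 0.0) * tvec
        regional[r] = course

    data = np.zeros(spec.shape, dtype=np.float32)
    for r in REGIONS:
        data[masks[r]] = regional[r].astype(np.float32)

    brain = masks["csf"] | masks["cgm"] | masks["cwm"]
    n_brain = int(brain.sum())
    if spec.colored_noise_sigma > 0 and n_brain:
        # chunk the per-voxel colored noise to bound memory
        idx = np.flatnonzero(brain.reshape(-1))
        flat = data.reshape(-1, t)
        step = max(1, 2_000_000 // t)
        for i0 in range(0, n_brain, step):
            sel = idx[i0:i0 + step]
            flat[sel] += _colored_noise(rng, len(sel), t, spec.tr,
                                        spec.colored_noise_sigma,
                                        spec.envelope_exponent).astype(np.float32)

    if spec.rician_sigma > 0:
        e1 = rng.standard_normal(spec.shape, dtype=np.float32) * spec.rician_sigma
        e2 = rng.standard_normal(spec.shape, dtype=np.float32) * spec.rician_sigma
        data = np.sqrt((data + e1) ** 2 + e2 ** 2)
        del e1, e2

    labels = np.zeros(spec.shape[:3], dtype=np.int16)
    name_to_label = {name: lab for lab, name in DEFAULT_LABEL_SCHEME.items()}
    for r in REGIONS:
        labels[masks[r]] = name_to_label[r]

    voxel_size = (2.0, 2.0, 2.0)
    affine = np.diag([*voxel_size, 1.0])
    image = Image4D(data=data, tr=spec.tr, voxel_size=voxel_size, affine=affine)
    labelmap = LabelMap(labels=labels)
    truth = PhantomTruth(frequencies=frequencies, amplitudes=amplitudes,
                         region_masks=masks, spec=spec)
    return image, labelmap, truth


def make_physio_traces(spec: PhantomSpec, sampling_rate: float = 250.0,
                       trigger_time: float = 10.0, tail: float = 5.0,
                       noise_sigma: float = 0.05) -> tuple[PhysioTrace, PhysioTrace]:
    """Matched ECG and respiration-belt recordings.

    Respiration is a sinusoid at the phantom's respiratory frequency; the ECG
    is a train of narrow Gaussian pulses at the cardiac frequency (R-waves,
    whose spectrum has lines at the rate and its harmonics).  The recording
    covers ``trigger_time`` seconds of pre-scan, the scan itself, and a short
    tail; the scan onset is stored as the trigger timestamp.
    """
    resp_f = spec.component("respiratory").frequency
    card_f = spec.component("cardiac").frequency
    if spec.snap_to_grid:
        t_n = spec.shape[3]
        resp_f = _snapped_frequency(resp_f, t_n, spec.tr)
        card_f = _snapped_frequency(card_f, t_n, spec.tr)
    if sampling_rate <= 2 * max(resp_f, card_f):
        raise ValueError("sampling_rate must exceed twice the highest component frequency")
    scan_duration = spec.shape[3] * spec.tr
    duration = trigger_time + scan_duration + tail
    n = int(round(duration * sampling_rate))
    tvec = np.arange(n) / sampling_rate
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 77]))

    respiration = np.sin(2 * np.pi * resp_f * tvec)
    respiration += noise_sigma * rng.standard_normal(n)

    # Gaussian R-wave pulses, width ~25 ms, one per cardiac period
    pulse_width = 0.025
    phase = (tvec * card_f) % 1.0
    dist = np.minimum(phase, 1.0 - phase) / card_f  # time to nearest beat
    ecg = np.exp(-0.5 * (dist / pulse_width) ** 2)
    ecg += noise_sigma * rng.standard_normal(n)

    resp_trace = PhysioTrace(samples=respiration, sampling_rate=sampling_rate,
                             channel="respiration", trigger_time=trigger_time)
    ecg_trace = PhysioTrace(samples=ecg, sampling_rate=sampling_rate,
                            channel="ecg", trigger_time=trigger_time)
    return ecg_trace, resp_trace
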