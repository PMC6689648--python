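"""Acoustic front-end: raw audio to strings of MFCC vectors.

Stages: (1) frame-wise ratio of song-band (500-1500 Hz) to total-band
energy, (2) song regions as maximal runs of frames with ratio above
threshold lasting at least a minimum duration, (3) a wideband envelope as
the summed magnitudes of Hilbert analytic signals over six bandpass
channels, (4) syllable-like peaks as sliding-window maxima passing a
prominence test and a refractory rule, (5) one 13-coefficient MFCC vector
per peak, grouped into strings by the region containing each peak.

Filter and MFCC internals not fixed by the constants above: 4th-order
Butterworth bands applied forward-backward (zero phase), Hann taper on the
DFT frames, a 26-filter mel bank over 0-8000 Hz with coefficients c0-c12,
no pre-emphasis, and a log floor for silent windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft, rfftfreq
from scipy.io import wavfile
from scipy.signal import butter, hilbert, sosfiltfilt

from .data import FeatureString, SongRegion

logger = logging.getLogger(__name__)

__all__ = [
    "AudioSignal",
    "FrameRatioSeries",
    "WidebandEnvelope",
    "PeakEvent",
    "DEFAULT_BAND_CUTOFFS",
    "read_wav",
    "write_wav",
    "compute_band_energy_ratio",
    "detect_song_regions",
    "compute_wideband_envelope",
    "detect_peaks",
    "extract_mfcc",
    "build_strings",
    "preprocess",
]

#: Six auditory-model bands (7 cutoffs).
DEFAULT_BAND_CUTOFFS = (80.0, 260.0, 600.0, 1240.0, 2420.0, 4650.0, 7999.0)


@dataclass
class AudioSignal:
    """Mono audio samples at a fixed rate (samples kept on their native
    amplitude scale; integer PCM is converted to float without rescaling,
    so prominence thresholds are in raw sample units)."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class FrameRatioSeries:
    """Per-frame song-band / total-band energy ratio; times are frame starts."""

    frame_times: np.ndarray
    r: np.ndarray
    window: float
    hop: float


@dataclass
class WidebandEnvelope:
    values: np.ndarray
    rate: float


@dataclass(frozen=True)
class PeakEvent:
    time: float
    envelope_value: float


def read_wav(path, channel: int = 0) -> AudioSignal:
    """Read a WAV file; multi-channel input selects one channel (default the
    first, as in the study's recordings)."""
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        data = data[:, channel]
    return AudioSignal(samples=data.astype(float), rate=float(rate))


def write_wav(path, signal: AudioSignal) -> None:
    wavfile.write(path, int(signal.rate), signal.samples.astype(np.float32))


# ---------------------------------------------------------------------------
# song-region detection
# ---------------------------------------------------------------------------

def compute_band_energy_ratio(signal: AudioSignal, window: float = 0.020,
                              hop: float = 0.010,
                              song_band: tuple[float, float] = (500.0, 1500.0),
                              total_band: tuple[float, float] = (0.0, 8000.0),
                              ) -> FrameRatioSeries:
    """Per-frame ratio of song-band to total-band spectral energy.

    Frames of ``window`` seconds every ``hop`` seconds, Hann-tapered;
    energy is the sum of squared DFT magnitudes inside each band (band
    edges inclusive).  Zero-energy frames yield r = 0 by convention.
    """
    if not (window > hop > 0):
        raise ValueError("need window > hop > 0")
    nyq = signal.rate / 2
    if not (0 <= total_band[0] <= song_band[0] < song_band[1] <= total_band[1] <= nyq):
        raise ValueError(f"need song_band within total_band within [0, {nyq}]")
    nwin = int(round(window * signal.rate))
    nhop = int(round(hop * signal.rate))
    x = signal.samples
    if len(x) < nwin:
        return FrameRatioSeries(np.empty(0), np.empty(0), window, hop)
    starts = np.arange(0, len(x) - nwin + 1, nhop)
    taper = np.hanning(nwin)
    freqs = rfftfreq(nwin, d=1.0 / signal.rate)
    in_song = (freqs >= song_band[0]) & (freqs <= song_band[1])
    in_total = (freqs >= total_band[0]) & (freqs <= total_band[1])
    r = np.zeros(len(starts))
    for i, s0 in enumerate(starts):
        spec = np.abs(rfft(x[s0:s0 + nwin] * taper)) ** 2
        tot = spec[in_total].sum()
        if tot > 0:
            r[i] = spec[in_song].sum() / tot
    return FrameRatioSeries(frame_times=starts / signal.rate, r=r,
                            window=window, hop=hop)


def detect_song_regions(ratios: FrameRatioSeries, threshold: float = 0.6,
                        min_duration: float = 0.5) -> list[SongRegion]:
    """Maximal runs of frames with r > threshold spanning >= min_duration.

    A region spans from the first qualifying frame's start to the last
    qualifying frame's end (start + window), half-open in seconds.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    above = ratios.r > threshold
    regions: list[SongRegion] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            start = ratios.frame_times[i]
            end = ratios.frame_times[j] + ratios.window
            if end - start >= min_duration:
                regions.append(SongRegion(start, end))
            i = j + 1
        else:
            i += 1
    return regions


# ---------------------------------------------------------------------------
# wideband envelope & peaks
# ---------------------------------------------------------------------------

def compute_wideband_envelope(signal: AudioSignal,
                              cutoffs=DEFAULT_BAND_CUTOFFS) -> WidebandEnvelope:
    """Sum of narrowband Hilbert-envelope magnitudes over the band stack.

    Each band is a 4th-order Butterworth bandpass applied forward-backward
    (zero phase, so peak timing is preserved).
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if len(cutoffs) < 2:
        raise ValueError("need at least 2 cutoff frequencies")
    if np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoffs must be strictly increasing")
    nyq = signal.rate / 2
    if cutoffs[0] <= 0 or cutoffs[-1] > nyq:
        raise ValueError(f"cutoffs must lie in (0, {nyq}]")
    env = np.zeros_like(signal.samples)
    hi_cap = 0.999 * nyq  # butter() rejects the exact Nyquist edge
    for lo, hi in zip(cutoffs[:-1], cutoffs[1:]):
        sos = butter(4, [lo, min(hi, hi_cap)], btype="bandpass", fs=signal.rate,
                     output="sos")
        band = sosfiltfilt(sos, signal.samples)
        env += np.abs(hilbert(band))
    return WidebandEnvelope(values=env, rate=signal.rate)


def detect_peaks(envelope: WidebandEnvelope, search_window: float = 0.300,
                 hop: float = 0.010, min_prominence: float = 1.0,
                 refractory: float = 0.150) -> list[PeakEvent]:
    """Sliding-window argmax candidates filtered by prominence and a
    refractory rule.

    A candidate is the maximum of each ``search_window`` slid by ``hop``
    (identical candidate times collapsed; within-window ties break to the
    earliest sample).  An argmax landing on a window edge is not a local
    peak of the envelope — only interior maxima qualify (otherwise a rising
    slope clipped by a window boundary would claim the refractory slot of
    the true apex that follows).  A candidate is accepted iff its height
    minus the window minimum reaches ``min_prominence`` in at least one
    window it wins, and no previously *accepted* peak lies within the
    preceding ``refractory`` interval.
    """
    if not (search_window > hop > 0):
        raise ValueError("need search_window > hop > 0")
    if refractory < 0:
        raise ValueError("refractory must be >= 0")
    v = envelope.values
    nwin = int(round(search_window * envelope.rate))
    nhop = int(round(hop * envelope.rate))
    if len(v) == 0:
        return []
    nwin = min(nwin, len(v))
    prominence: dict[int, float] = {}
    for s0 in range(0, len(v) - nwin + 1, nhop):
        seg = v[s0:s0 + nwin]
        k = int(np.argmax(seg))
        if k == 0 or k == nwin - 1:
            continue  # slope clipped by the window boundary, not a peak
        c = s0 + k
        prom = float(v[c] - seg.min())
        if prom > prominence.get(c, -np.inf):
            prominence[c] = prom
    accepted: list[PeakEvent] = []
    last_t = -np.inf
    for c in sorted(prominence):
        t = c / envelope.rate
        if prominence[c] >= min_prominence and t - last_t >= refractory:
            accepted.append(PeakEvent(time=t, envelope_value=float(v[c])))
            last_t = t
    return accepted


# ---------------------------------------------------------------------------
# MFCC extraction
# ---------------------------------------------------------------------------

def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, nfft: int, rate: float,
                    fmin: float, fmax: float) -> np.ndarray:
    edges = _mel_inv(np.linspace(_mel(fmin), _mel(fmax), n_filters + 2))
    freqs = rfftfreq(nfft, d=1.0 / rate)
    bank = np.zeros((n_filters, len(freqs)))
    for m in range(n_filters):
        lo, mid, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (freqs - lo) / (mid - lo)
        down = (hi - freqs) / (hi - mid)
        bank[m] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def extract_mfcc(signal: AudioSignal, peaks: list[PeakEvent],
                 window: float = 0.100, n_coeff: int = 13,
                 n_filters: int = 26, fmax: float | None = None,
                 log_floor: float = 1e-10) -> list[np.ndarray]:
    """One MFCC vector per peak, over [peak, peak + window).

    Windows overrunning the signal end are zero-padded.  The cepstrum is
    the orthonormal DCT-II of the floored log mel-filterbank energies of
    the Hann-tapered segment; coefficients c0..c(n_coeff-1) are returned,
    so a pure amplitude scaling moves only c0.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    nwin = int(round(window * signal.rate))
    fmax = fmax if fmax is not None else signal.rate / 2
    bank = _mel_filterbank(n_filters, nwin, signal.rate, 0.0, fmax)
    taper = np.hanning(nwin)
    out = []
    for p in peaks:
        i0 = int(round(p.time * signal.rate))
        if not (0 <= i0 < len(signal.samples)):
            raise ValueError(f"peak at {p.time:.3f}s lies outside the signal")
        seg = signal.samples[i0:i0 + nwin]
        if len(seg) < nwin:
            seg = np.pad(seg, (0, nwin - len(seg)))
        power = np.abs(rfft(seg * taper)) ** 2
        logmel = np.log(np.maximum(bank @ power, log_floor))
        out.append(dct(logmel, type=2, norm="ortho")[:n_coeff])
    return out


# ---------------------------------------------------------------------------
# string assembly & end-to-end
# ---------------------------------------------------------------------------

def build_strings(regions: list[SongRegion], peaks: list[PeakEvent],
                  vectors: list[np.ndarray],
                  id_prefix: str = "str") -> list[FeatureString]:
    """Group MFCC vectors into one string per region containing >= 1 peak.

    Peaks outside every region are discarded (count logged); vectors must
    align one-to-one with peaks.
    """
    if len(vectors) != len(peaks):
        raise ValueError("vectors must align one-to-one with peaks")
    buckets: dict[int, list[int]] = {i: [] for i in range(len(regions))}
    discarded = 0
    for pi, p in enumerate(sorted(range(len(peaks)), key=lambda i: peaks[i].time)):
        t = peaks[p].time
        for ri, reg in enumerate(regions):
            if reg.contains(t):
                buckets[ri].append(p)
                break
        else:
            discarded += 1
    if discarded:
        logger.info("discarded %d peak(s) outside all song regions", discarded)
    strings = []
    for ri, idxs in buckets.items():
        if not idxs:
            continue
        strings.append(FeatureString(
            string_id=f"{id_prefix}{len(strings):05d}",
            vectors=np.stack([vectors[i] for i in idxs]),
            region=regions[ri],
            peak_times=[peaks[i].time for i in idxs]))
    return strings


def preprocess(signal: AudioSignal, *, window: float = 0.020, hop: float = 0.010,
               song_band=(500.0, 1500.0), total_band=(0.0, 8000.0),
               region_threshold: float = 0.6, min_region_duration: float = 0.5,
               band_cutoffs=DEFAULT_BAND_CUTOFFS, search_window: float = 0.300,
               peak_hop: float = 0.010, min_prominence: float = 1.0,
               refractory: float = 0.150, mfcc_window: float = 0.100,
               n_coeff: int = 13, id_prefix: str = "str",
               ) -> tuple[list[FeatureString], dict]:
    """Full front-end pipeline; returns (strings, run summary)."""
    ratios = compute_band_energy_ratio(signal, window, hop, song_band, total_band)
    regions = detect_song_regions(ratios, region_threshold, min_region_duration)
    env = compute_wideband_envelope(signal, band_cutoffs)
    peaks = detect_peaks(env, search_window, peak_hop, min_prominence, refractory)
    vectors = extract_mfcc(signal, peaks, mfcc_window, n_coeff)
    in_any = sum(any(r.contains(p.time) for r in regions) for p in peaks)
    crossing = sum(
        any(r.contains(p.time) and p.time + mfcc_window > r.end for r in regions)
        for p in peaks)
    if crossing:
        logger.info("%d MFCC window(s) cross a region boundary", crossing)
    strings = build_strings(regions, peaks, vectors, id_prefix)
    summary = {
        "n_frames": len(ratios.r),
        "n_regions": len(regions),
        "n_peaks": len(peaks),
        "n_peaks_in_regions": int(in_any),
        "n_peaks_discarded": len(peaks) - int(in_any),
        "n_mfcc_windows_crossing_region_end": int(crossing),
        "n_strings": len(strings),
    }
    return strings, summary
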