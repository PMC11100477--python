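"""Spectrogram computation, F0 tracking and acoustic feature measurement.

Parameterizations follow standard bioacoustic practice for long-call
analysis: a 512-point (~92.9 ms at the canonical 5512.5 Hz rate) Hann
window with 90% overlap for measurement spectrograms, a 50 ms / 50%
overlap window for embedding spectrograms, F0 tracked as the dominant
spectral peak in a 50–1500 Hz band with an 85% relative amplitude gate,
and energy-distribution features (center and quartile frequencies)
computed from the power spectrum summed over frames within a selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .types import F0Contour, PulseAnnotation

DB_FLOOR = -120.0


@dataclass
class Spectrogram:
    """Power spectrogram in dB (time x frequency)."""

    magnitudes_db: np.ndarray  # (n_frames, n_bins)
    frame_times: np.ndarray
    bin_freqs: np.ndarray
    window_s: float
    overlap_frac: float

    @property
    def bin_spacing(self) -> float:
        return float(self.bin_freqs[1] - self.bin_freqs[0])

    def power(self) -> np.ndarray:
        """Linear power, inverting the 10*log10 scaling."""
        return 10.0 ** (self.magnitudes_db / 10.0)


def compute_spectrogram(
    audio: np.ndarray,
    sample_rate: float,
    n_fft: int = 512,
    window_kind: str = "hann",
    overlap_frac: float = 0.9,
    db_floor: float = DB_FLOOR,
) -> Spectrogram:
    """Short-time power spectrogram with dB conversion via ``10*log10``.

    Raises if the audio is shorter than one analysis window.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.size < n_fft:
        raise ValueError(
            f"audio ({audio.size} samples) shorter than one window ({n_fft})")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError(f"overlap_frac must be in [0, 1) (got {overlap_frac})")
    noverlap = int(round(n_fft * overlap_frac))
    freqs, times, sxx = signal.spectrogram(
        audio, fs=sample_rate, window=signal.get_window(window_kind, n_fft),
        nperseg=n_fft, noverlap=noverlap, nfft=n_fft, mode="psd",
        detrend=False)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(sxx.T)
    db = np.maximum(db, db_floor)
    return Spectrogram(
        magnitudes_db=db, frame_times=times, bin_freqs=freqs,
        window_s=n_fft / sample_rate, overlap_frac=overlap_frac)


def spectral_resolution(
    window_s: float,
    overlap_frac: float = 0.9,
    n_fft: int = 512,
) -> dict[str, float]:
    """Measurement precision implied by a window length and overlap.

    ``bin_spacing`` is the DFT bin spacing when ``n_fft`` samples span
    ``window_s`` seconds (i.e., 1/window_s for an un-padded transform);
    ``hop_s`` the frame advance; ``hann_3db_bw`` the 3 dB bandwidth of a
    Hann window, 1.44/window_s.
    """
    if window_s <= 0:
        raise ValueError(f"window_s must be positive (got {window_s})")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError(f"overlap_frac must be in [0, 1) (got {overlap_frac})")
    implied_sr = n_fft / window_s
    return {
        "bin_spacing": implied_sr / n_fft,
        "hop_s": window_s * (1.0 - overlap_frac),
        "hann_3db_bw": 1.44 / window_s,
    }


def extract_midpoint_clip(
    audio: np.ndarray,
    annotation: PulseAnnotation,
    sample_rate: float,
    clip_s: float = 0.9,
) -> np.ndarray:
    """Fixed-duration clip centered at the temporal midpoint of a pulse.

    The clip duration is fixed irrespective of the selection duration, so
    short pulses are returned with flanking audio; spans beyond the
    recording are zero-padded. Raises if the annotation lies entirely
    outside the recording.
    """
    audio = np.asarray(audio, dtype=float)
    n = audio.size
    rec_dur = n / sample_rate
    if annotation.begin_time >= rec_dur or annotation.end_time <= 0:
        raise ValueError(
            f"annotation [{annotation.begin_time}, {annotation.end_time}) lies "
            f"outside recording of duration {rec_dur:.3f} s")
    n_clip = int(round(clip_s * sample_rate))
    start = int(round(annotation.midpoint * sample_rate)) - n_clip // 2
    out = np.zeros(n_clip)
    src_lo, src_hi = max(start, 0), min(start + n_clip, n)
    if src_hi > src_lo:
        out[src_lo - start:src_hi - start] = audio[src_lo:src_hi]
    return out


def track_f0(
    spectrogram: Spectrogram,
    band: tuple[float, float] = (50.0, 1500.0),
    amp_threshold: float = 0.85,
    tonality_ratio: float = 10.0,
) -> F0Contour:
    """Track F0 as the dominant in-band spectral peak per frame.

    A frame is voiced when (a) its in-band peak amplitude reaches
    ``amp_threshold`` times the maximum in-band frame amplitude of the
    whole clip (relative amplitude gate) and (b) the peak power exceeds
    ``tonality_ratio`` times the frame's mean in-band power — a tonality
    gate that rejects broadband noise, whose peak-to-mean power ratio
    stays well below that of a harmonic sound concentrated in one bin.
    Unvoiced frames are NaN.
    """
    lo, hi = band
    freqs = spectrogram.bin_freqs
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(
            f"band {band} outside spectrogram range ({freqs[0]:.1f}-{freqs[-1]:.1f} Hz)")
    sel = (freqs >= lo) & (freqs <= hi)
    power = spectrogram.power()[:, sel]
    amp = np.sqrt(power)
    peak_amp = amp.max(axis=1)
    ref = peak_amp.max()
    voiced = peak_amp >= amp_threshold * ref if ref > 0 else np.zeros(len(peak_amp), bool)
    with np.errstate(invalid="ignore"):
        voiced &= power.max(axis=1) >= tonality_ratio * power.mean(axis=1)
    peak_freq = freqs[sel][np.argmax(amp, axis=1)]
    f0 = np.where(voiced, peak_freq, np.nan)
    return F0Contour(frame_times=spectrogram.frame_times, f0_hz=f0,
                     band=band, amp_threshold=amp_threshold)


def _energy_quantile_freq(spectrum: np.ndarray, freqs: np.ndarray, frac: float) -> float:
    """Smallest bin frequency at which cumulative energy reaches ``frac``."""
    cum = np.cumsum(spectrum)
    total = cum[-1]
    idx = int(np.searchsorted(cum, frac * total))
    return float(freqs[min(idx, len(freqs) - 1)])


def measure_features(
    audio: np.ndarray,
    annotation: PulseAnnotation,
    sample_rate: float,
    n_fft: int = 512,
    overlap_frac: float = 0.9,
    f0_band: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Measure the core acoustic features of one annotated pulse.

    Energy-distribution features (peak, center, quartile frequencies) are
    computed from the power spectrum summed over frames, restricted to the
    selection's frequency band; ``mean_peak_freq`` averages the per-frame
    peak frequency; F0 extrema come from :func:`track_f0` on the selection.
    All features are time/frequency statistics, hence invariant to global
    amplitude scaling of the audio.
    """
    audio = np.asarray(audio, dtype=float)
    i0 = int(round(annotation.begin_time * sample_rate))
    i1 = int(round(annotation.end_time * sample_rate))
    clip = audio[max(i0, 0):max(i1, 0)]
    spec = compute_spectrogram(clip, sample_rate, n_fft=n_fft,
                               overlap_frac=overlap_frac)
    freqs = spec.bin_freqs
    sel = (freqs >= annotation.low_freq) & (freqs <= annotation.high_freq)
    power = spec.power()[:, sel]
    floor_power = 10.0 ** (DB_FLOOR / 10.0)
    if not sel.any() or power.sum() <= 1.01 * power.size * floor_power:
        raise ValueError(
            f"selection band ({annotation.low_freq}-{annotation.high_freq} Hz) "
            "contains no energy")
    fsel = freqs[sel]
    summed = power.sum(axis=0)

    peak_freq = float(fsel[int(np.argmax(summed))])
    center = _energy_quantile_freq(summed, fsel, 0.5)
    q1 = _energy_quantile_freq(summed, fsel, 0.25)
    q3 = _energy_quantile_freq(summed, fsel, 0.75)
    mean_peak = float(np.mean(fsel[np.argmax(power, axis=1)]))

    band = f0_band
    if band is None:
        band = (max(50.0, float(freqs[0])), min(1500.0, float(freqs[-1])))
    contour = track_f0(spec, band=band)
    return {
        "duration": annotation.duration,
        "peak_freq": peak_freq,
        "center_freq": center,
        "mean_peak_freq": mean_peak,
        "freq_q1": q1,
        "freq_q3": q3,
        "f0_min": contour.f0_min,
        "f0_max": contour.f0_max,
    }


def filter_annotations(
    table: pd.DataFrame,
    min_duration: float = 0.2,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the pulse screening rules, reporting attrition per rule.

    Rules are applied sequentially: duration >= ``min_duration`` (separates
    pulses from short grumble/bubble sounds), tonal (F0 contour at least
    partially visible), not noisy (no disturbing background sound), and
    f0_valid (F0 extrema screened as accurate). Row order is preserved.
    """
    dur = table["end_time"] - table["begin_time"]
    counts: dict[str, int] = {}
    keep = dur >= min_duration
    counts["duration"] = int((~keep).sum())
    for col, want in (("tonal", True), ("noisy", False), ("f0_valid", True)):
        if col in table.columns:
            rule = table[col].astype(bool) == want
        else:
            rule = pd.Series(True, index=table.index)
        name = "atonal" if col == "tonal" else ("noisy" if col == "noisy" else "f0_invalid")
        counts[name] = int((keep & ~rule).sum())
        keep &= rule
    return table.loc[keep].copy(), counts
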