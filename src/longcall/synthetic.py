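"""Synthetic long-call generator.

Emulates the statistical structure of flanged-male orangutan long-call
pulse data: a feature table with two latent frequency clusters — a
high-frequency group (huitus HU, volcano VO, high roar HR, center
frequencies ~440–483 Hz) and a low-frequency group (low roar LR,
intermediary IN, sigh SI, ~203–266 Hz) — bridged by a graded continuum,
plus audio pulses whose F0 contours realize the published shape
definitions (roars rise to a mid-pulse maximum, sighs start at their
maximum and fall, huitus pulses have a silent gap between ascending and
descending parts).

Each pulse carries a gradedness coordinate λ ∈ [0, 1]: 0 is the pure
low-cluster archetype, 1 the pure high-cluster archetype, and planted
graded pulses sit in between with feature means linearly interpolated
between the archetypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .types import F0Contour

HIGH_CLASSES = ("HU", "VO", "HR")
LOW_CLASSES = ("LR", "IN", "SI")
PULSE_CLASSES = HIGH_CLASSES + LOW_CLASSES
REVISED_CLASSES = ("Roar", "Sigh", "Intermediate")

#: mapping from the six-type scheme to the revised three-type scheme
REVISED_MAP = {
    "HU": "Roar",
    "VO": "Roar",
    "HR": "Roar",
    "LR": "Intermediate",
    "IN": "Intermediate",
    "SI": "Sigh",
}

CORE_FEATURES = (
    "duration",
    "center_freq",
    "peak_freq",
    "mean_peak_freq",
    "freq_q1",
    "freq_q3",
    "f0_min",
    "f0_max",
)

# Archetype frequency means (Hz) per pulse type: center, peak, mean peak,
# first/third energy quartiles; durations (s) and F0 extrema are realistic
# values for this call system (high cluster F0 max ~600-800 Hz, low ~200-260).
DEFAULT_CLUSTER_MEANS: dict[str, dict[str, float]] = {
    "HU": dict(duration=0.8, center_freq=443.3, peak_freq=421.0, mean_peak_freq=436.4,
               freq_q1=370.3, freq_q3=585.3, f0_min=280.0, f0_max=800.0),
    "VO": dict(duration=0.9, center_freq=483.1, peak_freq=442.3, mean_peak_freq=505.6,
               freq_q1=376.7, freq_q3=592.6, f0_min=300.0, f0_max=820.0),
    "HR": dict(duration=1.2, center_freq=440.0, peak_freq=409.9, mean_peak_freq=450.1,
               freq_q1=358.7, freq_q3=533.8, f0_min=260.0, f0_max=700.0),
    "LR": dict(duration=1.1, center_freq=266.3, peak_freq=252.2, mean_peak_freq=271.8,
               freq_q1=231.4, freq_q3=312.0, f0_min=160.0, f0_max=320.0),
    "IN": dict(duration=0.9, center_freq=249.7, peak_freq=242.7, mean_peak_freq=244.6,
               freq_q1=225.5, freq_q3=288.8, f0_min=150.0, f0_max=300.0),
    "SI": dict(duration=1.3, center_freq=203.0, peak_freq=201.1, mean_peak_freq=194.6,
               freq_q1=172.5, freq_q3=239.1, f0_min=110.0, f0_max=250.0),
}

DEFAULT_CLUSTER_SDS: dict[str, dict[str, float]] = {
    cls: dict(duration=0.2,
              **{f: (35.0 if cls in HIGH_CLASSES else 22.0)
                 for f in ("center_freq", "peak_freq", "mean_peak_freq",
                           "freq_q1", "freq_q3")},
              f0_min=(45.0 if cls in HIGH_CLASSES else 25.0),
              f0_max=(70.0 if cls in HIGH_CLASSES else 35.0))
    for cls in PULSE_CLASSES
}

# Class composition mirroring the imbalance of real long-call datasets
# (sighs dominate the let-down phase, huitus/volcano pulses are rare).
DEFAULT_CLASS_PROBS = {
    "HU": 0.04, "VO": 0.04, "HR": 0.14, "LR": 0.17, "IN": 0.14, "SI": 0.47,
}

# F0 contour shape families per class. Frequencies in Hz, positions as
# fractions of pulse duration. LR peaks below 350 Hz by construction,
# consistent with its low-cluster membership.
DEFAULT_SHAPE_PARAMS: dict[str, dict] = {
    "HU": dict(family="huitus", peak_range=(600.0, 1000.0), start_range=(250.0, 400.0),
               end_range=(250.0, 400.0), peak_pos_range=(0.45, 0.55),
               gap_frac_range=(0.10, 0.20)),
    "VO": dict(family="roar", peak_range=(600.0, 1000.0), start_range=(250.0, 400.0),
               end_range=(200.0, 350.0), peak_pos_range=(0.45, 0.55)),
    "HR": dict(family="roar", peak_range=(420.0, 800.0), start_range=(200.0, 300.0),
               end_range=(180.0, 280.0), peak_pos_range=(0.42, 0.58)),
    "LR": dict(family="roar", peak_range=(250.0, 345.0), start_range=(150.0, 220.0),
               end_range=(130.0, 200.0), peak_pos_range=(0.42, 0.58)),
    "IN": dict(family="intermediate", peak_range=(250.0, 345.0),
               start_range=(220.0, 330.0), end_range=(100.0, 160.0),
               peak_pos_range=(0.42, 0.58), bump_range=(40.0, 90.0)),
    "SI": dict(family="sigh", start_range=(200.0, 330.0), end_range=(80.0, 150.0)),
    # revised three-type scheme
    "Roar": dict(family="roar", peak_range=(420.0, 900.0), start_range=(200.0, 330.0),
                 end_range=(180.0, 300.0), peak_pos_range=(0.42, 0.58)),
    "Sigh": dict(family="sigh", start_range=(200.0, 330.0), end_range=(80.0, 150.0)),
    "Intermediate": dict(family="intermediate", peak_range=(250.0, 345.0),
                         start_range=(220.0, 330.0), end_range=(100.0, 160.0),
                         peak_pos_range=(0.42, 0.58), bump_range=(40.0, 90.0)),
}


@dataclass
class SyntheticSpec:
    """Generative parameters for a synthetic long-call dataset.

    λ banding: pulses with gradedness λ ≤ ``lambda_low`` carry low-cluster
    labels, λ ≥ ``lambda_high`` high-cluster labels, and pulses in between
    are labeled intermediary (IN).
    """

    n_pulses: int = 500
    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    graded_fraction: float = 0.1
    cluster_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_CLUSTER_MEANS.items()})
    cluster_sds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_CLUSTER_SDS.items()})
    f0_shape_params: dict[str, dict] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_SHAPE_PARAMS.items()})
    snr_db: float = 30.0
    sample_rate: float = 5512.5
    seed: int = 0
    lambda_low: float = 0.3
    lambda_high: float = 0.7
    n_extra_features: int = 38
    n_males: int = 13
    calls_per_male: int = 10
    pulses_per_call: tuple[int, int] = (6, 12)
    silence_range: tuple[float, float] = (0.5, 3.0)
    frame_rate: float = 100.0
    n_harmonics: int = 2

    def validate(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_probs must sum to 1 (got {total})")
        unknown = set(self.class_probs) - set(self.cluster_means)
        if unknown:
            raise ValueError(f"class_probs contains classes without cluster_means: {sorted(unknown)}")
        if not 0.0 <= self.graded_fraction <= 1.0:
            raise ValueError(f"graded_fraction must be in [0, 1] (got {self.graded_fraction})")
        if not 0.0 <= self.lambda_low < self.lambda_high <= 1.0:
            raise ValueError(
                f"lambda_low/lambda_high must satisfy 0 <= low < high <= 1 "
                f"(got {self.lambda_low}, {self.lambda_high})")
        max_f0 = max(
            max(p.get("peak_range", p.get("start_range", (0.0, 0.0))))
            for p in self.f0_shape_params.values())
        if self.sample_rate <= 2.0 * self.n_harmonics * max_f0:
            raise ValueError(
                f"sample_rate ({self.sample_rate}) must exceed twice the highest "
                f"generated harmonic ({self.n_harmonics} x {max_f0} Hz)")
        if self.n_pulses < 0:
            raise ValueError(f"n_pulses must be non-negative (got {self.n_pulses})")


@dataclass
class TruthRecord:
    """Ground truth for one generated pulse."""

    pulse_id: str
    true_class: str
    revised_class: str
    gradedness: float  # λ: 0 = low-cluster archetype, 1 = high-cluster archetype
    is_graded: bool


def _archetypes(spec: SyntheticSpec) -> tuple[dict, dict, dict, dict]:
    """Low/high archetype means and sds: unweighted means over the class sets."""
    feats = CORE_FEATURES

    def avg(classes, table):
        present = [c for c in classes if c in table]
        return {f: float(np.mean([table[c][f] for c in present])) for f in feats}

    return (avg(LOW_CLASSES, spec.cluster_means), avg(HIGH_CLASSES, spec.cluster_means),
            avg(LOW_CLASSES, spec.cluster_sds), avg(HIGH_CLASSES, spec.cluster_sds))


def _class_for_lambda(lam: float, spec: SyntheticSpec, rng: np.random.Generator) -> str:
    """Label a graded pulse according to the λ banding declared in the spec."""
    if lam >= spec.lambda_high:
        pool = [c for c in HIGH_CLASSES if c in spec.class_probs]
    elif lam <= spec.lambda_low:
        pool = [c for c in LOW_CLASSES if c in spec.class_probs]
    else:
        return "IN"
    if not pool:
        return "IN"
    p = np.array([spec.class_probs[c] for c in pool])
    return str(rng.choice(pool, p=p / p.sum()))


def generate_feature_table(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Draw a labeled acoustic feature table with planted graded pulses.

    Non-graded pulses are sampled from their class's multivariate-normal
    feature distribution (diagonal covariance); graded pulses have feature
    means linearly interpolated between the low and high cluster archetypes
    at their λ. Extra features are noisy linear readouts of λ (half of them
    carry signal, half are pure noise), standing in for the large battery of
    correlated spectral measurements real pipelines extract.

    Returns the feature table (one row per pulse, with ``pulse_id``,
    ``male_id``, ``true_class``, ``revised_class``, ``gradedness`` columns
    followed by feature columns) and the truth records.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_pulses
    low_mean, high_mean, low_sd, high_sd = _archetypes(spec)
    classes = list(spec.class_probs)
    probs = np.array([spec.class_probs[c] for c in classes])

    is_graded = rng.random(n) < spec.graded_fraction
    rows, truth = [], []
    for i in range(n):
        pid = f"p{i:05d}"
        if is_graded[i]:
            lam = float(rng.uniform())
            cls = _class_for_lambda(lam, spec, rng)
            mean = {f: (1 - lam) * low_mean[f] + lam * high_mean[f] for f in CORE_FEATURES}
            sd = {f: (1 - lam) * low_sd[f] + lam * high_sd[f] for f in CORE_FEATURES}
        else:
            cls = str(rng.choice(classes, p=probs))
            lam = 1.0 if cls in HIGH_CLASSES else 0.0
            mean = spec.cluster_means[cls]
            sd = spec.cluster_sds[cls]
        vals = {f: rng.normal(mean[f], sd[f]) for f in CORE_FEATURES}
        # keep physical orderings intact under sampling noise
        q1, ctr, q3 = sorted((vals["freq_q1"], vals["center_freq"], vals["freq_q3"]))
        vals["freq_q1"], vals["center_freq"], vals["freq_q3"] = q1, ctr, q3
        vals["f0_min"], vals["f0_max"] = sorted((vals["f0_min"], vals["f0_max"]))
        vals["duration"] = max(vals["duration"], 0.2)
        rev = REVISED_MAP.get(cls, "Intermediate")
        rows.append({"pulse_id": pid, "male_id": f"M{i % spec.n_males:02d}",
                     "true_class": cls, "revised_class": rev,
                     "gradedness": lam, **vals})
        truth.append(TruthRecord(pid, cls, rev, lam, bool(is_graded[i])))

    table = pd.DataFrame(rows)

    if spec.n_extra_features > 0 and n > 0:
        struct = np.random.default_rng([spec.seed, 17])
        k = spec.n_extra_features
        loadings = struct.normal(size=k)
        loadings[k // 2:] = 0.0  # second half: pure noise features
        lam_std = (table["gradedness"].to_numpy() - 0.5) * 2.0
        noise = rng.normal(size=(n, k))
        extras = lam_std[:, None] * loadings[None, :] + noise
        for j in range(k):
            table[f"x{j:02d}"] = extras[:, j]
    return table, truth


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the numeric acoustic feature columns of a generated table."""
    meta = {"pulse_id", "male_id", "true_class", "revised_class", "gradedness"}
    return [c for c in table.columns if c not in meta]


def synthesize_f0_contour(
    pulse_class: str,
    f0_shape_params: dict | None = None,
    duration_s: float = 1.0,
    seed: int = 0,
    frame_rate: float = 100.0,
) -> F0Contour:
    """Draw an F0 contour realizing a pulse type's shape definition.

    Roar-family contours ascend to a single maximum near mid-duration and
    then descend; sigh contours start at their maximum and fall
    monotonically; huitus contours are roar-shaped with an unvoiced gap
    (NaN frames) between the ascending and descending parts; intermediate
    contours either start at their maximum with a later ascending bump
    (variant a) or are roar-shaped with a sub-350 Hz peak (variant b).
    """
    if duration_s < 0.2:
        raise ValueError(f"duration_s must be >= 0.2 s (got {duration_s})")
    params = f0_shape_params
    if params is None:
        if pulse_class not in DEFAULT_SHAPE_PARAMS:
            raise ValueError(
                f"unknown pulse class {pulse_class!r}; registered classes: "
                f"{sorted(DEFAULT_SHAPE_PARAMS)}")
        params = DEFAULT_SHAPE_PARAMS[pulse_class]
    rng = np.random.default_rng(seed)
    n_frames = max(int(round(duration_s * frame_rate)), 4)
    t = np.arange(n_frames) / frame_rate
    rel = t / duration_s

    def draw(key, fallback):
        if key[:-6] + "_hz" in params:  # explicit fixed value e.g. peak_hz
            return float(params[key[:-6] + "_hz"])
        lo, hi = params.get(key, fallback)
        return float(rng.uniform(lo, hi))

    family = params.get("family", "roar")
    if family in ("roar", "huitus"):
        peak = draw("peak_range", (400.0, 800.0))
        start = min(draw("start_range", (150.0, 250.0)), peak - 60.0)
        end = min(draw("end_range", (150.0, 250.0)), peak - 60.0)
        pos = draw("peak_pos_range", (0.45, 0.55))
        f0 = np.where(
            rel <= pos,
            start + (peak - start) * np.sin(0.5 * np.pi * np.clip(rel / pos, 0, 1)) ** 2,
            end + (peak - end) * np.sin(0.5 * np.pi * np.clip((1 - rel) / (1 - pos), 0, 1)) ** 2,
        )
        f0[int(np.argmin(np.abs(rel - pos)))] = peak  # maximum lands exactly on a frame
        if family == "huitus":
            gap = draw("gap_frac_range", (0.10, 0.20))
            mask = np.abs(rel - pos) < gap / 2
            if not mask.any():
                mask[int(np.argmin(np.abs(rel - pos)))] = True
            f0[mask] = np.nan
    elif family == "sigh":
        start = draw("start_range", (220.0, 320.0))
        end = draw("end_range", (80.0, 150.0))
        f0 = end + (start - end) * (1 - rel) ** 1.5
    elif family == "intermediate":
        if params.get("variant") == "a" or (params.get("variant") is None and rng.random() < 0.5):
            # (a): maximum at the start, descending into a valley, then a
            # clear later ascending portion that stays below the start
            start = draw("start_range", (220.0, 330.0))
            end = draw("end_range", (100.0, 160.0))
            bump = min(draw("bump_range", (40.0, 90.0)), start - end - 10.0)
            valley_pos, crest_pos = 0.55, 0.8
            f0 = np.empty_like(rel)
            desc = rel < valley_pos
            f0[desc] = end + (start - end) * (1 - rel[desc] / valley_pos) ** 1.2
            rise = (rel >= valley_pos) & (rel < crest_pos)
            f0[rise] = end + bump * (rel[rise] - valley_pos) / (crest_pos - valley_pos)
            tail = rel >= crest_pos
            f0[tail] = end + bump * (1 - rel[tail]) / (1 - crest_pos)
            f0[0] = start
        else:
            # (b): roar-shaped with a sub-350 Hz maximum
            sub = dict(params, family="roar")
            sub.setdefault("peak_range", (250.0, 345.0))
            sub["start_range"] = (150.0, 210.0)
            sub["end_range"] = (130.0, 190.0)
            return synthesize_f0_contour(
                pulse_class, sub, duration_s, seed=int(rng.integers(2**31)),
                frame_rate=frame_rate)
    else:
        raise ValueError(
            f"unknown contour family {family!r}; registered families: "
            "roar, sigh, huitus, intermediate")
    return F0Contour(frame_times=t, f0_hz=f0)


def synthesize_pulse_audio(
    contour: F0Contour,
    n_harmonics: int = 2,
    harmonic_rolloff_db: float = 6.0,
    snr_db: float | None = 30.0,
    sample_rate: float = 5512.5,
    seed: int = 0,
    peak_amplitude: float = 0.5,
) -> np.ndarray:
    """Render a harmonic stack following an F0 contour, plus background noise.

    Phase is integrated sample-by-sample so the fundamental tracks the
    contour continuously; harmonic ``h`` is attenuated by
    ``(h-1) * harmonic_rolloff_db`` dB. Unvoiced frames are silent (smoothed
    amplitude gate). ``snr_db=None`` disables noise.
    """
    voiced = contour.voiced
    if voiced.any():
        max_f0 = float(np.nanmax(contour.f0_hz))
        if sample_rate <= 2.0 * n_harmonics * max_f0:
            raise ValueError(
                f"sample_rate ({sample_rate}) must exceed twice the highest harmonic "
                f"({n_harmonics} x {max_f0:.0f} Hz): aliasing")
    duration = contour.frame_times[-1] + (
        contour.frame_times[1] - contour.frame_times[0] if len(contour.frame_times) > 1 else 0.01)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    rng = np.random.default_rng(seed)

    if not voiced.any():
        return rng.normal(0.0, 0.01, size=n)

    f0_frames = np.where(voiced, contour.f0_hz, np.nan)
    vt = contour.frame_times[voiced]
    f0_samples = np.interp(t, vt, f0_frames[voiced])
    gate = np.interp(t, contour.frame_times, voiced.astype(float)) > 0.5

    phase = 2.0 * np.pi * np.cumsum(f0_samples) / sample_rate
    sig = np.zeros(n)
    for h in range(1, n_harmonics + 1):
        amp = 10.0 ** (-(h - 1) * harmonic_rolloff_db / 20.0)
        sig += amp * np.sin(h * phase)

    # smooth the voicing gate and apply short edge ramps to avoid clicks
    win = max(int(0.01 * sample_rate), 1)
    kernel = np.hanning(2 * win + 1)
    kernel /= kernel.sum()
    env = np.convolve(gate.astype(float), kernel, mode="same")
    ramp = min(int(0.02 * sample_rate), n // 2)
    if ramp > 0:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] *= edge
        env[-ramp:] *= edge[::-1]
    sig *= env
    peak = np.abs(sig).max()
    if peak > 0:
        sig *= peak_amplitude / peak

    if snr_db is not None and math.isfinite(snr_db):
        p_sig = float(np.mean(sig**2))
        if p_sig > 0:
            noise_std = math.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
            sig = sig + rng.normal(0.0, noise_std, size=n)
    return sig


def generate_longcall_dataset(
    spec: SyntheticSpec,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, tuple[float, np.ndarray]], pd.DataFrame, list[TruthRecord]]:
    """Render whole long-call recordings with tight pulse annotations.

    Each of ``n_males`` males contributes ``calls_per_male`` recordings; a
    recording concatenates per-pulse audio separated by silences drawn
    uniformly from ``silence_range``. Annotation rows carry Raven-style
    begin/end times tightly bounding each pulse and per-male identifiers.
    If ``out_dir`` is given, recordings are written as 16-bit PCM mono WAV.

    Returns ``(recordings, annotation_table, truth)`` where ``recordings``
    maps recording id to ``(sample_rate, samples)``.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    classes = list(spec.class_probs)
    probs = np.array([spec.class_probs[c] for c in classes])
    sr = spec.sample_rate

    recordings: dict[str, tuple[float, np.ndarray]] = {}
    ann_rows = []
    truth: list[TruthRecord] = []
    pulse_counter = 0
    for m in range(spec.n_males):
        male = f"M{m:02d}"
        for c in range(spec.calls_per_male):
            rec_id = f"{male}_call{c:02d}"
            lo, hi = spec.pulses_per_call
            n_p = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            chunks: list[np.ndarray] = []
            cursor = 0.0
            for _ in range(n_p):
                gap = float(rng.uniform(*spec.silence_range))
                chunks.append(np.zeros(int(round(gap * sr))))
                cursor += len(chunks[-1]) / sr
                cls = str(rng.choice(classes, p=probs))
                dur = max(float(rng.normal(spec.cluster_means[cls]["duration"],
                                           spec.cluster_sds[cls]["duration"])), 0.25)
                contour = synthesize_f0_contour(
                    cls, spec.f0_shape_params.get(cls), dur,
                    seed=int(rng.integers(2**31)), frame_rate=spec.frame_rate)
                audio = synthesize_pulse_audio(
                    contour, n_harmonics=spec.n_harmonics, snr_db=spec.snr_db,
                    sample_rate=sr, seed=int(rng.integers(2**31)))
                begin, end = cursor, cursor + len(audio) / sr
                chunks.append(audio)
                cursor = end
                pid = f"p{pulse_counter:05d}"
                pulse_counter += 1
                high_band = 1500.0 if cls in ("HU", "VO") else 1000.0
                ann_rows.append(dict(
                    pulse_id=pid, recording_id=rec_id, male_id=male,
                    begin_time=begin, end_time=end,
                    low_freq=50.0, high_freq=high_band,
                    tonal=True, noisy=False, f0_valid=True, true_class=cls))
                lam = 1.0 if cls in HIGH_CLASSES else 0.0
                truth.append(TruthRecord(pid, cls, REVISED_MAP.get(cls, "Intermediate"),
                                         lam, False))
            chunks.append(np.zeros(int(round(float(rng.uniform(*spec.silence_range)) * sr))))
            if n_p == 0:
                continue
            samples = np.concatenate(chunks)
            recordings[rec_id] = (sr, samples)

    ann = pd.DataFrame(ann_rows, columns=[
        "pulse_id", "recording_id", "male_id", "begin_time", "end_time",
        "low_freq", "high_freq", "tonal", "noisy", "f0_valid", "true_class"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec_id, (rate, samples) in recordings.items():
            pcm = np.clip(samples, -1.0, 1.0)
            wavfile.write(out / f"{rec_id}.wav", int(round(rate)),
                          (pcm * 32767).astype(np.int16))
    return recordings, ann, truth


def simulate_observer_labels(
    true_labels,
    n_observers: int = 3,
    accuracy: float = 0.85,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Simulate audio-visual labels from imperfect human observers.

    Each observer independently keeps the true label with probability
    ``accuracy`` and otherwise substitutes a different class drawn
    uniformly. Used by the reliability stage of the synthetic pipeline.
    """
    true_labels = list(true_labels)
    alphabet = sorted(set(true_labels))
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for o in range(n_observers):
        labels = []
        for lab in true_labels:
            if rng.random() < accuracy or len(alphabet) < 2:
                labels.append(lab)
            else:
                others = [a for a in alphabet if a != lab]
                labels.append(str(rng.choice(others)))
        out[f"obs{o + 1}"] = labels
    return out
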