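"""Synthetic rating-labeled EEG sessions.

The generator emulates the statistical structure the classifier feeds on:
each channel is a sum of four band-limited Gaussian noise carriers (one
per analysis band, RMS amplitude set by a per-rating multiplier), a 1/f
background, and white sensor noise, all in microvolts at 128 Hz.  A
15 s class-neutral baseline precedes the videos, and optional blink
artifacts (300-600 uV frontal transients) exercise the artifact
rejection path.

The default signature encodes the empirically reported liking
correlates qualitatively: elevated FC5 alpha power and depressed O1
activity for highly rated stimuli, reversed for low ratings.  A
"separable" signature spreads strong monotone multipliers across several
channels so the full pipeline has a cleanly recoverable structure; a
"hard" signature keeps the overlapping default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .config import RunConfig
from .eeg_io import DEFAULT_SAMPLING_RATE, EPOC_MONTAGE, EEGRecording, SessionMetadata, SubjectProfile, VideoEvent
from .errors import ParameterError
from .features import FeatureMatrix
from .preprocess import DEFAULT_BANDS, band_sos

#: Carrier RMS amplitudes per band in microvolts before multipliers.
DEFAULT_BAND_RMS: dict[str, float] = {"theta": 4.0, "alpha": 5.0, "beta": 3.0, "gamma": 2.0}


@dataclass
class SignatureConfig:
    """Per-rating band-power multipliers plus noise and artifact settings.

    ``class_multipliers[rating][channel][band]`` scales that carrier's RMS
    amplitude; the band key ``"all"`` scales every band of the channel.
    Missing entries default to 1 (class-neutral).
    """

    class_multipliers: dict[int, dict[str, dict[str, float]]] = field(default_factory=dict)
    band_rms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_RMS))
    background_rms: float = 3.0      # 1/f background, uV
    sensor_noise_rms: float = 1.5    # white noise floor, uV
    blink_rate_per_min: float = 2.0
    blink_amp_uv: tuple[float, float] = (300.0, 600.0)
    blink_width_s: float = 0.4

    def __post_init__(self) -> None:
        for rating, chans in self.class_multipliers.items():
            for ch, bands in chans.items():
                for band, m in bands.items():
                    if not m > 0:
                        raise ParameterError(
                            f"multiplier for rating {rating}, {ch}/{band} must be > 0"
                        )
        if self.blink_rate_per_min < 0:
            raise ParameterError("blink rate must be >= 0")

    def multiplier(self, rating: int | None, channel: str, band: str) -> float:
        if rating is None:
            return 1.0
        chans = self.class_multipliers.get(rating, {})
        bands = chans.get(channel, {})
        return bands.get(band, 1.0) * bands.get("all", 1.0)


def default_signature() -> SignatureConfig:
    """Overlapping, qualitatively realistic signature (the 'hard' setting):
    FC5 alpha rises with the rating, O1 broadband activity falls."""
    return SignatureConfig(
        class_multipliers={
            1: {"FC5": {"alpha": 0.70}, "O1": {"all": 1.40}},
            2: {"FC5": {"alpha": 0.85}, "O1": {"all": 1.20}},
            3: {},
            4: {"FC5": {"alpha": 1.40}, "O1": {"all": 0.80}},
            5: {"FC5": {"alpha": 1.80}, "O1": {"all": 0.60}},
        },
    )


def separable_signature() -> SignatureConfig:
    """Disjoint class-conditional multipliers over several channels, with a
    low noise floor: every rating has a distinct multi-channel power
    pattern the pipeline can recover."""
    alpha = {1: 0.40, 2: 0.80, 3: 1.30, 4: 2.00, 5: 3.00}
    beta = {1: 0.50, 2: 0.85, 3: 1.25, 4: 1.80, 5: 2.60}
    occ = {1: 2.40, 2: 1.70, 3: 1.20, 4: 0.85, 5: 0.60}
    mult: dict[int, dict[str, dict[str, float]]] = {}
    for r in range(1, 6):
        per: dict[str, dict[str, float]] = {}
        for ch in ("AF3", "AF4", "F3", "F4", "FC5", "FC6"):
            per[ch] = {"alpha": alpha[r]}
        for ch in ("P7", "P8"):
            per[ch] = {"beta": beta[r]}
        for ch in ("O1", "O2"):
            per[ch] = {"all": occ[r]}
        mult[r] = per
    return SignatureConfig(
        class_multipliers=mult, background_rms=2.0, sensor_noise_rms=1.0,
    )


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _unit_rms_band_noise(rng: np.random.Generator, shape: tuple[int, int],
                         sos: np.ndarray) -> np.ndarray:
    """Band-limited Gaussian noise normalized to unit RMS per channel."""
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-shaped noise, unit RMS per channel."""
    n = shape[-1]
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _segment(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    cfg: SignatureConfig,
    rating: int | None,
    band_sections: dict[str, np.ndarray],
    channels: tuple[str, ...],
) -> np.ndarray:
    nc = len(channels)
    out = np.zeros((nc, n_samples))
    for band, sos in band_sections.items():
        carrier = _unit_rms_band_noise(rng, (nc, n_samples), sos)
        amps = np.array(
            [cfg.band_rms[band] * cfg.multiplier(rating, ch, band) for ch in channels]
        )
        out += amps[:, None] * carrier
    if cfg.background_rms > 0:
        out += cfg.background_rms * _pink_noise(rng, (nc, n_samples))
    if cfg.sensor_noise_rms > 0:
        out += cfg.sensor_noise_rms * rng.standard_normal((nc, n_samples))
    return out


def _inject_blinks(
    rng: np.random.Generator,
    data: np.ndarray,
    fs: float,
    cfg: SignatureConfig,
    channels: tuple[str, ...],
) -> None:
    """Add raised-cosine blink transients on the frontal electrodes, in place."""
    if cfg.blink_rate_per_min <= 0:
        return
    n = data.shape[-1]
    duration_min = n / fs / 60.0
    n_events = rng.poisson(cfg.blink_rate_per_min * duration_min)
    width = int(round(cfg.blink_width_s * fs))
    if width < 2 or n_events == 0:
        return
    shape = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / (width - 1)))
    frontal = {"AF3": 1.0, "AF4": 1.0, "F7": 0.6, "F8": 0.6}
    rows = [(channels.index(ch), w) for ch, w in frontal.items() if ch in channels]
    for _ in range(n_events):
        t0 = rng.integers(0, max(1, n - width))
        amp = rng.uniform(*cfg.blink_amp_uv)
        for row, w in rows:
            data[row, t0:t0 + width] += amp * w * shape


def generate_session(
    ratings: list[int],
    durations_s: list[float] | None = None,
    cfg: SignatureConfig | None = None,
    seed: int = 0,
    fs: float = DEFAULT_SAMPLING_RATE,
    baseline_s: float = 15.0,
    channels: tuple[str, ...] = EPOC_MONTAGE,
) -> tuple[EEGRecording, SessionMetadata]:
    """Generate one rating-labeled session.

    The recording starts with a class-neutral ``baseline_s`` segment
    (stored in ``EEGRecording.baseline``) followed by one segment per
    video whose band amplitudes follow the rating's multipliers.  Video
    durations default to uniform draws on [20, 60] s, the typical ad
    length range.  All randomness flows from ``seed``; the same seed
    yields a bit-identical session.
    """
    cfg = cfg or default_signature()
    for r in ratings:
        if r not in (1, 2, 3, 4, 5):
            raise ParameterError(f"rating {r!r} outside 1..5")
    rng = np.random.default_rng(seed)
    if durations_s is None:
        durations_s = [float(d) for d in rng.uniform(20.0, 60.0, size=len(ratings))]
    if len(durations_s) != len(ratings):
        raise ParameterError("durations and ratings must have equal length")

    band_sections = {b: band_sos(fs, lo, hi) for b, (lo, hi) in DEFAULT_BANDS.items()}
    baseline = _segment(rng, int(round(baseline_s * fs)), fs, cfg, None, band_sections, channels)

    segments: list[np.ndarray] = []
    videos: list[VideoEvent] = []
    t = baseline_s
    for i, (rating, dur) in enumerate(zip(ratings, durations_s)):
        n = int(round(dur * fs))
        seg = _segment(rng, n, fs, cfg, rating, band_sections, channels)
        _inject_blinks(rng, seg, fs, cfg, channels)
        segments.append(seg)
        videos.append(VideoEvent(
            video_id=f"ad{i + 1:03d}", start_s=t, end_s=t + n / fs,
            rating=rating, remembered=bool(rng.random() < 0.5),
            description=f"synthetic advertisement {i + 1} (rating {rating})",
        ))
        t += n / fs

    rec = EEGRecording(
        channel_labels=channels, sampling_rate=fs,
        data=np.concatenate([baseline] + segments, axis=-1),
        baseline=baseline,
    )
    session = SessionMetadata(subject=SubjectProfile(subject_id=f"synth-{seed}"), videos=videos)
    session.validate()
    return rec, session


def generate_feature_dataset(
    n_per_class: int,
    separation: str = "separable",
    seed: int = 0,
    cfg: SignatureConfig | None = None,
    duration_s: float = 22.0,
    run_config: RunConfig | None = None,
) -> FeatureMatrix:
    """Labeled feature matrix from a full synthetic pipeline run.

    Generates one session with ``n_per_class`` videos per rating (order
    shuffled), each ``duration_s`` long, runs band-limiting, baseline
    correction, artifact rejection and feature extraction, and returns
    the per-window feature matrix.  ``separation='separable'`` uses
    disjoint class-conditional multipliers, ``'hard'`` the overlapping
    defaults; pass ``cfg`` to override either.
    """
    from .pipeline import extract_features  # local import to avoid a cycle

    if n_per_class < 2:
        raise ParameterError("n_per_class must be >= 2")
    if cfg is None:
        if separation == "separable":
            cfg = separable_signature()
        elif separation == "hard":
            cfg = default_signature()
        else:
            raise ParameterError(f"unknown separation {separation!r}")
    rng = np.random.default_rng(seed)
    ratings = np.repeat(np.arange(1, 6), n_per_class)
    rng.shuffle(ratings)
    rec, session = generate_session(
        ratings=[int(r) for r in ratings],
        durations_s=[duration_s] * ratings.size,
        cfg=cfg,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return extract_features(rec, session, run_config or RunConfig())
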