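"""End-to-end feature extraction: recording + session -> feature matrix.

Order of operations (documented because it matters): band-limit first,
center against the baseline mean, then flag artifact samples on the
band-limited signal, then band-decompose.  Statistics are computed over
clean samples only; the baseline's band power is removed from every
window's Welch band power before the logarithm.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import RunConfig
from .eeg_io import EEGRecording, SessionMetadata, SYMMETRIC_PAIRS
from .errors import DegenerateWindowError
from .features import (
    FeatureMatrix,
    WindowSpec,
    assemble_features,
    asymmetry_stats,
    feature_names,
    slide_windows,
    welch_band_power,
    welch_log_psd,
    window_statistics,
)
from .preprocess import ArtifactMask, band_decompose, bandlimit, baseline_center, reject_artifacts


def extract_features(
    rec: EEGRecording,
    session: SessionMetadata,
    config: RunConfig | None = None,
) -> FeatureMatrix:
    """Run the full per-window feature pipeline over a session."""
    cfg = (config or RunConfig()).validate()
    fs = rec.sampling_rate
    band_names = tuple(cfg.bands)
    channels = rec.channel_labels

    rec = bandlimit(rec, cfg.filter.hp_hz, cfg.filter.lp_hz, cfg.filter.order)
    if cfg.baseline.correct:
        rec = baseline_center(rec)
    if cfg.artifact.enabled:
        rec, mask = reject_artifacts(rec, cfg.artifact.threshold_uv, cfg.artifact.pad_s)
    else:
        mask = ArtifactMask.clean(rec.n_samples)
    bands = band_decompose(rec, cfg.bands, cfg.filter.order)

    baseline_bp = None
    if cfg.baseline.correct and rec.baseline is not None and rec.baseline.shape[-1] >= 128:
        baseline_bp = welch_band_power(rec.baseline, fs, cfg.bands)  # (channels, bands)

    spec = WindowSpec(cfg.window.length_s, cfg.window.overlap_s)
    nominal = int(round(spec.length_s * fs))

    # -- first pass: per-window blocks and PSD magnitudes -----------------
    per_video: list[dict] = []
    for video in session.videos:
        v0 = int(round(video.start_s * fs))
        v1 = min(int(round(video.end_s * fs)), rec.n_samples)
        wins = slide_windows((v1 - v0) / fs, spec)
        rows = []
        for (ws, we, padded) in wins:
            a = v0 + int(round(ws * fs))
            b = v0 + int(round(we * fs))
            mslice = mask.slice(a, b)
            try:
                row = _window_blocks(
                    rec, bands, a, b, mslice, padded, nominal, fs, cfg, baseline_bp, band_names
                )
            except DegenerateWindowError:
                warnings.warn(
                    f"window [{ws:.1f}, {we:.1f}]s of video {video.video_id!r} dropped: "
                    "too few clean samples",
                    stacklevel=2,
                )
                continue
            rows.append(row)
        per_video.append({"video": video, "rows": rows})

    # -- session-wide PSD statistics for the Z-index ----------------------
    all_powers = np.array(
        [row["power"] for entry in per_video for row in entry["rows"]]
    )  # (n_windows, n_channels)
    mu = all_powers.mean(axis=0) if all_powers.size else np.zeros(len(channels))
    sigma = all_powers.std(axis=0, ddof=1) if all_powers.shape[0] > 1 else np.zeros(len(channels))

    names = feature_names(channels, band_names, SYMMETRIC_PAIRS, cfg.blocks)
    X_rows, labels, video_ids = [], [], []
    any_rating = any(v.rating is not None for v in session.videos)
    for entry in per_video:
        video, rows = entry["video"], entry["rows"]
        if not rows:
            continue
        z = np.zeros(len(channels))
        if "z" in cfg.blocks:
            n_w = len(rows)
            if n_w >= 2 and np.all(sigma > 0):
                x_bar = np.mean([row["power"] for row in rows], axis=0)
                z = (x_bar - mu) / (sigma / np.sqrt(n_w))
            else:
                warnings.warn(
                    f"Z-index undefined for video {video.video_id!r} "
                    f"(windows={n_w}); emitting 0",
                    stacklevel=2,
                )
        for row in rows:
            X_rows.append(assemble_features(
                row["stat"] if "stat" in cfg.blocks else None,
                row["psd"] if "psd" in cfg.blocks else None,
                row["asym"] if "asym" in cfg.blocks else None,
                z if "z" in cfg.blocks else None,
                channels, band_names, SYMMETRIC_PAIRS,
            ))
            labels.append(video.rating)
            video_ids.append(video.video_id)

    return FeatureMatrix(
        names=names,
        X=np.asarray(X_rows) if X_rows else np.empty((0, len(names))),
        labels=np.asarray(labels, dtype=int) if any_rating and all(l is not None for l in labels) else None,
        video_ids=video_ids,
        config_hash=cfg.hash(),
    )


def _window_blocks(rec, bands, a, b, mslice, padded, nominal, fs, cfg, baseline_bp, band_names):
    """All feature blocks of one window; raises DegenerateWindowError when
    fewer than 2 clean samples remain."""
    band_wins = {name: bands[name].data[:, a:b] for name in band_names}
    stat = np.stack(
        [window_statistics(band_wins[name], mslice) for name in band_names], axis=1
    )  # (channels, bands, 19)

    # spectral path: zero-pad truncated final windows to nominal length
    full = rec.data[:, a:b]
    if padded and full.shape[-1] < nominal:
        padn = nominal - full.shape[-1]
        full_sp = np.pad(full, ((0, 0), (0, padn)))
        mask_sp = np.pad(mslice, (0, padn))
    else:
        full_sp, mask_sp = full, mslice
    psd, _degenerate = welch_log_psd(full_sp, fs, baseline_bp, mask_sp, cfg.bands)

    asym = asymmetry_stats(band_wins, rec.channel_labels, SYMMETRIC_PAIRS, mslice)

    # per-window broadband power (3-47 Hz) feeding the Z-index
    keep = ~mask_sp
    if int(keep.sum()) >= 128:
        bp = welch_band_power(full_sp[:, keep], fs, cfg.bands)
        power = bp.sum(axis=-1)
    else:
        power = np.zeros(full.shape[0])
    return {"stat": stat, "psd": psd, "asym": asym, "power": power}


def predict_session(
    model,
    rec: EEGRecording,
    session: SessionMetadata,
    config: RunConfig | None = None,
):
    """Per-window and per-video predicted ratings for one session.

    Returns ``(features, window_ratings, video_ratings)`` where
    ``video_ratings`` maps video id to the majority vote over its
    windows (ties toward the smaller rating).
    """
    from .classify import majority_rating, predict_batch

    features = extract_features(rec, session, config)
    window_ratings = predict_batch(model, features)
    video_ratings: dict[str, int] = {}
    for vid in dict.fromkeys(features.video_ids or []):
        sel = np.asarray([v == vid for v in features.video_ids])
        video_ratings[vid] = majority_rating(window_ratings[sel])
    return features, window_ratings, video_ratings
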