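"""Per-window feature extraction.

Each advertisement's band-decomposed signal is cut into 10 s windows with
4 s overlap and summarized by four feature blocks:

* **stat** — 19 time-domain statistics per channel per band
  (14 x 4 x 19 = 1064 features),
* **psd** — log band power from a Welch estimate (128-sample segments,
  64 overlap, Hann taper) with the baseline band power removed before the
  logarithm (14 x 4 = 56 features),
* **asym** — the same 19 statistics of the left-minus-right difference
  series of the 7 symmetric electrode pairs, bands concatenated
  (7 x 19 = 133 features),
* **z** — the containing video's per-channel Z-index, the standardized
  deviation of the video's PSD distribution mean from the session mean
  (14 features).

The default vector is 1064 + 56 + 133 + 14 = 1267 features, in a fixed,
versioned order.  All statistics are computed over artifact-free samples
only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .eeg_io import EPOC_MONTAGE, SYMMETRIC_PAIRS
from .errors import (
    DegenerateWindowError,
    MontageError,
    ParameterError,
    UndefinedIndexError,
    ValidationError,
)
from .preprocess import DEFAULT_BANDS

FEATURE_SCHEMA_VERSION = "adlike-features-v1"

#: Floor applied to corrected band powers before taking the logarithm.
PSD_EPSILON = 1e-12

#: The 19 per-window statistics, in schema order.  The count is pinned to
#: 19 descriptors per band and channel; the set is standard EEG windowing
#: practice: location/scale/shape summaries, signal magnitude, waveform
#: complexity (Hjorth) and energy.
STAT_NAMES: tuple[str, ...] = (
    "mean", "sd", "var", "min", "max", "range", "median", "q1", "q3", "iqr",
    "skewness", "kurtosis", "rms", "mad", "line_length", "zero_crossings",
    "hjorth_mobility", "hjorth_complexity", "energy",
)

N_STATS = len(STAT_NAMES)  # 19


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 10 s windows advancing by 6 s (4 s overlap)."""

    length_s: float = 10.0
    overlap_s: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_s < self.length_s:
            raise ParameterError(
                f"overlap {self.overlap_s}s must lie in [0, length={self.length_s}s)"
            )

    @property
    def hop_s(self) -> float:
        return self.length_s - self.overlap_s


def slide_windows(duration_s: float, spec: WindowSpec = WindowSpec()) -> list[tuple[float, float, bool]]:
    """Window start/end times over ``[0, duration_s]``.

    Windows start at 0, hop, 2*hop, ...; the count for a duration of at
    least one window length is ``ceil((duration - length)/hop) + 1``, so a
    30 s ad under the default spec yields 5 windows.  A final window whose
    nominal end exceeds the duration is truncated (``padded=True``: it is
    zero-padded for spectral estimation and truncated for time-domain
    statistics).  A clip shorter than one window produces a single
    truncated window with a warning rather than an error.
    """
    if duration_s <= 0:
        raise ParameterError("duration must be positive")
    if duration_s < spec.length_s:
        warnings.warn(
            f"clip of {duration_s}s is shorter than the {spec.length_s}s window; "
            "emitting one truncated window",
            stacklevel=2,
        )
        return [(0.0, duration_s, True)]
    n = math.ceil((duration_s - spec.length_s) / spec.hop_s) + 1
    out: list[tuple[float, float, bool]] = []
    for i in range(n):
        start = i * spec.hop_s
        end = start + spec.length_s
        if end > duration_s + 1e-9:
            out.append((start, duration_s, True))
        else:
            out.append((start, end, False))
    return out


# ---------------------------------------------------------------------------
# The 19 window statistics
# ---------------------------------------------------------------------------

def window_statistics(series: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Compute the 19 statistics of one or many series.

    Parameters
    ----------
    series
        Array of shape ``(..., n)``; statistics are taken over the last
        axis.
    mask
        Optional boolean contamination flags of shape ``(n,)``; flagged
        samples are excluded.  Difference-based statistics (line length,
        zero crossings, Hjorth parameters) only use sample pairs that are
        adjacent in the original series and both clean, so excised
        stretches do not create spurious jumps.

    Returns
    -------
    Array of shape ``(..., 19)`` in :data:`STAT_NAMES` order.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    if mask is None:
        valid = np.ones(n, dtype=bool)
    else:
        valid = ~np.asarray(mask, dtype=bool)
        if valid.shape != (n,):
            raise ValidationError("mask length differs from series length")
    if int(valid.sum()) < 2:
        raise DegenerateWindowError(
            f"only {int(valid.sum())} clean samples in window; need at least 2"
        )

    xv = x[..., valid]
    m = int(valid.sum())

    mean = xv.mean(axis=-1)
    dev = xv - mean[..., None]
    m2 = np.mean(dev**2, axis=-1)          # population second moment
    var = dev.var(axis=-1, ddof=1) if m > 1 else np.zeros_like(mean)
    sd = np.sqrt(var)
    mn = xv.min(axis=-1)
    mx = xv.max(axis=-1)
    q1, med, q3 = np.percentile(xv, [25, 50, 75], axis=-1)
    rms = np.sqrt(np.mean(xv**2, axis=-1))
    mad = np.mean(np.abs(dev), axis=-1)
    energy = np.sum(xv**2, axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(m2 > 0, np.mean(dev**3, axis=-1) / np.where(m2 > 0, m2, 1) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, np.mean(dev**4, axis=-1) / np.where(m2 > 0, m2, 1) ** 2 - 3.0, 0.0)

    # difference statistics over pairs adjacent in the original series
    pair_ok = valid[:-1] & valid[1:]
    d = x[..., 1:] - x[..., :-1]
    dv = d[..., pair_ok]
    if dv.shape[-1] > 0:
        line_length = np.mean(np.abs(dv), axis=-1)
        var_d = np.var(dv, axis=-1)
    else:
        line_length = np.zeros_like(mean)
        var_d = np.zeros_like(mean)
    zc = np.sum((x[..., :-1] * x[..., 1:] < 0)[..., pair_ok], axis=-1).astype(float)

    var_x = np.var(xv, axis=-1)  # population variance for Hjorth ratios
    with np.errstate(invalid="ignore", divide="ignore"):
        mobility = np.where(var_x > 0, np.sqrt(var_d / np.where(var_x > 0, var_x, 1)), 0.0)

    triple_ok = valid[:-2] & valid[1:-1] & valid[2:]
    dd = x[..., 2:] - 2 * x[..., 1:-1] + x[..., :-2]
    ddv = dd[..., triple_ok]
    var_dd = np.var(ddv, axis=-1) if ddv.shape[-1] > 0 else np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        mob_d = np.where(var_d > 0, np.sqrt(var_dd / np.where(var_d > 0, var_d, 1)), 0.0)
        complexity = np.where(mobility > 0, mob_d / np.where(mobility > 0, mobility, 1), 0.0)

    return np.stack(
        [mean, sd, var, mn, mx, mx - mn, med, q1, q3, q3 - q1, skew, kurt,
         rms, mad, line_length, zc, mobility, complexity, energy],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# Welch band power
# ---------------------------------------------------------------------------

def welch_band_power(
    x: np.ndarray,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
    nperseg: int = 128,
    noverlap: int = 64,
) -> np.ndarray:
    """Integrated band power (uV^2) per band via Welch's PSD estimate.

    ``x`` has shape ``(..., n)`` with ``n >= nperseg``.  Band power is the
    PSD integrated (sum x bin width) over the band's inclusive frequency
    bins, so a flat spectrum yields power proportional to bandwidth.
    """
    bands = bands or DEFAULT_BANDS
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend=False, axis=-1,
    )
    df = freqs[1] - freqs[0]
    out = []
    for lo, hi in bands.values():
        sel = (freqs >= lo) & (freqs <= hi)
        out.append(psd[..., sel].sum(axis=-1) * df)
    return np.stack(out, axis=-1)


def welch_log_psd(
    window: np.ndarray,
    fs: float,
    baseline_band_power: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
    nperseg: int = 128,
    noverlap: int = 64,
) -> tuple[np.ndarray, bool]:
    """Log band power of one window, baseline-corrected.

    Flagged samples are dropped before the Welch estimate; if fewer than
    ``nperseg`` clean samples remain, or the corrected powers all collapse
    to the floor, the window is reported degenerate and every band takes
    the value ``log(PSD_EPSILON)``.

    Returns ``(log_power, degenerate)`` with ``log_power`` of shape
    ``(..., n_bands)`` in natural-log units.
    """
    x = np.asarray(window, dtype=float)
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        x = x[..., keep]
    n_bands = len(bands or DEFAULT_BANDS)
    if x.shape[-1] < nperseg:
        shape = x.shape[:-1] + (n_bands,)
        return np.full(shape, np.log(PSD_EPSILON)), True
    power = welch_band_power(x, fs, bands, nperseg, noverlap)
    if baseline_band_power is not None:
        power = power - np.asarray(baseline_band_power, dtype=float)
    floored = np.maximum(power, PSD_EPSILON)
    degenerate = bool(np.all(floored <= PSD_EPSILON))
    return np.log(floored), degenerate


# ---------------------------------------------------------------------------
# Asymmetry block
# ---------------------------------------------------------------------------

def asymmetry_stats(
    band_windows: dict[str, np.ndarray],
    channel_labels: tuple[str, ...] = EPOC_MONTAGE,
    pairs: tuple[tuple[str, str], ...] = SYMMETRIC_PAIRS,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Statistics of left-minus-right difference series per electrode pair.

    For each of the 7 symmetric pairs the per-band difference series are
    concatenated and summarized by the 19 window statistics, giving the
    133-entry asymmetry block.  Returns shape ``(n_pairs, 19)``.
    """
    labels = tuple(channel_labels)
    for left, right in pairs:
        if left not in labels or right not in labels:
            missing = [e for e in (left, right) if e not in labels]
            raise MontageError(f"asymmetry pair missing electrode(s) {missing}")
    band_names = tuple(band_windows)
    n = band_windows[band_names[0]].shape[-1]
    li = [labels.index(left) for left, _ in pairs]
    ri = [labels.index(right) for _, right in pairs]
    diffs = np.concatenate(
        [band_windows[b][li, :] - band_windows[b][ri, :] for b in band_names], axis=-1
    )  # (n_pairs, n_bands * n)
    big_mask = None if mask is None else np.tile(np.asarray(mask, dtype=bool), len(band_names))
    if big_mask is not None and big_mask.size != diffs.shape[-1]:
        raise ValidationError("mask length does not match band window length")
    return window_statistics(diffs, big_mask)


# ---------------------------------------------------------------------------
# Z-index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZIndexInputs:
    """Inputs for the Z-index of one channel over one video.

    ``x_bar`` is the mean of the video's N PSD values; ``mu`` and
    ``sigma`` are the mean and standard deviation of PSD activity over the
    whole session.
    """

    x_bar: float
    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise UndefinedIndexError(f"Z-index needs N >= 2 PSD values, got {self.n}")
        if not self.sigma > 0:
            raise UndefinedIndexError("Z-index undefined for zero session-wide sigma")


def z_index(zi: ZIndexInputs) -> float:
    """Standardized deviation ``(X_bar - mu) / (sigma / sqrt(N))``."""
    return (zi.x_bar - zi.mu) / (zi.sigma / math.sqrt(zi.n))


def valence_pair_correlation(
    z_by_video: np.ndarray,
    ratings: np.ndarray,
    channel_labels: tuple[str, ...] = EPOC_MONTAGE,
    pairs: tuple[tuple[str, str], ...] = SYMMETRIC_PAIRS,
) -> dict[str, dict[str, float] | None]:
    """Pearson r between left and right channel Z values, per valence group.

    Videos rated above 3 form the pleasant group, below 3 the unpleasant
    group; rating 3 is excluded.  A group with fewer than two videos
    yields ``None`` (flagged absent).  This is a training-time diagnostic:
    it needs labels, so it is never part of the per-window feature vector.
    """
    z = np.asarray(z_by_video, dtype=float)
    ratings = np.asarray(ratings)
    labels = tuple(channel_labels)
    out: dict[str, dict[str, float] | None] = {}
    for group, sel in (("pleasant", ratings > 3), ("unpleasant", ratings < 3)):
        if int(sel.sum()) < 2:
            out[group] = None
            continue
        corr: dict[str, float] = {}
        for left, right in pairs:
            zl = z[sel, labels.index(left)]
            zr = z[sel, labels.index(right)]
            if np.std(zl) == 0 or np.std(zr) == 0:
                corr[f"{left}-{right}"] = float("nan")
            else:
                corr[f"{left}-{right}"] = float(spstats.pearsonr(zl, zr)[0])
        out[group] = corr
    return out


# ---------------------------------------------------------------------------
# Schema and assembly
# ---------------------------------------------------------------------------

DEFAULT_BLOCKS = ("stat", "psd", "asym", "z")


def feature_names(
    channel_labels: tuple[str, ...] = EPOC_MONTAGE,
    band_names: tuple[str, ...] = tuple(DEFAULT_BANDS),
    pairs: tuple[tuple[str, str], ...] = SYMMETRIC_PAIRS,
    blocks: tuple[str, ...] = DEFAULT_BLOCKS,
) -> list[str]:
    """The deterministic feature schema: ``{block}.{channel|pair}.{band}.{stat}``."""
    names: list[str] = []
    if "stat" in blocks:
        names += [
            f"stat.{ch}.{b}.{s}"
            for ch in channel_labels for b in band_names for s in STAT_NAMES
        ]
    if "psd" in blocks:
        names += [f"psd.{ch}.{b}" for ch in channel_labels for b in band_names]
    if "asym" in blocks:
        names += [f"asym.{l}-{r}.all.{s}" for l, r in pairs for s in STAT_NAMES]
    if "z" in blocks:
        names += [f"z.{ch}" for ch in channel_labels]
    return names


def assemble_features(
    stat_block: np.ndarray | None,
    psd_block: np.ndarray | None,
    asym_block: np.ndarray | None,
    z_block: np.ndarray | None,
    channel_labels: tuple[str, ...] = EPOC_MONTAGE,
    band_names: tuple[str, ...] = tuple(DEFAULT_BANDS),
    pairs: tuple[tuple[str, str], ...] = SYMMETRIC_PAIRS,
) -> np.ndarray:
    """Concatenate per-window blocks in schema order, checking shapes.

    ``stat_block`` has shape (channels, bands, 19), ``psd_block``
    (channels, bands), ``asym_block`` (pairs, 19) and ``z_block``
    (channels,).  Blocks set to None are omitted (toggled off).
    """
    nc, nb, np_ = len(channel_labels), len(band_names), len(pairs)
    parts: list[np.ndarray] = []
    if stat_block is not None:
        if stat_block.shape != (nc, nb, N_STATS):
            raise ValidationError(
                f"stat block shape {stat_block.shape} != {(nc, nb, N_STATS)}"
            )
        parts.append(stat_block.reshape(-1))
    if psd_block is not None:
        if psd_block.shape != (nc, nb):
            raise ValidationError(f"psd block shape {psd_block.shape} != {(nc, nb)}")
        parts.append(psd_block.reshape(-1))
    if asym_block is not None:
        if asym_block.shape != (np_, N_STATS):
            raise ValidationError(f"asym block shape {asym_block.shape} != {(np_, N_STATS)}")
        parts.append(asym_block.reshape(-1))
    if z_block is not None:
        if z_block.shape != (nc,):
            raise ValidationError(f"z block shape {z_block.shape} != {(nc,)}")
        parts.append(np.asarray(z_block, dtype=float))
    if not parts:
        raise ValidationError("all feature blocks disabled; nothing to assemble")
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# Feature matrix container
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Windows x features with optional 1-5 labels and video bookkeeping."""

    names: list[str]
    X: np.ndarray
    labels: np.ndarray | None = None
    video_ids: list[str] | None = None
    schema_version: str = FEATURE_SCHEMA_VERSION
    config_hash: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValidationError(
                f"feature matrix shape {self.X.shape} inconsistent with "
                f"{len(self.names)} names"
            )
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names are not unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.X.shape[0],):
                raise ValidationError("label count differs from window count")
        if self.video_ids is not None and len(self.video_ids) != self.X.shape[0]:
            raise ValidationError("video id count differs from window count")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureMatrix(
            names=self.names,
            X=self.X[idx],
            labels=None if self.labels is None else self.labels[idx],
            video_ids=None if self.video_ids is None else [self.video_ids[i] for i in idx],
            schema_version=self.schema_version,
            config_hash=self.config_hash,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.names)
        if self.video_ids is not None:
            df.insert(0, "video_id", self.video_ids)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# schema={self.schema_version} config={self.config_hash}\n")
            df.to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
        schema_version, config_hash = FEATURE_SCHEMA_VERSION, ""
        if first.startswith("#"):
            for token in first[1:].split():
                if token.startswith("schema="):
                    schema_version = token[len("schema="):]
                elif token.startswith("config="):
                    config_hash = token[len("config="):]
        df = pd.read_csv(path, comment="#")
        labels = df.pop("label").to_numpy(dtype=int) if "label" in df.columns else None
        video_ids = df.pop("video_id").astype(str).tolist() if "video_id" in df.columns else None
        return cls(
            names=list(df.columns),
            X=df.to_numpy(dtype=float),
            labels=labels,
            video_ids=video_ids,
            schema_version=schema_version,
            config_hash=config_hash,
        )
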