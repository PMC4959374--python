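"""Reading and writing EEG recordings and session metadata.

A recording is a channels x samples matrix in microvolts with an ordered
list of 10-20 electrode labels; the reference montage is the 14-electrode
consumer-headset subset ``EPOC_MONTAGE``.  The canonical interchange format
is CSV (one header row of channel labels, one row per sample); EDF is
supported read-only.  Session metadata — who watched which advertisement
when, the 1-5 liking rating and whether the ad was later remembered — lives
in a small XML document.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import MontageError, ParseError, ValidationError

#: The 14-channel 10-20 montage of the low-cost headset, in capture order.
EPOC_MONTAGE: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Left/right symmetric electrode pairs used for asymmetry features.
SYMMETRIC_PAIRS: tuple[tuple[str, str], ...] = (
    ("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
    ("T7", "T8"), ("P7", "P8"), ("O1", "O2"),
)

DEFAULT_SAMPLING_RATE = 128.0


@dataclass
class EEGRecording:
    """Multichannel EEG recording in microvolts.

    Parameters
    ----------
    channel_labels
        Ordered 10-20 electrode names, one per data row.
    sampling_rate
        Sampling frequency in Hz (128 for the reference headset).
    data
        Real matrix of shape ``(n_channels, n_samples)``, microvolts.
    baseline
        Optional pre-session segment with the same channel ordering,
        used for baseline correction.
    """

    channel_labels: tuple[str, ...]
    sampling_rate: float
    data: np.ndarray
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording contains non-finite samples")
        if self.baseline is not None:
            self.baseline = np.asarray(self.baseline, dtype=float)
            if self.baseline.shape[0] != len(self.channel_labels):
                raise ValidationError("baseline channel count differs from data")
            if not np.all(np.isfinite(self.baseline)):
                raise ValidationError("baseline contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MontageError(f"channel {label!r} not present in montage") from None

    def with_data(self, data: np.ndarray, baseline: np.ndarray | None = None) -> "EEGRecording":
        """Copy of this recording with replaced sample matrices."""
        return replace(self, data=data, baseline=baseline if baseline is not None else self.baseline)

    def reorder(self, montage: tuple[str, ...] | list[str]) -> "EEGRecording":
        """Return a copy with channels permuted into ``montage`` order."""
        montage = tuple(montage)
        missing = [m for m in montage if m not in self.channel_labels]
        extra = [c for c in self.channel_labels if c not in montage]
        if missing or extra:
            raise MontageError(
                f"montage mismatch: missing {missing or 'none'}, unexpected {extra or 'none'}"
            )
        idx = [self.channel_labels.index(m) for m in montage]
        return EEGRecording(
            channel_labels=montage,
            sampling_rate=self.sampling_rate,
            data=self.data[idx],
            baseline=None if self.baseline is None else self.baseline[idx],
        )


@dataclass
class VideoEvent:
    """One advertisement viewing: timing, liking rating and recall flag."""

    video_id: str
    start_s: float
    end_s: float
    rating: int | None = None
    remembered: bool = False
    description: str = ""

    def validate(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"video {self.video_id!r}: start {self.start_s} must precede end {self.end_s}"
            )
        if self.rating is not None and self.rating not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"video {self.video_id!r}: rating {self.rating} outside 1..5"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SubjectProfile:
    subject_id: str = "anonymous"
    age: int | None = None
    gender: str = ""
    concentration_level: str = ""  # metadata only, never a model feature

    def validate(self) -> None:
        if self.concentration_level and self.concentration_level not in ("high", "medium", "low"):
            raise ValidationError(
                f"concentration level {self.concentration_level!r} not in high/medium/low"
            )


@dataclass
class SessionMetadata:
    """Subject profile plus the ordered, non-overlapping list of viewings."""

    subject: SubjectProfile = field(default_factory=SubjectProfile)
    videos: list[VideoEvent] = field(default_factory=list)

    def validate(self) -> None:
        self.subject.validate()
        for v in self.videos:
            v.validate()
        ordered = sorted(self.videos, key=lambda v: v.start_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_s < a.end_s:
                raise ValidationError(
                    f"videos {a.video_id!r} and {b.video_id!r} overlap "
                    f"({a.start_s}-{a.end_s} vs {b.start_s}-{b.end_s})"
                )

    def sorted(self) -> "SessionMetadata":
        return SessionMetadata(
            subject=self.subject,
            videos=sorted(self.videos, key=lambda v: v.start_s),
        )

    @property
    def is_labeled(self) -> bool:
        return bool(self.videos) and all(v.rating is not None for v in self.videos)


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path,
    format: str = "csv",
    expected_montage: tuple[str, ...] | list[str] = EPOC_MONTAGE,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    baseline_path: str | Path | None = None,
) -> EEGRecording:
    """Read a recording and reorder its channels to ``expected_montage``.

    CSV files carry one header row of channel labels and one row per
    sample, values in microvolts.  EDF files are imported through ``mne``
    (install the ``edf`` extra) and converted from volts to microvolts.
    An optional companion CSV at ``baseline_path`` supplies the
    pre-session baseline segment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        labels, data = _read_csv_matrix(path)
    elif format == "edf":
        labels, data, sampling_rate = _read_edf(path)
    else:
        raise ParseError(f"unknown recording format {format!r}")

    rec = EEGRecording(labels, sampling_rate, data)
    rec = rec.reorder(tuple(expected_montage))
    if baseline_path is not None:
        blabels, bdata = _read_csv_matrix(Path(baseline_path))
        brec = EEGRecording(blabels, sampling_rate, bdata).reorder(tuple(expected_montage))
        rec = replace(rec, baseline=brec.data)
    return rec


def write_recording(rec: EEGRecording, path: str | Path, baseline_path: str | Path | None = None) -> None:
    """Write a recording (and optionally its baseline) as canonical CSV."""
    _write_csv_matrix(Path(path), rec.channel_labels, rec.data)
    if baseline_path is not None:
        if rec.baseline is None:
            raise ValidationError("recording has no baseline segment to write")
        _write_csv_matrix(Path(baseline_path), rec.channel_labels, rec.baseline)


def _read_csv_matrix(path: Path) -> tuple[tuple[str, ...], np.ndarray]:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header:
            raise ParseError(f"{path}: empty file")
        labels = tuple(h.strip() for h in header.split(","))
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != len(labels):
                raise ParseError(
                    f"{path}: row {lineno} has {len(cells)} cells, expected {len(labels)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric cell in row {lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no sample rows")
    return labels, np.asarray(rows, dtype=float).T


def _write_csv_matrix(path: Path, labels: tuple[str, ...], data: np.ndarray) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(labels) + "\n")
        np.savetxt(fh, np.asarray(data).T, delimiter=",", fmt="%.9f")


def _read_edf(path: Path) -> tuple[tuple[str, ...], np.ndarray, float]:
    try:
        import mne
    except ImportError:  # pragma: no cover - mne is an optional extra
        raise ParseError(
            "EDF import requires mne; install the 'edf' extra (pip install adlike[edf])"
        ) from None
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads volts; store microvolts
    return tuple(raw.ch_names), data, float(raw.info["sfreq"])


# ---------------------------------------------------------------------------
# Session XML I/O
# ---------------------------------------------------------------------------
#
# Schema: root <session>; child <subject id age gender concentration/>;
# child <videos> holding <video id start end rating remembered> elements,
# each with a <description> text child.  Times are seconds relative to the
# start of the recording.

def read_session(path: str | Path) -> SessionMetadata:
    """Parse a session XML document, validating ratings and timing."""
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ParseError(f"{path}: malformed XML: {exc}") from None
    root = tree.getroot()
    if root.tag != "session":
        raise ParseError(f"{path}: root element is {root.tag!r}, expected 'session'")

    subj_el = root.find("subject")
    subject = SubjectProfile()
    if subj_el is not None:
        subject = SubjectProfile(
            subject_id=subj_el.get("id", "anonymous"),
            age=int(subj_el.get("age")) if subj_el.get("age") else None,
            gender=subj_el.get("gender", ""),
            concentration_level=subj_el.get("concentration", ""),
        )

    videos: list[VideoEvent] = []
    videos_el = root.find("videos")
    if videos_el is not None:
        for el in videos_el.findall("video"):
            rating_attr = el.get("rating")
            desc_el = el.find("description")
            try:
                video = VideoEvent(
                    video_id=el.get("id", ""),
                    start_s=float(el.get("start")),
                    end_s=float(el.get("end")),
                    rating=int(rating_attr) if rating_attr not in (None, "") else None,
                    remembered=el.get("remembered", "false").lower() == "true",
                    description=desc_el.text or "" if desc_el is not None else "",
                )
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: bad video element: {exc}") from None
            videos.append(video)

    session = SessionMetadata(subject=subject, videos=videos).sorted()
    session.validate()
    return session


def write_session(session: SessionMetadata, path: str | Path) -> None:
    """Serialize session metadata as XML; videos are written sorted by start."""
    session.validate()
    session = session.sorted()
    root = ET.Element("session")
    subj = session.subject
    attrs = {"id": subj.subject_id}
    if subj.age is not None:
        attrs["age"] = str(subj.age)
    if subj.gender:
        attrs["gender"] = subj.gender
    if subj.concentration_level:
        attrs["concentration"] = subj.concentration_level
    ET.SubElement(root, "subject", attrs)
    videos_el = ET.SubElement(root, "videos")
    for v in session.videos:
        v_el = ET.SubElement(
            videos_el,
            "video",
            {
                "id": v.video_id,
                "start": repr(v.start_s),
                "end": repr(v.end_s),
                "remembered": "true" if v.remembered else "false",
                **({"rating": str(v.rating)} if v.rating is not None else {}),
            },
        )
        ET.SubElement(v_el, "description").text = v.description
    ET.indent(root)
    ET.ElementTree(root).write(str(path), encoding="utf-8", xml_declaration=True)
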