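"""Containers and file I/O for multichannel EEG recordings.

The in-memory model mirrors how seizure-prediction studies organise their
data: a :class:`Recording` is a continuous multichannel signal (microvolts)
with seizure/artifact annotations; a :class:`Epoch` is one fixed-length
labeled window (the unit of feature extraction); an :class:`EpochSet` is an
ordered collection of same-shape epochs; a :class:`FeatureMatrix` is the
epochs-by-features table fed to screening and classification.

Supported on-disk formats
-------------------------
* EDF (16-bit European Data Format) for continuous scalp-EEG style data.
  Reading goes through :mod:`mne`; writing uses a minimal EDF writer since
  samples are stored as 16-bit integers against a per-channel physical
  range, round trips are exact only up to that quantization.
* Matrix-style clips (MATLAB v5 via :func:`scipy.io.loadmat`, HDF5 via
  :mod:`h5py`) for intracranial 10-minute segments with one label per clip.
* Tab-separated feature tables (lossless text round trip, header row).
* A plain-text annotation sidecar (``subject<TAB>onset_s<TAB>offset_s``),
  because EDF alone carries no machine-readable seizure onsets.

Readers never resample or filter; all mutation happens in
:mod:`preictal.preprocess`. Sample indices are 0-based, times are seconds
from recording start, intervals are half-open ``[t0, t1)``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


SEIZURE = "seizure"
ARTIFACT_EXCLUDE = "artifact_exclude"
_ANNOTATION_LABELS = frozenset({SEIZURE, ARTIFACT_EXCLUDE})


class EpochLabel(IntEnum):
    UNLABELED = -1
    INTERICTAL = 0
    PREICTAL = 1


@dataclass(frozen=True)
class Annotation:
    """One annotated interval: ``[onset, onset + duration)`` seconds."""

    onset: float
    duration: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in _ANNOTATION_LABELS:
            raise ValueError(f"unknown annotation label {self.label!r}")
        if self.duration < 0:
            raise ValueError("annotation duration must be >= 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    ``data`` has shape ``(n_channels, n_samples)``; ``fs`` is the shared
    sampling rate in Hz; ``channel_labels`` are unique strings in channel
    order; ``annotations`` mark seizures and excluded artifact spans.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    annotations: list[Annotation] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("n_channels must equal len(channel_labels)")
        dup = _first_duplicate(self.channel_labels)
        if dup is not None:
            raise ValueError(f"duplicate channel label {dup!r}")
        for a in self.annotations:
            if not 0 <= a.onset <= self.duration_s:
                raise ValueError(
                    f"annotation onset {a.onset} outside [0, {self.duration_s}]"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def seizure_onsets(self) -> list[float]:
        return sorted(a.onset for a in self.annotations if a.label == SEIZURE)


@dataclass
class Epoch:
    """One fixed-length window of a recording.

    ``group`` ties preictal epochs to the seizure they precede (and
    interictal epochs to a matched block) for seizure-wise cross-validation.
    """

    data: np.ndarray
    label: EpochLabel = EpochLabel.UNLABELED
    t_start: float = 0.0
    subject_id: str = ""
    group: int = -1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (n_channels, n_samples)")


class EpochSet:
    """Ordered, homogeneous collection of epochs.

    Temporal order is preserved (majority voting depends on it) and every
    epoch must share the same shape, sampling rate and channel labels.
    """

    def __init__(
        self,
        epochs: Sequence[Epoch],
        fs: float,
        channel_labels: list[str],
        epoch_seconds: float = 5.0,
    ):
        epochs = list(epochs)
        if fs <= 0 or epoch_seconds <= 0:
            raise ValueError("fs and epoch_seconds must be > 0")
        n_expected = int(round(epoch_seconds * fs))
        for e in epochs:
            if e.data.shape != (len(channel_labels), n_expected):
                raise ValueError(
                    f"epoch at t={e.t_start} has shape {e.data.shape}, "
                    f"expected {(len(channel_labels), n_expected)}"
                )
        self.epochs = epochs
        self.fs = float(fs)
        self.channel_labels = list(channel_labels)
        self.epoch_seconds = float(epoch_seconds)

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, i: int) -> Epoch:
        return self.epochs[i]

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.epochs], dtype=np.int64)

    def groups(self) -> np.ndarray:
        return np.array([e.group for e in self.epochs], dtype=np.int64)

    def data_array(self) -> np.ndarray:
        """Stack as (n_epochs, n_channels, n_epoch_samples)."""
        return np.stack([e.data for e in self.epochs])


@dataclass
class FeatureMatrix:
    """Epochs-by-features table with per-epoch class labels.

    ``values`` is ``(n_samples, n_features)``; ``feature_names`` encode
    (channel, feature) provenance such as ``ch3_fuzzyen``; ``labels`` holds
    :class:`EpochLabel` integers (or None when unlabeled).
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match n_features")
        dup = _first_duplicate(self.feature_names)
        if dup is not None:
            raise ValueError(f"duplicate feature name {dup!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels must align with rows")
        if self.values.shape[0] and self.values.shape[1]:
            all_nan = np.all(np.isnan(self.values), axis=0)
            if all_nan.any():
                bad = self.feature_names[int(np.argmax(all_nan))]
                raise ValueError(f"feature {bad!r} is all-NaN")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            self.values[:, idx],
            [self.feature_names[i] for i in idx],
            None if self.labels is None else self.labels.copy(),
        )


def _first_duplicate(names: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            return n
        seen.add(n)
    return None


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_scan_header(path: Path) -> tuple[list[str], list[int], float, int]:
    """Parse the fixed-width ASCII EDF header.

    Returns (labels, samples_per_record, record_duration, n_records).
    Used to validate label uniqueness and a single sampling rate before the
    data are handed to mne (which silently renames duplicates).
    """
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            rec_dur = float(head[244:252].decode("ascii").strip())
            n_sig = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed EDF header") from exc
        sig_head = f.read(256 * n_sig)
        if len(sig_head) < 256 * n_sig:
            raise FormatError(f"{path}: truncated EDF signal headers")
    labels = [
        sig_head[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
        for i in range(n_sig)
    ]
    off = n_sig * (16 + 80 + 8 * 5 + 80)
    spr = [
        int(sig_head[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
        for i in range(n_sig)
    ]
    return labels, spr, rec_dur, n_records


def read_edf(path: str | Path, annotations: list[Annotation] | None = None,
             subject_id: str | None = None) -> Recording:
    """Read a one-rate 16-bit EDF file into a :class:`Recording`.

    ``annotations`` (e.g. from :func:`read_annotation_sidecar`) are attached
    verbatim; EDF itself carries no machine-readable seizure onsets here.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels, spr, rec_dur, _ = _edf_scan_header(path)
    data_labels = [l for l in labels if l != "EDF Annotations"]
    dup = _first_duplicate(data_labels)
    if dup is not None:
        raise FormatError(f"{path}: duplicate channel label {dup!r}")
    rates = {s / rec_dur for l, s in zip(labels, spr) if l != "EDF Annotations"}
    if len(rates) > 1:
        raise FormatError(
            f"{path}: mixed sampling rates {sorted(rates)} are unsupported"
        )
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        annotations=list(annotations or []),
        subject_id=path.stem if subject_id is None else subject_id,
    )


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` as a minimal 16-bit EDF file.

    One data record per second (``fs`` must be a positive integer); the
    trailing partial second, if any, is zero-padded. Each channel's
    physical range is its data range widened to the 8-character ASCII
    header representation, so samples round-trip within half a digital
    step of that written range.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape
    n_rec = int(np.ceil(n_samp / fs)) if n_samp else 0

    def fmt(value: float, width: int = 8) -> bytes:
        for p in range(7, -1, -1):
            s = f"{value:.{p}g}"
            if len(s) <= width:
                return s.ljust(width).encode("ascii")
        raise ValueError(f"cannot format {value} in {width} chars")

    pmins, pmaxs, gains = [], [], []
    for ch in rec.data:
        lo = float(ch.min()) if ch.size else -1.0
        hi = float(ch.max()) if ch.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
        # round the range outward so the 8-char header string brackets it
        lo_s, hi_s = float(fmt(lo).strip()), float(fmt(hi).strip())
        if lo_s > lo:
            lo_s = float(fmt(lo - abs(lo) * 1e-6 - 1e-6).strip())
        if hi_s < hi:
            hi_s = float(fmt(hi + abs(hi) * 1e-6 + 1e-6).strip())
        pmins.append(lo_s)
        pmaxs.append(hi_s)
        gains.append((hi_s - lo_s) / (_EDF_DIG_MAX - _EDF_DIG_MIN))

    with open(path, "wb") as f:
        head = b"".join(
            [
                b"0".ljust(8),
                rec.subject_id[:80].ljust(80).encode("ascii", "replace"),
                b"".ljust(80),
                b"01.01.00",
                b"00.00.00",
                str(256 * (1 + n_ch)).ljust(8).encode(),
                b"".ljust(44),
                str(n_rec).ljust(8).encode(),
                b"1".ljust(8),
                str(n_ch).ljust(4).encode(),
            ]
        )
        f.write(head)
        f.write(b"".join(l[:16].ljust(16).encode() for l in rec.channel_labels))
        f.write(b"".ljust(80) * n_ch)
        f.write(b"uV".ljust(8) * n_ch)
        f.write(b"".join(fmt(v) for v in pmins))
        f.write(b"".join(fmt(v) for v in pmaxs))
        f.write(str(_EDF_DIG_MIN).ljust(8).encode() * n_ch)
        f.write(str(_EDF_DIG_MAX).ljust(8).encode() * n_ch)
        f.write(b"".ljust(80) * n_ch)
        f.write(str(fs).ljust(8).encode() * n_ch)
        f.write(b"".ljust(32) * n_ch)
        padded = np.zeros((n_ch, n_rec * fs))
        padded[:, :n_samp] = rec.data
        for r in range(n_rec):
            for c in range(n_ch):
                block = padded[c, r * fs : (r + 1) * fs]
                dig = np.round(
                    (block - pmins[c]) / gains[c] + _EDF_DIG_MIN
                ).astype(np.int16)
                f.write(struct.pack(f"<{fs}h", *dig))


def edf_quantization_step(rec: Recording) -> np.ndarray:
    """Per-channel physical size of one 16-bit digital step as written."""
    steps = []
    for ch in rec.data:
        lo = float(ch.min()) if ch.size else -1.0
        hi = float(ch.max()) if ch.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
        steps.append((hi - lo) / (_EDF_DIG_MAX - _EDF_DIG_MIN))
    return np.array(steps)


def read_annotation_sidecar(path: str | Path, subject_id: str | None = None
                            ) -> list[Annotation]:
    """Read the seizure sidecar: ``subject<TAB>onset_s<TAB>offset_s[<TAB>label]``.

    Lines whose subject does not match ``subject_id`` (when given) are
    skipped; a missing label column defaults to ``seizure``.
    """
    out: list[Annotation] = []
    for raw_line in Path(path).read_text().splitlines():
        line = raw_line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"sidecar line needs >=3 fields: {line!r}")
        subj, onset_s, offset_s = parts[0], float(parts[1]), float(parts[2])
        label = parts[3] if len(parts) > 3 else SEIZURE
        if subject_id is not None and subj != subject_id:
            continue
        out.append(Annotation(onset_s, offset_s - onset_s, label))
    return out


# ---------------------------------------------------------------------------
# Matrix-style clips
# ---------------------------------------------------------------------------

_RATE_KEYS = ("fs", "sampling_frequency", "sampling_rate", "freq")


def read_clip_matrix(path: str | Path, label: EpochLabel,
                     subject_id: str = "") -> Recording:
    """Read a channels-by-samples clip (MATLAB v5 or HDF5 layout).

    The file must hold a numeric array under ``data`` and a scalar
    sampling rate under one of ``fs``/``sampling_frequency``/
    ``sampling_rate``/``freq``. The whole clip receives one seizure-state
    annotation carrying ``label`` (preictal or interictal).
    """
    path = Path(path)
    contents: dict[str, np.ndarray] = {}
    try:
        from scipy.io import loadmat

        mat = loadmat(str(path))
        contents = {k: np.asarray(v) for k, v in mat.items()
                    if not k.startswith("__")}
    except (NotImplementedError, ValueError, OSError):
        # MATLAB v7.3 and plain HDF5 containers both land here
        try:
            import h5py

            with h5py.File(path, "r") as h5:
                contents = {k: np.asarray(h5[k]) for k in h5.keys()}
        except Exception as exc:
            raise FormatError(
                f"{path}: unreadable clip container ({exc})"
            ) from exc

    if "data" not in contents:
        raise FormatError(f"{path}: no 'data' array in clip")
    data = np.atleast_2d(np.asarray(contents["data"], dtype=np.float64))
    rate = None
    for key in _RATE_KEYS:
        if key in contents:
            rate = float(np.asarray(contents[key]).ravel()[0])
            break
    if rate is None:
        raise FormatError(
            f"{path}: no sampling-rate field (looked for {_RATE_KEYS})"
        )
    if data.shape[0] > data.shape[1]:  # stored samples-by-channels
        data = data.T
    n_ch = data.shape[0]
    rec = Recording(
        data=data,
        fs=rate,
        channel_labels=[f"ch{i}" for i in range(n_ch)],
        subject_id=subject_id or path.stem,
    )
    # the whole clip carries one class label (per-clip ground truth)
    rec.clip_label = EpochLabel(label)  # type: ignore[attr-defined]
    return rec


# ---------------------------------------------------------------------------
# Feature tables (TSV)
# ---------------------------------------------------------------------------

_LABEL_COL = "label"


def write_feature_table(fm: FeatureMatrix, path: str | Path) -> None:
    """Lossless TSV round trip: header row, shortest-repr floats, NaN kept."""
    if _LABEL_COL in fm.feature_names:
        raise ValueError(f"feature name {_LABEL_COL!r} collides with label column")
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    if fm.labels is not None:
        df.insert(0, _LABEL_COL, fm.labels)
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    labels = None
    if _LABEL_COL in df.columns:
        labels = df.pop(_LABEL_COL).to_numpy(dtype=np.int64)
    return FeatureMatrix(
        df.to_numpy(dtype=np.float64), list(df.columns), labels
    )
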