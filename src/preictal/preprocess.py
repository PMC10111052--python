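"""Cleaning, epoching and preictal/interictal labeling.

The cleaning chain is the standard scalp-EEG recipe: per-channel baseline
(mean) removal, a fourth-order Butterworth band-pass (0.5-70 Hz default)
applied forward-backward so filtering is zero-phase (phase-based
connectivity downstream must not see filter phase distortion), and an
optional mains notch (50 Hz default, Q=30 IIR). An ICA artifact-removal
stage is exposed only as a pluggable hook (identity by default): component
rejection is an interactive, expert-guided step that cannot be reproduced
programmatically.

Labeling rules (seizure-prediction convention):

* preictal  -- epochs fully inside ``[onset - preictal_minutes, onset)``;
* a seizure closer than ``min_interseizure_minutes`` to the previous one is
  skipped as a prediction target (its preictal window would overlap the
  previous event), though it still counts when measuring interictal
  distance;
* interictal -- epochs farther than ``interictal_gap_hours`` from every
  seizure, measured conservatively to both onset and offset;
* epochs overlapping an ``artifact_exclude`` span, and everything else
  (ictal, post-ictal, near-seizure), are dropped;
* the trailing partial window is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal

from .io_eeg import (
    ARTIFACT_EXCLUDE,
    SEIZURE,
    Epoch,
    EpochLabel,
    EpochSet,
    Recording,
)


class ConfigError(ValueError):
    """Invalid preprocessing configuration for the given recording."""


@dataclass
class PreprocessConfig:
    """Cleaning + labeling parameters.

    Defaults follow the scalp-EEG profile (30 min preictal horizon, 50 Hz
    mains). Intracranial profiles typically use ``preictal_minutes=60`` and
    ``notch_hz=None``.
    """

    bandpass_low: float = 0.5
    bandpass_high: float = 70.0
    butter_order: int = 4
    notch_hz: float | None = 50.0
    notch_q: float = 30.0
    epoch_seconds: float = 5.0
    preictal_minutes: float = 30.0
    interictal_gap_hours: float = 4.0
    min_interseizure_minutes: float = 30.0

    def validate_epoching(self) -> None:
        if self.epoch_seconds <= 0:
            raise ConfigError("epoch_seconds must be > 0")

    def validate(self, fs: float) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ConfigError("need 0 < bandpass_low < bandpass_high")
        if self.bandpass_high >= fs / 2:
            raise ConfigError(
                f"bandpass_high {self.bandpass_high} >= Nyquist {fs / 2}"
            )
        if self.notch_hz is not None and self.notch_hz >= fs / 2:
            raise ConfigError(f"notch {self.notch_hz} >= Nyquist {fs / 2}")
        self.validate_epoching()


def remove_baseline(rec: Recording) -> Recording:
    """Subtract each channel's mean (baseline-drift removal)."""
    if rec.n_samples < 1:
        raise ValueError("empty recording")
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return Recording(data, rec.fs, list(rec.channel_labels),
                     list(rec.annotations), rec.subject_id)


def bandpass(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Zero-phase Butterworth band-pass; shape preserved."""
    cfg.validate(rec.fs)
    sos = signal.butter(
        cfg.butter_order,
        [cfg.bandpass_low, cfg.bandpass_high],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(data, rec.fs, list(rec.channel_labels),
                     list(rec.annotations), rec.subject_id)


def notch(rec: Recording, notch_hz: float | None, q: float = 30.0) -> Recording:
    """Zero-phase IIR mains notch; ``notch_hz=None`` is the identity."""
    if notch_hz is None:
        return rec
    if notch_hz >= rec.fs / 2:
        raise ConfigError(f"notch {notch_hz} >= Nyquist {rec.fs / 2}")
    b, a = signal.iirnotch(notch_hz, q, fs=rec.fs)
    data = signal.filtfilt(b, a, rec.data, axis=1)
    return Recording(data, rec.fs, list(rec.channel_labels),
                     list(rec.annotations), rec.subject_id)


IcaHook = Callable[[Recording], Recording]


def clean(rec: Recording, cfg: PreprocessConfig,
          ica_hook: IcaHook | None = None) -> Recording:
    """Baseline removal -> band-pass -> notch -> optional artifact hook."""
    cfg.validate(rec.fs)
    out = remove_baseline(rec)
    out = bandpass(out, cfg)
    out = notch(out, cfg.notch_hz, cfg.notch_q)
    if ica_hook is not None:
        out = ica_hook(out)
    return out


def _target_seizures(onsets: list[float], min_gap_s: float) -> list[bool]:
    """Which seizures are usable prediction targets (inter-seizure gap rule)."""
    usable = []
    for i, on in enumerate(onsets):
        usable.append(i == 0 or on - onsets[i - 1] >= min_gap_s)
    return usable


def label_and_epoch(rec: Recording, cfg: PreprocessConfig) -> EpochSet:
    """Cut the recording on a fixed grid and label each epoch.

    Epochs are tiled from t=0 every ``epoch_seconds``; the trailing partial
    window is dropped. Preictal epochs carry the index of their target
    seizure in ``Epoch.group``; unlabeled epochs are dropped entirely when
    annotations are present, and kept as UNLABELED when the recording has
    no annotations at all.
    """
    cfg.validate_epoching()
    n_per = int(round(cfg.epoch_seconds * rec.fs))
    if n_per > rec.n_samples:
        raise ValueError("epoch longer than recording")
    n_epochs = rec.n_samples // n_per

    seiz = sorted(
        (a for a in rec.annotations if a.label == SEIZURE),
        key=lambda a: a.onset,
    )
    onsets = [a.onset for a in seiz]
    offsets = [a.offset for a in seiz]
    usable = _target_seizures(onsets, cfg.min_interseizure_minutes * 60.0)
    artifacts = [a for a in rec.annotations if a.label == ARTIFACT_EXCLUDE]

    pre_s = cfg.preictal_minutes * 60.0
    gap_s = cfg.interictal_gap_hours * 3600.0
    has_ann = bool(rec.annotations)

    epochs: list[Epoch] = []
    for k in range(n_epochs):
        t0 = k * cfg.epoch_seconds
        t1 = t0 + cfg.epoch_seconds
        if any(a.onset < t1 and a.offset > t0 for a in artifacts):
            continue
        window = rec.data[:, k * n_per : (k + 1) * n_per]
        if not has_ann:
            epochs.append(Epoch(window, EpochLabel.UNLABELED, t0,
                                rec.subject_id))
            continue
        label = None
        group = -1
        for i, on in enumerate(onsets):
            if usable[i] and on - pre_s <= t0 and t1 <= on:
                label, group = EpochLabel.PREICTAL, i
                break
        if label is None:
            far = all(
                t1 <= on - gap_s or t0 >= off + gap_s
                for on, off in zip(onsets, offsets)
            )
            if far and onsets:
                label = EpochLabel.INTERICTAL
            elif not onsets:
                label = EpochLabel.UNLABELED
        if label is None:
            continue
        if label == EpochLabel.INTERICTAL:
            # tie interictal epochs to the next usable seizure so each CV
            # fold holds out a matched interictal block
            upcoming = [i for i, on in enumerate(onsets)
                        if usable[i] and on >= t1]
            usable_all = [i for i in range(len(onsets)) if usable[i]]
            if upcoming:
                group = upcoming[0]
            elif usable_all:
                group = usable_all[-1]
        epochs.append(Epoch(window, label, t0, rec.subject_id, group))

    return EpochSet(epochs, rec.fs, list(rec.channel_labels),
                    cfg.epoch_seconds)
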