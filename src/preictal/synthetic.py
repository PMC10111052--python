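"""Seeded generators for desk-scale testing of the whole pipeline.

Two generators:

* :func:`generate_eeg` builds a two-class multichannel "EEG" recording in
  which preictal and interictal stretches differ along exactly the three
  axes the feature families measure: inter-channel phase coupling (a
  shared oscillatory source mixed at a class-specific weight -> PLV),
  signal complexity (class-specific white-noise scale -> fuzzy entropy)
  and rhythm band power (class-specific band amplitude gains -> RPSD/SPR).
  Every channel is  coupling * shared + (1 - coupling) * private + AR(2)
  pink-like background + white noise,  where shared and private parts are
  sums of five band-limited oscillators with randomized frequencies and
  phases. The default configuration is the "easy" study condition: strong
  preictal coupling (0.9 vs 0.1), doubled preictal noise (complexity up
  before seizures), and 1.5x interictal band gains (spectral power higher
  between seizures); each contrast is independently switchable so
  temporal-only / spatial-only ablations have a synthetic analogue.

* :func:`generate_planted_features` builds a feature matrix with known
  column roles (class-informative, exact redundant copies, constants, and
  label-shuffled noise clones) for selection-recovery experiments.

All outputs are bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .io_eeg import Annotation, EpochLabel, FeatureMatrix, Recording, SEIZURE

#: AR(2) coefficients for the pink-like background: poles at 0.95 and 0.40
AR_COEFFS = (1.35, -0.38)

_BAND_FREQS = ((0.5, 4.0), (4.0, 8.0), (8.0, 14.0), (14.0, 30.0), (30.0, 45.0))


@dataclass
class SynthEEGConfig:
    """Study conditions for the two-class synthetic EEG.

    The timeline repeats one unit per seizure: an interictal block of
    ``preictal_span_s`` seconds, a preictal block of the same length, the
    seizure onset, and a post-onset guard. Defaults encode the easy
    desk-scale condition (a 5-minute analogue of a 30-minute preictal
    horizon, 4 seizures, 8 channels at 256 Hz).
    """

    n_channels: int = 8
    fs: float = 128.0
    duration_s: float = 2640.0
    seizure_times: tuple[float, ...] = (600.0, 1260.0, 1920.0, 2580.0)
    preictal_span_s: float = 300.0
    postictal_guard_s: float = 60.0
    coupling_interictal: float = 0.1
    coupling_preictal: float = 0.9
    noise_scale_interictal: float = 5.0
    noise_scale_preictal: float = 10.0
    band_gain_interictal: tuple[float, ...] = (30.0, 15.0, 15.0, 7.5, 4.5)
    band_gain_preictal: tuple[float, ...] = (20.0, 10.0, 10.0, 5.0, 3.0)
    ar_scale: float = 8.0
    epoch_seconds: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.coupling_interictal <= 1
                and 0 <= self.coupling_preictal <= 1):
            raise ValueError("coupling weights must lie in [0, 1]")
        if self.noise_scale_preictal < self.noise_scale_interictal:
            raise ValueError(
                "preictal noise scale must be >= interictal (complexity "
                "rises before seizures in this model)"
            )
        if any(g <= 0 for g in
               self.band_gain_interictal + self.band_gain_preictal):
            raise ValueError("band gains must be > 0")
        if self.fs <= 2 * _BAND_FREQS[-1][1]:
            raise ValueError("fs must exceed twice the highest oscillation")
        for t in self.seizure_times:
            if not 0 < t <= self.duration_s:
                raise ValueError(f"seizure time {t} outside recording")
            if t - self.preictal_span_s < 0:
                raise ValueError(f"preictal span before seizure at {t} "
                                 "starts before the recording")

    @classmethod
    def null(cls, **overrides) -> "SynthEEGConfig":
        """All class contrasts switched off (no separating signal)."""
        base = dict(
            coupling_interictal=0.5,
            coupling_preictal=0.5,
            noise_scale_interictal=7.5,
            noise_scale_preictal=7.5,
            band_gain_interictal=(25.0, 12.5, 12.5, 6.25, 3.75),
            band_gain_preictal=(25.0, 12.5, 12.5, 6.25, 3.75),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class EpochTruth:
    """Generator ground truth on the 5-s epoch grid."""

    t_start: np.ndarray
    labels: np.ndarray  # EpochLabel integers
    groups: np.ndarray  # seizure/unit index, -1 when unlabeled


def _class_params(cfg: SynthEEGConfig, label: int):
    if label == EpochLabel.PREICTAL:
        return (cfg.coupling_preictal, cfg.noise_scale_preictal,
                cfg.band_gain_preictal)
    return (cfg.coupling_interictal, cfg.noise_scale_interictal,
            cfg.band_gain_interictal)


def _oscillation(rng: np.random.Generator, t: np.ndarray,
                 gains: tuple[float, ...]) -> np.ndarray:
    out = np.zeros_like(t)
    for (lo, hi), g in zip(_BAND_FREQS, gains):
        f = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * np.pi)
        out += g * np.sin(2 * np.pi * f * t + phase)
    return out


def _ar_background(rng: np.random.Generator, n: int, scale: float
                   ) -> np.ndarray:
    w = rng.standard_normal(n)
    a1, a2 = AR_COEFFS
    x = lfilter([1.0], [1.0, -a1, -a2], w)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def _segments(cfg: SynthEEGConfig) -> list[tuple[float, float, int, int]]:
    """(t0, t1, label, unit) covering [0, duration); label UNLABELED in guards."""
    onsets = sorted(cfg.seizure_times)
    marks: list[tuple[float, float, int, int]] = []
    cursor = 0.0
    for k, on in enumerate(onsets):
        pre0 = on - cfg.preictal_span_s
        if pre0 < cursor - 1e-9:
            raise ValueError("preictal spans overlap; space the seizures out")
        if pre0 > cursor:
            marks.append((cursor, pre0, int(EpochLabel.INTERICTAL), k))
        marks.append((pre0, on, int(EpochLabel.PREICTAL), k))
        guard_end = min(on + cfg.postictal_guard_s, cfg.duration_s)
        if guard_end > on:
            marks.append((on, guard_end, int(EpochLabel.UNLABELED), k))
        cursor = guard_end
    if cursor < cfg.duration_s:
        marks.append((cursor, cfg.duration_s, int(EpochLabel.INTERICTAL),
                      len(onsets) - 1))
    return marks


def generate_eeg(cfg: SynthEEGConfig) -> tuple[Recording, EpochTruth]:
    """Synthesize the recording and its ground-truth epoch labels.

    Interictal epochs inherit the unit index of the seizure they precede
    (``EpochTruth.groups``), giving each fold of seizure-wise CV a matched
    interictal block.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = int(round(cfg.duration_s * cfg.fs))
    data = np.zeros((cfg.n_channels, n_total))

    for (t0, t1, label, _unit) in _segments(cfg):
        i0, i1 = int(round(t0 * cfg.fs)), int(round(t1 * cfg.fs))
        if i1 <= i0:
            continue
        n = i1 - i0
        t = np.arange(i0, i1) / cfg.fs
        coupling, noise_scale, gains = _class_params(cfg, label)
        shared = _oscillation(rng, t, gains)
        for c in range(cfg.n_channels):
            private = _oscillation(rng, t, gains)
            background = _ar_background(rng, n, cfg.ar_scale)
            white = noise_scale * rng.standard_normal(n)
            data[c, i0:i1] = (
                coupling * shared + (1.0 - coupling) * private
                + background + white
            )

    annotations = [Annotation(on, 0.0, SEIZURE) for on in
                   sorted(cfg.seizure_times)]
    rec = Recording(
        data=data,
        fs=cfg.fs,
        channel_labels=[f"synth{i}" for i in range(cfg.n_channels)],
        annotations=annotations,
        subject_id=f"synthetic-{cfg.seed}",
    )

    # ground truth on the epoch grid: an epoch keeps a class label only
    # when it lies entirely inside a segment of that class
    n_epochs = int(cfg.duration_s // cfg.epoch_seconds)
    t_start = np.arange(n_epochs) * cfg.epoch_seconds
    labels = np.full(n_epochs, int(EpochLabel.UNLABELED), dtype=np.int64)
    groups = np.full(n_epochs, -1, dtype=np.int64)
    for (t0, t1, label, unit) in _segments(cfg):
        if label == EpochLabel.UNLABELED:
            continue
        inside = (t_start >= t0 - 1e-9) & (t_start + cfg.epoch_seconds <= t1 + 1e-9)
        labels[inside] = label
        groups[inside] = unit
    return rec, EpochTruth(t_start=t_start, labels=labels, groups=groups)


@dataclass
class PlantedFeatureConfig:
    """Feature matrix with known column roles.

    informative: class-shifted unit Gaussians (between-class mean shift =
    ``effect_size``); redundant: exact copies of informative columns
    (cyclically); constant: one repeated value; noise: informative-style
    draws against a permuted label vector (identical marginal, no class
    association).
    """

    n_samples: int = 500
    n_informative: int = 5
    n_redundant: int = 5
    n_constant: int = 10
    n_noise: int = 10
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_samples, self.n_informative, self.n_redundant,
                  self.n_constant, self.n_noise)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        total = sum(counts[1:])
        if total < 2:
            raise ValueError("need at least 2 features")
        if self.n_redundant and not self.n_informative:
            raise ValueError("redundant copies need informative sources")


def generate_planted_features(cfg: PlantedFeatureConfig
                              ) -> tuple[FeatureMatrix, list[str]]:
    """Build the planted matrix; returns (matrix, per-column roles)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    y = rng.permutation(np.repeat(
        [int(EpochLabel.INTERICTAL), int(EpochLabel.PREICTAL)],
        [n - n // 2, n // 2],
    ))

    def informative_column(labels: np.ndarray) -> np.ndarray:
        shift = (labels == EpochLabel.PREICTAL) - 0.5
        return shift * cfg.effect_size + rng.standard_normal(n)

    cols: list[np.ndarray] = []
    names: list[str] = []
    roles: list[str] = []
    for i in range(cfg.n_informative):
        cols.append(informative_column(y))
        names.append(f"informative{i}")
        roles.append("informative")
    for i in range(cfg.n_redundant):
        cols.append(cols[i % cfg.n_informative].copy())
        names.append(f"redundant{i}")
        roles.append("redundant")
    for i in range(cfg.n_constant):
        cols.append(np.full(n, 1.0))
        names.append(f"constant{i}")
        roles.append("constant")
    for i in range(cfg.n_noise):
        cols.append(informative_column(rng.permutation(y)))
        names.append(f"noise{i}")
        roles.append("noise")

    fm = FeatureMatrix(np.column_stack(cols), names, y)
    return fm, roles
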