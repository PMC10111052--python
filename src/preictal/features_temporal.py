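"""Per-channel temporal features: fuzzy entropy and spectral band powers.

Fuzzy entropy (FuzzyEn)
-----------------------
FuzzyEn(m, r, N) = ln Phi^m(r) - ln Phi^{m+1}(r), where Phi^d(r) averages,
over all length-d embedded templates with their windowed mean removed, the
fuzzy (Gaussian-like) similarity A = exp(-ln2 * (d_cheb / r)^2) between
template pairs (self-matches excluded; Chebyshev distance after baseline
removal). The tolerance is r = r_factor * std(x), so FuzzyEn is invariant
to amplitude scaling and offsets. Low values mean a regular, predictable
signal (a sinusoid); high values mean a complex one (noise). A degenerate
zero-variance epoch returns 0 by convention.

The hot path is a numba kernel (O(N^2) pairs); a vectorized
pdist-based fallback is used when numba is unavailable. Both follow the
same literal definition.

Band powers
-----------
Welch's averaged periodogram (Hamming segments, 50% overlap by default)
estimates the PSD; the rhythm power in each canonical EEG band (delta,
theta, alpha, beta, gamma) is the natural log of the summed PSD over that
band (RPSD), and the 10 spectral power ratios (SPR) are all ordered
higher-minus-lower band differences of the RPSDs, i.e. log band-power
ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.spatial.distance import pdist, squareform

from .preprocess import ConfigError

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

#: log floor substituted for log(0) band power
LOG_FLOOR = float(np.log(np.finfo(np.float64).tiny))


@dataclass(frozen=True)
class FuzzyEnParams:
    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("tolerance factor must be > 0")


@dataclass(frozen=True)
class WelchParams:
    segment_seconds: float = 1.0
    overlap_fraction: float = 0.5
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.segment_seconds <= 0:
            raise ValueError("segment_seconds must be > 0")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")


@dataclass(frozen=True)
class BandSet:
    """Ordered, contiguous canonical EEG rhythm bands (Hz)."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 14.0),
        ("beta", 14.0, 30.0),
        ("gamma", 30.0, 70.0),
    )

    def __post_init__(self) -> None:
        for (n0, l0, h0), (n1, l1, h1) in zip(self.bands, self.bands[1:]):
            if h0 != l1:
                raise ValueError(f"bands {n0} and {n1} are not contiguous")
            if l0 >= h0 or l1 >= h1:
                raise ValueError("band edges must be increasing")

    @classmethod
    def default(cls, gamma_high: float = 70.0) -> "BandSet":
        """Canonical bands with the gamma ceiling at the band-pass cutoff."""
        return cls(
            (
                ("delta", 0.5, 4.0),
                ("theta", 4.0, 8.0),
                ("alpha", 8.0, 14.0),
                ("beta", 14.0, 30.0),
                ("gamma", 30.0, float(gamma_high)),
            )
        )

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]


#: SPR naming convention: higher band minus lower band.
SPR_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("TD", "theta", "delta"),
    ("AD", "alpha", "delta"),
    ("BD", "beta", "delta"),
    ("GD", "gamma", "delta"),
    ("AT", "alpha", "theta"),
    ("BT", "beta", "theta"),
    ("GT", "gamma", "theta"),
    ("BA", "beta", "alpha"),
    ("GA", "gamma", "alpha"),
    ("GB", "gamma", "beta"),
)


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=False)
    def _phi_kernel(x: np.ndarray, d: int, r: float) -> float:
        n = x.shape[0]
        nv = n - d + 1
        mu = np.empty(nv)
        for i in range(nv):
            s = 0.0
            for p in range(d):
                s += x[i + p]
            mu[i] = s / d
        acc = np.zeros(nv)
        c = math.log(2.0) / (r * r)
        for i in range(nv):
            for j in range(i + 1, nv):
                dm = 0.0
                for p in range(d):
                    v = abs((x[i + p] - mu[i]) - (x[j + p] - mu[j]))
                    if v > dm:
                        dm = v
                a = math.exp(-c * dm * dm)
                acc[i] += a
                acc[j] += a
        total = 0.0
        for i in range(nv):
            total += acc[i] / (nv - 1)
        return total / nv


def _phi_numpy(x: np.ndarray, d: int, r: float) -> float:
    emb = np.lib.stride_tricks.sliding_window_view(x, d)
    emb = emb - emb.mean(axis=1, keepdims=True)
    dist = pdist(emb, metric="chebyshev")
    a = np.exp(-np.log(2.0) * (dist / r) ** 2)
    rows = squareform(a).sum(axis=1)  # diagonal is zero: self excluded
    nv = emb.shape[0]
    return float((rows / (nv - 1)).mean())


def _phi(x: np.ndarray, d: int, r: float) -> float:
    if _HAVE_NUMBA:
        return float(_phi_kernel(x, d, r))
    return _phi_numpy(x, d, r)


def fuzzy_entropy(x: np.ndarray, params: FuzzyEnParams = FuzzyEnParams()
                  ) -> float:
    """Fuzzy entropy of a single-channel epoch.

    Requires ``len(x) >= m + 2`` (so the (m+1)-template set has at least
    two members). Returns 0.0 for a zero-variance epoch (the tolerance
    r = r_factor * std would be undefined).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("fuzzy_entropy expects a 1-D signal")
    n, m = x.shape[0], params.m
    if n < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples, got {n}")
    r = params.r_factor * float(np.std(x))
    if r == 0.0:
        return 0.0
    return math.log(_phi(x, m, r)) - math.log(_phi(x, m + 1, r))


def welch_psd(x: np.ndarray, fs: float,
              wp: WelchParams = WelchParams()) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of one epoch: (frequencies, nonnegative power densities)."""
    x = np.asarray(x, dtype=np.float64)
    nperseg = int(round(wp.segment_seconds * fs))
    if nperseg > x.shape[-1]:
        raise ConfigError(
            f"Welch segment ({nperseg} samples) longer than epoch "
            f"({x.shape[-1]} samples)"
        )
    freqs, psd = _signal.welch(
        x,
        fs=fs,
        window=wp.window,
        nperseg=nperseg,
        noverlap=int(nperseg * wp.overlap_fraction),
    )
    return freqs, psd


def rpsd(freqs: np.ndarray, psd: np.ndarray,
         bands: BandSet = BandSet()) -> np.ndarray:
    """Per-band log-summed power (natural log), one value per band.

    A band whose total power is zero maps to :data:`LOG_FLOOR`; a band with
    no grid frequency raises (the PSD resolution cannot resolve it).
    """
    out = np.empty(len(bands.bands))
    last = len(bands.bands) - 1
    for i, (name, lo, hi) in enumerate(bands.bands):
        mask = (freqs >= lo) & ((freqs <= hi) if i == last else (freqs < hi))
        if not mask.any():
            raise ValueError(
                f"no spectral grid frequency falls in band {name} "
                f"[{lo}, {hi}) -- increase the Welch segment length"
            )
        total = float(psd[mask].sum())
        out[i] = np.log(total) if total > 0 else LOG_FLOOR
    return out


def spr(rpsd_values: np.ndarray, bands: BandSet = BandSet()) -> np.ndarray:
    """All 10 ordered higher-minus-lower band RPSD differences."""
    rpsd_values = np.asarray(rpsd_values, dtype=np.float64)
    if rpsd_values.shape != (len(bands.bands),):
        raise ValueError("expected one RPSD value per band")
    idx = {name: i for i, name in enumerate(bands.names)}
    return np.array(
        [rpsd_values[idx[hi]] - rpsd_values[idx[lo]] for _, hi, lo in SPR_PAIRS]
    )


def temporal_feature_names(n_channels: int,
                           bands: BandSet = BandSet()) -> list[str]:
    names: list[str] = []
    for c in range(n_channels):
        names.append(f"ch{c}_fuzzyen")
        names.extend(f"ch{c}_rpsd_{b}" for b in bands.names)
        names.extend(f"ch{c}_spr_{p[0]}" for p in SPR_PAIRS)
    return names


def temporal_feature_block(
    epoch_data: np.ndarray,
    fs: float,
    fuzzy: FuzzyEnParams = FuzzyEnParams(),
    welch: WelchParams = WelchParams(),
    bands: BandSet = BandSet(),
) -> tuple[np.ndarray, list[str]]:
    """16 temporal features per channel: 1 FuzzyEn + 5 RPSD + 10 SPR.

    Returns (values, names) with deterministic ``ch{idx}_{feat}`` naming.
    """
    epoch_data = np.atleast_2d(np.asarray(epoch_data, dtype=np.float64))
    n_ch = epoch_data.shape[0]
    values: list[float] = []
    for c in range(n_ch):
        x = epoch_data[c]
        values.append(fuzzy_entropy(x, fuzzy))
        freqs, psd = welch_psd(x, fs, welch)
        bp = rpsd(freqs, psd, bands)
        values.extend(bp)
        values.extend(spr(bp, bands))
    return np.array(values), temporal_feature_names(n_ch, bands)
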