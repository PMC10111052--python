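"""Two-dimensional filter screen: independence x information.

The screen is unsupervised. For a feature matrix with m features over n
samples:

* independence of feature i:  ind_i = sum_{k != i} (1 - |r_ik|), the sum of
  one-minus-absolute Pearson correlations against every other feature
  (range [0, m-1]; large = non-redundant). A zero-variance feature has no
  defined correlation and is assigned r = 0 against all others.
* information of feature i:  inf_i = var(X_i) * H(X_i), the population
  variance times the Shannon entropy (bits) of the feature's equal-width
  histogram over its observed range (10 bins by default). Variance
  captures fluctuation, entropy captures value diversity; a constant
  feature carries zero information.
* score_i = ind_i * inf_i; features are ranked by descending score and the
  top k survive.

The ablation baselines rank by a single criterion (independence or
information) or perform no selection at all (original column order).
Ranking ties break deterministically toward the lower original index.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io_eeg import FeatureMatrix

__all__ = [
    "FeatureMatrix",
    "SelectionScheme",
    "SelectionResult",
    "independence",
    "information",
    "score_and_select",
]


class SelectionScheme(str, Enum):
    NONE = "none"
    INDEPENDENCE = "independence"
    INFORMATION = "information"
    SCORE = "score"


@dataclass
class SelectionResult:
    ind: np.ndarray
    info: np.ndarray
    score: np.ndarray
    selected: list[int]
    k: int
    scheme: SelectionScheme

    def selected_names(self, fm: FeatureMatrix) -> list[str]:
        return [fm.feature_names[i] for i in self.selected]

    def to_dict(self, fm: FeatureMatrix | None = None) -> dict:
        d = {
            "scheme": self.scheme.value,
            "k": self.k,
            "selected": list(map(int, self.selected)),
            "ind": self.ind.tolist(),
            "info": self.info.tolist(),
            "score": self.score.tolist(),
        }
        if fm is not None:
            d["selected_names"] = self.selected_names(fm)
        return d


def _values(fm: FeatureMatrix | np.ndarray) -> np.ndarray:
    v = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)
    return np.asarray(v, dtype=np.float64)


def independence(fm: FeatureMatrix | np.ndarray) -> np.ndarray:
    """ind_i = sum over k != i of (1 - |pearson r_ik|)."""
    x = _values(fm)
    n, m = x.shape
    if n < 3:
        raise ValueError("independence needs at least 3 samples")
    sd = x.std(axis=0)
    ok = sd > 0
    r = np.zeros((m, m))
    if ok.sum() >= 2:
        r[np.ix_(ok, ok)] = np.corrcoef(x[:, ok], rowvar=False)
    np.fill_diagonal(r, 1.0)
    # |r| can exceed 1 by rounding; clip to keep ind >= 0
    absr = np.minimum(np.abs(r), 1.0)
    return (m - 1) - (absr.sum(axis=1) - 1.0)


def information(fm: FeatureMatrix | np.ndarray, bins: int = 10) -> np.ndarray:
    """inf_i = population variance x histogram Shannon entropy (bits)."""
    if bins < 2:
        raise ValueError("need at least 2 histogram bins")
    x = _values(fm)
    n, m = x.shape
    out = np.empty(m)
    for i in range(m):
        col = x[:, i]
        var = float(col.var())  # population (1/N) convention
        if var == 0.0:
            out[i] = 0.0
            continue
        lo, hi = float(col.min()), float(col.max())
        span = hi - lo
        if not np.isfinite(span) or span <= max(abs(lo), abs(hi)) * 1e-12:
            # numerically one level: no resolvable diversity
            out[i] = 0.0
            continue
        counts, _ = np.histogram(col, bins=bins)
        p = counts[counts > 0] / n
        h = float(-(p * np.log2(p)).sum())
        out[i] = var * h
    return out


def _ranked(criterion: np.ndarray) -> np.ndarray:
    """Indices sorted by criterion descending, ties to lower index."""
    m = criterion.shape[0]
    return np.lexsort((np.arange(m), -criterion))


def score_and_select(
    fm: FeatureMatrix | np.ndarray,
    scheme: SelectionScheme | str = SelectionScheme.SCORE,
    k: int | None = None,
    bins: int = 10,
) -> SelectionResult:
    """Rank features under ``scheme`` and keep the top ``k``.

    ``k`` defaults to the top 20% of features (at least 1); the ``none``
    scheme keeps the first ``k`` columns in their original order.
    """
    scheme = SelectionScheme(scheme)
    x = _values(fm)
    m = x.shape[1]
    if k is None:
        k = max(1, int(np.ceil(0.2 * m)))
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    ind = independence(fm)
    info = information(fm, bins=bins)
    score = ind * info
    if scheme == SelectionScheme.NONE:
        order = np.arange(m)
    elif scheme == SelectionScheme.INDEPENDENCE:
        order = _ranked(ind)
    elif scheme == SelectionScheme.INFORMATION:
        order = _ranked(info)
    else:
        order = _ranked(score)
    return SelectionResult(
        ind=ind,
        info=info,
        score=score,
        selected=[int(i) for i in order[:k]],
        k=k,
        scheme=scheme,
    )
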