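"""Scale transforms, low-reactivity pre-filtering, and ELISA quantification.

The analysis scale is log2 MFI, sample-wise median-centered: subtracting each
serum's median reactivity across the marker panel removes multiplicative
sample effects (dilution, labelling efficiency) and additive-in-log batch
effects shared across a sample's markers.

Transforms are exposed both as scikit-learn-style transformers (composable in
``sklearn.pipeline.Pipeline``) and as thin module-level functions operating on
:class:`~seropanel.datatypes.MfiMatrix`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import MfiMatrix, StandardCurve


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Empirical nearest-rank quantile: smallest observed value whose
    cumulative fraction reaches ``q``.

    Chosen so that quantile cutoffs are always attained data values, which the
    cutoff-escalation scan over observed values requires.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile level must be in (0, 1), got {q}")
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(q * v.size))
    return float(v[k - 1])


class Log2Transformer(BaseEstimator, TransformerMixin):
    """Element-wise log2 of strictly positive intensities."""

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite=True)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        df = isinstance(X, pd.DataFrame)
        arr = check_array(X, ensure_all_finite=True)
        if (arr <= 0).any():
            i, j = np.argwhere(arr <= 0)[0]
            raise ValueError(f"non-positive intensity at row {i}, column {j}")
        out = np.log2(arr)
        if df:
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


class SampleMedianCenterer(BaseEstimator, TransformerMixin):
    """Subtract each sample row's median across markers (log2 scale).

    Stateless by design: the centering statistic is a property of each sample,
    not of a training set, so ``transform`` on new samples never leaks
    information between cohorts. Idempotent.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite=True)
        if X.shape[1] < 2:
            raise ValueError("median centering needs at least 2 markers per sample")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        df = isinstance(X, pd.DataFrame)
        arr = check_array(X, ensure_all_finite=True)
        if arr.shape[1] < 2:
            raise ValueError("median centering needs at least 2 markers per sample")
        out = arr - np.median(arr, axis=1, keepdims=True)
        if df:
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


class LowReactivityFilter(BaseEstimator, TransformerMixin):
    """Drop markers whose 75% quantile of log2 MFI across all samples does not
    exceed a reactivity floor.

    Applied on the *uncentered* log2 scale: the absolute threshold (default
    log2 MFI 10) is meaningless after per-sample centering. Markers are
    retained iff their nearest-rank ``quantile`` across samples is strictly
    greater than ``threshold``.

    Attributes
    ----------
    support_ : ndarray of bool
        Mask of retained markers.
    retained_, dropped_ : list
        Column labels (or indices) by decision, for the run manifest.
    """

    def __init__(self, quantile: float = 0.75, threshold: float = 10.0):
        self.quantile = quantile
        self.threshold = threshold

    def fit(self, X, y=None):
        if not 0 < self.quantile < 1:
            raise ValueError(f"quantile must be in (0, 1), got {self.quantile}")
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
        arr = check_array(X, ensure_all_finite=True)
        q75 = np.array([nearest_rank_quantile(arr[:, j], self.quantile) for j in range(arr.shape[1])])
        self.quantile_values_ = q75
        self.support_ = q75 > self.threshold
        labels = cols if cols is not None else list(range(arr.shape[1]))
        self.feature_names_in_ = np.array(labels, dtype=object)
        self.retained_ = [l for l, keep in zip(labels, self.support_) if keep]
        self.dropped_ = [l for l, keep in zip(labels, self.support_) if not keep]
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.retained_]
        arr = check_array(X, ensure_all_finite=True)
        return arr[:, self.support_]


# --- MfiMatrix-level functions ----------------------------------------------

def log2_transform(m: MfiMatrix) -> MfiMatrix:
    """Transform a linear-scale matrix to log2. Hard error off-scale."""
    if m.scale != "linear":
        raise ValueError(f"log2_transform expects a linear-scale matrix, got {m.scale!r}")
    out = Log2Transformer().fit_transform(m.data)
    return MfiMatrix(out, scale="log2")


def median_center(m: MfiMatrix) -> MfiMatrix:
    """Sample-wise median-center a log2 matrix; every output row has median 0."""
    if m.scale != "log2":
        raise ValueError(f"median_center expects a log2-scale matrix, got {m.scale!r}")
    out = SampleMedianCenterer().fit_transform(m.data)
    return MfiMatrix(out, scale="log2_centered")


def prefilter_low_reactivity(
    m: MfiMatrix, q: float = 0.75, threshold: float = 10.0
) -> tuple[MfiMatrix, list[str], list[str]]:
    """Apply the 75%-quantile low-reactivity pre-filter on uncentered log2 MFI.

    Returns (filtered matrix, retained marker names, dropped marker names);
    both lists go into the run manifest.
    """
    if m.scale != "log2":
        raise ValueError(
            f"prefilter runs on the uncentered log2 scale, got {m.scale!r}"
        )
    f = LowReactivityFilter(quantile=q, threshold=threshold).fit(m.data)
    return MfiMatrix(f.transform(m.data), scale=m.scale), list(f.retained_), list(f.dropped_)


# --- ELISA titer estimation --------------------------------------------------

def elisa_quantify(
    od: np.ndarray | list[float], curve: StandardCurve
) -> pd.DataFrame:
    """Estimate titers (U/ml) from ELISA optical densities via the standard curve.

    Interpolation is piecewise-linear on the (log2 concentration, response)
    plane — with only five standards a log-linear fit is better constrained
    than a four-parameter logistic. Out-of-range ODs are censored: below the
    lowest standard's response -> ``"<2.5"``, above the highest -> ``">40"``
    (bounds from the ladder); censored titers are NaN and should be excluded
    from downstream cutoff calibration unless explicitly mapped to the range
    bounds.

    Returns a DataFrame with columns ``od``, ``titer``, ``censored``
    (one of ``""``, ``"<low"``, ``">high"`` rendered with the ladder bounds).
    """
    od = np.asarray(od, dtype=float)
    conc = np.asarray(curve.concentrations, dtype=float)
    resp = np.asarray(curve.responses, dtype=float)
    logc = np.log2(conc)
    if not curve.increasing:  # competitive format: flip to increasing response
        resp = resp[::-1]
        logc = logc[::-1]
    titer = np.full(od.shape, np.nan)
    censored = np.full(od.shape, "", dtype=object)
    low_flag = f"<{curve.lower:g}"
    high_flag = f">{curve.upper:g}"
    lo_resp, hi_resp = resp[0], resp[-1]
    below = od < lo_resp
    above = od > hi_resp
    inside = ~(below | above)
    titer[inside] = 2.0 ** np.interp(od[inside], resp, logc)
    if curve.increasing:
        censored[below] = low_flag
        censored[above] = high_flag
    else:
        censored[below] = high_flag
        censored[above] = low_flag
    return pd.DataFrame({"od": od, "titer": titer, "censored": censored})
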