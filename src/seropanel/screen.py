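"""Univariate candidate screening and control-anchored binarization.

Two screening layers mirror the two study phases:

* discovery-style criteria on log2, sample-median-centered data — SAM-type
  moderated d-statistic with permutation significance (pass: p <= alpha,
  fold change >= 1.5, d >= 2) and a rank test with a quantile-span criterion
  (pass: p <= alpha, max |case - control| quantile difference >= 1 log2 unit,
  fold change >= 1.5);
* validation-style criteria — Mann-Whitney U on intensities plus Fisher's
  exact test on positivity calls after binarization.

Binarization is anchored on healthy controls (HC): the per-marker cutoff is
the nearest-rank 98% quantile of HC intensities (at most 2% of the calibration
HC above it), optionally escalated to a higher observed value whenever that
removes HC positives without losing a single case positive. Positivity is
strictly greater-than the cutoff.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import MfiMatrix
from .preprocess import nearest_rank_quantile

# --- univariate statistics ---------------------------------------------------

def mann_whitney(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, case vs control.

    Returns (U for the case side, two-sided p). The p-value is exact (by
    enumeration of rank assignments) when n_case + n_control <= 12 and there
    are no ties; otherwise the normal approximation with tie and continuity
    correction is used.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([case, control])
    no_ties = np.unique(pooled).size == pooled.size
    if case.size + control.size <= 12 and no_ties:
        res = stats.mannwhitneyu(case, control, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            case, control, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def fold_change(case: np.ndarray, control: np.ndarray) -> float:
    """Linear-scale ratio of group medians for log2-scale inputs:
    2 ** (median(case) - median(control)), reported as case/control."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("empty group")
    return float(2.0 ** (np.median(case) - np.median(control)))


def quantile_span(case: np.ndarray, control: np.ndarray,
                  levels: tuple[float, ...] = (0.25, 0.5, 0.75)) -> float:
    """Max over the checked quantile levels of |case quantile - control quantile|
    in log2 units (the 'absolute span' criterion of the discovery screen)."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    spans = [
        abs(nearest_rank_quantile(case, q) - nearest_rank_quantile(control, q))
        for q in levels
    ]
    return float(max(spans))


def sam_d(case: np.ndarray, control: np.ndarray, s0: float = 0.0) -> float:
    """SAM-type moderated d-statistic.

    d = (mean(case) - mean(control)) / (s + s0), with s the pooled standard
    error of the mean difference and s0 a small positive fudge factor that
    damps markers with near-zero scatter.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = case.size, control.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    s = pooled_se(case, control)
    if s + s0 == 0:
        raise ValueError("zero scatter and s0 = 0: d undefined")
    return float((case.mean() - control.mean()) / (s + s0))


def pooled_se(case: np.ndarray, control: np.ndarray) -> float:
    """Pooled standard error of the difference in means."""
    n1, n2 = case.size, control.size
    ss = ((case - case.mean()) ** 2).sum() + ((control - control.mean()) ** 2).sum()
    return float(np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2)))


_EXACT_PERM_LIMIT = 30000  # enumerate when C(n, n1) is below this


def sam_permutation_p(
    case: np.ndarray,
    control: np.ndarray,
    s0: float = 0.0,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p for the SAM d-statistic.

    All group-label assignments are enumerated when there are at most
    ``_EXACT_PERM_LIMIT`` of them; otherwise ``n_permutations`` Monte-Carlo
    label shuffles are drawn (observed labelling included in the reference
    set, so p >= 1/(n_permutations + 1)).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    d_obs = abs(sam_d(case, control, s0=s0))
    pooled = np.concatenate([case, control])
    n1, n = case.size, case.size + control.size
    if math.comb(n, n1) <= _EXACT_PERM_LIMIT:
        count = total = 0
        for idx in itertools.combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            d = abs(sam_d(pooled[mask], pooled[~mask], s0=s0))
            count += d >= d_obs - 1e-12
            total += 1
        return count / total
    rng = rng if rng is not None else np.random.default_rng(0)
    count = 1  # observed labelling
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        d = abs(sam_d(pooled[perm[:n1]], pooled[perm[n1:]], s0=s0))
        count += d >= d_obs - 1e-12
    return count / (n_permutations + 1)


def fisher_exact(bin_case: np.ndarray, bin_control: np.ndarray) -> float:
    """Two-sided Fisher's exact p comparing positivity between two groups.

    Sums hypergeometric probabilities of all tables no more probable than the
    observed one. An empty margin (no positives or no negatives anywhere)
    carries no information: p = 1 with a warning.
    """
    bin_case = np.asarray(bin_case, dtype=bool)
    bin_control = np.asarray(bin_control, dtype=bool)
    a, b = int(bin_case.sum()), int((~bin_case).sum())
    c, d = int(bin_control.sum()), int((~bin_control).sum())
    if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
        warnings.warn("degenerate 2x2 table (empty margin); p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# --- cutoff calibration ------------------------------------------------------

def calibrate_cutoff(
    hc: np.ndarray, case: np.ndarray, q: float = 0.98, escalate: bool = True
) -> tuple[float, bool]:
    """Control-anchored positivity cutoff with optional escalation.

    Base cutoff: nearest-rank ``q``-quantile of the HC intensities, applied as
    a strict greater-than threshold (so at most a fraction 1 - q of the
    calibration HC can be positive). Escalation scans the distinct observed
    values (HC and case pooled) above the base cutoff and returns the largest
    candidate that strictly reduces the HC positive count while leaving the
    case positive count unchanged — higher specificity at identical
    sensitivity. Returns (cutoff, escalated flag).
    """
    hc = np.asarray(hc, dtype=float)
    case = np.asarray(case, dtype=float)
    if hc.size < 10:
        raise ValueError(
            f"need >= 10 control values to calibrate a {q:.0%} quantile cutoff "
            f"(got {hc.size}); consider pooling controls"
        )
    c0 = nearest_rank_quantile(hc, q)
    if not escalate or case.size == 0:
        return c0, False
    base_case = int((case > c0).sum())
    base_hc = int((hc > c0).sum())
    candidates = np.unique(np.concatenate([hc, case]))
    candidates = candidates[candidates > c0]
    for c in candidates[::-1]:  # largest qualifying candidate wins
        if int((case > c).sum()) == base_case and int((hc > c).sum()) < base_hc:
            return float(c), True
    return c0, False


class ControlQuantileBinarizer(BaseEstimator, TransformerMixin):
    """Per-marker binarization anchored on the healthy-control quantile.

    scikit-learn-style transformer: ``fit(X, y)`` learns one cutoff per marker
    from ``X`` (samples x markers on the analysis scale) where ``y`` marks
    each sample as control (calibration HC) or case; ``transform`` turns any
    matrix with the same markers into boolean positivity calls
    (value strictly greater than cutoff).

    Parameters
    ----------
    quantile : float, default 0.98
        HC quantile defining the base cutoff (nearest-rank convention).
    escalate : bool, default True
        Raise cutoffs through observed values whenever HC positives can be
        removed without changing case positives.
    control_label : any, default "HC"
        Value of ``y`` identifying calibration controls; all other samples
        are the escalation case set.

    Attributes
    ----------
    cutoffs_ : ndarray of float
        Final per-marker cutoff.
    base_cutoffs_ : ndarray of float
        Unescalated HC-quantile cutoffs (cutoffs_ >= base_cutoffs_).
    escalated_ : ndarray of bool
    n_controls_ : int
    """

    def __init__(self, quantile: float = 0.98, escalate: bool = True, control_label="HC"):
        self.quantile = quantile
        self.escalate = escalate
        self.control_label = control_label

    def fit(self, X, y):
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
        arr = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if arr.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        is_control = y == self.control_label
        if not is_control.any():
            raise ValueError(f"no samples labelled {self.control_label!r} to calibrate on")
        hc = arr[is_control]
        case = arr[~is_control]
        p = arr.shape[1]
        cutoffs = np.empty(p)
        base = np.empty(p)
        esc = np.zeros(p, dtype=bool)
        for j in range(p):
            base[j] = nearest_rank_quantile(hc[:, j], self.quantile)
            cutoffs[j], esc[j] = calibrate_cutoff(
                hc[:, j], case[:, j], q=self.quantile, escalate=self.escalate
            )
        self.cutoffs_ = cutoffs
        self.base_cutoffs_ = base
        self.escalated_ = esc
        self.n_controls_ = int(is_control.sum())
        self.n_features_in_ = p
        self.feature_names_in_ = np.array(cols, dtype=object) if cols else None
        return self

    def transform(self, X):
        check_is_fitted(self)
        if isinstance(X, pd.DataFrame):
            if self.feature_names_in_ is not None:
                missing = [c for c in self.feature_names_in_ if c not in X.columns]
                if missing:
                    raise KeyError(f"markers missing from matrix: {missing}")
                X = X.loc[:, list(self.feature_names_in_)]
            calls = X.to_numpy(dtype=float) > self.cutoffs_
            return pd.DataFrame(calls, index=X.index, columns=X.columns)
        arr = np.asarray(X, dtype=float)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError("marker dimension mismatch")
        return arr > self.cutoffs_

    def cutoff_table(self) -> pd.DataFrame:
        """Per-marker cutoffs as a persistable table (base and final values,
        escalation flag, calibration-control count)."""
        check_is_fitted(self)
        idx = (
            list(self.feature_names_in_)
            if self.feature_names_in_ is not None
            else list(range(self.n_features_in_))
        )
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs_,
                "base_cutoff": self.base_cutoffs_,
                "base_quantile_level": self.quantile,
                "escalated": self.escalated_,
                "n_hc_used": self.n_controls_,
            },
            index=pd.Index(idx, name="marker"),
        )


def binarize(m: MfiMatrix, cutoffs: pd.DataFrame) -> pd.DataFrame:
    """Apply a persisted cutoff table to a matrix: call = value > cutoff,
    uniformly for all groups. Hard error on markers without a cutoff."""
    missing = [c for c in m.marker_names if c not in cutoffs.index]
    if missing:
        raise KeyError(f"no cutoff for markers: {missing}")
    cut = cutoffs.loc[m.marker_names, "cutoff"].to_numpy(dtype=float)
    calls = m.values() > cut
    return pd.DataFrame(calls, index=m.data.index, columns=m.data.columns)


# --- prevalence --------------------------------------------------------------

def prevalence_table(calls: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each group positive per marker, with counts.

    Returns a tidy frame (marker, group, n, n_positive, prevalence,
    prevalence_pct); empty groups are excluded with a warning.
    """
    rows = []
    for group, sub in meta.groupby("group", sort=True, observed=True):
        ids = [s for s in sub["sample_id"] if s in calls.index]
        if not ids:
            warnings.warn(f"group {group!r} has no samples in the call matrix", stacklevel=2)
            continue
        sub_calls = calls.loc[ids]
        n = len(ids)
        pos = sub_calls.sum(axis=0)
        for marker in calls.columns:
            k = int(pos[marker])
            rows.append(
                {
                    "marker": marker,
                    "group": group,
                    "n": n,
                    "n_positive": k,
                    "prevalence": k / n,
                    "prevalence_pct": 100.0 * k / n,
                }
            )
    return pd.DataFrame(rows)


def coprevalence_matrix(calls: pd.DataFrame, sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Symmetric marker x marker co-prevalence matrix on a sample subset.

    Diagonal: single-marker prevalence; off-diagonal (i, k): fraction of the
    subset positive for *both* markers. Fractions, not percents.
    """
    sub = calls if sample_ids is None else calls.loc[list(sample_ids)]
    if sub.shape[0] == 0:
        raise ValueError("empty sample subset")
    b = sub.to_numpy(dtype=float)
    co = (b.T @ b) / b.shape[0]
    return pd.DataFrame(co, index=calls.columns, columns=calls.columns)


# --- full screen -------------------------------------------------------------

@dataclass
class ScreenCriteria:
    """Pass/fail thresholds for the screening criteria sets."""

    alpha: float = 0.05
    fold_change_min: float = 1.5
    d_score_min: float = 2.0
    span_min: float = 1.0


def screen_markers(
    m: MfiMatrix,
    meta: pd.DataFrame,
    case_group: str = "SjD",
    control_group: str = "HC",
    criteria: ScreenCriteria | None = None,
    s0: float | None = None,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    cutoff_quantile: float = 0.98,
    escalate: bool = True,
) -> tuple[pd.DataFrame, ControlQuantileBinarizer, pd.DataFrame]:
    """Run the full univariate screen of case vs control on the analysis scale.

    Computes per marker: Mann-Whitney p, linear fold change of medians, SAM d
    with permutation p, quantile span, calibrated cutoff, Fisher's exact p on
    the binarized calls, per-group prevalence, and which criteria sets passed.

    ``s0`` defaults to the median of per-marker pooled standard errors across
    all screened markers (a standard SAM fudge-factor choice).

    Returns (screen table, fitted binarizer, boolean call matrix for all
    samples in ``m``).
    """
    criteria = criteria or ScreenCriteria()
    rng = rng if rng is not None else np.random.default_rng(0)
    meta = meta.loc[m.sample_ids]
    case_ids = meta.index[meta["group"] == case_group]
    ctrl_ids = meta.index[meta["group"] == control_group]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need at least 2 case and 2 control samples")
    Xcase = m.data.loc[case_ids]
    Xctrl = m.data.loc[ctrl_ids]

    if s0 is None:
        ses = [
            pooled_se(Xcase[c].to_numpy(), Xctrl[c].to_numpy()) for c in m.marker_names
        ]
        s0 = float(np.median(ses))

    # control-anchored binarization, calibrated on HC with the case group as
    # the escalation set
    calib = pd.concat([Xctrl, Xcase])
    y = np.array([control_group] * len(ctrl_ids) + [case_group] * len(case_ids))
    binz = ControlQuantileBinarizer(
        quantile=cutoff_quantile, escalate=escalate, control_label=control_group
    ).fit(calib, y)
    calls = binz.transform(m.data)

    prev = prevalence_table(calls, meta.assign(sample_id=meta.index))
    prev_wide = prev.pivot(index="marker", columns="group", values="prevalence")

    rows = []
    for j, marker in enumerate(m.marker_names):
        case_v = Xcase[marker].to_numpy()
        ctrl_v = Xctrl[marker].to_numpy()
        u, mw_p = mann_whitney(case_v, ctrl_v)
        fc = fold_change(case_v, ctrl_v)
        d = sam_d(case_v, ctrl_v, s0=s0)
        d_p = sam_permutation_p(case_v, ctrl_v, s0=s0, n_permutations=n_permutations, rng=rng)
        span = quantile_span(case_v, ctrl_v)
        f_p = fisher_exact(
            calls.loc[case_ids, marker].to_numpy(), calls.loc[ctrl_ids, marker].to_numpy()
        )
        fc_effect = max(fc, 1.0 / fc)  # two-sided fold-change criterion
        pass_sam = (d_p <= criteria.alpha) and (fc_effect >= criteria.fold_change_min) and (
            abs(d) >= criteria.d_score_min
        )
        pass_wilcoxon = (
            (mw_p <= criteria.alpha)
            and (span >= criteria.span_min)
            and (fc_effect >= criteria.fold_change_min)
        )
        rows.append(
            {
                "marker": marker,
                "mw_u": u,
                "mw_p": mw_p,
                "fold_change": fc,
                "sam_d": d,
                "sam_p": d_p,
                "span": span,
                "fisher_p": f_p,
                "cutoff": binz.cutoffs_[j],
                "escalated": bool(binz.escalated_[j]),
                "pass_sam": pass_sam,
                "pass_wilcoxon": pass_wilcoxon,
                "pass_mw": mw_p <= criteria.alpha,
                "pass_fisher": f_p <= criteria.alpha,
            }
        )
    table = pd.DataFrame(rows).set_index("marker")
    for g in prev_wide.columns:
        table[f"prevalence_{g}"] = prev_wide[g]
    return table.reset_index(), binz, calls
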