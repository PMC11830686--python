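"""Marker-by-outcome clinical association screening.

Each binary clinical characteristic (laboratory flags, ESSDAI organ domains,
biopsy grade) is regressed on each marker's centered log2 level by logistic
regression, complete-case (patients with a missing flag are excluded per
outcome). P-values are Benjamini-Hochberg adjusted across the markers within
each outcome, and an association is flagged when both statistically robust
(raw p <= 0.05) and practically meaningful (|coefficient| >= 0.45 log-odds per
log2-MFI unit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .datatypes import MfiMatrix, clinical_flag_columns


@dataclass
class LogisticFit:
    coefficient: float
    stderr: float
    p: float
    intercept: float
    n: int
    converged: bool
    estimable: bool


_SEPARATION_COEF = 25.0  # |log-odds per unit| beyond this on standardized data
# is numerically indistinguishable from separation


def fit_logistic(outcome: np.ndarray, level: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome on one marker level.

    Newton iterations (iteratively reweighted least squares) with a 1e-8
    log-likelihood tolerance and at most 100 iterations; Wald p for the level
    coefficient. Completely separated data are flagged non-estimable (NaN
    coefficient) rather than returning a silently divergent estimate.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(level, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcome and level must have equal length")
    classes = np.unique(y)
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary (0/1)")
    if classes.size < 2:
        raise ValueError("outcome has a single class; association undefined")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, y.size, False, False)
    coef = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) * np.std(x) > _SEPARATION_COEF:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, y.size, bool(res.mle_retvals.get("converged", False)), False)
    return LogisticFit(
        coefficient=coef,
        stderr=se,
        p=float(res.pvalues[1]),
        intercept=float(res.params[0]),
        n=int(y.size),
        converged=bool(res.mle_retvals.get("converged", False)),
        estimable=True,
    )


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def association_screen(
    m: MfiMatrix,
    meta: pd.DataFrame,
    outcomes: list[str] | None = None,
    group: str = "SjD",
    alpha: float = 0.05,
    coef_min: float = 0.45,
    min_complete: int = 10,
) -> pd.DataFrame:
    """Screen every marker against every binary clinical outcome.

    Complete-case per outcome: patients of ``group`` with a non-null flag.
    Outcomes with fewer than ``min_complete`` complete cases or a single
    observed class are skipped with a warning. BH adjustment runs across the
    markers within each outcome (each clinical question is its own screen).
    ``passes_filter`` = (raw p <= alpha) AND (|coefficient| >= coef_min).

    Returns a tidy table with one row per (marker, outcome): coefficient,
    standard error, Wald 95% CI, p, q, n_complete, estimable, passes_filter —
    forest-plot-ready.
    """
    if m.scale != "log2_centered":
        raise ValueError(
            f"association screen expects the centered analysis scale, got {m.scale!r}"
        )
    meta = meta.loc[m.sample_ids]
    if outcomes is None:
        outcomes = clinical_flag_columns(meta)
    missing = [o for o in outcomes if o not in meta.columns]
    if missing:
        raise KeyError(f"outcomes absent from metadata: {missing}")

    rows = []
    in_group = meta["group"] == group
    for outcome in outcomes:
        flags = meta[outcome]
        complete = in_group & flags.notna()
        n_complete = int(complete.sum())
        if n_complete < min_complete:
            warnings.warn(
                f"outcome {outcome!r}: only {n_complete} complete cases (< {min_complete}); skipped",
                stacklevel=2,
            )
            continue
        y = flags[complete].astype(bool).to_numpy().astype(float)
        if np.unique(y).size < 2:
            warnings.warn(f"outcome {outcome!r}: single observed class; skipped", stacklevel=2)
            continue
        X = m.data.loc[complete.index[complete]]
        fits = {mk: fit_logistic(y, X[mk].to_numpy()) for mk in m.marker_names}
        est_markers = [mk for mk, f in fits.items() if f.estimable]
        qvals = dict(zip(est_markers, bh_adjust([fits[mk].p for mk in est_markers]))) if est_markers else {}
        for mk in m.marker_names:
            f = fits[mk]
            q = float(qvals[mk]) if mk in qvals else np.nan
            passes = bool(
                f.estimable and f.p <= alpha and abs(f.coefficient) >= coef_min
            )
            rows.append(
                {
                    "marker": mk,
                    "outcome": outcome,
                    "n_complete": f.n,
                    "coefficient": f.coefficient,
                    "stderr": f.stderr,
                    "ci_low": f.coefficient - 1.959963984540054 * f.stderr,
                    "ci_high": f.coefficient + 1.959963984540054 * f.stderr,
                    "p": f.p,
                    "q": q,
                    "estimable": f.estimable,
                    "passes_filter": passes,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "marker", "outcome", "n_complete", "coefficient", "stderr",
            "ci_low", "ci_high", "p", "q", "estimable", "passes_filter",
        ],
    )
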