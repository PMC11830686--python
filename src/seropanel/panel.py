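"""OR-rule diagnostic panels for the seronegative subgroup.

A panel is an ordered set of binarized IgG markers; a sample is predicted
positive if *any* panel marker call is positive. Markers are chosen by greedy
forward selection: seed with the most prevalent marker in the target subgroup
(Ro/SSA-negative patients), then repeatedly add the marker with the largest
incremental union sensitivity — the operational meaning of "high sensitivity
and low co-prevalence to the previous markers" — subject to a hard
healthy-control specificity floor. Union coverage is submodular, so the greedy
panel carries the usual (1 - 1/e) guarantee relative to the best same-size
panel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.proportion import proportion_confint

from .datatypes import MfiMatrix


def target_mask(meta: pd.DataFrame, target: str = "ro_ssa_negative") -> pd.Series:
    """Boolean mask over samples for a named target subgroup.

    ``"ro_ssa_negative"``: SjD patients without Ro/SSA antibodies (the
    diagnostically hard subgroup); ``"sjd"``: all patients. Ro/SSA status must
    be non-null for every patient when the seronegative target is requested.
    """
    if target == "sjd":
        return meta["group"] == "SjD"
    if target == "ro_ssa_negative":
        sjd = meta["group"] == "SjD"
        ro = meta["ro_ssa_positive"]
        if bool(ro[sjd].isna().any()):
            bad = meta.loc[sjd & ro.isna(), "sample_id"].tolist()
            raise ValueError(f"Ro/SSA status missing for SjD samples: {bad[:5]}")
        return sjd & ~ro.fillna(False).astype(bool)
    raise ValueError(f"unknown target selector {target!r}")


class ForwardPanelSelector(BaseEstimator, ClassifierMixin):
    """Greedy forward selection of an OR-rule marker panel.

    scikit-learn-style classifier over *binarized* calls: ``fit(X, y)`` with
    ``X`` a samples x markers boolean matrix and ``y`` binary (1 = target
    subgroup, 0 = healthy controls); ``predict`` ORs the selected markers'
    calls.

    Parameters
    ----------
    max_k : int, default 5
        Maximum panel size; selection stops earlier when no candidate adds
        target coverage.
    min_spec_hc : float, default 0.95
        Hard floor on panel specificity in the controls (y == 0) throughout
        selection.

    Ties at any step break by higher single-marker control specificity, then
    lexicographic marker label, for determinism.

    Attributes
    ----------
    markers_ : list
        Selected marker labels in selection order.
    marginal_gains_ : list of int
        Newly covered target samples contributed by each marker at its
        selection step.
    sensitivity_, specificity_ : float
        In-sample union sensitivity and control specificity of the panel.
    """

    def __init__(self, max_k: int = 5, min_spec_hc: float = 0.95):
        self.max_k = max_k
        self.min_spec_hc = min_spec_hc

    def fit(self, X, y):
        if self.max_k < 1:
            raise ValueError("max_k must be >= 1")
        labels = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.shape(X)[1]))
        B = np.asarray(X, dtype=bool)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary: 1 = target subgroup, 0 = controls")
        tgt = B[y == 1]
        ctrl = B[y == 0]
        n_tgt, n_ctrl = tgt.shape[0], ctrl.shape[0]
        if n_tgt == 0:
            raise ValueError("empty target subgroup")
        if n_ctrl == 0:
            raise ValueError("no control samples to enforce the specificity floor")

        single_spec = 1.0 - ctrl.mean(axis=0)
        order_key = {
            j: (-single_spec[j], str(labels[j])) for j in range(len(labels))
        }

        selected: list[int] = []
        gains: list[int] = []
        covered = np.zeros(n_tgt, dtype=bool)
        ctrl_pos = np.zeros(n_ctrl, dtype=bool)
        while len(selected) < self.max_k:
            best_j, best_gain = None, -1
            for j in range(len(labels)):
                if j in selected:
                    continue
                spec = 1.0 - (ctrl_pos | ctrl[:, j]).mean()
                if spec < self.min_spec_hc:
                    continue
                gain = int((tgt[:, j] & ~covered).sum())
                if gain > best_gain or (
                    gain == best_gain and best_j is not None and order_key[j] < order_key[best_j]
                ):
                    best_j, best_gain = j, gain
            if best_j is None:
                if not selected:
                    raise ValueError(
                        f"no marker satisfies the control specificity floor {self.min_spec_hc}"
                    )
                break
            if selected and best_gain == 0:
                break  # no marker adds coverage
            selected.append(best_j)
            gains.append(best_gain)
            covered |= tgt[:, best_j]
            ctrl_pos |= ctrl[:, best_j]

        self.feature_names_in_ = np.array(labels, dtype=object)
        self.n_features_in_ = len(labels)
        self.support_ = np.isin(np.arange(len(labels)), selected)
        self.markers_ = [labels[j] for j in selected]
        self.marginal_gains_ = gains
        self.sensitivity_ = float(covered.mean())
        self.specificity_ = float(1.0 - ctrl_pos.mean())
        self.classes_ = np.array([0, 1])
        return self

    def _calls(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [m for m in self.markers_ if m not in X.columns]
            if missing:
                raise KeyError(f"panel markers missing from call matrix: {missing}")
            return X.loc[:, self.markers_].to_numpy(dtype=bool)
        arr = np.asarray(X, dtype=bool)
        idx = [list(self.feature_names_in_).index(m) for m in self.markers_]
        return arr[:, idx]

    def predict(self, X):
        check_is_fitted(self)
        return self._calls(X).any(axis=1).astype(int)


@dataclass
class PanelModel:
    """A persisted OR-rule panel: ordered markers, their cutoffs, and metrics."""

    markers: list[str]
    cutoffs: dict[str, float]
    marginal_gains: list[int] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    rule: str = "or"

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("a panel needs at least one marker")
        missing = [m for m in self.markers if m not in self.cutoffs]
        if missing:
            raise ValueError(f"markers without cutoffs: {missing}")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def predict_panel(panel: PanelModel | list[str], calls: pd.DataFrame) -> pd.Series:
    """Per-sample OR-rule prediction from binarized calls."""
    markers = panel.markers if isinstance(panel, PanelModel) else list(panel)
    missing = [m for m in markers if m not in calls.columns]
    if missing:
        raise KeyError(f"panel markers missing from call matrix: {missing}")
    return calls.loc[:, markers].any(axis=1)


def evaluate_panel(
    panel: PanelModel | list[str],
    calls: pd.DataFrame,
    meta: pd.DataFrame,
    target: str = "ro_ssa_negative",
) -> dict:
    """Sensitivity in the target subgroup and specificity vs HC (and vs NSS
    when present), each with an exact (Clopper-Pearson) binomial 95% CI."""
    meta = meta.loc[calls.index]
    pred = predict_panel(panel, calls)
    tmask = target_mask(meta, target)
    if int(tmask.sum()) == 0:
        raise ValueError(f"target subgroup {target!r} is empty")

    def rate_ci(k: int, n: int) -> tuple[float, tuple[float, float]]:
        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
        return k / n, (float(lo), float(hi))

    n_t = int(tmask.sum())
    k_t = int(pred[tmask].sum())
    sens, sens_ci = rate_ci(k_t, n_t)
    out = {
        "n_target": n_t,
        "sensitivity": sens,
        "sensitivity_ci": sens_ci,
    }
    for grp, key in (("HC", "specificity_hc"), ("NSS", "specificity_nss")):
        gmask = meta["group"] == grp
        n_g = int(gmask.sum())
        if n_g == 0:
            continue
        k_neg = int((~pred[gmask]).sum())
        spec, spec_ci = rate_ci(k_neg, n_g)
        out[key] = spec
        out[f"{key}_ci"] = spec_ci
        out[f"n_{grp.lower()}"] = n_g
    return out


def forward_select_panel(
    calls: pd.DataFrame,
    meta: pd.DataFrame,
    cutoffs: pd.DataFrame,
    target: str = "ro_ssa_negative",
    max_k: int = 5,
    min_spec_hc: float = 0.95,
    candidates: list[str] | None = None,
    isotype: str = "IgG",
) -> PanelModel:
    """Build an OR-rule panel for the target subgroup from binarized calls.

    Candidates default to the ``isotype`` channels (panels are built from IgG
    reactivity — IgA levels track disease activity and drift over time).
    Selection fits :class:`ForwardPanelSelector` on target-vs-HC samples; the
    returned :class:`PanelModel` records selection order, marginal gains,
    in-sample metrics, and the co-prevalence submatrix of the chosen markers.
    """
    from .screen import coprevalence_matrix

    meta = meta.loc[calls.index]
    if candidates is None:
        candidates = [c for c in calls.columns if str(c).endswith(f"|{isotype}")]
    if not candidates:
        raise ValueError("no candidate markers")
    tmask = target_mask(meta, target)
    hmask = meta["group"] == "HC"
    keep = tmask | hmask
    X = calls.loc[keep, candidates]
    y = tmask[keep].astype(int).to_numpy()
    sel = ForwardPanelSelector(max_k=max_k, min_spec_hc=min_spec_hc).fit(X, y)

    cut_slice = {m: float(cutoffs.loc[m, "cutoff"]) for m in sel.markers_}
    model = PanelModel(
        markers=list(sel.markers_),
        cutoffs=cut_slice,
        marginal_gains=list(sel.marginal_gains_),
    )
    metrics = evaluate_panel(model, calls, meta, target=target)
    metrics["selection_sensitivity"] = sel.sensitivity_
    metrics["selection_specificity_hc"] = sel.specificity_
    model.metrics = metrics
    co = coprevalence_matrix(calls.loc[:, sel.markers_], meta.index[tmask].tolist())
    model.metrics["target_coprevalence"] = co.round(6).to_dict()
    return model


def pca_qc(m: MfiMatrix, meta: pd.DataFrame) -> dict:
    """Cohort-comparability QC via PCA of the centered analysis matrix.

    Returns the first two component coordinates, explained-variance fractions,
    and pairwise distances between per-cohort centroids in the PC1/PC2 plane
    (comparable cohorts have overlapping clouds, i.e. small centroid
    distances relative to the cloud spread).
    """
    if m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("PCA QC needs at least 3 samples and 2 markers")
    X = m.values()
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < 1:
        raise ValueError("matrix has no variation: nothing for PCA to assess")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(Xc)
    coord_df = pd.DataFrame(coords, index=m.data.index, columns=["PC1", "PC2"])
    meta = meta.loc[m.sample_ids]
    centroids = coord_df.groupby(meta["cohort"].to_numpy()).mean()
    dists = {}
    names = list(centroids.index)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            dists[f"{a}~{b}"] = float(
                np.linalg.norm(centroids.loc[a] - centroids.loc[b])
            )
    return {
        "coordinates": coord_df,
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        "cohort_centroids": centroids,
        "centroid_distances": dists,
    }
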