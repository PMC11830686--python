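"""Synthetic multiplex-serology cohorts with a ground-truth ledger.

Generative model, per sample j and antigen-isotype channel i, on the log2
scale::

    log2 MFI_ij = mu_i + delta_ij * e_i + c_j + b_batch(j) + eps_ij

* ``mu_i``      marker background (log2 MFI) — bead/antigen-specific baseline;
* ``delta_ij``  responder indicator, Bernoulli(pi_{i, group(j)}) — the planted
  seroprevalence structure; markers may be grouped into *disjoint responder
  sets* (each sample responds to at most one marker of the group), the
  structure a complementary diagnostic panel exploits;
* ``e_i``       responder effect, a pure location shift in log2 units
  (binarization is threshold-based, so shifts are the relevant alternative);
* ``c_j``       per-sample scaling offset (dilution/labelling), removed by
  sample-median centering;
* ``b``         per-batch offset; one batch per simulated center, emulating
  multi-center recruitment;
* ``eps_ij``    Normal(0, sigma_i) measurement noise.

The emitted matrix is ``2 ** (log2 value)`` (linear MFI). Ro/SSA status of
disease samples is the responder indicator of a designated marker
(``"RO60|IgG"`` by default), so the seronegative subgroup is defined by the
same generative process the analysis sees.

Binary clinical outcomes are attached per a logistic ledger:
``outcome ~ Bernoulli(expit(beta0 + beta * x))`` with ``x`` the centered log2
level of the linked marker, plus configurable missingness for complete-case
handling.

Everything is deterministic under ``rng_seed``.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .datatypes import GROUPS, MfiMatrix, validate_sample_meta
from .preprocess import log2_transform, median_center

DEFAULT_RO_MARKER = "RO60|IgG"

#: multi-center structure: fractions of each group recruited per center
DEFAULT_COHORT_FRACTIONS: dict[str, dict[str, float]] = {
    "SjD": {"hannover": 0.625, "berlin": 0.208, "udine": 0.167},
    "HC": {"hannover": 1.0},
    "NSS": {"hannover": 1.0},
    "RA": {"hannover": 1.0},
    "SLE": {"hannover": 1.0},
    "SSc": {"hannover": 1.0},
}


@dataclass
class Association:
    """One planted marker -> clinical-outcome link (logistic)."""

    outcome: str
    marker: str
    beta: float
    beta0: float = 0.0


@dataclass
class SimTruth:
    """Ground-truth ledger for a simulated cohort.

    ``prevalence`` maps group label -> per-marker responder probability array
    (aligned with ``markers``). ``disjoint_groups`` lists marker-name groups
    whose responder sets are sampled without overlap. After
    :func:`simulate_cohort`, ``responders`` holds the realized delta matrix
    and ``sample_offsets`` / ``batch_offsets`` the realized nuisance terms.
    """

    markers: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    effect: np.ndarray
    prevalence: dict[str, np.ndarray]
    sample_offset_sd: float = 0.3
    batch_offset_sd: float = 0.25
    cohort_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_COHORT_FRACTIONS)
    )
    disjoint_groups: list[list[str]] = field(default_factory=list)
    associations: list[Association] = field(default_factory=list)
    missing_fraction: float = 0.0
    ro_ssa_marker: str = DEFAULT_RO_MARKER
    rng_seed: int = 0
    # filled by simulate_cohort
    responders: pd.DataFrame | None = None
    sample_offsets: pd.Series | None = None
    batch_offsets: dict[str, float] | None = None

    def __post_init__(self) -> None:
        p = len(self.markers)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.effect = np.asarray(self.effect, dtype=float)
        for name, arr in (("mu", self.mu), ("sigma", self.sigma), ("effect", self.effect)):
            if arr.shape != (p,):
                raise ValueError(f"{name} must have one value per marker")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be strictly positive")
        if (self.effect < 0).any():
            raise ValueError("effect sizes must be non-negative")
        self.prevalence = {g: np.asarray(v, dtype=float) for g, v in self.prevalence.items()}
        for g, arr in self.prevalence.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in prevalence map")
            if arr.shape != (p,):
                raise ValueError(f"prevalence[{g}] must have one value per marker")
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("prevalences must lie in [0, 1]")
        seen: set[str] = set()
        for grp in self.disjoint_groups:
            for mk in grp:
                if mk not in self.markers:
                    raise ValueError(f"disjoint-group marker {mk!r} not in truth")
                if mk in seen:
                    raise ValueError(f"marker {mk!r} in more than one disjoint group")
                seen.add(mk)
        for a in self.associations:
            if a.marker not in self.markers:
                raise ValueError(f"association references unknown marker {a.marker!r}")

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in truth") from None


def _assign_cohorts(group: str, n: int, fractions: dict[str, dict[str, float]]) -> list[str]:
    fr = fractions.get(group, {"hannover": 1.0})
    names = sorted(fr)
    counts = [int(round(fr[c] * n)) for c in names]
    # fix rounding drift on the largest center
    drift = n - sum(counts)
    counts[int(np.argmax([fr[c] for c in names]))] += drift
    out: list[str] = []
    for c, k in zip(names, counts):
        out.extend([c] * max(k, 0))
    return out[:n]


def simulate_cohort(
    truth: SimTruth, n_per_group: dict[str, int]
) -> tuple[MfiMatrix, pd.DataFrame, SimTruth]:
    """Draw a cohort from the generative model.

    Returns (linear-scale MfiMatrix, sample metadata table, truth with the
    realized responder indicators and nuisance offsets filled in). The input
    truth is not mutated. Deterministic under ``truth.rng_seed``.
    """
    for g, n in n_per_group.items():
        if g not in truth.prevalence:
            raise KeyError(f"group {g!r} requested but absent from the prevalence map")
        if n < 1:
            raise ValueError(f"need at least 1 sample per requested group (got {g}: {n})")
    rng = np.random.default_rng(truth.rng_seed)
    truth = dataclasses.replace(truth)
    p = len(truth.markers)

    sample_ids: list[str] = []
    groups: list[str] = []
    cohorts: list[str] = []
    for g in sorted(n_per_group):
        n = n_per_group[g]
        sample_ids.extend(f"{g}_{k:04d}" for k in range(n))
        groups.extend([g] * n)
        cohorts.extend(_assign_cohorts(g, n, truth.cohort_fractions))
    n_total = len(sample_ids)

    all_cohorts = sorted(set(cohorts))
    batch_offsets = {
        c: float(rng.normal(0.0, truth.batch_offset_sd)) for c in all_cohorts
    }
    c_j = rng.normal(0.0, truth.sample_offset_sd, size=n_total)

    # responder indicators
    delta = np.zeros((n_total, p), dtype=bool)
    group_arr = np.asarray(groups)
    disjoint_idx = [
        [truth.marker_index(mk) for mk in grp] for grp in truth.disjoint_groups
    ]
    in_disjoint = set(i for grp in disjoint_idx for i in grp)
    for g in sorted(n_per_group):
        rows = np.flatnonzero(group_arr == g)
        pi = truth.prevalence[g]
        # independent markers
        for i in range(p):
            if i in in_disjoint:
                continue
            delta[rows, i] = rng.random(rows.size) < pi[i]
        # disjoint responder groups: each sample responds to at most one member
        for grp in disjoint_idx:
            probs = pi[grp]
            if probs.sum() > 1.0 + 1e-12:
                raise ValueError(
                    f"disjoint-group prevalences for group {g!r} sum to {probs.sum():.3f} > 1"
                )
            u = rng.random(rows.size)
            edges = np.cumsum(probs)
            cat = np.searchsorted(edges, u)  # == len(grp) -> non-responder
            for k, i in enumerate(grp):
                delta[rows[cat == k], i] = True

    eps = rng.normal(0.0, 1.0, size=(n_total, p)) * truth.sigma
    b_j = np.array([batch_offsets[c] for c in cohorts])
    log2_mfi = (
        truth.mu
        + delta * truth.effect
        + c_j[:, None]
        + b_j[:, None]
        + eps
    )
    matrix = MfiMatrix(
        pd.DataFrame(2.0 ** log2_mfi, index=sample_ids, columns=truth.markers),
        scale="linear",
    )

    if truth.ro_ssa_marker in truth.markers:
        ro = delta[:, truth.marker_index(truth.ro_ssa_marker)]
    else:
        ro = np.zeros(n_total, dtype=bool)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "cohort": cohorts,
            "ro_ssa_positive": ro,
        }
    )
    meta = validate_sample_meta(meta)

    truth.responders = pd.DataFrame(delta, index=sample_ids, columns=truth.markers)
    truth.sample_offsets = pd.Series(c_j, index=sample_ids)
    truth.batch_offsets = batch_offsets
    return matrix, meta, truth


def attach_clinical_outcomes(
    matrix: MfiMatrix,
    meta: pd.DataFrame,
    truth: SimTruth,
    groups: tuple[str, ...] = ("SjD",),
    seed_offset: int = 1,
) -> pd.DataFrame:
    """Generate binary clinical flags from the association ledger.

    For each ledger entry, ``outcome ~ Bernoulli(expit(beta0 + beta * x))``
    with ``x`` the *centered log2* level of the linked marker. Outcomes are
    generated for samples in ``groups`` (patients; everyone else is null), and
    ``truth.missing_fraction`` of the generated flags is blanked at random to
    exercise complete-case handling. Returns an augmented metadata table.
    """
    if not truth.associations:
        return meta.copy()
    for a in truth.associations:
        if a.marker not in matrix.marker_names:
            raise KeyError(f"association marker {a.marker!r} absent from the matrix")
    rng = np.random.default_rng(truth.rng_seed + seed_offset)
    centered = matrix
    if centered.scale == "linear":
        centered = log2_transform(centered)
    if centered.scale == "log2":
        centered = median_center(centered)
    meta = meta.copy()
    in_groups = meta["group"].isin(groups).to_numpy()
    for a in truth.associations:
        x = centered.data[a.marker].to_numpy()
        prob = expit(a.beta0 + a.beta * x)
        draws = rng.random(len(meta)) < prob
        flags = pd.array([pd.NA] * len(meta), dtype="boolean")
        flags[in_groups] = draws[in_groups]
        if truth.missing_fraction > 0:
            blank = rng.random(len(meta)) < truth.missing_fraction
            flags[blank & in_groups] = pd.NA
        meta[a.outcome] = flags
    return meta


# --- study-condition truth builders -----------------------------------------

def default_truth(
    n_antigens: int = 46,
    responder_fraction: float = 0.4,
    low_reactivity_fraction: float = 0.1,
    sigma: float = 0.5,
    effect: float = 3.0,
    hc_prevalence: float = 0.01,
    seed: int = 0,
) -> SimTruth:
    """Study-shaped default truth: candidate antigens in both isotype channels
    plus the canonical ``RO60|IgG`` seropositivity marker.

    A ``responder_fraction`` of channels carries disease-specific responders
    with seroprevalences up to ~19% in the patient group; control prevalence
    stays at or below the 2% calibration budget. A small fraction of channels
    is low-reactivity (background below the log2-MFI-10 pre-filter floor).
    Effect defaults to 3 log2 units (= 6 sigma): seropositive sera sit roughly
    an order of magnitude above background, as bead-array responders do.
    """
    rng = np.random.default_rng(seed)
    markers = [DEFAULT_RO_MARKER]
    for k in range(n_antigens):
        markers.append(f"AG{k:03d}|IgG")
        markers.append(f"AG{k:03d}|IgA")
    p = len(markers)
    mu = rng.uniform(10.5, 13.0, size=p)
    n_low = int(round(low_reactivity_fraction * (p - 1)))
    low_idx = rng.choice(np.arange(1, p), size=n_low, replace=False)
    mu[low_idx] = rng.uniform(7.0, 9.5, size=n_low)
    sig = np.full(p, sigma)
    eff = np.full(p, effect)

    pi_sjd = np.zeros(p)
    pi_sjd[0] = 0.74  # Ro/SSA-positive fraction of patients
    candidates = np.setdiff1d(np.arange(1, p), low_idx)
    n_resp = int(round(responder_fraction * candidates.size))
    resp_idx = rng.choice(candidates, size=n_resp, replace=False)
    pi_sjd[resp_idx] = rng.uniform(0.03, 0.19, size=n_resp)

    pi_hc = np.full(p, hc_prevalence)
    pi_hc[0] = 0.02
    pi_other = np.clip(pi_sjd * rng.uniform(0.0, 0.3, size=p), 0, 1)
    prevalence = {
        "SjD": pi_sjd,
        "HC": pi_hc,
        "NSS": np.maximum(pi_other, hc_prevalence),
        "RA": np.maximum(pi_other, hc_prevalence),
        "SLE": np.maximum(pi_other, hc_prevalence),
        "SSc": np.maximum(pi_other, hc_prevalence),
    }
    # plant two clinical associations on responder channels (one positive, one
    # negative link) plus 15% missingness, so downstream complete-case
    # association screening has structure to find
    associations = []
    if n_resp >= 2:
        resp_sorted = sorted(int(i) for i in resp_idx)
        associations = [
            Association(outcome="pulmonary", marker=markers[resp_sorted[0]], beta=1.0, beta0=-1.0),
            Association(outcome="articular", marker=markers[resp_sorted[1]], beta=-0.8, beta0=-0.5),
        ]
    return SimTruth(
        markers=markers, mu=mu, sigma=sig, effect=eff, prevalence=prevalence,
        associations=associations, missing_fraction=0.15, rng_seed=seed,
    )


def null_truth(n_markers: int = 50, sigma: float = 0.5, mu: float = 11.0, seed: int = 0) -> SimTruth:
    """All-null truth (no responders anywhere): the type-I-error scenario."""
    markers = [f"NUL{k:03d}|IgG" for k in range(n_markers)]
    zeros = np.zeros(n_markers)
    prevalence = {g: zeros.copy() for g in GROUPS}
    return SimTruth(
        markers=markers,
        mu=np.full(n_markers, mu),
        sigma=np.full(n_markers, sigma),
        effect=zeros.copy(),
        prevalence=prevalence,
        ro_ssa_marker="<none>",
        rng_seed=seed,
    )


def planted_panel_truth(
    planted_prevalences: tuple[float, ...] = (0.12, 0.10, 0.08),
    n_null: int = 50,
    sigma: float = 0.5,
    effect: float = 3.0,
    mu: float = 11.0,
    hc_prevalence: float = 0.0,
    seed: int = 0,
) -> SimTruth:
    """Truth with complementary panel markers planted among null channels.

    The planted markers form one disjoint responder group in the patient
    population (pairwise-disjoint responder sets — the structure an OR-rule
    panel is built to exploit); every other channel is null everywhere. A
    shared background ``mu`` keeps the sample-median centering residual
    marker-independent.
    """
    planted = [f"PAN{k}|IgG" for k in range(len(planted_prevalences))]
    nulls = [f"NUL{k:03d}|IgG" for k in range(n_null)]
    markers = planted + nulls
    p = len(markers)
    pi_sjd = np.zeros(p)
    pi_sjd[: len(planted)] = planted_prevalences
    pi_hc = np.zeros(p)
    pi_hc[: len(planted)] = hc_prevalence
    eff = np.zeros(p)
    eff[: len(planted)] = effect
    prevalence = {g: np.zeros(p) for g in GROUPS}
    prevalence["SjD"] = pi_sjd
    prevalence["HC"] = pi_hc
    return SimTruth(
        markers=markers,
        mu=np.full(p, mu),
        sigma=np.full(p, sigma),
        effect=eff,
        prevalence=prevalence,
        disjoint_groups=[planted],
        ro_ssa_marker="<none>",
        rng_seed=seed,
    )


def association_truth(
    beta: float = 1.0,
    beta0: float = -1.0,
    outcome: str = "pulmonary",
    n_null: int = 50,
    sigma: float = 0.5,
    mu: float = 11.0,
    responder_prevalence: float = 0.2,
    effect: float = 2.0,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> SimTruth:
    """Truth with one marker tied to a binary clinical outcome among nulls.

    The linked marker has patient responders (so its centered level varies);
    the outcome follows the logistic ledger on that level. All other channels
    are null and outcome-independent.
    """
    linked = "ASSOC|IgA"
    markers = [linked] + [f"NUL{k:03d}|IgA" for k in range(n_null)]
    p = len(markers)
    pi = np.zeros(p)
    pi[0] = responder_prevalence
    eff = np.zeros(p)
    eff[0] = effect
    prevalence = {g: np.zeros(p) for g in GROUPS}
    prevalence["SjD"] = pi
    return SimTruth(
        markers=markers,
        mu=np.full(p, mu),
        sigma=np.full(p, sigma),
        effect=eff,
        prevalence=prevalence,
        associations=[Association(outcome=outcome, marker=linked, beta=beta, beta0=beta0)],
        missing_fraction=missing_fraction,
        ro_ssa_marker="<none>",
        rng_seed=seed,
    )


# --- model-implied operating points ------------------------------------------

def panel_operating_point(
    truth: SimTruth,
    cutoffs: pd.Series | dict[str, float],
    panel_markers: list[str],
    group: str,
    centering_residual_sd: float | None = None,
    n_quad: int = 64,
) -> float:
    """Model-implied probability that a random ``group`` sample is OR-positive
    on ``panel_markers`` at the given *centered-scale* cutoffs.

    Valid for truths with a common background ``mu`` (e.g.
    :func:`planted_panel_truth`): sample-median centering then leaves, per
    channel, ``delta*e + eps - m`` with ``m`` the sample's median noise
    residual, approximately Normal(0, sigma * sqrt(pi / (2 p))). The residual
    is integrated out by Gauss-Hermite quadrature; disjoint responder groups
    are handled exactly conditional on the residual.
    """
    mu = truth.mu
    if not np.allclose(mu, mu[0]):
        raise ValueError("operating point requires a common background mu")
    p = len(truth.markers)
    sigma_bar = float(np.mean(truth.sigma))
    if centering_residual_sd is None:
        centering_residual_sd = sigma_bar * np.sqrt(np.pi / (2.0 * p))
    cut = {mk: float(cutoffs[mk]) for mk in panel_markers}
    pi = truth.prevalence[group]
    idx = {mk: truth.marker_index(mk) for mk in panel_markers}

    disjoint_members = {mk for grp in truth.disjoint_groups for mk in grp}
    panel_set = set(panel_markers)
    groups_in_panel = [
        [mk for mk in grp if mk in panel_set] for grp in truth.disjoint_groups
    ]
    groups_in_panel = [g for g in groups_in_panel if g]
    independents = [mk for mk in panel_markers if mk not in disjoint_members]

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    m_vals = nodes * np.sqrt(2.0) * centering_residual_sd  # m ~ N(0, sd)
    w = weights / np.sqrt(np.pi)

    def phi_neg(mk: str, responder: bool, m: np.ndarray) -> np.ndarray:
        i = idx[mk]
        shift = truth.effect[i] if responder else 0.0
        return norm.cdf((cut[mk] + m - shift) / truth.sigma[i])

    p_neg = np.ones_like(m_vals)
    for grp in groups_in_panel:
        probs = np.array([pi[idx[mk]] for mk in grp])
        none_prob = 1.0 - probs.sum()
        acc = none_prob * np.prod([phi_neg(mk, False, m_vals) for mk in grp], axis=0)
        for k, mk in enumerate(grp):
            term = probs[k] * phi_neg(mk, True, m_vals)
            for other in grp:
                if other != mk:
                    term = term * phi_neg(other, False, m_vals)
            acc = acc + term
        p_neg = p_neg * acc
    for mk in independents:
        i = idx[mk]
        p_neg = p_neg * (
            (1.0 - pi[i]) * phi_neg(mk, False, m_vals) + pi[i] * phi_neg(mk, True, m_vals)
        )
    return float(1.0 - np.sum(w * p_neg))
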