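"""Univariate statistics, cutoff calibration/escalation, and prevalence.

Brute-force enumeration oracles (written here, independent of the
implementation path) back every exact-statistics assertion.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from seropanel import (
    MfiMatrix,
    binarize,
    calibrate_cutoff,
    coprevalence_matrix,
    fisher_exact,
    fold_change,
    mann_whitney,
    prevalence_table,
    sam_d,
    sam_permutation_p,
    screen_markers,
)
from seropanel.screen import ControlQuantileBinarizer, pooled_se, quantile_span

# --- independent oracles -----------------------------------------------------

def mw_u_stat(case, control):
    """U statistic for the case side, by direct pair counting."""
    u = 0.0
    for x in case:
        for y in control:
            u += (x > y) + 0.5 * (x == y)
    return u


def mw_enumeration_p(case, control):
    """Two-sided exact Mann-Whitney p by full enumeration of labelings."""
    pooled = list(case) + list(control)
    n1 = len(case)
    mu = n1 * len(control) / 2.0
    obs = abs(mw_u_stat(case, control) - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        grp1 = [pooled[i] for i in idx]
        grp2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        count += abs(mw_u_stat(grp1, grp2) - mu) >= obs - 1e-12
        total += 1
    return count / total


def sam_enumeration_p(case, control, s0):
    """Two-sided permutation p for the moderated d by full enumeration."""

    def d_stat(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        s = math.sqrt((1 / a.size + 1 / b.size) * ss / (a.size + b.size - 2))
        return (a.mean() - b.mean()) / (s + s0)

    pooled = list(case) + list(control)
    n1 = len(case)
    obs = abs(d_stat(case, control))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        grp1 = [pooled[i] for i in idx]
        grp2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        count += abs(d_stat(grp1, grp2)) >= obs - 1e-12
        total += 1
    return count / total


def fisher_enumeration_p(a, b, c, d):
    """Two-sided Fisher p: sum hypergeometric P of tables no more probable."""
    n, k1, k2 = a + b + c + d, a + b, a + c
    p_obs = hypergeom.pmf(a, n, k1, k2)
    total = 0.0
    for x in range(max(0, k1 + k2 - n), min(k1, k2) + 1):
        p = hypergeom.pmf(x, n, k1, k2)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def escalation_scan_oracle(hc, case, c0):
    """Largest observed candidate above c0 keeping case positives and
    strictly reducing HC positives; None if no candidate qualifies."""
    base_case = (case > c0).sum()
    base_hc = (hc > c0).sum()
    best = None
    for c in np.unique(np.concatenate([hc, case])):
        if c <= c0:
            continue
        if (case > c).sum() == base_case and (hc > c).sum() < base_hc:
            if best is None or c > best:
                best = c
    return best


# --- Mann-Whitney ------------------------------------------------------------

class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = mann_whitney([4, 5, 6], [1, 2, 3])
        assert u == 9.0
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_for_all_splits_of_seven(self):
        values = [1.0, 2.5, 3.0, 4.7, 5.1, 6.0, 9.3]
        for n1 in (2, 3):  # splits of 7 distinct values (complement covers rest)
            for idx in itertools.combinations(range(7), n1):
                case = [values[i] for i in idx]
                control = [values[i] for i in range(7) if i not in idx]
                _, p = mann_whitney(case, control)
                assert p == pytest.approx(mw_enumeration_p(case, control), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [1, 2, 3])


# --- SAM d -------------------------------------------------------------------

class TestSamD:
    def test_zero_scatter_with_fudge(self):
        assert sam_d([3, 3, 3], [1, 1, 1], s0=1.0) == pytest.approx(2.0)

    def test_symmetry(self):
        assert sam_d([1, 2, 3], [1, 2, 3], s0=0.1) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="d undefined"):
            sam_d([3, 3, 3], [1, 1, 1], s0=0.0)

    def test_permutation_p_matches_enumeration(self, rng):
        for _ in range(10):
            case = rng.normal(1.0, 1.0, size=3)
            control = rng.normal(0.0, 1.0, size=3)
            p = sam_permutation_p(case, control, s0=0.1)
            assert p == pytest.approx(sam_enumeration_p(case, control, 0.1), abs=1e-12)


class TestFoldChange:
    @pytest.mark.parametrize(
        "case,control,expected",
        [
            ([10.0, 10.0], [9.0, 9.0], 2.0),
            ([1.0], [1.0], 1.0),
            ([np.log2(3.0)], [0.0], 3.0),
        ],
    )
    def test_known_values(self, case, control, expected):
        assert fold_change(case, control) == pytest.approx(expected)


# --- cutoff calibration ------------------------------------------------------

class TestCalibrateCutoff:
    def test_base_quantile_no_escalation_possible(self):
        c, esc = calibrate_cutoff(np.arange(1.0, 11.0), np.array([]), q=0.98)
        assert c == 10.0 and esc is False

    def test_no_escalation_when_hc_already_clean(self):
        hc = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 12], dtype=float)
        c, esc = calibrate_cutoff(hc, np.array([15.0, 20.0]), q=0.98)
        assert c == 12.0 and esc is False

    def test_escalates_through_observed_values(self):
        hc = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 12], dtype=float)
        c, esc = calibrate_cutoff(hc, np.array([15.0, 20.0]), q=0.9)
        assert c == 12.0 and esc is True

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="pooling controls"):
            calibrate_cutoff(np.arange(9.0), np.arange(3.0))

    def test_escalation_matches_scan_oracle_and_is_monotone(self, rng):
        from seropanel.preprocess import nearest_rank_quantile

        for _ in range(200):
            hc = rng.normal(0, 1, size=rng.integers(10, 25))
            case = rng.normal(rng.uniform(0, 2), 1, size=rng.integers(2, 15))
            q = float(rng.uniform(0.7, 0.98))
            c0 = nearest_rank_quantile(hc, q)
            cutoff, esc = calibrate_cutoff(hc, case, q=q)
            oracle = escalation_scan_oracle(hc, case, c0)
            if esc:
                assert cutoff == oracle
            else:
                assert oracle is None and cutoff == c0
            # escalation never loses case sensitivity nor HC specificity
            assert (case > cutoff).sum() == (case > c0).sum()
            assert (hc > cutoff).sum() <= (hc > c0).sum()
            assert cutoff >= c0


class TestBinarize:
    @pytest.fixture
    def calls_setup(self):
        df = pd.DataFrame(
            [[1.0, 5.0], [2.0, 3.0]], index=["s1", "s2"], columns=["A|IgG", "B|IgG"]
        )
        m = MfiMatrix(df, scale="log2_centered")
        cutoffs = pd.DataFrame(
            {"cutoff": [2.0, 4.0]}, index=pd.Index(["A|IgG", "B|IgG"], name="marker")
        )
        return m, cutoffs

    def test_boundary_value_is_negative(self, calls_setup):
        m, cutoffs = calls_setup
        calls = binarize(m, cutoffs)
        assert not calls.loc["s2", "A|IgG"]  # 2.0 > 2.0 is False
        assert calls.loc["s1", "B|IgG"]

    def test_all_below_gives_all_false(self):
        df = pd.DataFrame([[0.1, 0.2]], index=["s"], columns=["A|IgG", "B|IgG"])
        cutoffs = pd.DataFrame({"cutoff": [1.0, 1.0]},
                               index=pd.Index(["A|IgG", "B|IgG"], name="marker"))
        assert not binarize(MfiMatrix(df, scale="log2_centered"), cutoffs).any().any()

    def test_missing_marker_rejected(self, calls_setup):
        m, cutoffs = calls_setup
        with pytest.raises(KeyError, match="B"):
            binarize(m, cutoffs.iloc[:1])

    def test_recompute_from_persisted_table_is_identical(self, rng, tmp_path):
        from seropanel import io

        arr = rng.normal(0, 1, size=(30, 4))
        df = pd.DataFrame(arr, index=[f"s{i}" for i in range(30)],
                          columns=[f"M{j}|IgG" for j in range(4)])
        m = MfiMatrix(df, scale="log2_centered")
        y = np.array(["HC"] * 15 + ["SjD"] * 15)
        binz = ControlQuantileBinarizer(quantile=0.9).fit(df, y)
        calls = binz.transform(df)
        path = tmp_path / "cut.csv"
        io.write_cutoff_table(binz.cutoff_table(), path)
        calls2 = binarize(m, io.read_cutoff_table(path))
        pd.testing.assert_frame_equal(calls, calls2)


# --- Fisher ------------------------------------------------------------------

class TestFisherExact:
    def test_diagonal_table(self):
        p = fisher_exact([1, 1, 1], [0, 0, 0])  # [[3,0],[0,3]]
        assert p == pytest.approx(0.1)

    def test_balanced_table(self):
        p = fisher_exact([1, 0], [1, 0])  # [[1,1],[1,1]]
        assert p == pytest.approx(1.0)

    def test_empty_margin_warns(self):
        with pytest.warns(UserWarning, match="empty margin"):
            assert fisher_exact([0, 0], [0, 0]) == 1.0

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 5, size=4)
            if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
                continue
            calls_case = [True] * a + [False] * b
            calls_ctrl = [True] * c + [False] * d
            assert fisher_exact(calls_case, calls_ctrl) == pytest.approx(
                fisher_enumeration_p(a, b, c, d), abs=1e-9
            )


# --- prevalence --------------------------------------------------------------

class TestPrevalence:
    @pytest.fixture
    def calls_meta(self):
        idx = [f"p{i}" for i in range(16)] + [f"h{i}" for i in range(8)]
        calls = pd.DataFrame(False, index=idx, columns=["A|IgG", "B|IgG"])
        calls.loc[["p0", "p1", "p2"], "A|IgG"] = True
        calls.loc[["p1", "p2", "p3"], "B|IgG"] = True
        meta = pd.DataFrame(
            {
                "sample_id": idx,
                "group": ["SjD"] * 16 + ["HC"] * 8,
                "cohort": "x",
            }
        ).set_index(pd.Index(idx))
        return calls, meta

    def test_counting(self, calls_meta):
        calls, meta = calls_meta
        tab = prevalence_table(calls, meta)
        row = tab[(tab.marker == "A|IgG") & (tab.group == "SjD")].iloc[0]
        assert row["prevalence_pct"] == pytest.approx(18.75)
        assert row["n_positive"] + (row["n"] - row["n_positive"]) == row["n"]

    def test_coprevalence_counts_and_symmetry(self):
        idx = [f"s{i}" for i in range(10)]
        calls = pd.DataFrame(False, index=idx, columns=["A|IgG", "B|IgG"])
        calls.loc[["s1", "s2", "s3"], "A|IgG"] = True
        calls.loc[["s2", "s3", "s4"], "B|IgG"] = True
        co = coprevalence_matrix(calls)
        assert co.loc["A|IgG", "A|IgG"] == pytest.approx(0.3)
        assert co.loc["B|IgG", "B|IgG"] == pytest.approx(0.3)
        assert co.loc["A|IgG", "B|IgG"] == pytest.approx(0.2)
        pd.testing.assert_frame_equal(co, co.T)

    def test_coprevalence_bounded_by_diagonals(self, rng):
        calls = pd.DataFrame(
            rng.random((40, 6)) < 0.3,
            index=[f"s{i}" for i in range(40)],
            columns=[f"M{j}|IgG" for j in range(6)],
        )
        co = coprevalence_matrix(calls).to_numpy()
        diag = np.diag(co)
        assert (co <= np.minimum.outer(diag, diag) + 1e-12).all()

    def test_disjoint_markers_have_zero_coprevalence(self):
        idx = ["a", "b", "c", "d"]
        calls = pd.DataFrame(
            [[True, False], [True, False], [False, True], [False, False]],
            index=idx, columns=["A|IgG", "B|IgG"],
        )
        assert coprevalence_matrix(calls).loc["A|IgG", "B|IgG"] == 0.0


class TestScreenMarkers:
    def test_strong_marker_flagged_null_not(self, rng):
        n_case, n_ctrl = 60, 40
        strong = np.concatenate([rng.normal(2.0, 0.5, n_case), rng.normal(0, 0.5, n_ctrl)])
        null = rng.normal(0, 0.5, n_case + n_ctrl)
        idx = [f"p{i}" for i in range(n_case)] + [f"h{i}" for i in range(n_ctrl)]
        m = MfiMatrix(
            pd.DataFrame({"STRONG|IgG": strong, "NULL|IgG": null}, index=idx),
            scale="log2_centered",
        )
        meta = pd.DataFrame(
            {"sample_id": idx, "group": ["SjD"] * n_case + ["HC"] * n_ctrl, "cohort": "x"}
        ).set_index(pd.Index(idx))
        table, binz, calls = screen_markers(m, meta, rng=np.random.default_rng(0))
        table = table.set_index("marker")
        assert table.loc["STRONG|IgG", "pass_mw"] and table.loc["STRONG|IgG", "pass_fisher"]
        assert table.loc["STRONG|IgG", "pass_sam"]
        assert not table.loc["NULL|IgG", "pass_fisher"]
        assert table.loc["STRONG|IgG", "prevalence_SjD"] > 0.9
        assert table.loc["STRONG|IgG", "prevalence_HC"] <= 0.05
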