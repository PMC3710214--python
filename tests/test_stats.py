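"""Exact statistics kernel, cross-checked against independent routes."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mpsi_predict import (
    Contingency2x2,
    fisher_exact_two_sided,
    mann_whitney_exact,
    roc_auc,
    round_half_up_percent,
)


def fisher_log_factorial(a, b, c, d):
    """Independent probability-based two-sided Fisher via log-factorials."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def logp(k):
        return (
            math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1)
            - math.lgamma(r2 - c1 + k + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    obs = logp(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        lp = logp(k)
        if lp <= obs + 1e-7:
            total += math.exp(lp)
    return min(1.0, total)


class TestRocAuc:
    def test_reference_activities(self, cohort):
        """The 18 labeled activities give AUC 77/81 (printed 0.951)."""
        sub = [r for r in cohort if r.idua_activity is not None]
        curve = roc_auc([r.idua_activity for r in sub], [r.is_hurler for r in sub])
        assert curve.auc == pytest.approx(77 / 81)
        assert round(curve.auc, 3) == 0.951

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.9, 1.0], [True, True, False, False]).auc == 1.0

    def test_all_ties(self):
        assert roc_auc([1.0, 1.0, 1.0], [True, False, True]).auc == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])

    @given(
        st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=8),
        st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=8),
    )
    def test_label_inversion_and_monotone_invariance(self, pos, neg):
        values = pos + neg
        labels = [True] * len(pos) + [False] * len(neg)
        auc = roc_auc(values, labels).auc
        inverted = roc_auc(values, [not l for l in labels]).auc
        assert auc == pytest.approx(1 - inverted)
        # scaling by a power of two is exact in floats, hence strictly
        # monotone even for values separated by one ulp
        transformed = [4.0 * v for v in values]
        assert roc_auc(transformed, labels).auc == pytest.approx(auc)

    def test_matches_sklearn(self, cohort):
        sklearn = pytest.importorskip("sklearn.metrics")
        sub = [r for r in cohort if r.idua_activity is not None]
        values = [r.idua_activity for r in sub]
        labels = [r.is_hurler for r in sub]
        # sklearn scores "high = positive"; negate for the low-is-positive
        # orientation
        expected = sklearn.roc_auc_score(labels, [-v for v in values])
        assert roc_auc(values, labels).auc == pytest.approx(expected)

    def test_curve_export(self):
        curve = roc_auc([0.1, 0.9], [True, False])
        text = curve.to_delimited()
        assert text.splitlines()[0] == "cutoff\tsensitivity\tspecificity"
        assert len(text.splitlines()) == 3


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[7, 2], [1, 9]], 0.00548),
            ([[4, 5], [0, 10]], 0.0325),
            ([[1, 1], [1, 1]], 1.0),
        ],
    )
    def test_reference_tables(self, table, expected):
        assert fisher_exact_two_sided(table) == pytest.approx(expected, rel=2e-3)

    def test_against_scipy_and_log_factorial(self):
        """Sweep all tables with total <= 10: the enumeration agrees with
        scipy and with an independent log-factorial formulation."""
        for n in range(1, 11):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        p = fisher_exact_two_sided(Contingency2x2(a, b, c, d))
                        assert p == pytest.approx(
                            sps.fisher_exact([[a, b], [c, d]])[1], abs=1e-9
                        )
                        assert p == pytest.approx(
                            fisher_log_factorial(a, b, c, d), abs=1e-6
                        )

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            Contingency2x2(-1, 0, 0, 2)
        with pytest.raises(ValueError):
            Contingency2x2(0, 0, 0, 0)


def brute_force_mw_p(x, y):
    """Two-sided Mann-Whitney p by exhaustive label permutation."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(
            (1.0 if a > b else 0.5 if a == b else 0.0) for a in xs for b in ys
        )

    mid = n * (len(pooled) - n) / 2
    d_obs = abs(u_of(range(n)) - mid)
    combos = list(itertools.combinations(range(len(pooled)), n))
    hits = sum(1 for idx in combos if abs(u_of(idx) - mid) >= d_obs - 1e-12)
    return hits / len(combos)


class TestMannWhitney:
    def test_hurler_vs_scheie_complete_separation(self, cohort):
        """Hurler activities sit entirely below Scheie activities: U = 0 and
        the exact two-sided p is 2/715."""
        h = [r.idua_activity for r in cohort
             if r.phenotype == "H" and r.idua_activity is not None]
        s = [r.idua_activity for r in cohort
             if r.phenotype == "S" and r.idua_activity is not None]
        assert (len(h), len(s)) == (9, 4)
        u, p = mann_whitney_exact(h, s)
        assert u == 0.0
        assert p == pytest.approx(2 / 715)

    def test_identical_samples(self):
        _, p = mann_whitney_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_minimal_samples(self):
        u, p = mann_whitney_exact([1.0], [2.0])
        assert u == 0.0
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=5),
        st.lists(st.integers(0, 20), min_size=1, max_size=5),
    )
    def test_matches_brute_force_enumeration(self, x, y):
        """p equals the fraction of label permutations at least as extreme,
        for all n_x + n_y <= 10 (ties handled by the permutation path)."""
        x = [float(v) for v in x]
        y = [float(v) for v in y]
        _, p = mann_whitney_exact(
            x, y, rng=np.random.default_rng(7)
        )
        expected = brute_force_mw_p(x, y)
        if len(set(x + y)) == len(x) + len(y):
            assert p == pytest.approx(expected)  # exact path
        else:
            assert p == pytest.approx(expected, abs=0.02)  # permutation path

    def test_auc_u_identity(self, cohort):
        """AUC equals U/(n_pos · n_neg) with U counting non-H-above-H pairs."""
        sub = [r for r in cohort if r.idua_activity is not None]
        pos = [r.idua_activity for r in sub if r.is_hurler]
        neg = [r.idua_activity for r in sub if not r.is_hurler]
        curve = roc_auc([*pos, *neg], [True] * len(pos) + [False] * len(neg))
        u, _ = mann_whitney_exact(neg, pos)
        assert curve.auc == pytest.approx(u / (len(pos) * len(neg)))


@pytest.mark.parametrize(
    "fraction, expected", [(0.8235, 82), (0.556, 56), (0.889, 89), (0.625, 63)]
)
def test_round_half_up_percent(fraction, expected):
    assert round_half_up_percent(fraction) == expected
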