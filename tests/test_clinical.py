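"""KOOS change scores and the Spearman rank association."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gaitshift.clinical import (associate, koos_change, magnitude_label,
                                spearman)
from gaitshift.io import KoosRecord
from gaitshift.oneclass import OutlierResult


def _rec(sid, tp, vals):
    return KoosRecord(sid, tp, *vals)


class TestKoosChange:
    def test_uniform_improvement(self):
        c = koos_change(_rec("A", "pre", [50] * 4), _rec("A", "post", [60] * 4))
        assert c.mean_change == pytest.approx(10.0)
        assert c.clipped_change == pytest.approx(10.0)

    def test_deterioration_clips_to_zero(self):
        c = koos_change(_rec("A", "pre", [60] * 4), _rec("A", "post", [50] * 4))
        assert c.mean_change == pytest.approx(-10.0)
        assert c.clipped_change == 0.0

    def test_mixed_subscale_changes_average(self):
        pre = _rec("A", "pre", [50, 50, 50, 50])
        post = _rec("A", "post", [58, 46, 56, 52])
        c = koos_change(pre, post)
        assert c.mean_change == pytest.approx(3.0)
        assert c.clipped_change == pytest.approx(3.0)

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            koos_change(_rec("A", "pre", [50] * 4), _rec("B", "post", [60] * 4))

    def test_wrong_timepoint_order_rejected(self):
        with pytest.raises(ValueError, match="timepoint"):
            koos_change(_rec("A", "post", [50] * 4), _rec("A", "pre", [60] * 4))


def _brute_spearman(x, y):
    """Independent oracle: rank by sorting with mid-rank ties, Pearson on
    ranks by the explicit formula, p by looping over all n! permutations."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        v_sorted = np.asarray(v)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and v_sorted[j + 1] == v_sorted[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    def pearson(a, b):
        a = a - np.mean(a)
        b = b - np.mean(b)
        return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))

    rx, ry = ranks(x), ranks(y)
    rho = pearson(rx, ry)
    count = 0
    total = 0
    for perm in permutations(range(len(x))):
        total += 1
        if abs(pearson(rx, ry[list(perm)])) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)

    def test_perfect_inverse(self):
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_matches_brute_force_oracle_with_ties_at_n8(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 6, 8])      # one tie in x
        y = np.array([2.0, 1, 3, 4, 6, 5, 7, 7])      # swap + tie in y
        rho, p = spearman(x, y)
        rho_b, p_b = _brute_spearman(x, y)
        assert rho == pytest.approx(rho_b, abs=1e-12)
        assert p == pytest.approx(p_b, abs=1e-12)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.sampled_from(["exp", "cube", "affine"]))
    def test_invariant_under_strictly_monotone_transforms(self, seed, kind):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        f = {"exp": np.exp, "cube": lambda v: v ** 3,
             "affine": lambda v: 3.0 * v + 1.0}[kind]
        rho, p = spearman(x, y)
        rho2, p2 = spearman(f(x), y)
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)


class TestMagnitudeLabel:
    @pytest.mark.parametrize("rho,label", [
        (0.05, "negligible"), (-0.09, "negligible"),
        (0.10, "small"), (0.29, "small"),
        (0.30, "medium"), (-0.49, "medium"),
        (0.50, "large"), (0.55, "large"), (-0.9, "large"),
    ])
    def test_bands(self, rho, label):
        assert magnitude_label(rho) == label


class TestAssociate:
    @staticmethod
    def _pair(sid, pct, change):
        res = OutlierResult.from_decisions(np.array([-1.0] * int(pct)
                                                    + [1.0] * (100 - int(pct))))
        pre = _rec(sid, "pre", [50] * 4)
        post = _rec(sid, "post", [50 + change] * 4)
        return res, koos_change(pre, post)

    def test_monotone_cohort_gives_rho_one(self):
        pairs = [self._pair(f"S{i}", pct, chg) for i, (pct, chg) in
                 enumerate([(0, 1), (10, 5), (20, 12), (40, 20), (80, 30)])]
        out = associate(pairs)
        assert out.rho == pytest.approx(1.0)
        assert out.label == "large"

    def test_constant_outlier_pcts_rejected(self):
        pairs = [self._pair(f"S{i}", 10, chg) for i, chg in enumerate([1, 5, 9, 14])]
        with pytest.raises(ValueError, match="undefined"):
            associate(pairs)

    def test_fewer_than_four_subjects_rejected(self):
        pairs = [self._pair(f"S{i}", p, c) for i, (p, c) in
                 enumerate([(0, 1), (10, 5), (20, 9)])]
        with pytest.raises(ValueError, match="4"):
            associate(pairs)

    def test_report_frame_has_per_subject_rows(self):
        pairs = [self._pair(f"S{i}", pct, chg) for i, (pct, chg) in
                 enumerate([(0, 1), (10, 5), (20, 12), (40, 20)])]
        df = associate(pairs).to_frame()
        assert list(df.columns) == ["subject_id", "outlier_pct", "mean_change",
                                    "clipped_change"]
        assert len(df) == 4
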