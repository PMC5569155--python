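"""Thresholded performance, ROC/AUC, Youden cutoffs, ICC and chi-square."""

import numpy as np
import pytest

import swequant as sq
from swequant.diagnostics import ConfusionCounts, apply_display_adjustment


def mann_whitney_auc(values, labels):
    """Oracle: pairwise concordance count with half-credit ties."""
    v = np.asarray(values, float)
    y = np.asarray(labels, int)
    pos, neg = v[y == 1], v[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def youden_exhaustive(values, labels):
    """Oracle: scan every midpoint threshold with explicit counting."""
    v = np.asarray(values, float)
    y = np.asarray(labels, int)
    distinct = np.unique(v)
    best = (None, -np.inf)
    for cut in 0.5 * (distinct[:-1] + distinct[1:]):
        se = np.mean(v[y == 1] > cut)
        sp = np.mean(v[y == 0] <= cut)
        j = se + sp - 1
        if j > best[1] + 1e-12:
            best = (cut, j)
    return best


class TestConfusion:
    @pytest.mark.parametrize(
        "values,labels,thr,expected",
        [
            ([90, 70], [1, 0], 80, (1, 0, 1, 0)),
            ([10, 20], [1, 0], 80, (0, 0, 1, 1)),
            ([50, 60, 95, 85], [0, 0, 1, 1], 80, (2, 0, 2, 0)),
        ],
    )
    def test_examples(self, values, labels, thr, expected):
        assert sq.confusion_at_threshold(values, labels, thr) == expected

    def test_comparator_switch(self):
        assert sq.confusion_at_threshold([80], [1], 80, "gt").tp == 0
        assert sq.confusion_at_threshold([80], [1], 80, "ge").tp == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sq.confusion_at_threshold([], [], 80)


class TestSeSpDa:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((1, 0, 1, 0), (100.0, 100.0, 100.0)),
            ((0, 0, 1, 1), (0.0, 100.0, 50.0)),
        ],
    )
    def test_examples(self, counts, expected):
        assert sq.se_sp_da(ConfusionCounts(*counts)) == expected

    def test_hand_arithmetic(self):
        se, sp, da = sq.se_sp_da(ConfusionCounts(8, 2, 6, 4))
        assert se == pytest.approx(66.7, abs=0.05)
        assert sp == pytest.approx(75.0)
        assert da == pytest.approx(70.0)

    def test_zero_denominator_gives_nan(self):
        se, sp, da = sq.se_sp_da(ConfusionCounts(0, 3, 5, 0))
        assert np.isnan(se) and sp == pytest.approx(62.5)


class TestRocAuc:
    def test_perfect_separation(self):
        _, a = sq.roc_auc([1, 2, 9, 10], [0, 0, 1, 1])
        assert a == 1.0

    def test_all_tied_values(self):
        _, a = sq.roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert a == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_mann_whitney_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        values = np.round(rng.lognormal(4, 0.6, n), 1)  # induces ties
        _, a = sq.roc_auc(values, labels)
        assert a == pytest.approx(mann_whitney_auc(values, labels), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            sq.roc_auc([1, 2], [1, 1])


class TestYouden:
    def test_perfect_separation_midpoint(self):
        cut, j = sq.youden_optimal([10, 20, 90, 100], [0, 0, 1, 1])
        assert cut == 55.0 and j == pytest.approx(1.0)

    def test_identical_distributions_j_zero(self):
        cut, j = sq.youden_optimal([30, 60, 30, 60], [0, 0, 1, 1])
        assert j == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        benign = rng.lognormal(3.6, 0.5, 20)
        malig = rng.lognormal(4.8, 0.5, 30)
        values = np.concatenate([benign, malig])
        labels = np.array([0] * 20 + [1] * 30)
        cut, j = sq.youden_optimal(values, labels)
        ocut, oj = youden_exhaustive(values, labels)
        assert cut == pytest.approx(ocut) and j == pytest.approx(oj)

    def test_j_at_optimum_at_least_fixed_threshold(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.lognormal(3.5, 0.5, 40), rng.lognormal(5, 0.5, 60)])
        labels = np.array([0] * 40 + [1] * 60)
        _, j = sq.youden_optimal(values, labels)
        se, sp, _ = sq.se_sp_da(sq.confusion_at_threshold(values, labels, 80.0))
        assert j >= se / 100 + sp / 100 - 1 - 1e-12


class TestIcc:
    def test_identical_columns_is_one(self):
        x = np.random.default_rng(0).normal(50, 10, 12)
        assert sq.icc_absolute_single(np.stack([x, x], 1)) == pytest.approx(1.0)

    def test_constant_offset_below_one(self):
        x = np.random.default_rng(1).normal(50, 10, 12)
        icc = sq.icc_absolute_single(np.stack([x, x + 8.0], 1))
        assert icc < 1.0
        # consistency form forgives the offset
        assert sq.icc_absolute_single(np.stack([x, x + 8.0], 1), form="icc3") == pytest.approx(1.0)

    def test_matches_mean_squares_formula(self):
        rng = np.random.default_rng(2)
        x = rng.normal(60, 15, (6, 2))
        n, k = x.shape
        grand = x.mean()
        msr = k * np.sum((x.mean(1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((x.mean(0) - grand) ** 2) / (k - 1)
        mse = (np.sum((x - grand) ** 2) - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert sq.icc_absolute_single(x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("shape", [(6, 2), (20, 3), (50, 5)])
    def test_matches_pingouin_icc2(self, shape):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(shape[0])
        x = rng.normal(70, 20, shape)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(shape[0]), shape[1]),
                "rater": np.tile(np.arange(shape[1]), shape[0]),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, "subject", "rater", "score")
        ref_icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert sq.icc_absolute_single(x) == pytest.approx(ref_icc2, abs=1e-10)

    def test_invariant_to_subject_reordering(self):
        rng = np.random.default_rng(4)
        x = rng.normal(50, 5, (15, 3))
        perm = rng.permutation(15)
        assert sq.icc_absolute_single(x[perm]) == pytest.approx(
            sq.icc_absolute_single(x), abs=1e-12
        )

    def test_noise_decreases_agreement(self):
        rng = np.random.default_rng(5)
        base = rng.normal(80, 25, 60)
        iccs = []
        for sigma in (1.0, 5.0, 15.0):
            noisy = np.stack([base + rng.normal(0, sigma, 60) for _ in range(3)], 1)
            iccs.append(sq.icc_absolute_single(noisy))
        assert iccs[0] > iccs[1] > iccs[2]

    def test_missing_cells_rejected(self):
        x = np.ones((4, 2))
        x[1, 1] = np.nan
        with pytest.raises(ValueError):
            sq.icc_absolute_single(x)


class TestChiSquare:
    def test_null_table(self):
        chi2, p, sig = sq.chi_square_2x2([[50, 50], [50, 50]])
        assert chi2 == 0 and p == pytest.approx(1.0) and not sig

    def test_hand_computed_statistic(self):
        chi2, p, sig = sq.chi_square_2x2([[50, 50], [30, 70]])
        assert chi2 == pytest.approx(8.3333, abs=5e-4)
        assert sig

    def test_alpha_boundary_inclusive(self):
        # p == alpha counts as significant
        chi2, p, sig = sq.chi_square_2x2([[50, 50], [50, 50]], alpha=1.0)
        assert sig

    def test_symmetric_under_row_and_column_swap(self):
        t = np.array([[12, 30], [25, 9]])
        a = sq.chi_square_2x2(t)
        b = sq.chi_square_2x2(t[::-1, ::-1])
        assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            sq.chi_square_2x2([[0, 0], [5, 5]])

    def test_mcnemar_option(self):
        stat, p, sig = sq.mcnemar_2x2([[30, 10], [4, 56]])
        assert stat == pytest.approx((10 - 4) ** 2 / (10 + 4))


class TestCompareRoutes:
    @staticmethod
    def _identical_cohort():
        rng = np.random.default_rng(0)
        n = 40
        labels = np.array([0] * 15 + [1] * 25)
        vals = {
            "e_max": np.where(labels, rng.lognormal(4.9, 0.4, n), rng.lognormal(3.7, 0.4, n)),
            "e_mean": np.where(labels, rng.lognormal(4.5, 0.4, n), rng.lognormal(3.3, 0.4, n)),
            "sd": np.where(labels, rng.lognormal(2.3, 0.3, n), rng.lognormal(1.5, 0.3, n)),
        }
        values = {r: {p: v.copy() for p, v in vals.items()} for r in ("A", "B")}
        return sq.Cohort(lesion_ids=[f"l{i}" for i in range(n)], labels=labels, values=values)

    def test_identical_routes_agree_perfectly(self):
        report = sq.compare_routes(self._identical_cohort())
        assert np.allclose(report.icc["icc"], 1.0)
        aucs = report.performance.groupby("parameter")["auc"].nunique()
        assert (aucs == 1).all()

    def test_degraded_route_has_lower_sd_auc(self):
        cohort = sq.make_cohort(sq.default_cohort_spec(seed=9))
        report = sq.compare_routes(cohort)
        perf = report.performance.set_index(["route", "parameter"])
        assert perf.loc[("JPG", "sd"), "auc"] < perf.loc[("QDE", "sd"), "auc"]

    def test_short_route_skipped_with_warning(self):
        cohort = self._identical_cohort()
        cohort.values["empty"] = {
            "e_max": np.array([]), "e_mean": np.array([]), "sd": np.array([])
        }
        # realign: the empty route is misaligned, so construct directly
        cohort.values.pop("empty")
        one = sq.Cohort(
            lesion_ids=["x"], labels=np.array([1]),
            values={"solo": {"e_max": np.array([90.0]),
                             "e_mean": np.array([60.0]), "sd": np.array([8.0])}},
        )
        with pytest.warns(UserWarning, match="skipped"):
            report = sq.compare_routes(one)
        assert report.performance.empty

    def test_display_adjustment_clamps_only_e_params(self):
        cohort = self._identical_cohort()
        cohort.values["A"]["e_max"][0] = 250.0
        cohort.values["A"]["sd"][0] = 250.0
        adj = apply_display_adjustment(cohort, ceiling=180.0)
        assert adj.values["A"]["e_max"][0] == 180.0
        assert adj.values["A"]["sd"][0] == 250.0
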