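"""Sham thresholding, Dunnett T3 / SMM machinery, hierarchical testing, biodistribution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from evuptake import simulate, stats
from evuptake.simulate import ExperimentDesign, Treatment
from evuptake.stats import (
    dunnett_t3,
    fraction_positive,
    grubbs_critical,
    hierarchical_anova,
    normalize_biodistribution,
    sham_threshold,
    smm_cdf,
)


class TestShamThreshold:
    def test_no_outliers_keeps_maximum(self):
        thr = sham_threshold([1.0, 2.0, 3.0])
        assert thr.value == 3.0 and thr.removed_indices == []

    def test_gross_outlier_removed_then_max_of_rest(self):
        thr = sham_threshold([1.0, 2.0, 3.0, 100.0])
        assert thr.removed_indices == [3]
        assert thr.value == 3.0 and thr.n_used == 3

    def test_identical_values_keep_everything(self):
        thr = sham_threshold([5.0, 5.0, 5.0, 5.0])
        assert thr.value == 5.0 and thr.removed_indices == []

    def test_idempotent_on_retained_values(self):
        vals = np.array([1.0, 2.0, 3.0, 100.0])
        first = sham_threshold(vals)
        retained = np.delete(vals, first.removed_indices)
        second = sham_threshold(retained)
        assert second.removed_indices == [] and second.value == first.value

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError):
            sham_threshold([1.0, 2.0])

    def test_sd_rule_also_available(self):
        thr = sham_threshold(list(range(10)) + [1000.0], rule="sd", sd_factor=3.0)
        assert thr.removed_indices == [10]

    def test_grubbs_critical_matches_published_table(self):
        # standard two-sided 5% critical values
        assert grubbs_critical(10, 0.05) == pytest.approx(2.290, abs=0.002)
        assert grubbs_critical(20, 0.05) == pytest.approx(2.709, abs=0.002)


class TestFractionPositive:
    @pytest.fixture
    def measurements(self):
        rng = np.random.default_rng(0)
        rows = []
        for tr, mean in (("sham", 5.0), ("ev", 12.0)):
            for h in range(3):
                for c in range(20):
                    rows.append(
                        {
                            "treatment": tr,
                            "heart_id": f"{tr}{h}",
                            "value": rng.normal(mean, 1.0),
                        }
                    )
        return pd.DataFrame(rows)

    def test_sham_positivity_zero_by_construction(self, measurements):
        sham_vals = measurements[measurements.treatment == "sham"].value.to_numpy()
        thr = sham_threshold(sham_vals)
        by_tr, _ = fraction_positive(measurements, thr, "value")
        assert by_tr["sham"] == 0.0

    def test_strong_effect_gives_full_positivity(self, measurements):
        thr = sham_threshold(measurements[measurements.treatment == "sham"].value.to_numpy())
        by_tr, by_heart = fraction_positive(measurements, thr, "value")
        assert by_tr["ev"] > 0.95
        assert set(by_heart.index.get_level_values(0)) == {"sham", "ev"}

    def test_infinite_threshold_zero_everywhere(self, measurements):
        by_tr, _ = fraction_positive(measurements, float("inf"), "value")
        assert (by_tr == 0.0).all()

    def test_monotone_nonincreasing_in_threshold(self, measurements):
        fracs = [
            fraction_positive(measurements, t, "value")[0]["ev"] for t in (2.0, 6.0, 10.0, 14.0)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestSMM:
    def test_k1_equals_two_sided_t(self):
        for q, df in ((1.0, 4.0), (2.5, 7.3), (4.0, 12.0)):
            assert 1 - smm_cdf(q, 1, df) == pytest.approx(2 * sps.t.sf(q, df), abs=1e-8)

    def test_matches_monte_carlo(self):
        # SMM: max of k |N(0,1)| over a shared chi/sqrt(df) denominator
        rng = np.random.default_rng(42)
        k, df, n = 3, 6.0, 200_000
        z = np.abs(rng.standard_normal((n, k))).max(axis=1)
        s = np.sqrt(rng.chisquare(df, n) / df)
        m = z / s
        for q in (1.5, 2.5, 3.5):
            assert smm_cdf(q, k, df) == pytest.approx((m <= q).mean(), abs=0.01)

    def test_more_comparisons_larger_p(self):
        p1 = 1 - smm_cdf(2.0, 1, 8.0)
        p3 = 1 - smm_cdf(2.0, 3, 8.0)
        assert p3 > p1


class TestDunnettT3:
    def test_zero_variance_tie_reports_no_difference(self):
        res = dunnett_t3({"ctl": [5.0, 5.0, 5.0], "g": [5.0, 5.0, 5.0]}, "ctl")
        assert res.p_adj.iloc[0] == 1.0

    def test_single_unit_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2 units|fewer than 2"):
            res = dunnett_t3({"ctl": [1.0, 2.0, 3.0], "solo": [9.0]}, "ctl")
        assert len(res) == 0

    def test_obvious_difference_detected(self):
        res = dunnett_t3(
            {"ctl": [1.0, 1.1, 0.9, 1.0], "hi": [9.0, 9.2, 8.8, 9.1]}, "ctl"
        )
        assert res.p_adj.iloc[0] < 0.01 and res.estimate.iloc[0] == pytest.approx(8.05, abs=0.1)


class TestHierarchicalAnova:
    def _null_design(self, seed, heart_sd=5.0):
        return ExperimentDesign(
            treatments=[Treatment("sham", 20.0), Treatment("wt", 20.0)],
            hearts_per_group={"sham": 4, "wt": 3},
            cells_per_heart=30,
            heart_sd=heart_sd,
            cell_sd=5.0,
            seed=seed,
        )

    def test_duplicating_cells_within_hearts_changes_nothing(self):
        df = simulate.simulate_cell_values(self._null_design(0))
        doubled = pd.concat([df, df], ignore_index=True)
        a = hierarchical_anova(df, "value", "sham")
        b = hierarchical_anova(doubled, "value", "sham")
        assert a.comparisons.p_adj.iloc[0] == pytest.approx(b.comparisons.p_adj.iloc[0], abs=1e-12)
        assert a.anova_p == pytest.approx(b.anova_p, abs=1e-12)

    def test_power_increases_with_effect_size(self):
        # fixed design, growing uptake effect: rejection rate must rise monotonically
        rates = []
        for effect in (0.0, 5.0, 15.0):
            rej = 0
            for rep in range(60):
                design = ExperimentDesign(
                    treatments=[Treatment("sham", 20.0), Treatment("ev", 20.0 + effect)],
                    hearts_per_group=4,
                    cells_per_heart=20,
                    heart_sd=2.0,
                    cell_sd=5.0,
                    seed=10_000 + rep,
                )
                df = simulate.simulate_cell_values(design)
                res = hierarchical_anova(df, "value", "sham")
                rej += int(res.comparisons.p_adj.iloc[0] < 0.05)
            rates.append(rej / 60)
        assert rates[0] < rates[1] < rates[2]

    def test_missing_control_is_an_error(self):
        df = simulate.simulate_cell_values(self._null_design(1))
        with pytest.raises(ValueError):
            hierarchical_anova(df, "value", "nonexistent")

    def test_zero_variance_tie_is_p_one(self):
        rows = [
            {"treatment": t, "heart_id": f"{t}{h}", "value": 3.0}
            for t in ("sham", "ev")
            for h in range(3)
        ]
        res = hierarchical_anova(pd.DataFrame(rows), "value", "sham")
        assert res.anova_p == 1.0 and res.comparisons.p_adj.iloc[0] == 1.0


class TestBiodistribution:
    def _table(self, heart_fold=9.0, noise_cv=0.0, seed=0):
        return simulate.simulate_biodistribution(
            {"targeted": {"heart": heart_fold, "liver": 1.0, "lung": 1.5}},
            n_per_group=6,
            noise_cv=noise_cv,
            seed=seed,
        )

    def test_noise_free_heart_fold_recovered_exactly(self):
        _, folds, _ = normalize_biodistribution(self._table())
        heart = folds[(folds.group == "targeted") & (folds.organ == "heart")]
        assert heart.fold_vs_control.iloc[0] == pytest.approx(9.0, abs=1e-12)

    def test_control_folds_are_one(self):
        _, folds, _ = normalize_biodistribution(self._table())
        ctl = folds[folds.group == "control"]
        assert np.allclose(ctl.fold_vs_control, 1.0)

    def test_doubling_dose_halves_folds(self):
        tab = self._table()
        tab.loc[tab.group == "targeted", "dose"] *= 2.0
        _, folds, _ = normalize_biodistribution(tab)
        heart = folds[(folds.group == "targeted") & (folds.organ == "heart")]
        assert heart.fold_vs_control.iloc[0] == pytest.approx(4.5, abs=1e-12)

    def test_missing_control_organ_rows_error(self):
        tab = self._table()
        tab = tab[~((tab.group == "control") & (tab.organ == "heart"))]
        with pytest.raises(ValueError):
            normalize_biodistribution(tab)

    def test_nonpositive_dose_rejected(self):
        tab = self._table()
        tab.loc[0, "dose"] = 0.0
        with pytest.raises(ValueError):
            normalize_biodistribution(tab)
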