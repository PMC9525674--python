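"""ROI summaries, artifact exclusion, ANOVA/post-hoc and trend reports."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleodect.quantify import (
    ROIRole,
    ROISet,
    age_trend,
    anova_oneway,
    anova_posthoc,
    contrast_structures,
    exclude_artifact_rois,
    plant_cubic_rois,
    summarize_roi,
)


class TestSummarizeROI:
    def test_constant_roi(self):
        img = np.full((3, 3, 3), 5.0)
        s = summarize_roi(img, np.ones_like(img, dtype=bool))
        assert (s.mean, s.sd, s.median) == (5.0, 0.0, 5.0)
        assert (s.vmin, s.vmax) == (5.0, 5.0)

    def test_hand_computed_values(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        s = summarize_roi(img, np.ones_like(img, dtype=bool))
        assert s.mean == 2.5
        assert s.sd == pytest.approx(math.sqrt(5 / 3))  # sample SD of {1,2,3,4}
        assert s.median == 2.5
        assert (s.vmin, s.vmax) == (1.0, 4.0)

    def test_report_format_mirrors_printed_style(self):
        img = np.array([0.0, 0.0, 0.0, 14.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        s = summarize_roi(img, np.ones_like(img, dtype=bool))
        assert s.report() == "1 ± 4 HU; 0, 0–14 HU"

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_roi(np.ones((2, 2)), np.zeros((2, 2), dtype=bool))


class TestArtifactExclusion:
    def _rois(self, shape=(6, 6, 1)):
        labels = np.zeros(shape, dtype=int)
        labels[:3, :, 0] = 1
        labels[3:, :, 0] = 2
        roles = {
            1: ROIRole("bone", "s"),
            2: ROIRole("sediment", "s"),
        }
        return ROISet(labels=labels, roles=roles)

    def test_empty_mask_excludes_nothing(self):
        rois = self._rois()
        out = exclude_artifact_rois(rois, np.zeros(rois.labels.shape, bool))
        assert out.excluded == {}

    def test_fully_contaminated_roi_excluded(self):
        rois = self._rois()
        mask = rois.labels == 1
        out = exclude_artifact_rois(rois, mask, 0.05)
        assert 1 in out.excluded and 2 not in out.excluded
        assert out.active_codes == [2]

    def test_threshold_is_strict_with_count_oracle(self):
        """An ROI at exactly the threshold fraction is retained."""
        labels = np.zeros((20, 1, 1), dtype=int)
        labels[:20] = 1
        mask = np.zeros_like(labels, dtype=bool)
        mask[:5] = True  # 5/20 = 0.25 exactly
        # brute-force count oracle
        frac = sum(bool(m) for l, m in zip(labels.ravel(), mask.ravel()) if l == 1) / 20
        assert frac == 0.25
        rois = ROISet(labels=labels, roles={1: ROIRole("bone", "s")})
        assert exclude_artifact_rois(rois, mask, max_fraction=0.25).excluded == {}
        assert 1 in exclude_artifact_rois(rois, mask, max_fraction=0.2499).excluded


class TestANOVA:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        f, p = anova_oneway([g, g.copy()])
        assert (f, p) == (0.0, 1.0)

    def test_hugely_separated_groups(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(100.0, 1.0, 10)
        _, p = anova_oneway([a, b])
        assert p < 1e-6

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(i, 1.0, 8) for i in range(3)]
        f, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_two_groups_reproduce_pooled_t(self, rng):
        """With two groups the ANOVA F equals the pooled-variance t squared."""
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.7, 1.0, 9)
        f, p_f = anova_oneway([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t.statistic**2, abs=1e-10)
        assert p_f == pytest.approx(t.pvalue, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            anova_oneway([np.array([1.0]), np.array([2.0, 3.0])])


class TestPostHoc:
    def test_bonferroni_is_m_times_raw_capped(self, rng):
        groups = {k: rng.normal(i * 0.5, 1.0, 6) for i, k in enumerate("abcd")}
        comp = anova_posthoc(groups)
        m = len(comp.pairwise)
        assert m == 6
        for r in comp.pairwise.itertuples():
            assert r.p_bonferroni == pytest.approx(min(1.0, m * r.p_raw))
            assert r.p_bonferroni >= r.p_raw

    def test_tukey_no_more_conservative_than_bonferroni(self, rng):
        """In balanced designs Tukey HSD is at most as conservative as
        Bonferroni (checked empirically over random datasets)."""
        worse = 0
        for trial in range(30):
            groups = {k: rng.normal(0.0, 1.0, 6) for k in "abc"}
            comp = anova_posthoc(groups)
            worse += int(
                (comp.pairwise["p_tukey"] > comp.pairwise["p_bonferroni"] + 1e-9).any()
            )
        assert worse == 0

    def test_tukey_matches_statsmodels(self, rng):
        """Tukey HSD p values agree with statsmodels' independent
        implementation."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {k: rng.normal(i * 0.8, 1.0, 7) for i, k in enumerate("abc")}
        comp = anova_posthoc(groups)
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), 7)
        ref = pairwise_tukeyhsd(values, labels)
        assert comp.pairwise["p_tukey"].to_numpy() == pytest.approx(
            np.asarray(ref.pvalues, dtype=float), abs=1e-6
        )

    def test_identical_groups_give_unit_pvalues(self):
        g = np.array([2.0, 2.5, 3.0])
        comp = anova_posthoc({"a": g, "b": g.copy()})
        assert comp.p_value == 1.0
        assert (comp.pairwise["p_tukey"] == 1.0).all()
        assert not comp.significant


class TestContrasts:
    def _frame(self, bone_mu, sed_mu, rng, specimen="S", n=10, sd=1.0):
        rows = []
        for structure, mu in (("bone", bone_mu), ("sediment", sed_mu)):
            for v in rng.normal(mu, sd, n):
                rows.append({"specimen": specimen, "structure": structure, "value": v})
        return pd.DataFrame(rows)

    def test_separated_structures_significant(self, rng):
        df = self._frame(1800.0, 10.0, rng, sd=100.0)
        comp = contrast_structures(df)["S"]
        assert comp.significant
        assert (comp.pairwise["p_tukey"] < 0.05).all()

    def test_identical_structures_not_significant(self, rng):
        vals = rng.normal(100.0, 5.0, 10)
        rows = [
            {"specimen": "S", "structure": s, "value": v}
            for s in ("bone", "sediment")
            for v in vals
        ]
        comp = contrast_structures(pd.DataFrame(rows))["S"]
        assert not comp.significant

    def test_missing_structure_skipped_with_warning(self, rng, caplog):
        df = pd.DataFrame(
            [{"specimen": "S", "structure": "bone", "value": v} for v in range(5)]
        )
        with caplog.at_level("WARNING"):
            out = contrast_structures(df)
        assert out == {}
        assert "single structure" in caplog.text


class TestAgeTrend:
    def _frame(self, means, ages=None, habitat="terrestrial", n=3, sd=1e-6):
        ages = ages or list(range(len(means)))
        rows = []
        rng = np.random.default_rng(0)
        for i, (mu, age) in enumerate(zip(means, ages)):
            for v in rng.normal(mu, sd, n):
                rows.append(
                    {"specimen": f"sp{i}", "age_ma": age, "habitat": habitat, "value": v}
                )
        return pd.DataFrame(rows)

    def test_increasing_means_monotone(self):
        trend = age_trend(self._frame([0.0, 100.0, 2000.0, 3500.0]))
        assert trend.monotone and trend.violations == ()
        assert [s for s, _, _ in trend.order] == ["sp0", "sp1", "sp2", "sp3"]

    def test_shuffled_means_reports_violating_pair(self):
        trend = age_trend(self._frame([0.0, 2000.0, 100.0, 3500.0]))
        assert not trend.monotone
        assert ("sp1", "sp2") in trend.violations

    def test_marine_specimens_ignored(self):
        df = pd.concat(
            [
                self._frame([0.0, 1000.0]),
                self._frame([9000.0], ages=[50], habitat="marine"),
            ],
            ignore_index=True,
        )
        df.loc[df["habitat"] == "marine", "specimen"] = "marine0"
        trend = age_trend(df)
        assert all(s.startswith("sp") for s, _, _ in trend.order)


class TestPlantROIs:
    def test_rois_disjoint_and_inside_mask(self, rng):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[2:18, 2:18, 2:18] = True
        labels = plant_cubic_rois(mask, n_rois=10, size=3, rng=rng)
        for code in range(1, 11):
            roi = labels == code
            assert roi.sum() == 27
            assert mask[roi].all()

    def test_impossible_placement_raises(self, rng):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(RuntimeError, match="could not place"):
            plant_cubic_rois(mask, n_rois=2, size=3, rng=rng, max_tries=200)
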