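"""Trimming, normalization and composite Z-score arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micromorph import scoring as sc


def _manual_fences(values, m=1.7):
    """Independent quartile computation: linear interpolation between order
    statistics at positions (n-1)*q."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size

    def quantile(q):
        pos = (n - 1) * q
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return q1 - m * iqr, q3 + m * iqr


class TestTrimming:
    def test_worked_example(self):
        values = [10, 11, 12, 13, 14, 100]
        lo, hi = sc.TrimRule().fences(np.asarray(values, float))
        assert (lo, hi) == (7.0, 18.0)  # Q1=11.25, Q3=13.75, IQR=2.5
        kept, mask = sc.trim_outliers(values)
        assert list(kept) == [10, 11, 12, 13, 14]
        assert list(mask) == [True] * 5 + [False]

    def test_all_equal_keeps_everything(self):
        kept, mask = sc.trim_outliers([5.0] * 8)
        assert mask.all()

    def test_values_within_fences_identity(self):
        values = [1.0, 2.0, 3.0, 4.0]
        kept, mask = sc.trim_outliers(values)
        assert list(kept) == values

    def test_small_sample_skips_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            kept, mask = sc.trim_outliers([1.0, 2.0, 100.0])
        assert mask.all()

    def test_agrees_with_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            v = rng.normal(0, 1, n) * 10.0 ** int(rng.integers(-2, 3))
            if rng.random() < 0.3:
                v[0] *= 50  # force occasional gross outliers
            lo, hi = _manual_fences(v)
            _, mask = sc.trim_outliers(v)
            np.testing.assert_array_equal(mask, (v >= lo) & (v <= hi))

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=30))
    def test_trimming_idempotent(self, values):
        import warnings as _warnings

        kept, _ = sc.trim_outliers(values)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # second pass may drop below n=4
            kept2, mask2 = sc.trim_outliers(kept)
        # fences recomputed on kept data can only exclude further, never
        # resurrect; a second pass keeps a subset
        assert len(kept2) <= len(kept)

    def test_trimmer_estimator_interface(self):
        from sklearn.base import clone

        tr = sc.QuartileFenceTrimmer(multiplier=1.7)
        assert clone(tr).get_params()["multiplier"] == 1.7
        tr.fit([10, 11, 12, 13, 14, 100])
        assert (tr.lower_fence_, tr.upper_fence_) == (7.0, 18.0)
        np.testing.assert_array_equal(tr.predict([8, 100]), [1, -1])


class TestNormalization:
    @pytest.mark.parametrize(
        "value,mean,mode,expected",
        [(6.0, 3.0, "n_fold", 2.0), (6.0, 3.0, "delta", 3.0),
         (3.0, 3.0, "n_fold", 1.0), (3.0, 3.0, "delta", 0.0)],
    )
    def test_modes(self, value, mean, mode, expected):
        out, reason = sc.normalize_to_controls(value, mean, mode)
        assert out == expected and reason == "ok"

    def test_zero_control_mean_is_reason_coded(self):
        out, reason = sc.normalize_to_controls(6.0, 0.0, "n_fold")
        assert np.isnan(out) and reason == "zero_control_mean"


class TestZScores:
    def test_z_arithmetic(self):
        assert sc.z_test(10.0, 10.0, 2.0)[0] == 0.0
        assert sc.z_test(12.0, 10.0, 2.0)[0] == 1.0
        z, reason = sc.z_test(12.0, 10.0, 0.0)
        assert np.isnan(z) and reason == "zero_sigma"

    def test_cluster_mean_and_missing_handling(self):
        assert sc.cluster_z([1.0, -1.0]) == 0.0
        assert sc.cluster_z([0.5]) == 0.5
        assert sc.cluster_z([1.0, 2.0, 3.0]) == 2.0
        assert sc.cluster_z([1.0, np.nan, 3.0]) == 2.0  # non-missing members
        assert np.isnan(sc.cluster_z([np.nan, np.nan]))

    def test_cluster_order_invariance_and_linearity(self):
        vals = [0.3, -1.2, 2.5]
        assert sc.cluster_z(vals) == sc.cluster_z(vals[::-1])
        assert sc.cluster_z([3 * v for v in vals]) == pytest.approx(
            3 * sc.cluster_z(vals)
        )

    def test_combined_arithmetic(self):
        assert sc.combined_z(1.0, 0.5) == 0.75
        assert sc.combined_z(0.0, 0.0) == 0.0
        assert sc.combined_z(-2.0, 2.0) == 0.0
        assert np.isnan(sc.combined_z(np.nan, 1.0))
        assert np.isnan(sc.combined_z(1.0, np.nan))

    def test_reference_population_scores_to_standard_normal(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(3.0, 2.0, 5000)
        scorer = sc.ReferenceZScorer().fit(ref)
        z = scorer.transform(ref)
        assert np.mean(z) == pytest.approx(0.0, abs=0.05)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=0.05)

    def test_zero_sigma_reference_gives_nan(self):
        scorer = sc.ReferenceZScorer().fit([2.0, 2.0, 2.0])
        assert np.isnan(scorer.transform([2.0])).all()


class TestPanel:
    def _tables(self):
        rng = np.random.default_rng(0)
        rows = []
        for geno, shiftmap in (("CTRL", {"LPS+BzATP": 20.0}),
                               ("KO", {"LPS+BzATP": 6.0})):
            for i in range(6):
                for treatment in ("BzATP", "LPS+BzATP"):
                    for analyte in ("IL-1b", "IL-6", "TNFa", "IL-4", "IL-10"):
                        base = shiftmap.get(treatment, 1.0)
                        rows.append(
                            {"animal": f"{geno.lower()}{i}", "genotype": geno,
                             "treatment": treatment, "analyte": analyte,
                             "n_fold": base * rng.lognormal(0, 0.1)}
                        )
        cyto = pd.DataFrame(rows)
        rows = []
        for geno, rmean in (("CTRL", 1.10), ("KO", 1.04)):
            for i in range(6):
                for treatment in ("BzATP", "LPS+BzATP"):
                    r = rng.normal(rmean, 0.01)
                    for metric, val in (("roundness", r), ("aspect_ratio", 1 / r)):
                        rows.append(
                            {"animal": f"{geno.lower()}{i}", "genotype": geno,
                             "treatment": treatment, "metric": metric,
                             "n_fold": val}
                        )
        shape = pd.DataFrame(rows)
        return cyto, shape

    def test_panel_structure_and_combined_definition(self):
        cyto, shape = self._tables()
        panel = sc.build_zscore_panel(cyto, shape)
        assert len(panel) == 6 * 2  # KO animals x treatments
        row = panel.iloc[0]
        assert row["proif_z"] == pytest.approx(
            (row["pro_core_z"] + row["roundness_z"]) / 2
        )
        assert row["antiif_z"] == pytest.approx(
            (row["anti_core_z"] + row["aspect_ratio_z"]) / 2
        )

    def test_programmed_attenuation_yields_negative_proif(self):
        cyto, shape = self._tables()
        panel = sc.build_zscore_panel(cyto, shape)
        lps = panel[panel["treatment"] == "LPS+BzATP"]
        assert lps["proif_z"].mean() < 0

    def test_parametric_pipeline_attenuation_direction(self):
        from micromorph.pipeline import effect_directions, run_parametric_experiment

        res = run_parametric_experiment(seed=77, n_animals_per_genotype=6,
                                        cells_per_animal=200)
        assert effect_directions(res)["proif_z_attenuated_in_ko"]
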