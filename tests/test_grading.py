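import numpy as np
import pandas as pd
import pytest

from seedbed3d import (
    TextureParams,
    classify_grade,
    evaluate_against_reference,
    load_grade_references,
    r_squared,
    rep,
    rmse,
    split_calibration_validation,
)
from seedbed3d.errors import InputError, UndefinedStatisticError
from seedbed3d.grading import load_composition_table


@pytest.fixture(scope="module")
def references():
    return load_grade_references()


class TestGradeReferences:
    def test_ten_grades_with_valid_compositions(self, references):
        assert [r.grade for r in references] == list(range(1, 11))
        for r in references:
            assert r.composition.fractions.sum() == pytest.approx(1.0)

    def test_characteristic_roughness_increases_with_grade(self, references):
        sa = [r.sa_ref for r in references]
        sq = [r.sq_ref for r in references]
        assert all(a < b for a, b in zip(sa, sa[1:]))
        assert all(a < b for a, b in zip(sq, sq[1:]))


class TestClassifyGrade:
    def test_reference_rows_self_consistent(self, references):
        """Each grade's own characteristic (Sa, Sq) classifies as itself."""
        for r in references:
            params = TextureParams(sa=r.sa_ref, sq=r.sq_ref, ssk=0.0, sku=3.0)
            assert classify_grade(params, references) == r.grade

    def test_known_points(self, references):
        assert classify_grade(TextureParams(17.89, 27.13, 0.0, 3.0), references) == 6
        assert classify_grade(TextureParams(1.28, 1.46, 0.0, 3.0), references) == 1

    def test_midpoint_tie_goes_to_lower_grade(self, references):
        r1, r2 = references[0], references[1]
        mid = TextureParams(
            sa=(r1.sa_ref + r2.sa_ref) / 2, sq=(r1.sq_ref + r2.sq_ref) / 2,
            ssk=0.0, sku=3.0,
        )
        assert classify_grade(mid, references) == r1.grade

    def test_monotone_in_roughness(self, references):
        """Jointly increasing Sa and Sq never decreases the grade."""
        sa_grid = np.linspace(0.5, 60, 40)
        sq_grid = np.linspace(0.6, 80, 40)
        grades = [
            classify_grade(TextureParams(sa, sq, 0.0, 3.0), references)
            for sa, sq in zip(sa_grid, sq_grid)
        ]
        assert all(g2 >= g1 for g1, g2 in zip(grades, grades[1:]))

    def test_rejects_missing_parameters(self, references):
        with pytest.raises(InputError):
            classify_grade(TextureParams(float("nan"), 1.0, 0.0, 3.0), references)


class TestAgreementStatistics:
    def test_perfect_line_and_anticorrelation(self):
        assert r_squared([2, 4, 6], [1, 2, 3]) == pytest.approx(1.0)
        # perfect anti-correlation also squares to 1 (documented behavior)
        assert r_squared([3, 2, 1], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # r^2 = (4.7)^2 / (5.0 * 4.5) computed by hand beforehand
        assert r_squared([1.1, 1.9, 3.2, 3.8], [1, 2, 3, 4]) == pytest.approx(
            0.9817777777777778, rel=1e-12
        )

    def test_r2_definitions_coincide_on_fitted_line(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = 2 * x + 1
        assert r_squared(y, y, method="sse") == pytest.approx(1.0)
        assert r_squared(y, 2 * x + 1, method="pearson") == pytest.approx(1.0)

    def test_r2_undefined_for_constant_series(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared([1, 1, 1], [1, 2, 3])

    def test_rmse_examples(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([1, 2, 3], [1, 2, 2]) == pytest.approx(np.sqrt(1 / 3))
        # shift invariance
        assert rmse([11, 12, 13], [11, 12, 12]) == pytest.approx(np.sqrt(1 / 3))

    def test_rmse_length_mismatch(self):
        with pytest.raises(InputError):
            rmse([1, 2], [1, 2, 3])

    def test_rep_examples(self):
        assert rep([1, 2, 3], [1, 2, 3]) == 0.0
        assert rep([1, 2, 3], [1, 2, 2]) == pytest.approx(100 * np.sqrt(1 / 3) / (5 / 3))
        # scale invariance
        assert rep([10, 20, 30], [10, 20, 20]) == pytest.approx(
            rep([1, 2, 3], [1, 2, 2])
        )

    def test_rep_undefined_for_zero_mean_reference(self):
        with pytest.raises(UndefinedStatisticError):
            rep([1, -1, 0], [1, -1, 0])


def simulated_plots(n_per_grade=30, noise=0.0, bias=0.0, seed=0):
    rng = np.random.default_rng(seed)
    tex = load_composition_table()["grade"]
    rows = []
    for grade in range(1, 11):
        for k in range(n_per_grade):
            sa = 2.0 + 5.0 * grade + rng.normal(0, 0.5)
            rows.append(
                {
                    "plot_id": f"g{grade}_{k}",
                    "grade": grade,
                    "Sa_mm": sa + rng.normal(0, noise) + bias,
                    "Sq_mm": 1.3 * sa + rng.normal(0, noise) + bias,
                }
            )
    return pd.DataFrame(rows)


class TestSplit:
    def test_300_records_split_150_150(self):
        df = simulated_plots(30)
        cal, val = split_calibration_validation(df, fraction=0.5, seed=3)
        assert len(cal) == 150 and len(val) == 150

    def test_partition_and_determinism(self):
        df = simulated_plots(6)
        c1, v1 = split_calibration_validation(df, seed=5)
        c2, v2 = split_calibration_validation(df, seed=5)
        assert list(c1.index) == list(c2.index)
        assert set(c1.index) | set(v1.index) == set(df.index)
        assert set(c1.index).isdisjoint(v1.index)
        c3, _ = split_calibration_validation(df, seed=6)
        assert list(c3.index) != list(c1.index)

    def test_stratified_by_grade(self):
        df = simulated_plots(6)
        cal, _ = split_calibration_validation(df, fraction=0.5, seed=1)
        assert (cal.groupby("grade").size() == 3).all()


class TestEvaluateAgainstReference:
    def test_identical_series_scores_perfectly(self):
        sensor = simulated_plots(10, seed=1)
        manual = sensor.copy()
        report = evaluate_against_reference(sensor, manual, seed=1)
        assert len(report) == 12  # 2 parameters x 3 grade groups x 2 datasets
        assert np.allclose(report["RMSE"], 0.0)
        assert np.allclose(report["REP_percent"], 0.0)
        assert np.allclose(report["R2"], 1.0)

    def test_constant_bias_gives_rmse_bias_r2_one(self):
        sensor = simulated_plots(10, seed=2)
        manual = sensor.copy()
        sensor = sensor.assign(Sa_mm=sensor.Sa_mm + 2.5, Sq_mm=sensor.Sq_mm + 2.5)
        report = evaluate_against_reference(sensor, manual, seed=2)
        assert np.allclose(report["RMSE"], 2.5)
        assert np.allclose(report["R2"], 1.0)  # R^2 is blind to bias

    def test_noise_level_recovered_as_rmse(self):
        manual = simulated_plots(50, seed=3)
        noisy = simulated_plots(50, noise=1.0, seed=3)
        report = evaluate_against_reference(noisy, manual, seed=3)
        assert report["RMSE"].mean() == pytest.approx(1.0, rel=0.15)

    def test_permutation_invariance(self):
        sensor = simulated_plots(8, noise=0.5, seed=4)
        manual = simulated_plots(8, seed=4)
        r1 = evaluate_against_reference(sensor, manual, seed=9)
        shuffled = sensor.sample(frac=1.0, random_state=7).reset_index(drop=True)
        r2 = evaluate_against_reference(shuffled, manual, seed=9)
        cols = ["parameter", "grade_group", "dataset"]
        m1 = r1.set_index(cols).sort_index()
        m2 = r2.set_index(cols).sort_index()
        pd.testing.assert_frame_equal(m1, m2)

    def test_unmatched_ids_listed(self):
        sensor = simulated_plots(4, seed=5)
        manual = simulated_plots(4, seed=5).iloc[:-1]
        with pytest.raises(InputError, match="g10_3"):
            evaluate_against_reference(sensor, manual)
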