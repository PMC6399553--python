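"""Windowing, the six feature families and feature-matrix assembly."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_grid, toy_entry
from ssipre.features import (
    BLM_KINDS,
    FLM_KINDS,
    WindowSpec,
    abnormal_features,
    build_feature_matrix,
    feature_test,
    window_counts,
    window_mean,
    window_slope,
)
from ssipre.preprocess import DailyGrid, aggregate_daily, impute_locf
from ssipre.synth import PatientRecord


def full_grid(values_by_patient: dict[str, list[float]], obs_days: int) -> DailyGrid:
    """Fully observed single-test grid; lists run oldest -> newest."""
    pids = sorted(values_by_patient)
    vals = np.array([values_by_patient[p] for p in pids])[:, None, :]
    mask = np.ones_like(vals, dtype=bool)
    return DailyGrid(pids, ["T"], obs_days, vals.astype(float), mask)


class TestWindowSpec:
    def test_default_windows_partition_interval(self):
        ws = WindowSpec.for_interval(60)
        wins = ws.windows("CRP")
        assert wins == [("S", 2, 0), ("M", 15, 3), ("L", 60, 16)]
        covered = sorted(d for _, hi, lo in wins for d in range(lo, hi + 1))
        assert covered == list(range(61))

    def test_fifteen_day_interval_single_window(self):
        ws = WindowSpec.for_interval(15)
        assert ws.windows("CRP") == [("W", 15, 0)]

    def test_per_test_override(self):
        ws = WindowSpec(obs_days=60, per_test={"CRP": (1, 13)})
        assert ws.windows("CRP")[0] == ("S", 1, 0)
        assert ws.windows("Albumin")[0] == ("S", 2, 0)

    def test_boundary_validation(self):
        with pytest.raises(ValueError):
            WindowSpec(obs_days=60, s_hi=3)
        with pytest.raises(ValueError):
            WindowSpec(obs_days=60, m_hi=19)


class TestWindowMean:
    def test_constant_series(self):
        grid = full_grid({"P1": [3.0] * 6}, obs_days=5)
        assert window_mean(grid, "T", (4, 1))[0] == 3.0

    def test_arithmetic(self):
        grid = full_grid({"P1": [9.0, 9.0, 9.0, 1.0, 2.0, 3.0]}, obs_days=5)
        assert window_mean(grid, "T", (2, 0))[0] == 2.0

    def test_matches_bruteforce_on_random_grids(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(4, 11))
        grid = full_grid({f"P{i}": list(vals[i]) for i in range(4)}, obs_days=10)
        for hi, lo in [(10, 0), (7, 3), (2, 2)]:
            expected = [
                np.mean([vals[i][10 - d] for d in range(lo, hi + 1)]) for i in range(4)
            ]
            got = window_mean(grid, "T", (hi, lo))
            # patients sorted P0..P3, same order as vals rows
            assert np.allclose(got, expected)


def bruteforce_slope(points: list[tuple[float, float]]) -> float:
    """OLS slope by scanning a fine slope grid around the data (SSE argmin)."""
    ts = np.array([t for t, _ in points])
    ys = np.array([y for _, y in points])
    cands = np.linspace(-10, 10, 200001)
    # for each slope the optimal intercept is mean(y - b t)
    sse = [np.sum((ys - (b * ts + np.mean(ys - b * ts))) ** 2) for b in cands]
    return float(cands[int(np.argmin(sse))])


class TestWindowSlope:
    def test_flat_series_zero(self):
        grid = full_grid({"P1": [4.0] * 6}, obs_days=5)
        assert window_slope(grid, "T", (5, 0))[0] == 0.0

    def test_two_point_line(self):
        # day 1 -> day 0, value rises by 2 over 1 day toward surgery
        grid = full_grid({"P1": [0.0, 1.0, 3.0]}, obs_days=2)
        assert window_slope(grid, "T", (1, 0))[0] == pytest.approx(2.0)

    def test_three_point_example_matches_bruteforce(self):
        # (t, y) = (0, 0), (1, 1), (2, 3) with t increasing toward surgery
        grid = full_grid({"P1": [0.0, 1.0, 3.0]}, obs_days=2)
        got = window_slope(grid, "T", (2, 0))[0]
        assert got == pytest.approx(1.5)
        assert got == pytest.approx(bruteforce_slope([(0, 0), (1, 1), (2, 3)]), abs=1e-3)

    def test_single_day_window_zero(self):
        grid = full_grid({"P1": [5.0, 6.0, 7.0]}, obs_days=2)
        assert window_slope(grid, "T", (1, 1))[0] == 0.0

    def test_rising_toward_surgery_positive(self):
        grid = full_grid({"P1": [1.0, 2.0, 3.0, 4.0]}, obs_days=3)
        assert window_slope(grid, "T", (3, 0))[0] > 0


class TestWindowCounts:
    def test_definition(self):
        grid = make_grid(
            {("P1", "T"): {0: 1.0, 1: 1.0, 2: 1.0, 10: 1.0, 11: 1.0, 12: 1.0}}, obs_days=20
        )
        nmbr, prop = window_counts(grid, "T", (2, 0))
        assert nmbr[0] == 3 and prop[0] == 0.5

    def test_zero_total(self):
        grid = make_grid({("P1", "T"): {}}, obs_days=5, patient_ids=["P1"], test_names=["T"])
        nmbr, prop = window_counts(grid, "T", (5, 0))
        assert nmbr[0] == 0 and prop[0] == 0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**20 - 1))
    def test_window_proportions_conserved(self, bits):
        """S+M+L proportions sum to 1 whenever any observation exists."""
        mask_bits = [(bits >> i) & 1 for i in range(21)]
        series = {("P1", "T"): {d: 1.0 for d in range(21) if mask_bits[d]}}
        grid = make_grid(series, obs_days=20, patient_ids=["P1"], test_names=["T"])
        ws = WindowSpec(obs_days=20)
        props = [window_counts(grid, "T", (hi, lo))[1][0] for _, hi, lo in ws.windows("T")]
        nmbrs = [window_counts(grid, "T", (hi, lo))[0][0] for _, hi, lo in ws.windows("T")]
        total = sum(mask_bits)
        assert sum(nmbrs) == total
        assert sum(props) == pytest.approx(1.0 if total else 0.0)


class TestAbnormalFeatures:
    def test_definition_arithmetic(self):
        entry = toy_entry(lo=4.0, hi=10.0)
        grid = make_grid({("P1", "T"): {3: 3.0, 2: 5.0, 1: 12.0, 0: 12.0}}, obs_days=5)
        nmbr, high, low, abn = abnormal_features(grid, entry, (5, 0))
        assert (nmbr[0], high[0], low[0], abn[0]) == (3, 0.5, 0.25, 0.75)

    def test_empty_window_zeros(self):
        entry = toy_entry()
        grid = make_grid({("P1", "T"): {5: 3.0}}, obs_days=5)
        nmbr, high, low, abn = abnormal_features(grid, entry, (2, 0))
        assert (nmbr[0], high[0], low[0], abn[0]) == (0, 0, 0, 0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_high_plus_low_equals_abn(self, seed):
        rng = np.random.default_rng(seed)
        entry = toy_entry(lo=-0.5, hi=0.5)
        days = rng.choice(11, size=rng.integers(1, 11), replace=False)
        series = {("P1", "T"): {int(d): float(rng.normal()) for d in days}}
        grid = make_grid(series, obs_days=10, patient_ids=["P1"], test_names=["T"])
        _, high, low, abn = abnormal_features(grid, entry, (10, 0))
        assert high[0] + low[0] == pytest.approx(abn[0])
        assert 0 <= abn[0] <= 1


@pytest.fixture(scope="module")
def built(catalog, small_cohort):
    _, patients, labs = small_cohort
    raw = aggregate_daily(labs, 60, [p.patient_id for p in patients],
                          [e.test_name for e in catalog])
    imputed = impute_locf(raw, catalog)
    return raw, imputed, patients


class TestBuildFeatureMatrix:
    def test_flm_has_252_test_features(self, built, catalog):
        raw, imputed, patients = built
        X = build_feature_matrix(imputed, raw, WindowSpec.for_interval(60), catalog,
                                 patients, "FLM")
        assert X.shape[1] == 252 + 2
        assert X.attrs["feature_set"] == "FLM"

    def test_blm_has_128_columns(self, built, catalog):
        raw, imputed, patients = built
        X = build_feature_matrix(imputed, raw, WindowSpec.for_interval(60), catalog,
                                 patients, "BLM")
        assert X.shape[1] == 128

    def test_crp_baseline_columns(self, built, catalog):
        raw, imputed, patients = built
        X = build_feature_matrix(imputed, raw, WindowSpec.for_interval(60), catalog,
                                 patients, "CRP")
        assert list(X.columns) == ["CRP_mean_S", "CRP_mean_M", "CRP_mean_L", "age", "sex"]

    def test_fifteen_day_flm_has_84_test_features(self, catalog, small_cohort):
        _, patients, labs = small_cohort
        raw = aggregate_daily(labs, 15, [p.patient_id for p in patients],
                              [e.test_name for e in catalog])
        imputed = impute_locf(raw, catalog)
        X = build_feature_matrix(imputed, raw, WindowSpec.for_interval(15), catalog,
                                 patients, "FLM")
        assert X.shape[1] == 84 + 2

    def test_table_style_names_present(self, built, catalog):
        raw, imputed, patients = built
        X = build_feature_matrix(imputed, raw, WindowSpec.for_interval(60), catalog,
                                 patients, "FLM")
        for name in ["Leukocytes_nmbr_test_M", "CRP_mean_M", "Hemoglobin_prop_nmbr_test_S",
                     "ALP_high_abn_prop_M", "Albumin_slope_L"]:
            assert name in X.columns

    def test_no_missing_entries_and_proportions_bounded(self, built, catalog):
        raw, imputed, patients = built
        X = build_feature_matrix(imputed, raw, WindowSpec.for_interval(60), catalog,
                                 patients, "FLM")
        assert X.notna().all().all()
        prop_cols = [c for c in X.columns if "prop" in c]
        assert ((X[prop_cols] >= 0) & (X[prop_cols] <= 1)).all().all()

    def test_unknown_feature_set_rejected(self, built, catalog):
        raw, imputed, patients = built
        with pytest.raises(ValueError, match="feature_set"):
            build_feature_matrix(imputed, raw, WindowSpec.for_interval(60), catalog,
                                 patients, "XLM")

    def test_kind_sets(self):
        assert len(FLM_KINDS) == 6 and len(BLM_KINDS) == 3


def test_feature_test_mapping(catalog):
    assert feature_test("Bilirubin.total_mean_M", catalog) == "Bilirubin.total"
    assert feature_test("age", catalog) is None
    with pytest.raises(KeyError):
        feature_test("Nonsense_mean_S", catalog)
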