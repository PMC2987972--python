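import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comoscreen.errors import DataError
from comoscreen.screen import (ComorbidityScreen, ScreenConfig, apply_filters,
                               odds_ratio, period_prevalence, rank_order,
                               relative_risk, round_half_up,
                               rr_confidence_interval, top_k_report)


def members_df(n_case, n_control):
    return pd.DataFrame({
        "person_id": [f"c{i}" for i in range(n_case)] +
                     [f"k{i}" for i in range(n_control)],
        "arm": ["case"] * n_case + ["control"] * n_control,
    })


def claims_df(rows):
    df = pd.DataFrame(rows, columns=["person_id", "service_date", "icd9"])
    df["service_date"] = pd.to_datetime(df["service_date"])
    df["claim_kind"] = "encounter"
    return df


def table(n_case, N_case, n_control, N_control):
    df = pd.DataFrame({"icd9": ["x"], "n_case": [n_case], "N_case": [N_case],
                       "n_control": [n_control], "N_control": [N_control]})
    df["p_case"] = df["n_case"] / df["N_case"]
    df["p_control"] = df["n_control"] / df["N_control"]
    return df


# --- period prevalence -----------------------------------------------------

def test_person_counted_once_per_code():
    claims = claims_df([("c0", "2006-08-01", "4019"),
                        ("c0", "2006-09-01", "4019"),
                        ("c0", "2007-01-01", "4019")])
    prev = period_prevalence(claims, members_df(2, 2))
    assert prev.set_index("icd9").loc["4019", "n_case"] == 1


def test_window_is_closed_on_both_ends():
    claims = claims_df([("c0", "2006-06-30", "1110"),   # day before window
                        ("c0", "2006-07-01", "2220"),
                        ("c0", "2007-06-30", "3330"),
                        ("c0", "2007-07-01", "4440")])  # day after window
    prev = period_prevalence(claims, members_df(1, 1))
    assert set(prev["icd9"]) == {"2220", "3330"}


def test_duplicating_claims_leaves_prevalence_unchanged():
    claims = claims_df([("c0", "2006-08-01", "4019"),
                        ("k0", "2006-09-01", "4019"),
                        ("k1", "2007-02-01", "2449")])
    base = period_prevalence(claims, members_df(2, 3))
    doubled = period_prevalence(pd.concat([claims, claims], ignore_index=True),
                                members_df(2, 3))
    pd.testing.assert_frame_equal(base, doubled)


def test_all_claim_kinds_count_toward_prevalence():
    claims = claims_df([("c0", "2006-08-01", "4019")])
    claims["claim_kind"] = "lab"
    prev = period_prevalence(claims, members_df(1, 1))
    assert prev.set_index("icd9").loc["4019", "n_case"] == 1


def test_empty_cohort_rejected():
    with pytest.raises(DataError):
        period_prevalence(claims_df([]), members_df(0, 0))


def test_printed_prevalence_percent_examples():
    # percent cells reproduce from their printed count and denominator
    assert round_half_up(100 * 12773 / 62681, 1) == 20.4
    assert round_half_up(100 * 1540 / 61591, 1) == 2.5


# --- relative risk and intervals -------------------------------------------

@pytest.mark.parametrize("args,expected", [
    ((20, 100, 10, 100), 2.0),
    ((15, 200, 15, 200), 1.0),
    ((40, 61591, 10, 61591), 4.0),
])
def test_relative_risk_closed_form(args, expected):
    assert relative_risk(table(*args)).iloc[0] == pytest.approx(expected)


def test_equal_arm_denominators_cancel():
    df = table(37, 5000, 21, 5000)
    assert relative_risk(df).iloc[0] == 37 / 21


def test_rr_undefined_when_no_affected_controls():
    assert np.isnan(relative_risk(table(5, 100, 0, 100)).iloc[0])


def test_ci_contains_one_for_equal_counts():
    low, high = rr_confidence_interval(table(25, 1000, 25, 1000))
    assert low.iloc[0] < 1.0 < high.iloc[0]


def test_ci_flagged_on_zero_cell():
    low, high = rr_confidence_interval(table(0, 100, 5, 100))
    assert np.isnan(low.iloc[0]) and np.isnan(high.iloc[0])


def test_katz_interval_matches_parametric_bootstrap():
    """Katz log-method endpoints vs a 100,000-draw binomial parametric
    bootstrap percentile interval, within 10% of the interval width.

    The comparison is on the log scale — the scale on which a ratio interval
    is symmetric and the Katz method operates.
    """
    n1, N1, n0, N0 = 30, 1000, 15, 1000
    low, high = rr_confidence_interval(table(n1, N1, n0, N0))
    low, high = low.iloc[0], high.iloc[0]
    rng = np.random.default_rng(20060701)
    d1 = rng.binomial(N1, n1 / N1, 100000)
    d0 = rng.binomial(N0, n0 / N0, 100000)
    keep = d0 > 0
    rr_star = (d1[keep] / N1) / (d0[keep] / N0)
    b_low, b_high = np.percentile(rr_star, [2.5, 97.5])
    log_width = np.log(high) - np.log(low)
    assert abs(np.log(low) - np.log(b_low)) < 0.1 * log_width
    assert abs(np.log(high) - np.log(b_high)) < 0.1 * log_width


def test_odds_ratio_closed_form():
    res = odds_ratio(table(20, 100, 10, 100))
    assert res["odds_ratio"].iloc[0] == pytest.approx(2.25)


def test_odds_ratio_symmetric_table_is_one():
    res = odds_ratio(table(30, 60, 30, 60))
    assert res["odds_ratio"].iloc[0] == pytest.approx(1.0)
    assert res["or_ci_low"].iloc[0] < 1.0 < res["or_ci_high"].iloc[0]


def test_odds_ratio_zero_cell_flagged_no_correction():
    res = odds_ratio(table(0, 100, 10, 100))
    assert res.isna().all(axis=None)


@given(st.integers(1, 99), st.integers(1, 99), st.integers(100, 500),
       st.integers(100, 500))
@settings(max_examples=100)
def test_or_farther_from_one_than_rr(n1, n0, N1, N0):
    df = table(n1, N1, n0, N0)
    rr = relative_risk(df).iloc[0]
    or_ = odds_ratio(df)["odds_ratio"].iloc[0]
    if not np.isclose(rr, 1.0):
        assert abs(np.log(or_)) > abs(np.log(rr))


# --- filters and ranking ---------------------------------------------------

def ten_row_fixture():
    rows = [
        ("4019", 100, 90), ("2449", 80, 40), ("5163", 30, 25),
        ("7200", 50, 50),   # dorsopathy: excluded
        ("7100", 40, 30),   # arthropathy: excluded
        ("99640", 20, 20),  # orthopedic device complication: excluded
        ("2550", 10, 19),   # rare in controls
        ("2841", 5, 2),     # rare in controls
        ("2859", 60, 20),   # boundary: exactly 20 controls, kept
        ("515", 33, 21),
    ]
    df = pd.DataFrame(rows, columns=["icd9", "n_case", "n_control"])
    df["N_case"] = df["N_control"] = 1000
    df["p_case"] = df["n_case"] / 1000
    df["p_control"] = df["n_control"] / 1000
    df["rr"] = relative_risk(df)
    return df


def test_filter_fixture_keeps_exactly_five():
    kept, dropped = apply_filters(ten_row_fixture())
    assert set(kept["icd9"]) == {"4019", "2449", "5163", "2859", "515"}
    assert dropped == {"excluded_code": 3, "rare_in_controls": 2}


def test_control_count_boundary():
    df = ten_row_fixture()
    kept, _ = apply_filters(df)
    assert "2859" in set(kept["icd9"])   # n_control = 20 kept
    assert "2550" not in set(kept["icd9"])  # n_control = 19 dropped


def test_filters_commute():
    df = ten_row_fixture()
    cfg = ScreenConfig()
    only_rare = df[df["n_control"] >= cfg.min_control_count]
    excl_then_rare, _ = apply_filters(only_rare, cfg)
    rare_then_excl = only_rare[~only_rare["icd9"].map(cfg.exclude)]
    assert (set(excl_then_rare["icd9"])
            == set(rare_then_excl["icd9"])
            == set(apply_filters(df, cfg)[0]["icd9"]))


def test_rank_order_matches_independent_sort():
    rng = np.random.default_rng(11)
    df = pd.DataFrame({
        "icd9": [f"{200 + i}" for i in range(100)],
        "n_case": rng.integers(20, 200, 100),
        "rr": rng.choice([0.5, 1.0, 2.0, 2.5, 3.0], 100),
    })
    expected = [r.icd9 for r in sorted(
        df.itertuples(), key=lambda r: (-r.rr, -r.n_case, r.icd9))]
    ranked = rank_order(df)
    assert ranked["icd9"].tolist() == expected
    assert ranked["rank"].tolist() == list(range(1, 101))


def test_rank_tie_broken_by_larger_case_count():
    df = pd.DataFrame({"icd9": ["1110", "2220"], "n_case": [40, 50],
                       "rr": [2.0, 2.0]})
    assert rank_order(df)["icd9"].tolist() == ["2220", "1110"]


def test_already_sorted_input_unchanged():
    df = pd.DataFrame({"icd9": ["1110", "2220", "3330"],
                       "n_case": [5, 4, 3], "rr": [3.0, 2.0, 1.0]})
    assert rank_order(df)["icd9"].tolist() == ["1110", "2220", "3330"]


# --- report formatting -----------------------------------------------------

def test_report_rounding_conventions():
    df = pd.DataFrame({
        "icd9": ["6960"], "n_case": [1540], "p_case": [1540 / 61591],
        "rr": [12.2951], "ci_low": [10.52], "ci_high": [15.06], "rank": [1],
    })
    rep = top_k_report(df, k=30)
    assert rep["pct"].iloc[0] == "2.5%"
    assert rep["rr"].iloc[0] == "12.3"
    assert rep["ci_95"].iloc[0] == "10.5-15.1"
    assert rep["description"].iloc[0] == "Psoriatic arthropathy"


def test_half_up_rounding():
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(12.25, 1) == 12.3
    assert round_half_up(2.04999, 1) == 2.0


def test_report_empty_input_has_header_only():
    rep = top_k_report(pd.DataFrame(columns=["icd9", "n_case", "p_case", "rr",
                                             "ci_low", "ci_high", "rank"]))
    assert len(rep) == 0
    assert list(rep.columns) == ["rank", "icd9", "description", "n_case",
                                 "pct", "rr", "ci_95"]


def test_report_k_larger_than_rows_returns_all():
    df = pd.DataFrame({"icd9": ["1110"], "n_case": [30], "p_case": [0.03],
                       "rr": [2.0], "ci_low": [1.5], "ci_high": [2.7],
                       "rank": [1]})
    assert len(top_k_report(df, k=30)) == 1


# --- model object ----------------------------------------------------------

def test_screen_model_end_to_end():
    claims = claims_df(
        [(f"c{i}", "2006-08-01", "4019") for i in range(40)] +
        [(f"k{i}", "2006-08-01", "4019") for i in range(20)] +
        [(f"c{i}", "2006-09-01", "7200") for i in range(30)] +
        [(f"k{i}", "2007-01-01", "2449") for i in range(25)] +
        [(f"c{i}", "2007-01-01", "2449") for i in range(25)])
    res = ComorbidityScreen(claims, members_df(100, 100)).fit()
    assert res.n_codes_recorded == 3
    assert set(res.table["icd9"]) == {"4019", "2449"}  # 7200 excluded
    row = res.table.set_index("icd9").loc["4019"]
    assert row["rr"] == pytest.approx(2.0)
    assert "Comorbidity screen" in res.summary()
    assert res.table["rank"].tolist() == [1, 2]


def test_screen_results_csv_round_trip(tmp_path):
    claims = claims_df(
        [(f"c{i}", "2006-08-01", "4019") for i in range(40)] +
        [(f"k{i}", "2006-08-01", "4019") for i in range(20)])
    res = ComorbidityScreen(claims, members_df(50, 50)).fit()
    path = tmp_path / "ranked.csv"
    res.to_csv(path)
    back = pd.read_csv(path, dtype={"icd9": str})
    assert back["icd9"].tolist() == ["4019"]
    assert back["rr"].iloc[0] == pytest.approx(2.0)
    assert back["pct_case"].iloc[0] == 80.0
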