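"""Turbidity screening, light integration and interval summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seditherm import waterquality as wq


# -- despiking ----------------------------------------------------------


def _despike_oracle(vals):
    """Literal restatement of the screening rule, applied independently."""
    keep = []
    for i, v in enumerate(vals):
        if np.isnan(v):
            continue
        if v < 0:
            continue
        if 0 < i < len(vals) - 1:
            mean_n = (vals[i - 1] + vals[i + 1]) / 2
            if not np.isnan(mean_n) and v > 3 and v > 2.5 * mean_n:
                continue
        keep.append(v)
    return keep


def test_despike_spike_removed():
    s, _ = wq.despike_turbidity(pd.Series([1.0, 10.0, 1.0]))
    assert s.tolist() == [1.0, 1.0]


def test_despike_below_ratio_kept():
    s, _ = wq.despike_turbidity(pd.Series([1.0, 4.0, 3.0]))
    assert s.tolist() == [1.0, 4.0, 3.0]


def test_despike_hand_trace():
    s, mask = wq.despike_turbidity(pd.Series([-0.2, 2.0, 2.5, 50.0, 2.0, -1.0]))
    assert s.tolist() == [2.0, 2.5, 2.0]
    assert mask.tolist() == ["negative", "kept", "kept", "spike", "kept", "negative"]


def test_despike_all_missing_warns():
    with pytest.warns(UserWarning):
        s, _ = wq.despike_turbidity(pd.Series([np.nan, np.nan]))
    assert s.empty


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-5, max_value=100, allow_nan=False, allow_infinity=False),
        min_size=3,
        max_size=30,
    )
)
def test_despike_matches_predicate_oracle(vals):
    """Removal is exactly the stated predicate, order preserved, single pass."""
    s, _ = wq.despike_turbidity(pd.Series(vals))
    assert s.tolist() == pytest.approx(_despike_oracle(np.asarray(vals)))


# -- daily light integral ------------------------------------------------


def _par_series(values):
    idx = pd.date_range("2011-01-01", periods=len(values), freq="10min")
    return pd.Series(values, index=idx)


def test_dli_constant_par():
    s = _par_series([100.0] * 144)
    assert wq.daily_light_integral(s).iloc[0] == pytest.approx(8.64)


def test_dli_zero_par():
    s = _par_series([0.0] * 144)
    assert wq.daily_light_integral(s).iloc[0] == 0.0


def test_dli_half_sinusoid_closed_form():
    """12-h half-sine day: DLI = (2/pi) * P_max * 43200e-6, within 0.5%."""
    idx = pd.date_range("2011-01-01", periods=144, freq="10min")
    h = idx.hour + idx.minute / 60
    pmax = 800.0
    par = np.where((h >= 6) & (h <= 18), pmax * np.sin(np.pi * (h - 6) / 12), 0.0)
    dli = wq.daily_light_integral(pd.Series(par, index=idx)).iloc[0]
    expect = (2 / np.pi) * pmax * 43200e-6
    assert dli == pytest.approx(expect, rel=0.005)


def test_dli_linearity(rng):
    idx = pd.date_range("2011-01-01", periods=144, freq="10min")
    par = pd.Series(rng.uniform(0, 500, 144), index=idx)
    d1 = wq.daily_light_integral(par).iloc[0]
    d3 = wq.daily_light_integral(3.0 * par).iloc[0]
    assert d3 == pytest.approx(3.0 * d1, rel=1e-12)
    assert d1 >= 0


def test_dli_negative_par_rejected():
    with pytest.raises(ValueError):
        wq.daily_light_integral(_par_series([-1.0] * 144))


def test_dli_incomplete_day_flagged():
    s = _par_series([100.0] * 100)  # 100/144 < 80%
    assert np.isnan(wq.daily_light_integral(s).iloc[0])


# -- running mean --------------------------------------------------------


def test_running_mean_constant():
    s = pd.Series(np.full(30, 2.5))
    assert (wq.running_mean(s, 14).dropna() == 2.5).all()


def test_running_mean_single_jump():
    s = pd.Series([0.0] * 13 + [14.0])
    assert wq.running_mean(s, 14).iloc[-1] == pytest.approx(1.0)


def test_running_mean_brute_force(rng):
    vals = pd.Series(rng.normal(size=60))
    rm = wq.running_mean(vals, 14)
    for i in range(13, 60):
        assert rm.iloc[i] == pytest.approx(vals.iloc[i - 13 : i + 1].mean(), abs=1e-12)


def test_running_mean_window_longer_than_series_warns():
    with pytest.warns(UserWarning):
        out = wq.running_mean(pd.Series([1.0, 2.0]), 14)
    assert out.isna().all()


def test_running_mean_bad_window():
    with pytest.raises(ValueError):
        wq.running_mean(pd.Series([1.0]), 0)


# -- interval summaries --------------------------------------------------


def _daily_frame(n_days, rng):
    idx = pd.date_range("2011-01-01", periods=n_days, freq="D")
    df = pd.DataFrame(
        {
            "temp_mean_c": rng.uniform(24, 31, n_days),
            "temp_max_c": rng.uniform(25, 33, n_days),
            "ntu_mean": rng.uniform(0, 20, n_days),
            "sed_max": rng.uniform(0, 1, n_days),
            "dli": rng.uniform(0, 10, n_days),
        },
        index=idx,
    )
    df["dli_14d"] = wq.running_mean(df["dli"], 14)
    return df


def test_interval_summary_brute_force(rng):
    daily = _daily_frame(45, rng)
    dates = [daily.index[0], daily.index[14], daily.index[28], daily.index[44]]
    out = wq.interval_pressure_summary(daily, dates, site_id="s")
    assert len(out) == 3
    for i in range(3):
        sel = daily[(daily.index > dates[i]) & (daily.index <= dates[i + 1])]
        row = out.iloc[i]
        assert row.light_worst == pytest.approx(sel["dli_14d"].min())
        assert row.sed_worst == pytest.approx(sel["sed_max"].max())
        assert row.temp_worst == pytest.approx(sel["temp_mean_c"].max())
        assert row.ssc_proxy == pytest.approx(sel["ntu_mean"].mean())
        assert row.light_worst <= row.light_dli_14d + 1e-12


def test_interval_summary_permutation_invariant(rng):
    """Min/max/mean summaries ignore within-interval ordering."""
    daily = _daily_frame(30, rng)
    dates = [daily.index[0], daily.index[29]]
    base = wq.interval_pressure_summary(daily, dates)
    shuffled = daily.copy()
    perm = rng.permutation(29) + 1  # permute interior days' values, keep index
    cols = ["temp_mean_c", "ntu_mean", "sed_max", "dli_14d"]
    shuffled.loc[shuffled.index[1:30], cols] = daily.iloc[perm][cols].to_numpy()
    out = wq.interval_pressure_summary(shuffled, dates)
    for col in ["light_worst", "sed_worst", "temp_worst", "ssc_proxy"]:
        assert out[col].iloc[0] == pytest.approx(base[col].iloc[0])


def test_interval_summary_needs_two_dates(rng):
    with pytest.raises(ValueError):
        wq.interval_pressure_summary(_daily_frame(10, rng), [pd.Timestamp("2011-01-01")])
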