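"""Pressure-metric derivation from raw water-quality sensor series.

Raw 10-minute series of turbidity (NTU), benthic photosynthetically active
radiation (PAR, µmol photons m⁻² s⁻¹), temperature (°C) and a relative
sedimentation index (scaled to [0, 1]) are screened and aggregated into the
stressor metrics used by the response models:

* turbidity despiking — negative values removed; an interior value is removed
  when it exceeds 3 NTU and 2.5× the mean of its two neighbours;
* daily light integral (DLI, mol photons m⁻² d⁻¹) — time integral of PAR over
  the civil day;
* 14-day trailing running mean of DLI;
* per survey-interval summaries — "worst case" light (interval minimum of the
  running-mean DLI), maximum sedimentation, maximum daily-mean temperature,
  and mean screened turbidity as the suspended-sediment (SSC) proxy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400.0
EXPECTED_READINGS_PER_DAY = 144  # 10-min cadence


def despike_turbidity(ntu: pd.Series, spike_level: float = 3.0, spike_ratio: float = 2.5):
    """Screen a turbidity series: drop negatives and isolated spikes.

    A value ``v`` at an interior position is removed iff ``v > spike_level``
    and ``v > spike_ratio × mean(previous, next)`` where the neighbours are
    taken from the *original* series (single pass, no cascading).  Endpoints
    are exempt from the spike rule.  Values below 0 NTU are always removed.

    Returns ``(screened, mask)`` where ``screened`` is the series with removed
    entries dropped (index preserved) and ``mask`` is a same-index Series of
    reasons: ``"kept"``, ``"negative"`` or ``"spike"``.
    """
    s = pd.Series(ntu).astype(float)
    if s.isna().all():
        warnings.warn("all-missing turbidity series", stacklevel=2)
        return s.dropna(), pd.Series("missing", index=s.index, dtype=object)

    vals = s.to_numpy()
    reason = np.full(len(s), "kept", dtype=object)
    reason[np.isnan(vals)] = "missing"
    reason[vals < 0] = "negative"
    if len(s) >= 3:
        prev, nxt = vals[:-2], vals[2:]
        mid = vals[1:-1]
        neigh_mean = (prev + nxt) / 2.0
        with np.errstate(invalid="ignore"):
            spike = (mid > spike_level) & (mid > spike_ratio * neigh_mean)
        spike &= ~np.isnan(neigh_mean) & ~np.isnan(mid)
        # negatives take precedence as a removal reason
        interior = reason[1:-1]
        interior[spike & (interior == "kept")] = "spike"
    mask = pd.Series(reason, index=s.index, dtype=object)
    screened = s[mask == "kept"]
    return screened, mask


def daily_light_integral(par: pd.Series, min_completeness: float = 0.8) -> pd.Series:
    """Daily light integral from a 10-minute PAR series.

    PAR (µmol photons m⁻² s⁻¹) is integrated over each civil day with the
    trapezoidal rule between samples plus rectangular closure from the first
    sample back to 00:00 and from the last sample to 24:00, then converted to
    mol photons m⁻² d⁻¹ (×10⁻⁶).  Days with fewer than
    ``min_completeness × 144`` readings are returned as NaN.
    """
    s = pd.Series(par).astype(float)
    if not isinstance(s.index, pd.DatetimeIndex):
        raise TypeError("par series must have a DatetimeIndex")
    if (s.dropna() < 0).any():
        raise ValueError("negative PAR values; screen upstream")

    out = {}
    for day, g in s.groupby(s.index.normalize()):
        g = g.dropna()
        if len(g) < min_completeness * EXPECTED_READINGS_PER_DAY:
            out[day] = np.nan
            continue
        t = (g.index - day).total_seconds().to_numpy()
        v = g.to_numpy()
        integral = np.trapezoid(v, t) if len(v) > 1 else 0.0
        integral += v[0] * (t[0] - 0.0)  # closure to start of day
        integral += v[-1] * (SECONDS_PER_DAY - t[-1])  # closure to end of day
        out[day] = integral * 1e-6
    return pd.Series(out, name="dli").sort_index()


def running_mean(daily: pd.Series, window_days: int = 14, min_frac: float = 0.5) -> pd.Series:
    """Trailing running mean over ``window_days`` ending on each day.

    Days where fewer than ``min_frac`` of the window's values are present are
    NaN.  The window content rule is recorded in ``Series.attrs``.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    s = pd.Series(daily).astype(float)
    if len(s) < window_days:
        warnings.warn(
            f"running-mean window ({window_days}) exceeds series length ({len(s)})",
            stacklevel=2,
        )
    min_periods = max(1, int(np.ceil(min_frac * window_days)))
    out = s.rolling(window_days, min_periods=min_periods).mean()
    out.attrs["window_days"] = window_days
    out.attrs["min_periods"] = min_periods
    return out


def daily_metrics(wq: pd.DataFrame, light_window: int = 14) -> pd.DataFrame:
    """Per-day metrics from a raw site series.

    ``wq`` has a DatetimeIndex at 10-min cadence with columns ``ntu, par,
    temp_c, sed_index``.  Returns a per-day frame with ``dli, dli_14d,
    temp_mean_c, temp_max_c, ntu_mean, sed_max``.
    """
    screened, _ = despike_turbidity(wq["ntu"])
    day = wq.index.normalize()
    out = pd.DataFrame(
        {
            "temp_mean_c": wq["temp_c"].groupby(day).mean(),
            "temp_max_c": wq["temp_c"].groupby(day).max(),
            "ntu_mean": screened.groupby(screened.index.normalize()).mean(),
            "sed_max": wq["sed_index"].groupby(day).max(),
        }
    )
    out["dli"] = daily_light_integral(wq["par"])
    out["dli_14d"] = running_mean(out["dli"], light_window)
    return out


def interval_pressure_summary(
    daily: pd.DataFrame, survey_dates, site_id: str | None = None
) -> pd.DataFrame:
    """Per survey-interval pressure summary from per-day metrics.

    Interval ``i`` covers days in ``(survey_dates[i], survey_dates[i + 1]]``
    — the conditions leading up to the later survey.  Emits one row per
    interval with ``light_dli_14d`` (interval mean of the running-mean DLI),
    ``light_worst`` (interval minimum of the running-mean DLI), ``ssc_proxy``
    (mean screened NTU), ``sed_worst`` (max sedimentation index),
    ``temp_worst`` (max daily-mean temperature) and ``temp_mean``.
    """
    dates = pd.to_datetime(pd.Index(survey_dates)).sort_values()
    if len(dates) < 2:
        raise ValueError("need at least two survey dates")
    rows = []
    for i in range(len(dates) - 1):
        sel = daily[(daily.index > dates[i]) & (daily.index <= dates[i + 1])]
        if sel.empty or sel["dli_14d"].dropna().empty:
            warnings.warn(f"interval {i} has no usable data", stacklevel=2)
        rows.append(
            {
                "site_id": site_id,
                "interval_idx": i,
                "light_dli_14d": sel["dli_14d"].mean(),
                "light_worst": sel["dli_14d"].min(),
                "ssc_proxy": sel["ntu_mean"].mean(),
                "sed_worst": sel["sed_max"].max(),
                "temp_worst": sel["temp_mean_c"].max(),
                "temp_mean": sel["temp_mean_c"].mean(),
            }
        )
    return pd.DataFrame(rows)


def process_site(wq: pd.DataFrame, survey_dates, site_id: str | None = None):
    """Convenience: raw series → (daily metrics, interval summary)."""
    daily = daily_metrics(wq)
    summary = interval_pressure_summary(daily, survey_dates, site_id=site_id)
    return daily, summary
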