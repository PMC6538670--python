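"""Colony health scores: category ↔ proportion conversion and event derivation.

Coral colonies are scored at each field survey on a seven-category scale for
partial mortality, bleaching and sediment cover.  Categories map to percentage
bands (1 = 0%, 2 = 1–5%, 3 = 6–33%, 4 = 34–65%, 5 = 66–95%, 6 = 96–99%,
7 = 100%) whose midpoints are used as continuous proportional cover.  A
partial-mortality *event* is an increase in a colony's mortality score between
two consecutive surveys; the associated *loss* is the difference in midpoint
proportions.  Bleaching events are score increases on the bleaching scale, and
a colony's ``bleached_status`` latches to 1 from the first bleaching evidence
onward (configurable to concurrent-only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Proportional cover midpoints of the seven scoring categories.
SCORE_MIDPOINTS = {1: 0.0, 2: 0.03, 3: 0.19, 4: 0.495, 5: 0.805, 6: 0.970, 7: 1.0}

#: Upper percentage bound (inclusive) of each category band.
_BAND_UPPER = {1: 0, 2: 5, 3: 33, 4: 65, 5: 95, 6: 99, 7: 100}


def score_to_midpoint(category):
    """Convert a scoring category (1–7) to its proportional cover midpoint.

    Accepts a scalar or array-like; raises ``ValueError`` on out-of-range
    categories.
    """
    arr = np.asarray(category)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if not np.isin(arr, list(SCORE_MIDPOINTS)).all():
        bad = arr[~np.isin(arr, list(SCORE_MIDPOINTS))]
        raise ValueError(f"score categories must be in 1..7, got {bad.tolist()}")
    out = np.array([SCORE_MIDPOINTS[int(c)] for c in arr])
    return float(out[0]) if scalar else out


def proportion_to_score(p):
    """Inverse midpoint binning: map a proportion to its scoring category.

    ``round(100 * p)`` is placed in the band [0, 1–5, 6–33, 34–65, 66–95,
    96–99, 100]% whose upper edge is inclusive.
    """
    arr = np.asarray(p, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    pct = np.round(100 * arr).astype(int)
    uppers = np.array([_BAND_UPPER[c] for c in range(1, 8)])
    idx = np.searchsorted(uppers, pct, side="left")
    scores = idx + 1
    return int(scores[0]) if scalar else scores


def derive_events(panel: pd.DataFrame, latch_bleached: bool = True) -> pd.DataFrame:
    """Derive per-interval bleaching and mortality events from a colony panel.

    Parameters
    ----------
    panel
        One row per colony × survey with columns ``colony_id, site_id, group,
        survey_idx, mort_score, bleach_score`` and optionally ``excluded``.
    latch_bleached
        If True (default) ``bleached_status`` stays 1 from the first bleaching
        evidence onward; otherwise it reflects only the current survey.

    Returns
    -------
    DataFrame with one row per colony × interval: ``interval_idx`` (index of
    the interval's starting survey), ``live_cover_t``, ``mort_event``,
    ``loss``, ``bleach_event``, ``bleached_status``.  Intervals with either
    endpoint excluded are dropped.
    """
    required = {"colony_id", "site_id", "group", "survey_idx", "mort_score", "bleach_score"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    df = panel.sort_values(["colony_id", "survey_idx"]).reset_index(drop=True)
    if "excluded" not in df.columns:
        df = df.assign(excluded=False)

    rows = []
    for colony_id, g in df.groupby("colony_id", sort=False):
        mort = g["mort_score"].to_numpy()
        if (np.diff(mort) < 0).any():
            bad = g["survey_idx"].to_numpy()[np.where(np.diff(mort) < 0)[0]]
            raise ValueError(
                f"mortality score decreases for colony {colony_id!r} "
                f"after survey index {bad.tolist()}"
            )
        bleach = g["bleach_score"].to_numpy()
        excl = g["excluded"].to_numpy().astype(bool)
        sidx = g["survey_idx"].to_numpy()
        # bleaching evidence at survey s: any score > 1, or any prior increase
        evidence = bleach > 1
        status = np.maximum.accumulate(evidence) if latch_bleached else evidence
        mid = score_to_midpoint(mort)
        for i in range(len(g) - 1):
            if excl[i] or excl[i + 1]:
                continue
            loss = mid[i + 1] - mid[i]
            rows.append(
                {
                    "colony_id": colony_id,
                    "site_id": g["site_id"].iat[0],
                    "group": g["group"].iat[0],
                    "interval_idx": int(sidx[i]),
                    "live_cover_t": 1.0 - mid[i],
                    "mort_event": int(mort[i + 1] > mort[i]),
                    "loss": float(loss),
                    "bleach_event": int(bleach[i + 1] > bleach[i]),
                    "bleached_status": int(status[i + 1]),
                }
            )
    events = pd.DataFrame(
        rows,
        columns=[
            "colony_id",
            "site_id",
            "group",
            "interval_idx",
            "live_cover_t",
            "mort_event",
            "loss",
            "bleach_event",
            "bleached_status",
        ],
    )
    return events


def site_bleach_binomial(events: pd.DataFrame) -> pd.DataFrame:
    """Tally bleaching events into binomial (successes, trials) cells.

    Cells are site × interval × group; ``trials`` counts colonies observed at
    both interval endpoints (i.e. rows of the event table), ``successes``
    counts bleaching events.  Empty cells simply do not appear.
    """
    if events.empty:
        return pd.DataFrame(columns=["site_id", "interval_idx", "group", "successes", "trials"])
    out = (
        events.groupby(["site_id", "interval_idx", "group"], sort=True)
        .agg(successes=("bleach_event", "sum"), trials=("bleach_event", "size"))
        .reset_index()
    )
    return out


def endpoint_summary(panel: pd.DataFrame) -> dict:
    """Final-survey mortality score frequencies and headline fractions per group.

    Returns a dict keyed by group with a frequency table over final mortality
    scores 1..7, the whole-colony mortality fraction (final score 7), the
    no-mortality fraction (final score 1), and rounded-percent strings
    (nearest integer; fractions below 1% reported as ``"<1%"``).
    """
    df = panel.sort_values(["colony_id", "survey_idx"])
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    finals = df.groupby("colony_id").tail(1)
    out = {}
    for group, g in finals.groupby("group"):
        freq = g["mort_score"].value_counts().reindex(range(1, 8), fill_value=0)
        n = len(g)
        whole = int(freq[7])
        none = int(freq[1])
        out[group] = {
            "n_colonies": n,
            "final_score_freq": {int(k): int(v) for k, v in freq.items()},
            "whole_mortality_frac": whole / n if n else np.nan,
            "no_mortality_frac": none / n if n else np.nan,
            "whole_mortality_pct": _fmt_pct(whole / n) if n else "NA",
            "no_mortality_pct": _fmt_pct(none / n) if n else "NA",
        }
    return out


def _fmt_pct(frac: float) -> str:
    if 0 < frac < 0.01:
        return "<1%"
    return f"{round(100 * frac):d}%"
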