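"""Monte-Carlo composition of the sub-models into cumulative-impact scenarios.

Expected fortnightly coral loss is composed from the three fitted sub-models
along the two hurdle pathways::

    E[loss] = P(bleach) * P(mort | bleached) * E[loss | mort, bleached]
            + (1 - P(bleach)) * P(mort | unbleached) * E[loss | mort, unbleached]

evaluated, per posterior-style parameter draw, under three scenarios across a
descending light grid L:

* **thermal alone** — high temperature, high light (31 °C, 8.8 mol photons
  m⁻² d⁻¹): thermal stress with no dredging;
* **dredging alone** — low temperature (25 °C) across the light grid;
* **cumulative** — high temperature (31 °C) across the light grid.

The theoretical **additive** curve is thermal-alone plus dredging-alone
(clipped at 1).  Subtracting it from the cumulative curve gives the
interaction index: draws with a positive index are synergistic (worse than
expected independently), negative antagonistic.  Two light thresholds are
derived: the light of peak antagonism probability and the light at which the
median interaction crosses zero.

For massive corals, whose mortality also responds to sedimentation, a
monotone log-linear map from interval light to interval sedimentation
(fitted on observed water-quality summaries) supplies the sedimentation
covariate at each grid light level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "ScenarioPrediction",
    "pathway_loss",
    "fit_sedimentation_light_map",
    "scenario_curves",
    "classify_interaction",
    "light_thresholds",
]


@dataclass
class ScenarioConfig:
    """Scenario constants and Monte-Carlo settings.

    Defaults follow the study scenarios: high temperature 31 °C, low 25 °C,
    high light 8.8 mol photons m⁻² d⁻¹, light grid descending 8.8 → 0.1.
    """

    light_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(8.8, 0.1 - 1e-9, -0.05), 4)
    )
    t_high: float = 31.0
    t_low: float = 25.0
    l_high: float = 8.8
    group: str = "branching"
    n_draws: int = 1000
    seed: int = 0
    sed_map: object = None  # callable light -> sedimentation (massive group)
    pair_draws: bool = True  # pair draws across sub-models by index

    def __post_init__(self):
        g = np.asarray(self.light_grid, dtype=float)
        if (g <= 0).any():
            raise ValueError("light grid must be positive")
        if not (np.all(np.diff(g) < 0) or np.all(np.diff(g) > 0)):
            raise ValueError("light grid must be strictly monotone")
        if self.t_high <= self.t_low:
            raise ValueError("t_high must exceed t_low")
        self.light_grid = g


@dataclass
class ScenarioPrediction:
    """Per-draw scenario curves and summaries over the light grid."""

    light: np.ndarray
    loss_thermal: np.ndarray  # (D,)
    loss_dredging: np.ndarray  # (D, L)
    loss_cumulative: np.ndarray  # (D, L)
    loss_additive: np.ndarray  # (D, L)
    config: ScenarioConfig

    @property
    def interaction(self) -> np.ndarray:
        return self.loss_cumulative - self.loss_additive

    def summary(self) -> pd.DataFrame:
        """Median and 95% band of each curve per grid light value."""

        def q(a):
            return (
                np.median(a, axis=0),
                np.quantile(a, 0.025, axis=0),
                np.quantile(a, 0.975, axis=0),
            )

        cols = {}
        for name, arr in [
            ("dredging", self.loss_dredging),
            ("cumulative", self.loss_cumulative),
            ("additive", self.loss_additive),
            ("interaction", self.interaction),
        ]:
            med, lo, hi = q(arr)
            cols[f"{name}_med"] = med
            cols[f"{name}_lo"] = lo
            cols[f"{name}_hi"] = hi
        p_syn, p_ant = classify_interaction(self)
        cols["p_synergy"] = p_syn
        cols["p_antagonism"] = p_ant
        return pd.DataFrame({"light": self.light, **cols})


def pathway_loss(p_bleach, p_mort_bleached, p_mort_unbleached, loss_bleached, loss_unbleached):
    """Expected loss from the two-branch (bleached / unbleached) hurdle tree.

    ``E = p_b * p_m|b * loss|b + (1 - p_b) * p_m|u * loss|u``.  All arguments
    must lie in [0, 1]; broadcasts like numpy.
    """
    args = [
        np.asarray(a, dtype=float)
        for a in (p_bleach, p_mort_bleached, p_mort_unbleached, loss_bleached, loss_unbleached)
    ]
    for a in args:
        if ((a < 0) | (a > 1)).any():
            raise ValueError("pathway_loss arguments must lie in [0, 1]")
    pb, pmb, pmu, lb, lu = args
    return pb * pmb * lb + (1 - pb) * pmu * lu


def fit_sedimentation_light_map(pressure_summary: pd.DataFrame):
    """Monotone log-linear map interval light → interval sedimentation.

    Regresses worst-case interval sedimentation on log worst-case light over
    the observed water-quality summaries and returns a callable clipped to
    [0, 1].  The slope is constrained non-positive (lower light — heavier
    dredging — never maps to less sedimentation).
    """
    df = pressure_summary.dropna(subset=["light_worst", "sed_worst"])
    df = df[df["light_worst"] > 0]
    x = np.log(df["light_worst"].to_numpy(dtype=float))
    y = df["sed_worst"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    b = min(b, 0.0)

    def sed_of_light(light):
        return np.clip(a + b * np.log(np.asarray(light, dtype=float)), 0.0, 1.0)

    sed_of_light.intercept, sed_of_light.slope = float(a), float(b)
    return sed_of_light


def _predict_frame(light, temp, sed_map, group, bleached, sed=None):
    light = np.atleast_1d(np.asarray(light, dtype=float))
    n = len(light)
    df = pd.DataFrame(
        {
            "light": light,
            "temp": np.full(n, temp),
            "group": group,
            "bleached_status": bleached,
        }
    )
    if sed_map is not None:
        df["sed"] = sed_map(light)
    elif sed is not None:
        df["sed"] = sed
    df["live_cover_t"] = 1.0
    return df


def scenario_curves(models: dict, cfg: ScenarioConfig) -> ScenarioPrediction:
    """Compose fitted sub-models into per-draw scenario loss curves.

    ``models`` maps ``"bleach"``, ``"incidence"``, ``"loss"`` to fitted
    sub-models (anything exposing ``predict(df, params)`` and
    ``draws(n, seed)``).  Draws of distinct sub-models are paired by index
    (independent sub-model fits) unless ``cfg.pair_draws`` is False, in which
    case each sub-model's draw order is independently shuffled.
    """
    bleach, incidence, loss = models["bleach"], models["incidence"], models["loss"]
    D = cfg.n_draws
    rng = np.random.default_rng(cfg.seed)
    dsets = {
        name: m.draws(D, seed=int(rng.integers(2**31)))
        for name, m in [("bleach", bleach), ("incidence", incidence), ("loss", loss)]
    }
    if not cfg.pair_draws:
        for name in dsets:
            dsets[name] = dsets[name][rng.permutation(D)]

    L = cfg.light_grid
    sed_map = cfg.sed_map if cfg.group == "massive" else None

    def expected(temp, light):
        """(len(light), D) expected-loss matrix across all draws."""
        p_b = bleach.predict_many(
            _predict_frame(light, temp, sed_map, cfg.group, 0), dsets["bleach"]
        )
        p_mb = incidence.predict_many(
            _predict_frame(light, temp, sed_map, cfg.group, 1), dsets["incidence"]
        )
        p_mu = incidence.predict_many(
            _predict_frame(light, temp, sed_map, cfg.group, 0), dsets["incidence"]
        )
        l_b = loss.predict_many(
            _predict_frame(light, temp, sed_map, cfg.group, 1), dsets["loss"]
        )
        l_u = loss.predict_many(
            _predict_frame(light, temp, sed_map, cfg.group, 0), dsets["loss"]
        )
        return pathway_loss(p_b, p_mb, p_mu, l_b, l_u)

    thermal = expected(cfg.t_high, [cfg.l_high])[0]  # (D,)
    dredging = expected(cfg.t_low, L).T  # (D, L)
    cumulative = expected(cfg.t_high, L).T
    additive = np.clip(thermal[:, None] + dredging, 0.0, 1.0)
    return ScenarioPrediction(
        light=L,
        loss_thermal=thermal,
        loss_dredging=dredging,
        loss_cumulative=cumulative,
        loss_additive=additive,
        config=cfg,
    )


def classify_interaction(pred: ScenarioPrediction):
    """Per-light synergy / antagonism probabilities over draws.

    ``p_synergy(L)`` is the fraction of draws with interaction > 0,
    ``p_antagonism`` the fraction < 0 (exact zeros count toward neither).
    """
    inter = pred.interaction
    if inter.shape[0] < 1:
        raise ValueError("need at least one draw")
    p_syn = (inter > 0).mean(axis=0)
    p_ant = (inter < 0).mean(axis=0)
    return p_syn, p_ant


def light_thresholds(pred: ScenarioPrediction) -> dict:
    """Light thresholds from the scenario prediction.

    * ``l_peak_antagonism`` — grid argmax of the antagonism probability,
      with a 95% interval from the per-draw argmin of the interaction curve;
    * ``l_crossover`` — light at which the median interaction changes sign
      (linear interpolation between bracketing grid points; lowest-light
      crossing if several), with a 95% interval from per-draw crossovers.
      ``None`` when the median curve never changes sign.
    """
    L = pred.light
    med = np.median(pred.interaction, axis=0)
    _, p_ant = classify_interaction(pred)
    # argmax of antagonism probability; plateaus of p_ant = 1 are broken
    # toward the most negative median interaction
    top = np.flatnonzero(p_ant >= p_ant.max() - 1e-12)
    l_peak = float(L[top[int(np.argmin(med[top]))]])
    per_draw_peak = L[np.argmin(pred.interaction, axis=1)]
    peak_int = tuple(np.quantile(per_draw_peak, [0.025, 0.975]))

    def crossover_of(curve):
        sign = np.sign(curve)
        changes = np.where(np.diff(sign) != 0)[0]
        if len(changes) == 0:
            return None
        # lowest light = last index on a descending grid, first on ascending
        order = np.argsort(L)
        asc_L, asc_c = L[order], curve[order]
        ch = np.where(np.diff(np.sign(asc_c)) != 0)[0]
        if len(ch) == 0:
            return None
        i = ch[0]
        x0, x1, y0, y1 = asc_L[i], asc_L[i + 1], asc_c[i], asc_c[i + 1]
        if y1 == y0:
            return float(x0)
        return float(x0 + (0.0 - y0) * (x1 - x0) / (y1 - y0))

    l_cross = crossover_of(med)
    draw_cross = [crossover_of(pred.interaction[d]) for d in range(pred.interaction.shape[0])]
    draw_cross = [c for c in draw_cross if c is not None]
    cross_int = tuple(np.quantile(draw_cross, [0.025, 0.975])) if draw_cross else (None, None)
    return {
        "l_peak_antagonism": l_peak,
        "l_peak_antagonism_95": peak_int,
        "l_crossover": l_cross,
        "l_crossover_95": cross_int,
    }
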