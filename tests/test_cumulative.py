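"""Scenario composition, interaction classification and light thresholds."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from seditherm import cumulative as cm
from seditherm import synthgen


def test_pathway_loss_degenerate_branch():
    assert cm.pathway_loss(0.0, 0.9, 0.2, 0.5, 0.1) == pytest.approx(0.2 * 0.1)


def test_pathway_loss_arithmetic():
    assert cm.pathway_loss(0.5, 0.4, 0.2, 0.3, 0.1) == pytest.approx(0.07)


def test_pathway_loss_exhaustive_grid():
    """Exhaustive check against brute-force expectation over the 2-branch tree."""
    vals = [0.0, 0.25, 0.5, 0.75, 1.0]
    for pb, pmb, pmu, lb, lu in product(vals, repeat=5):
        # oracle: enumerate the bleached/unbleached branches explicitly
        expect = pb * (pmb * lb) + (1 - pb) * (pmu * lu)
        assert cm.pathway_loss(pb, pmb, pmu, lb, lu) == pytest.approx(expect, abs=1e-12)


def test_pathway_loss_rejects_out_of_range():
    with pytest.raises(ValueError):
        cm.pathway_loss(1.2, 0.5, 0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        cm.pathway_loss(0.5, 0.5, 0.5, -0.1, 0.5)


def test_pathway_loss_bounds_and_monotonicity(rng):
    for _ in range(200):
        a = rng.uniform(0, 1, 5)
        v = cm.pathway_loss(*a)
        assert v <= max(a[3], a[4]) + 1e-12
        assert v <= max(a[1], a[2]) + 1e-12
        bumped = a.copy()
        i = rng.integers(1, 5)
        bumped[i] = min(1.0, bumped[i] + 0.1)
        assert cm.pathway_loss(*bumped) >= v - 1e-12


class _FakeModel:
    """Analytic stand-in sub-model; draws perturb coefficients, not outputs.

    ``fn(df, eps)`` maps a covariate frame and a parameter-perturbation
    vector to a response in [0, 1].
    """

    def __init__(self, fn, n_params=3, jitter=0.0):
        self.fn = fn
        self.n_params = n_params
        self.jitter = jitter

    def draws(self, n, seed, scale=1.0):
        r = np.random.default_rng(seed)
        return r.normal(0.0, self.jitter, (n, self.n_params))

    def predict_many(self, df, params):
        cols = [self.fn(df, params[d]) for d in range(params.shape[0])]
        return np.clip(np.column_stack(cols), 0.0, 1.0)

    def predict(self, df, params=None):
        eps = params if params is not None else np.zeros(self.n_params)
        return self.fn(df, eps)


def _fake_models(truth, group="branching", jitter=0.0015):
    """Sub-models evaluating the synthetic ground truth, with the leading
    coefficient-perturbations entering the incidence logit."""

    def bleach(df, eps):
        return synthgen.bleach_probability(truth, df["temp"], df["light"], group)

    def incidence(df, eps):
        eta = synthgen.incidence_logit(
            truth, group, df["light"], df["temp"],
            df.get("sed", 0.0), df["bleached_status"],
        )
        c = truth.incidence[group]
        light = df["light"].to_numpy(dtype=float)
        temp = df["temp"].to_numpy(dtype=float)
        eta = eta + eps[0] + eps[1] * np.exp(-light / c.light_scale) + eps[2] * (
            temp - c.temp_ref
        )
        return expit(eta)

    def loss(df, eps):
        return np.broadcast_to(
            synthgen.loss_mean(truth, group, df["bleached_status"].to_numpy()), (len(df),)
        ).astype(float)

    return {
        "bleach": _FakeModel(bleach, jitter=jitter),
        "incidence": _FakeModel(incidence, jitter=jitter),
        "loss": _FakeModel(loss, jitter=jitter),
    }


def test_endpoint_identity():
    """At L = L_high the cumulative scenario equals thermal-alone, so the
    interaction there is exactly −loss_dredging(L_high)."""
    truth = synthgen.default_truth()
    models = _fake_models(truth, jitter=0.0)
    cfg = cm.ScenarioConfig(n_draws=5, seed=1)
    pred = cm.scenario_curves(models, cfg)
    inter_at_high = pred.interaction[:, 0]
    assert inter_at_high == pytest.approx(-pred.loss_dredging[:, 0], abs=1e-12)


def additive_null_models(alpha_t=0.01, alpha_l=0.02, sigma=0.5):
    """Truly additive rare-risk truth with zero baseline at the anchors.

    Expected loss p(T, L) = f(T) + g(L) with f(25) = 0 and g(8.8) = 0, so
    cumulative = thermal-alone + dredging-alone holds exactly.  Draw noise is
    multiplicative (logit-scale), emulating posterior uncertainty of a fitted
    risk model; exact structural zeros stay zero.
    """
    from scipy.special import logit as _logit

    def incidence(df, eps):
        T = df["temp"].to_numpy(dtype=float)
        L = df["light"].to_numpy(dtype=float)
        base = alpha_t * (T - 25.0) / 6.0 + alpha_l * (8.8 - L) / 8.7
        pos = base > 0
        eta = _logit(np.where(pos, base, 0.5))
        eta = eta + eps[0] + eps[1] * (T - 25.0) / 6.0 + eps[2] * (8.8 - L) / 8.7
        return np.where(pos, expit(eta), 0.0)

    def bleach(df, eps):
        return np.zeros(len(df))

    def loss(df, eps):
        return np.ones(len(df))

    return {
        "bleach": _FakeModel(bleach, jitter=0.0),
        "incidence": _FakeModel(incidence, jitter=sigma),
        "loss": _FakeModel(loss, jitter=0.0),
    }


def test_additive_null_calibration():
    """Truly additive rare-risk truth: median interaction ~0 and the
    classifier shows no false certainty below the high-light anchor (at the
    anchor itself interaction = -loss_dredging(L_high) identically)."""
    pred = cm.scenario_curves(
        additive_null_models(), cm.ScenarioConfig(n_draws=400, seed=2)
    )
    med = np.median(pred.interaction, axis=0)
    assert np.abs(med).max() < 0.01
    p_syn, _ = cm.classify_interaction(pred)
    interior = slice(1, None)  # grid below the L_high anchor
    assert np.all((p_syn[interior] > 0.3) & (p_syn[interior] < 0.7))


def test_classify_degenerate_and_symmetric(rng):
    truth = synthgen.default_truth()
    pred = cm.scenario_curves(_fake_models(truth, jitter=0.0), cm.ScenarioConfig(n_draws=3, seed=0))
    pred.loss_cumulative = pred.loss_additive + 0.05
    p_syn, p_ant = cm.classify_interaction(pred)
    assert np.all(p_syn == 1.0) and np.all(p_ant == 0.0)
    # symmetric draws around zero
    pred.loss_cumulative = pred.loss_additive + rng.normal(0, 1, pred.loss_cumulative.shape)
    p_syn, _ = cm.classify_interaction(pred)
    assert np.all(np.abs(p_syn - 0.5) < 3 / np.sqrt(3) + 0.5)


def test_classify_matches_tally_oracle(rng):
    truth = synthgen.default_truth()
    pred = cm.scenario_curves(
        _fake_models(truth, jitter=0.0), cm.ScenarioConfig(n_draws=50, seed=3)
    )
    inter = rng.normal(0, 0.01, pred.loss_cumulative.shape)
    pred.loss_cumulative = np.clip(pred.loss_additive + inter, 0, 1)
    p_syn, p_ant = cm.classify_interaction(pred)
    actual = pred.interaction
    for j in range(0, actual.shape[1], 37):
        assert p_syn[j] == sum(1 for d in actual[:, j] if d > 0) / actual.shape[0]
        assert p_ant[j] == sum(1 for d in actual[:, j] if d < 0) / actual.shape[0]
    assert np.all(p_syn + p_ant <= 1.0)


def _pred_with_interaction(curve_fn, L=None, n_draws=9):
    L = L if L is not None else np.arange(8.8, 0.1 - 1e-9, -0.05)
    base = np.tile(curve_fn(L), (n_draws, 1))
    dredging = np.full_like(base, 0.01)
    additive = dredging + 0.02
    cfg = cm.ScenarioConfig(light_grid=L, n_draws=n_draws, seed=0)
    return cm.ScenarioPrediction(
        light=L,
        loss_thermal=np.full(n_draws, 0.02),
        loss_dredging=dredging,
        loss_cumulative=additive + base,
        loss_additive=additive,
        config=cfg,
    )


def test_crossover_linear_inversion():
    """Median interaction 0.5 − L/4 crosses zero at exactly L = 2."""
    pred = _pred_with_interaction(lambda L: 0.5 - L / 4)
    th = cm.light_thresholds(pred)
    assert th["l_crossover"] == pytest.approx(2.0, abs=1e-9)


def test_no_crossing_reported_absent():
    pred = _pred_with_interaction(lambda L: -0.1 - 0.01 * L)
    th = cm.light_thresholds(pred)
    assert th["l_crossover"] is None
    assert th["l_peak_antagonism"] == pytest.approx(
        pred.light[np.argmin(-0.1 - 0.01 * pred.light)]
    )


def test_mechanism_crossover_matches_analytic_zero():
    """Threshold extraction on truth-composed curves recovers the analytic
    zero of the interaction within grid resolution."""
    truth = synthgen.default_truth()
    cfg = cm.ScenarioConfig(n_draws=50, seed=4)
    pred = cm.scenario_curves(_fake_models(truth, jitter=1e-4), cfg)
    L = cfg.light_grid
    E = synthgen.true_expected_loss
    inter_true = E(truth, 31.0, L) - (E(truth, 31.0, 8.8) + E(truth, 25.0, L))
    # analytic zero by fine bisection between bracketing grid points
    i = np.where(np.diff(np.sign(inter_true[np.argsort(L)])) != 0)[0]
    asc = np.sort(L)
    from scipy.optimize import brentq

    f = lambda l: float(E(truth, 31.0, l) - (E(truth, 31.0, 8.8) + E(truth, 25.0, l)))
    true_zero = brentq(f, asc[i[0]], asc[i[0] + 1])
    th = cm.light_thresholds(pred)
    assert th["l_crossover"] == pytest.approx(true_zero, abs=0.05 + 1e-6)


def test_scenario_reproducibility():
    truth = synthgen.default_truth()
    cfg = cm.ScenarioConfig(n_draws=20, seed=9)
    p1 = cm.scenario_curves(_fake_models(truth), cfg)
    p2 = cm.scenario_curves(_fake_models(truth), cfg)
    assert np.array_equal(p1.loss_cumulative, p2.loss_cumulative)
    assert np.array_equal(p1.loss_thermal, p2.loss_thermal)


def test_sed_map_monotone():
    df = pd.DataFrame(
        {
            "light_worst": np.geomspace(0.2, 9, 40),
            "sed_worst": np.clip(0.8 - 0.3 * np.log(np.geomspace(0.2, 9, 40)), 0, 1),
        }
    )
    sed = cm.fit_sedimentation_light_map(df)
    grid = np.linspace(0.2, 9, 50)
    vals = sed(grid)
    assert np.all(np.diff(vals) <= 1e-12)
    assert np.all((vals >= 0) & (vals <= 1))


def test_scenario_config_validation():
    with pytest.raises(ValueError):
        cm.ScenarioConfig(light_grid=np.array([1.0, -1.0]))
    with pytest.raises(ValueError):
        cm.ScenarioConfig(t_high=20.0, t_low=25.0)
    with pytest.raises(ValueError):
        cm.ScenarioConfig(light_grid=np.array([1.0, 3.0, 2.0]))
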