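"""Synthetic-data generator: structure, determinism, degenerate limits."""

import numpy as np
import pandas as pd
import pytest

from seditherm import synthgen, waterquality
from seditherm.synthgen import GroundTruth, IncidenceCoefs, LossCoefs, SiteConfig, WQDecay


def _mean_dli(frame):
    return waterquality.daily_light_integral(frame["par"]).mean()


def test_water_quality_determinism(small_sites):
    truth = synthgen.default_truth()
    a = synthgen.generate_water_quality(small_sites, 30, truth, seed=5)
    b = synthgen.generate_water_quality(small_sites, 30, truth, seed=5)
    for k in a:
        assert a[k].equals(b[k])  # bit-identical
    c = synthgen.generate_water_quality(small_sites, 30, truth, seed=6)
    assert not a["near"].equals(c["near"])


def test_light_increases_with_distance(small_wq):
    assert _mean_dli(small_wq["far"]) > _mean_dli(small_wq["near"])


def test_sedimentation_decreases_with_distance(small_wq):
    assert small_wq["near"]["sed_index"].mean() > small_wq["far"]["sed_index"].mean()
    for f in small_wq.values():
        assert f["sed_index"].between(0, 1).all()
        assert f.index.is_monotonic_increasing


def test_no_pressure_limit(small_sites):
    """Zero plume amplitude: expected light and sedimentation equal across sites."""
    truth = synthgen.default_truth()
    truth.wq.pressure_amplitude = 0.0
    wq = synthgen.generate_water_quality(small_sites, 90, truth, seed=3)
    dlis = [_mean_dli(f) for f in wq.values()]
    assert max(dlis) - min(dlis) < 0.05 * np.mean(dlis)
    seds = [f["sed_index"].mean() for f in wq.values()]
    assert max(seds) - min(seds) < 0.02


def test_invalid_parameters():
    with pytest.raises(ValueError):
        GroundTruth(wq=WQDecay(length_scale_km=0.0))
    with pytest.raises(ValueError):
        GroundTruth(re_sd_site=-0.1)
    with pytest.raises(ValueError):
        GroundTruth(loss={"branching": LossCoefs(mean_unbleached=0.9, bleached_multiplier=1.3)})
    truth = synthgen.default_truth()
    with pytest.raises(ValueError, match="duplicate"):
        synthgen.generate_water_quality(
            [SiteConfig("a", 1.0), SiteConfig("a", 2.0)], 30, truth, seed=1
        )
    with pytest.raises(ValueError):
        synthgen.generate_water_quality([SiteConfig("a", 1.0)], 10, truth, seed=1)


def test_site_category_bands():
    assert SiteConfig("x", 0.19).category == "near"
    assert SiteConfig("x", 6.0).category == "intermediate"
    assert SiteConfig("x", 32.8).category == "far"
    sites = synthgen.default_sites()
    assert len(sites) == 17
    assert all(0.19 <= s.distance_km <= 32.8 for s in sites)


def test_bleaching_impossible_limit(small_sites, small_wq):
    truth = synthgen.default_truth()
    truth.bleach.intercept = -np.inf
    panel = synthgen.simulate_health_trajectories(
        small_wq, small_sites, 3, 3, truth, 14, seed=4
    )
    assert (panel["bleach_score"] == 1).all()


def test_saturation_limit(small_sites, small_wq):
    """Certain incidence with total loss kills every colony in one interval."""
    truth = synthgen.default_truth()
    truth.incidence = {
        g: IncidenceCoefs(intercept=50.0, low_light_slope=0, temp_slope=0, bleached_offset=0)
        for g in ("branching", "massive")
    }
    truth.loss = {
        g: LossCoefs(mean_unbleached=1.0, bleached_multiplier=1.0, dispersion=None)
        for g in ("branching", "massive")
    }
    truth.re_sd_site = truth.re_sd_colony = 0.0
    truth.exclusion_rate = 0.0
    panel = synthgen.simulate_health_trajectories(
        small_wq, small_sites, 3, 3, truth, 14, seed=4
    )
    after_first = panel[panel["survey_idx"] >= 1]
    assert (after_first["mort_score"] == 7).all()


def test_mortality_monotone_and_absorbing(small_panel):
    panel, _ = small_panel
    for _, g in panel.groupby("colony_id"):
        scores = g.sort_values("survey_idx")["mort_score"].to_numpy()
        assert (np.diff(scores) >= 0).all()
        dead = np.where(scores == 7)[0]
        if len(dead):
            assert (scores[dead[0] :] == 7).all()


def test_zero_vs_partial_mortality_tally(small_sites, small_wq):
    """High incidence with small losses: partial mortality outnumbers none."""
    truth = synthgen.default_truth()
    truth.incidence["massive"] = IncidenceCoefs(
        intercept=-0.5, low_light_slope=0, temp_slope=0, sed_slope=0, bleached_offset=0
    )
    truth.loss["massive"] = LossCoefs(mean_unbleached=0.05, bleached_multiplier=1.0)
    truth.re_sd_site = truth.re_sd_colony = 0.0
    panel = synthgen.simulate_health_trajectories(
        small_wq, small_sites, 1, 30, truth, 14, seed=9
    )
    finals = panel[panel.group == "massive"].sort_values("survey_idx").groupby("colony_id").tail(1)
    frac_zero = (finals["mort_score"] == 1).mean()
    frac_partial = finals["mort_score"].between(2, 6).mean()
    assert frac_zero < frac_partial


def test_baseline_event_rate_calibration(small_sites):
    """With no pressure, no anomaly and flat covariate effects, the latent
    event rate matches the intercept-implied probability within binomial CI."""
    truth = synthgen.default_truth()
    truth.wq.pressure_amplitude = 0.0
    truth.wq.anomaly_delta = 0.0
    p_target = 0.15
    icpt = float(np.log(p_target / (1 - p_target)))
    truth.incidence = {
        g: IncidenceCoefs(intercept=icpt, low_light_slope=0, temp_slope=0, sed_slope=0)
        for g in ("branching", "massive")
    }
    truth.re_sd_site = truth.re_sd_colony = 0.0
    truth.exclusion_rate = 0.0
    wq = synthgen.generate_water_quality(small_sites, 150, truth, seed=21)
    _, latent = synthgen.simulate_health_trajectories(
        wq, small_sites, 20, 20, truth, 14, seed=22, return_latent=True
    )
    live = latent[latent["cum_mortality_start"] < 1]  # at-risk intervals only
    n = len(live)
    rate = live["mort_event"].mean()
    half_width = 1.96 * np.sqrt(p_target * (1 - p_target) / n)
    assert n * p_target * (1 - p_target) > 9  # enough information
    assert abs(rate - p_target) < max(half_width, 0.02)


def test_truth_yaml_roundtrip(tmp_path):
    truth = synthgen.default_truth()
    truth.bleach.intercept = -0.7
    path = tmp_path / "truth.yaml"
    synthgen.truth_to_yaml(truth, path)
    back = synthgen.truth_from_yaml(path)
    assert back == truth


def test_panel_health_determinism(small_sites, small_wq):
    truth = synthgen.default_truth()
    p1 = synthgen.simulate_health_trajectories(small_wq, small_sites, 3, 4, truth, 14, seed=7)
    p2 = synthgen.simulate_health_trajectories(small_wq, small_sites, 3, 4, truth, 14, seed=7)
    assert p1.equals(p2)
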