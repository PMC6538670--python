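"""Synthetic water-quality and colony-health data with known ground truth.

The study's raw monitoring data are restricted, so this module generates data
with the same statistical structure: ~17 sites spanning 0.19–32.8 km from a
dredging pressure source, 10-minute water-quality sensor series over ~530
days, fortnightly colony photo surveys (~10 branching and ~23 massive
colonies per site), water-quality pressure decaying exponentially with
distance, a seasonal temperature cycle with a one-week warm anomaly, and
colony health generated from known bleaching / mortality-incidence /
tissue-loss response functions.  The generative functions are the inverse of
the models the analysis fits, so every ground-truth parameter is available
for recovery testing.

The bleaching response is a *gated* logistic: bleaching requires both high
temperature (soft threshold at 29 °C) and high light (soft threshold at
4 mol photons m⁻² d⁻¹) — the product-of-logistic-ramps form is smooth and
differentiable rather than a hard indicator.  Mortality incidence is a
logistic in a low-light stress term (rising as light → 0), thermal excess,
sedimentation (massive corals only) and bleached status, with persistent
site and colony random intercepts.  Conditional loss given an event is a
beta draw whose mean is ~30% higher for bleached colonies.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import colonyscoring, waterquality

__all__ = [
    "SiteConfig",
    "GroundTruth",
    "default_sites",
    "default_truth",
    "generate_water_quality",
    "simulate_health_trajectories",
    "bleach_probability",
    "incidence_probability",
    "loss_mean",
    "true_expected_loss",
    "truth_to_yaml",
    "truth_from_yaml",
]

SECONDS_PER_STEP = 600  # 10-min cadence
STEPS_PER_DAY = 144
HALF_SINE_FACTOR = (2 / np.pi) * 43200e-6  # DLI per unit peak PAR, 12-h daylight


@dataclass
class SiteConfig:
    """A monitoring site on the distance-to-dredging gradient."""

    site_id: str
    distance_km: float
    depth_m: float = 7.0

    @property
    def category(self) -> str:
        """Distance band: near (<1.5 km), intermediate (4–15), far (24–32)."""
        d = self.distance_km
        if d < 1.5:
            return "near"
        if d <= 15:
            return "intermediate"
        return "far"


@dataclass
class BleachCoefs:
    intercept: float = -1.0
    thermal_slope: float = 1.2  # per degC above t_gate
    l_gate: float = 4.0  # mol photons m-2 d-1
    t_gate: float = 29.0  # degC
    interaction_slope: float = 0.0  # (T - t_gate) x (L - l_gate)
    gate_width_t: float = 0.5
    gate_width_l: float = 0.8
    massive_offset: float = -1.0  # lower bleaching probability for massives


@dataclass
class IncidenceCoefs:
    intercept: float = -3.5
    low_light_slope: float = 3.5  # on exp(-light / light_scale)
    temp_slope: float = 0.3  # per degC above temp_ref
    sed_slope: float = 0.0  # massive only
    bleached_offset: float = 1.5  # logits
    light_scale: float = 1.0
    temp_ref: float = 27.0


@dataclass
class LossCoefs:
    mean_unbleached: float = 0.10
    bleached_multiplier: float = 1.3
    dispersion: float | None = 8.0  # beta precision; None = deterministic


@dataclass
class WQDecay:
    ambient_dli: float = 7.0  # annual-mean daily light integral
    dli_seasonal_amp: float = 2.5
    ambient_sed: float = 0.05
    pressure_amplitude: float = 3.0  # optical-depth scale of the plume at source
    length_scale_km: float = 2.0
    ntu_base: float = 0.5
    ntu_scale: float = 8.0
    temp_mean: float = 26.5
    temp_seasonal_amp: float = 2.5
    anomaly_delta: float = 3.0  # a week of unusually warm water
    anomaly_days: int = 7
    noise_sd: float = 0.25  # lognormal sd of daily pressure noise


@dataclass
class GroundTruth:
    """All generative parameters, exposed for recovery tests."""

    bleach: BleachCoefs = field(default_factory=BleachCoefs)
    incidence: dict = field(
        default_factory=lambda: {
            "branching": IncidenceCoefs(),
            "massive": IncidenceCoefs(
                intercept=-3.8,
                low_light_slope=2.5,
                temp_slope=0.2,
                sed_slope=2.0,
                bleached_offset=0.8,
            ),
        }
    )
    loss: dict = field(
        default_factory=lambda: {
            "branching": LossCoefs(mean_unbleached=0.10),
            "massive": LossCoefs(mean_unbleached=0.04, dispersion=12.0),
        }
    )
    wq: WQDecay = field(default_factory=WQDecay)
    re_sd_site: float = 0.3
    re_sd_colony: float = 0.5
    exclusion_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.wq.length_scale_km <= 0:
            raise ValueError("length_scale_km must be positive")
        if self.re_sd_site < 0 or self.re_sd_colony < 0:
            raise ValueError("random-effect SDs must be non-negative")
        for g, lc in self.loss.items():
            mu_max = lc.mean_unbleached * max(lc.bleached_multiplier, 1.0)
            if not (0 < lc.mean_unbleached <= 1 and mu_max <= 1):
                raise ValueError(f"loss means for {g!r} must lie in (0, 1]")


def default_truth(**overrides) -> GroundTruth:
    """The default study-condition ground truth."""
    return GroundTruth(**overrides)


def default_sites(n: int = 17) -> list:
    """17 sites in the near / intermediate / far bands of the study envelope."""
    distances = [
        0.19, 0.35, 0.55, 0.8, 1.1, 1.4,  # near (<1.5 km)
        4.0, 6.0, 8.0, 10.5, 12.5, 15.0,  # intermediate (4-15 km)
        24.0, 26.5, 29.0, 31.0, 32.8,  # far (24-32.8 km)
    ]
    sites = [SiteConfig(f"S{i + 1:02d}", d) for i, d in enumerate(distances[:n])]
    return sites


# ---------------------------------------------------------------------------
# response functions (the generative inverse of the fitted models)
# ---------------------------------------------------------------------------


def _sigmoid(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def bleach_probability(truth: GroundTruth, temp, light, group="branching"):
    """Gated light × temperature bleaching probability."""
    b = truth.bleach
    temp = np.asarray(temp, dtype=float)
    light = np.asarray(light, dtype=float)
    eta = (
        b.intercept
        + b.thermal_slope * (temp - b.t_gate)
        + b.interaction_slope * (temp - b.t_gate) * (light - b.l_gate)
        + (b.massive_offset if group == "massive" else 0.0)
    )
    gate = _sigmoid((temp - b.t_gate) / b.gate_width_t) * _sigmoid(
        (light - b.l_gate) / b.gate_width_l
    )
    return _sigmoid(eta) * gate


def incidence_logit(truth: GroundTruth, group, light, temp, sed=0.0, bleached=0):
    c = truth.incidence[group]
    light = np.asarray(light, dtype=float)
    return (
        c.intercept
        + c.low_light_slope * np.exp(-light / c.light_scale)
        + c.temp_slope * (np.asarray(temp, dtype=float) - c.temp_ref)
        + c.sed_slope * np.asarray(sed, dtype=float)
        + c.bleached_offset * np.asarray(bleached)
    )


def incidence_probability(truth, group, light, temp, sed=0.0, bleached=0, re=0.0):
    """Partial-mortality event probability (random effects default to 0)."""
    return _sigmoid(incidence_logit(truth, group, light, temp, sed, bleached) + re)


def loss_mean(truth: GroundTruth, group, bleached=0):
    c = truth.loss[group]
    mult = np.where(np.asarray(bleached).astype(bool), c.bleached_multiplier, 1.0)
    return np.minimum(c.mean_unbleached * mult, 1.0)


def true_expected_loss(truth: GroundTruth, temp, light, sed=0.0, group="branching"):
    """Analytic expected fortnightly loss via the two-branch pathway (RE = 0).

    This is the closed-form truth curve against which the Monte-Carlo
    pipeline's mechanism recovery is judged.
    """
    p_b = bleach_probability(truth, temp, light, group)
    p_mb = incidence_probability(truth, group, light, temp, sed, bleached=1)
    p_mu = incidence_probability(truth, group, light, temp, sed, bleached=0)
    return p_b * p_mb * loss_mean(truth, group, 1) + (1 - p_b) * p_mu * loss_mean(
        truth, group, 0
    )


def site_pressure(truth: GroundTruth, distance_km):
    """Dimensionless plume pressure at a site (optical-depth scale)."""
    return truth.wq.pressure_amplitude * np.exp(
        -np.asarray(distance_km, dtype=float) / truth.wq.length_scale_km
    )


# ---------------------------------------------------------------------------
# water-quality generation
# ---------------------------------------------------------------------------


def generate_water_quality(
    sites,
    n_days: int,
    truth: GroundTruth,
    seed: int,
    start: str = "2010-05-19",
) -> dict:
    """Generate 10-min water-quality series per site.

    Returns a dict ``site_id → DataFrame`` (DatetimeIndex at 10-min cadence;
    columns ``ntu, par, temp_c, sed_index``).  Light, turbidity and
    sedimentation pressure scale with ``exp(-distance / length_scale)``;
    temperature follows a seasonal sinusoid with a warm-anomaly window placed
    mid-summer; PAR follows a diel half-sinusoid whose daily integral equals
    the day's DLI.  Bit-identical under a fixed (config, seed).
    """
    if n_days < 28:
        raise ValueError("n_days must be >= 28")
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate site ids")
    if len({s.distance_km for s in sites}) < 2:
        raise ValueError("need >= 2 sites with distinct distances")
    wq = truth.wq
    start_ts = pd.Timestamp(start)
    days = np.arange(n_days)
    doy = (start_ts.dayofyear + days) % 365.25
    # southern-hemisphere summer peak around mid-January (doy ~15)
    season = np.cos(2 * np.pi * (doy - 15) / 365.25)
    temp_clim = wq.temp_mean + wq.temp_seasonal_amp * season
    anomaly = np.zeros(n_days)
    peak_days = np.where(season > 0.995)[0]
    if len(peak_days) and wq.anomaly_days > 0:
        a0 = int(peak_days[0])
        anomaly[a0 : a0 + wq.anomaly_days] = wq.anomaly_delta
    dli_clim = np.maximum(wq.ambient_dli + wq.dli_seasonal_amp * season, 0.3)

    tod = np.arange(STEPS_PER_DAY) * SECONDS_PER_STEP / 3600.0  # hours
    diel = np.where(
        (tod >= 6) & (tod <= 18), np.sin(np.pi * (tod - 6) / 12.0), 0.0
    )

    out = {}
    for i, site in enumerate(sites):
        rng = np.random.default_rng([seed, i])
        p0 = site_pressure(truth, site.distance_km)
        press = p0 * rng.lognormal(0.0, wq.noise_sd, n_days)
        dli = dli_clim * rng.lognormal(0.0, 0.1, n_days) * np.exp(-press)
        temp_day = temp_clim + anomaly + rng.normal(0.0, 0.15, n_days)
        sed_day = np.clip(
            wq.ambient_sed
            + (1 - wq.ambient_sed) * (1 - np.exp(-press))
            + rng.normal(0.0, 0.02, n_days),
            0.0,
            1.0,
        )
        ntu_day = wq.ntu_base + wq.ntu_scale * press

        pmax = dli / HALF_SINE_FACTOR
        par = (pmax[:, None] * diel[None, :]).ravel()
        par *= rng.lognormal(0.0, 0.05, par.shape)
        temp = np.repeat(temp_day, STEPS_PER_DAY) + 0.2 * np.repeat(
            np.ones(n_days), STEPS_PER_DAY
        ) * np.tile(np.sin(2 * np.pi * tod / 24.0), n_days)
        ntu = np.repeat(ntu_day, STEPS_PER_DAY) * rng.lognormal(0.0, 0.3, n_days * STEPS_PER_DAY)
        # occasional sensor artefacts: spikes and small negative excursions
        n_steps = n_days * STEPS_PER_DAY
        spikes = rng.random(n_steps) < 5e-4
        ntu = np.where(spikes, ntu * 25 + 5, ntu)
        negs = rng.random(n_steps) < 3e-4
        ntu = np.where(negs, -rng.uniform(0.05, 0.5, n_steps), ntu)
        sed = np.clip(
            np.repeat(sed_day, STEPS_PER_DAY) + rng.normal(0, 0.005, n_steps), 0.0, 1.0
        )
        idx = pd.date_range(start_ts, periods=n_steps, freq="10min")
        out[site.site_id] = pd.DataFrame(
            {"ntu": ntu, "par": par, "temp_c": temp, "sed_index": sed}, index=idx
        )
    return out


# ---------------------------------------------------------------------------
# colony-health simulation
# ---------------------------------------------------------------------------


def survey_dates_for(wq_frame: pd.DataFrame, survey_interval_days: int):
    start = wq_frame.index[0].normalize()
    end = wq_frame.index[-1].normalize()
    return pd.date_range(start, end, freq=f"{survey_interval_days}D")


def simulate_health_trajectories(
    wq: dict,
    sites,
    n_branching: int,
    n_massive: int,
    truth: GroundTruth,
    survey_interval_days: int,
    seed: int,
    return_latent: bool = False,
):
    """Simulate per-colony categorical score trajectories.

    Per colony per survey interval: bleaching drawn from the gated
    light × temperature logistic; a partial-mortality event from the
    group-specific incidence logistic (with persistent site and colony
    random intercepts); loss given an event from the conditional beta
    distribution.  Cumulative mortality is non-decreasing and is emitted on
    the 7-category scale via the inverse midpoint binning (so sub-category
    losses may not register as score changes).  With
    ``return_latent=True`` also returns the latent event table (true
    probabilities, events and continuous losses) for recovery testing.
    """
    if survey_interval_days < 7:
        raise ValueError("survey_interval_days must be >= 7")
    if n_branching < 1 or n_massive < 1:
        raise ValueError("colony counts must be >= 1")
    rng = np.random.default_rng([seed, 9999])
    site_map = {s.site_id: s for s in sites}

    panel_rows, latent_rows = [], []
    for si, (site_id, frame) in enumerate(sorted(wq.items())):
        site = site_map[site_id]
        dates = survey_dates_for(frame, survey_interval_days)
        daily, summary = waterquality.process_site(frame, dates, site_id=site_id)
        srng = np.random.default_rng([seed, si, 1])
        u_site = srng.normal(0.0, truth.re_sd_site) if truth.re_sd_site > 0 else 0.0
        colonies = [("branching", j) for j in range(n_branching)] + [
            ("massive", j) for j in range(n_massive)
        ]
        for group, j in colonies:
            crng = np.random.default_rng([seed, si, 2, 0 if group == "branching" else 1, j])
            u_col = crng.normal(0.0, truth.re_sd_colony) if truth.re_sd_colony > 0 else 0.0
            excluded_from = None
            if truth.exclusion_rate > 0 and crng.random() < truth.exclusion_rate:
                excluded_from = int(crng.integers(1, max(2, len(dates))))
            colony_id = f"{site_id}-{group[0].upper()}{j + 1:02d}"
            m = 0.0  # cumulative dead fraction
            bleach_score = 1
            bleached_latent = 0
            for t, date in enumerate(dates):
                excl = excluded_from is not None and t >= excluded_from
                m_start = m
                if t > 0:
                    row = summary.iloc[t - 1]
                    light = row["light_worst"]
                    temp = row["temp_worst"]
                    sed = row["sed_worst"]
                    if np.isnan(light) or np.isnan(temp):
                        light, temp, sed = truth.wq.ambient_dli, truth.wq.temp_mean, 0.0
                    # bleaching
                    p_b = float(bleach_probability(truth, temp, light, group))
                    bleach_event = 0
                    if bleach_score == 1 and m < 1.0:
                        bleach_event = int(crng.random() < p_b)
                        if bleach_event:
                            bleach_score = 4
                            bleached_latent = 1
                    else:
                        bleach_score = max(1, bleach_score - 2)  # recovery
                    # mortality
                    p_m = float(
                        incidence_probability(
                            truth, group, light, temp, sed, bleached_latent,
                            re=u_site + u_col,
                        )
                    )
                    mort_event = int(m < 1.0 and crng.random() < p_m)
                    loss = 0.0
                    if mort_event:
                        mu = float(loss_mean(truth, group, bleached_latent))
                        lc = truth.loss[group]
                        if lc.dispersion is None:
                            loss = mu
                        else:
                            a = mu * lc.dispersion
                            b = (1 - mu) * lc.dispersion
                            loss = float(crng.beta(max(a, 1e-6), max(b, 1e-6)))
                        m = min(1.0, m + loss)
                    latent_rows.append(
                        {
                            "colony_id": colony_id,
                            "site_id": site_id,
                            "group": group,
                            "interval_idx": t - 1,
                            "cum_mortality_start": m_start,
                            "light": light,
                            "temp": temp,
                            "sed": sed,
                            "p_bleach": p_b,
                            "bleach_event": bleach_event,
                            "bleached_status": bleached_latent,
                            "p_mort": p_m,
                            "mort_event": mort_event,
                            "loss": loss,
                            "excluded": excl,
                        }
                    )
                mort_score = colonyscoring.proportion_to_score(m)
                sed_cover = 1
                if group == "massive" and t > 0:
                    sed_cover = int(
                        colonyscoring.proportion_to_score(
                            min(1.0, max(0.0, sed * 0.5 + crng.normal(0, 0.03)))
                        )
                    )
                panel_rows.append(
                    {
                        "colony_id": colony_id,
                        "site_id": site_id,
                        "group": group,
                        "survey_idx": t,
                        "survey_date": date,
                        "mort_score": int(mort_score),
                        "bleach_score": int(bleach_score),
                        "sedcover_score": sed_cover,
                        "excluded": excl,
                        "excluded_reason": "dislodged" if excl else "",
                    }
                )
    panel = pd.DataFrame(panel_rows)
    if return_latent:
        return panel, pd.DataFrame(latent_rows)
    return panel


# ---------------------------------------------------------------------------
# config serialization
# ---------------------------------------------------------------------------


def truth_to_yaml(truth: GroundTruth, path):
    d = asdict(truth)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def truth_from_yaml(path) -> GroundTruth:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["bleach"] = BleachCoefs(**d["bleach"])
    d["incidence"] = {g: IncidenceCoefs(**v) for g, v in d["incidence"].items()}
    d["loss"] = {g: LossCoefs(**v) for g, v in d["loss"].items()}
    d["wq"] = WQDecay(**d["wq"])
    return GroundTruth(**d)


def write_wq_csvs(wq: dict, outdir):
    """One CSV per site: ISO-8601 timestamp, ntu, par_umol_m2_s, temp_c, sed_index."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for site_id, frame in wq.items():
        df = frame.rename(columns={"par": "par_umol_m2_s"})
        df.index.name = "timestamp"
        df.to_csv(outdir / f"wq_{site_id}.csv", float_format="%.5g")
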