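"""End-to-end pipeline: generate → derive → fit → compose → classify.

A configured run writes every stage product (CSV/JSON tables, model
summaries, optional figures) into a run directory together with a structured
log, a config snapshot and a manifest of SHA-256 checksums.  All stochastic
stages take explicit seeds from the config, so rerunning the same config
reproduces the manifest checksums of all data products.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import (
    colonyscoring,
    cumulative,
    distance,
    fullsubsets,
    hurdlefit,
    pathsem,
    synthgen,
    waterquality,
)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    outdir: str = "seditherm_run"
    n_sites: int = 17
    n_days: int = 530
    survey_interval_days: int = 14
    n_branching: int = 10
    n_massive: int = 23
    n_draws: int = 1000
    k: int = 5
    t_high: float = 31.0
    t_low: float = 25.0
    l_high: float = 8.8
    light_grid_step: float = 0.05
    parsimony_window: float = 2.0
    latch_bleached: bool = True
    groups: tuple = ("branching", "massive")
    figures: bool = False
    seeds: dict = field(
        default_factory=lambda: {"synthgen": 1, "health": 2, "draws": 3, "distance": 4}
    )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        return cls(**d)


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig, truth: synthgen.GroundTruth | None = None) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logf = open(out / "run.log", "w")

    def log(stage_name, **kv):
        msg = f"{stage_name} " + " ".join(f"{k}={v}" for k, v in kv.items())
        logf.write(msg + "\n")
        logf.flush()

    stage = "config"
    try:
        config.to_yaml(out / "config.yaml")
        truth = truth or synthgen.default_truth()
        synthgen.truth_to_yaml(truth, out / "truth.yaml")

        stage = "synthgen"
        sites = synthgen.default_sites(config.n_sites)
        wq = synthgen.generate_water_quality(
            sites, config.n_days, truth, seed=config.seeds["synthgen"]
        )
        log(stage, seed=config.seeds["synthgen"], sites=len(sites), days=config.n_days)
        panel = synthgen.simulate_health_trajectories(
            wq,
            sites,
            config.n_branching,
            config.n_massive,
            truth,
            config.survey_interval_days,
            seed=config.seeds["health"],
        )
        panel.to_csv(out / "colony_panel.csv", index=False)
        log("health", seed=config.seeds["health"], rows=len(panel))

        stage = "waterquality"
        summaries, dailies = [], []
        for site_id, frame in sorted(wq.items()):
            dates = synthgen.survey_dates_for(frame, config.survey_interval_days)
            daily, summary = waterquality.process_site(frame, dates, site_id=site_id)
            daily = daily.assign(site_id=site_id)
            dailies.append(daily)
            summaries.append(summary)
        daily_all = pd.concat(dailies)
        daily_all.index.name = "date"
        daily_all.to_csv(out / "daily_metrics.csv", float_format="%.6g")
        pressure = pd.concat(summaries, ignore_index=True)
        pressure.to_csv(out / "pressure_summary.csv", index=False, float_format="%.6g")
        log(stage, rows=len(pressure))

        stage = "colonyscoring"
        events = colonyscoring.derive_events(panel, latch_bleached=config.latch_bleached)
        events.to_csv(out / "events.csv", index=False, float_format="%.6g")
        summary = colonyscoring.endpoint_summary(panel)
        (out / "endpoint_summary.json").write_text(json.dumps(summary, indent=2))
        log(stage, events=int(events["mort_event"].sum()), rows=len(events))

        stage = "hurdlefit"
        pressure_keyed = pressure.rename(
            columns={"light_worst": "light", "temp_worst": "temp", "sed_worst": "sed"}
        )[["site_id", "interval_idx", "light", "temp", "sed"]]
        cells = colonyscoring.site_bleach_binomial(events).merge(
            pressure_keyed, on=["site_id", "interval_idx"]
        ).dropna(subset=["light", "temp"])
        bleach_model = hurdlefit.BleachingModel(k=config.k).fit(cells)
        ev = events.merge(pressure_keyed, on=["site_id", "interval_idx"]).dropna(
            subset=["light", "temp"]
        )
        models = {}
        for group in config.groups:
            evg = ev[ev["group"] == group]
            preds = ("light", "temp", "sed") if group == "massive" else ("light", "temp")
            inc = hurdlefit.IncidenceModel(predictors=preds, k=config.k).fit(evg)
            loss_rows = evg[evg["mort_event"] == 1].copy()
            loss_rows = loss_rows[loss_rows["loss"] > 0]
            loss = hurdlefit.LossModel(k=config.k, min_rows=10).fit(loss_rows)
            models[group] = {"bleach": bleach_model, "incidence": inc, "loss": loss}
            log(
                stage,
                group=group,
                inc_aicc=round(inc.aicc_, 2),
                loss_aicc=round(loss.aicc_, 2),
            )
        _write_model_summaries(models, out / "models.json")

        stage = "fullsubsets"
        for group in config.groups:
            evg = ev[ev["group"] == group]
            pool = ["light", "temp", "sed"] if group == "massive" else ["light", "temp"]
            corr = evg[pool].corr()
            cand = fullsubsets.enumerate_candidates(pool, corr, max_size=3)
            fitted = {}
            for c in cand.candidates:
                terms = [f"s({p}, k={config.k})" for p in c.predictors] or ["1"]
                formula = "mort_event ~ " + " + ".join(terms)
                fitted[c.label] = hurdlefit.IncidenceModel(formula=formula).fit(evg)
            table = fullsubsets.compare(fitted)
            table.to_csv(out / f"fullsubsets_{group}.csv", index=False, float_format="%.6g")
            pd.Series(table.attrs["importance"]).rename("importance").to_csv(
                out / f"importance_{group}.csv", float_format="%.6g"
            )
            log(stage, group=group, best=fullsubsets.select_best(table, config.parsimony_window))

        stage = "pathsem"
        for group in config.groups:
            tab = _site_survey_means(ev, pressure, group, panel)
            dag = pathsem.default_dag(group)
            nodes = [n for n in dag.nodes if n != dag.sink]
            try:
                std = pathsem.standardize(
                    tab[nodes + ["mortality_mean"]], response="mortality_mean"
                )
                fit = pathsem.PathAnalysis(dag=dag).fit(std)
            except ValueError as err:
                log(stage, group=group, skipped=repr(err))
                continue
            pd.Series(fit.total_effects_).rename("total_effect").to_csv(
                out / f"path_totals_{group}.csv", float_format="%.6g"
            )
            pd.Series(
                {f"{a}->{b}": v for (a, b), v in fit.edge_coefs_.items()}
            ).rename("coef").to_csv(out / f"path_edges_{group}.csv", float_format="%.6g")
            log(stage, group=group, n=fit.n_obs_)

        stage = "cumulative"
        sed_map = cumulative.fit_sedimentation_light_map(pressure)
        thresholds = {}
        for group in config.groups:
            grid = np.round(
                np.arange(config.l_high, 0.1 - 1e-9, -config.light_grid_step), 4
            )
            cfg = cumulative.ScenarioConfig(
                light_grid=grid,
                t_high=config.t_high,
                t_low=config.t_low,
                l_high=config.l_high,
                group=group,
                n_draws=config.n_draws,
                seed=config.seeds["draws"],
                sed_map=sed_map,
            )
            pred = cumulative.scenario_curves(models[group], cfg)
            pred.summary().to_csv(
                out / f"scenario_{group}.csv", index=False, float_format="%.6g"
            )
            thresholds[group] = _jsonable(cumulative.light_thresholds(pred))
            if config.figures:
                _plot_scenario(pred, out / f"scenario_{group}.png")
            log(stage, group=group, crossover=thresholds[group]["l_crossover"])
        (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2))

        stage = "distance"
        dist = pd.Series({s.site_id: s.distance_km for s in sites})
        ed_results = {}
        dates = synthgen.survey_dates_for(next(iter(wq.values())), config.survey_interval_days)
        for group in config.groups:
            ed_results[group] = {}
            for temp in (config.t_high, config.t_low):
                sl = distance.predict_site_loss(
                    models[group],
                    pressure,
                    temp,
                    group=group,
                    sed_map=sed_map if group == "massive" else None,
                    survey_dates=dates,
                )
                if sl.empty or sl["site_id"].map(dist).nunique() < 5:
                    ed_results[group][f"T{temp:g}"] = {"ed_km": None, "note": "insufficient data"}
                    continue
                dm = distance.DistanceDecayModel(k=config.k).fit(sl, dist)
                ed = dm.effect_distance(seed=config.seeds["distance"])
                ed_results[group][f"T{temp:g}"] = _jsonable(ed)
                pd.DataFrame({"distance_km": dm.grid_km_, "loss": dm.curve_}).to_csv(
                    out / f"distance_curve_{group}_T{temp:g}.csv",
                    index=False,
                    float_format="%.6g",
                )
                log(stage, group=group, temp=temp, ed_km=ed["ed_km"])
        (out / "effect_distance.json").write_text(json.dumps(ed_results, indent=2))

        stage = "manifest"
        manifest = {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name not in ("manifest.json", "run.log")
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log("done", files=len(manifest))
        return manifest
    except Exception as exc:  # noqa: BLE001 - abort with stage name and partial manifest
        partial = {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name not in ("manifest.json", "run.log")
        }
        (out / "manifest.partial.json").write_text(json.dumps(partial, indent=2))
        log("abort", stage=stage, error=repr(exc))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logf.close()


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (tuple, list)):
            out[k] = [None if x is None else float(x) for x in v]
        elif v is None:
            out[k] = None
        else:
            out[k] = float(v)
    return out


def _site_survey_means(
    ev: pd.DataFrame, pressure: pd.DataFrame, group: str, panel: pd.DataFrame
) -> pd.DataFrame:
    evg = ev[ev["group"] == group]
    agg = (
        evg.groupby(["site_id", "interval_idx"])
        .agg(
            mortality_mean=("loss", "mean"),
            bleaching=("bleached_status", "mean"),
        )
        .reset_index()
    )
    pk = pressure.rename(
        columns={
            "ssc_proxy": "ssc",
            "light_worst": "light",
            "sed_worst": "sedimentation",
            "temp_worst": "temperature",
        }
    )
    tab = agg.merge(pk, on=["site_id", "interval_idx"]).dropna(
        subset=["ssc", "light", "sedimentation", "temperature"]
    )
    if group == "massive":
        # observed sediment-cover score means at the interval's closing survey
        pg = panel[panel["group"] == group].copy()
        pg["interval_idx"] = pg["survey_idx"] - 1
        pg["sediment_cover"] = colonyscoring.score_to_midpoint(pg["sedcover_score"])
        cover = (
            pg[pg["interval_idx"] >= 0]
            .groupby(["site_id", "interval_idx"])["sediment_cover"]
            .mean()
            .reset_index()
        )
        tab = tab.merge(cover, on=["site_id", "interval_idx"], how="left").dropna(
            subset=["sediment_cover"]
        )
    return tab


def _write_model_summaries(models: dict, path):
    out = {}
    for group, trio in models.items():
        out[group] = {
            name: {
                "coef": dict(zip(m.coef_names_, map(float, m.coef_))),
                "re_sd": m.re_sd_,
                "loglik": m.loglik_,
                "aicc": m.aicc_,
                "n_obs": m.n_obs_,
            }
            for name, m in trio.items()
        }
    pathlib.Path(path).write_text(json.dumps(out, indent=2))


def _plot_scenario(pred, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = pred.summary()
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 7), sharex=True)
    for name, color in [("dredging", "k"), ("cumulative", "r"), ("additive", "b")]:
        ax1.plot(s["light"], s[f"{name}_med"], color=color, label=name)
        ax1.fill_between(s["light"], s[f"{name}_lo"], s[f"{name}_hi"], color=color, alpha=0.15)
    ax1.set_ylabel("fortnightly loss")
    ax1.legend()
    ax2.plot(s["light"], s["interaction_med"], "purple")
    ax2.fill_between(
        s["light"], s["interaction_lo"], s["interaction_hi"], color="purple", alpha=0.15
    )
    ax2.axhline(0, color="grey", lw=0.5)
    ax2.set_xlabel("light (mol photons m$^{-2}$ d$^{-1}$)")
    ax2.set_ylabel("cumulative − additive")
    ax2.invert_xaxis()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
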