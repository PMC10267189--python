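"""Pipeline orchestration, configuration, file formats and logging.

Stage order: simulate/ingest → preprocess → network (CCM) → jacobians
(MDR S-map) → stability → stats.  Every stage persists its artifacts as
CSV/JSON under the output directory, so a failed run keeps completed
stages and ``resume=True`` picks up where it stopped.  A manifest records
the configuration, seed and per-stage timing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ccm import infer_network, network_metrics
from .mdr import ALPHA_GRID, LAMBDA_GRID, THETA_GRID, estimate_jacobians
from .preprocess import (AbundanceTable, TrophicAssignment, fill_missing,
                         filter_rare, zscore)
from .stability import stability_table
from .synth import SimConfig, simulate_foodweb
from .effects import CROSSED, SITE_ONLY, fit_mixed_model, fit_per_web_models

log = logging.getLogger("foodwebedm")

__all__ = ["PipelineConfig", "run_pipeline", "read_inputs", "STAGES"]

STAGES = ("simulate", "preprocess", "network", "jacobians", "stability",
          "stats")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults reproduce the study settings:
    E examined from 2–9, 100 seasonal surrogates, lags 0 to −2, 1000
    candidate / 100 kept SSRs, CV window 6 (sensitivity 12), rare-species
    window 6 (sensitivity 8)."""

    # inputs: either paths to CSVs, or a simulation config
    abundance_csv: str | None = None
    trophic_csv: str | None = None
    simulate: SimConfig | None = field(default_factory=SimConfig)
    # preprocessing
    rare_window: int = 6
    rare_min_nonzero: int = 1
    rare_mode: str = "blocks"
    include_rare: bool = False
    # EDM / CCM
    E_min: int = 2
    E_max: int = 9
    library_start: int = 10
    library_step: int = 5
    n_surrogates: int = 100
    n_subsamples: int = 100
    lags: tuple = (0, -1, -2)
    # MDR S-map
    theta_grid: tuple = THETA_GRID
    lambda_grid: tuple = LAMBDA_GRID
    alpha_grid: tuple = ALPHA_GRID
    n_ssr_candidates: int = 1000
    n_ssr_keep: int = 100
    # stability
    cv_window: int = 6
    sensitivity: bool = False
    # stats
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.sensitivity:
            self.cv_window = 12
            self.rare_window = 8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**sim) if isinstance(sim, dict) else None
        if raw.get("abundance_csv"):
            cfg.simulate = None
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def read_inputs(abundance_csv, trophic_csv):
    """Load and validate the abundance panel and trophic assignment."""
    table = AbundanceTable.read_csv(abundance_csv)
    trophic = TrophicAssignment.read_csv(trophic_csv)
    unknown = [sp for sp in trophic.levels if sp not in table.species]
    if unknown:
        log.warning("trophic table lists unknown species: %s", unknown)
    trophic.validate_against(table)
    return table, trophic


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_json_default))


class _Runner:
    def __init__(self, config: PipelineConfig, resume: bool):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self.timings = {}

    def stage(self, name, marker, fn):
        marker = self.out / marker
        if self.resume and marker.exists():
            log.info("stage %s: outputs exist, skipping (resume)", name)
            return
        log.info("stage %s: start", name)
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at stage {name!r}: {exc}"
                               ) from exc
        self.timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.1fs", name, self.timings[name])


def run_pipeline(config: PipelineConfig, resume: bool = False,
                 until: str = "stats") -> dict:
    """Execute the pipeline and return the bundle of in-memory results.

    ``until`` stops after the named stage (inclusive).  All artifacts are
    written under ``config.out_dir``.
    """
    r = _Runner(config, resume)
    out = r.out
    bundle: dict = {"out_dir": str(out)}
    last = STAGES.index(until)

    # ---- simulate / ingest ------------------------------------------------
    def do_ingest():
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            table, truth = simulate_foodweb(sim)
            trophic = TrophicAssignment(dict(zip(truth.species,
                                                 truth.levels)))
            truth_dir = out / "truth"
            truth_dir.mkdir(exist_ok=True)
            pd.DataFrame(truth.true_adjacency, index=truth.species,
                         columns=truth.species).to_csv(
                             truth_dir / "adjacency.csv")
            n_t, s, _ = truth.true_jacobians.shape
            t_i, i_i, j_i = np.meshgrid(range(n_t), range(s), range(s),
                                        indexing="ij")
            pd.DataFrame({"t": t_i.ravel(), "i": i_i.ravel(),
                          "j": j_i.ravel(),
                          "value": truth.true_jacobians.ravel()}
                         ).to_csv(truth_dir / "jacobians.csv", index=False)
            bundle["truth"] = truth
        else:
            if not (config.abundance_csv and config.trophic_csv):
                raise ValueError("need abundance_csv and trophic_csv when "
                                 "not simulating")
            table, trophic = read_inputs(config.abundance_csv,
                                         config.trophic_csv)
        table.to_csv(out / "abundance.csv")
        trophic.to_frame().to_csv(out / "trophic.csv", index=False)
        bundle["raw_table"] = table
        bundle["trophic"] = trophic

    r.stage("simulate", "abundance.csv", do_ingest)
    if "raw_table" not in bundle:
        bundle["raw_table"] = AbundanceTable.read_csv(out / "abundance.csv")
        bundle["trophic"] = TrophicAssignment.read_csv(out / "trophic.csv")
    if last < 1:
        _finish(r, config, out)
        return bundle

    # ---- preprocess -------------------------------------------------------
    def do_preprocess():
        table, n_filled = fill_missing(bundle["raw_table"])
        if not config.include_rare:
            table = filter_rare(table, config.rare_min_nonzero,
                                config.rare_window, config.rare_mode)
        if not table.species:
            raise ValueError("rare-species filter removed every species")
        std, raw = zscore(table)
        std.to_csv(out / "standardised.csv")
        raw.to_csv(out / "preprocessed.csv")
        bundle["std_table"] = std
        bundle["table"] = raw
        bundle["n_filled"] = n_filled

    r.stage("preprocess", "standardised.csv", do_preprocess)
    if "std_table" not in bundle:
        bundle["std_table"] = AbundanceTable.read_csv(
            out / "standardised.csv", standardised=True)
        bundle["table"] = AbundanceTable.read_csv(out / "preprocessed.csv")
    if last < 2:
        _finish(r, config, out)
        return bundle

    std, raw, trophic = bundle["std_table"], bundle["table"], bundle["trophic"]

    # ---- CCM network ------------------------------------------------------
    def do_network():
        nets, metrics, E_by = {}, {}, {}
        edge_frames = []
        for site in std.sites:
            panel = std.site_panel(site)
            net, E_map = infer_network(
                panel, seed=config.seed,
                E_range=range(config.E_min, config.E_max + 1),
                lags=config.lags, n_surrogates=config.n_surrogates,
                n_subsamples=config.n_subsamples)
            nets[site] = net
            E_by[site] = E_map
            metrics[site] = network_metrics(net, trophic)
            frame = net.to_frame()
            frame.insert(0, "site", site)
            edge_frames.append(frame)
            net.adjacency().to_csv(out / f"adjacency_{site}.csv")
        pd.concat(edge_frames).to_csv(out / "edges.csv", index=False)
        _write_json(out / "network_metrics.json", metrics)
        _write_json(out / "embedding_dimensions.json", E_by)
        bundle["networks"] = nets
        bundle["network_metrics"] = metrics
        bundle["E_by_site"] = E_by

    r.stage("network", "edges.csv", do_network)
    if last < 3:
        _finish(r, config, out)
        return bundle

    # ---- MDR S-map Jacobians ---------------------------------------------
    def do_jacobians():
        jacs = {}
        frames = []
        hyper = {}
        for site in std.sites:
            jac = estimate_jacobians(
                bundle["networks"][site], std.site_panel(site),
                theta_grid=config.theta_grid,
                lambda_grid=config.lambda_grid,
                alpha_grid=config.alpha_grid, seed=config.seed,
                E_by_species=bundle["E_by_site"][site],
                n_candidates=config.n_ssr_candidates,
                n_keep=config.n_ssr_keep)
            jacs[site] = jac
            frame = jac.to_frame()
            frame.insert(0, "site", site)
            frames.append(frame)
            hyper[site] = jac.hyperparams
        pd.concat(frames).to_csv(out / "jacobians.csv", index=False)
        _write_json(out / "smap_hyperparams.json", hyper)
        bundle["jacobians"] = jacs

    r.stage("jacobians", "jacobians.csv", do_jacobians)
    if last < 4:
        _finish(r, config, out)
        return bundle

    # ---- stability metrics ------------------------------------------------
    def do_stability():
        trophic.validate_against(raw)
        frames = []
        for site in raw.sites:
            jac = bundle.get("jacobians", {}).get(site)
            frames.append(stability_table(
                raw.site_panel(site), raw.site_temperature(site), jac,
                trophic, window=config.cv_window, site=site))
        stab = pd.concat(frames).reset_index()
        stab.to_csv(out / "stability.csv", index=False)
        bundle["stability"] = stab

    r.stage("stability", "stability.csv", do_stability)
    if "stability" not in bundle:
        bundle["stability"] = pd.read_csv(out / "stability.csv")
    if last < 5:
        _finish(r, config, out)
        return bundle

    # ---- effect estimation ------------------------------------------------
    def do_stats():
        stab = bundle["stability"].copy()
        multi_site = stab["site"].nunique() > 1
        # the seasonal panel carries year/season back in for random effects
        idx = raw.data.index.to_frame(index=False)
        stab = stab.merge(
            idx.assign(t=idx.groupby("site").cumcount()),
            on=["site", "t"], how="left")
        pairs = []
        for resp, spec in (("TrJ", CROSSED),
                           ("contribution_producer", CROSSED),
                           ("contribution_consumer", CROSSED),
                           ("contribution_predator", CROSSED),
                           ("ln_cv_community", SITE_ONLY),
                           ("phi_community", SITE_ONLY)):
            if resp not in stab.columns:
                continue
            for pred in ("ln_temperature_F", "ln_richness", "simpson"):
                pairs.append((resp, pred, spec))
        rows = []
        for resp, pred, spec in pairs:
            try:
                est = fit_mixed_model(stab, resp, pred,
                                      random_spec=spec) if multi_site \
                    else _single_site_ols(stab, resp, pred)
            except ValueError as exc:
                log.warning("skipping %s ~ %s: %s", resp, pred, exc)
                continue
            rows.append({"response": resp, "predictor": pred,
                         "slope": est.slope, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "p_value": est.p_value,
                         "random_spec": est.random_spec, "n_obs": est.n_obs})
            if multi_site:
                per_web, summary = fit_per_web_models(stab, resp, pred)
                rows[-1].update({"n_webs_negative": summary["n_negative"],
                                 "n_webs_positive": summary["n_positive"]})
        effects = pd.DataFrame(rows)
        effects.to_csv(out / "effects.csv", index=False)
        bundle["effects"] = effects

    r.stage("stats", "effects.csv", do_stats)
    _finish(r, config, out)
    return bundle


def _single_site_ols(stab, resp, pred):
    from .effects import EffectEstimate
    import statsmodels.api as sm
    sub = stab[[resp, pred]].replace([np.inf, -np.inf], np.nan).dropna()
    if len(sub) < 3 or np.ptp(sub[pred].to_numpy()) == 0:
        raise ValueError(f"insufficient data for {resp} ~ {pred}")
    fit = sm.OLS(sub[resp], sm.add_constant(sub[pred])).fit()
    conf = fit.conf_int()
    return EffectEstimate(
        response=resp, predictor=pred, slope=float(fit.params[pred]),
        ci_low=float(conf.loc[pred, 0]), ci_high=float(conf.loc[pred, 1]),
        p_value=float(fit.pvalues[pred]), random_spec="none (OLS)",
        n_obs=len(sub))


def _finish(runner: _Runner, config: PipelineConfig, out: Path) -> None:
    manifest = {
        "package": "foodwebedm",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stage_seconds": runner.timings,
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _write_json(out / "manifest.json", manifest)
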