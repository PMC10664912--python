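"""End-to-end orchestration: simulate (optional) -> harmonize -> weight ->
synthetic population -> ratios -> baselines -> report.

A run is driven by a single hierarchical config (YAML/dict), writes plain
delimited-text and JSON outputs into one directory, and records a manifest
(config hash, seeds, input digests, per-stage record counts, solver
diagnostics, chosen hyperparameters, timestamps). Given identical config and
seeds the numeric tables are byte-identical across runs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import baselines as bl
from . import harmonize as hz
from . import ratios as rt
from . import simulate as sim
from . import synthpop as sp
from . import weighting as wt


class ConfigError(ValueError):
    pass


_TOP_KEYS = {"seed", "simulate", "inputs", "weighting", "baselines", "output"}


def _validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "simulate" not in config and "inputs" not in config:
        raise ConfigError("config needs either a 'simulate' or an 'inputs' section")
    cfg = {
        "seed": int(config.get("seed", 0)),
        "simulate": config.get("simulate"),
        "inputs": config.get("inputs"),
        "weighting": dict(config.get("weighting") or {}),
        "baselines": dict(config.get("baselines") or {}),
        "output": dict(config.get("output") or {}),
    }
    for section, allowed in (
        ("weighting", {"eps_rel", "eps_abs", "maxiter"}),
        ("baselines", {"n_runs", "hyperparameters", "search", "n_splits",
                       "test_fraction", "grid_axes", "pool", "objective_mode", "min_train"}),
        ("output", {"use_raw_masses", "marginalize"}),
    ):
        bad = set(cfg[section]) - allowed
        if bad:
            raise ConfigError(f"unknown keys in {section!r}: {sorted(bad)}")
    return cfg


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return _validate_config(yaml.safe_load(fh))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured pipeline, writing all artifacts to ``out_dir``.

    Raises :class:`ConfigError` before any computation if the config is
    malformed; any stage error aborts with the manifest written as far as it
    got.
    """
    cfg = _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": cfg["seed"],
        "stages": {},
    }

    def stamp(stage: str, **info) -> None:
        manifest["stages"][stage] = {
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            **info,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        # ---- inputs -------------------------------------------------------
        if cfg["simulate"] is not None:
            scfg = sim.ScenarioConfig(**{**cfg["simulate"], "seed": cfg["seed"]})
            data = sim.simulate_scenario(scfg)
            scheme = data.truth.scheme
            survey_raw, register_raw, targets = data.survey, data.register, data.marginals
            survey_raw.to_csv(out / "survey.csv", index=False)
            register_raw.to_csv(out / "register.csv", index=False)
            data.truth.cells.to_csv(out / "truth.csv", index=False)
            marg = {f: dict(c) for f, c in targets.proportions.items()}
            marg["N_pop"] = targets.n_pop
            (out / "marginals.json").write_text(json.dumps(marg, indent=2))
            stamp("simulate", survey_rows=len(survey_raw), register_rows=len(register_raw),
                  inputs="simulated")
        else:
            paths = {k: Path(v) for k, v in cfg["inputs"].items()}
            survey_raw = _read_table(paths["survey"])
            register_raw = _read_table(paths["register"])
            targets = hz.MarginalTargets.from_dict(
                json.loads(Path(paths["marginals"]).read_text())
            )
            scheme = targets.implied_scheme()
            stamp("inputs", digests={k: _digest(p) for k, p in paths.items()})

        # ---- harmonize ----------------------------------------------------
        sample, survey_report = hz.filter_survey(survey_raw, scheme)
        register, register_report = hz.filter_accidents(register_raw, scheme)
        sample.values.to_csv(out / "harmonized_survey.csv", index=False)
        register.records.to_csv(out / "harmonized_register.csv", index=False)
        (out / "filter_report.json").write_text(json.dumps(
            {"survey": survey_report.to_dict(), "register": register_report.to_dict()},
            indent=2))
        stamp("harmonize", survey_retained=sample.S, register_retained=register.M)

        # ---- weighting ----------------------------------------------------
        settings = wt.SolverSettings(**cfg["weighting"])
        Y = wt.build_indicator_matrix(sample, scheme)
        w = wt.solve_weights(Y, targets, settings)
        pd.DataFrame({"instance": range(w.S), "weight": w.w}).to_csv(
            out / "weights.csv", index=False)
        (out / "weight_diagnostics.json").write_text(json.dumps(w.diagnostics, indent=2))
        stamp("weighting", **w.diagnostics, iterations=w.n_iter)

        # ---- synthetic population -----------------------------------------
        pop = sp.weights_to_population(sample, w, scheme, targets.n_pop)
        pop.table.to_csv(out / "population.csv", index=False)
        stamp("synthpop", n_pop=pop.n_pop, cells=pop.L,
              marginals=sp.population_marginals(pop))

        # ---- ratios -------------------------------------------------------
        use_raw = bool(cfg["output"].get("use_raw_masses", False))
        ratio_table = rt.compute_ratios(register, pop, use_raw_masses=use_raw)
        ratio_table.table.to_csv(out / "ratios.csv", index=False)
        marg_req = cfg["output"].get("marginalize")
        if marg_req:
            agg = rt.aggregate_ratios(ratio_table, list(marg_req))
            agg.table.to_csv(out / "ratios_aggregated.csv", index=False)
        stamp("ratios", cells=len(ratio_table.table),
              valid_cells=int(ratio_table.table["valid"].sum()),
              accidents=int(ratio_table.table["accidents"].sum()))

        # ---- baselines ----------------------------------------------------
        bcfg = cfg["baselines"]
        params = bcfg.get("hyperparameters")
        if bcfg.get("search"):
            grid = bl.HyperparameterGrid(axes=bcfg["grid_axes"]) if bcfg.get("grid_axes") \
                else bl.HyperparameterGrid()
            sel = bl.search_hyperparameters(
                ratio_table, grid,
                n_splits=int(bcfg.get("n_splits", 100)),
                test_fraction=float(bcfg.get("test_fraction", 0.33)),
                seed=cfg["seed"], pool=int(bcfg.get("pool", 100)))
            sel.scores.to_csv(out / "selection_scores.csv", index=False)
            (out / "selection.json").write_text(json.dumps(sel.chosen, indent=2))
            params = sel.chosen
        baseline_table = bl.predict_baselines(
            ratio_table, hyperparameters=params,
            n_runs=int(bcfg.get("n_runs", 10)), seed=cfg["seed"],
            min_train=int(bcfg.get("min_train", 10)),
            objective_mode=bcfg.get("objective_mode", "ratio"))
        baseline_table.table.to_csv(out / "baselines.csv", index=False)
        stamp("baselines",
              hyperparameters=params or bl.SELECTED_HYPERPARAMETERS,
              n_runs=baseline_table.n_runs,
              baseline_r2=bl.baseline_r2(baseline_table),
              linear_r2=bl.fit_linear_comparator(ratio_table))

        # ---- report -------------------------------------------------------
        report = {
            "survey": survey_report.to_dict(),
            "register": register_report.to_dict(),
            "entropy": w.diagnostics["entropy"],
            "uniform_entropy": w.diagnostics["uniform_entropy"],
            "n_pop": pop.n_pop,
            "total_accidents": int(ratio_table.table["accidents"].sum()),
            "national_ratio": float(
                rt.aggregate_ratios(ratio_table, list(scheme.features)).table["ratio"].iloc[0]
            ),
            "baseline_r2": bl.baseline_r2(baseline_table),
            "linear_r2": bl.fit_linear_comparator(ratio_table),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        stamp("report")
    except Exception as e:
        stamp("error", error=f"{type(e).__name__}: {e}")
        raise
    return out
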