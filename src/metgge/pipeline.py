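"""End-to-end orchestration: data -> ANOVA -> index -> GGE -> ML validation.

``run_pipeline`` executes the stages in dependency order, writes every
result as CSV/JSON under an output directory, and records a manifest with
input hashes and the seed so a rerun with the same configuration is
bit-reproducible for every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gge
from .errors import ConfigError, MetggeError
from .genetics import (
    descriptive_stats,
    genetic_parameters,
    percent_contribution,
    two_way_anova,
    variance_components,
)
from .met_data import METDataset, load_long_csv, to_two_way, validate_balance
from .selection import IndexSpec, append_index_trait
from .simulate import CrossoverSpec, SimulationConfig, simulate_met
from .validation import ModelSpec, build_feature_matrix, grid_search


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (file input or simulation)."""

    input_csv: str | None = None
    simulation: dict | None = None
    traits: list[str] = field(default_factory=list)
    index_traits: list[str] = field(default_factory=list)
    index_weights: list[float] | None = None
    k: float = 2.06
    ml_family: str | None = None
    ml_grid: dict = field(default_factory=dict)
    ml_selection_metric: str = "rmse"
    out_dir: str = "met_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ConfigError("exactly one of input_csv / simulation required")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        if not isinstance(payload, dict):
            raise ConfigError("config file must hold a mapping")
        return cls(**payload)


def _sim_config(payload: dict, seed: int) -> SimulationConfig:
    payload = dict(payload)
    crossover = payload.pop("crossover", None)
    if crossover is not None:
        crossover = CrossoverSpec(**crossover)
    payload.setdefault("seed", seed)
    return SimulationConfig(crossover=crossover, **payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _load(config: PipelineConfig) -> METDataset:
    if config.input_csv is not None:
        return load_long_csv(config.input_csv)
    return simulate_met(_sim_config(config.simulation, config.seed))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}
    stage = "load"
    try:
        dataset = _load(config)
        balance = validate_balance(dataset)
        manifest["stages"].append(stage)
        traits = config.traits or dataset.trait_names
        if config.index_traits:
            stage = "index"
            spec = IndexSpec(config.index_traits, config.index_weights)
            dataset = append_index_trait(dataset, spec)
            traits = traits + ["BLPSI"]
            manifest["stages"].append(stage)

        stage = "anova"
        anova_rows, params = [], {}
        for trait in traits:
            table = two_way_anova(dataset, trait)
            try:
                pct = percent_contribution(table)
            except MetggeError:  # all-zero mean squares
                pct = {}
            for source in table.df:
                anova_rows.append(
                    {"trait": trait, "source": source, "df": table.df[source],
                     "SS": table.ss[source], "MS": table.ms[source],
                     "pct_contribution": pct.get(source)}
                )
            two_way = to_two_way(dataset, trait)
            gmeans = two_way.values.mean(axis=1)
            mean, mn, mx = descriptive_stats(gmeans)
            entry = {"mean": mean, "min": mn, "max": mx,
                     "var_genotype_means": float(np.var(gmeans, ddof=1))}
            if "error" in table.ms:
                comp = variance_components(table)
                entry.update(var_g_mom=comp.var_g, var_ge_mom=comp.var_ge,
                             var_err_mom=comp.var_err, truncated=comp.truncated)
                denom = comp.var_g + comp.var_ge / table.e + comp.var_err / (
                    table.e * table.r)
                if denom > 0 and comp.var_g > 0 and mean != 0:
                    h2 = comp.var_g / denom
                    gp = genetic_parameters(comp.var_g, h2, mean, k=config.k)
                    entry.update(h2=h2, gcv=gp.gcv, pcv=gp.pcv, ga=gp.ga,
                                 ga_pct=gp.ga_pct)
            params[trait] = entry
        pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
        _write_json(out / "genetic_parameters.json", params)
        manifest["stages"].append(stage)

        stage = "gge"
        gge_payload = {}
        for trait in traits:
            two_way = to_two_way(dataset, trait)
            if np.allclose(gge.center_environment(two_way), 0):
                gge_payload[trait] = {"degenerate": "centered matrix is zero"}
                continue
            model_g = gge.fit_gge(two_way, gge.GENOTYPE_FOCUSED)
            model_e = gge.fit_gge(two_way, gge.ENVIRONMENT_FOCUSED)
            payload = {
                "singular_values": model_g.singular_values,
                "variance_explained": model_g.variance_explained,
            }
            try:
                frame_g = gge.aec_frame(model_g)
                ms = gge.mean_stability(model_g, frame_g)
                ranked = gge.rank_vs_ideal(ms)
                ranked.rename_axis("genotype").to_csv(
                    out / f"gge_{trait}_genotypes.csv")
                frame_e = gge.aec_frame(model_e)
                env = gge.environment_metrics(model_e, frame_e)
                env.rename_axis("environment").to_csv(
                    out / f"gge_{trait}_environments.csv")
                www = gge.which_won_where(model_g)
                payload.update(
                    hull_vertices=www.hull_vertices,
                    mega_environments=www.mega_environments,
                    winners={str(k): v for k, v in www.winners.items()},
                )
            except MetggeError as exc:
                payload["degenerate"] = str(exc)
            gge_payload[trait] = payload
        _write_json(out / "gge.json", gge_payload)
        manifest["stages"].append(stage)

        if config.ml_family:
            stage = "mlval"
            ml_payload = {}
            for trait in traits:
                X, y = build_feature_matrix(dataset, trait)
                spec = ModelSpec(config.ml_family, config.ml_grid,
                                 config.ml_selection_metric, seed=config.seed)
                result = grid_search(spec, X, y)
                ml_payload[trait] = {
                    "best_params": result.best_params,
                    "metrics": result.best_metrics.as_dict(),
                }
                result.table.to_csv(out / f"mlval_{trait}.csv", index=False)
            _write_json(out / "mlval.json", ml_payload)
            manifest["stages"].append(stage)
    except MetggeError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(out / "manifest.json", manifest)
        raise
    manifest["balance"] = {"complete": balance.complete, "r": balance.r}
    for path in sorted(out.glob("*")):
        if path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    _write_json(out / "manifest.json", manifest)
    return manifest
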