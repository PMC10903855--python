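"""File formats: population/sample CSVs, YAML configs, JSON tree export.

CSV dialect: comma-separated, UTF-8, mandatory header, ``.`` decimal.
Population files carry ``unit_id,y,stratum,x1..xp`` with one row per unit;
sample files use the identical layout with ``y`` and ``stratum`` left blank
on non-sampled rows.  Configuration files are YAML mappings whose keys are
schema-validated before any computation — unknown keys are rejected by
name, so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .cart import FittedTree, TreeSpec
from .evaluation import ModelConfig, StudyConfig, table2_models
from .forest import TreeEnsemble
from .population import ConfigurationError, Population, SurveySample, SyntheticConfig


# ---------------------------------------------------------------------------
# populations and samples


def population_to_frame(pop: Population) -> pd.DataFrame:
    df = pd.DataFrame({"unit_id": pop.unit_id, "y": pop.y, "stratum": pop.stratum})
    return pd.concat([df, pop.covariates.reset_index(drop=True)], axis=1)


def write_population_csv(pop: Population, path: str | Path) -> Path:
    path = Path(path)
    population_to_frame(pop).to_csv(path, index=False)
    return path


def read_population_csv(path: str | Path, H: int | None = None) -> Population:
    df = pd.read_csv(path)
    for col in ("unit_id", "y", "stratum"):
        if col not in df.columns:
            raise ValueError(f"population CSV is missing required column {col!r}")
    if df[["y", "stratum"]].isna().any().any():
        raise ValueError("population CSV must not contain blank y or stratum values")
    covs = df.drop(columns=["unit_id", "y", "stratum"])
    stratum = df["stratum"].to_numpy(dtype=int)
    return Population(
        unit_id=df["unit_id"].to_numpy(dtype=int),
        y=df["y"].to_numpy(dtype=float),
        stratum=stratum,
        covariates=covs,
        H=H if H is not None else int(stratum.max()),
    )


def write_sample_csv(sample: SurveySample, path: str | Path) -> Path:
    path = Path(path)
    s = pd.DataFrame(
        {"unit_id": sample.sampled_ids, "y": sample.y, "stratum": sample.stratum}
    )
    s = pd.concat([s, sample.covariates.reset_index(drop=True)], axis=1)
    ns = pd.DataFrame(
        {
            "unit_id": sample.nonsampled_ids,
            "y": np.nan,
            "stratum": np.nan,
        }
    )
    ns = pd.concat([ns, sample.nonsampled_covariates.reset_index(drop=True)], axis=1)
    both = pd.concat([s, ns], axis=0).sort_values("unit_id")
    both.to_csv(path, index=False)
    return path


def read_sample_csv(path: str | Path, H: int | None = None) -> SurveySample:
    df = pd.read_csv(path)
    sampled = df["y"].notna() & df["stratum"].notna()
    covs = df.drop(columns=["unit_id", "y", "stratum"])
    stratum = df.loc[sampled, "stratum"].to_numpy(dtype=int)
    return SurveySample(
        sampled_ids=df.loc[sampled, "unit_id"].to_numpy(dtype=int),
        y=df.loc[sampled, "y"].to_numpy(dtype=float),
        stratum=stratum,
        covariates=covs[sampled].reset_index(drop=True),
        nonsampled_ids=df.loc[~sampled, "unit_id"].to_numpy(dtype=int),
        nonsampled_covariates=covs[~sampled].reset_index(drop=True),
        N=len(df),
        H=H if H is not None else int(stratum.max()),
    )


def estimates_to_frame(estimates, n: int | None = None, model: str = "") -> pd.DataFrame:
    """Tidy rows ``n,model,stratum,variant,lambda_hat,mean_hat,total_hat,
    model_variance`` from a list of DomainEstimate objects."""
    return pd.DataFrame(
        [
            {
                "n": n,
                "model": model,
                "stratum": e.stratum,
                "variant": e.variant,
                "lambda_hat": e.lambda_hat,
                "mean_hat": e.mean_hat,
                "total_hat": e.total_hat,
                "model_variance": e.model_variance,
            }
            for e in estimates
        ]
    )


# ---------------------------------------------------------------------------
# configuration parsing


def _from_mapping(cls, data: Mapping[str, Any], context: str):
    """Build a dataclass from a mapping, rejecting unknown keys by name."""
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{context}: expected a mapping, got {type(data).__name__}")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(
            f"{context}: unknown key(s) {sorted(unknown)}; allowed: {sorted(fields)}"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{context}: {exc}") from exc


def parse_population_config(data: Mapping[str, Any]) -> SyntheticConfig:
    """``population:`` block -> SyntheticConfig."""
    return _from_mapping(SyntheticConfig, data, "population")


def parse_tree_spec(data: Mapping[str, Any], context: str) -> TreeSpec:
    return _from_mapping(TreeSpec, data, context)


def parse_models_config(data: Any) -> list[ModelConfig]:
    """``models:`` block -> model grid.

    Either the literal string ``table2`` (the packaged six-model grid) or a
    list of ``{name, classification: {...}, regression: {...}, n_trees,
    mtry_classification, mtry_regression}`` mappings.
    """
    if isinstance(data, str):
        if data == "table2":
            return table2_models()
        raise ConfigurationError(f"models: unknown preset {data!r} (expected 'table2')")
    if not isinstance(data, list):
        raise ConfigurationError("models: expected 'table2' or a list of model mappings")
    out = []
    for i, entry in enumerate(data):
        if not isinstance(entry, Mapping):
            raise ConfigurationError(f"models[{i}]: expected a mapping")
        known = {
            "name", "classification", "regression", "n_trees",
            "mtry_classification", "mtry_regression",
        }
        unknown = set(entry) - known
        if unknown:
            raise ConfigurationError(
                f"models[{i}]: unknown key(s) {sorted(unknown)}; allowed: {sorted(known)}"
            )
        for req in ("classification", "regression"):
            if req not in entry:
                raise ConfigurationError(f"models[{i}]: missing required key {req!r}")
        out.append(
            ModelConfig(
                name=str(entry.get("name", i + 1)),
                classification=parse_tree_spec(
                    entry["classification"], f"models[{i}].classification"
                ),
                regression=parse_tree_spec(
                    entry["regression"], f"models[{i}].regression"
                ),
                n_trees=int(entry.get("n_trees", 1)),
                mtry_classification=entry.get("mtry_classification"),
                mtry_regression=entry.get("mtry_regression"),
            )
        )
    return out


def load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level of the config must be a mapping")
    return data


def parse_study_config(data: Mapping[str, Any], base_dir: Path | None = None) -> StudyConfig:
    """``study`` config mapping -> StudyConfig.

    ``population`` is either a mapping (synthetic config) or a path to a
    population CSV, resolved relative to ``base_dir``.
    """
    known = {"population", "sample_sizes", "models", "Q", "seed", "scale", "variants"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"study: unknown key(s) {sorted(unknown)}; allowed: {sorted(known)}"
        )
    if "population" not in data:
        raise ConfigurationError("study: missing required key 'population'")
    pop_spec = data["population"]
    if isinstance(pop_spec, Mapping):
        population: SyntheticConfig | Population = parse_population_config(pop_spec)
    else:
        path = Path(pop_spec)
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        population = read_population_csv(path)
    if "sample_sizes" not in data:
        raise ConfigurationError("study: missing required key 'sample_sizes'")
    models = parse_models_config(data["models"]) if "models" in data else None
    try:
        return StudyConfig(
            population=population,
            sample_sizes=tuple(int(n) for n in data["sample_sizes"]),
            models=tuple(models) if models is not None else None,
            Q=int(data.get("Q", 1000)),
            seed=int(data.get("seed", 0)),
            scale=str(data.get("scale", "mean")),
            variants=tuple(
                data.get(
                    "variants",
                    ("dgcart_direct", "dgcart_combined", "dgcart_smoothed"),
                )
            ),
        )
    except ValueError as exc:
        raise ConfigurationError(f"study: {exc}") from exc


# ---------------------------------------------------------------------------
# model export


def save_model_json(model: FittedTree | TreeEnsemble, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, indent=1)
    return path
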