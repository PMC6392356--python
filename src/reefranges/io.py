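"""Table I/O, run configuration, and the end-to-end pipeline.

All tables are plain UTF-8 CSV (comma delimiter, "." decimal); missing
PLD is an empty field.  ``run_pipeline`` ties the stages together —
simulate (or load) -> range metric -> complete-data fit -> focal-subset
fit -> null model -> sensitivity — and writes every result table plus a
manifest recording inputs, seeds and outputs so a run can be reproduced
exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .range_metrics import DEFAULT_EPS, range_table
from .schema import SPECIES_COLUMNS, TRAIT_LEVELS
from .subset_nullmodel import null_model_test
from .subset_sensitivity import compare_to_focal, sensitivity_analysis
from .synthetic_data import (
    default_effect_config, default_pool_config, default_tep_geometry,
    headline_bias_config, make_species_pool, assign_focal_subset,
    simulate_occurrences, simulate_range_sizes,
)
from .trait_model import full_analysis

logger = logging.getLogger(__name__)

#: Documented synonyms accepted on input and normalised to the vocabulary.
SPAWNING_SYNONYMS = {
    "benthic": "nonpelagic",
    "demersal": "nonpelagic",
    "mouthbrooding": "nonpelagic",
    "livebearer": "nonpelagic",
    "live_birth": "nonpelagic",
    "viviparous": "nonpelagic",
}


def read_species_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a species/trait table.

    ``column_map`` renames source columns to the documented schema (useful
    for externally deposited files whose headers differ).  Unknown
    categorical values raise an error naming the row and column;
    ``pld_days`` may be empty (and 0 is valid, e.g. viviparous species).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(SPECIES_COLUMNS) - {"pld_days"} - set(df.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    if "pld_days" not in df.columns:
        df["pld_days"] = np.nan
    if df["species_id"].duplicated().any():
        dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise ValueError(f"duplicate species_id: {dups[:5]}")
    df["spawning_mode"] = df["spawning_mode"].replace(SPAWNING_SYNONYMS)
    for trait, levels in TRAIT_LEVELS.items():
        bad = ~df[trait].isin(levels)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"row {i}: unknown value {df[trait].iloc[i]!r} in column {trait!r} "
                f"(allowed: {list(levels)})"
            )
    if (df["body_size_cm"] <= 0).any():
        raise ValueError("body_size_cm must be positive")
    if (df["pld_days"].dropna() < 0).any():
        raise ValueError("pld_days must be >= 0")
    logger.info("read %d species from %s", len(df), path)
    return df


def read_occurrence_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species_id", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
    if np.any(np.abs(df["lon"]) > 180) or np.any(np.abs(df["lat"]) > 90):
        raise ValueError("coordinates out of bounds")
    return df


def read_range_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species_id", "range_km"} - set(df.columns)
    if missing:
        raise ValueError(f"range table missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
    return path


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    out_dir: str = "results"
    occurrences_path: str | None = None   # None -> simulate synthetic data
    species_path: str | None = None
    subset_col: str = "in_focal_subset"
    include_pld_in_focal_fit: bool = True
    d_ref_km: float = 6000.0
    eps: float = DEFAULT_EPS
    weight_floor: float = 0.001
    n_draws: int = 10_000
    n_replicates: int = 1000
    subset_size: int = 148
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("d_ref_km", "eps", "n_draws", "n_replicates", "subset_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**data)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write result CSVs plus a manifest.

    Returns the output directory.  With no input paths configured, the
    pipeline runs on the bundled synthetic study conditions (497 species,
    biased 148-species focal subset).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds_used: dict[str, int] = {}

    if config.species_path and config.occurrences_path:
        species = read_species_table(config.species_path)
        occurrences = read_occurrence_table(config.occurrences_path)
    else:
        logger.info("no input paths configured: generating synthetic data")
        pool = make_species_pool(default_pool_config(seed=config.seed))
        ranges_true = simulate_range_sizes(pool, default_effect_config(), seed=config.seed + 1)
        occurrences = simulate_occurrences(
            pool, ranges_true, default_tep_geometry(), seed=config.seed + 2
        )
        species = assign_focal_subset(pool, headline_bias_config(), seed=config.seed + 3)
        seeds_used.update({
            "pool": config.seed, "ranges": config.seed + 1,
            "occurrences": config.seed + 2, "focal_subset": config.seed + 3,
        })
        write_table(species, out / "species.csv")
        write_table(occurrences, out / "occurrences.csv")

    ranges = range_table(occurrences, d_ref_km=config.d_ref_km, eps=config.eps)
    write_table(ranges, out / "ranges.csv")

    complete = full_analysis(
        species, ranges, include_pld=False,
        weight_floor=config.weight_floor, d_ref_km=config.d_ref_km, eps=config.eps,
    )
    write_table(complete.effects.table, out / "effects_complete.csv")

    focal = full_analysis(
        species, ranges, include_pld=config.include_pld_in_focal_fit,
        subset_col=config.subset_col,
        weight_floor=config.weight_floor, d_ref_km=config.d_ref_km, eps=config.eps,
    )
    write_table(focal.effects.table, out / "effects_focal.csv")

    focal_ids = species.loc[species[config.subset_col].astype(bool), "species_id"].to_numpy()
    seeds_used["null_model"] = config.seed + 4
    nm = null_model_test(species, focal_ids, n_draws=config.n_draws, seed=config.seed + 4)
    write_table(nm.table, out / "null_model.csv")

    seeds_used["sensitivity"] = config.seed + 5
    sens = sensitivity_analysis(
        species, ranges, n_replicates=config.n_replicates,
        subset_size=len(focal_ids), seed=config.seed + 5,
        weight_floor=config.weight_floor, d_ref_km=config.d_ref_km, eps=config.eps,
    )
    write_table(sens.p_values, out / "sensitivity_p_values.csv")
    write_table(sens.effects, out / "sensitivity_effects.csv")
    comparison = compare_to_focal(sens, focal.effects, complete.effects, strict=False)
    write_table(comparison, out / "sensitivity_comparison.csv")

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "seeds_used": seeds_used,
        "n_species": int(len(species)),
        "n_focal": int(len(focal_ids)),
        "n_models_complete": int(complete.n_models),
        "n_unconverged_complete": int(complete.n_unconverged),
        "null_model_n_significant": int(nm.n_significant),
        "sensitivity_n_failed": int(sens.n_failed),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
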