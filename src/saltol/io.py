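"""Trait-table I/O, run configuration and the end-to-end pipeline."""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bivariate import BivariateQuantileRegressor
from .depth import DirectionSet, build_envelope, find_p_star, bivariate_median
from .models import (
    DEFAULT_QUANTILE_GRID,
    build_condition_design,
    coefficient_profiles,
    compute_swp,
    profiles_to_frame,
    swp_trait_model,
)
from .selection import select_top_accessions
from .simulate import (
    NON_SALINE,
    SALINE,
    TRAIT_COLUMNS,
    TRAIT_NAMES,
    SyntheticConfig,
    generate_trait_table,
)

__all__ = ["RunConfig", "read_trait_table", "write_trait_table", "run_pipeline"]

logger = logging.getLogger("saltol")

_CONDITION_SYNONYMS = {
    "saline": SALINE,
    "salt": SALINE,
    "0": SALINE,
    "non_saline": NON_SALINE,
    "non-saline": NON_SALINE,
    "nonsaline": NON_SALINE,
    "fresh": NON_SALINE,
    "control": NON_SALINE,
    "1": NON_SALINE,
}

_NUMERIC_COLUMNS = [c for c in TRAIT_COLUMNS if c not in ("accession_id", "condition")]


def read_trait_table(path) -> pd.DataFrame:
    """Read and validate a trait-table CSV.

    Condition labels are normalised from the common synonyms (saline/0,
    non-saline/fresh/control/1; 1 codes non-saline).  Errors report the
    offending rows; accessions observed under a single condition trigger a
    warning (paired analyses will drop them later).
    """
    df = pd.read_csv(path, dtype={"accession_id": str})
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    cond = df["condition"].astype(str).str.strip().str.lower()
    unknown = df.index[~cond.isin(_CONDITION_SYNONYMS)] + 2  # header + 1-based
    if len(unknown):
        raise ValueError(
            f"{path}: unrecognised condition labels at file rows "
            f"{list(unknown[:10])}"
        )
    df["condition"] = cond.map(_CONDITION_SYNONYMS)

    for c in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()] + 2
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric values in column {c!r} at file rows "
                f"{list(bad[:10])}"
            )
        df[c] = coerced

    dup = df.duplicated(subset=["accession_id", "condition"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate accession x condition pairs: "
            f"{sorted(df.loc[dup, 'accession_id'].unique())[:10]}"
        )
    if (df["yield_g_m2"] < 0).any():
        rows = list(df.index[df["yield_g_m2"] < 0] + 2)
        raise ValueError(f"{path}: negative yield at file rows {rows[:10]}")

    counts = df.groupby("accession_id")["condition"].nunique()
    unpaired = counts.index[counts < 2]
    if len(unpaired):
        warnings.warn(
            f"{path}: {len(unpaired)} accession(s) observed under one condition "
            f"only (e.g. {sorted(unpaired)[:5]}); they are excluded from "
            "paired analyses",
            UserWarning,
            stacklevel=2,
        )
    logger.info(
        "read %d rows, %d accessions from %s", len(df), df["accession_id"].nunique(), path
    )
    return df[TRAIT_COLUMNS]


def write_trait_table(table: pd.DataFrame, path) -> None:
    table[TRAIT_COLUMNS].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str | None = None
    synthetic: dict | None = None  # SyntheticConfig fields when simulating
    covariates: list = field(default_factory=lambda: list(TRAIT_NAMES))
    quantiles: list = field(default_factory=lambda: list(DEFAULT_QUANTILE_GRID))
    alpha: float = 0.05
    p1: float = 0.85
    p2: float = 0.9
    n_directions: int = 360
    n_directions_bivariate: int = 32
    spline_knots: list | None = None
    envelope_levels: list = field(default_factory=lambda: [0.1, 0.25])
    bivariate_covariate: str = "grain_number"
    bivariate_grid_size: int = 9
    seed: int = 0
    outdir: str = "saltol_output"
    plots: bool = False

    def __post_init__(self) -> None:
        for lv in [self.alpha, self.p1, self.p2, *self.quantiles, *self.envelope_levels]:
            if not 0.0 < lv < 1.0:
                raise ValueError(f"level {lv} outside (0, 1)")
        if self.n_directions < 8:
            raise ValueError("n_directions must be >= 8")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(data, fh, indent=2)
            else:
                yaml.safe_dump(data, fh)


def _load_input(config: RunConfig) -> pd.DataFrame:
    if config.input_path:
        return read_trait_table(config.input_path)
    synth = dict(config.synthetic or {})
    synth.setdefault("seed", config.seed)
    return generate_trait_table(SyntheticConfig(**synth))


def run_pipeline(config: RunConfig, stages=("simulate", "uqr", "swp", "select", "envelope", "bivreg")):
    """Run the requested stages, writing tidy CSVs into ``config.outdir``.

    Returns a dict of the in-memory stage results.  Identical config and
    seed reproduce identical outputs (all randomness flows through the
    single seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    t0 = time.perf_counter()
    logger.info("saltol %s | seed=%d outdir=%s", __version__, config.seed, outdir)

    table = _load_input(config)
    results["table"] = table
    if "simulate" in stages:
        write_trait_table(table, outdir / "trait_table.csv")

    def _stage(name, fn):
        t = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %-8s %6.2fs", name, time.perf_counter() - t)
        return out

    if "uqr" in stages:
        def _uqr():
            X, y = build_condition_design(table, config.covariates)
            profiles = coefficient_profiles(X, y, config.quantiles, config.alpha)
            frame = profiles_to_frame(profiles)
            frame.to_csv(outdir / "yield_profiles.csv", index=False)
            return profiles
        results["uqr"] = _stage("uqr", _uqr)

    swp_table = None
    if {"swp", "select", "envelope", "bivreg"} & set(stages):
        swp_table = compute_swp(table)
        results["swp_table"] = swp_table

    if "swp" in stages:
        def _swp():
            profiles, ols = swp_trait_model(
                table, config.quantiles, config.alpha, config.covariates
            )
            frame = profiles_to_frame(profiles)
            frame.to_csv(outdir / "swp_profiles.csv", index=False)
            pd.DataFrame(
                {
                    "covariate": ols.names,
                    "estimate": ols.coefficients,
                    "std_error": ols.std_errors,
                    "p_value": ols.p_values,
                }
            ).to_csv(outdir / "swp_ols.csv", index=False)
            return profiles, ols
        results["swp"] = _stage("swp", _swp)

    if "select" in stages:
        def _select():
            logger.info("selection levels p1=%.2f p2=%.2f", config.p1, config.p2)
            sel = select_top_accessions(swp_table, config.p1, config.p2)
            sel.to_csv(outdir / "selection.csv", index=False)
            return sel
        results["select"] = _stage("select", _select)

    if "envelope" in stages:
        def _envelope():
            Y = swp_table[["y_s", "y_c"]].to_numpy()
            directions = DirectionSet.uniform(config.n_directions)
            rows = []
            envs = {}
            for p in config.envelope_levels:
                envs[p] = build_envelope(Y, p, directions)
            star = find_p_star(Y, directions)
            envs[star.p_star] = star.envelope
            med = bivariate_median(star.envelope)
            logger.info("p*=%.3f bivariate median=(%.2f, %.2f)", star.p_star, *med)
            for p, env in sorted(envs.items()):
                for i, v in enumerate(env.vertices):
                    rows.append({"p": p, "vertex_index": i, "y_s": v[0], "y_c": v[1]})
            pd.DataFrame(rows).to_csv(outdir / "envelopes.csv", index=False)
            return envs, star
        results["envelope"] = _stage("envelope", _envelope)

    if "bivreg" in stages:
        def _bivreg():
            Y = swp_table[["y_s", "y_c"]].to_numpy()
            saline = (
                table[table["condition"] == SALINE]
                .set_index("accession_id")
                .loc[swp_table["accession_id"]]
            )
            x = saline[config.bivariate_covariate].to_numpy(dtype=float)
            model = BivariateQuantileRegressor(
                n_directions=config.n_directions_bivariate,
                knots=config.spline_knots,
            ).fit(x, Y)
            qlo, qhi = np.quantile(x, [0.1, 0.9])
            grid = np.linspace(qlo, qhi, config.bivariate_grid_size)
            curve = model.swp_curve(grid)
            curve.to_csv(outdir / "swp_curve.csv", index=False)
            return model, curve
        results["bivreg"] = _stage("bivreg", _bivreg)

    if config.plots:
        from . import plots

        plots.export_all(results, outdir)

    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return results
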