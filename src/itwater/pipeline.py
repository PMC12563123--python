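"""End-to-end orchestration: generate -> descriptors -> statistics -> report.

For every configured (model, cluster size) the pipeline generates a seeded
synthetic ensemble, computes per-frame descriptor sets, writes the
per-combination CSVs (named ``{size}M_{space}_{model}.csv``), screens each
(model, size, space, measure) cell for normality, runs Welch's t-test on all
model pairs, and produces the mean-vs-size scaling series.

Sub-seeds are derived deterministically per (model, size) with CRC32, so the
whole run is reproducible from the one top-level seed while different models
still receive statistically independent jitter streams — identical-geometry
models (SPC vs SPC/eps in electron_count mode) then form an honest null pair
with the nominal 5% false-significance rate, not artificially equal samples.

All output CSVs are comma-separated, '.'-decimal, UTF-8, header row, values
in atomic units at full double precision.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .density import QuadratureSpec
from .descriptors import MEASURES
from .forcefield import SPC, SPCE_EPS, TIP3P, ForceFieldParams
from .stats import DegenerateSampleError, normality_screen, welch_t
from .synthetic import EnsembleSpec, make_descriptor_samples

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "ScalingReport", "run_pipeline", "scaling_report", "subseed"]

DEFAULT_SIZES = (1, 3, 5, 7, 9, 11)
_SPACE_NAMES = {"r": "position", "p": "momentum"}


def subseed(seed: int, model: str, size: int) -> int:
    """Stable per-(model, size) sub-seed below 2^31."""
    return zlib.crc32(f"{seed}|{model}|{size}".encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class RunConfig:
    models: tuple[ForceFieldParams, ...] = (SPC, SPCE_EPS, TIP3P)
    cluster_sizes: tuple[int, ...] = DEFAULT_SIZES
    n_frames: int = 30
    seed: int = 0
    jitter_sigma: float = 0.01
    oo_distance_range: tuple[float, float] = (2.6, 3.2)
    weight_mode: str = "electron_count"
    quad: QuadratureSpec = field(default_factory=QuadratureSpec)
    r_cut: float = 3.5
    outdir: Path | None = None

    def __post_init__(self) -> None:
        if not self.cluster_sizes:
            raise ValueError("cluster_sizes must be non-empty")
        if len({m.name for m in self.models}) != len(self.models):
            raise ValueError("model names must be unique")


@dataclass
class ScalingReport:
    """Mean-vs-size series with per-size normalized model shares."""

    series: pd.DataFrame  # model, size, space, measure, mean, share
    monotonicity: pd.DataFrame  # model, space, measure, trend


@dataclass
class PipelineResult:
    table: pd.DataFrame
    normality: pd.DataFrame
    welch: pd.DataFrame
    scaling: ScalingReport | None
    csv_paths: list[Path]


def _safe_name(model: str) -> str:
    return model.replace("/", "-").replace(" ", "_")


def _write_combination_csvs(table: pd.DataFrame, outdir: Path) -> list[Path]:
    paths = []
    for (size, space, model), grp in table.groupby(["size", "space", "model"], sort=True):
        wide = grp.pivot(index="frame", columns="measure", values="value")[list(MEASURES)]
        path = outdir / f"{size}M_{_SPACE_NAMES[space]}_{_safe_name(model)}.csv"
        wide.to_csv(path, float_format="%.17g")
        paths.append(path)
    return paths


def _normality_table(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (model, size, space, measure), grp in table.groupby(
        ["model", "size", "space", "measure"], sort=True
    ):
        try:
            res = normality_screen(grp["value"].to_numpy())
            rows.append(
                {
                    "model": model,
                    "size": size,
                    "space": space,
                    "measure": measure,
                    "W": res.W,
                    "p_value": res.p_value,
                    "r_squared": res.r_squared,
                    "verdict": res.verdict,
                }
            )
        except DegenerateSampleError:
            rows.append(
                {
                    "model": model,
                    "size": size,
                    "space": space,
                    "measure": measure,
                    "W": np.nan,
                    "p_value": np.nan,
                    "r_squared": np.nan,
                    "verdict": "degenerate",
                }
            )
    return pd.DataFrame(rows)


def _welch_matrix(table: pd.DataFrame) -> pd.DataFrame:
    models = sorted(table["model"].unique())
    rows = []
    for (size, space, measure), grp in table.groupby(["size", "space", "measure"], sort=True):
        by_model = {m: g["value"].to_numpy() for m, g in grp.groupby("model")}
        for ma, mb in itertools.combinations(models, 2):
            if ma not in by_model or mb not in by_model:
                continue
            try:
                res = welch_t(by_model[ma], by_model[mb])
                rows.append(
                    {
                        "model_a": ma,
                        "model_b": mb,
                        "size": size,
                        "space": space,
                        "measure": measure,
                        "t": res.t,
                        "df": res.df,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
            except DegenerateSampleError:
                rows.append(
                    {
                        "model_a": ma,
                        "model_b": mb,
                        "size": size,
                        "space": space,
                        "measure": measure,
                        "t": np.nan,
                        "df": np.nan,
                        "p_value": np.nan,
                        "significant": False,
                    }
                )
    return pd.DataFrame(rows)


def scaling_report(table: pd.DataFrame) -> ScalingReport:
    """Per-(measure, space, model) mean vs cluster size, normalized model
    shares per size, and a monotonicity flag per series.

    Missing (model, size) cells stay as NaN gap markers; nothing is
    interpolated.  Requires at least two distinct sizes.
    """
    sizes = sorted(table["size"].unique())
    if len(sizes) < 2:
        raise ValueError("scaling report needs at least two cluster sizes")
    means = (
        table.groupby(["measure", "space", "model", "size"], sort=True)["value"]
        .mean()
        .rename("mean")
        .reset_index()
    )
    # normalized share of each model in the per-size total, per (measure, space)
    totals = means.groupby(["measure", "space", "size"])["mean"].transform("sum")
    means["share"] = means["mean"] / totals

    mono_rows = []
    for (measure, space, model), grp in means.groupby(["measure", "space", "model"]):
        series = grp.sort_values("size")["mean"].to_numpy()
        if np.any(np.isnan(series)) or len(series) < 2:
            trend = "gap"
        elif np.all(np.diff(series) > 0):
            trend = "increasing"
        elif np.all(np.diff(series) < 0):
            trend = "decreasing"
        else:
            trend = "non-monotonic"
        mono_rows.append({"measure": measure, "space": space, "model": model, "trend": trend})
    return ScalingReport(series=means, monotonicity=pd.DataFrame(mono_rows))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full generate -> descriptors -> statistics -> report chain."""
    tables = []
    for ff in config.models:
        for size in config.cluster_sizes:
            spec = EnsembleSpec(
                n_molecules=size,
                n_frames=config.n_frames,
                jitter_sigma=config.jitter_sigma,
                oo_distance_range=config.oo_distance_range,
                seed=subseed(config.seed, ff.name, size),
            )
            logger.info(
                "generate+descriptors: model=%s size=%d frames=%d seed=%d",
                ff.name,
                size,
                config.n_frames,
                spec.seed,
            )
            tables.append(
                make_descriptor_samples(
                    ff, spec, weight_mode=config.weight_mode, quad=config.quad
                )
            )
    table = pd.concat(tables, ignore_index=True)

    logger.info("normality screen over %d cells", table.groupby(["model", "size", "space", "measure"]).ngroups)
    normality = _normality_table(table)
    welch = _welch_matrix(table)
    scaling = scaling_report(table) if len(config.cluster_sizes) >= 2 else None

    csv_paths: list[Path] = []
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        csv_paths = _write_combination_csvs(table, outdir)
        normality.to_csv(outdir / "normality_screen.csv", index=False, float_format="%.17g")
        welch.to_csv(outdir / "welch_matrix.csv", index=False, float_format="%.17g")
        csv_paths += [outdir / "normality_screen.csv", outdir / "welch_matrix.csv"]
        if scaling is not None:
            scaling.series.to_csv(outdir / "scaling_series.csv", index=False, float_format="%.17g")
            csv_paths.append(outdir / "scaling_series.csv")
        logger.info("wrote %d CSV files to %s", len(csv_paths), outdir)
    return PipelineResult(table=table, normality=normality, welch=welch, scaling=scaling, csv_paths=csv_paths)
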