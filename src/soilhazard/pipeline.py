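"""End-to-end hazard assessment: samples -> variograms -> kriging ->
multivariate zoning -> contamination indices -> classified hazard maps.

Per metal, the concentrations are z-scored, an empirical semivariogram is
fitted with every candidate family, each fit is leave-one-out
cross-validated, and the best model (|MSE| + |RMSSE - 1|) drives ordinary
kriging over the analysis grid; predictions are mapped back to
concentration scale (the z-transform is affine, so this is exact).
Fitted variograms are therefore reported on z-score scale, as survey
semivariogram tables conventionally are.  Hazard rasters are computed
cell-wise from the kriged concentration grids (CF per metal, then PLI as
their geometric mean), not by interpolating sample-level indices.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geostat, indices, multivariate, synthetic
from .defaults import bbox_km, default_backgrounds, load_defaults
from .io import (
    SampleSet,
    ValidationError,
    read_ascii_grid,
    read_sample_csv,
    write_ascii_grid,
    write_sample_csv,
)

__all__ = ["PipelineConfig", "HazardReport", "run"]

SCHEMA_VERSION = "1"
log = logging.getLogger("soilhazard")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; YAML-loadable."""

    input_csv: str | None = None          # None -> generate synthetic samples
    metals: list[str] | None = None       # None -> all metals in the table
    backgrounds: dict[str, float] = dc_field(default_factory=default_backgrounds)
    families: tuple[str, ...] = geostat.FAMILIES
    cell_size: float = 1.0                # km
    bbox: tuple[float, float, float, float] | None = None
    mask_grid: str | None = None          # optional .asc of 1/0 (mapped/outside)
    cf_scheme: indices.ClassScheme = indices.CF_SCHEME
    pli_scheme: indices.ClassScheme = indices.PLI_SCHEME
    neighborhood: int = 16
    out_dir: str = "soilhazard_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        simple = {
            "input_csv", "metals", "cell_size", "mask_grid", "neighborhood",
            "out_dir", "seed", "log_level",
        }
        for key in simple & raw.keys():
            kwargs[key] = raw[key]
        if "backgrounds" in raw:
            kwargs["backgrounds"] = {k: float(v) for k, v in raw["backgrounds"].items()}
        if "families" in raw:
            kwargs["families"] = tuple(raw["families"])
        if "bbox" in raw:
            kwargs["bbox"] = tuple(raw["bbox"])
        for name, default_upper in (("cf_scheme", True), ("pli_scheme", False)):
            if name in raw:
                kwargs[name] = indices.ClassScheme(
                    tuple(float(b) for b in raw[name]["bounds"]),
                    tuple(raw[name]["labels"]),
                    upper=raw[name].get("upper", default_upper),
                )
        return cls(**kwargs)

    def canonical(self) -> dict:
        """JSON-safe dict used for hashing and provenance."""
        return {
            "input_csv": self.input_csv,
            "metals": self.metals,
            "backgrounds": dict(sorted(self.backgrounds.items())),
            "families": list(self.families),
            "cell_size": self.cell_size,
            "bbox": list(self.bbox) if self.bbox else None,
            "mask_grid": self.mask_grid,
            "cf_scheme": {"bounds": list(self.cf_scheme.bounds),
                          "labels": list(self.cf_scheme.labels)},
            "pli_scheme": {"bounds": list(self.pli_scheme.bounds),
                           "labels": list(self.pli_scheme.labels)},
            "neighborhood": self.neighborhood,
            "seed": self.seed,
        }


@dataclass
class HazardReport:
    """Aggregated machine-readable results of one pipeline run."""

    report: dict
    samples: SampleSet
    contamination: pd.DataFrame
    cf_percentages: pd.DataFrame
    pli_areas: pd.DataFrame
    rasters: dict[str, geostat.KrigingRaster] = dc_field(repr=False, default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _load_samples(config: PipelineConfig) -> SampleSet:
    if config.input_csv is not None:
        samples = read_sample_csv(config.input_csv)
    else:
        samples = synthetic.generate_sample_set(
            synthetic.default_config(seed=config.seed)
        )
    if config.metals:
        samples = samples.subset_metals(list(config.metals))
    missing = [m for m in samples.metals if m not in config.backgrounds]
    if missing:
        raise ValidationError(f"no background concentration for metals: {missing}")
    return samples


def _apply_mask(grid: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return grid
    if mask.shape != grid.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match analysis grid {grid.shape}"
        )
    return np.where(mask > 0, grid, np.nan)


def run(config: PipelineConfig) -> HazardReport:
    """Execute the full workflow and write all products to ``out_dir``.

    Outputs: samples.csv, variogram_cv.csv, per-metal prediction and
    variance grids (.asc), contamination.csv, cf_category_percentages.csv,
    cluster_stats.csv / cluster_anova.csv, pli_class.asc (+ JSON legend),
    pli_areas.csv, report.json and run.log.  Any stage failure writes a
    FAILED marker naming the stage and metal, then re-raises.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    stage = "load"
    metal = None
    try:
        report = _run_stages(config, out)
    except Exception as exc:
        stage = getattr(exc, "_stage", stage)
        metal = getattr(exc, "_metal", metal)
        marker = f"FAILED at stage={stage}" + (f" metal={metal}" if metal else "")
        (out / "FAILED").write_text(marker + f": {exc}\n", encoding="utf-8")
        log.error(marker)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return report


def _tag(exc: Exception, stage: str, metal: str | None = None) -> Exception:
    exc._stage = stage  # noqa: SLF001 - failure provenance for the marker file
    exc._metal = metal
    return exc


def _run_stages(config: PipelineConfig, out: Path) -> HazardReport:
    t0 = time.time()
    # (1) samples
    try:
        samples = _load_samples(config)
    except Exception as exc:
        raise _tag(exc, "load")
    write_sample_csv(samples, out / "samples.csv")
    log.info("loaded %d samples, %d metals", samples.n, len(samples.metals))

    bbox = config.bbox
    if bbox is None:
        if config.input_csv is None:
            bbox = bbox_km()
        else:
            c = samples.coords
            bbox = (c[:, 0].min(), c[:, 1].min(), c[:, 0].max(), c[:, 1].max())
    mask = None
    if config.mask_grid:
        mask_arr, _, _ = read_ascii_grid(config.mask_grid)
        mask = np.nan_to_num(mask_arr, nan=0.0)

    # (2) per-metal geostatistics
    per_metal: dict[str, dict] = {}
    cv_rows: list[dict] = []
    rasters: dict[str, geostat.KrigingRaster] = {}
    for m in samples.metals:
        try:
            z = samples.values(m)
            mu, sd = z.mean(), z.std(ddof=1)
            if sd == 0:
                raise ValidationError(f"metal {m} has zero variance")
            zs = samples.frame.copy()
            zs[m] = (z - mu) / sd
            z_samples = SampleSet(zs[["id", "x", "y", m]], nonnegative=False)
            best, table = geostat.select_best_model(
                z_samples, m, families=config.families, k=config.neighborhood
            )
            spd_label, ratio = geostat.classify_spd(best)
            raster_z = geostat.krige_grid(
                z_samples, m, best, bbox, config.cell_size, k=config.neighborhood
            )
            raster = geostat.KrigingRaster(
                raster_z.origin,
                raster_z.cell_size,
                _apply_mask(mu + sd * raster_z.prediction, mask),
                _apply_mask(sd**2 * raster_z.variance, mask),
            )
        except Exception as exc:
            raise _tag(exc, "geostat", m)
        rasters[m] = raster
        write_ascii_grid(out / f"{m}_pred.asc", raster.prediction, raster.origin, raster.cell_size)
        write_ascii_grid(out / f"{m}_var.asc", raster.variance, raster.origin, raster.cell_size)
        winner = table[0]
        per_metal[m] = {
            "family": best.family,
            "nugget": round(best.nugget, 4),
            "partial_sill": round(best.partial_sill, 4),
            "sill": round(best.sill, 4),
            "range_km": round(best.range_, 3),
            "shape": round(best.shape, 3) if best.family == "stable" else None,
            "effective_range_km": round(best.effective_range, 3),
            "nugget_sill_ratio": round(ratio, 2),
            "spd": spd_label,
            "mse": round(winner["mse"], 4),
            "rmsse": round(winner["rmsse"], 4),
        }
        for row in table:
            cv_rows.append(
                {
                    "metal": m,
                    "family": row["family"],
                    "nugget": row["model"].nugget,
                    "partial_sill": row["model"].partial_sill,
                    "range_km": row["model"].range_,
                    "objective": row["objective"],
                    "mse": row["mse"],
                    "rmsse": row["rmsse"],
                    "score": row["score"],
                    "selected": row["family"] == best.family,
                }
            )
        log.info("%s: %s model, SPD %s (ratio %.2f)", m, best.family, spd_label, ratio)
    pd.DataFrame(cv_rows).to_csv(out / "variogram_cv.csv", index=False, float_format="%.6g")

    # (3) multivariate zoning
    try:
        z_all = multivariate.zscore(samples)
        r, _ = multivariate.pearson_matrix(samples.matrix())
        pca_res = multivariate.pca(samples.matrix())
        if pca_res.kmo <= 0.5:
            log.warning("KMO %.3f <= 0.5: sampling adequacy questionable", pca_res.kmo)
        anchor = samples.values("Fe") if "Fe" in samples.metals else None
        labels, _ = multivariate.hcluster(z_all, k=2, anchor=anchor)
        cluster_rep = multivariate.cluster_summary(samples, labels)
    except Exception as exc:
        raise _tag(exc, "multivariate")
    pd.DataFrame(r, index=samples.metals, columns=samples.metals).to_csv(
        out / "correlation.csv", float_format="%.4f"
    )
    pd.DataFrame(
        {
            "eigenvalue": pca_res.eigenvalues,
            "variance_pct": pca_res.variance_pct,
            "cumulative_pct": pca_res.cumulative_pct,
        },
        index=[f"F{i + 1}" for i in range(len(pca_res.eigenvalues))],
    ).to_csv(out / "pca_eigen.csv", float_format="%.4f")
    pca_res.loadings.to_csv(out / "pca_loadings.csv", float_format="%.4f")
    pd.DataFrame(
        pca_res.scores, index=samples.frame["id"], columns=pca_res.loadings.columns
    ).to_csv(out / "pca_scores.csv", float_format="%.4f")
    cluster_rep.stats.to_csv(out / "cluster_stats.csv", index=False, float_format="%.6g")
    cluster_rep.anova.to_csv(out / "cluster_anova.csv", index=False, float_format="%.6g")

    # (4) contamination indices
    try:
        contamination = indices.contamination_table(
            samples, config.backgrounds, config.cf_scheme, config.pli_scheme
        )
        cf_pct = indices.cf_category_percentages(
            samples, labels, config.backgrounds, config.cf_scheme
        )
        cf_grids = {
            m: rasters[m].prediction / config.backgrounds[m] for m in samples.metals
        }
        stack = np.stack([np.clip(g, 1e-12, None) for g in cf_grids.values()])
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pli_grid = np.exp(np.nanmean(np.log(stack), axis=0))
        pli_grid[~np.isfinite(rasters[samples.metals[0]].prediction)] = np.nan
        pli_class = config.pli_scheme.classify(pli_grid)
        pli_areas = indices.classified_area(pli_class, config.cell_size)
    except Exception as exc:
        raise _tag(exc, "indices")
    contamination.round(4).to_csv(out / "contamination.csv", index=False)
    cf_pct.round({"percentage": 2}).to_csv(out / "cf_category_percentages.csv", index=False)
    pli_areas.round({"area_km2": 2, "percentage": 2}).to_csv(out / "pli_areas.csv", index=False)
    level_code = {lab: i for i, lab in enumerate(config.pli_scheme.labels)}
    coded = np.array(
        [[level_code.get(v, -9999) if v is not None else np.nan for v in row]
         for row in pli_class], dtype=float
    )
    first = rasters[samples.metals[0]]
    write_ascii_grid(out / "pli_class.asc", coded, first.origin, first.cell_size)
    write_ascii_grid(out / "pli.asc", pli_grid, first.origin, first.cell_size)
    with open(out / "pli_class_legend.json", "w", encoding="utf-8") as fh:
        json.dump(level_code, fh, indent=2, sort_keys=True)

    # (5) report
    cfg_json = json.dumps(config.canonical(), sort_keys=True)
    report = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "version": _package_version(),
            "hazard_raster_convention": "cell-wise CF/PLI from kriged concentrations",
            "elapsed_s": round(time.time() - t0, 2),
        },
        "n_samples": samples.n,
        "metals": per_metal,
        "multivariate": {
            "kmo": round(pca_res.kmo, 4),
            "kmo_adequate": bool(pca_res.kmo > 0.5),
            "bartlett": {
                "chi2": round(pca_res.bartlett_chi2, 3),
                "df": pca_res.bartlett_df,
                "p": float(f"{pca_res.bartlett_p:.3g}"),
            },
            "eigenvalues": [round(v, 4) for v in pca_res.eigenvalues],
            "variance_pct": [round(v, 3) for v in pca_res.variance_pct],
            "cumulative_pct": [round(v, 3) for v in pca_res.cumulative_pct],
            "n_components": pca_res.n_components,
            "cluster_sizes": {str(k): v for k, v in cluster_rep.cluster_sizes.items()},
        },
        "indices": {
            "sample_pli": {
                "min": round(float(contamination["PLI"].min()), 4),
                "mean": round(float(contamination["PLI"].mean()), 4),
                "max": round(float(contamination["PLI"].max()), 4),
            },
            "pli_levels": [
                {
                    "level": str(rec["level"]),
                    "cells": int(rec["cells"]),
                    "area_km2": round(float(rec["area_km2"]), 4),
                    "percentage": round(float(rec["percentage"]), 4),
                }
                for rec in pli_areas.to_dict(orient="records")
            ],
        },
    }
    result = HazardReport(report, samples, contamination, cf_pct, pli_areas, rasters)
    result.to_json(out / "report.json")
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return result


def _package_version() -> str:
    from . import __version__

    return __version__
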