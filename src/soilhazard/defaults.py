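"""Packaged default parameters for the emulated Al-Baha survey.

The YAML shipped under ``soilhazard/data`` holds the survey's published
summary statistics (per-metal mean/sd/min, z-score variograms, Pearson
correlations, two-zone mean shifts), the upper-crust geochemical
backgrounds, the mapped pollution-zone means, and the categorical class
schemes.  Everything here is plain data access; interpretation lives in
the analysis modules.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

__all__ = ["load_defaults", "default_backgrounds", "bbox_km", "zone_means"]


@lru_cache(maxsize=1)
def load_defaults() -> dict:
    """Parsed contents of the packaged default-parameter YAML."""
    ref = resources.files("soilhazard.data").joinpath("albaha_defaults.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def default_backgrounds() -> dict[str, float]:
    """Upper-continental-crust background concentrations, mg/kg."""
    return dict(load_defaults()["backgrounds"])


def zone_means() -> dict[str, dict[str, float]]:
    """Published mean concentrations of the moderate/strong pollution zones."""
    return {k: dict(v) for k, v in load_defaults()["zone_means"].items()}


def bbox_km(cfg: dict | None = None) -> tuple[float, float, float, float]:
    """Planar-km bounding box (xmin, ymin, xmax, ymax) of the study area.

    Longitude/latitude degrees are mapped to km by an equirectangular
    projection: 1 deg lat = ``km_per_degree`` km, 1 deg lon scaled by the
    cosine of the mid-latitude.
    """
    area = (cfg or load_defaults())["study_area"]
    kpd = area["km_per_degree"]
    mid_lat = 0.5 * (area["lat_min"] + area["lat_max"])
    x_extent = (area["lon_max"] - area["lon_min"]) * kpd * np.cos(np.radians(mid_lat))
    y_extent = (area["lat_max"] - area["lat_min"]) * kpd
    return (0.0, 0.0, float(x_extent), float(y_extent))
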