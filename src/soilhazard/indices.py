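"""Contamination indices: CF, PLI, categorical classes, and area accounting.

The contamination factor CF = C_metal / C_background compares a measured
concentration to the geochemical background (average upper continental
crust here).  The pollution load index PLI of a site is the geometric
mean of its CFs over all metals.  Default class schemes:

* CF:  < 1 low, 1-3 moderate, 3-6 considerable, >= 6 very high
  (each threshold belongs to the class above it);
* PLI: <= 1 unpolluted, 1-2 moderate, > 2 strong
  (each threshold belongs to the class below it, so PLI = 1 is clean).

Both schemes are configurable so alternative published cut points can be
swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .defaults import default_backgrounds
from .io import SampleSet, ValidationError

__all__ = [
    "ClassScheme",
    "CF_SCHEME",
    "PLI_SCHEME",
    "contamination_factor",
    "classify_cf",
    "pli",
    "classify_pli",
    "contamination_table",
    "cf_category_percentages",
    "classified_area",
]


@dataclass(frozen=True)
class ClassScheme:
    """Ordered step-function classification of a nonnegative index.

    ``bounds`` are strictly increasing cut points; ``labels`` has one
    more entry than ``bounds``.  ``upper=True`` assigns a value equal to
    a cut point to the class above it (CF convention), ``False`` to the
    class below (PLI convention).
    """

    bounds: tuple[float, ...]
    labels: tuple[str, ...]
    upper: bool = True

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.bounds) + 1:
            raise ValidationError("need exactly len(bounds)+1 labels")
        if any(b2 <= b1 for b1, b2 in zip(self.bounds, self.bounds[1:])):
            raise ValidationError("bounds must be strictly increasing")

    def classify(self, value):
        arr = np.asarray(value, dtype=float)
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ValidationError("index values must be >= 0")
        side = "right" if self.upper else "left"
        idx = np.searchsorted(np.asarray(self.bounds), arr, side=side)
        out = np.asarray(self.labels, dtype=object)[idx]
        out = np.where(np.isfinite(arr), out, None)
        return out.item() if np.isscalar(value) or arr.ndim == 0 else out


CF_SCHEME = ClassScheme((1.0, 3.0, 6.0), ("low", "moderate", "considerable", "very_high"), upper=True)
PLI_SCHEME = ClassScheme((1.0, 2.0), ("unpolluted", "moderate", "strong"), upper=False)


def contamination_factor(c, background: float):
    """CF = concentration / background; background must be positive."""
    if background <= 0:
        raise ValidationError("background concentration must be > 0")
    c = np.asarray(c, dtype=float)
    if np.any(c[np.isfinite(c)] < 0):
        raise ValidationError("concentrations must be >= 0")
    out = c / background
    return float(out) if out.ndim == 0 else out


def classify_cf(cf, scheme: ClassScheme = CF_SCHEME):
    """Contamination-factor category (low/moderate/considerable/very_high)."""
    return scheme.classify(cf)


def pli(cfs, n: int | None = None) -> float:
    """Pollution load index: the n-th root of the product of n CFs.

    Computed in log space for stability; a zero CF forces PLI = 0 (with
    a warning, since a single censored metal then hides all others).
    """
    cfs = np.asarray(cfs, dtype=float).ravel()
    if cfs.size == 0:
        raise ValidationError("PLI needs at least one contamination factor")
    if n is not None and n != cfs.size:
        raise ValidationError(f"n={n} does not match {cfs.size} CF values")
    if np.any(cfs < 0) or np.any(~np.isfinite(cfs)):
        raise ValidationError("contamination factors must be finite and >= 0")
    if np.any(cfs == 0.0):
        warnings.warn("zero contamination factor forces PLI = 0", stacklevel=2)
        return 0.0
    return float(np.exp(np.mean(np.log(cfs))))


def classify_pli(value, scheme: ClassScheme = PLI_SCHEME):
    """Pollution-load-index level (unpolluted/moderate/strong by default)."""
    return scheme.classify(value)


def contamination_table(
    samples: SampleSet,
    backgrounds: dict[str, float] | None = None,
    cf_scheme: ClassScheme = CF_SCHEME,
    pli_scheme: ClassScheme = PLI_SCHEME,
) -> pd.DataFrame:
    """Per-sample CF per metal, CF categories, PLI and PLI level.

    Columns: ``id``, ``CF_<metal>``, ``CFclass_<metal>``, ``PLI``,
    ``PLI_level``.  The PLI of each row is the geometric mean of that
    row's CFs (over the metals present in the table).
    """
    backgrounds = backgrounds if backgrounds is not None else default_backgrounds()
    missing = [m for m in samples.metals if m not in backgrounds]
    if missing:
        raise ValidationError(f"no background concentration for metals: {missing}")
    out = pd.DataFrame({"id": samples.frame["id"]})
    cf_cols = []
    for metal in samples.metals:
        cf = contamination_factor(samples.values(metal), backgrounds[metal])
        out[f"CF_{metal}"] = cf
        out[f"CFclass_{metal}"] = classify_cf(cf, cf_scheme)
        cf_cols.append(f"CF_{metal}")
    cf_matrix = out[cf_cols].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["PLI"] = [pli(row) for row in cf_matrix]
    out["PLI_level"] = classify_pli(out["PLI"].to_numpy(), pli_scheme)
    return out


def cf_category_percentages(
    samples: SampleSet,
    clusters,
    backgrounds: dict[str, float] | None = None,
    cf_scheme: ClassScheme = CF_SCHEME,
) -> pd.DataFrame:
    """Per-cluster, per-metal CF category percentages.

    Returns a long-format table (cluster, metal, category, count,
    percentage); percentages within one (cluster, metal) pair sum to
    100.  Percentages are exact; round only for display.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != samples.n:
        raise ValidationError("cluster labels must cover all samples")
    table = contamination_table(samples, backgrounds, cf_scheme)
    rows = []
    for cluster in np.unique(clusters):
        mask = clusters == cluster
        size = int(mask.sum())
        if size == 0:
            raise ValidationError(f"empty cluster {cluster}")
        for metal in samples.metals:
            cats = table.loc[mask, f"CFclass_{metal}"]
            for label in cf_scheme.labels:
                count = int((cats == label).sum())
                rows.append(
                    {
                        "cluster": cluster,
                        "metal": metal,
                        "category": label,
                        "count": count,
                        "percentage": 100.0 * count / size,
                    }
                )
    return pd.DataFrame(rows)


def classified_area(
    raster,
    cell_size: float,
    total_area: float | None = None,
) -> pd.DataFrame:
    """Area (km^2) and share (%) of each level of a categorical raster.

    Missing cells (None/NaN) are excluded.  ``total_area`` defaults to
    the summed area of mapped cells; pass the surveyed area explicitly
    when the mapped region is known independently of the grid.
    """
    arr = np.asarray(raster, dtype=object).ravel()
    valid = np.array(
        [v is not None and not (isinstance(v, float) and np.isnan(v)) for v in arr]
    )
    if not valid.any():
        raise ValidationError("all raster cells are missing")
    if cell_size <= 0:
        raise ValidationError("cell_size must be > 0")
    labels, counts = np.unique(arr[valid].astype(str), return_counts=True)
    areas = counts * cell_size**2
    total = float(total_area) if total_area is not None else float(areas.sum())
    return pd.DataFrame(
        {
            "level": labels,
            "cells": counts,
            "area_km2": areas,
            "percentage": 100.0 * areas / total,
        }
    )
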