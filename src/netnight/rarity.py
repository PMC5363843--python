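"""Species rarity: local abundance, regional abundance, geographic range,
the independence-weighted rarity index RI, and quartile classes.

Three complementary dimensions of rarity are measured per species within
a dataset:

* ``LA`` — local abundance: for each site where the species occurs, the
  mean number of its captures per replicate night divided by the total
  captures of all species at that site; LA is the median of those
  per-site values.
* ``RA`` — regional abundance: total records in the dataset divided by
  the number of sites at which the species was recorded.
* ``GR`` — geographic range: area (km²) of the minimum convex polygon of
  the occupied-site coordinates.

Each metric is log(x+1)-transformed, min–max standardised to [0, 1]
across species, and combined into a weighted mean

    RI_i = (LA_i·ω_LA + RA_i·ω_RA + GR_i·ω_GR) / (ω_LA + ω_RA + ω_GR)

where each weight expresses how independent its metric is of the other
two, via the Pearson correlations r between the standardised metrics.
Species are then classed Rare (RI ≤ Q1), Common (RI ≥ Q3) or Uncommon.
The index is dataset-relative: the same species can be rare in one
region and common in another.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .io import AbundanceMatrix

EARTH_RADIUS_KM = 6371.0088


def local_abundance(matrix: AbundanceMatrix) -> pd.Series:
    """Median over occupied sites of the species' share of site captures."""
    data = matrix.data
    site_totals = data.groupby(level="site").sum().sum(axis=1)  # all-species captures per site
    mean_per_night = data.groupby(level="site").mean()  # species mean captures/night per site
    share = mean_per_night.div(site_totals, axis=0)
    occupied = data.groupby(level="site").sum() > 0
    la = share.where(occupied).median(axis=0, skipna=True)
    return la.fillna(0.0)


def regional_abundance(matrix: AbundanceMatrix) -> pd.Series:
    """Total dataset records per species divided by its occupied-site count."""
    data = matrix.data
    totals = data.sum(axis=0)
    n_sites = (data.groupby(level="site").sum() > 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ra = totals / n_sites.replace(0, np.nan)
    return ra.fillna(0.0)


def _laea_project(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Spherical Lambert azimuthal equal-area projection (km), centred on
    the point cloud's mean coordinate.  Equal-area by construction, so
    planar hull areas equal spherical ones for regional extents."""
    lam = np.radians(lon)
    phi = np.radians(lat)
    lam0, phi0 = lam.mean(), phi.mean()
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-12, None))
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return np.column_stack([x, y])


def geographic_range(lon: np.ndarray, lat: np.ndarray) -> float:
    """Minimum-convex-polygon area (km²) of occupied-site coordinates.

    Fewer than three non-collinear sites give a degenerate hull: 0 km².
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size == 0:
        raise ValueError("geographic range needs at least one occupied site")
    if np.isnan(lon).any() or np.isnan(lat).any():
        raise ValueError("missing coordinates among occupied sites")
    if lon.size < 3:
        return 0.0
    xy = _laea_project(lon, lat)
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    return float(getattr(hull, "area", 0.0))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = np.min(values), np.max(values)
    if hi - lo == 0:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance metric: treating |r| as 0", stacklevel=3)
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def independence_weights(
    la_s: np.ndarray,
    ra_s: np.ndarray,
    gr_s: np.ndarray,
    variant: str = "half_plus_mean",
) -> tuple[float, float, float]:
    """Weights expressing each metric's independence from the other two.

    ``half_plus_mean`` (default): ω_LA = 1/2 + (1−|r_LARA|)/2 + (1−|r_LAGR|)/2,
    and symmetrically for RA and GR.  ``half_sum_sq`` replaces |r| with r².
    Correlations are computed across species on the standardised metrics —
    the quantities the index actually averages.
    """
    if len(la_s) < 3:
        raise ValueError("independence weights need at least 3 species")
    r_lara = _abs_corr(la_s, ra_s)
    r_lagr = _abs_corr(la_s, gr_s)
    r_ragr = _abs_corr(ra_s, gr_s)
    if variant == "half_plus_mean":
        def omega(r1: float, r2: float) -> float:
            return 0.5 + (1 - r1) / 2 + (1 - r2) / 2
    elif variant == "half_sum_sq":
        def omega(r1: float, r2: float) -> float:
            return 0.5 * ((1 - r1**2) + (1 - r2**2))
    else:
        raise ValueError(f"unknown weight variant {variant!r}")
    return omega(r_lara, r_lagr), omega(r_lara, r_ragr), omega(r_lagr, r_ragr)


def rarity_index(
    la: np.ndarray, ra: np.ndarray, gr: np.ndarray, variant: str = "half_plus_mean"
) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    """RI per species plus the weights and the standardised metric matrix."""
    la, ra, gr = (np.asarray(v, dtype=float) for v in (la, ra, gr))
    if la.size < 2:
        raise ValueError("standardisation needs at least 2 species")
    la_s = _minmax(np.log1p(la))
    ra_s = _minmax(np.log1p(ra))
    gr_s = _minmax(np.log1p(gr))
    w = independence_weights(la_s, ra_s, gr_s, variant=variant)
    ri = (la_s * w[0] + ra_s * w[1] + gr_s * w[2]) / sum(w)
    return ri, w, np.column_stack([la_s, ra_s, gr_s])


def classify_quartiles(ri: np.ndarray) -> np.ndarray:
    """Quartile classes: R if RI ≤ Q1, C if RI ≥ Q3, else U.

    Boundaries are inclusive so distinct values always yield non-empty
    R and C classes.  Degenerate distributions (all equal) satisfy both
    bounds and collapse to all-C with a warning; fewer than 4 species
    cannot support quartiles and are all classed U.
    """
    ri = np.asarray(ri, dtype=float)
    if ri.size < 4:
        warnings.warn("fewer than 4 species: all classified Uncommon", stacklevel=2)
        return np.array(["U"] * ri.size)
    q1, q3 = np.quantile(ri, [0.25, 0.75])
    if q1 == q3:
        warnings.warn("degenerate RI distribution: all classified Common", stacklevel=2)
        return np.array(["C"] * ri.size)
    classes = np.where(ri <= q1, "R", np.where(ri >= q3, "C", "U"))
    return classes


def rarity_profiles(
    matrix: AbundanceMatrix,
    sites: pd.DataFrame,
    variant: str = "half_plus_mean",
    extra_site_coords: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-species rarity table for one dataset.

    ``extra_site_coords`` optionally supplies occupied-site coordinates
    pooled from other datasets, widening the MCP the way a multi-region
    study would; by default the range is computed within the dataset.
    """
    data = matrix.data
    coord_frames = [sites]
    if extra_site_coords is not None:
        coord_frames.append(extra_site_coords)
    coords = pd.concat(coord_frames, ignore_index=True).drop_duplicates("site").set_index("site")

    la = local_abundance(matrix)
    ra = regional_abundance(matrix)
    occupied_by_site = data.groupby(level="site").sum() > 0
    gr = {}
    for sp in data.columns:
        occ = list(occupied_by_site.index[occupied_by_site[sp]])
        if not occ:
            gr[sp] = 0.0
            continue
        missing = [s for s in occ if s not in coords.index]
        if missing:
            raise ValueError(f"missing coordinates for occupied site(s) {missing}")
        gr[sp] = geographic_range(
            coords.loc[occ, "lon"].to_numpy(), coords.loc[occ, "lat"].to_numpy()
        )
    gr = pd.Series(gr)

    ri, w, std = rarity_index(la.to_numpy(), ra.to_numpy(), gr.to_numpy(), variant=variant)
    classes = classify_quartiles(ri)
    table = pd.DataFrame(
        {
            "species": data.columns,
            "n_records": data.sum(axis=0).to_numpy(),
            "LA": la.to_numpy(),
            "RA": ra.to_numpy(),
            "GR_km2": gr.to_numpy(),
            "LA_s": std[:, 0],
            "RA_s": std[:, 1],
            "GR_s": std[:, 2],
            "omega_LA": w[0],
            "omega_RA": w[1],
            "omega_GR": w[2],
            "RI": ri,
            "rarity_class": classes,
        }
    )
    table["flag_zero_records"] = table["n_records"] == 0
    return table
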