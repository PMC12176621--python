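"""Gap-analysis summaries: gridded counts, hemisphere bias, depth statistics,
kernel-density profiles and phylum tallies.

All summaries are pure functions of their inputs — no randomness — so
identical data always yield identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from benthicsplit.bathymetry import BathymetryGrid

__all__ = [
    "depth_median",
    "grid_counts",
    "hemisphere_fraction",
    "kernel_density_profile",
    "phylum_counts",
    "shallowest_fraction_covering",
    "summary_report",
]


class SummaryError(ValueError):
    pass


def grid_counts(records: pd.DataFrame, cell_size: float = 1.0) -> pd.DataFrame:
    """Bin records into half-open lon/lat cells and count per label.

    Cells are ``[lon, lon + cell_size) x [lat, lat + cell_size)`` anchored at
    (-180, -90); longitude 180 wraps into the [-180, ...) cell.  Returns one
    row per non-empty cell with columns ``lon_bin, lat_bin, n_benthic,
    n_pelagic, n_total`` (label columns only when a ``label`` column exists).
    """
    if records.empty:
        return pd.DataFrame(columns=["lon_bin", "lat_bin", "n_total"])
    lon = records["longitude"].to_numpy(dtype=float).copy()
    lat = records["latitude"].to_numpy(dtype=float)
    lon[lon == 180.0] = -180.0
    df = pd.DataFrame(
        {
            "lon_bin": -180.0 + cell_size * np.floor((lon + 180.0) / cell_size),
            "lat_bin": -90.0 + cell_size * np.floor((lat + 90.0) / cell_size),
        }
    )
    if "label" in records.columns:
        df["label"] = records["label"].to_numpy()
        out = (
            df.groupby(["lon_bin", "lat_bin", "label"], observed=True)
            .size()
            .unstack("label", fill_value=0)
            .reset_index()
        )
        for lab in ("benthic", "pelagic"):
            out[f"n_{lab}"] = out.pop(lab) if lab in out.columns else 0
        out["n_total"] = out["n_benthic"] + out["n_pelagic"]
    else:
        out = df.groupby(["lon_bin", "lat_bin"]).size().rename("n_total").reset_index()
    return out.sort_values(["lon_bin", "lat_bin"]).reset_index(drop=True)


def hemisphere_fraction(records: pd.DataFrame) -> float:
    """Fraction of records in the northern hemisphere (latitude > 0).

    Latitude exactly 0 counts as southern, fixed for determinism.
    """
    if records.empty:
        raise SummaryError("hemisphere_fraction: no records")
    return float((records["latitude"] > 0).mean())


def depth_median(records: pd.DataFrame) -> float:
    """Linear-interpolated median of record depth in metres."""
    if records.empty:
        raise SummaryError("depth_median: no records")
    return float(np.median(records["record_depth_m"].to_numpy(dtype=float)))


def kernel_density_profile(
    records: pd.DataFrame,
    axis: str = "latitude",
    bandwidth: float | str = "auto",
    n_grid: int = 512,
    scale: float = 1000.0,
) -> pd.DataFrame:
    """Gaussian kernel density of records along latitude or depth.

    Silverman bandwidth by default; the profile is evaluated on ``n_grid``
    regular points spanning the data range padded by three bandwidths.
    Density values are multiplied by ``scale`` (x1000 by convention, for
    readability); the ``density`` column holds the raw normalised density.
    """
    col = {"latitude": "latitude", "depth": "record_depth_m"}.get(axis)
    if col is None:
        raise SummaryError(f"unknown axis {axis!r}; use 'latitude' or 'depth'")
    values = records[col].to_numpy(dtype=float)
    if np.unique(values).size < 2:
        raise SummaryError(f"kernel density needs >= 2 distinct {axis} values")
    if bandwidth == "auto":
        kde = gaussian_kde(values, bw_method="silverman")
    else:
        kde = gaussian_kde(values, bw_method=float(bandwidth) / values.std(ddof=1))
    bw = kde.factor * values.std(ddof=1)
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, n_grid)
    dens = kde(grid)
    return pd.DataFrame({axis: grid, "density": dens, "density_x1000": scale * dens})


def phylum_counts(
    records: pd.DataFrame, top_n: int = 10
) -> tuple[pd.DataFrame, int]:
    """Ranked phylum tallies (descending count, ties alphabetical).

    Records without a phylum are excluded from the ranking and returned as a
    separate ``unassigned`` count.
    """
    phyla = records.get("phylum", pd.Series(dtype=object))
    missing = phyla.isna() | (phyla.astype(str).str.strip() == "")
    counts = (
        phyla[~missing]
        .value_counts()
        .rename_axis("phylum")
        .reset_index(name="count")
        .sort_values(["count", "phylum"], ascending=[False, True])
        .head(top_n)
        .reset_index(drop=True)
    )
    return counts, int(missing.sum())


def shallowest_fraction_covering(
    records: pd.DataFrame,
    grid: BathymetryGrid,
    mass: float = 0.5,
    area_weighted: bool = True,
) -> float:
    """Fraction of the seafloor shallower than the record-depth quantile at ``mass``.

    Answers "what fraction of the ocean floor do the shallowest ``mass`` of
    records cover?".  Ocean-cell areas are weighted by cos(latitude) of the
    cell center by default (``area_weighted=False`` counts cells instead).
    """
    if records.empty:
        raise SummaryError("shallowest_fraction_covering: no records")
    if not 0 < mass <= 1:
        raise SummaryError("mass must be in (0, 1]")
    q = float(np.quantile(records["record_depth_m"].to_numpy(dtype=float), mass))
    seabed = grid.seabed_depth()
    ocean = ~np.isnan(seabed)
    if not ocean.any():
        raise SummaryError("grid has no ocean cells")
    if area_weighted:
        w = np.cos(np.deg2rad(grid.lat_centers))[:, None] * np.ones(grid.shape[1])[None, :]
    else:
        w = np.ones(grid.shape)
    w_ocean = w[ocean].sum()
    w_shallow = w[ocean & (seabed <= q)].sum()
    return float(w_shallow / w_ocean)


def summary_report(
    records: pd.DataFrame, grid: BathymetryGrid | None = None, top_n: int = 10
) -> dict:
    """JSON-ready gap-analysis report for a classified dataset."""
    report: dict = {"n_records": len(records)}
    for lab in ("benthic", "pelagic"):
        sub = records[records["label"] == lab] if "label" in records.columns else records
        if sub.empty:
            continue
        phyla, unassigned = phylum_counts(sub, top_n=top_n)
        entry = {
            "n": len(sub),
            "northern_fraction": hemisphere_fraction(sub),
            "median_depth_m": depth_median(sub),
            "top_phyla": phyla.to_dict(orient="records"),
            "n_phylum_unassigned": unassigned,
        }
        if grid is not None and lab == "benthic":
            entry["seafloor_fraction_shallowest_half"] = shallowest_fraction_covering(
                sub, grid, mass=0.5
            )
        report[lab] = entry
        if "label" not in records.columns:
            break
    return report
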