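"""Depth-horizon subsets: training data for the benthic-cloud clustering.

A depth horizon is a nominal seabed depth (optionally with a narrow band
around it).  Records whose seabed depth falls in the band form the horizon's
training subset.  Because erroneous entries often carry depths far greater
than the bathymetry allows, each subset is trimmed at an upper quantile of
record depth before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DepthHorizon",
    "HorizonSubset",
    "default_horizons",
    "select_horizon_subset",
    "trim_percentile",
]

#: artifact-default horizon targets in metres (config-driven; any set of
#: seabed depths covering the bathymetric range of interest works)
DEFAULT_HORIZON_DEPTHS = (
    100.0, 250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0,
    2500.0, 3000.0, 3500.0, 4000.0, 4500.0, 5000.0, 6000.0,
)

#: band half-width as a fraction of the target depth
DEFAULT_BAND_FRACTION = 0.01


class HorizonError(ValueError):
    """Raised when a horizon subset cannot be built or trimmed."""


@dataclass(frozen=True)
class DepthHorizon:
    """A seabed-depth value (or narrow band) used to subset records.

    ``band_halfwidth_m = 0`` means an exact-match horizon.
    """

    target_depth_m: float
    band_halfwidth_m: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.target_depth_m < 30:
            raise ValueError(f"horizon target {self.target_depth_m} m must be >= 30 m")
        if self.band_halfwidth_m < 0:
            raise ValueError("band_halfwidth_m must be >= 0")
        if not self.label:
            object.__setattr__(self, "label", f"{self.target_depth_m:g}m")

    @property
    def band(self) -> tuple[float, float]:
        """Closed seabed-depth interval [lo, hi] of the horizon."""
        return (
            self.target_depth_m - self.band_halfwidth_m,
            self.target_depth_m + self.band_halfwidth_m,
        )


def default_horizons(
    depths: tuple[float, ...] = DEFAULT_HORIZON_DEPTHS,
    band_fraction: float = DEFAULT_BAND_FRACTION,
) -> list[DepthHorizon]:
    """The 14 artifact-default horizons with proportional (+-1%) bands."""
    return [DepthHorizon(d, band_fraction * d) for d in depths]


@dataclass
class HorizonSubset:
    """Records whose seabed depth lies within one horizon's band."""

    horizon: DepthHorizon
    records: pd.DataFrame
    trimmed_count: int = 0
    percentile_cut_m: float | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def is_empty(self) -> bool:
        return len(self.records) == 0


def select_horizon_subset(records: pd.DataFrame, horizon: DepthHorizon) -> HorizonSubset:
    """Select records with seabed depth in the horizon's closed band.

    Requires ``seabed_depth_m``; an empty subset is returned (not an error)
    so the caller can skip the horizon with a warning.
    """
    if "seabed_depth_m" not in records.columns:
        raise HorizonError("records lack seabed_depth_m; run attach_seabed_depth first")
    lo, hi = horizon.band
    mask = (records["seabed_depth_m"] >= lo) & (records["seabed_depth_m"] <= hi)
    return HorizonSubset(horizon=horizon, records=records.loc[mask].reset_index(drop=True))


def trim_percentile(
    subset: HorizonSubset, q: float = 0.95, min_size: int = 20
) -> HorizonSubset:
    """Remove records deeper than the q-quantile of record depth.

    The cut is the linear-interpolation (type-7) empirical quantile; records
    with ``record_depth_m`` strictly greater than the cut are removed.  This
    targets erroneous entries whose depths far exceed what the bathymetry
    allows.  At ``q = 0.95`` no more than ``ceil(0.05 n) + 1`` records can be
    removed.
    """
    n = len(subset)
    if n < min_size:
        raise HorizonError(
            f"horizon {subset.horizon.label}: {n} records is below the "
            f"minimum subset size {min_size}"
        )
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    depths = subset.records["record_depth_m"].to_numpy(dtype=float)
    cut = float(np.quantile(depths, q, method="linear"))
    keep = depths <= cut
    return replace(
        subset,
        records=subset.records.loc[keep].reset_index(drop=True),
        trimmed_count=int((~keep).sum()),
        percentile_cut_m=cut,
    )
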