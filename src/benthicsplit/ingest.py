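"""Read occurrence tables, attach seabed depth and apply record-level filters.

Occurrence records are held in a :class:`pandas.DataFrame` with canonical
columns::

    record_id        opaque string
    latitude         degrees in [-90, 90]
    longitude        degrees in [-180, 180]
    record_depth_m   observation depth, metres positive down, >= 0
    phylum, kingdom, scientific_name   optional strings
    seabed_depth_m   metres positive down (added by attach_seabed_depth)

Input files use Darwin-Core-style headers (the OBIS export dialect) by
default; a ``column_map`` overrides individual names.  Malformed rows are
never silently dropped: every reader/filter returns a
:class:`RejectionReport` so that input count = survivors + rejections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from benthicsplit.bathymetry import BathymetryGrid

__all__ = [
    "CANONICAL_COLUMNS",
    "DWC_COLUMN_MAP",
    "RejectionReport",
    "attach_seabed_depth",
    "filter_depth_range",
    "read_occurrences",
    "write_occurrences",
]

#: canonical name -> Darwin Core term used in input/output files
DWC_COLUMN_MAP: dict[str, str] = {
    "record_id": "occurrenceID",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "depth": "depth",
    "depth_min": "minimumDepthInMeters",
    "depth_max": "maximumDepthInMeters",
    "phylum": "phylum",
    "kingdom": "kingdom",
    "scientific_name": "scientificName",
}

CANONICAL_COLUMNS = [
    "record_id",
    "latitude",
    "longitude",
    "record_depth_m",
    "phylum",
    "kingdom",
    "scientific_name",
]


class IngestError(ValueError):
    """Fatal configuration or I/O error while reading occurrence data."""


@dataclass
class RejectionReport:
    """Per-record rejection log for one filtering operation.

    ``n_input == n_valid + len(rejections)`` always holds.
    """

    operation: str
    n_input: int
    n_valid: int
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["record_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.n_input != self.n_valid + len(self.rejections):
            raise ValueError(
                f"{self.operation}: record count not conserved "
                f"({self.n_input} != {self.n_valid} + {len(self.rejections)})"
            )

    @property
    def counts(self) -> dict[str, int]:
        """Rejection count per reason."""
        if self.rejections.empty:
            return {}
        return self.rejections["reason"].value_counts().to_dict()

    def to_csv(self, path: str | Path) -> None:
        self.rejections.to_csv(path, index=False)


def read_occurrences(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
    interval_midpoint: bool = True,
) -> tuple[pd.DataFrame, RejectionReport]:
    """Read a delimited occurrence table and validate every row.

    Parameters
    ----------
    path
        CSV/TSV file with a header row (UTF-8).
    column_map
        Overrides for :data:`DWC_COLUMN_MAP` entries (canonical -> file name).
    delimiter
        Field separator; inferred from the extension when omitted
        (``.tsv`` -> tab, else comma).
    interval_midpoint
        When the single ``depth`` column is absent or empty but both
        minimum/maximum depth columns parse, use their midpoint (the OBIS
        ``depth`` convention).

    Returns
    -------
    (records, report)
        Valid records satisfying all invariants, plus the rejection report
        covering every discarded input row.
    """
    path = Path(path)
    cmap = dict(DWC_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise IngestError(f"cannot read occurrence file {path}: {exc}") from exc
    except pd.errors.ParserError as exc:
        raise IngestError(f"unparseable occurrence file {path}: {exc}") from exc

    for canonical in ("latitude", "longitude"):
        if cmap[canonical] not in raw.columns:
            raise IngestError(
                f"required column '{cmap[canonical]}' (for {canonical}) missing from {path}"
            )
    has_depth = cmap["depth"] in raw.columns
    has_interval = cmap["depth_min"] in raw.columns and cmap["depth_max"] in raw.columns
    if not has_depth and not has_interval:
        raise IngestError(
            f"no depth column in {path}: need '{cmap['depth']}' or both "
            f"'{cmap['depth_min']}'/'{cmap['depth_max']}'"
        )

    n = len(raw)
    if cmap["record_id"] in raw.columns:
        record_id = raw[cmap["record_id"]].astype(str)
    else:
        record_id = pd.Series([f"row{i}" for i in range(n)], index=raw.index)

    lat = pd.to_numeric(raw[cmap["latitude"]], errors="coerce")
    lon = pd.to_numeric(raw[cmap["longitude"]], errors="coerce")
    depth = pd.to_numeric(raw[cmap["depth"]], errors="coerce") if has_depth else pd.Series(np.nan, index=raw.index)
    if interval_midpoint and has_interval:
        dmin = pd.to_numeric(raw[cmap["depth_min"]], errors="coerce")
        dmax = pd.to_numeric(raw[cmap["depth_max"]], errors="coerce")
        midpoint = 0.5 * (dmin + dmax)
        depth = depth.fillna(midpoint)

    reason = pd.Series("", index=raw.index, dtype=object)
    bad_lat = lat.isna() | (lat < -90) | (lat > 90)
    bad_lon = lon.isna() | (lon < -180) | (lon > 180)
    missing_depth = depth.isna()
    neg_depth = ~missing_depth & (depth < 0)
    # first failing check wins, in a fixed order
    reason[neg_depth] = "negative depth"
    reason[missing_depth] = "missing depth"
    reason[bad_lon] = "invalid longitude"
    reason[bad_lat] = "invalid latitude"
    ok = reason == ""

    def _opt(canonical: str) -> pd.Series:
        col = cmap[canonical]
        if col in raw.columns:
            s = raw[col].replace("", pd.NA)
            return s
        return pd.Series(pd.NA, index=raw.index, dtype=object)

    records = pd.DataFrame(
        {
            "record_id": record_id[ok],
            "latitude": lat[ok],
            "longitude": lon[ok],
            "record_depth_m": depth[ok],
            "phylum": _opt("phylum")[ok],
            "kingdom": _opt("kingdom")[ok],
            "scientific_name": _opt("scientific_name")[ok],
        }
    ).reset_index(drop=True)
    report = RejectionReport(
        operation="read_occurrences",
        n_input=n,
        n_valid=len(records),
        rejections=pd.DataFrame(
            {"record_id": record_id[~ok], "reason": reason[~ok]}
        ).reset_index(drop=True),
    )
    return records, report


def write_occurrences(records: pd.DataFrame, path: str | Path) -> None:
    """Write records in the Darwin-Core CSV dialect :func:`read_occurrences` reads."""
    out = pd.DataFrame(
        {
            DWC_COLUMN_MAP["record_id"]: records["record_id"],
            DWC_COLUMN_MAP["latitude"]: records["latitude"],
            DWC_COLUMN_MAP["longitude"]: records["longitude"],
            DWC_COLUMN_MAP["depth"]: records["record_depth_m"],
        }
    )
    for canonical in ("phylum", "kingdom", "scientific_name"):
        if canonical in records.columns:
            out[DWC_COLUMN_MAP[canonical]] = records[canonical]
    out.to_csv(path, index=False)


def attach_seabed_depth(
    records: pd.DataFrame, grid: BathymetryGrid
) -> tuple[pd.DataFrame, RejectionReport]:
    """Attach nearest-cell seabed depth; drop records over land or off-grid.

    Seabed depth is the (positive) depth of the grid cell containing each
    record's coordinates — no interpolation.  Records in cells with
    elevation >= 0 are removed with reason ``"on land"`` (the classic
    museum-location artefact); records outside the grid extent with reason
    ``"outside grid"``.
    """
    depth, status = grid.seabed_depth_at(
        records["longitude"].to_numpy(), records["latitude"].to_numpy()
    )
    ok = status == "ocean"
    survivors = records.loc[ok].copy()
    survivors["seabed_depth_m"] = depth[ok]
    report = RejectionReport(
        operation="attach_seabed_depth",
        n_input=len(records),
        n_valid=int(ok.sum()),
        rejections=pd.DataFrame(
            {"record_id": records.loc[~ok, "record_id"], "reason": status[~ok]}
        ).reset_index(drop=True),
    )
    return survivors.reset_index(drop=True), report


def filter_depth_range(
    records: pd.DataFrame, min_depth: float = 30.0
) -> tuple[pd.DataFrame, RejectionReport]:
    """Keep records with ``record_depth_m >= min_depth`` (inclusive bound).

    The 30 m default excludes recreational-diver depths, the convention for
    "offshore" data; there is no upper bound.
    """
    ok = records["record_depth_m"] >= min_depth
    report = RejectionReport(
        operation="filter_depth_range",
        n_input=len(records),
        n_valid=int(ok.sum()),
        rejections=pd.DataFrame(
            {
                "record_id": records.loc[~ok, "record_id"],
                "reason": f"depth shallower than {min_depth:g} m",
            }
        ).reset_index(drop=True),
    )
    return records.loc[ok].reset_index(drop=True), report
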