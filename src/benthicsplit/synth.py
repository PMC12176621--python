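"""Synthetic bathymetry and labelled occurrence data with known ground truth.

The generator emulates the statistical structure the classifier assumes:

* a **benthic cloud** concentrated just above the seabed — depths drawn as
  ``seabed - |N(0, benthic_offset_sd_m)|`` with the offset truncated at four
  standard deviations;
* a **surface-biased pelagic column** — depths ``30 + Exp(pelagic_surface_
  scale_m)`` truncated below the benthic cloud's ceiling
  (``seabed - 4 * benthic_offset_sd_m``), so truth labels are unambiguous;
* a small fraction of **erroneous** records deeper than the seabed
  (``seabed * U(1.1, 3)``), the classic depth-entry error;
* optional **trawl-line artefacts**: equally spaced tracks of truly pelagic
  records whose depth entry was (mis)filled with the seabed depth;
* configurable hemisphere bias and phylum composition.

Everything is driven by one seed; identical configuration gives
bitwise-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from benthicsplit.bathymetry import BathymetryGrid
from benthicsplit.horizons import DEFAULT_HORIZON_DEPTHS

__all__ = [
    "GeneratorConfig",
    "RecoveryMetrics",
    "evaluate_recovery",
    "make_bathymetry",
    "simulate_records",
]

#: qualitative phylum mix: vertebrate-dominated, arthropods second — the
#: composition bias typical of trawl-heavy occurrence databases
DEFAULT_PHYLUM_WEIGHTS: dict[str, float] = {
    "Chordata": 0.45,
    "Arthropoda": 0.25,
    "Mollusca": 0.10,
    "Echinodermata": 0.07,
    "Cnidaria": 0.06,
    "Annelida": 0.04,
    "Porifera": 0.03,
}


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic occurrence generator."""

    seed: int = 0
    n_records: int = 50_000
    benthic_fraction: float = 0.66
    benthic_offset_sd_m: float = 25.0
    pelagic_surface_scale_m: float = 150.0
    erroneous_fraction: float = 0.01
    trawl_line_count: int = 0
    trawl_line_length: int = 100
    northern_fraction: float = 0.79
    min_depth_m: float = 30.0
    phylum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_WEIGHTS)
    )

    def __post_init__(self) -> None:
        for name in ("benthic_fraction", "erroneous_fraction", "northern_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise GeneratorError(f"{name}={v} must be in [0, 1]")
        if self.benthic_fraction + self.erroneous_fraction > 1:
            raise GeneratorError("benthic_fraction + erroneous_fraction exceeds 1")
        for name in ("benthic_offset_sd_m", "pelagic_surface_scale_m"):
            if getattr(self, name) <= 0:
                raise GeneratorError(f"{name} must be positive")
        if self.n_records < 1:
            raise GeneratorError("n_records must be >= 1")
        w = sum(self.phylum_weights.values())
        if w <= 0:
            raise GeneratorError("phylum_weights must sum to a positive value")


def make_bathymetry(
    seed: int = 0,
    extent: tuple[float, float, float, float] = (-30.0, 30.0, -60.0, 60.0),
    resolution: float = 0.5,
    horizon_depths: tuple[float, ...] = DEFAULT_HORIZON_DEPTHS,
    max_depth_m: float = 6500.0,
    noise_fraction: float = 0.02,
    land_fraction: float = 0.05,
) -> BathymetryGrid:
    """Deterministic shelf-slope-abyss ramp with exact-depth horizon stripes.

    Elevation descends from a land margin on the western edge through a
    shelf (~40 m) down to ``max_depth_m`` along longitude, with seeded
    low-amplitude noise.  For each horizon depth, the two ramp columns
    closest to it are set to exactly that depth, guaranteeing that every
    horizon band contains grid cells.
    """
    lon0, lon1, lat0, lat1 = extent
    nx = int(round((lon1 - lon0) / resolution))
    ny = int(round((lat1 - lat0) / resolution))
    if nx < 2 or ny < 1:
        raise GeneratorError("extent/resolution give an empty grid")
    n_land = max(1, int(round(land_fraction * nx)))
    n_ocean = nx - n_land
    if n_ocean < 2 * len(horizon_depths) + 2:
        raise GeneratorError(
            f"resolution too coarse: {n_ocean} ocean columns cannot hold "
            f"{len(horizon_depths)} horizons (need {2 * len(horizon_depths) + 2})"
        )
    rng = np.random.default_rng(seed)
    ramp = np.linspace(40.0, max_depth_m, n_ocean)  # per-column nominal depth
    depth_cols = np.repeat(ramp[None, :], ny, axis=0)
    depth_cols *= 1.0 + noise_fraction * rng.standard_normal((ny, n_ocean))
    # stamp exact horizon depths into the two nearest ramp columns
    for target in horizon_depths:
        j = int(np.abs(ramp - target).argmin())
        depth_cols[:, j] = target
        depth_cols[:, min(j + 1, n_ocean - 1)] = target
    depth_cols = np.clip(depth_cols, 5.0, None)
    elevation = np.concatenate(
        [np.full((ny, n_land), 50.0), -depth_cols], axis=1
    )
    lon_edges = lon0 + resolution * np.arange(nx + 1)
    lat_edges = lat0 + resolution * np.arange(ny + 1)
    return BathymetryGrid(lon_edges=lon_edges, lat_edges=lat_edges, elevation_m=elevation)


def _truncated_abs_normal(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    """|N(0, sd)| truncated at 4 sd (redraw), vectorised."""
    out = np.abs(rng.normal(0.0, sd, size))
    bad = out > 4 * sd
    while bad.any():
        out[bad] = np.abs(rng.normal(0.0, sd, int(bad.sum())))
        bad = out > 4 * sd
    return out


def _truncated_exponential(
    rng: np.random.Generator, scale: float, lo: float, hi: np.ndarray
) -> np.ndarray:
    """lo + Exp(scale) truncated to [lo, hi) by inverse-CDF sampling."""
    u = rng.random(hi.size)
    cap = 1.0 - np.exp(-(hi - lo) / scale)
    return lo - scale * np.log1p(-u * cap)


def _pick_cells(
    rng: np.random.Generator,
    eligible_iy: np.ndarray,
    eligible_ix: np.ndarray,
    lat_centers: np.ndarray,
    n: int,
    northern_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample cells (with replacement) with an exact hemisphere split."""
    north = lat_centers[eligible_iy] > 0
    n_north = int(round(n * northern_fraction))
    n_south = n - n_north
    picks = []
    for mask, count in ((north, n_north), (~north, n_south)):
        pool = np.flatnonzero(mask)
        if count > 0 and pool.size == 0:
            pool = np.arange(eligible_iy.size)  # hemisphere empty: fall back to all
        if count > 0:
            picks.append(rng.choice(pool, size=count, replace=True))
    sel = np.concatenate(picks) if picks else np.empty(0, dtype=np.int64)
    return eligible_iy[sel], eligible_ix[sel]


def simulate_records(
    config: GeneratorConfig, grid: BathymetryGrid
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Draw a labelled occurrence dataset over a bathymetry grid.

    Returns ``(records, info)``: records carry the canonical occurrence
    columns plus ``true_label`` (benthic / pelagic / erroneous),
    ``true_seabed_m`` and ``trawl_line`` (-1 for ordinary records), already
    shuffled; ``info`` reports class counts and the number of pelagic draws
    re-homed to deeper cells because their cell was too shallow for an
    unambiguous pelagic depth.

    Class counts are exact by construction: ``round(n * benthic_fraction)``
    benthic and ``round(n * erroneous_fraction)`` erroneous records, the
    rest pelagic.  Trawl-line records (``trawl_line_count`` lines of
    ``trawl_line_length`` points, truly pelagic but with the seabed depth in
    the depth field) are appended on top of ``n_records``.
    """
    rng = np.random.default_rng(config.seed)
    seabed = grid.seabed_depth()
    lat_c, lon_c = grid.lat_centers, grid.lon_centers
    res_lon, res_lat = grid.resolution

    ocean = ~np.isnan(seabed)
    benthic_ok = ocean & (seabed >= config.min_depth_m)
    pelagic_ceiling = seabed - 4 * config.benthic_offset_sd_m
    pelagic_ok = ocean & (pelagic_ceiling > config.min_depth_m)
    if not benthic_ok.any():
        raise GeneratorError("no ocean cells deep enough for benthic records")
    if not pelagic_ok.any():
        raise GeneratorError("no ocean cells deep enough for unambiguous pelagic records")

    n = config.n_records
    n_benthic = int(round(n * config.benthic_fraction))
    n_err = int(round(n * config.erroneous_fraction))
    n_pelagic = n - n_benthic - n_err

    def cells_of(mask: np.ndarray, count: int) -> tuple[np.ndarray, np.ndarray]:
        iy, ix = np.nonzero(mask)
        return _pick_cells(rng, iy, ix, lat_c, count, config.northern_fraction)

    # benthic: just above the seabed
    by, bx = cells_of(benthic_ok, n_benthic)
    b_seabed = seabed[by, bx]
    b_depth = np.maximum(
        config.min_depth_m, b_seabed - _truncated_abs_normal(rng, config.benthic_offset_sd_m, n_benthic)
    )

    # pelagic: surface-biased, kept clear of the benthic cloud; draws landing
    # in too-shallow cells are re-homed to a random eligible deep cell
    py, px = cells_of(ocean & (seabed >= config.min_depth_m), n_pelagic)
    shallow = pelagic_ceiling[py, px] <= config.min_depth_m
    n_redrawn = int(shallow.sum())
    if n_redrawn:
        ry, rx = cells_of(pelagic_ok, n_redrawn)
        py[shallow], px[shallow] = ry, rx
    p_ceiling = pelagic_ceiling[py, px]
    p_depth = _truncated_exponential(
        rng, config.pelagic_surface_scale_m, config.min_depth_m, p_ceiling
    )

    # erroneous: deeper than the seabed allows
    ey, ex = cells_of(benthic_ok, n_err)
    e_seabed = seabed[ey, ex]
    e_depth = e_seabed * rng.uniform(1.1, 3.0, n_err)

    iy = np.concatenate([by, py, ey])
    ix = np.concatenate([bx, px, ex])
    depth = np.concatenate([b_depth, p_depth, e_depth])
    true_label = np.concatenate(
        [
            np.repeat("benthic", n_benthic),
            np.repeat("pelagic", n_pelagic),
            np.repeat("erroneous", n_err),
        ]
    )
    trawl_id = np.full(iy.size, -1, dtype=np.int64)

    # trawl-line artefacts: constant-depth pelagic tows mis-entered with the
    # seabed depth at each ping
    for line in range(config.trawl_line_count):
        ty, tx = cells_of(pelagic_ok, 1)
        step = rng.choice([-1, 1]) * max(1, int(round(0.5 / res_lat)))
        ys = np.clip(ty[0] + step * np.arange(config.trawl_line_length), 0, grid.shape[0] - 1)
        xs = np.full_like(ys, tx[0])
        keep = ~np.isnan(seabed[ys, xs])
        iy = np.concatenate([iy, ys[keep]])
        ix = np.concatenate([ix, xs[keep]])
        depth = np.concatenate([depth, seabed[ys[keep], xs[keep]]])
        true_label = np.concatenate([true_label, np.repeat("pelagic", int(keep.sum()))])
        trawl_id = np.concatenate([trawl_id, np.full(int(keep.sum()), line, dtype=np.int64)])

    total = iy.size
    jitter_lon = rng.uniform(-0.499, 0.499, total) * res_lon
    jitter_lat = rng.uniform(-0.499, 0.499, total) * res_lat
    phyla = np.array(list(config.phylum_weights))
    weights = np.array(list(config.phylum_weights.values()), dtype=float)
    weights = weights / weights.sum()

    records = pd.DataFrame(
        {
            "latitude": lat_c[iy] + jitter_lat,
            "longitude": lon_c[ix] + jitter_lon,
            "record_depth_m": depth,
            "phylum": rng.choice(phyla, size=total, p=weights),
            "kingdom": "Animalia",
            "scientific_name": pd.NA,
            "true_label": true_label,
            "true_seabed_m": seabed[iy, ix],
            "trawl_line": trawl_id,
        }
    )
    records = records.sample(frac=1.0, random_state=np.random.RandomState(config.seed)).reset_index(
        drop=True
    )
    records.insert(0, "record_id", [f"r{i:07d}" for i in range(total)])
    info = {
        "n_benthic_truth": n_benthic,
        "n_pelagic_truth": n_pelagic + (total - n),
        "n_erroneous_truth": n_err,
        "n_trawl_points": int(total - n),
        "n_pelagic_redrawn_deeper": n_redrawn,
        "n_total": int(total),
    }
    return records, info


@dataclass
class RecoveryMetrics:
    """Classification quality against generator truth."""

    confusion: pd.DataFrame          # truth class x predicted label
    accuracy: float                  # over benthic/pelagic truth records
    expected_accuracy: float         # erroneous truth scored as expected-benthic
    precision: dict[str, float]
    recall: dict[str, float]
    erroneous_labelled_benthic: float


def evaluate_recovery(
    classified: pd.DataFrame, truth: pd.DataFrame
) -> RecoveryMetrics:
    """Score predicted labels against the generator's truth labels.

    ``classified`` needs ``record_id`` and ``label``; ``truth`` needs
    ``record_id`` and ``true_label``.  Erroneous-truth records (deeper than
    the seabed) are scored separately: under the classification rule their
    expected label is benthic.  ``accuracy`` covers benthic/pelagic truth
    only; ``expected_accuracy`` additionally counts an erroneous record as
    correct when labelled benthic.
    """
    merged = classified[["record_id", "label"]].merge(
        truth[["record_id", "true_label"]], on="record_id", how="outer", indicator=True
    )
    if (merged["_merge"] != "both").any():
        missing = int((merged["_merge"] != "both").sum())
        raise GeneratorError(f"record id mismatch between classified and truth ({missing} rows)")
    confusion = pd.crosstab(merged["true_label"], merged["label"])
    bp = merged[merged["true_label"].isin(["benthic", "pelagic"])]
    correct = (bp["label"] == bp["true_label"]).sum()
    accuracy = float(correct / len(bp)) if len(bp) else float("nan")
    err = merged[merged["true_label"] == "erroneous"]
    err_benthic = float((err["label"] == "benthic").mean()) if len(err) else float("nan")
    expected_ok = correct + (err["label"] == "benthic").sum()
    expected_accuracy = float(expected_ok / len(merged))
    precision, recall = {}, {}
    for lab in ("benthic", "pelagic"):
        pred = merged["label"] == lab
        true = bp["true_label"] == lab
        precision[lab] = float((bp.loc[bp["label"] == lab, "true_label"] == lab).mean()) if (bp["label"] == lab).any() else float("nan")
        recall[lab] = float((bp.loc[true, "label"] == lab).mean()) if true.any() else float("nan")
        del pred
    return RecoveryMetrics(
        confusion=confusion,
        accuracy=accuracy,
        expected_accuracy=expected_accuracy,
        precision=precision,
        recall=recall,
        erroneous_labelled_benthic=err_benthic,
    )
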