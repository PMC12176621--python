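"""End-to-end pipeline: ingest -> horizons -> clustering -> model -> classify -> summaries.

One :class:`PipelineConfig` drives the whole run.  Every stage's record
counts are written into a :class:`RunManifest` whose conservation ledger
must reconcile: raw input = valid + rejected, valid = ocean + land/off-grid,
classified = benthic + pelagic.  Re-running with identical config and
inputs reproduces byte-identical outputs (no timestamps, all randomness
seeded, deterministic tie-breaks throughout).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from benthicsplit._version import __version__ as _VERSION
from benthicsplit.bathymetry import BathymetryGrid, read_bathymetry
from benthicsplit.cloud_model import (
    BenthicCloudModel,
    classify,
    fit_benthic_minima_model,
    save_model,
)
from benthicsplit.clustering import cluster_horizon
from benthicsplit.horizons import (
    DEFAULT_BAND_FRACTION,
    DEFAULT_HORIZON_DEPTHS,
    DepthHorizon,
    select_horizon_subset,
    trim_percentile,
)
from benthicsplit.ingest import (
    RejectionReport,
    attach_seabed_depth,
    filter_depth_range,
    read_occurrences,
)
from benthicsplit.summaries import grid_counts, summary_report
from benthicsplit.synth import GeneratorConfig

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "child_seed"]

log = logging.getLogger("benthicsplit")


def child_seed(master: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class HorizonStageConfig:
    targets: list[float] = field(default_factory=lambda: list(DEFAULT_HORIZON_DEPTHS))
    band_fraction: float = DEFAULT_BAND_FRACTION
    trim_q: float = 0.95
    min_subset_size: int = 20

    def horizons(self) -> list[DepthHorizon]:
        return [DepthHorizon(t, self.band_fraction * t) for t in self.targets]


@dataclass
class ClusterStageConfig:
    kmin: int = 2
    kmax: int = 10
    pam_threshold: int = 2000
    n_subsamples: int = 5
    subsample_size: int | None = None
    #: horizon label -> fixed k, the hook for expert-chosen solutions
    k_override: dict[str, int] = field(default_factory=dict)


@dataclass
class ModelStageConfig:
    basis_dim: int = 10
    degree: int = 3
    min_pairs: int = 6


@dataclass
class IngestStageConfig:
    min_depth_m: float = 30.0
    column_map: dict[str, str] = field(default_factory=dict)
    interval_midpoint: bool = True
    delimiter: str | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    ingest: IngestStageConfig = field(default_factory=IngestStageConfig)
    horizons: HorizonStageConfig = field(default_factory=HorizonStageConfig)
    clustering: ClusterStageConfig = field(default_factory=ClusterStageConfig)
    model: ModelStageConfig = field(default_factory=ModelStageConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs: dict = {"seed": data.get("seed", 0)}
        sections = {
            "ingest": IngestStageConfig,
            "horizons": HorizonStageConfig,
            "clustering": ClusterStageConfig,
            "model": ModelStageConfig,
            "generator": GeneratorConfig,
        }
        for name, klass in sections.items():
            if name in data:
                kwargs[name] = klass(**data[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)


@dataclass
class RunManifest:
    """Machine-readable account of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    input_digests: dict[str, str]
    counts: dict[str, int]
    horizon_table: list[dict]
    rejection_reasons: dict[str, dict[str, int]]
    model_diagnostics: dict[str, float]

    def reconciles(self) -> bool:
        """Conservation ledger: every stage's counts must balance."""
        c = self.counts
        ok = c["n_raw"] == c["n_valid"] + c["n_read_rejected"]
        ok &= c["n_valid"] == c["n_with_seabed"] + c["n_land_or_offgrid"]
        ok &= c["n_with_seabed"] == c["n_depth_filtered"] + c["n_too_shallow"]
        ok &= c["n_depth_filtered"] == c["n_benthic"] + c["n_pelagic"]
        return bool(ok)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    occurrences: str | Path | pd.DataFrame,
    bathymetry: str | Path | BathymetryGrid,
    out_dir: str | Path | None = None,
) -> tuple[RunManifest, dict]:
    """Execute the full classification pipeline.

    ``occurrences``/``bathymetry`` may be file paths (CSV/TSV, NetCDF) or
    in-memory objects.  When ``out_dir`` is given, all stage outputs are
    written there: classified records, rejection reports, horizon audit,
    cluster diagnostics, model JSON, summaries and the run manifest.

    Returns ``(manifest, results)`` where results holds the classified
    DataFrame (``"classified"``), the fitted model (``"model"``), the
    horizon envelopes (``"envelopes"``) and the summary report
    (``"summary"``).
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}
    rejections: dict[str, dict[str, int]] = {}

    # stage 1: read inputs
    if isinstance(occurrences, (str, Path)):
        digests["occurrences"] = _digest(Path(occurrences))
        records, read_report = read_occurrences(
            occurrences,
            column_map=config.ingest.column_map or None,
            delimiter=config.ingest.delimiter,
            interval_midpoint=config.ingest.interval_midpoint,
        )
    else:
        digests["occurrences"] = "in-memory"
        records = occurrences.reset_index(drop=True)
        read_report = RejectionReport("read_occurrences", len(records), len(records))
    rejections["read"] = read_report.counts
    n_raw, n_valid = read_report.n_input, len(records)
    log.info("ingest: %d raw rows, %d valid records", n_raw, n_valid)

    if isinstance(bathymetry, (str, Path)):
        digests["bathymetry"] = _digest(Path(bathymetry))
        grid = read_bathymetry(bathymetry)
    else:
        digests["bathymetry"] = "in-memory"
        grid = bathymetry
    log.info(
        "bathymetry: %dx%d cells, resolution %.4g x %.4g deg",
        *grid.shape, *grid.resolution
    )

    # stage 2: seabed depth + depth filter
    records, seabed_report = attach_seabed_depth(records, grid)
    rejections["seabed"] = seabed_report.counts
    records, depth_report = filter_depth_range(records, config.ingest.min_depth_m)
    rejections["depth_filter"] = depth_report.counts
    log.info(
        "seabed attach: %d kept, %d removed; depth filter: %d kept",
        seabed_report.n_valid, len(seabed_report.rejections), len(records),
    )

    # stage 3+4: horizon subsets, trim, cluster
    envelopes = []
    horizon_table: list[dict] = []
    diag_rows: list[dict] = []
    for horizon in config.horizons.horizons():
        subset = select_horizon_subset(records, horizon)
        row: dict = {"horizon": horizon.label, "n_before": len(subset)}
        if len(subset) < config.horizons.min_subset_size:
            row.update(skipped=True, reason="too few records")
            horizon_table.append(row)
            log.warning("horizon %s skipped: %d records", horizon.label, len(subset))
            continue
        trimmed = trim_percentile(
            subset, q=config.horizons.trim_q, min_size=config.horizons.min_subset_size
        )
        env, sol = cluster_horizon(
            trimmed,
            kmin=config.clustering.kmin,
            kmax=config.clustering.kmax,
            seed=child_seed(config.seed, f"cluster:{horizon.label}"),
            k_override=config.clustering.k_override.get(horizon.label),
            pam_threshold=config.clustering.pam_threshold,
            n_subsamples=config.clustering.n_subsamples,
            subsample_size=config.clustering.subsample_size,
        )
        envelopes.append(env)
        row.update(
            skipped=False,
            n_after_trim=len(trimmed),
            trimmed=trimmed.trimmed_count,
            percentile_cut_m=trimmed.percentile_cut_m,
            chosen_k=env.chosen_k,
            asw=sol.asw,
            benthic_min_m=env.benthic_min_m,
            benthic_max_m=env.benthic_max_m,
            fallback=env.fallback,
            n_members=env.n_members,
        )
        horizon_table.append(row)
        for k, asw in env.asw_by_k.items():
            diag_rows.append({"horizon": horizon.label, "k": k, "asw": asw})
        log.info(
            "horizon %s: n=%d, k=%d, ASW=%.3f, envelope [%.1f, %.1f] m",
            horizon.label, len(trimmed), env.chosen_k, sol.asw or float("nan"),
            env.benthic_min_m, env.benthic_max_m,
        )

    # stage 5: threshold model
    model = fit_benthic_minima_model(
        envelopes,
        basis_dim=config.model.basis_dim,
        degree=config.model.degree,
        min_pairs=config.model.min_pairs,
    )
    log.info(
        "model: edf=%.2f, deviance explained=%.4f, alpha=%.3g",
        model.edf, model.deviance_explained, model.alpha,
    )

    # stage 6: classification
    classified, counts = classify(records, model)
    log.info("classified: %d benthic, %d pelagic", counts["n_benthic"], counts["n_pelagic"])

    # stage 7: summaries
    summary = summary_report(classified, grid)
    cells = grid_counts(classified)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=_VERSION,
        input_digests=digests,
        counts={
            "n_raw": n_raw,
            "n_valid": n_valid,
            "n_read_rejected": n_raw - n_valid,
            "n_with_seabed": seabed_report.n_valid,
            "n_land_or_offgrid": len(seabed_report.rejections),
            "n_depth_filtered": depth_report.n_valid,
            "n_too_shallow": len(depth_report.rejections),
            "n_benthic": counts["n_benthic"],
            "n_pelagic": counts["n_pelagic"],
            "n_qc_flagged": counts["n_qc_flagged"],
            "n_horizons_used": len(envelopes),
        },
        horizon_table=horizon_table,
        rejection_reasons=rejections,
        model_diagnostics={
            "edf": model.edf,
            "deviance_explained": model.deviance_explained,
            "alpha": model.alpha,
            "scale": model.scale,
        },
    )
    if not manifest.reconciles():
        raise RuntimeError("manifest conservation ledger does not reconcile")

    results = {
        "classified": classified,
        "model": model,
        "envelopes": envelopes,
        "summary": summary,
        "grid_counts": cells,
    }
    if out is not None:
        classified.to_csv(out / "classified.csv", index=False)
        pd.DataFrame(horizon_table).to_csv(out / "horizon_audit.csv", index=False)
        pd.DataFrame(diag_rows).to_csv(out / "cluster_diagnostics.csv", index=False)
        model.diagnostics_table().to_csv(out / "model_diagnostics.csv", index=False)
        save_model(model, out / "model.json")
        cells.to_csv(out / "grid_counts.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        pd.concat(
            [read_report.rejections, seabed_report.rejections, depth_report.rejections]
        ).to_csv(out / "rejections.csv", index=False)
        manifest.to_json(out / "manifest.json")
    return manifest, results
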