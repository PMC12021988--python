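"""End-to-end orchestration: ingest/generate → filter → annotate → analyses.

A run is specified by a :class:`RunConfig` (optionally loaded from YAML),
executes its enabled stages in a fixed order in a single process, writes all
module exports as plain CSV/JSON, and finishes with a manifest recording
parameters, seeds, input hashes and filter tallies so a run is fully
reconstructible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import results_frame, subgroup_analysis
from .dataset import AnalysisParams, StudyDataset
from .emd import cohort_histograms, emd_1d, emd_2d, histogram_1d
from .geometry import annotate_positions, pooled_counts
from .io import apply_study_filters, read_qupath_geojson, read_tabular, write_tabular
from .randomness import population_r_values
from .synthetic import SyntheticConfig, generate_cohort

log = logging.getLogger("isletmc")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "islet-mc-run"
    seed: Optional[int] = None
    # input: either a synthetic config or paths to detection exports
    synthetic: Optional[SyntheticConfig] = None
    input_format: Optional[str] = None  # 'geojson' or 'tabular'
    input_cells: Optional[str] = None
    input_islets: Optional[str] = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    run_association: bool = True
    run_randomness: bool = True
    run_emd2d: bool = True
    n_bins_1d: int = 20
    bins_2d: int = 10
    n_siblings: int = 1
    export_cells: bool = True
    include_boundaries: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if not (self.run_association or self.run_randomness or self.run_emd2d):
            raise ValueError("at least one analysis must be enabled")
        stochastic = (
            self.synthetic is not None or self.run_association or self.run_randomness
        )
        if stochastic and self.seed is None:
            raise ValueError("seed is mandatory when any stochastic step is enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "synthetic" in doc and doc["synthetic"] is not None:
            doc["synthetic"] = SyntheticConfig(**doc["synthetic"])
        if "params" in doc and doc["params"] is not None:
            doc["params"] = AnalysisParams(**doc["params"])
        return cls(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_dataset(config: RunConfig, manifest: dict) -> StudyDataset:
    if config.synthetic is not None:
        synth = config.synthetic
        if synth.seed != config.seed and config.seed is not None:
            synth = SyntheticConfig(**{**asdict_config(synth), "seed": config.seed})
        manifest["inputs"]["synthetic_config"] = hashlib.sha256(
            json.dumps(asdict_config(synth), sort_keys=True).encode()
        ).hexdigest()
        log.info("generating synthetic cohort: %d islets, theta=%.2f, seed=%d",
                 synth.n_islets, synth.adherence, synth.seed)
        return generate_cohort(synth)
    if config.input_cells is None or config.input_islets is None:
        raise PipelineError("config must give either a synthetic block or input paths")
    for p in (config.input_cells, config.input_islets):
        manifest["inputs"][str(p)] = _sha256(Path(p))
    if config.input_format == "geojson":
        return read_qupath_geojson(config.input_islets, config.input_cells,
                                   params=config.params)
    return read_tabular(config.input_cells, config.input_islets, params=config.params)


def asdict_config(cfg) -> dict:
    return {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "islet-mc",
        "version": __version__,
        "seed": config.seed,
        "params": asdict_config(config.params),
        "inputs": {},
        "stages": {},
        "outputs": [],
    }
    failed = False

    def record(stage, status, **extra):
        manifest["stages"][stage] = {"status": status, **extra}

    try:
        dataset = _load_dataset(config, manifest)
        record("load", "ok", n_islets=dataset.n_islets, n_cells=dataset.n_cells)

        dataset = apply_study_filters(dataset)
        tallies = dict(dataset.provenance["filters"])
        tallies["empty_islets"] = len(tallies["empty_islets"])
        manifest["filter_tallies"] = tallies
        record("filter", "ok", **tallies)
        log.info("filters: %s", tallies)

        annotate_positions(dataset)
        pooled = pooled_counts(dataset)
        record("annotate", "ok", pooled=asdict_config(pooled))
        log.info("pooled counts: N=%d NB=%d B=%d M=%d C=%d NB_m=%d (d_min=%g)",
                 pooled.N, pooled.NB, pooled.B, pooled.M, pooled.C, pooled.NB_m,
                 config.params.d_min)

        if config.export_cells:
            write_tabular(dataset, out / "cells.csv", out / "islets.csv",
                          include_boundaries=config.include_boundaries)
            manifest["outputs"] += ["cells.csv", "islets.csv"]
        counts = dataset.islets_frame()
        counts.to_csv(out / "islet_counts.csv", index=False)
        manifest["outputs"].append("islet_counts.csv")
    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        record("load/filter/annotate", "failed", error=str(exc))
        _write_manifest(out, manifest)
        raise PipelineError(str(exc)) from exc

    if config.run_association:
        try:
            results = subgroup_analysis(
                dataset, n_resamples=config.params.n_bootstrap, seed=config.seed
            )
            results_frame(results).to_csv(out / "association.csv", index=False)
            manifest["outputs"].append("association.csv")
            record("association", "ok", n_groups=len(results))
            log.info("association: %d subgroups, bootstrap=%d, seed=%s",
                     len(results), config.params.n_bootstrap, config.seed)
        except Exception as exc:  # noqa: BLE001
            record("association", "failed", error=str(exc))
            failed = True
    else:
        record("association", "skipped")

    if config.run_randomness:
        try:
            observed = population_r_values(dataset, "observed")
            siblings = population_r_values(
                dataset, "siblings", n_replicates=config.n_siblings, seed=config.seed
            )
            observed.to_csv(out / "r_values_observed.csv", index=False)
            siblings.to_csv(out / "r_values_siblings.csv", index=False)
            manifest["outputs"] += ["r_values_observed.csv", "r_values_siblings.csv"]
            obs_u = observed[~observed["constrained"]]["r"].to_numpy()
            sib_u = siblings[~siblings["constrained"]]["r"].to_numpy()
            res = emd_1d(
                histogram_1d(sib_u, config.n_bins_1d),
                histogram_1d(obs_u, config.n_bins_1d),
            )
            pd.DataFrame(res.transport_plan).to_csv(
                out / "emd1d_transport_plan.csv", index=False, header=False
            )
            emd_doc = {
                "emd_1d": res.distance,
                "n_bins": config.n_bins_1d,
                "normalization": res.normalization,
                "n_observed_unconstrained": int(obs_u.size),
                "n_sibling_unconstrained": int(sib_u.size),
                "n_islets": int(observed.shape[0]),
                "orientation": "source=digital siblings, target=observed",
            }
            with open(out / "emd1d.json", "w", encoding="utf-8") as fh:
                json.dump(emd_doc, fh, indent=2, sort_keys=True)
            manifest["outputs"] += ["emd1d_transport_plan.csv", "emd1d.json"]
            record("randomness", "ok", emd_1d=res.distance,
                   n_unconstrained=int(obs_u.size))
            log.info("randomness: %d unconstrained islets, emd_1d=%.5f (%d bins)",
                     obs_u.size, res.distance, config.n_bins_1d)
        except Exception as exc:  # noqa: BLE001
            record("randomness", "failed", error=str(exc))
            failed = True
    else:
        record("randomness", "skipped")

    if config.run_emd2d:
        try:
            ctrl, t1d = cohort_histograms(dataset, bins_per_axis=config.bins_2d)
            res2 = emd_2d(ctrl, t1d)
            pd.DataFrame(res2.transport_plan).to_csv(
                out / "emd2d_transport_plan.csv", index=False, header=False
            )
            with open(out / "emd2d.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "emd_2d": res2.distance,
                        "bins_per_axis": config.bins_2d,
                        "normalization": res2.normalization,
                        "area_scale_um2": ctrl.area_scale,
                        "n_control": ctrl.n_samples,
                        "n_t1d": t1d.n_samples,
                    },
                    fh, indent=2, sort_keys=True,
                )
            manifest["outputs"] += ["emd2d_transport_plan.csv", "emd2d.json"]
            record("emd2d", "ok", emd_2d=res2.distance)
            log.info("emd2d: distance=%.5f (%d bins/axis)", res2.distance, config.bins_2d)
        except Exception as exc:  # noqa: BLE001
            record("emd2d", "failed", error=str(exc))
            failed = True
    else:
        record("emd2d", "skipped")

    manifest["completed"] = not failed
    _write_manifest(out, manifest)
    if failed:
        raise PipelineError("one or more stages failed; see manifest.json")
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
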