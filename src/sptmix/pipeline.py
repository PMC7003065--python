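"""Seeded end-to-end orchestration: simulate -> link -> D* -> fit -> stats.

A run covers one or more conditions (species sets), each with several
independent replicates. One global seed fans out to per-replicate child
seeds through ``numpy.random.SeedSequence.spawn`` (children are spawned in
condition-major, replicate-minor order), so replicates are statistically
independent yet the whole run is reproducible. All intermediate tables are
written under the output directory, along with a manifest recording the
configuration and package versions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import write_dstars, write_fit, write_localizations, write_tracks
from .linking import LinkingConfig, filter_tracks_min_steps, link_localizations, tracks_to_table
from .mixture import ClassificationThresholds, compute_dstars, fit_mixture, immobile_fraction
from .replicates import GroupComparison, ReplicateSummary, compare_groups, summarize_replicates
from .simulate import (
    CONTROL_SPECIES,
    DART_SPECIES,
    AcquisitionConfig,
    CellGeometry,
    SpeciesModel,
    simulate_movie,
)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "load_config"]

log = logging.getLogger("sptmix")

DEFAULT_CONDITIONS: Dict[str, Sequence[SpeciesModel]] = {
    "control": CONTROL_SPECIES,
    "darT": DART_SPECIES,
}


@dataclass
class PipelineConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    geometry: CellGeometry = field(default_factory=CellGeometry)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    species: Sequence[SpeciesModel] = CONTROL_SPECIES
    conditions: Optional[Dict[str, Sequence[SpeciesModel]]] = None
    min_steps: int = 4
    k_species: int = 3
    seed: int = 0
    output_dir: str = "spt_out"

    def __post_init__(self) -> None:
        if self.min_steps < 1:
            raise ValueError("min_steps must be >= 1")
        if self.k_species < 1:
            raise ValueError("k_species must be >= 1")

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            return obj

        return conv(dataclasses.asdict(self))


def _species_list(entries: Sequence[Mapping]) -> List[SpeciesModel]:
    return [
        SpeciesModel(float(e["diffusion_coefficient"]), float(e["occupancy"]))
        for e in entries
    ]


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file of flat sections
    mirroring the config dataclasses; absent sections take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "acquisition" in raw:
        kwargs["acquisition"] = AcquisitionConfig(**raw["acquisition"])
    if "geometry" in raw:
        kwargs["geometry"] = CellGeometry(**raw["geometry"])
    if "linking" in raw:
        kwargs["linking"] = LinkingConfig(**raw["linking"])
    if "thresholds" in raw:
        kwargs["thresholds"] = ClassificationThresholds(**raw["thresholds"])
    if "species" in raw:
        kwargs["species"] = _species_list(raw["species"])
    if "conditions" in raw:
        kwargs["conditions"] = {
            name: _species_list(entries) for name, entries in raw["conditions"].items()
        }
    for key in ("min_steps", "k_species", "seed", "output_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


class PipelineStageError(RuntimeError):
    """Failure in a pipeline stage, annotated with condition/replicate."""

    def __init__(self, stage: str, condition: str, replicate: int, cause: Exception):
        super().__init__(
            f"stage '{stage}' failed for condition '{condition}' replicate {replicate}: {cause}"
        )
        self.stage = stage
        self.condition = condition
        self.replicate = replicate


def _replicate_pass(
    config: PipelineConfig,
    species: Sequence[SpeciesModel],
    rng: np.random.Generator,
    out: Path,
    condition: str,
    rep: int,
) -> dict:
    stage = "simulate"
    try:
        locs, truth = simulate_movie(config.acquisition, species, config.geometry, rng)
        write_localizations(locs, out / "localizations.csv")
        truth.emitters.to_csv(out / "ground_truth.csv", index=False)
        stage = "link"
        tracks = link_localizations(locs, config.linking)
        stage = "filter"
        kept = filter_tracks_min_steps(tracks, config.min_steps)
        write_tracks(tracks_to_table(kept), out / "tracks.tsv")
        stage = "dstar"
        dstars = compute_dstars(kept, config.acquisition.frame_interval, config.min_steps)
        write_dstars(dstars, out / "dstars.csv")
        stage = "fit"
        fit = fit_mixture(
            dstars,
            k=config.k_species,
            n_steps=config.min_steps,
            seed=int(rng.integers(2**31)),
        )
        write_fit(fit, out / "fit.json")
        stage = "immobile_fraction"
        frac = immobile_fraction(fit)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineStageError(stage, condition, rep, exc) from exc
    log.info(
        "condition=%s replicate=%d tracks=%d kept=%d immobile=%.1f%%",
        condition, rep, len(tracks), len(kept), frac,
    )
    return {
        "immobile_percent": frac,
        "n_tracks": len(kept),
        "n_cells": config.geometry.n_cells,
        "n_localizations": len(locs),
    }


def run_pipeline(
    config: PipelineConfig,
    n_replicates_per_condition: int = 4,
    conditions: Optional[Mapping[str, Sequence[SpeciesModel]]] = None,
) -> dict:
    """Run the full analysis for each condition and replicate and compare
    conditions pairwise.

    Returns (and writes to ``<output_dir>/report.json``) a report holding
    one :class:`ReplicateSummary` per condition and one
    :class:`GroupComparison` per condition pair.
    """
    conds = dict(conditions) if conditions is not None else (
        dict(config.conditions) if config.conditions else dict(DEFAULT_CONDITIONS)
    )
    if n_replicates_per_condition < 1:
        raise ValueError("need at least one replicate per condition")
    root = Path(config.output_dir)
    root.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(config.seed).spawn(
        len(conds) * n_replicates_per_condition
    )

    summaries: List[ReplicateSummary] = []
    per_condition: Dict[str, dict] = {}
    i = 0
    for name, species in conds.items():
        fracs, n_tracks, n_cells = [], 0, 0
        for rep in range(n_replicates_per_condition):
            out = root / name / f"rep{rep}"
            out.mkdir(parents=True, exist_ok=True)
            res = _replicate_pass(
                config, species, np.random.default_rng(children[i]), out, name, rep
            )
            i += 1
            fracs.append(res["immobile_percent"])
            n_tracks += res["n_tracks"]
            n_cells += res["n_cells"]
        summary = summarize_replicates(fracs, name, n_cells=n_cells, n_tracks=n_tracks)
        summaries.append(summary)
        per_condition[name] = dataclasses.asdict(summary)

    comparisons: List[GroupComparison] = []
    names = list(conds) if n_replicates_per_condition >= 2 else []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            comparisons.append(
                compare_groups(
                    per_condition[names[a]]["replicate_fractions"],
                    per_condition[names[b]]["replicate_fractions"],
                    label_a=names[a],
                    label_b=names[b],
                )
            )

    report = {
        "conditions": [dataclasses.asdict(s) for s in summaries],
        "comparisons": [dataclasses.asdict(c) for c in comparisons],
    }
    (root / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    manifest = {
        "sptmix_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "n_replicates_per_condition": n_replicates_per_condition,
        "conditions": {
            name: [dataclasses.asdict(s) for s in species] for name, species in conds.items()
        },
        "config": config.to_dict(),
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report
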