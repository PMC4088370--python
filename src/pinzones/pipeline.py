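"""Full-analysis orchestration: load/generate -> decompose -> tables -> tests.

The pipeline is driven by an :class:`AnalysisConfig` (typically loaded from
YAML), validates all inputs before computing anything, and writes a
deterministic report bundle: zone assignments, a zone-metrics table,
per-annotation distribution tables with pairwise proportion tests, pathway
enrichment tables, optional KEGG Mapper colour files, and a run manifest
recording inputs, parameters, seed, package version and output checksums.
Outputs carry no timestamps, so identical config + seed gives byte-identical
bundles.  All randomness flows from the single top-level seed; each
synthetic stage receives a derived sub-seed so adding a stage does not
perturb earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import pinzones
from pinzones import metric_space, network_io, synthetic_data, zone_annotation, zone_stats

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Configuration of a full zone analysis run."""

    outdir: str
    network: str | None = None
    network_format: str = "tsv"
    merge_with: str | None = None
    merge_format: str = "tsv"
    synthetic_preset: str | None = None
    annotations: str | None = None  # GMT of annotation classes (zone basis)
    expression_sets: str | None = None  # GMT of expression-derived sets (set basis)
    pathways: str | None = None  # GMT of pathways for enrichment
    presence_matrices: dict[str, str] = field(default_factory=dict)  # label -> path
    threshold: float = 0.99
    alpha: float = 0.01
    pairs: str = "all"
    seed: int = 0
    kegg_colours: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.network is None) == (self.synthetic_preset is None):
            raise ValueError("exactly one of 'network' and 'synthetic_preset' is required")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.threshold <= 1:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        paths = [self.network, self.merge_with, self.annotations,
                 self.expression_sets, self.pathways, *self.presence_matrices.values()]
        for p in paths:
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.synthetic_preset is not None and self.synthetic_preset not in synthetic_data.PRESETS:
            raise KeyError(f"unknown preset {self.synthetic_preset!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _subseed(base: int, stage: int) -> int:
    # stable per-stage derivation, kept below 2**31
    return int(np.random.SeedSequence(entropy=base, spawn_key=(stage,)).generate_state(1)[0] % (2**31))


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole analysis and write the report bundle; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": {"name": "pinzones", "version": pinzones.__version__},
        "config": dataclasses.asdict(config),
        "stages": [],
        "outputs": {},
    }

    def emit(name: str) -> Path:
        path = outdir / name
        manifest["outputs"][name] = None  # checksum filled at the end
        return path

    stage = "load_network"
    try:
        if config.synthetic_preset is not None:
            params = synthetic_data.preset_params(
                config.synthetic_preset, seed=_subseed(config.seed, 0)
            )
            net, truth = synthetic_data.generate_core_periphery(params)
            network_io.write_edge_list(net, emit("network.tsv"))
            with open(emit("planted_truth.tsv"), "w") as handle:
                handle.write("node\tzone\n")
                for node in sorted(truth.zone_of):
                    handle.write(f"{node}\t{truth.zone_of[node]}\n")
        else:
            net = network_io.read_edge_list(config.network, format=config.network_format)
            if config.merge_with is not None:
                other = network_io.read_edge_list(config.merge_with, format=config.merge_format)
                net = network_io.merge_networks(net, other)
        manifest["network"] = {"nodes": len(net), "edges": net.number_of_edges()}
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise PipelineError(stage, exc) from exc

    stage = "decompose"
    try:
        decomposition = metric_space.decompose(net)
        decomposition.validate(net)
        network_io.write_zone_assignments(decomposition, emit("zone_assignments.tsv"))
        metric_space.write_zone_metrics(net, decomposition, emit("zone_metrics.tsv"))
        manifest["decomposition"] = {
            "centres": sorted(decomposition.centres),
            "radius": decomposition.radius,
            "diameter": decomposition.diameter,
            "n_zones": decomposition.radius,
            "unreachable": len(decomposition.unreachable),
        }
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "annotation_distributions"
    try:
        if config.annotations is not None:
            sets = network_io.read_annotation_sets(config.annotations)
            for name in sorted(sets):
                report = zone_annotation.zone_distribution(decomposition, sets[name], basis="zone")
                report.to_frame().to_csv(emit(f"distribution_{name}.tsv"), sep="\t")
                tests = zone_stats.pairwise_zone_tests(
                    report, alpha=config.alpha, pairs=config.pairs
                )
                zone_stats.tests_to_frame(tests).to_csv(
                    emit(f"tests_{name}.tsv"), sep="\t", index=False
                )
            manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "expression_distributions"
    try:
        expression_sets = []
        if config.expression_sets is not None:
            expression_sets.extend(
                network_io.read_annotation_sets(config.expression_sets).values()
            )
        for label in sorted(config.presence_matrices):
            matrix = network_io.read_presence_matrix(config.presence_matrices[label])
            consistent = zone_annotation.filter_consistent_genes(
                matrix, threshold=config.threshold, label=label
            )
            expression_sets.append(consistent.as_annotation())
        if expression_sets:
            expression_sets.sort(key=lambda s: s.name)
            reports, average = zone_annotation.multi_set_distribution(
                decomposition, expression_sets, basis="set"
            )
            zone_annotation.distribution_matrix(reports, average).to_csv(
                emit("expression_distribution.tsv"), sep="\t"
            )
            manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "enrichment"
    try:
        if config.pathways is not None:
            pathways = [
                v for _, v in sorted(network_io.read_annotation_sets(config.pathways).items())
            ]
            universe = set(decomposition.zone_of)
            rows = []
            for k, members in decomposition.zones().items():
                for res in zone_stats.hypergeometric_enrichment(
                    members, pathways, universe, alpha=config.alpha
                ):
                    rows.append({"zone": k, **dataclasses.asdict(res)})
            frame = pd.DataFrame(rows)
            frame.to_csv(emit("enrichment.tsv"), sep="\t", index=False)
            manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "kegg_colours"
    try:
        if config.kegg_colours:
            network_io.export_kegg_mapper(
                {v: k for v, k in decomposition.zone_of.items() if k >= 1},
                emit("kegg_zone_colours.tsv"),
                skip_missing=True,
            )
            manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    for name in list(manifest["outputs"]):
        manifest["outputs"][name] = _sha256(outdir / name)
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest


def rerun_from_manifest(manifest_path: str | Path) -> dict:
    """Re-execute a run from its manifest; reproduces the bundle exactly."""
    with open(manifest_path) as handle:
        manifest = json.load(handle)
    config = AnalysisConfig(**manifest["config"])
    return run_full_analysis(config)
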