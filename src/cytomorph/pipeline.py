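"""End-to-end orchestration: sections in, tables, reports and figures out.

The pipeline composes the stages — synthetic section generation (optional),
per-layer soma segmentation, morphometry, factorial statistics and figure
rendering — and writes every artifact with provenance (config hash and
seed).  Each stage is also exposed on its own so that the CLI subcommands
compose: running stages separately produces byte-identical outputs to one
``all`` run on the same inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import synth
from .image import CalibratedImage, LayerMap, read_image, read_layer_map, write_image, write_layer_map
from .morphometry import TABLE_COLUMNS, build_morphometry_table
from .segment import Component, ComponentSet, SegmentationParams, segment_cells
from .stats import AnalysisBundle, ModelSpec, run_full_analysis
from .plots import render_figures

log = logging.getLogger("cytomorph")

_CSV_FLOAT = "%.10g"


@dataclasses.dataclass
class PipelineConfig:
    """Run configuration; see ``from_yaml`` for the file schema."""

    output_dir: Path
    seed: int = 0
    n_specimens: int = 2
    sections_per_side: int = 1
    synth_config: synth.SynthConfig | None = None  # None -> load inputs from disk
    inputs: list[dict] | None = None  # [{"image": ..., "layer_map": ...}, ...]
    segmentation: SegmentationParams = dataclasses.field(default_factory=SegmentationParams)
    density_radius: float = 50.0
    model: ModelSpec = dataclasses.field(default_factory=ModelSpec)
    plots: bool = True

    def __post_init__(self) -> None:
        if self.density_radius <= 0:
            raise ValueError("density_radius must be > 0")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        seed = int(doc.get("seed", 0))
        syn = None
        n_specimens = 2
        sections_per_side = 1
        if "synth" in doc:
            block = doc["synth"] or {}
            n_specimens = int(block.get("n_specimens", 2))
            sections_per_side = int(block.get("sections_per_side", 1))
            if "config" in block:
                syn = synth.config_from_yaml(block["config"])
                syn = dataclasses.replace(syn, seed=seed)
            else:
                syn = synth.default_config(seed=seed)
        inputs = doc.get("inputs")
        return cls(
            output_dir=Path(doc.get("output_dir", "cytomorph_out")),
            seed=seed,
            n_specimens=n_specimens,
            sections_per_side=sections_per_side,
            synth_config=syn,
            inputs=inputs,
            segmentation=SegmentationParams(**(doc.get("segmentation") or {})),
            density_radius=float(doc.get("density_radius", 50.0)),
            model=ModelSpec(**(doc.get("model") or {})),
            plots=bool(doc.get("plots", True)),
        )

    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (not file locations)."""
        doc = dataclasses.asdict(self)
        doc.pop("output_dir", None)
        doc.pop("inputs", None)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _provenance_header(config: PipelineConfig) -> str:
    return f"# cytomorph config_hash={config.config_hash()} seed={config.seed}\n"


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, index=False, float_format=_CSV_FLOAT, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a morphometry/summary CSV written by the pipeline."""
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# stages

def stage_synth(config: PipelineConfig) -> list[dict]:
    """Generate the synthetic cohort onto disk; returns the input manifest."""
    if config.synth_config is None:
        raise ValueError("no synth block configured")
    out = config.output_dir / "sections"
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    triples = synth.generate_cohort(
        config.synth_config, config.n_specimens, config.sections_per_side
    )
    for trip in triples:
        stem = trip.image.section_id
        img_path = out / f"{stem}.tif"
        map_path = out / f"{stem}.layers.tif"
        truth_path = out / f"{stem}.truth.csv"
        write_image(trip.image, img_path)
        write_layer_map(trip.layer_map, map_path)
        _write_table(trip.truth, truth_path, config)
        manifest.append({
            "image": str(img_path), "layer_map": str(map_path),
            "truth": str(truth_path),
        })
    synth.config_to_yaml(config.synth_config, out / "synth_config.yaml")
    log.info("synth: wrote %d sections to %s", len(manifest), out)
    return manifest


def _load_section(entry: dict) -> tuple[CalibratedImage, LayerMap]:
    img_path, map_path = Path(entry["image"]), Path(entry["layer_map"])
    try:
        image = read_image(img_path)
    except Exception as exc:
        raise IOError(f"unreadable image {img_path}: {exc}") from exc
    try:
        layer_map = read_layer_map(map_path)
    except Exception as exc:
        raise IOError(f"unreadable layer map {map_path}: {exc}") from exc
    if image.shape != layer_map.shape:
        raise ValueError(
            f"alignment error: image {img_path} shape {image.shape} != "
            f"layer map {map_path} shape {layer_map.shape}"
        )
    return image, layer_map


def stage_segment(config: PipelineConfig, entry: dict) -> Path:
    """Segment one section; writes an int32 component-label TIFF."""
    image, layer_map = _load_section(entry)
    comps = segment_cells(image, layer_map, config.segmentation)
    labels = np.zeros(image.shape, dtype=np.int32)
    for comp in comps:
        labels[comp.rows, comp.cols] = comp.label
    img_path = Path(entry["image"])
    out = img_path.parent / (img_path.stem + ".components.tif")
    tifffile.imwrite(out, labels)
    log.info("segment: %s -> %d components", entry["image"], len(comps))
    return out


def components_from_label_raster(
    labels: np.ndarray, image: CalibratedImage, layer_map: LayerMap,
    params: SegmentationParams,
) -> ComponentSet:
    """Rebuild a ComponentSet from a persisted component-label raster."""
    comps = []
    h, w = labels.shape
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        order = np.lexsort((cols, rows))
        rows, cols = rows[order], cols[order]
        lid = int(layer_map.labels[rows[0], cols[0]])
        on_border = bool(
            rows[0] == 0 or cols.min() == 0 or rows[-1] == h - 1 or cols.max() == w - 1
        )
        comps.append(Component(int(lab), rows, cols, lid, on_border))
    comps.sort(key=lambda c: c.label)
    return ComponentSet(
        components=comps, shape=labels.shape,
        microns_per_pixel=image.microns_per_pixel, params=params,
        specimen_id=image.specimen_id, side=image.side, section_id=image.section_id,
    )


def stage_measure(config: PipelineConfig, entry: dict, labels_path: Path) -> Path:
    """Measure a segmented section into a per-section morphometry CSV."""
    image, layer_map = _load_section(entry)
    labels = tifffile.imread(labels_path)
    comps = components_from_label_raster(labels, image, layer_map, config.segmentation)
    table = build_morphometry_table(comps, density_radius=config.density_radius)
    out = labels_path.parent / (Path(entry["image"]).stem + ".morphometry.csv")
    _write_table(table, out, config)
    log.info("measure: %s -> %d cells", entry["image"], len(table))
    return out


def stage_analyze(config: PipelineConfig, cohort_csv: Path) -> AnalysisBundle:
    table = read_table(cohort_csv)
    bundle = run_full_analysis(table, config.model)
    stats_dir = config.output_dir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    bundle.to_json(stats_dir / "anova.json")
    bundle.summaries_to_csv(stats_dir)
    log.info("analyze: wrote reports to %s", stats_dir)
    return bundle


def stage_report(config: PipelineConfig, cohort_csv: Path,
                 bundle: AnalysisBundle | None = None) -> list[Path]:
    table = read_table(cohort_csv)
    figs = render_figures(table, bundle, config.output_dir / "figures")
    log.info("report: wrote %d figures", len(figs))
    return figs


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the output directory.

    Inputs come either from the configured synthetic cohort or from the
    explicit ``inputs`` manifest of image / layer-map path pairs.  Outputs:
    per-section morphometry tables, the pooled cohort table, group
    summaries, ANOVA reports, figures and ``run_log.json`` with full
    parameter provenance.
    """
    config.output_dir.mkdir(parents=True, exist_ok=True)
    if config.synth_config is not None:
        manifest = stage_synth(config)
    elif config.inputs:
        manifest = config.inputs
    else:
        raise ValueError("config provides neither a synth block nor inputs")

    section_tables = []
    for entry in manifest:
        labels_path = stage_segment(config, entry)
        csv_path = stage_measure(config, entry, labels_path)
        section_tables.append(read_table(csv_path))
    cohort = pd.concat(section_tables, ignore_index=True)[TABLE_COLUMNS]
    cohort_csv = config.output_dir / "cohort_morphometry.csv"
    _write_table(cohort, cohort_csv, config)

    bundle = stage_analyze(config, cohort_csv)
    if config.plots:
        stage_report(config, cohort_csv, bundle)

    run_log = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_sections": len(manifest),
        "n_cells": int(len(cohort)),
        "segmentation": dataclasses.asdict(config.segmentation),
        "density_radius_um": config.density_radius,
        "model": dataclasses.asdict(config.model),
        "notices": bundle.notices,
    }
    (config.output_dir / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True)
    )
    log.info("pipeline complete: %s (%d cells)", config.output_dir, len(cohort))
    return config.output_dir
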