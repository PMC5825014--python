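"""End-to-end pipeline: denoise -> threshold -> memberships -> multi-scale
opening -> spine extraction -> morphometry -> classification -> outputs.

The library entry point is :func:`run` on in-memory objects;
:func:`run_files` wraps it with file I/O, writes every artifact (label
TIFF, feature CSV, effective config YAML, log) into the output directory
and is what the command-line interface calls.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import classify as _classify
from . import image_io, morphometry, mso
from .errors import ValidationError
from .fuzzy import IntensityBands
from .image_io import IntensityVolume, SeedSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """All tunables of the pipeline, serialisable to/from YAML."""

    spacing: tuple[float, float, float] = (0.2, 0.07, 0.07)
    denoise_sigma: tuple[float, float, float] = (0.5, 0.5, 0.5)  # voxels per axis
    theta: Optional[float] = None          # None -> Otsu
    min_voxels: int = 27
    i_spine: Optional[float] = None        # None -> auto (two-threshold Otsu)
    i_dendrite: Optional[float] = None
    scale_step: Optional[float] = None     # None -> min(spacing)
    l: int = 2                             # deepest-point neighbourhood radius
    tau_stubby_um: float = 0.15
    tau_spread: float = 0.5
    tau_ratio: float = 0.65
    head_frac: float = 0.6
    merge_radius_um: float = 0.35
    valley_frac: float = 0.5
    smooth_window: int = 5

    def classify_params(self) -> _classify.ClassifyParams:
        return _classify.ClassifyParams(
            tau_stubby_um=self.tau_stubby_um,
            tau_spread=self.tau_spread,
            tau_ratio=self.tau_ratio,
            head_frac=self.head_frac,
            merge_radius_um=self.merge_radius_um,
            valley_frac=self.valley_frac,
            smooth_window=self.smooth_window,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("spacing", "denoise_sigma"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return Path(path)


@dataclass
class PipelineResult:
    segmentation: mso.SegmentationResult
    regions: list
    bands: IntensityBands
    table: pd.DataFrame
    params: PipelineParams


def run(vol: IntensityVolume, seeds: SeedSet, params: PipelineParams | None = None) -> PipelineResult:
    """Run the full pipeline on an in-memory volume and seed set."""
    params = params or PipelineParams(spacing=vol.spacing)
    if tuple(params.spacing) != tuple(vol.spacing):
        params = dataclasses.replace(params, spacing=vol.spacing)
    seeds.check_bounds(vol.shape)

    denoised = image_io.gaussian_denoise(vol, params.denoise_sigma)
    logger.info("denoise: sigma=%s", params.denoise_sigma)

    bands = None
    if params.i_spine is not None and params.i_dendrite is not None:
        data = denoised.data
        bands = IntensityBands(float(data.min()), params.i_spine, params.i_dendrite, float(data.max()))
    obj, bands = mso.threshold_foreground(denoised, theta=params.theta,
                                          min_voxels=params.min_voxels, bands=bands)
    logger.info("foreground: %d voxels, bands=(%.3g, %.3g, %.3g, %.3g)",
                int(obj.support.sum()), bands.i_min, bands.i_spine, bands.i_dendrite, bands.i_max)

    seg = mso.multi_scale_opening(obj, seeds, scale_step=params.scale_step)
    regions = mso.extract_spine_components(seg, seeds)
    logger.info("multi-scale opening: K=%d spine regions", seg.k)

    cparams = params.classify_params()
    for region in regions:
        morphometry.analyze_spine(region, seg.dendrite_mask, l=params.l)
        if not region.detached:
            _classify.flag_branched(region, cparams)
        _classify.classify_spine(region, cparams)

    table = image_io.features_table(regions)
    table["rule"] = [r.decision_trace.get("rule") for r in regions]
    return PipelineResult(segmentation=seg, regions=regions, bands=bands, table=table, params=params)


def run_files(
    stack_path,
    seeds_path,
    out_dir,
    params: PipelineParams | None = None,
    config_path=None,
) -> PipelineResult:
    """File-based pipeline: read stack and seeds, run, write all outputs."""
    if config_path is not None:
        params = PipelineParams.from_yaml(config_path)
    params = params or PipelineParams()
    stack_path, seeds_path = Path(stack_path), Path(seeds_path)
    if not stack_path.exists():
        raise ValidationError(f"stack not found: {stack_path}")
    if not seeds_path.exists():
        raise ValidationError(f"seeds not found: {seeds_path}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("spinemorph")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        vol = image_io.read_stack(stack_path, params.spacing)
        seeds = image_io.read_seeds(seeds_path, shape=vol.shape)
        result = run(vol, seeds, params)
        image_io.write_outputs(result.segmentation.labels, result.regions, out_dir)
        result.params.to_yaml(out_dir / "config_used.yaml")
        traces = {str(r.spine_id): r.decision_trace for r in result.regions}
        (out_dir / "decision_traces.json").write_text(json.dumps(traces, indent=2, sort_keys=True))
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
    return result
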