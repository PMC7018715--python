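"""Shared I/O and provenance: multi-page TIFF stacks with voxel-size
metadata, binary masks, delimited tables, configuration files and
per-invocation provenance records.

Voxel sizes are mandatory metadata (all headline metrics are in nm): they
are written both into TIFF resolution tags (x/y) plus ImageJ-style slice
spacing (z) and into a JSON sidecar next to the stack, and are required on
read unless explicitly overridden.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .stack import VolumeStack, array_checksum

__all__ = [
    "read_stack",
    "write_stack",
    "write_mask",
    "read_mask",
    "ProvenanceRecord",
    "load_pipeline_config",
    "run_config",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_stack(vol: VolumeStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF with voxel-size tags and a JSON
    sidecar; integer data round-trips bit-exactly."""
    path = Path(path)
    data = vol.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    vz, vy, vx = vol.voxel_size_nm
    # resolution tags are pixels per unit; use micrometres
    tifffile.imwrite(
        path,
        data,
        resolution=(1000.0 / vx, 1000.0 / vy),
        metadata={"spacing": vz / 1000.0, "unit": "um", "axes": "ZYX"},
        imagej=data.dtype in (np.dtype("uint8"), np.dtype("uint16"), np.dtype("float32")),
    )
    sidecar = {
        "voxel_size_nm": list(vol.voxel_size_nm),
        "fiber_axis": list(np.asarray(vol.fiber_axis, dtype=float)),
        "meta": {k: v for k, v in vol.meta.items() if _jsonable(v)},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(v: Any) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_stack(
    path: str | Path,
    voxel_size_nm: tuple[float, float, float] | None = None,
) -> VolumeStack:
    """Read a multi-page TIFF stack; voxel size comes from the sidecar, the
    TIFF tags, or the explicit override — in that priority — else an error
    demanding ``--voxel`` is raised."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"mixed page shapes in {path}: {shapes}")
        data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        vox = voxel_size_nm
        fiber_axis: Any = "z"
        meta: dict = {}
        side = _sidecar_path(path)
        if side.exists():
            sc = json.loads(side.read_text())
            vox = vox or tuple(sc["voxel_size_nm"])
            fiber_axis = sc.get("fiber_axis", "z")
            meta = sc.get("meta", {})
        elif vox is None:
            vox = _voxel_from_tags(tf)
    if vox is None:
        raise ValueError(
            f"{path} carries no voxel-size metadata; pass voxel_size_nm (--voxel)"
        )
    return VolumeStack(data, vox, fiber_axis=fiber_axis, meta=meta)


def _voxel_from_tags(tf: "tifffile.TiffFile"):
    page = tf.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is None or yres is None:
        return None
    def to_nm(tag):
        num, den = tag.value
        if num == 0:
            return None
        return 1000.0 * den / num  # pixels per um -> nm per pixel
    vx = to_nm(xres)
    vy = to_nm(yres)
    vz = None
    if tf.imagej_metadata:
        sp = tf.imagej_metadata.get("spacing")
        if sp:
            vz = float(sp) * 1000.0
    if vx is None or vy is None or vz is None:
        return None
    return (vz, vy, vx)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as 8-bit {0, 255} multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool).astype(np.uint8) * 255))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    return np.asarray(arr) > 0


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

@dataclass
class ProvenanceRecord:
    """One record per CLI invocation / pipeline run."""

    tool: str
    version: str
    parameters: dict
    input_checksums: dict = field(default_factory=dict)
    output_checksums: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ProvenanceRecord":
        return cls(**json.loads(text))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


# ---------------------------------------------------------------------------
# pipeline configuration files
# ---------------------------------------------------------------------------

def load_pipeline_config(path: str | Path):
    """Load a :class:`~granuloscope.preprocess.PipelineConfig` from a YAML
    (or JSON) mapping; unknown keys are rejected by name.

    The mapping may contain ``preset: tissue|thread`` plus field overrides.
    """
    from .preprocess import PipelineConfig, pipeline_preset

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    preset_name = raw.pop("preset", None)
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("voxel_size_nm", "median_radius_vox", "destripe_band", "stages"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if preset_name is not None:
        cfg = pipeline_preset(preset_name, **raw)
    else:
        cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def run_config(
    config_file: str | Path,
    input_path: str | Path,
    out_dir: str | Path,
    save_intermediates: bool = False,
    voxel_size_nm: tuple[float, float, float] | None = None,
):
    """Execute a configured preprocessing pipeline on a TIFF stack and emit
    outputs plus exactly one provenance record.

    Identical config + inputs produce identical output checksums.
    """
    from . import __version__
    from .preprocess import run_pipeline

    cfg = load_pipeline_config(config_file)
    vol = read_stack(input_path, voxel_size_nm=voxel_size_nm or cfg.voxel_size_nm)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = run_pipeline(vol, cfg, keep_intermediates=save_intermediates)

    outputs: dict[str, str] = {}
    final_path = out_dir / "processed.tif"
    write_stack(result.final, final_path)
    outputs["processed.tif"] = array_checksum(result.final.data)
    if result.mask is not None:
        write_mask(result.mask, out_dir / "mask.tif")
        outputs["mask.tif"] = array_checksum(result.mask)
    if result.shifts is not None:
        np.savetxt(
            out_dir / "shifts.tsv",
            np.column_stack([np.arange(len(result.shifts)), result.shifts]),
            fmt=("%d", "%.4f", "%.4f"),
            delimiter="\t",
            header="slice\tdy\tdx",
            comments="",
        )
    if save_intermediates:
        for name, arr in result.intermediates.items():
            if arr.dtype == bool:
                write_mask(arr, out_dir / f"stage_{name}.tif")
            else:
                write_stack(vol.copy_with(arr), out_dir / f"stage_{name}.tif")

    record = ProvenanceRecord(
        tool="granuloscope.run_config",
        version=__version__,
        parameters={"config": dataclasses.asdict(cfg), "python": sys.version.split()[0]},
        input_checksums={str(input_path): array_checksum(vol.data)},
        output_checksums=outputs,
        stage_seconds={s.name: s.seconds for s in result.stages},
    )
    record.parameters["stage_checksums"] = {s.name: s.checksum for s in result.stages}
    record.write(out_dir / "provenance.json")
    return result, record
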