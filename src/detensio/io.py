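"""File I/O: calibrated TIFF stacks, series/intensity CSVs, result JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .degradomics import IntensityTable
from .fiber import ImageStack, OrientationDistribution
from .perfusion import EnhancementSeries

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "read_enhancement_series",
    "read_intensity_table",
    "read_fasta",
    "write_result_json",
    "write_histogram_csv",
    "file_sha256",
]


def read_image_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an ImageStack.

    Calibration comes from the arguments or, failing that, from a sidecar
    JSON ``<name>.json`` next to the file with keys ``pixel_size_um`` and
    optionally ``z_step_um``.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:  # pages-first -> (y, x, z)
        data = np.moveaxis(data, 0, -1)
    sidecar = path.with_suffix(path.suffix + ".json")
    if (pixel_size_um is None or (data.ndim == 3 and z_step_um is None)) and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size_um = pixel_size_um or meta.get("pixel_size_um")
        z_step_um = z_step_um or meta.get("z_step_um")
    if pixel_size_um is None:
        raise ValueError(
            f"no pixel_size_um given and no sidecar {sidecar.name} found"
        )
    return ImageStack(
        voxels=np.asarray(data, dtype=np.float64),
        pixel_size_um=float(pixel_size_um),
        z_step_um=float(z_step_um) if z_step_um is not None else None,
    )


def write_image_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an ImageStack as TIFF plus a calibration sidecar JSON."""
    path = Path(path)
    vox = stack.voxels
    if vox.ndim == 3:
        vox = np.moveaxis(vox, -1, 0)
    peak = vox.max()
    scaled = (vox / peak * 65535).astype(np.uint16) if peak > 0 else vox.astype(np.uint16)
    tifffile.imwrite(path, scaled)
    meta = {"pixel_size_um": stack.pixel_size_um}
    if stack.z_step_um is not None:
        meta["z_step_um"] = stack.z_step_um
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_enhancement_series(
    path: str | Path, c_blood: float | None = None
) -> EnhancementSeries:
    """Read a CSV with columns ``t_min, C_t[, C_blood]``."""
    df = pd.read_csv(path)
    if "t_min" not in df.columns or "C_t" not in df.columns:
        raise ValueError("series CSV needs columns t_min and C_t")
    if c_blood is not None:
        cb: float | np.ndarray = float(c_blood)
    elif "C_blood" in df.columns:
        cb = df["C_blood"].to_numpy(dtype=np.float64)
    else:
        raise ValueError("provide c_blood or a C_blood column")
    return EnhancementSeries(
        t_min=df["t_min"].to_numpy(dtype=np.float64),
        c_t=df["C_t"].to_numpy(dtype=np.float64),
        c_blood=cb,
    )


def read_intensity_table(
    intensities_csv: str | Path, groups_json: str | Path
) -> IntensityTable:
    """Read a protein x sample intensity CSV plus a sample->group JSON map."""
    abundance = pd.read_csv(intensities_csv, index_col=0)
    groups = pd.Series(json.loads(Path(groups_json).read_text()))
    return IntensityTable(abundance=abundance, groups=groups)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning {id: sequence} (first token of header)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_result_json(path: str | Path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_histogram_csv(path: str | Path, dist: OrientationDistribution) -> None:
    pd.DataFrame(
        {"bin_center_deg": dist.bin_centers_deg, "p": dist.p}
    ).to_csv(path, index=False)
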