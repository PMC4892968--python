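"""File I/O: section stacks as PNG series, plotted points as CSV.

Volumes are handled by :class:`tracemap.geometry.Volume` (NIfTI-1);
transform chains serialize themselves to JSON.  Section stacks are stored
as a directory of 16-bit grayscale PNGs in rostro-caudal order plus a
YAML sidecar holding the geometry and the intensity scale.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import ContractViolation
from .geometry import SectionStack

CELL_COLUMNS = ["animal", "tracer", "kind", "section", "x_mm", "y_mm"]


def write_stack(stack, directory):
    """Write a stack as 0000.png, 0001.png, ... plus ``stack.yaml``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lo = min(float(np.min(s)) for s in stack.sections)
    hi = max(float(np.max(s)) for s in stack.sections)
    scale = (hi - lo) or 1.0
    for i, img in enumerate(stack.sections):
        data = np.clip((img - lo) / scale, 0, 1)
        iio.imwrite(
            directory / f"{i:04d}.png", (data * 65535).round().astype(np.uint16)
        )
    meta = {
        "n_sections": len(stack),
        "in_plane_spacing_mm": float(stack.in_plane_spacing),
        "section_spacing_mm": float(stack.section_spacing),
        "in_plane_origin_mm": [float(v) for v in stack.in_plane_origin],
        "ap_origin_mm": float(stack.ap_origin),
        "intensity_offset": lo,
        "intensity_scale": scale,
    }
    with open(directory / "stack.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_stack(directory):
    directory = Path(directory)
    with open(directory / "stack.yaml") as fh:
        meta = yaml.safe_load(fh)
    sections = []
    for i in range(meta["n_sections"]):
        img = iio.imread(directory / f"{i:04d}.png").astype(float) / 65535.0
        sections.append(img * meta["intensity_scale"] + meta["intensity_offset"])
    return SectionStack(
        sections=sections,
        in_plane_spacing=meta["in_plane_spacing_mm"],
        section_spacing=meta["section_spacing_mm"],
        in_plane_origin=np.asarray(meta["in_plane_origin_mm"]),
        ap_origin=meta["ap_origin_mm"],
    )


def write_cells_csv(cells, path):
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ContractViolation(f"cells table missing columns {missing}")
    cells.to_csv(path, index=False)


def read_cells_csv(path):
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ContractViolation(f"cells CSV missing columns {missing}")
    return df
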