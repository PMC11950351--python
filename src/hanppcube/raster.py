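"""Raster layer I/O: single-band float TIFF, north-up, row-major.

Layers are written as plain single-band TIFF (float64 for value layers,
int32 for the country partition).  The grid is fully described by the
shared :class:`~hanppcube.grid.GridSpec`, so no projection metadata is
needed; a missing-data sentinel distinct from true zero can be stored in
the image description tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["write_layer", "read_layer", "NODATA"]

NODATA = -9999.0


def write_layer(path, array: np.ndarray, nodata: float | None = None,
                overwrite: bool = False) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"nodata": nodata} if nodata is not None else {}
    tifffile.imwrite(path, np.asarray(array), description=json.dumps(meta))
    return path


def read_layer(path) -> tuple[np.ndarray, float | None]:
    """Read a layer; returns (array, nodata-or-None)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        desc = page.tags.get("ImageDescription")
        nodata = None
        if desc is not None:
            try:
                nodata = json.loads(desc.value).get("nodata")
            except (ValueError, AttributeError):
                nodata = None
    return arr, nodata
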