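"""Tile-grid directory I/O: per-tile TIFF stacks plus a grid manifest.

Layout: ``tile_c{col}_r{row}.tif`` stacks (pages are z) next to a
``grid.json`` with keys ``columns``, ``rows`` and ``overlap``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .stitching import CountingReader, Tile, TileGrid

__all__ = ["load_tile_dir", "save_tile_dir"]


def load_tile_dir(path, chunk_size: int = 32) -> TileGrid:
    import tifffile

    path = Path(path)
    meta = json.loads((path / "grid.json").read_text())
    tiles = []
    for c in range(meta["columns"]):
        for r in range(meta["rows"]):
            f = path / f"tile_c{c}_r{r}.tif"
            if not f.exists():
                raise IOError(f"missing tile {f}")
            arr = tifffile.imread(str(f))  # (z, y, x)
            data = np.ascontiguousarray(arr.transpose(2, 1, 0))
            tiles.append(Tile(reader=CountingReader(data, chunk_size),
                              col=c, row=r, overlap=meta["overlap"]))
    return TileGrid(tiles=tiles, cols=meta["columns"], rows=meta["rows"])


def save_tile_dir(grid: TileGrid, path) -> None:
    import tifffile

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "grid.json").write_text(json.dumps(
        {"columns": grid.cols, "rows": grid.rows,
         "overlap": grid.tiles[0].overlap}))
    for t in grid.tiles:
        data = t.reader.read_block(0, t.shape[2])
        tifffile.imwrite(str(path / f"tile_c{t.col}_r{t.row}.tif"),
                         np.ascontiguousarray(data.transpose(2, 1, 0)))
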