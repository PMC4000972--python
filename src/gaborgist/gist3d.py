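"""Spatiotemporal gist descriptor: coarse-grid average pooling of filter responses.

Each filtered volume is divided into a 4 x 4 x 4 grid of spatiotemporal
subregions and each subregion is replaced by the arithmetic mean of its
responses, yielding 64 numbers per kernel.  Concatenating over the default
four-kernel bank gives the 256-dimensional gist feature of a clip.  The
layout is kernel-major, cells in (row-block, col-block, time-block)
lexicographic order.

Because the kernels are zero-DC, the gist of a clip is invariant (to
numerical precision) under adding a constant intensity offset, and because
pooling is a mean over large subregions the descriptor tolerates small
spatial and temporal shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gabor3d import FilterBank, filter_volume_bank
from .video_io import VideoVolume

__all__ = ["GistFeature", "pool_grid", "extract_gist", "write_feature_table",
           "read_feature_table", "GRID"]

#: Pooling grid: 4 row-blocks x 4 col-blocks x 4 time-blocks per response.
GRID: tuple[int, int, int] = (4, 4, 4)


@dataclass(frozen=True)
class GistFeature:
    """Pooled descriptor; ``values`` has length 64 x n_kernels (256 default)."""

    values: np.ndarray
    n_kernels: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.size != 64 * self.n_kernels:
            raise ValueError(
                f"gist length must be 64 x n_kernels = {64 * self.n_kernels}, "
                f"got {values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("gist feature contains non-finite entries")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


def _edges(d: int, g: int) -> np.ndarray:
    # near-equal partition: bin edges at floor(i*d/g), exhaustive and disjoint
    return (np.arange(g + 1) * d) // g


def pool_grid(response: np.ndarray, grid: tuple[int, int, int] = GRID) -> np.ndarray:
    """Average-pool a 3-D response over a ``grid`` of subregions.

    Subregions partition each axis at edges ``floor(i * d / g)``, so every
    voxel belongs to exactly one cell even when a dimension is not divisible
    by the grid.  Returns the flattened cell means in (row-block, col-block,
    time-block) lexicographic order (length 64 for the default grid).
    """
    response = np.asarray(response, dtype=np.float64)
    if response.ndim != 3:
        raise ValueError(f"response must be 3-D, got shape {response.shape}")
    for d, g in zip(response.shape, grid):
        if d < g:
            raise ValueError(
                f"response shape {response.shape} too small for a {grid} grid"
            )
    e0, e1, e2 = (_edges(d, g) for d, g in zip(response.shape, grid))
    out = np.empty(grid[0] * grid[1] * grid[2], dtype=np.float64)
    i = 0
    for a in range(grid[0]):
        for b in range(grid[1]):
            for c in range(grid[2]):
                block = response[e0[a]:e0[a + 1], e1[b]:e1[b + 1], e2[c]:e2[c + 1]]
                out[i] = block.mean()
                i += 1
    return out


def extract_gist(volume: VideoVolume | np.ndarray, bank: FilterBank) -> GistFeature:
    """Filter a volume with every kernel of the bank and pool each response.

    The result is the concatenation of :func:`pool_grid` outputs in bank
    order — 256 values for the default four-kernel bank.
    """
    responses = filter_volume_bank(volume, bank)
    values = np.concatenate([pool_grid(r) for r in responses])
    return GistFeature(values=values, n_kernels=len(bank))


# ---------------------------------------------------------------------------
# feature table (CSV: clip_id,patient_id,label,f000..f255)
# ---------------------------------------------------------------------------

def write_feature_table(rows: Sequence[tuple[str, str, str, GistFeature]], path) -> None:
    """Write one row per clip: ``clip_id,patient_id,label,f000..fNNN``."""
    if not rows:
        raise ValueError("no feature rows to write")
    n = len(rows[0][3])
    cols = [f"f{i:03d}" for i in range(n)]
    records = []
    for clip_id, patient_id, label, feat in rows:
        if len(feat) != n:
            raise ValueError("inconsistent feature dimensions across clips")
        rec = {"clip_id": clip_id, "patient_id": patient_id, "label": label}
        rec.update(zip(cols, feat.values))
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV back into a DataFrame (features in f-columns)."""
    df = pd.read_csv(path, dtype={"clip_id": str, "patient_id": str, "label": str})
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    if not fcols:
        raise ValueError(f"no feature columns found in {path}")
    return df
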