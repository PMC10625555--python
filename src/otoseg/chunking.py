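"""Sliding-window decomposition of volumes into overlapping cubic chunks and
mean-fusion re-assembly of per-chunk predictions.

Default geometry follows the pipeline's working configuration: 128-voxel
cubic chunks advanced with an isotropic stride of 25 voxels. Per axis the
chunk origins are the arithmetic progression {0, s, 2s, ...} with the final
origin snapped to ``dim - chunk`` so the last chunk abuts the volume
boundary; this guarantees every voxel is covered at least once. Volumes
smaller than the chunk along an axis are zero-padded symmetrically first
(:func:`pad_to_chunk`) and cropped after aggregation.

Overlapping predictions are fused by the unweighted voxel mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np


class ChunkingError(ValueError):
    pass


@dataclass(frozen=True)
class ChunkGrid:
    chunk_shape: tuple[int, int, int]
    stride: int
    origins: tuple[tuple[int, int, int], ...]
    volume_shape: tuple[int, int, int]

    @property
    def n_chunks(self) -> int:
        return len(self.origins)

    def to_json(self) -> str:
        return json.dumps(
            {
                "chunk_shape": list(self.chunk_shape),
                "stride": self.stride,
                "volume_shape": list(self.volume_shape),
                "origins": [list(o) for o in self.origins],
            }
        )


def _axis_origins(dim: int, chunk: int, stride: int) -> list[int]:
    if dim < chunk:
        raise ChunkingError(
            f"axis of size {dim} smaller than chunk {chunk}; pad the volume first"
        )
    last = dim - chunk
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)  # snap the final chunk to the boundary
    return origins


def plan_chunks(volume_shape, chunk: int = 128, stride: int = 25) -> ChunkGrid:
    """Plan the sliding-window grid for a volume of ``volume_shape``."""
    if stride <= 0:
        raise ChunkingError(f"stride must be positive, got {stride}")
    if chunk <= 0:
        raise ChunkingError(f"chunk size must be positive, got {chunk}")
    if stride > chunk:
        raise ChunkingError(
            f"stride {stride} exceeds chunk {chunk}; the window would leave "
            "uncovered gaps"
        )
    shape = tuple(int(s) for s in volume_shape)
    per_axis = [_axis_origins(d, chunk, stride) for d in shape]
    origins = tuple(product(*per_axis))
    return ChunkGrid(
        chunk_shape=(chunk,) * 3, stride=stride, origins=origins, volume_shape=shape
    )


def extract(data: np.ndarray, grid: ChunkGrid):
    """Yield chunk copies in ``grid.origins`` order."""
    cz, cy, cx = grid.chunk_shape
    if tuple(data.shape) != grid.volume_shape:
        raise ChunkingError(
            f"volume shape {data.shape} does not match grid {grid.volume_shape}"
        )
    for oz, oy, ox in grid.origins:
        yield data[oz : oz + cz, oy : oy + cy, ox : ox + cx].copy()


def coverage_count(grid: ChunkGrid) -> np.ndarray:
    """Per-voxel number of chunks covering it."""
    count = np.zeros(grid.volume_shape, dtype=np.int32)
    cz, cy, cx = grid.chunk_shape
    for oz, oy, ox in grid.origins:
        count[oz : oz + cz, oy : oy + cy, ox : ox + cx] += 1
    return count


def aggregate(predictions, grid: ChunkGrid, channels: int | None = None) -> np.ndarray:
    """Fuse per-chunk maps into a full-volume map by unweighted voxel mean.

    ``predictions``: sequence aligned with ``grid.origins``; each item is a
    (D,H,W) array or (C,D,H,W) with a shared leading channel axis.
    """
    preds = list(predictions)
    if len(preds) != grid.n_chunks:
        raise ChunkingError(
            f"got {len(preds)} chunk predictions for {grid.n_chunks} origins"
        )
    cz, cy, cx = grid.chunk_shape
    first = np.asarray(preds[0])
    has_channels = first.ndim == 4
    c = first.shape[0] if has_channels else 1
    acc = np.zeros((c, *grid.volume_shape), dtype=np.float64)
    count = np.zeros(grid.volume_shape, dtype=np.int32)
    for origin, p in zip(grid.origins, preds):
        if p is None:
            raise ChunkingError(f"missing chunk prediction at origin {origin}")
        p = np.asarray(p)
        if not has_channels:
            p = p[None]
        if p.shape[1:] != grid.chunk_shape:
            raise ChunkingError(
                f"chunk at origin {origin} has shape {p.shape[1:]}, "
                f"expected {grid.chunk_shape}"
            )
        oz, oy, ox = origin
        acc[:, oz : oz + cz, oy : oy + cy, ox : ox + cx] += p
        count[oz : oz + cz, oy : oy + cy, ox : ox + cx] += 1
    if count.min() < 1:
        raise ChunkingError("grid does not cover every voxel")
    out = acc / count[None]
    return out if has_channels else out[0]


def pad_to_chunk(data: np.ndarray, chunk: int, value: float = 0.0):
    """Symmetrically pad axes smaller than ``chunk``; returns (padded, slices)
    where ``slices`` crops back to the original extent."""
    pads, crops = [], []
    for d in data.shape:
        if d >= chunk:
            pads.append((0, 0))
            crops.append(slice(0, d))
        else:
            total = chunk - d
            lo = total // 2
            pads.append((lo, total - lo))
            crops.append(slice(lo, lo + d))
    padded = np.pad(data, pads, constant_values=value)
    return padded, tuple(crops)
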