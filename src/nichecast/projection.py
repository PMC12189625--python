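"""HSI projection: replicate-mean prediction, 0.2-degree block averaging,
five-level classification, and the binary suitability flag."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import EnvLayerStack, GridSpec
from .errors import AlignmentError, ConfigError, DataError

BLOCK_FACTOR = 4  # 0.05 deg cells -> 0.2 deg blocks

CLASS_NAMES = (
    "Unsuitability",
    "Low suitability",
    "Moderate suitability",
    "High suitability",
    "Optimal suitability",
)
#: HSI >= 0.4 (class index >= 2) counts as suitable habitat.
SUITABLE_THRESHOLD = 0.4
_BIN_EDGES = (0.2, 0.4, 0.6, 0.8)


def classify_hsi(value):
    """Class index 0-4 for HSI in [0,1].

    Bins are left-closed/right-open, with the top bin closed:
    [0,0.2) [0.2,0.4) [0.4,0.6) [0.6,0.8) [0.8,1.0].
    """
    v = np.asarray(value, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise DataError("HSI values must lie in [0, 1]")
    idx = np.digitize(v, _BIN_EDGES, right=False)
    return idx if idx.shape else int(idx)


def class_name(index) -> str:
    return CLASS_NAMES[int(index)]


@dataclass
class SuitabilityGrid:
    """0.2-degree block-mean HSI with class labels and binary suitability."""

    grid: GridSpec  # the block grid
    hsi: np.ndarray  # block-mean HSI, NaN where invalid
    valid: np.ndarray  # block has >= 1 unmasked constituent cell

    def __post_init__(self):
        self.hsi = np.asarray(self.hsi, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.hsi.shape != self.grid.shape or self.valid.shape != self.grid.shape:
            raise AlignmentError("block fields do not match block grid")

    @property
    def classes(self) -> np.ndarray:
        """Class index 0-4 per valid block; -1 where invalid."""
        out = np.full(self.grid.shape, -1, dtype=int)
        out[self.valid] = classify_hsi(self.hsi[self.valid])
        return out

    @property
    def suitable(self) -> np.ndarray:
        """Boolean suitable flag (HSI >= 0.4); False where invalid."""
        out = np.zeros(self.grid.shape, dtype=bool)
        out[self.valid] = self.hsi[self.valid] >= SUITABLE_THRESHOLD
        return out


def project_hsi(
    models, stack: EnvLayerStack, output: str = "logistic"
) -> np.ndarray:
    """Cell-wise mean of the replicate models' predictions on *stack*.

    Returns a 0.05-degree field (NaN on masked cells).
    """
    models = list(models)
    if not models:
        raise ConfigError("need at least one fitted model")
    for v in models[0].variables:
        if v not in stack.layers:
            raise DataError(f"variable {v!r} missing from stack")
    design = stack.background_matrix(models[0].variables)
    acc = np.zeros(design.shape[0])
    for m in models:
        if m.variables != models[0].variables:
            raise ConfigError("replicate models disagree on variables")
        acc += m.predict(design, output=output)
    acc /= len(models)
    out = np.full(stack.grid.shape, np.nan)
    out[stack.mask] = acc
    return out


def block_average(
    hsi: np.ndarray, grid: GridSpec, factor: int = BLOCK_FACTOR
) -> SuitabilityGrid:
    """Mean HSI over each ``factor x factor`` block, ignoring masked cells.

    Blocks with no unmasked constituent cell are invalid. The fine grid must
    tile exactly into blocks.
    """
    hsi = np.asarray(hsi, dtype=float)
    if hsi.shape != grid.shape:
        raise AlignmentError("HSI field does not match grid")
    block_grid = grid.coarsen(factor)
    r, c = block_grid.shape
    tiles = hsi.reshape(r, factor, c, factor).swapaxes(1, 2).reshape(r, c, -1)
    finite = np.isfinite(tiles)
    counts = finite.sum(axis=2)
    sums = np.where(finite, tiles, 0.0).sum(axis=2)
    valid = counts > 0
    means = np.full((r, c), np.nan)
    means[valid] = sums[valid] / counts[valid]
    return SuitabilityGrid(grid=block_grid, hsi=means, valid=valid)
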