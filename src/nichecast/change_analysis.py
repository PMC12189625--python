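"""Present-vs-future comparison: change categories, suitable areas and
trends, HSI-weighted latitudinal centroids, richness, and MPA overlap.

Areas use a spherical-rectangle approximation with 111.195 km per degree
(authalic radius); longitudinal extent scales with the cosine of the block
center latitude. Coordinates stay in decimal degrees throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError
from .projection import SuitabilityGrid

KM_PER_DEGREE = 111.195

# Change-category codes.
ABSENCE, CONSTRICTION, EXPANSION, STABILITY = 0, 1, 2, 3
CHANGE_CATEGORY_NAMES = ("Absence", "Constriction", "Expansion", "Stability")

# MPA overlap codes.
MPA_ABSENCE, MPA_UNPROTECTED, MPA_PROTECTED = 0, 1, 2
MPA_CLASS_NAMES = ("Absence", "Unprotected", "Protected")


def change_category(present_suitable, future_suitable):
    """Truth table: (False,False)->Absence, (True,False)->Constriction,
    (False,True)->Expansion, (True,True)->Stability."""
    p = np.asarray(present_suitable, dtype=bool)
    f = np.asarray(future_suitable, dtype=bool)
    out = np.where(p, np.where(f, STABILITY, CONSTRICTION), np.where(f, EXPANSION, ABSENCE))
    return out if out.shape else int(out)


def change_category_grid(
    present: SuitabilityGrid, future: SuitabilityGrid
) -> np.ndarray:
    """Per-block category; -1 on blocks invalid in either grid."""
    if present.grid != future.grid:
        raise AlignmentError("present and future grids differ")
    valid = present.valid & future.valid
    out = np.full(present.grid.shape, -1, dtype=int)
    out[valid] = change_category(present.suitable[valid], future.suitable[valid])
    return out


def block_area_km2(lat, cell_size: float) -> np.ndarray:
    """Area of a cell_size x cell_size block centered at latitude *lat*."""
    lat = np.asarray(lat, dtype=float)
    return (cell_size * KM_PER_DEGREE) ** 2 * np.cos(np.radians(lat))


def suitable_area(grid: SuitabilityGrid) -> tuple[float, pd.Series]:
    """Total suitable area in 10^3 km^2, plus the per-latitude-band vector.

    The band vector is indexed by block-center latitude and is also in
    10^3 km^2.
    """
    suit = grid.suitable
    lats = grid.grid.lats()
    per_row = np.array(
        [
            block_area_km2(lats[i], grid.grid.cell_size) * suit[i].sum()
            for i in range(grid.grid.n_rows)
        ]
    )
    bands = pd.Series(per_row / 1e3, index=lats, name="area_1e3_km2")
    return float(bands.sum()), bands


def trend_percent(present_area: float, future_area: float) -> float:
    """100 * (future - present) / present, rounded to 2 decimals.

    Undefined (NaN) when the present area is not positive.
    """
    if present_area <= 0:
        return float("nan")
    return round(100.0 * (future_area - present_area) / present_area, 2)


def weighted_centroid(grid: SuitabilityGrid) -> float:
    """Latitude centroid: sum(lat * HSI) / sum(HSI) over all valid blocks."""
    hsi = grid.hsi[grid.valid]
    lat_mesh = np.broadcast_to(
        grid.grid.lats()[:, None], grid.grid.shape
    )[grid.valid]
    total = np.nansum(hsi)
    if not total > 0:
        return float("nan")
    return float(np.nansum(lat_mesh * hsi) / total)


def richness(per_species: dict[str, SuitabilityGrid]) -> np.ndarray:
    """Per-block count of species whose suitable flag is set (0 = Absence).

    Counts over blocks valid for at least one species; blocks invalid for
    every species are -1.
    """
    grids = list(per_species.values())
    if not grids:
        raise DataError("no species grids supplied")
    base = grids[0].grid
    for g in grids[1:]:
        if g.grid != base:
            raise AlignmentError("species grids are not aligned")
    any_valid = np.zeros(base.shape, dtype=bool)
    count = np.zeros(base.shape, dtype=int)
    for g in grids:
        any_valid |= g.valid
        count += g.suitable.astype(int)
    out = np.where(any_valid, count, -1)
    return out


def mpa_overlap(
    richness_grid: np.ndarray,
    mpa_block_mask: np.ndarray,
    block_grid,
) -> tuple[np.ndarray, float]:
    """Classify blocks and compute the protected fraction.

    richness 0 -> Absence; richness >= 1 inside the MPA -> Protected, else
    Unprotected. Invalid blocks (richness < 0) stay -1. The protected
    fraction is Protected area / (Protected + Unprotected area) * 100,
    cosine-weighted by latitude; NaN when no block is suitable.
    """
    richness_grid = np.asarray(richness_grid)
    mpa = np.asarray(mpa_block_mask, dtype=bool)
    if richness_grid.shape != mpa.shape or richness_grid.shape != block_grid.shape:
        raise AlignmentError("richness and MPA mask are not aligned")
    out = np.full(richness_grid.shape, -1, dtype=int)
    out[richness_grid == 0] = MPA_ABSENCE
    out[(richness_grid >= 1) & mpa] = MPA_PROTECTED
    out[(richness_grid >= 1) & ~mpa] = MPA_UNPROTECTED
    lat_mesh = np.broadcast_to(block_grid.lats()[:, None], block_grid.shape)
    areas = block_area_km2(lat_mesh, block_grid.cell_size)
    prot = float(areas[out == MPA_PROTECTED].sum())
    unprot = float(areas[out == MPA_UNPROTECTED].sum())
    frac = float("nan") if prot + unprot == 0 else 100.0 * prot / (prot + unprot)
    return out, frac


def block_mpa_mask(cell_mask: np.ndarray, grid, factor: int = 4) -> np.ndarray:
    """Coarsen a 0/1 cell mask to blocks: any flagged constituent cell
    marks the block as inside the MPA."""
    cell_mask = np.asarray(cell_mask)
    block_grid = grid.coarsen(factor)
    r, c = block_grid.shape
    tiles = cell_mask.reshape(r, factor, c, factor).swapaxes(1, 2).reshape(r, c, -1)
    return tiles.max(axis=2) > 0


@dataclass
class ChangeSummary:
    """One species x scenario x period comparison."""

    species: str
    scenario: str
    period: str
    present_area: float  # 10^3 km^2
    future_area: float  # 10^3 km^2
    trend: float  # percent
    categories: np.ndarray  # per-block codes, -1 invalid
    present_centroid: float  # deg N
    future_centroid: float  # deg N

    @property
    def centroid_shift(self) -> float:
        return self.future_centroid - self.present_centroid


def summarize_change(
    species: str,
    scenario: str,
    period: str,
    present: SuitabilityGrid,
    future: SuitabilityGrid,
) -> ChangeSummary:
    """Assemble the full comparison, asserting the area-conservation
    identities (Stability+Constriction = present, Stability+Expansion =
    future, by area over jointly valid blocks)."""
    cats = change_category_grid(present, future)
    joint = cats >= 0
    p_area, _ = suitable_area(_restrict(present, joint))
    f_area, _ = suitable_area(_restrict(future, joint))
    areas = _category_areas(cats, present.grid)
    assert np.isclose(
        areas[STABILITY] + areas[CONSTRICTION], p_area, rtol=1e-9, atol=1e-9
    ), "category areas do not reconstruct the present suitable area"
    assert np.isclose(
        areas[STABILITY] + areas[EXPANSION], f_area, rtol=1e-9, atol=1e-9
    ), "category areas do not reconstruct the future suitable area"
    return ChangeSummary(
        species=species,
        scenario=scenario,
        period=period,
        present_area=p_area,
        future_area=f_area,
        trend=trend_percent(p_area, f_area),
        categories=cats,
        present_centroid=weighted_centroid(present),
        future_centroid=weighted_centroid(future),
    )


def _restrict(grid: SuitabilityGrid, keep: np.ndarray) -> SuitabilityGrid:
    return SuitabilityGrid(
        grid=grid.grid,
        hsi=np.where(keep, grid.hsi, np.nan),
        valid=grid.valid & keep,
    )


def _category_areas(cats: np.ndarray, block_grid) -> dict[int, float]:
    lat_mesh = np.broadcast_to(block_grid.lats()[:, None], block_grid.shape)
    areas = block_area_km2(lat_mesh, block_grid.cell_size) / 1e3
    return {
        code: float(areas[cats == code].sum())
        for code in (ABSENCE, CONSTRICTION, EXPANSION, STABILITY)
    }


def summary_table(summaries: list[ChangeSummary]) -> pd.DataFrame:
    """Long-format table of areas and trends (one row per species x
    scenario x period), mirroring the reporting layout."""
    rows = [
        {
            "species": s.species,
            "scenario": s.scenario,
            "period": s.period,
            "present_area_1e3_km2": round(s.present_area, 2),
            "future_area_1e3_km2": round(s.future_area, 2),
            "trend_percent": s.trend,
            "present_centroid_degN": round(s.present_centroid, 2),
            "future_centroid_degN": round(s.future_centroid, 2),
            "centroid_shift_deg": round(s.centroid_shift, 2),
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
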