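"""Change products: direction maps, cross-model agreement, magnitude maps,
novel-cover masks, and proportion summaries.

Direction compares projected to baseline cover with an explicit tolerance
(the default 0 registers even a 1 % -> 1.002 % rise as positive change).
Agreement scores a cell by the signed majority count over models: +k when k
models form the positive majority, -k for a negative majority, 0 for ties;
unanimity over four models gives the +/-4 endpoints.  Magnitude is reported
as a signed proportion of baseline cover, undefined where the baseline is
zero; zero-to-positive transitions are flagged separately as novel cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import CoverField, RasterGrid

__all__ = [
    "DirectionField",
    "AgreementMap",
    "MagnitudeField",
    "ChangeSummary",
    "change_direction",
    "agreement_map",
    "magnitude_map",
    "summarize_proportions",
    "ensemble_magnitude",
    "all_zero_cover_mask",
    "TOL_PRESETS",
]

#: Named tolerance presets: "any-change" counts every signed difference;
#: "gt5pct" requires an absolute cover change above 0.05.
TOL_PRESETS = {"any-change": 0.0, "gt5pct": 0.05}


@dataclass(frozen=True)
class DirectionField:
    """Per-cell direction of change: +1 / -1 / 0, NaN for NoData."""

    grid: RasterGrid
    direction: np.ndarray
    tol: float


@dataclass(frozen=True)
class AgreementMap:
    """Signed majority count over models, in {-n_models .. +n_models}."""

    grid: RasterGrid
    score: np.ndarray
    n_models: int


@dataclass(frozen=True)
class MagnitudeField:
    """Relative change (proj - base)/base, NaN where base == 0 or NoData;
    novel_mask flags zero-to-positive transitions."""

    grid: RasterGrid
    relative: np.ndarray
    novel_mask: np.ndarray


@dataclass(frozen=True)
class ChangeSummary:
    """Table-style proportion summary over cells with baseline cover > 0."""

    p_up: float
    p_down: float
    p_same: float
    n_cells_considered: int
    n_nodata_excluded: int
    tol: float

    def as_dict(self) -> dict:
        return {
            "p_up": self.p_up,
            "p_down": self.p_down,
            "p_same": self.p_same,
            "n_cells_considered": self.n_cells_considered,
            "n_nodata_excluded": self.n_nodata_excluded,
            "tol": self.tol,
        }


def _check_grids(a: RasterGrid, b: RasterGrid) -> None:
    if not a.same_geometry(b):
        raise ValueError("fields are on different grids")


def change_direction(base: CoverField, proj: CoverField,
                     tol: float = 0.0) -> DirectionField:
    """+1 where proj - base > tol, -1 where base - proj > tol, else 0;
    NoData wherever either input is NoData."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    _check_grids(base.grid, proj.grid)
    diff = proj.cover - base.cover
    direction = np.where(diff > tol, 1.0, np.where(-diff > tol, -1.0, 0.0))
    direction = np.where(np.isfinite(base.cover) & np.isfinite(proj.cover),
                         direction, np.nan)
    return DirectionField(base.grid, direction, tol)


def agreement_map(directions: list[DirectionField]) -> AgreementMap:
    """Signed majority count across models.

    Per cell, with n+ positive and n- negative votes: score = +n+ when
    n+ > n-, -n- when n- > n+, and 0 on ties (including all-zero).  NoData
    wherever any member is NoData.
    """
    if len(directions) < 2:
        raise ValueError("agreement needs >= 2 models")
    grid = directions[0].grid
    for d in directions[1:]:
        _check_grids(grid, d.grid)
    stack = np.stack([d.direction for d in directions])
    n_pos = np.sum(stack == 1.0, axis=0).astype(float)
    n_neg = np.sum(stack == -1.0, axis=0).astype(float)
    score = np.where(n_pos > n_neg, n_pos, np.where(n_neg > n_pos, -n_neg, 0.0))
    score = np.where(np.all(np.isfinite(stack), axis=0), score, np.nan)
    return AgreementMap(grid, score, len(directions))


def magnitude_map(base: CoverField, proj: CoverField) -> MagnitudeField:
    """Relative change as a proportion of baseline cover; NoData where the
    baseline is zero; novel where baseline == 0 and projection > 0."""
    _check_grids(base.grid, proj.grid)
    b, p = base.cover, proj.cover
    valid = np.isfinite(b) & np.isfinite(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (p - b) / b
    rel = np.where(valid & (b > 0), rel, np.nan)
    novel = valid & (b == 0) & (p > 0)
    return MagnitudeField(base.grid, rel, novel)


def summarize_proportions(base: CoverField, proj: CoverField,
                          tol: float = 0.0) -> ChangeSummary:
    """Proportions of cells increasing / decreasing / unchanged, relative to
    the cells with baseline cover > 0; NoData cells are excluded and
    counted."""
    direction = change_direction(base, proj, tol).direction
    b, p = base.cover, proj.cover
    both = np.isfinite(b) & np.isfinite(p)
    eligible = both & (b > 0)
    on_mask = base.grid.land_mask
    n_nodata = int(np.sum(on_mask & ~(np.isfinite(b) & np.isfinite(p))))
    n = int(eligible.sum())
    if n == 0:
        raise ValueError("no eligible cells (baseline cover > 0 with data)")
    d = direction[eligible]
    return ChangeSummary(
        p_up=float(np.mean(d == 1.0)),
        p_down=float(np.mean(d == -1.0)),
        p_same=float(np.mean(d == 0.0)),
        n_cells_considered=n,
        n_nodata_excluded=n_nodata,
        tol=tol,
    )


def ensemble_magnitude(members: list[MagnitudeField]) -> MagnitudeField:
    """Per-cell mean of the defined relative changes over ensemble members;
    NoData only where every member is undefined; novel mask = union."""
    if not members:
        raise ValueError("ensemble_magnitude needs >= 1 member")
    grid = members[0].grid
    for m in members[1:]:
        _check_grids(grid, m.grid)
    stack = np.stack([m.relative for m in members])
    count = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, np.nansum(stack, axis=0) / count, np.nan)
    novel = np.logical_or.reduce([m.novel_mask for m in members])
    return MagnitudeField(grid, mean, novel)


def all_zero_cover_mask(base: CoverField,
                        projections: list[CoverField]) -> np.ndarray:
    """Cells with zero cover in the baseline and in every projection —
    the 'unsuitable for agriculture in all model projections' reading,
    kept separate from the tie score of the agreement map."""
    grid = base.grid
    for p in projections:
        _check_grids(grid, p.grid)
    out = np.isfinite(base.cover) & (base.cover == 0)
    for p in projections:
        out &= np.isfinite(p.cover) & (p.cover == 0)
    return out
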