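"""Hemisphere-mirrored tile grid scoring of microglial reactivity.

Reactivity on a microglial-marker section is scored on a lattice of
200x200 µm tiles. The grid is anchored at the anatomical midline and grown
laterally over the non-lesioned (contralesional) hemisphere; each tile is
mirrored across the midline to define its partner on the lesioned side, so
the contralesional hemisphere defines the tiles analyzed ipsilesionally.

A tile counts as "high reactivity" when its mean gray value exceeds the
mean + 1.5 SD of the non-excluded contralesional tile means of the same
section. The per-section outcome is the high-tile ratio per hemisphere and
their difference (ipsilesional minus contralesional). Stroke core and
artifacts can be excluded via a binary mask; a tile with at least 20% of
its pixels masked (default) is dropped from both counts.

Sections are attributed to one of three anterior-posterior analysis
windows: region F (+3.8 to +4.5 mm from bregma; infarct only), region E
(-0.1 to +0.2 mm; infarct and stimulation electrode) and region D (-2.0 to
-1.7 mm; electrode only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import mean as _mean
from typing import Sequence

import numpy as np

from .imaging import SectionImage

#: Closed AP windows (mm from bregma) of the three analysis regions.
REGION_WINDOWS: dict[str, tuple[float, float]] = {
    "F": (3.8, 4.5),   # rostral: infarct only
    "E": (-0.1, 0.2),  # mid: infarct + electrode
    "D": (-2.0, -1.7),  # caudal: electrode only
}

DEFAULT_TILE_UM = 200.0
DEFAULT_SD_MULTIPLIER = 1.5
DEFAULT_EXCLUDED_PIXEL_FRACTION = 0.2


@dataclass
class Tile:
    row0: int
    col0: int
    size_px: int
    hemisphere: str       # "ipsi" or "contra"
    partner: int          # index of the mirrored tile in TileGrid.tiles

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.size_px),
                slice(self.col0, self.col0 + self.size_px))


@dataclass
class TileGrid:
    """Mirrored tile lattice for one section: equal tile counts per
    hemisphere, mirror pairing an involution by construction."""

    tile_um: float
    tile_px: int
    midline_col: int
    tiles: list[Tile]

    def hemisphere_indices(self, hemisphere: str) -> list[int]:
        return [i for i, t in enumerate(self.tiles) if t.hemisphere == hemisphere]


@dataclass
class TileStats:
    """Per-tile means and exclusion flags, plus per-hemisphere tallies."""

    grid: TileGrid
    mean_gray: np.ndarray   # per tile; NaN when no analyzable pixel
    excluded: np.ndarray    # bool per tile

    def analyzed(self, hemisphere: str) -> np.ndarray:
        idx = np.array(self.grid.hemisphere_indices(hemisphere), dtype=int)
        keep = ~self.excluded[idx]
        return self.mean_gray[idx[keep]]


@dataclass
class ReactivityResult:
    """High-reactivity tile ratios of one section."""

    ap_mm: float
    region: str | None          # "D", "E", "F" or None
    threshold: float
    ratio_ipsi: float
    ratio_contra: float

    @property
    def ratio_diff(self) -> float:
        return self.ratio_ipsi - self.ratio_contra


def build_grid(section: SectionImage,
               tile_um: float = DEFAULT_TILE_UM) -> TileGrid:
    """Lay out the mirrored tile lattice for one section.

    Tiles are anchored at the midline column and at the top image row and
    grown outward in whole tiles; incomplete border tiles are dropped, and
    the lateral extent is limited by the narrower hemisphere so that every
    contralesional tile has an ipsilesional mirror partner.
    """
    if tile_um < section.um_per_px:
        raise ValueError("tile must be at least one pixel")
    tile_px = max(1, int(round(tile_um / section.um_per_px)))
    height, width = section.shape
    m = section.midline_col
    n_rows = height // tile_px
    n_lat = min(m, width - m) // tile_px
    if n_rows == 0 or n_lat == 0:
        raise ValueError("tile larger than hemisphere: no tiles fit")
    # lesion side "right" means image columns >= midline are ipsilesional
    right_is_ipsi = section.lesion_side == "right"
    tiles: list[Tile] = []
    for r in range(n_rows):
        for k in range(n_lat):
            right_col0 = m + k * tile_px
            left_col0 = m - (k + 1) * tile_px
            i_right = len(tiles)
            tiles.append(Tile(r * tile_px, right_col0, tile_px,
                              "ipsi" if right_is_ipsi else "contra",
                              i_right + 1))
            tiles.append(Tile(r * tile_px, left_col0, tile_px,
                              "contra" if right_is_ipsi else "ipsi",
                              i_right))
    return TileGrid(tile_um=tile_um, tile_px=tile_px, midline_col=m,
                    tiles=tiles)


def tile_means(section: SectionImage, grid: TileGrid,
               exclusion: np.ndarray | None = None,
               excluded_pixel_fraction: float = DEFAULT_EXCLUDED_PIXEL_FRACTION,
               ) -> TileStats:
    """Mean gray value per tile over non-excluded pixels.

    ``exclusion`` is a boolean mask (True = excluded pixel: stroke core or
    artifact). A tile whose excluded-pixel fraction reaches
    ``excluded_pixel_fraction`` is flagged excluded and contributes to no
    hemisphere tally; its mirror partner is *not* auto-excluded, since
    ratios are computed per hemisphere rather than per pair.
    """
    img = np.asarray(section.pixels, dtype=float)
    if exclusion is not None:
        exclusion = np.asarray(exclusion, dtype=bool)
        if exclusion.shape != img.shape:
            raise ValueError(
                f"exclusion mask shape {exclusion.shape} != image {img.shape}")
    means = np.full(len(grid.tiles), np.nan)
    excluded = np.zeros(len(grid.tiles), dtype=bool)
    for i, tile in enumerate(grid.tiles):
        sl = tile.slices()
        patch = img[sl]
        if exclusion is not None:
            bad = exclusion[sl]
            frac = bad.mean()
            if frac >= excluded_pixel_fraction:
                excluded[i] = True
            good = patch[~bad]
            if good.size:
                means[i] = good.mean()
        else:
            means[i] = patch.mean()
        if np.isnan(means[i]):
            excluded[i] = True
    return TileStats(grid=grid, mean_gray=means, excluded=excluded)


def reactivity_threshold(contra_tile_means: Sequence[float] | np.ndarray,
                         sd_multiplier: float = DEFAULT_SD_MULTIPLIER) -> float:
    """High-reactivity threshold: mean + ``sd_multiplier`` x sample SD
    (n-1 denominator) of the contralesional tile means of one section."""
    values = np.asarray(contra_tile_means, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two contralesional tiles")
    return float(values.mean() + sd_multiplier * values.std(ddof=1))


def high_tile_ratio(stats: TileStats, threshold: float,
                    ap_mm: float | None = None) -> ReactivityResult:
    """Fraction of analyzed tiles above ``threshold`` per hemisphere.

    Both hemispheres are classified against the single contralesionally
    derived threshold; the headline statistic is their difference
    (ipsilesional minus contralesional).
    """
    ratios = {}
    for hemi in ("ipsi", "contra"):
        vals = stats.analyzed(hemi)
        if vals.size == 0:
            raise ValueError(f"no analyzed tiles in {hemi} hemisphere")
        ratios[hemi] = float((vals > threshold).mean())
    ap = float(ap_mm) if ap_mm is not None else math.nan
    return ReactivityResult(ap_mm=ap, region=assign_region(ap),
                            threshold=threshold,
                            ratio_ipsi=ratios["ipsi"],
                            ratio_contra=ratios["contra"])


def assign_region(ap_mm: float) -> str | None:
    """Map an AP position to its analysis region (closed intervals);
    ``None`` outside all three windows."""
    if math.isnan(ap_mm):
        return None
    for name, (lo, hi) in REGION_WINDOWS.items():
        if lo <= ap_mm <= hi:
            return name
    return None


def score_section(section: SectionImage,
                  exclusion: np.ndarray | None = None,
                  tile_um: float = DEFAULT_TILE_UM,
                  sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
                  excluded_pixel_fraction: float = DEFAULT_EXCLUDED_PIXEL_FRACTION,
                  ) -> ReactivityResult:
    """Full per-section scoring: grid, tile means, threshold, ratios."""
    if section.channel != "iba1":
        raise ValueError("reactivity scoring runs on the iba1 channel")
    grid = build_grid(section, tile_um=tile_um)
    stats = tile_means(section, grid, exclusion,
                       excluded_pixel_fraction=excluded_pixel_fraction)
    thr = reactivity_threshold(stats.analyzed("contra"), sd_multiplier)
    return high_tile_ratio(stats, thr, ap_mm=section.ap_mm)


@dataclass
class AnimalReactivity:
    """Per-animal summary over sections: one value per region (mean
    ratio_diff over that region's sections) plus their pooled mean."""

    region_values: dict[str, float]
    pooled_mean: float | None
    missing_regions: list[str]


def animal_reactivity_summary(results: Sequence[ReactivityResult],
                              regions: Sequence[str] = ("D", "E", "F"),
                              ) -> AnimalReactivity:
    """Summarize one animal's section results into region values.

    Sections outside every region window are ignored. The pooled output is
    the set of region values and their mean (one data point per
    animal-region, pooled by averaging); regions without sections are
    reported missing rather than zero.
    """
    if not results:
        raise ValueError("no section results to summarize")
    region_values: dict[str, float] = {}
    missing: list[str] = []
    for region in regions:
        diffs = [r.ratio_diff for r in results if r.region == region]
        if diffs:
            region_values[region] = _mean(diffs)
        else:
            missing.append(region)
    pooled = _mean(region_values.values()) if region_values else None
    return AnimalReactivity(region_values=region_values,
                            pooled_mean=pooled,
                            missing_regions=missing)
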