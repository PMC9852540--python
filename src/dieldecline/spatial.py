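"""Per-pixel diel-niche richness and per-threat proportional-decline layers
on an equal-area grid.

Per cell and niche the proportion layer is

    (# species in the niche, declining, carrying the threat, present in the
     cell, and not overridden for the cell's country) / (# species in the
     niche present in the cell)

with the default assumption that a declining species is declining
throughout its range, except where a (species, country) override marks it
non-declining. Two masking modes exist: ``richness`` masks cells whose niche
richness is <= 5; ``decliners`` masks cells whose numerator is <= 5.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import write_raster
from .types import (
    DielNiche,
    GridSpec,
    RangeStack,
    SpeciesRecord,
    ThreatCategory,
    TrendClass,
)

LOW_RICHNESS_CUTOFF = 5


class MaskReason(enum.IntEnum):
    NONE = 0
    NO_SPECIES = 1
    LOW_RICHNESS = 2


@dataclass
class DeclineRaster:
    grid: GridSpec
    niche: DielNiche
    threat: ThreatCategory
    proportion: np.ndarray  # float, NaN where masked
    mask_reason: np.ndarray  # MaskReason codes, uint8
    numerator: np.ndarray
    denominator: np.ndarray


def _record_index(stack: RangeStack, records: Sequence[SpeciesRecord]) -> dict[str, SpeciesRecord]:
    by_id = {r.species_id: r for r in records}
    missing = [s for s in stack.species_ids if s not in by_id]
    if missing:
        raise ValueError(f"species in range stack absent from records: {missing[:5]}")
    return by_id


def richness_raster(
    stack: RangeStack, records: Sequence[SpeciesRecord], niche: DielNiche
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell count of niche members present; cells at 0 are flagged.

    Returns (counts as nrows x ncols int array, mask_reason array).
    """
    by_id = _record_index(stack, records)
    rows = [i for i, s in enumerate(stack.species_ids) if by_id[s].diel_niche is niche]
    counts = stack.presence[rows].sum(axis=0).astype(int) if rows else np.zeros(stack.grid.n_cells, int)
    counts = counts.reshape(stack.grid.shape)
    mask = np.where(counts == 0, np.uint8(MaskReason.NO_SPECIES), np.uint8(MaskReason.NONE))
    return counts, mask


def decline_proportion_raster(
    stack: RangeStack,
    records: Sequence[SpeciesRecord],
    niche: DielNiche,
    threat: ThreatCategory,
    overrides: Optional[set[tuple[str, str]]] = None,
    country_raster: Optional[np.ndarray] = None,
    mask_mode: str = "richness",
) -> DeclineRaster:
    """Proportion of a niche's species declining from one threat, per cell.

    ``country_raster`` is an integer/string-coded array aligned to the grid;
    ``overrides`` holds (species_id, country_code) pairs where the species is
    known not to be declining — those cells leave the numerator (the
    denominator, niche richness, is unchanged).
    """
    if mask_mode not in ("richness", "decliners"):
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    by_id = _record_index(stack, records)
    overrides = overrides or set()
    if overrides:
        known = set(stack.species_ids)
        bad = [p for p in overrides if p[0] not in known]
        if bad:
            raise ValueError(f"override references species not in stack: {bad[:5]}")
        if country_raster is None:
            raise ValueError("overrides supplied without a country raster")
    if country_raster is not None:
        country_flat = np.asarray(country_raster).reshape(-1)
        if country_flat.size != stack.grid.n_cells:
            raise ValueError("country raster does not match grid")
        override_countries = {c for _, c in overrides}
        unknown_c = override_countries - {str(c) for c in np.unique(country_flat)}
        if unknown_c:
            raise ValueError(f"override references unknown countries: {sorted(unknown_c)}")

    n_cells = stack.grid.n_cells
    denom = np.zeros(n_cells, dtype=int)
    numer = np.zeros(n_cells, dtype=int)
    for i, sid in enumerate(stack.species_ids):
        rec = by_id[sid]
        if rec.diel_niche is not niche:
            continue
        present = stack.presence[i]
        denom += present
        is_decliner = (
            rec.trend_class is TrendClass.DECLINING and rec.threats_known and threat in rec.threats
        )
        if is_decliner:
            contrib = present.copy()
            if country_raster is not None:
                for country in (c for s, c in overrides if s == sid):
                    contrib &= ~(country_flat.astype(str) == country)
            numer += contrib

    mask = np.full(n_cells, np.uint8(MaskReason.NONE))
    mask[denom == 0] = np.uint8(MaskReason.NO_SPECIES)
    low = (numer if mask_mode == "decliners" else denom) <= LOW_RICHNESS_CUTOFF
    mask[(mask == MaskReason.NONE) & low] = np.uint8(MaskReason.LOW_RICHNESS)
    prop = np.full(n_cells, np.nan)
    ok = mask == MaskReason.NONE
    prop[ok] = numer[ok] / denom[ok]
    shape = stack.grid.shape
    return DeclineRaster(
        stack.grid, niche, threat,
        prop.reshape(shape), mask.reshape(shape),
        numer.reshape(shape), denom.reshape(shape),
    )


NODATA = -9999.0


def write_decline_maps(layers: Sequence[DeclineRaster], directory: str | Path) -> list[Path]:
    """One float TIFF per (niche, threat) with nodata for masked cells, plus a
    companion byte raster carrying the mask reason."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for layer in layers:
        base = f"decline_{layer.niche.value}_{layer.threat.value}"
        arr = np.where(np.isnan(layer.proportion), NODATA, layer.proportion).astype(np.float32)
        p = directory / f"{base}.tif"
        write_raster(arr, layer.grid, p, nodata=NODATA,
                     extra_meta={"niche": layer.niche.value, "threat": layer.threat.value})
        write_raster(layer.mask_reason.astype(np.uint8), layer.grid, directory / f"{base}_mask.tif")
        paths.append(p)
    return paths


def default_report_niches() -> list[DielNiche]:
    """Niches included in default map reports. Crepuscular layers are
    producible but excluded by default: crepuscular richness is <= 5 species
    over most of the land surface, so nearly every cell would be masked."""
    return [n for n in DielNiche if n is not DielNiche.CREPUSCULAR]
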