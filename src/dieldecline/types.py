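"""Shared data model: diel niches, IUCN vocabulary, threats, species records,
tree ensembles and equal-area grids.

Every downstream stage (classification, phylogenetic regression, mapping)
consumes these containers; file formats live in :mod:`dieldecline.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import dendropy
import numpy as np


class DielNiche(str, enum.Enum):
    """Dominant activity pattern. ``NOCTURNAL`` is the regression base level.

    The order of members is the documented fixed state order used for
    deterministic tie-breaking in discrete-trait imputation.
    """

    NOCTURNAL = "nocturnal"
    CREPUSCULAR = "crepuscular"
    CATHEMERAL = "cathemeral"
    DIURNAL = "diurnal"


#: Fixed state order (also the tie-break order for imputation).
NICHE_ORDER: tuple[DielNiche, ...] = tuple(DielNiche)

#: Non-base niche levels, i.e. the regression terms.
NICHE_TERMS: tuple[DielNiche, ...] = tuple(n for n in DielNiche if n is not DielNiche.NOCTURNAL)


class ThreatCategory(str, enum.Enum):
    """The ten anthropogenic threat categories."""

    HABITAT_LOSS = "habitat_loss"
    HARVESTING = "harvesting"
    CONFLICT = "conflict"
    CLIMATE_CHANGE = "climate_change"
    NON_NATIVE = "non_native"
    POLLUTION = "pollution"
    HYBRIDIZATION = "hybridization"
    PREY_DEPLETION = "prey_depletion"
    DISEASE = "disease"
    INBREEDING = "inbreeding"


class IucnCategory(str, enum.Enum):
    LC = "LC"
    NT = "NT"
    VU = "VU"
    EN = "EN"
    CR = "CR"
    DD = "DD"
    NE = "NE"


#: Categories that trigger the declining-by-category rule when the trend is unknown.
THREATENED_CATEGORIES = frozenset(
    {IucnCategory.NT, IucnCategory.VU, IucnCategory.EN, IucnCategory.CR}
)


class IucnTrend(str, enum.Enum):
    DECREASING = "decreasing"
    STABLE = "stable"
    INCREASING = "increasing"
    UNKNOWN = "unknown"


class LiteratureTrend(str, enum.Enum):
    DECLINING = "declining"
    NON_DECLINING = "non_declining"
    UNKNOWN = "unknown"


class TrendClass(str, enum.Enum):
    DECLINING = "declining"
    NON_DECLINING = "non_declining"
    UNCLASSIFIED = "unclassified"


class TrendProvenance(str, enum.Enum):
    IUCN_TREND = "iucn_trend"
    CATEGORY_RULE = "category_rule"
    LITERATURE = "literature"
    NONE = "none"


@dataclass
class SpeciesRecord:
    """One mammal species with the observables used by all three model families.

    Invariants (enforced by :func:`validate_record`):

    * a declining/non-declining ``trend_class`` always carries a provenance;
    * ``threats_known=False`` implies an empty threat set.
    """

    species_id: str
    binomial: str = ""
    order: str = ""
    diel_niche: Optional[DielNiche] = None
    niche_imputed: bool = False
    iucn_category: IucnCategory = IucnCategory.NE
    iucn_trend_raw: IucnTrend = IucnTrend.UNKNOWN
    literature_trend: LiteratureTrend = LiteratureTrend.UNKNOWN
    trend_class: TrendClass = TrendClass.UNCLASSIFIED
    trend_provenance: TrendProvenance = TrendProvenance.NONE
    threats: frozenset[ThreatCategory] = field(default_factory=frozenset)
    threats_known: bool = False
    is_marine: bool = False
    is_fossorial: bool = False
    body_mass_kg: Optional[float] = None

    def copy(self, **changes) -> "SpeciesRecord":
        return replace(self, **changes)

    @property
    def declining(self) -> bool:
        return self.trend_class is TrendClass.DECLINING


def validate_record(rec: SpeciesRecord) -> None:
    """Raise ``ValueError`` on an internally inconsistent record."""
    if rec.trend_class is not TrendClass.UNCLASSIFIED and rec.trend_provenance is TrendProvenance.NONE:
        raise ValueError(f"{rec.species_id}: classified trend without provenance")
    if not rec.threats_known and rec.threats:
        raise ValueError(f"{rec.species_id}: threats set but threats_known is False")
    if rec.body_mass_kg is not None and rec.body_mass_kg <= 0:
        raise ValueError(f"{rec.species_id}: non-positive body mass")


def validate_table(records: Sequence[SpeciesRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.species_id in seen:
            raise ValueError(f"duplicate species_id: {rec.species_id!r}")
        seen.add(rec.species_id)
        validate_record(rec)


# ---------------------------------------------------------------------------
# Trees


def normalize_label(label: str) -> str:
    """Canonical tip label: underscores become spaces, whitespace collapsed.

    Supertree conventions differ (``Homo_sapiens`` vs ``Homo sapiens``); all
    matching between trees and species tables goes through this one rule.
    """
    return " ".join(label.replace("_", " ").split())


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [normalize_label(leaf.taxon.label) for leaf in tree.leaf_node_iter()]


@dataclass
class TreeEnsemble:
    """An ordered posterior sample of phylogenies over one shared tip set."""

    trees: list[dendropy.Tree]
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("empty tree ensemble")
        ref = set(tip_labels(self.trees[0]))
        for i, t in enumerate(self.trees[1:], start=1):
            labels = set(tip_labels(t))
            if labels != ref:
                diff = sorted(labels.symmetric_difference(ref))
                raise ValueError(f"tree {i} tip set differs from tree 0: {diff}")

    @property
    def tip_set(self) -> frozenset[str]:
        return frozenset(tip_labels(self.trees[0]))

    def __len__(self) -> int:
        return len(self.trees)

    def sample(self, b: int, seed: Optional[int] = None) -> "TreeEnsemble":
        """Draw ``b`` trees without replacement; deterministic under ``seed``."""
        if b > len(self.trees):
            raise ValueError(f"requested B={b} from {len(self.trees)} trees")
        s = self.rng_seed if seed is None else seed
        rng = np.random.default_rng(s)
        idx = rng.choice(len(self.trees), size=b, replace=False)
        return TreeEnsemble([self.trees[i] for i in idx], rng_seed=s)


# ---------------------------------------------------------------------------
# Grids and range stacks


@dataclass(frozen=True)
class GridSpec:
    """Equal-area raster geometry.

    Cells are indexed row-major and 0-based with the origin at the grid's
    upper-left corner; cell ``(r, c)`` covers
    ``[xmin + c*dx, xmin + (c+1)*dx) x (ymax - (r+1)*dx, ymax - r*dx]``.
    """

    crs_id: str
    cell_size_m: float
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0 or self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("cell size and grid shape must be positive")
        if not np.isclose(self.xmin + self.ncols * self.cell_size_m, self.xmax):
            raise ValueError("ncols inconsistent with extent and cell size")
        if not np.isclose(self.ymin + self.nrows * self.cell_size_m, self.ymax):
            raise ValueError("nrows inconsistent with extent and cell size")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def to_dict(self) -> dict:
        return {
            "crs_id": self.crs_id,
            "cell_size_m": self.cell_size_m,
            "extent": [self.xmin, self.ymin, self.xmax, self.ymax],
            "nrows": self.nrows,
            "ncols": self.ncols,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        xmin, ymin, xmax, ymax = d["extent"]
        return cls(d["crs_id"], d["cell_size_m"], xmin, ymin, xmax, ymax, d["nrows"], d["ncols"])


@dataclass
class RangeStack:
    """Species-by-cell binary presence on a shared grid.

    ``presence`` has shape (n_species, nrows*ncols), row-major cell order.
    """

    grid: GridSpec
    species_ids: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.species_ids), self.grid.n_cells):
            raise ValueError(
                f"presence shape {self.presence.shape} inconsistent with "
                f"{len(self.species_ids)} species x {self.grid.n_cells} cells"
            )
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species in range stack")

    def raster(self, species_id: str) -> np.ndarray:
        i = self.species_ids.index(species_id)
        return self.presence[i].reshape(self.grid.shape)
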