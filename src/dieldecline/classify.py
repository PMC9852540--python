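"""Rule-based derivations: analysis-set filtering, population-trend
assignment with provenance, threat sets, and the tidy per-niche summaries.

Trend assignment precedence
---------------------------
1. A known IUCN trend wins: decreasing -> declining; stable/increasing ->
   non-declining (provenance ``iucn_trend``).
2. Unknown trend but a threatened category (NT/VU/EN/CR) -> declining
   (provenance ``category_rule``). The rule is justified empirically: among
   threatened species whose trend *is* known, the overwhelming majority are
   decreasing (see :func:`category_trend_concordance`).
3. Otherwise a literature-derived trend, if any (provenance ``literature``).
4. Otherwise unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .types import (
    DielNiche,
    IucnCategory,
    IucnTrend,
    LiteratureTrend,
    SpeciesRecord,
    THREATENED_CATEGORIES,
    ThreatCategory,
    TrendClass,
    TrendProvenance,
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, the convention used for reported percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FilterLog:
    n_input: int = 0
    n_marine: int = 0
    n_fossorial: int = 0
    n_excluded: int = 0
    n_retained: int = 0


def filter_analysis_set(
    records: Sequence[SpeciesRecord],
) -> tuple[list[SpeciesRecord], FilterLog]:
    """Drop marine and highly/fully fossorial species (different light cues).

    Counts are logged per reason; a species carrying both flags is counted
    under both but excluded once.
    """
    log = FilterLog(n_input=len(records))
    kept: list[SpeciesRecord] = []
    for r in records:
        if r.is_marine:
            log.n_marine += 1
        if r.is_fossorial:
            log.n_fossorial += 1
        if r.is_marine or r.is_fossorial:
            log.n_excluded += 1
        else:
            kept.append(r)
    log.n_retained = len(kept)
    return kept, log


def assign_trend(
    iucn_trend_raw: IucnTrend,
    iucn_category: IucnCategory,
    literature_trend: LiteratureTrend,
) -> tuple[TrendClass, TrendProvenance]:
    if iucn_trend_raw is IucnTrend.DECREASING:
        return TrendClass.DECLINING, TrendProvenance.IUCN_TREND
    if iucn_trend_raw in (IucnTrend.STABLE, IucnTrend.INCREASING):
        return TrendClass.NON_DECLINING, TrendProvenance.IUCN_TREND
    # trend unknown from here on
    if iucn_category in THREATENED_CATEGORIES:
        return TrendClass.DECLINING, TrendProvenance.CATEGORY_RULE
    if literature_trend is LiteratureTrend.DECLINING:
        return TrendClass.DECLINING, TrendProvenance.LITERATURE
    if literature_trend is LiteratureTrend.NON_DECLINING:
        return TrendClass.NON_DECLINING, TrendProvenance.LITERATURE
    return TrendClass.UNCLASSIFIED, TrendProvenance.NONE


def assign_trends(records: Sequence[SpeciesRecord]) -> list[SpeciesRecord]:
    out = []
    for r in records:
        cls, prov = assign_trend(r.iucn_trend_raw, r.iucn_category, r.literature_trend)
        out.append(r.copy(trend_class=cls, trend_provenance=prov))
    return out


def category_trend_concordance(records: Sequence[SpeciesRecord]) -> Optional[float]:
    """Among threatened-category species with a *known* IUCN trend, the
    fraction decreasing. Returns None (undefined) on an empty denominator.

    This is the empirical justification for the category rule; on the study
    data it exceeds 0.91.
    """
    denom = [
        r
        for r in records
        if r.iucn_category in THREATENED_CATEGORIES and r.iucn_trend_raw is not IucnTrend.UNKNOWN
    ]
    if not denom:
        return None
    n_dec = sum(r.iucn_trend_raw is IucnTrend.DECREASING for r in denom)
    return n_dec / len(denom)


def build_threat_sets(
    records: Sequence[SpeciesRecord],
    threat_columns: Sequence[dict[ThreatCategory, Optional[int]]],
) -> list[SpeciesRecord]:
    """Populate threat sets from per-category 0/1/None columns.

    All-None means the knowledge state is missing (``threats_known=False``);
    a mix of None and 0/1 for one species is rejected as ambiguous.
    """
    if len(records) != len(threat_columns):
        raise ValueError("one threat-column mapping required per record")
    out = []
    for r, cols in zip(records, threat_columns):
        vals = [cols.get(t) for t in ThreatCategory]
        n_na = sum(v is None for v in vals)
        if 0 < n_na < len(vals):
            raise ValueError(f"{r.species_id}: mixed missing/non-missing threat columns")
        if n_na == len(vals):
            out.append(r.copy(threats=frozenset(), threats_known=False))
        else:
            threats = frozenset(t for t in ThreatCategory if cols.get(t) == 1)
            out.append(r.copy(threats=threats, threats_known=True))
    return out


def count_threats(record: SpeciesRecord) -> int:
    if not record.threats_known:
        raise ValueError(f"{record.species_id}: threats unknown; exclude upstream")
    return len(record.threats)


@dataclass
class ProvenanceSummary:
    counts: dict[TrendProvenance, int] = field(default_factory=dict)
    unclassified_by_category: dict[IucnCategory, int] = field(default_factory=dict)
    n_total: int = 0

    @property
    def n_unclassified(self) -> int:
        return self.counts.get(TrendProvenance.NONE, 0)


def trend_provenance_summary(records: Sequence[SpeciesRecord]) -> ProvenanceSummary:
    """Partition counts by trend provenance; unclassified split by category.

    The partition always sums exactly to the number of records.
    """
    s = ProvenanceSummary(n_total=len(records))
    for p in TrendProvenance:
        s.counts[p] = 0
    for r in records:
        s.counts[r.trend_provenance] += 1
        if r.trend_class is TrendClass.UNCLASSIFIED:
            s.unclassified_by_category[r.iucn_category] = (
                s.unclassified_by_category.get(r.iucn_category, 0) + 1
            )
    assert sum(s.counts.values()) == s.n_total
    return s


@dataclass
class NicheDeclineRow:
    niche: DielNiche
    n_total: int
    n_declining: int
    percent: Optional[float]  # None when the niche is empty


def niche_decline_table(records: Sequence[SpeciesRecord]) -> list[NicheDeclineRow]:
    """Per-niche decline counts and percentages.

    The denominator is every species in the niche; unclassified-trend species
    count in the denominator only. Percentages are half-up rounded to one
    decimal, the convention used in reporting.
    """
    rows = []
    for niche in DielNiche:
        members = [r for r in records if r.diel_niche is niche]
        n_dec = sum(r.trend_class is TrendClass.DECLINING for r in members)
        pct = round_half_up(100.0 * n_dec / len(members)) if members else None
        rows.append(NicheDeclineRow(niche, len(members), n_dec, pct))
    return rows


def megafauna_niche_fraction(
    records: Sequence[SpeciesRecord], mass_threshold_kg: float
) -> tuple[dict[DielNiche, Optional[float]], int, int]:
    """Composition of the heavy-bodied fauna by niche.

    Returns (per-niche fraction among species above the mass threshold,
    number of heavy species, number skipped for missing mass). Fractions are
    None when no species exceeds the threshold.
    """
    n_missing = sum(r.body_mass_kg is None for r in records)
    heavy = [r for r in records if r.body_mass_kg is not None and r.body_mass_kg > mass_threshold_kg]
    fracs: dict[DielNiche, Optional[float]] = {}
    for niche in DielNiche:
        if not heavy:
            fracs[niche] = None
        else:
            fracs[niche] = sum(r.diel_niche is niche for r in heavy) / len(heavy)
    return fracs, len(heavy), n_missing


def unknown_threat_percentage(records: Sequence[SpeciesRecord]) -> Optional[float]:
    """Percentage of declining species whose threats remain unknown,
    half-up rounded to one decimal. None when there are no decliners."""
    decliners = [r for r in records if r.trend_class is TrendClass.DECLINING]
    if not decliners:
        return None
    n_unknown = sum(not r.threats_known for r in decliners)
    return round_half_up(100.0 * n_unknown / len(decliners))
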