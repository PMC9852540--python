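import numpy as np
import pytest

from dieldecline.classify import assign_trends
from dieldecline.io import read_raster
from dieldecline.spatial import (
    LOW_RICHNESS_CUTOFF,
    MaskReason,
    decline_proportion_raster,
    richness_raster,
    write_decline_maps,
)
from dieldecline.types import (
    DielNiche,
    GridSpec,
    RangeStack,
    SpeciesRecord,
    ThreatCategory,
    TrendClass,
    TrendProvenance,
)


def small_grid(n=4):
    return GridSpec("EPSG:6933", 1.0, 0.0, 0.0, float(n), float(n), n, n)


def make_records_stack(seed=0, n_species=25, n=6, p_present=0.5):
    rng = np.random.default_rng(seed)
    grid = small_grid(n)
    records, presence = [], []
    for i in range(n_species):
        niche = DielNiche(list(DielNiche)[rng.integers(4)])
        declining = bool(rng.random() < 0.5)
        threats = frozenset(
            t for t in ThreatCategory if rng.random() < 0.4
        )
        records.append(
            SpeciesRecord(
                species_id=f"sp{i:03d}", diel_niche=niche,
                trend_class=TrendClass.DECLINING if declining else TrendClass.NON_DECLINING,
                trend_provenance=TrendProvenance.IUCN_TREND,
                threats=threats, threats_known=True,
            )
        )
        presence.append(rng.random(grid.n_cells) < p_present)
    return records, RangeStack(grid, [r.species_id for r in records], np.array(presence))


def proportion_bruteforce(stack, records, niche, threat, overrides, country, mask_mode):
    """Per-pixel recount with explicit loops."""
    by_id = {r.species_id: r for r in records}
    nr, nc = stack.grid.shape
    prop = np.full((nr, nc), np.nan)
    mask = np.zeros((nr, nc), dtype=int)
    for r in range(nr):
        for c in range(nc):
            cell = r * nc + c
            denom = numer = 0
            for i, sid in enumerate(stack.species_ids):
                rec = by_id[sid]
                if rec.diel_niche is not niche or not stack.presence[i, cell]:
                    continue
                denom += 1
                if (
                    rec.trend_class is TrendClass.DECLINING
                    and rec.threats_known
                    and threat in rec.threats
                    and not (country is not None and (sid, str(country[r, c])) in overrides)
                ):
                    numer += 1
            if denom == 0:
                mask[r, c] = int(MaskReason.NO_SPECIES)
            elif (numer if mask_mode == "decliners" else denom) <= LOW_RICHNESS_CUTOFF:
                mask[r, c] = int(MaskReason.LOW_RICHNESS)
            else:
                prop[r, c] = numer / denom
    return prop, mask


class TestRichness:
    def test_single_species_single_cell(self):
        grid = small_grid(3)
        presence = np.zeros((1, 9), dtype=bool)
        presence[0, 4] = True
        rec = SpeciesRecord(species_id="a", diel_niche=DielNiche.DIURNAL)
        counts, mask = richness_raster(RangeStack(grid, ["a"], presence), [rec], DielNiche.DIURNAL)
        assert counts[1, 1] == 1 and counts.sum() == 1
        assert mask[1, 1] == MaskReason.NONE and mask[0, 0] == MaskReason.NO_SPECIES

    def test_additive_disjoint_ranges(self):
        grid = small_grid(2)
        presence = np.array([[True, False, False, False], [False, True, False, False]])
        recs = [SpeciesRecord(species_id=s, diel_niche=DielNiche.NOCTURNAL) for s in ("a", "b")]
        counts, _ = richness_raster(RangeStack(grid, ["a", "b"], presence), recs, DielNiche.NOCTURNAL)
        assert counts.sum() == 2 and counts.max() == 1

    def test_matches_bruteforce(self):
        records, stack = make_records_stack(seed=3, n_species=20)
        for niche in DielNiche:
            counts, _ = richness_raster(stack, records, niche)
            by_id = {r.species_id: r for r in records}
            expected = np.zeros(stack.grid.n_cells, dtype=int)
            for cell in range(stack.grid.n_cells):
                expected[cell] = sum(
                    stack.presence[i, cell] and by_id[s].diel_niche is niche
                    for i, s in enumerate(stack.species_ids)
                )
            assert np.array_equal(counts.reshape(-1), expected)

    def test_unknown_species_rejected(self):
        records, stack = make_records_stack()
        with pytest.raises(ValueError, match="absent"):
            richness_raster(stack, records[:-1], DielNiche.DIURNAL)


class TestDeclineProportion:
    @pytest.mark.parametrize("mask_mode", ["richness", "decliners"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_with_overrides(self, seed, mask_mode):
        records, stack = make_records_stack(seed=seed, n_species=30, p_present=0.6)
        nr, nc = stack.grid.shape
        country = np.where(np.arange(nc)[None, :].repeat(nr, 0) < nc // 2, "C1", "C2")
        overrides = {(records[0].species_id, "C1"), (records[3].species_id, "C2")}
        for niche in (DielNiche.NOCTURNAL, DielNiche.DIURNAL):
            for threat in (ThreatCategory.HABITAT_LOSS, ThreatCategory.HARVESTING):
                layer = decline_proportion_raster(
                    stack, records, niche, threat, overrides, country, mask_mode
                )
                prop_o, mask_o = proportion_bruteforce(
                    stack, records, niche, threat, overrides, country, mask_mode
                )
                assert np.array_equal(layer.mask_reason.astype(int), mask_o)
                both = ~np.isnan(prop_o)
                assert np.allclose(layer.proportion[both], prop_o[both])
                assert np.isnan(layer.proportion[~both]).all()

    def test_simple_fraction_and_mask_boundary(self):
        grid = small_grid(1)
        n_sp = 10
        records = []
        presence = np.ones((n_sp, 1), dtype=bool)
        for i in range(n_sp):
            declining = i < 4
            records.append(
                SpeciesRecord(
                    species_id=f"s{i}", diel_niche=DielNiche.DIURNAL,
                    trend_class=TrendClass.DECLINING if declining else TrendClass.NON_DECLINING,
                    trend_provenance=TrendProvenance.IUCN_TREND,
                    threats=frozenset({ThreatCategory.HARVESTING}) if declining else frozenset(),
                    threats_known=True,
                )
            )
        stack = RangeStack(grid, [r.species_id for r in records], presence)
        layer = decline_proportion_raster(stack, records, DielNiche.DIURNAL,
                                          ThreatCategory.HARVESTING)
        assert layer.proportion[0, 0] == pytest.approx(0.4)
        # exactly 5 species in the niche -> masked low_richness in default mode
        stack5 = RangeStack(grid, [r.species_id for r in records[:5]], presence[:5])
        layer5 = decline_proportion_raster(stack5, records[:5], DielNiche.DIURNAL,
                                           ThreatCategory.HARVESTING)
        assert layer5.mask_reason[0, 0] == MaskReason.LOW_RICHNESS
        assert np.isnan(layer5.proportion[0, 0])

    def test_override_reduces_numerator_only(self):
        records, stack = make_records_stack(seed=7, n_species=40, p_present=0.9)
        country = np.full(stack.grid.shape, "C1")
        # pick a decliner with habitat_loss
        target = next(
            r for r in records
            if r.trend_class is TrendClass.DECLINING and ThreatCategory.HABITAT_LOSS in r.threats
        )
        base = decline_proportion_raster(stack, records, target.diel_niche,
                                         ThreatCategory.HABITAT_LOSS, set(), country)
        over = decline_proportion_raster(stack, records, target.diel_niche,
                                         ThreatCategory.HABITAT_LOSS,
                                         {(target.species_id, "C1")}, country)
        i = stack.species_ids.index(target.species_id)
        present = stack.presence[i].reshape(stack.grid.shape)
        assert np.array_equal(base.denominator, over.denominator)
        assert np.array_equal(base.numerator - over.numerator, present.astype(int))

    def test_invariants(self):
        records, stack = make_records_stack(seed=5, n_species=35, p_present=0.7)
        layer = decline_proportion_raster(stack, records, DielNiche.NOCTURNAL,
                                          ThreatCategory.HABITAT_LOSS)
        ok = layer.mask_reason == MaskReason.NONE
        assert np.all(layer.proportion[ok] >= 0) and np.all(layer.proportion[ok] <= 1)
        # proportion * denominator is an integer count
        prod = layer.proportion[ok] * layer.denominator[ok]
        assert np.allclose(prod, np.round(prod), atol=1e-9)
        assert np.all(layer.numerator <= layer.denominator)

    def test_unknown_override_species_rejected(self):
        records, stack = make_records_stack()
        country = np.full(stack.grid.shape, "C1")
        with pytest.raises(ValueError, match="not in stack"):
            decline_proportion_raster(stack, records, DielNiche.DIURNAL,
                                      ThreatCategory.HARVESTING,
                                      {("ghost", "C1")}, country)


class TestWriteMaps:
    def test_round_trip_and_nodata(self, tmp_path):
        records, stack = make_records_stack(seed=2, n_species=30, p_present=0.8)
        layer = decline_proportion_raster(stack, records, DielNiche.NOCTURNAL,
                                          ThreatCategory.HABITAT_LOSS)
        (p,) = write_decline_maps([layer], tmp_path)
        arr, grid, meta = read_raster(p)
        assert grid == stack.grid
        masked = layer.mask_reason != MaskReason.NONE
        assert np.all(arr[masked] == meta["nodata"])
        assert np.allclose(arr[~masked], layer.proportion[~masked], atol=1e-6)
        # companion mask band
        mask_arr, _, _ = read_raster(p.with_name(p.stem + "_mask.tif"))
        assert np.array_equal(mask_arr, layer.mask_reason)

    def test_deterministic_bytes(self, tmp_path):
        records, stack = make_records_stack(seed=2, n_species=30, p_present=0.8)
        layer = decline_proportion_raster(stack, records, DielNiche.NOCTURNAL,
                                          ThreatCategory.HABITAT_LOSS)
        (p1,) = write_decline_maps([layer], tmp_path / "a")
        (p2,) = write_decline_maps([layer], tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()
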