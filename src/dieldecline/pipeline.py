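"""Config-driven pipeline: classify -> fit -> sensitivity -> map, plus the
summary tables. Each stage writes its outputs and a manifest with the audit
trail of counts (excluded marine/fossorial, imputed niches, unclassified
trends, decliners) so every reported number is recomputable from files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify as cls
from . import io as dio
from . import spatial
from .ensemble import run_sensitivity, run_study, select_threat_models, summaries_to_frame
from .phylo import fit_mk, impute_tips
from .types import (
    DielNiche,
    SpeciesRecord,
    ThreatCategory,
    TreeEnsemble,
    TrendClass,
    normalize_label,
)

log = logging.getLogger("dieldecline")


def classify_stage(
    records: Sequence[SpeciesRecord],
    ensemble: Optional[TreeEnsemble] = None,
    impute: bool = True,
) -> tuple[list[SpeciesRecord], dict]:
    """Filter the analysis set, assign trends, and Mk-impute missing niches.

    Imputation uses an equal-rates Mk fit on the first ensemble tree over
    the observed niches; imputed species are flagged (and later excluded
    from every regression).
    """
    kept, flog = cls.filter_analysis_set(records)
    kept = cls.assign_trends(kept)
    n_missing = sum(r.diel_niche is None for r in kept)
    n_ties = 0
    if impute and n_missing and ensemble is not None:
        tree = ensemble.trees[0]
        tips_on_tree = {normalize_label(lf.taxon.label) for lf in tree.leaf_node_iter()}
        observed = {
            r.species_id: (r.diel_niche.value if r.diel_niche is not None else None)
            for r in kept
            if r.species_id in tips_on_tree
        }
        mk = fit_mk(tree, observed, model="equal_rates")
        assigned, ties = impute_tips(mk)
        n_ties = len(ties)
        kept = [
            r.copy(diel_niche=DielNiche(assigned[r.species_id]), niche_imputed=True)
            if r.diel_niche is None and r.species_id in assigned
            else r
            for r in kept
        ]
    prov = cls.trend_provenance_summary(kept)
    manifest = {
        "n_input": flog.n_input,
        "n_marine": flog.n_marine,
        "n_fossorial": flog.n_fossorial,
        "n_excluded": flog.n_excluded,
        "n_retained": flog.n_retained,
        "n_niche_missing": n_missing,
        "n_niche_imputed": sum(r.niche_imputed for r in kept),
        "n_imputation_ties": n_ties,
        "trend_provenance": {p.value: c for p, c in prov.counts.items()},
        "n_declining": sum(r.trend_class is TrendClass.DECLINING for r in kept),
        "n_unclassified": prov.n_unclassified,
        "n_regression": sum(
            r.diel_niche is not None and not r.niche_imputed for r in kept
        ),
    }
    return kept, manifest


def report_tables(records: Sequence[SpeciesRecord], summaries=None) -> dict[str, pd.DataFrame]:
    """Paper-shaped summary tables.

    ``decline_by_niche``: per-niche decline percentages; ``threat_counts``:
    distribution of the number of threats among decliners per niche;
    ``threat_by_niche``: per-threat decline percentage among decliners per
    niche, with tier annotations when fitted summaries are supplied.
    """
    rows = cls.niche_decline_table(records)
    fig1a = pd.DataFrame(
        [
            {"niche": r.niche.value, "n_total": r.n_total, "n_declining": r.n_declining,
             "percent_declining": r.percent}
            for r in rows
        ]
    )

    decliners = [r for r in records if r.trend_class is TrendClass.DECLINING and r.threats_known]
    tc_rows = []
    for niche in DielNiche:
        members = [r for r in decliners if r.diel_niche is niche]
        counts = pd.Series([len(r.threats) for r in members])
        total = len(members)
        for k in range(0, 11):
            n_k = int((counts == k).sum())
            if n_k or k <= 4:
                tc_rows.append(
                    {"niche": niche.value, "n_threats": k, "n_species": n_k,
                     "proportion": cls.round_half_up(100.0 * n_k / total) / 100 if total else None}
                )
    fig1b = pd.DataFrame(tc_rows)

    tiers = {}
    if summaries:
        for s in summaries:
            if s.model_id.startswith("decline_from_"):
                threat = s.model_id.removeprefix("decline_from_")
                tiers[threat] = {t: s.terms[t].tier for t in s.terms}
    tb_rows = []
    for threat in ThreatCategory:
        for niche in DielNiche:
            members = [r for r in decliners if r.diel_niche is niche]
            n_t = sum(threat in r.threats for r in members)
            pct = cls.round_half_up(100.0 * n_t / len(members)) if members else None
            term = niche.value if niche is not DielNiche.NOCTURNAL else "intercept"
            tb_rows.append(
                {"threat": threat.value, "niche": niche.value, "n_declining": len(members),
                 "n_declining_from_threat": n_t, "percent": pct,
                 "tier": tiers.get(threat.value, {}).get(term, "")}
            )
    fig2a = pd.DataFrame(tb_rows)
    return {"decline_by_niche": fig1a, "threat_counts": fig1b, "threat_by_niche": fig2a}


def map_stage(
    stack, records, overrides, country_raster, outdir: Path, mask_mode: str = "richness",
    niches: Optional[Sequence[DielNiche]] = None,
) -> list[Path]:
    """Richness and proportional-decline layers for the selected threats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    niches = list(niches) if niches is not None else spatial.default_report_niches()
    decliners = [r for r in records if r.trend_class is TrendClass.DECLINING]
    threats = select_threat_models(decliners) or [ThreatCategory.HABITAT_LOSS]
    paths = []
    for niche in niches:
        counts, mask = spatial.richness_raster(stack, records, niche)
        p = outdir / f"richness_{niche.value}.tif"
        dio.write_raster(counts.astype(np.int32), stack.grid, p)
        paths.append(p)
        layers = [
            spatial.decline_proportion_raster(
                stack, records, niche, threat, overrides, country_raster, mask_mode
            )
            for threat in threats
        ]
        paths.extend(spatial.write_decline_maps(layers, outdir))
    return paths


def run_pipeline(config: dict, outdir: str | Path) -> Path:
    """Run classify -> fit -> sensitivity -> map -> report from a config.

    Config keys: ``species_table``, ``trees`` (path or list), ``ranges``
    (directory of per-species rasters, optional), ``overrides`` (CSV,
    optional), ``country_raster`` (TIFF, optional), ``b``, ``seed``,
    ``unclassified_mode``, ``mask_mode``, ``variants`` (list).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    b = int(config.get("b", 100))
    mode = config.get("unclassified_mode", "code_zero")

    records = dio.read_species_table(config["species_table"])
    ensemble = dio.read_tree_ensemble(config["trees"])
    records, manifest = classify_stage(records, ensemble)
    manifest.update({"seed": seed, "B": b, "unclassified_mode": mode})
    dio.write_species_table(records, outdir / "species_classified.csv")

    log.info("classify: %s", manifest)
    summaries = run_study(records, ensemble, b=b, seed=seed, unclassified_mode=mode)
    summaries_to_frame(summaries).to_csv(outdir / "fits.csv", index=False)

    sens_frames = []
    for variant in config.get("variants", []):
        sens = run_sensitivity(records, ensemble, variant, b=b, seed=seed, unclassified_mode=mode)
        sens_frames.append(summaries_to_frame(sens))
    if sens_frames:
        pd.concat(sens_frames, ignore_index=True).to_csv(outdir / "sensitivity.csv", index=False)

    if config.get("ranges"):
        rdir = Path(config["ranges"])
        paths = {p.stem: p for p in sorted(rdir.glob("*.tif"))}
        paths = {sid: p for sid, p in paths.items() if any(r.species_id == sid for r in records)}
        grid = dio.read_raster(next(iter(paths.values())))[1]
        stack = dio.read_range_stack(paths, grid)
        overrides = (
            dio.read_override_table(config["overrides"]) if config.get("overrides") else set()
        )
        country = None
        if config.get("country_raster"):
            country = dio.read_raster(config["country_raster"])[0].astype(str)
        map_stage(stack, records, overrides, country, outdir / "maps",
                  mask_mode=config.get("mask_mode", "richness"))

    tables = report_tables(records, summaries)
    for name, df in tables.items():
        df.to_csv(outdir / f"report_{name}.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
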