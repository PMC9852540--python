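"""Run each model specification across a sampled tree ensemble and aggregate
per-tree fits into robustness-tiered summaries.

Each model is refitted once per sampled tree; reported are the mean and
sample SD (n-1 denominator) of per-tree coefficients, the fraction of
(converged) repetitions with p < 0.01, a tier symbol derived from that
fraction, and the mean pseudo-R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .phylo import FitResult, fit_phylo_logistic, fit_phylo_poisson_gee, niche_design
from .types import (
    DielNiche,
    IucnCategory,
    SpeciesRecord,
    ThreatCategory,
    TreeEnsemble,
    TrendClass,
    TrendProvenance,
)

P_THRESHOLD = 0.01
MIN_DECLINERS_PER_THREAT = 50


@dataclass
class ModelSpec:
    model_id: str
    family: str  # "logistic_mple" | "poisson_gee"
    response: str  # "declining" | "n_threats" | "declining_from:<threat>"
    subset: Optional[Callable[[SpeciesRecord], bool]] = None
    unclassified_mode: str = "code_zero"  # or "drop"


@dataclass
class TermSummary:
    term: str
    mean_coef: float
    sd_coef: float
    frac_p_lt_001: float
    tier: str


@dataclass
class EnsembleSummary:
    model_id: str
    terms: dict[str, TermSummary] = field(default_factory=dict)
    mean_pseudo_R2: float = np.nan
    B_used: int = 0
    n_converged: int = 0
    n_obs: int = 0
    unreliable: bool = False
    empty: bool = False
    message: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model_id": self.model_id,
                "term": t.term,
                "mean_coef": t.mean_coef,
                "sd_coef": t.sd_coef,
                "frac_p_lt_001": t.frac_p_lt_001,
                "tier": t.tier,
                "mean_pseudo_R2": self.mean_pseudo_R2,
                "n_obs": self.n_obs,
                "B_used": self.B_used,
                "n_converged": self.n_converged,
                "unreliable": self.unreliable,
            }
            for t in self.terms.values()
        ]
        return pd.DataFrame(rows)


def tier(frac_p_lt_001: float) -> str:
    """Robustness tier from the fraction of repetitions with p < 0.01.

    >= 0.90 -> '###'; [0.75, 0.90) -> '##'; [0.60, 0.75) -> '#'; else ''.
    """
    if not 0.0 <= frac_p_lt_001 <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if frac_p_lt_001 >= 0.90:
        return "###"
    if frac_p_lt_001 >= 0.75:
        return "##"
    if frac_p_lt_001 >= 0.60:
        return "#"
    return ""


def select_threat_models(decliners: Sequence[SpeciesRecord]) -> list[ThreatCategory]:
    """Threats affecting at least MIN_DECLINERS_PER_THREAT declining species,
    in the fixed category order."""
    counts = {t: 0 for t in ThreatCategory}
    for r in decliners:
        if r.threats_known:
            for t in r.threats:
                counts[t] += 1
    return [t for t in ThreatCategory if counts[t] >= MIN_DECLINERS_PER_THREAT]


def _analysis_records(records: Sequence[SpeciesRecord], spec: ModelSpec) -> list[SpeciesRecord]:
    """Apply the shared exclusions plus the spec's subset and response filters."""
    out = []
    for r in records:
        if r.diel_niche is None or r.niche_imputed:
            continue  # imputed niches are excluded from all regressions
        if spec.subset is not None and not spec.subset(r):
            continue
        out.append(r)
    if spec.response == "declining":
        if spec.unclassified_mode == "drop":
            out = [r for r in out if r.trend_class is not TrendClass.UNCLASSIFIED]
    elif spec.response == "n_threats" or spec.response.startswith("declining_from:"):
        out = [r for r in out if r.trend_class is TrendClass.DECLINING and r.threats_known]
    else:
        raise ValueError(f"unknown response {spec.response!r}")
    return out


def _response_vector(records: Sequence[SpeciesRecord], spec: ModelSpec) -> np.ndarray:
    if spec.response == "declining":
        return np.array([1.0 if r.trend_class is TrendClass.DECLINING else 0.0 for r in records])
    if spec.response == "n_threats":
        return np.array([float(len(r.threats)) for r in records])
    threat = ThreatCategory(spec.response.split(":", 1)[1])
    return np.array([1.0 if threat in r.threats else 0.0 for r in records])


def run_ensemble(
    spec: ModelSpec,
    records: Sequence[SpeciesRecord],
    ensemble: TreeEnsemble,
    b: int = 100,
    seed: int = 0,
) -> EnsembleSummary:
    """Fit one model spec on ``b`` trees sampled without replacement.

    Non-converged or degenerate per-tree fits are dropped from the
    aggregation (their count is reported); fewer than b/2 usable fits flag
    the summary unreliable.
    """
    recs = _analysis_records(records, spec)
    if not recs:
        return EnsembleSummary(spec.model_id, empty=True, message="empty analysis set")
    y = _response_vector(recs, spec)
    # empty niche levels are dropped from the design (singular otherwise)
    X, terms = niche_design([r.diel_niche for r in recs], drop_empty=True)
    tips = [r.species_id for r in recs]
    sampled = ensemble.sample(min(b, len(ensemble)), seed=seed)

    fits: list[FitResult] = []
    n_failed = 0
    cache: dict[str, FitResult] = {}  # identical trees get identical fits
    for tree in sampled.trees:
        key = tree.as_string(schema="newick")
        if key in cache:
            fit = cache[key]
        elif spec.family == "logistic_mple":
            fit = fit_phylo_logistic(y, X, tree, tips, terms=terms, model_id=spec.model_id)
        elif spec.family == "poisson_gee":
            fit = fit_phylo_poisson_gee(y, X, tree, tips, terms=terms, model_id=spec.model_id)
        else:
            raise ValueError(f"unknown family {spec.family!r}")
        cache[key] = fit
        if fit.converged and not fit.degenerate:
            fits.append(fit)
        else:
            n_failed += 1
    if n_failed:
        warnings.warn(f"{spec.model_id}: {n_failed} of {len(sampled)} per-tree fits dropped")
    return aggregate_fits(spec.model_id, fits, terms, b_used=len(sampled), n_obs=len(recs))


def aggregate_fits(
    model_id: str,
    fits: Sequence[FitResult],
    terms: Sequence[str],
    b_used: int,
    n_obs: int = 0,
) -> EnsembleSummary:
    """Aggregate converged per-tree fits: mean and sample SD (n-1) of each
    coefficient, fraction of repetitions with p < 0.01, tier, mean pseudo-R²."""
    summary = EnsembleSummary(model_id, B_used=b_used, n_converged=len(fits), n_obs=n_obs)
    if not fits:
        summary.empty = True
        summary.message = "no converged fits"
        summary.unreliable = True
        return summary
    coefs = np.array([f.coef_vector() for f in fits])
    pvals = np.array([[f.p_values[t] for t in terms] for f in fits])
    for j, t in enumerate(terms):
        frac = float(np.mean(pvals[:, j] < P_THRESHOLD))
        # identical per-tree fits must give exactly zero spread
        if len(fits) <= 1 or np.ptp(coefs[:, j]) == 0.0:
            sd = 0.0
        else:
            sd = float(np.std(coefs[:, j], ddof=1))
        summary.terms[t] = TermSummary(t, float(np.mean(coefs[:, j])), sd, frac, tier(frac))
    summary.mean_pseudo_R2 = float(np.mean([f.pseudo_R2 for f in fits]))
    summary.unreliable = len(fits) < b_used / 2
    return summary


def study_specs(
    records: Sequence[SpeciesRecord], unclassified_mode: str = "code_zero"
) -> list[ModelSpec]:
    """The three model families: decline ~ niche over the full analysis set;
    threat count ~ niche over decliners; per-threat decline ~ niche over
    decliners, for threats with enough declining species."""
    decliners = [r for r in records if r.trend_class is TrendClass.DECLINING]
    specs = [
        ModelSpec("decline", "logistic_mple", "declining", unclassified_mode=unclassified_mode),
        ModelSpec("n_threats", "poisson_gee", "n_threats"),
    ]
    for t in select_threat_models(decliners):
        specs.append(ModelSpec(f"decline_from_{t.value}", "logistic_mple", f"declining_from:{t.value}"))
    return specs


def run_study(
    records: Sequence[SpeciesRecord],
    ensemble: TreeEnsemble,
    b: int = 100,
    seed: int = 0,
    unclassified_mode: str = "code_zero",
) -> list[EnsembleSummary]:
    return [
        run_ensemble(spec, records, ensemble, b=b, seed=seed)
        for spec in study_specs(records, unclassified_mode)
    ]


VARIANTS = ("primates_only", "non_primates_only", "exclude_literature_trends", "threat_status_recode")


def apply_variant(records: Sequence[SpeciesRecord], variant: str) -> list[SpeciesRecord]:
    """Return the record list transformed for a sensitivity variant."""
    if variant == "primates_only":
        return [r for r in records if r.order == "Primates"]
    if variant == "non_primates_only":
        return [r for r in records if r.order != "Primates"]
    if variant == "exclude_literature_trends":
        return [
            r.copy(trend_class=TrendClass.UNCLASSIFIED, trend_provenance=TrendProvenance.NONE)
            if r.trend_provenance is TrendProvenance.LITERATURE
            else r
            for r in records
        ]
    if variant == "threat_status_recode":
        out = []
        for r in records:
            if r.iucn_category in (IucnCategory.VU, IucnCategory.EN, IucnCategory.CR):
                out.append(r.copy(trend_class=TrendClass.DECLINING,
                                  trend_provenance=TrendProvenance.CATEGORY_RULE))
            elif r.iucn_category in (IucnCategory.LC, IucnCategory.NT):
                out.append(r.copy(trend_class=TrendClass.NON_DECLINING,
                                  trend_provenance=TrendProvenance.CATEGORY_RULE))
            else:  # DD / NE carry no threat status to recode from
                out.append(r.copy(trend_class=TrendClass.UNCLASSIFIED,
                                  trend_provenance=TrendProvenance.NONE))
        return out
    raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")


def run_sensitivity(
    records: Sequence[SpeciesRecord],
    ensemble: TreeEnsemble,
    variant: str,
    b: int = 100,
    seed: int = 0,
    unclassified_mode: str = "code_zero",
) -> list[EnsembleSummary]:
    recs = apply_variant(records, variant)
    if not recs:
        return [EnsembleSummary(f"{variant}:empty", empty=True, message="empty subset")]
    out = run_study(recs, ensemble, b=b, seed=seed, unclassified_mode=unclassified_mode)
    for s in out:
        s.model_id = f"{variant}:{s.model_id}"
    return out


def summaries_to_frame(summaries: Sequence[EnsembleSummary]) -> pd.DataFrame:
    frames = [s.to_frame() for s in summaries if not s.empty]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
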