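"""Synthetic study-shaped inputs with known ground truth.

The generator emulates the statistical structure of the real inputs: a
birth-death phylogeny (rescaled to unit depth), diel niche evolved along it
under an F81-style Mk process with unequal stationary frequencies, decline
status drawn from a niche-dependent logistic model with a Brownian latent
phylogenetic effect, IUCN categories/trends/threat sets drawn consistently
with the downstream classification rules, and small contiguous range blobs
on an equal-area toy grid.

Default parameters mirror the magnitudes of the study system: ~40% of
nocturnal species declining with a +0.5 logit shift for diurnal species,
3% of niches missing, roughly 40% of IUCN trends unknown, and per-threat
rates dominated by habitat loss and harvesting.  Ground truth is returned
alongside the observable table so recovery is testable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath
from scipy.special import expit, logit

from .phylo import build_vcv
from .types import (
    DielNiche,
    GridSpec,
    IucnCategory,
    IucnTrend,
    LiteratureTrend,
    NICHE_ORDER,
    RangeStack,
    SpeciesRecord,
    ThreatCategory,
    TreeEnsemble,
    normalize_label,
)

#: study-like niche frequencies (nocturnal, crepuscular, cathemeral, diurnal)
DEFAULT_NICHE_FREQS = (0.695, 0.022, 0.105, 0.178)

#: logit-scale decline model: intercept (nocturnal base) and niche shifts
DEFAULT_DECLINE_LOGIT = {
    "intercept": float(logit(0.40)),
    DielNiche.CREPUSCULAR: -0.01,
    DielNiche.CATHEMERAL: 0.12,
    DielNiche.DIURNAL: 0.49,
}

#: per-threat probability among declining species, by niche order
#: (nocturnal, crepuscular, cathemeral, diurnal)
DEFAULT_THREAT_RATES = {
    ThreatCategory.HABITAT_LOSS: (0.91, 0.89, 0.88, 0.86),
    ThreatCategory.HARVESTING: (0.25, 0.25, 0.40, 0.52),
    ThreatCategory.CONFLICT: (0.04, 0.04, 0.07, 0.07),
    ThreatCategory.CLIMATE_CHANGE: (0.05, 0.05, 0.07, 0.04),
    ThreatCategory.NON_NATIVE: (0.06, 0.05, 0.03, 0.03),
    ThreatCategory.POLLUTION: (0.02, 0.02, 0.02, 0.02),
    ThreatCategory.HYBRIDIZATION: (0.01, 0.01, 0.01, 0.01),
    ThreatCategory.PREY_DEPLETION: (0.02, 0.02, 0.02, 0.02),
    ThreatCategory.DISEASE: (0.02, 0.02, 0.02, 0.02),
    ThreatCategory.INBREEDING: (0.01, 0.01, 0.01, 0.01),
}

#: probability that a species in a niche is a primate
PRIMATE_FRACTION = {
    DielNiche.NOCTURNAL: 0.033,
    DielNiche.CREPUSCULAR: 0.0,
    DielNiche.CATHEMERAL: 0.040,
    DielNiche.DIURNAL: 0.321,
}

#: natural-log body-mass location by niche (kg); cathemerality dominates megafauna
LOG_MASS_LOC = {
    DielNiche.NOCTURNAL: np.log(0.08),
    DielNiche.CREPUSCULAR: np.log(0.3),
    DielNiche.CATHEMERAL: np.log(5.0),
    DielNiche.DIURNAL: np.log(0.5),
}
LOG_MASS_SCALE = 2.0


def default_grid(nrows: int = 20, ncols: int = 20, cell_size_m: float = 96_500.0) -> GridSpec:
    return GridSpec("EPSG:6933", cell_size_m, 0.0, 0.0,
                    ncols * cell_size_m, nrows * cell_size_m, nrows, ncols)


@dataclass
class SynthConfig:
    """Generative parameters; defaults are the package's study-like conditions."""

    n_species: int = 800
    birth_rate: float = 1.0
    death_rate: float = 0.3
    mk_rate: float = 3.0  # F81 switching rate per unit (depth-normalised) time
    niche_base_freqs: tuple[float, float, float, float] = DEFAULT_NICHE_FREQS
    decline_logit: dict = field(default_factory=lambda: dict(DEFAULT_DECLINE_LOGIT))
    phylo_signal: float = 1.0  # variance of the Brownian latent effect at the tips
    threat_rates: dict = field(default_factory=lambda: dict(DEFAULT_THREAT_RATES))
    nondecliner_threat_scale: float = 0.3
    missing_niche_frac: float = 0.03
    unknown_trend_frac: float = 0.42
    literature_known_frac: float = 0.64  # of unknown-trend, non-rule species
    rule_category_frac: float = 0.07  # unknown-trend decliners given NT-CR
    rule_leak_frac: float = 0.01  # unknown-trend NON-decliners given NT-CR
    unknown_threat_frac: float = 0.013
    marine_frac: float = 0.024
    fossorial_frac: float = 0.047
    grid: GridSpec = field(default_factory=default_grid)
    range_cells_mean: float = 12.0
    n_trees: int = 10
    bl_jitter_sd: float = 0.1
    n_nni: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.niche_base_freqs), 1.0):
            raise ValueError("niche_base_freqs must sum to 1")
        if self.birth_rate <= self.death_rate:
            raise ValueError("birth_rate must exceed death_rate")


def _rngs(config: SynthConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


# ---------------------------------------------------------------------------
# Trees


def sim_tree(config: SynthConfig) -> dendropy.Tree:
    """Birth-death tree conditioned on ``n_species`` extant tips, branch
    lengths rescaled to unit maximum root-to-tip depth, tips labelled
    ``sp0001``..."""
    rng = random.Random(config.seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=config.death_rate,
        num_extant_tips=config.n_species,
        rng=rng,
        repeat_until_success=True,
    )
    leaves = list(tree.leaf_node_iter())
    for i, leaf in enumerate(leaves, start=1):
        leaf.taxon.label = f"sp{i:04d}"
    depth = max(sum(e.length or 0.0 for e in _edges_to_root(nd)) for nd in leaves)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree


def _edges_to_root(node) -> list:
    edges = []
    while node.parent_node is not None:
        edges.append(node.edge)
        node = node.parent_node
    return edges


def sim_ensemble(tree: dendropy.Tree, config: SynthConfig) -> TreeEnsemble:
    """Clone the tree ``n_trees`` times with log-normal branch-length jitter
    and optional nearest-neighbour-interchange moves; tip set preserved."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[3])
    pyrng = random.Random(config.seed + 1)
    trees = []
    for _ in range(config.n_trees):
        t = tree.clone(depth=1)
        if config.bl_jitter_sd > 0:
            for edge in t.preorder_edge_iter():
                if edge.length is not None and edge.length > 0:
                    edge.length *= float(np.exp(rng.normal(0.0, config.bl_jitter_sd)))
        for _ in range(config.n_nni):
            internal = [e for e in t.preorder_edge_iter()
                        if e.head_node and not e.head_node.is_leaf() and e.tail_node is not None]
            if internal:
                edge = pyrng.choice(internal)
                _nni(edge, pyrng)
        trees.append(t)
    return TreeEnsemble(trees, rng_seed=config.seed)


def _nni(edge, pyrng) -> None:
    """Swap one child of the edge's head with one sibling subtree."""
    head, tail = edge.head_node, edge.tail_node
    head_children = head.child_nodes()
    siblings = [c for c in tail.child_nodes() if c is not head]
    if len(head_children) < 2 or not siblings:
        return
    a = pyrng.choice(head_children)
    b = pyrng.choice(siblings)
    head.remove_child(a)
    tail.remove_child(b)
    head.add_child(b)
    tail.add_child(a)


# ---------------------------------------------------------------------------
# Traits, trends, threats


def _sim_mk_f81(tree: dendropy.Tree, rate: float, freqs: np.ndarray, rng) -> dict[str, int]:
    """Evolve a discrete state down the tree under the F81-style Mk process
    (stationary distribution ``freqs``, switching rate ``rate``)."""
    states: dict = {}
    k = len(freqs)
    root = tree.seed_node
    states[root] = int(rng.choice(k, p=freqs))
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent_state = states[node.parent_node]
        if rng.random() < np.exp(-rate * t):
            states[node] = parent_state
        else:
            states[node] = int(rng.choice(k, p=freqs))
    return {
        normalize_label(lf.taxon.label): states[lf] for lf in tree.leaf_node_iter()
    }


def sim_traits_and_trends(
    tree: dendropy.Tree, config: SynthConfig
) -> tuple[list[SpeciesRecord], pd.DataFrame]:
    """Generate the full species table plus a ground-truth sidecar.

    Returns (records with raw observables, truth DataFrame). Records carry
    the *raw* fields only; trend classes come from running
    :mod:`dieldecline.classify` on them.  Wherever trend information is
    emitted as known, the classification rules recover the generated truth.
    """
    (rng_niche, rng_latent, rng_decline, rng_threat,
     rng_miss, rng_misc, rng_mass) = _rngs(config, 7)

    labels, C = build_vcv(tree)
    C = C / np.diag(C).max()
    n = len(labels)
    niche_ix = _sim_mk_f81(tree, config.mk_rate, np.asarray(config.niche_base_freqs), rng_niche)
    niches = {lab: NICHE_ORDER[niche_ix[lab]] for lab in labels}

    if config.phylo_signal > 0:
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
        latent = np.sqrt(config.phylo_signal) * (L @ rng_latent.standard_normal(n))
    else:
        latent = np.zeros(n)

    dl = config.decline_logit
    eta = np.array([
        dl["intercept"] + dl.get(niches[lab], 0.0) + latent[i] for i, lab in enumerate(labels)
    ])
    decline = rng_decline.random(n) < expit(eta)

    records: list[SpeciesRecord] = []
    truth_rows = []
    for i, lab in enumerate(labels):
        niche = niches[lab]
        d = bool(decline[i])

        # threat draws (independent Bernoulli per category)
        scale = 1.0 if d else config.nondecliner_threat_scale
        threats = frozenset(
            t for t, rates in config.threat_rates.items()
            if rng_threat.random() < scale * rates[niche_ix[lab]]
        )
        threats_known = not (rng_threat.random() < config.unknown_threat_frac)

        # IUCN trend / category / literature trend, consistent with the rules
        trend_known = not (rng_misc.random() < config.unknown_trend_frac)
        literature = LiteratureTrend.UNKNOWN
        truth_recoverable = True
        if trend_known:
            if d:
                iucn_trend = IucnTrend.DECREASING
            else:
                iucn_trend = IucnTrend.STABLE if rng_misc.random() < 0.8 else IucnTrend.INCREASING
            category = _draw_category(d, rng_misc)
        else:
            iucn_trend = IucnTrend.UNKNOWN
            p_threatened = config.rule_category_frac if d else config.rule_leak_frac
            if rng_misc.random() < p_threatened:
                category = IucnCategory(rng_misc.choice(["NT", "VU", "EN", "CR"]))
                truth_recoverable = d  # the category rule codes these declining
            else:
                category = IucnCategory.LC if rng_misc.random() < 0.7 else IucnCategory.DD
                if rng_misc.random() < config.literature_known_frac:
                    literature = (
                        LiteratureTrend.DECLINING if d else LiteratureTrend.NON_DECLINING
                    )
                else:
                    truth_recoverable = False  # remains unclassified

        missing_niche = rng_miss.random() < config.missing_niche_frac
        mass = float(np.exp(rng_mass.normal(LOG_MASS_LOC[niche], LOG_MASS_SCALE)))
        is_primate = rng_misc.random() < PRIMATE_FRACTION[niche]
        order = "Primates" if is_primate else str(
            rng_misc.choice(["Rodentia", "Chiroptera", "Carnivora", "Artiodactyla"])
        )
        records.append(
            SpeciesRecord(
                species_id=lab,
                binomial=f"Genus {lab}",
                order=order,
                diel_niche=None if missing_niche else niche,
                iucn_category=category,
                iucn_trend_raw=iucn_trend,
                literature_trend=literature,
                threats=threats if threats_known else frozenset(),
                threats_known=threats_known,
                is_marine=bool(rng_misc.random() < config.marine_frac),
                is_fossorial=bool(rng_misc.random() < config.fossorial_frac),
                body_mass_kg=mass,
            )
        )
        truth_rows.append(
            {
                "species_id": lab,
                "true_niche": niche.value,
                "true_decline": d,
                "latent_effect": latent[i],
                "decline_prob": float(expit(eta[i])),
                "niche_missing": missing_niche,
                "trend_known": trend_known,
                "truth_recoverable": truth_recoverable,
                "n_threats_true": len(threats),
            }
        )
    return records, pd.DataFrame(truth_rows)


def _draw_category(declining: bool, rng) -> IucnCategory:
    if declining:
        cats, probs = ["LC", "NT", "VU", "EN", "CR", "DD"], [0.35, 0.15, 0.20, 0.15, 0.10, 0.05]
    else:
        cats, probs = ["LC", "NT", "VU", "EN", "CR", "DD"], [0.80, 0.10, 0.03, 0.01, 0.01, 0.05]
    return IucnCategory(rng.choice(cats, p=probs))


# ---------------------------------------------------------------------------
# Ranges


def sim_ranges(records: Sequence[SpeciesRecord], config: SynthConfig) -> RangeStack:
    """One contiguous random blob per species with Poisson(range_cells_mean)
    cells (at least one), grown by seeded neighbour accretion."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(9)[8])
    grid = config.grid
    nr, nc = grid.shape
    presence = np.zeros((len(records), grid.n_cells), dtype=bool)
    for i, rec in enumerate(records):
        target = max(1, int(rng.poisson(config.range_cells_mean)))
        target = min(target, grid.n_cells)
        start = (int(rng.integers(nr)), int(rng.integers(nc)))
        blob = {start}
        frontier = [start]
        while len(blob) < target and frontier:
            r, c = frontier[int(rng.integers(len(frontier)))]
            nbrs = [(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                    if 0 <= r + dr < nr and 0 <= c + dc < nc and (r + dr, c + dc) not in blob]
            if not nbrs:
                frontier.remove((r, c))
                continue
            cell = nbrs[int(rng.integers(len(nbrs)))]
            blob.add(cell)
            frontier.append(cell)
        for r, c in blob:
            presence[i, r * nc + c] = True
    return RangeStack(grid, [r.species_id for r in records], presence)


def sim_country_raster(config: SynthConfig, n_countries: int = 4) -> np.ndarray:
    """Vertical-band toy country raster with codes 'C1'..'Cn'."""
    nr, nc = config.grid.shape
    bands = np.array_split(np.arange(nc), n_countries)
    out = np.empty((nr, nc), dtype=object)
    for i, cols in enumerate(bands, start=1):
        out[:, cols] = f"C{i}"
    return out.astype(str)


def sim_overrides(
    records: Sequence[SpeciesRecord],
    stack: RangeStack,
    country_raster: np.ndarray,
    config: SynthConfig,
    n_overrides: int = 5,
) -> set[tuple[str, str]]:
    """A few (species, country) pairs where a declining species is marked
    non-declining, each chosen so the species is present in that country."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(11)[10])
    country_flat = country_raster.reshape(-1).astype(str)
    candidates = []
    for i, sid in enumerate(stack.species_ids):
        present_countries = sorted(set(country_flat[stack.presence[i]]))
        for c in present_countries:
            candidates.append((sid, c))
    if not candidates:
        return set()
    idx = rng.choice(len(candidates), size=min(n_overrides, len(candidates)), replace=False)
    return {candidates[i] for i in idx}


def simulate_bundle(config: SynthConfig):
    """Full input bundle: (records, truth frame, tree, ensemble, range stack,
    country raster, overrides)."""
    tree = sim_tree(config)
    ensemble = sim_ensemble(tree, config)
    records, truth = sim_traits_and_trends(tree, config)
    stack = sim_ranges(records, config)
    countries = sim_country_raster(config)
    overrides = sim_overrides(records, stack, countries, config)
    return records, truth, tree, ensemble, stack, countries, overrides
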