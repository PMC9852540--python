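"""Readers and writers for the formats every stage touches.

* species tables: UTF-8 CSV with one threat column per category (0/1/empty,
  empty meaning the knowledge state is missing);
* trees: Newick or Nexus, single- or multi-tree, via dendropy;
* presence/proportion rasters: single-band TIFF with the grid geometry
  serialised as JSON in the ImageDescription tag;
* override tables and run configs.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    DielNiche,
    GridSpec,
    IucnCategory,
    IucnTrend,
    LiteratureTrend,
    RangeStack,
    SpeciesRecord,
    ThreatCategory,
    TreeEnsemble,
    TrendClass,
    TrendProvenance,
    normalize_label,
    validate_table,
)

THREAT_COLUMNS = {t: f"threat_{t.value}" for t in ThreatCategory}

SPECIES_COLUMNS = [
    "species_id",
    "binomial",
    "order",
    "diel_niche",
    "iucn_category",
    "iucn_trend",
    "literature_trend",
    "is_marine",
    "is_fossorial",
    "body_mass_kg",
    *THREAT_COLUMNS.values(),
]

#: derived columns carried by classified outputs; optional on read
DERIVED_COLUMNS = ["niche_imputed", "trend_class", "trend_provenance"]


def _parse_enum(enum_cls, token: str, row: int, col: str):
    try:
        return enum_cls(token)
    except ValueError:
        raise ValueError(f"row {row}: unknown {col} token {token!r}") from None


def read_species_table(path: str | os.PathLike) -> list[SpeciesRecord]:
    """Read a species CSV into validated records.

    Missing values are empty fields: an empty ``diel_niche`` marks a species
    for downstream imputation; threat columns all empty mark the threat
    knowledge state itself as missing (``threats_known=False``).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"species table missing columns: {missing_cols}")

    records: list[SpeciesRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        niche = d["diel_niche"].strip()
        mass = d["body_mass_kg"].strip()
        threat_vals = {t: d[col].strip() for t, col in THREAT_COLUMNS.items()}
        n_na = sum(v == "" for v in threat_vals.values())
        if 0 < n_na < len(threat_vals):
            raise ValueError(
                f"row {i} ({d['species_id']}): mixed missing/non-missing threat "
                "columns (ambiguous knowledge state)"
            )
        threats_known = n_na == 0
        threats = frozenset(t for t, v in threat_vals.items() if threats_known and v == "1")
        if threats_known:
            bad = {t.value: v for t, v in threat_vals.items() if v not in ("0", "1")}
            if bad:
                raise ValueError(f"row {i}: non-binary threat values {bad}")

        derived = {}
        if "niche_imputed" in d:
            derived["niche_imputed"] = d["niche_imputed"].strip() == "1"
        if "trend_class" in d and d["trend_class"].strip():
            derived["trend_class"] = _parse_enum(TrendClass, d["trend_class"].strip(), i, "trend_class")
        if "trend_provenance" in d and d["trend_provenance"].strip():
            derived["trend_provenance"] = _parse_enum(
                TrendProvenance, d["trend_provenance"].strip(), i, "trend_provenance"
            )
        rec = SpeciesRecord(
            species_id=d["species_id"].strip(),
            binomial=d["binomial"].strip(),
            order=d["order"].strip(),
            diel_niche=None if niche == "" else _parse_enum(DielNiche, niche, i, "diel_niche"),
            iucn_category=_parse_enum(IucnCategory, d["iucn_category"].strip(), i, "iucn_category"),
            iucn_trend_raw=_parse_enum(IucnTrend, d["iucn_trend"].strip() or "unknown", i, "iucn_trend"),
            literature_trend=_parse_enum(
                LiteratureTrend, d["literature_trend"].strip() or "unknown", i, "literature_trend"
            ),
            threats=threats,
            threats_known=threats_known,
            is_marine=d["is_marine"].strip() == "1",
            is_fossorial=d["is_fossorial"].strip() == "1",
            body_mass_kg=None if mass == "" else float(mass),
            **derived,
        )
        records.append(rec)
    validate_table(records)
    return records


def write_species_table(records: Sequence[SpeciesRecord], path: str | os.PathLike) -> None:
    rows = []
    for r in records:
        row = {
            "species_id": r.species_id,
            "binomial": r.binomial,
            "order": r.order,
            "diel_niche": "" if r.diel_niche is None else r.diel_niche.value,
            "iucn_category": r.iucn_category.value,
            "iucn_trend": r.iucn_trend_raw.value,
            "literature_trend": r.literature_trend.value,
            "is_marine": "1" if r.is_marine else "0",
            "is_fossorial": "1" if r.is_fossorial else "0",
            "body_mass_kg": "" if r.body_mass_kg is None else repr(r.body_mass_kg),
        }
        for t, col in THREAT_COLUMNS.items():
            row[col] = ("1" if t in r.threats else "0") if r.threats_known else ""
        row["niche_imputed"] = "1" if r.niche_imputed else "0"
        row["trend_class"] = r.trend_class.value
        row["trend_provenance"] = r.trend_provenance.value
        rows.append(row)
    pd.DataFrame(rows, columns=SPECIES_COLUMNS + DERIVED_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trees


def _read_trees(path: str | os.PathLike) -> list[dendropy.Tree]:
    text = Path(path).read_text()
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    tl = dendropy.TreeList.get(data=text, schema=schema)
    return list(tl)


def read_tree_ensemble(paths: str | os.PathLike | Iterable[str | os.PathLike]) -> TreeEnsemble:
    """Read one or more Newick/Nexus files into a :class:`TreeEnsemble`.

    All trees must share one tip label set (after underscore/space
    normalisation); any negative branch length is rejected.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    trees: list[dendropy.Tree] = []
    for p in paths:
        try:
            batch = _read_trees(p)
        except Exception as exc:  # dendropy raises assorted parse errors
            raise ValueError(f"could not parse trees in {p}: {exc}") from exc
        trees.extend(batch)
    if not trees:
        raise ValueError("no trees found")
    for i, t in enumerate(trees):
        for edge in t.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"tree {i}: negative branch length {edge.length}")
    return TreeEnsemble(trees)


def write_tree_ensemble(ensemble: TreeEnsemble, path: str | os.PathLike) -> None:
    tl = dendropy.TreeList(ensemble.trees, taxon_namespace=ensemble.trees[0].taxon_namespace)
    tl.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# Rasters

_NODATA_FLOAT = -9999.0


def write_raster(
    array: np.ndarray,
    grid: GridSpec,
    path: str | os.PathLike,
    nodata: Optional[float] = None,
    extra_meta: Optional[dict] = None,
) -> None:
    """Write a single-band raster; grid geometry goes in the description tag."""
    arr = np.asarray(array)
    if arr.shape != grid.shape:
        raise ValueError(f"array shape {arr.shape} != grid shape {grid.shape}")
    meta = {"grid": grid.to_dict()}
    if nodata is not None:
        meta["nodata"] = nodata
    if extra_meta:
        meta.update(extra_meta)
    tifffile.imwrite(str(path), arr, description=json.dumps(meta))


def read_raster(path: str | os.PathLike) -> tuple[np.ndarray, GridSpec, dict]:
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    if "grid" not in meta:
        raise ValueError(f"{path}: no grid geometry in raster metadata")
    return arr, GridSpec.from_dict(meta["grid"]), meta


def read_range_stack(
    paths: dict[str, str | os.PathLike], grid: GridSpec
) -> RangeStack:
    """Read one presence raster per species into an aligned binary stack.

    ``paths`` maps species_id to raster file. Values must be 0/1/nodata;
    nodata is mapped to absence. A geometry mismatch names the offending file.
    """
    species_ids = sorted(paths)
    presence = np.zeros((len(species_ids), grid.n_cells), dtype=bool)
    for i, sid in enumerate(species_ids):
        arr, g, meta = read_raster(paths[sid])
        if g != grid:
            raise ValueError(f"raster {paths[sid]}: grid geometry mismatch")
        vals = np.asarray(arr, dtype=float)
        nodata = meta.get("nodata")
        if nodata is not None:
            vals = np.where(vals == nodata, 0.0, vals)
        vals = np.where(np.isnan(vals), 0.0, vals)
        bad = set(np.unique(vals)) - {0.0, 1.0}
        if bad:
            raise ValueError(f"raster {paths[sid]}: non-binary values {sorted(bad)}")
        presence[i] = vals.reshape(-1) == 1.0
    return RangeStack(grid, species_ids, presence)


def write_range_stack(stack: RangeStack, directory: str | os.PathLike) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for sid in stack.species_ids:
        p = directory / f"{sid}.tif"
        write_raster(stack.raster(sid).astype(np.uint8), stack.grid, p)
        out[sid] = p
    return out


# ---------------------------------------------------------------------------
# Override tables and configs


def read_override_table(path: str | os.PathLike) -> set[tuple[str, str]]:
    """(species_id, country_code) pairs where the species is not declining."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("species_id", "country_code"):
        if col not in df.columns:
            raise ValueError(f"override table missing column {col!r}")
    pairs = list(zip(df["species_id"], df["country_code"]))
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (species, country) pairs in override table")
    return set(pairs)


def write_override_table(pairs: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    df = pd.DataFrame(sorted(pairs), columns=["species_id", "country_code"])
    df.to_csv(path, index=False)


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def records_to_frame(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    """Tidy view of records including derived trend fields, for summaries."""
    rows = []
    for r in records:
        rows.append(
            {
                "species_id": r.species_id,
                "order": r.order,
                "diel_niche": None if r.diel_niche is None else r.diel_niche.value,
                "niche_imputed": r.niche_imputed,
                "iucn_category": r.iucn_category.value,
                "iucn_trend": r.iucn_trend_raw.value,
                "trend_class": r.trend_class.value,
                "trend_provenance": r.trend_provenance.value,
                "n_threats": len(r.threats) if r.threats_known else None,
                "threats_known": r.threats_known,
                "declining": r.trend_class is TrendClass.DECLINING,
            }
        )
    return pd.DataFrame(rows)
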