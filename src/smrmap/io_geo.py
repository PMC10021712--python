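"""Tabular and geospatial input/output, contiguity adjacency, and region remapping.

The pipeline's raw inputs are per-region age-stratified death counts and
populations (delimited text), region polygons (GeoJSON) or a precomputed
adjacency edge list, and a region hierarchy mapping the smallest units to the
middle and top administrative tiers.  This module reads and validates those
formats, derives queen/rook contiguity from polygons, applies ward-merge
remappings, and removes unknown-age records (whose expected deaths cannot be
standardized).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

#: Ten-year age bands with an open top band; the order is the reporting order.
AGE_STRATA: tuple[str, ...] = (
    "0-9", "10-19", "20-29", "30-39", "40-49",
    "50-59", "60-69", "70-79", "80+",
)

#: Case-insensitive labels treated as the unknown-age stratum.
UNKNOWN_AGE_ALIASES: frozenset[str] = frozenset({"unknown", "unk", "na", "n/a"})

COUNT_COLUMNS = ["region_id", "year", "age_stratum", "deaths", "population"]


class ValidationError(ValueError):
    """A record violates a data invariant (negative count, duplicate key...)."""


class ConfigurationError(ValueError):
    """The file does not match the declared column mapping."""


# ---------------------------------------------------------------------------
# Stratified counts
# ---------------------------------------------------------------------------

def read_counts(path, column_mapping: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited counts table into the canonical column layout.

    Parameters
    ----------
    path
        CSV/TSV file with one record per (region, year, age stratum).
    column_mapping
        Maps canonical names (``region_id``, ``year``, ``age_stratum``,
        ``deaths``, ``population``) to the column names found in the file.
        Omitted keys default to the canonical name itself.

    Returns
    -------
    DataFrame with columns ``region_id, year, age_stratum, deaths, population``.

    Raises
    ------
    ConfigurationError
        If a mapped column is absent from the file.
    ValidationError
        If counts are negative or (region, year, stratum) keys repeat; the
        message names the offending rows (1-based data line numbers).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype={0: str})
    mapping = {k: (column_mapping or {}).get(k, k) for k in COUNT_COLUMNS}
    missing = [v for v in mapping.values() if v not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mapped column(s) {missing} not found; file has {list(df.columns)}"
        )
    extra = [c for c in df.columns if c not in mapping.values()]
    if extra:
        logger.warning("%s: ignoring unmapped column(s) %s", path, extra)
    out = df[[mapping[k] for k in COUNT_COLUMNS]].copy()
    out.columns = COUNT_COLUMNS
    out["region_id"] = out["region_id"].astype(str)
    out["age_stratum"] = out["age_stratum"].astype(str)
    return validate_counts(out)


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the counts invariants; returns the frame with integer dtypes."""
    for col in ("deaths", "population"):
        bad = df.index[df[col] < 0]
        if len(bad):
            rows = df.loc[bad[:5], ["region_id", "year", "age_stratum"]]
            raise ValidationError(
                f"negative {col} at data row(s) {[i + 1 for i in bad[:5].tolist()]}: "
                f"{rows.to_dict('records')}"
            )
    dup = df.duplicated(subset=["region_id", "year", "age_stratum"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate (region_id, year, age_stratum) key: "
            f"({first['region_id']}, {first['year']}, {first['age_stratum']})"
        )
    out = df.copy()
    out["year"] = out["year"].astype(int)
    out["deaths"] = out["deaths"].astype(int)
    out["population"] = out["population"].astype(int)
    return out


def write_counts(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write a counts table as CSV (optionally with ``#`` metadata header lines)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def drop_unknown_age(
    df: pd.DataFrame, aliases: frozenset[str] = UNKNOWN_AGE_ALIASES
) -> tuple[pd.DataFrame, int]:
    """Remove unknown-age records; their expected deaths cannot be standardized.

    Returns the filtered table and the total number of excluded deaths, which
    callers log for data accounting.
    """
    is_unknown = df["age_stratum"].str.lower().isin(aliases)
    excluded = int(df.loc[is_unknown, "deaths"].sum())
    if excluded:
        logger.info("excluded %d deaths in unknown-age records", excluded)
    return df.loc[~is_unknown].reset_index(drop=True), excluded


# ---------------------------------------------------------------------------
# Region hierarchy
# ---------------------------------------------------------------------------

HIERARCHY_COLUMNS = ["unit_id", "middle_id", "top_id", "merged_into"]


def validate_hierarchy(df: pd.DataFrame) -> pd.DataFrame:
    """Check the unit -> middle -> top mapping invariants.

    Every unit maps to exactly one middle and one top region, the
    middle -> top assignment is consistent, and the merge relation (post-merge
    ward consolidations) is acyclic and points at known units.
    """
    df = df.copy()
    if "merged_into" not in df.columns:
        df["merged_into"] = pd.NA
    if df["unit_id"].duplicated().any():
        dupes = df.loc[df["unit_id"].duplicated(), "unit_id"].tolist()
        raise ValidationError(f"duplicate unit_id(s): {dupes[:5]}")
    m2t = df.groupby("middle_id")["top_id"].nunique()
    bad = m2t.index[m2t > 1].tolist()
    if bad:
        raise ValidationError(f"middle region(s) {bad[:5]} assigned to multiple top regions")
    known = set(df["unit_id"])
    targets = df["merged_into"].dropna()
    unknown = sorted(set(targets) - known)
    if unknown:
        raise ValidationError(f"merged_into target(s) not in table: {unknown[:5]}")
    resolve_merges(df)  # raises on cycles
    return df


def resolve_merges(hierarchy: pd.DataFrame) -> dict[str, str]:
    """Resolve merge chains to a unit -> final-unit mapping; error on cycles."""
    direct = {
        r.unit_id: r.merged_into
        for r in hierarchy.itertuples()
        if pd.notna(getattr(r, "merged_into", None))
    }
    resolved: dict[str, str] = {}
    for uid in hierarchy["unit_id"]:
        seen = {uid}
        cur = uid
        while cur in direct:
            cur = direct[cur]
            if cur in seen:
                raise ValidationError(f"merge cycle involving unit {uid}")
            seen.add(cur)
        resolved[uid] = cur
    return resolved


def apply_merges(df: pd.DataFrame, hierarchy: pd.DataFrame) -> pd.DataFrame:
    """Relabel merged source units to their targets and sum within keys.

    Emulates consolidating reorganized wards back into their parent cities:
    deaths and populations of merged units are added to the target unit for
    each (year, age stratum).
    """
    resolved = resolve_merges(hierarchy)
    out = df.copy()
    out["region_id"] = out["region_id"].map(lambda u: resolved.get(u, u))
    out = (
        out.groupby(["region_id", "year", "age_stratum"], as_index=False, sort=True)[
            ["deaths", "population"]
        ].sum()
    )
    return out[COUNT_COLUMNS]


def read_hierarchy(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    return validate_hierarchy(df)


def write_hierarchy(df: pd.DataFrame, path) -> None:
    cols = [c for c in HIERARCHY_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Adjacency:
    """Symmetric binary contiguity relation over the regions of one tier.

    ``region_ids`` is sorted for order-independence; ``pairs`` holds unordered
    id pairs stored as sorted tuples.  Regions with no neighbors (islands) are
    retained and flagged, never dropped here — the spatial tests decide how to
    treat them.
    """

    region_ids: tuple[str, ...]
    pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self):
        ids = set(self.region_ids)
        if len(ids) != len(self.region_ids):
            raise ValidationError("duplicate region_id in adjacency")
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"self-pair ({a}, {a})")
            if a not in ids or b not in ids:
                raise ValidationError(f"pair ({a}, {b}) references unknown region")

    @classmethod
    def from_pairs(cls, region_ids, pairs) -> "Adjacency":
        norm = frozenset(tuple(sorted((str(a), str(b)))) for a, b in pairs)
        return cls(tuple(sorted(str(r) for r in region_ids)), norm)

    @property
    def n(self) -> int:
        return len(self.region_ids)

    @property
    def neighbors(self) -> dict[str, list[str]]:
        nb: dict[str, list[str]] = {r: [] for r in self.region_ids}
        for a, b in self.pairs:
            nb[a].append(b)
            nb[b].append(a)
        return {k: sorted(v) for k, v in nb.items()}

    @property
    def islands(self) -> list[str]:
        deg = {r: 0 for r in self.region_ids}
        for a, b in self.pairs:
            deg[a] += 1
            deg[b] += 1
        return [r for r in self.region_ids if deg[r] == 0]

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Directed edge index arrays (both directions) into ``region_ids``."""
        pos = {r: i for i, r in enumerate(self.region_ids)}
        if not self.pairs:
            return np.empty(0, int), np.empty(0, int)
        ij = np.array(
            [(pos[a], pos[b]) for a, b in self.pairs]
            + [(pos[b], pos[a]) for a, b in self.pairs],
            dtype=int,
        )
        return ij[:, 0], ij[:, 1]

    def weight_matrix(self) -> np.ndarray:
        """Dense binary 0/1 weight matrix in ``region_ids`` order."""
        w = np.zeros((self.n, self.n))
        i, j = self.edge_arrays()
        w[i, j] = 1.0
        return w

    def subset(self, keep) -> "Adjacency":
        """Induced sub-relation on ``keep`` (used to drop undefined-SMR regions)."""
        keep = set(keep)
        return Adjacency.from_pairs(
            [r for r in self.region_ids if r in keep],
            [(a, b) for a, b in self.pairs if a in keep and b in keep],
        )

    def aggregate(self, parent_of: dict[str, str]) -> "Adjacency":
        """Contiguity at a coarser tier: parents touch iff any children touch.

        Valid for tiers formed by polygon union of their child regions.
        """
        parents = sorted(set(parent_of[r] for r in self.region_ids))
        pairs = {
            tuple(sorted((parent_of[a], parent_of[b])))
            for a, b in self.pairs
            if parent_of[a] != parent_of[b]
        }
        return Adjacency.from_pairs(parents, pairs)

    # -- edge-list file format: "id_a<TAB>id_b" per line; isolated regions
    #    appear on a line of their own so islands round-trip.
    def to_edgelist(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(self.pairs):
                fh.write(f"{a}\t{b}\n")
            for r in self.islands:
                fh.write(f"{r}\n")

    @classmethod
    def from_edgelist(cls, path) -> "Adjacency":
        ids: set[str] = set()
        pairs: set[tuple[str, str]] = set()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.strip().split("\t")
                if not parts or parts == [""]:
                    continue
                if len(parts) == 1:
                    ids.add(parts[0])
                else:
                    a, b = parts[0], parts[1]
                    ids.update((a, b))
                    pairs.add(tuple(sorted((a, b))))
        return cls.from_pairs(ids, pairs)


def read_geojson(path_or_obj, region_id_property: str = "region_id"):
    """Read a GeoJSON FeatureCollection into [(region_id, shapely geometry)]."""
    if isinstance(path_or_obj, dict):
        obj = path_or_obj
    else:
        with open(path_or_obj, encoding="utf-8") as fh:
            obj = json.load(fh)
    out = []
    for feat in obj["features"]:
        rid = str(feat["properties"][region_id_property])
        out.append((rid, geom_shape(feat["geometry"])))
    return out


def write_geojson(records, path, region_id_property: str = "region_id",
                  extra_properties: dict[str, dict] | None = None) -> None:
    """Write [(region_id, geometry)] as a GeoJSON FeatureCollection.

    ``extra_properties`` maps region_id -> property dict merged into each
    feature (e.g. bivariate class labels for choropleth rendering).
    """
    feats = []
    for rid, geom in records:
        props = {region_id_property: rid}
        props.update((extra_properties or {}).get(rid, {}))
        feats.append(
            {"type": "Feature", "properties": props, "geometry": geom_mapping(geom)}
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def build_adjacency(
    geoms,
    contiguity: str = "queen",
    snap: float = 1e-8,
    region_id_property: str = "region_id",
) -> Adjacency:
    """Derive binary contiguity from polygons: neighbors share a boundary point.

    Parameters
    ----------
    geoms
        A GeoJSON path / FeatureCollection dict, or a list of
        ``(region_id, shapely geometry)`` pairs.
    contiguity
        ``"queen"`` (any shared boundary point, the default — administrative
        boundary data rarely distinguishes corner contacts) or ``"rook"``
        (a shared boundary segment of positive length).
    snap
        Coordinates are snapped to this grid before testing contact, absorbing
        digitization slivers in national polygon files.

    Raises
    ------
    ValidationError
        On duplicate region ids or unrepairable geometries.
    """
    if contiguity not in ("queen", "rook"):
        raise ValueError(f"contiguity must be 'queen' or 'rook', got {contiguity!r}")
    if isinstance(geoms, (str, bytes)) or hasattr(geoms, "__fspath__") or isinstance(geoms, dict):
        geoms = read_geojson(geoms, region_id_property)
    ids = [rid for rid, _ in geoms]
    if len(set(ids)) != len(ids):
        dupes = sorted({r for r in ids if ids.count(r) > 1})
        raise ValidationError(f"duplicate region_id(s) in geometry: {dupes[:5]}")
    shapes = []
    for rid, g in geoms:
        if snap:
            g = shapely.set_precision(g, snap)
        if not g.is_valid:
            g = shapely.make_valid(g)
            if not g.is_valid or g.is_empty:
                raise ValidationError(f"invalid geometry for region {rid} could not be repaired")
        shapes.append(g)
    tree = STRtree(shapes)
    cand_i, cand_j = tree.query(shapes, predicate="intersects")
    pairs = set()
    for i, j in zip(cand_i.tolist(), cand_j.tolist()):
        if i >= j:
            continue
        inter = shapes[i].intersection(shapes[j])
        if inter.is_empty:
            continue
        if contiguity == "rook" and inter.length == 0 and inter.area == 0:
            continue  # corner-only contact
        pairs.add(tuple(sorted((ids[i], ids[j]))))
    adj = Adjacency.from_pairs(ids, pairs)
    if adj.islands:
        logger.info("%d island region(s) with no neighbors: %s",
                    len(adj.islands), adj.islands[:5])
    return adj
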