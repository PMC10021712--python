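"""End-to-end orchestration: counts + rates + geometry -> SMR tables,
posterior summaries, spatial tests, classifications, and a checksummed
manifest.

Stage order mirrors the analysis: unknown-age exclusion, ward merges,
expected deaths and raw SMRs per tier, Poisson-Gamma shrinkage per tier,
Global Moran's I per tier x estimator, quartile classification per tier,
bivariate cross-classification per tier pairing, and the raw-vs-shrunken
distribution comparison.  Gender slices run as independent invocations over
their own inputs.  Every output carries a metadata header (tool version,
seed, config hash) and the run is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import pandas as pd
import yaml

from . import __version__, classification, io_geo, moran, shrinkage, standardization

logger = logging.getLogger(__name__)

TIER_PAIRINGS = (("top", "unit"), ("middle", "unit"), ("top", "middle"))


@dataclasses.dataclass
class PipelineConfig:
    """Validated run configuration; all paths resolved relative to the config
    file location (or cwd when built programmatically)."""

    counts: dict[str, str]                 # slice name -> counts CSV
    hierarchy: str
    out_dir: str
    rates: dict[str, str] | None = None    # slice name -> rates CSV; else self-standardized
    geometry: str | None = None            # GeoJSON; or
    adjacency: str | None = None           # edge list (bypasses geometry)
    contiguity: str = "queen"
    seed: int = 0
    sampler: dict = dataclasses.field(default_factory=dict)
    boundary: str = "middle"               # quartile boundary convention
    island_policy: str = "keep"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def _res(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        for key in ("hierarchy", "geometry", "adjacency", "out_dir"):
            if raw.get(key):
                raw[key] = _res(raw[key])
        for key in ("counts", "rates"):
            if raw.get(key):
                raw[key] = {k: _res(v) for k, v in raw[key].items()}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.counts:
            raise ValueError("config must name at least one counts file")
        if self.geometry is None and self.adjacency is None:
            raise ValueError("config needs either geometry or adjacency")
        for label, path in [("hierarchy", self.hierarchy),
                            ("geometry", self.geometry),
                            ("adjacency", self.adjacency),
                            *[(f"counts[{k}]", v) for k, v in self.counts.items()],
                            *[(f"rates[{k}]", v) for k, v in (self.rates or {}).items()]]:
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{label}: {path}")

    def config_hash(self) -> str:
        # hash the scientific parameters only, not file locations, so a rerun
        # of the same analysis elsewhere produces byte-identical outputs
        params = {
            "slices": sorted(self.counts),
            "external_rates": sorted(self.rates) if self.rates else None,
            "contiguity": self.contiguity,
            "seed": self.seed,
            "sampler": self.sampler,
            "boundary": self.boundary,
            "island_policy": self.island_policy,
        }
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for every gender slice; returns the manifest.

    Any stage failure aborts with an exception naming the stage and, where
    known, the offending regions.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    header = [f"smrmap {__version__}", f"seed {config.seed}",
              f"config {config.config_hash()}"]
    artifacts: list[str] = []
    log: dict = {"slices": {}}

    hierarchy = io_geo.read_hierarchy(config.hierarchy)
    resolved = io_geo.resolve_merges(hierarchy)
    eff = hierarchy.copy()
    eff["unit_id"] = eff["unit_id"].map(resolved)
    eff = eff.drop_duplicates("unit_id")[["unit_id", "middle_id", "top_id"]]

    if config.adjacency:
        adj_unit = io_geo.Adjacency.from_edgelist(config.adjacency)
    else:
        adj_unit = io_geo.build_adjacency(config.geometry, contiguity=config.contiguity)
    if set(adj_unit.region_ids) != set(eff["unit_id"]):
        adj_unit = io_geo.Adjacency.from_pairs(
            [resolved.get(r, r) for r in adj_unit.region_ids],
            {(resolved.get(a, a), resolved.get(b, b)) for a, b in adj_unit.pairs
             if resolved.get(a, a) != resolved.get(b, b)})
    parent_of = {"middle": eff.set_index("unit_id")["middle_id"].to_dict(),
                 "top": eff.set_index("unit_id")["top_id"].to_dict()}
    adjacency = {"unit": adj_unit,
                 "middle": adj_unit.aggregate(parent_of["middle"]),
                 "top": adj_unit.aggregate(parent_of["top"])}
    log["islands"] = {t: len(a.islands) for t, a in adjacency.items()}

    def _emit(df: pd.DataFrame, name: str):
        path = os.path.join(config.out_dir, name)
        standardization.write_region_table(df, path, header_lines=header)
        artifacts.append(path)
        return path

    for slice_name, counts_path in sorted(config.counts.items()):
        slog: dict = {}
        counts = io_geo.read_counts(counts_path)
        slog["records_read"] = len(counts)
        counts, excluded = io_geo.drop_unknown_age(counts)
        slog["unknown_age_deaths_excluded"] = excluded
        counts = io_geo.apply_merges(counts, hierarchy)
        if config.rates and slice_name in config.rates:
            rates = standardization.read_rates(config.rates[slice_name])
        else:
            rates = standardization.reference_rates_from_counts(counts)
        tables = {"unit": standardization.make_region_table(counts, rates, tier="unit")}
        for tier in ("middle", "top"):
            tables[tier] = standardization.aggregate_tier(tables["unit"], eff, tier)

        moran_rows = []
        cls: dict[str, dict[str, pd.Series]] = {"raw": {}, "shrunk": {}}
        for tier in standardization.TIERS:
            tbl = tables[tier]
            # stable per-(slice, tier) seed offset; process-hash-independent
            offset = int.from_bytes(
                hashlib.sha256(f"{slice_name}:{tier}".encode()).digest()[:2], "big")
            settings = shrinkage.SamplerSettings(
                seed=config.seed + offset, **config.sampler)
            post = shrinkage.sample_posterior(tbl, settings)
            tbl = tbl.merge(post.summary(), on="region_id", how="left")
            tables[tier] = tbl
            _emit(tbl, f"{slice_name}_{tier}_region_table.csv")
            for est, col in (("raw", "raw_smr"), ("shrunk", "shrunk_smr")):
                vals = tbl.set_index("region_id")[col]
                try:
                    res = moran.moran_test_randomization(
                        vals, adjacency[tier], island_policy=config.island_policy)
                    moran_rows.append((tier, slice_name, est, res.I, res.expected_i,
                                       res.variance_i, res.z, res.p_value, res.n_used))
                except moran.DegenerateInputError as exc:
                    logger.warning("moran %s/%s/%s skipped: %s",
                                   slice_name, tier, est, exc)
                cls[est][tier] = classification.classify_q1q3(
                    vals, boundary=config.boundary)
        _emit(pd.DataFrame(moran_rows,
                           columns=["tier", "slice", "estimator", "I", "expected_i",
                                    "variance", "z", "p_value", "n"]),
              f"{slice_name}_moran.csv")

        for parent_tier, child_tier in TIER_PAIRINGS:
            if parent_tier == "top" and child_tier == "middle":
                mapping = eff[["middle_id", "top_id"]].drop_duplicates()
                key = "top_id"
            else:
                mapping, key = eff, f"{parent_tier}_id"
            biv = classification.bivariate_classify(
                cls["shrunk"][child_tier], cls["shrunk"][parent_tier], mapping, key)
            _emit(biv, f"{slice_name}_bivariate_{parent_tier}_{child_tier}.csv")
            _emit(classification.bivariate_summary(biv),
                  f"{slice_name}_bivariate_{parent_tier}_{child_tier}_summary.csv")
            if config.geometry and child_tier == "unit":
                # map-ready output: unit polygons carrying the bivariate class
                feats = io_geo.read_geojson(config.geometry)
                props = {r.region_id: {"pair_label": r.pair_label,
                                       "highlight": r.highlight}
                         for r in biv.itertuples()}
                gpath = os.path.join(
                    config.out_dir,
                    f"{slice_name}_bivariate_{parent_tier}_{child_tier}.geojson")
                io_geo.write_geojson(
                    [(rid, g) for rid, g in feats if rid in props],
                    gpath, extra_properties=props)
                artifacts.append(gpath)

        slog["wilcoxon"] = {
            tier: classification.compare_raw_vs_shrunk(
                tables[tier]["raw_smr"], tables[tier]["shrunk_smr"])
            for tier in standardization.TIERS}
        log["slices"][slice_name] = slog

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "log": log,
        "artifacts": {os.path.basename(p): _sha256(p) for p in sorted(artifacts)},
    }
    mpath = os.path.join(config.out_dir, "manifest.json")
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
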