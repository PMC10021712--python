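"""Synthetic study generator with the statistical structure the analysis assumes.

Emulates the shape of the real inputs — smallest units nested in middle and
top administrative tiers, ten-year aggregated counts, age in 10-year strata —
on a rectangular lattice of unit squares.  Counts are Poisson around
``e_i * theta_i`` with relative risks ``theta_i`` drawn from a Gamma(alpha,
beta) law, optionally mixed with neighbor averages to induce the positive
spatial autocorrelation observed in real mortality surfaces, so both the
model-faithful (independent) and spatially clustered regimes are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .io_geo import AGE_STRATA, Adjacency

# Annual deaths per person-year by 10-year age band, loosely shaped like a
# national suicide schedule (near zero in childhood, flat ~2e-4 in adulthood).
DEFAULT_AGE_RATES: dict[str, float] = {
    "0-9": 2e-6,
    "10-19": 5e-5,
    "20-29": 2.2e-4,
    "30-39": 2.2e-4,
    "40-49": 2.3e-4,
    "50-59": 2.5e-4,
    "60-69": 2.2e-4,
    "70-79": 2.0e-4,
    "80+": 2.1e-4,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative truth for one synthetic study.

    Defaults give a 20x20 lattice of 400 units nested in 100 middle and 25
    top regions (the scaled-down analogue of ~1,887 municipalities in 344
    secondary areas and 47 prefectures, under the constraint that tiers are
    rectangular lattice blocks), a decade of counts, log-normal unit
    populations with median ~30,000, and relative risks Gamma(10, 0.1) —
    mean 1, SD ~0.32 on the risk scale.
    """

    grid_shape: tuple[int, int] = (20, 20)
    n_middle: int = 100
    n_top: int = 25
    age_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_RATES))
    population_log_mean: float = 10.3
    population_log_sd: float = 1.0
    theta_shape: float = 10.0     # alpha_true
    theta_scale: float = 0.1      # beta_true; prior mean of risk = shape*scale
    spatial_mixing: float = 0.0   # rho: weight of the neighbor-averaged risk
    trend_amplitude: float = 0.0  # amplitude of a smooth lattice-wide risk trend
    n_years: int = 10
    start_year: int = 2009
    age_pyramid: tuple[float, ...] | None = None  # population share per band; uniform if None
    unknown_age_fraction: float = 0.0  # extra unknown-age deaths ~ Poisson(frac*e*theta)
    seed: int = 0

    @property
    def n_units(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def __post_init__(self):
        if not (0.0 <= self.spatial_mixing <= 1.0):
            raise ValueError("spatial_mixing must be in [0, 1]")
        if self.theta_shape <= 0 or self.theta_scale <= 0:
            raise ValueError("theta_shape and theta_scale must be positive")
        if any(r < 0 for r in self.age_rates.values()):
            raise ValueError("age rates must be non-negative")


def _block_grid(rows: int, cols: int, n_blocks: int,
                sub: tuple[int, int] | None = None) -> tuple[int, int]:
    """Pick the most nearly square (block_rows, block_cols) factorization of
    ``n_blocks`` whose blocks tile the rows x cols lattice; if ``sub`` gives a
    finer block grid, each coarse block must contain whole fine blocks."""
    best = None
    for br in range(1, n_blocks + 1):
        if n_blocks % br:
            continue
        bc = n_blocks // br
        if rows % br or cols % bc:
            continue
        if sub is not None and (sub[0] % br or sub[1] % bc):
            continue
        score = abs(np.log(br) - np.log(bc))
        if best is None or score < best[0]:
            best = (score, br, bc)
    if best is None:
        raise ValueError(
            f"cannot tile a {rows}x{cols} lattice with {n_blocks} congruent "
            f"rectangular blocks{' nested in the coarser tier' if sub else ''}"
        )
    return best[1], best[2]


def lattice_queen_pairs(rows: int, cols: int, unit_ids) -> set[tuple[str, str]]:
    """Analytic queen adjacency of a rows x cols lattice (ids in row-major order)."""
    ids = np.asarray(unit_ids, dtype=object).reshape(rows, cols)
    pairs = set()
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    pairs.add(tuple(sorted((ids[r, c], ids[rr, cc]))))
    return pairs


def simulate_hierarchy(config: SimulationConfig):
    """Build the lattice geometry, tier hierarchy, and its queen adjacency.

    Returns ``(hierarchy, features, adjacency)`` where ``hierarchy`` is a
    DataFrame (unit_id, middle_id, top_id, merged_into), ``features`` is a
    list of (unit_id, shapely polygon) unit squares, and ``adjacency`` is the
    analytically known lattice queen contiguity (consistent with
    ``build_adjacency`` on the emitted polygons, which the tests assert).
    """
    rows, cols = config.grid_shape
    mr, mc = _block_grid(rows, cols, config.n_middle)
    tr, tc = _block_grid(rows, cols, config.n_top, sub=(mr, mc))
    pad = len(str(config.n_units))
    recs, feats = [], []
    for r in range(rows):
        for c in range(cols):
            idx = r * cols + c
            uid = f"U{idx:0{pad}d}"
            mid = f"M{(r // (rows // mr)) * mc + (c // (cols // mc)):03d}"
            tid = f"T{(r // (rows // tr)) * tc + (c // (cols // tc)):02d}"
            recs.append((uid, mid, tid, pd.NA))
            feats.append((uid, box(c, r, c + 1, r + 1)))
    hierarchy = pd.DataFrame(recs, columns=["unit_id", "middle_id", "top_id", "merged_into"])
    unit_ids = hierarchy["unit_id"].tolist()
    adjacency = Adjacency.from_pairs(unit_ids, lattice_queen_pairs(rows, cols, unit_ids))
    return hierarchy, feats, adjacency


def simulate_risks(config: SimulationConfig, adjacency: Adjacency,
                   rng: np.random.Generator) -> pd.Series:
    """Draw per-unit relative risks.

    Independent draws ``theta0 ~ Gamma(shape, scale)`` are mixed with the
    average of each unit's neighbors' draws:
    ``theta = (1 - rho) * theta0 + rho * mean(theta0 over neighbors)``.
    Islands keep their own draw.  With ``rho = 0`` and no trend the risks are
    exactly the independent Gamma field the shrinkage model assumes.

    Neighbor mixing alone only correlates regions a step or two apart; real
    mortality surfaces also carry broad regional gradients that survive
    aggregation to the coarsest tier.  ``trend_amplitude > 0`` multiplies the
    field by a smooth half-period surface with a random phase (one broad
    high-risk hump across the lattice), normalized to mean one; the trend is
    defined on the lattice geometry and requires the row-major unit ordering
    the hierarchy generator emits.
    """
    ids = list(adjacency.region_ids)
    theta0 = rng.gamma(config.theta_shape, config.theta_scale, size=len(ids))
    rho = config.spatial_mixing
    if rho == 0.0:
        theta = theta0.copy()
    else:
        pos = {r: i for i, r in enumerate(ids)}
        nb = adjacency.neighbors
        theta = theta0.copy()
        for i, rid in enumerate(ids):
            js = [pos[x] for x in nb[rid]]
            if js:
                theta[i] = (1.0 - rho) * theta0[i] + rho * theta0[js].mean()
    if config.trend_amplitude > 0.0:
        rows, cols = config.grid_shape
        if len(ids) != rows * cols:
            raise ValueError("trend_amplitude requires the full lattice of units")
        r = np.arange(len(ids)) // cols
        c = np.arange(len(ids)) % cols
        phase = rng.uniform(0.0, 2.0 * np.pi, size=2)
        g = 1.0 + config.trend_amplitude * (
            np.sin(np.pi * r / rows + phase[0]) * np.sin(np.pi * c / cols + phase[1]))
        g = np.maximum(g, 0.05)
        theta *= g / g.mean()
    return pd.Series(theta, index=pd.Index(ids, name="region_id"), name="theta")


def simulate_counts(config: SimulationConfig, theta: pd.Series,
                    rng: np.random.Generator,
                    rate_multiplier: float = 1.0,
                    population_share: float = 1.0,
                    populations: np.ndarray | None = None):
    """Draw age-stratified populations and Poisson death counts.

    Per-unit total populations are log-normal and split across the age bands
    by the (fixed) age pyramid; populations are constant over the study years.
    Regional totals ``d_i ~ Poisson(e_i * theta_i)`` with
    ``e_i = sum_years sum_strata rate(stratum) * pop(i, stratum)`` are then
    spread across (year, stratum) cells multinomially with probability
    proportional to ``rate * pop``, so the emitted file has the stratified
    shape of the real data while the model operates on regional totals.

    Returns ``(counts, rates)``: the stratified records and the exact national
    reference rate table used (columns year, age_stratum, rate).

    ``rate_multiplier`` scales every age rate and ``population_share`` scales
    every population — used to carve gender slices out of one configuration;
    ``populations`` (units x strata, ints) overrides the internal draw so
    several slices can share one population surface.
    """
    ids = list(theta.index)
    strata = list(AGE_STRATA)
    pyramid = np.asarray(config.age_pyramid if config.age_pyramid is not None
                         else [1.0 / len(strata)] * len(strata))
    pyramid = pyramid / pyramid.sum()
    if populations is None:
        totals = rng.lognormal(config.population_log_mean, config.population_log_sd, len(ids))
        pops = np.floor(totals[:, None] * population_share * pyramid[None, :]).astype(int)
    else:
        pops = np.asarray(populations, dtype=int)
    rates = np.array([config.age_rates[s] for s in strata]) * rate_multiplier
    years = list(range(config.start_year, config.start_year + config.n_years))

    e = (pops * rates[None, :]).sum(axis=1) * config.n_years
    d = rng.poisson(e * theta.to_numpy())

    rows = []
    for i, rid in enumerate(ids):
        cell_w = (pops[i][None, :] * rates[None, :]).repeat(config.n_years, axis=0).ravel()
        if cell_w.sum() > 0:
            alloc = rng.multinomial(d[i], cell_w / cell_w.sum()).reshape(
                config.n_years, len(strata))
        else:
            alloc = np.zeros((config.n_years, len(strata)), dtype=int)
        for yi, year in enumerate(years):
            for si, s in enumerate(strata):
                rows.append((rid, year, s, int(alloc[yi, si]), int(pops[i, si])))
        if config.unknown_age_fraction > 0:
            extra = rng.poisson(config.unknown_age_fraction * e[i] * theta.loc[rid])
            for year in years:
                rows.append((rid, year, "unknown", 0, 0))
            if extra:
                rows[-config.n_years] = (rid, years[0], "unknown", int(extra), 0)
    counts = pd.DataFrame(rows, columns=["region_id", "year", "age_stratum",
                                         "deaths", "population"])
    rate_tbl = pd.DataFrame(
        [(y, s, config.age_rates[s] * rate_multiplier) for y in years for s in strata],
        columns=["year", "age_stratum", "rate"],
    )
    return counts, rate_tbl


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    hierarchy: pd.DataFrame
    features: list
    adjacency: Adjacency
    theta: pd.Series
    slices: dict[str, tuple[pd.DataFrame, pd.DataFrame]]  # name -> (counts, rates)


# Male/female rate multipliers chosen so deaths split roughly 69%/31% between
# equal-sized populations, as national suicide totals do.
SEX_RATE_MULTIPLIERS = {"men": 1.38, "women": 0.62}


def simulate_study(config: SimulationConfig, with_sexes: bool = False) -> SyntheticStudy:
    """Generate a full synthetic study: hierarchy, geometry, adjacency, risks,
    and counts — optionally as three gender slices (all = men + women,
    sharing the regional risk surface and halving the populations)."""
    rng = np.random.default_rng(config.seed)
    hierarchy, feats, adjacency = simulate_hierarchy(config)
    theta = simulate_risks(config, adjacency, rng)
    slices: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    if not with_sexes:
        slices["all"] = simulate_counts(config, theta, rng)
    else:
        strata = list(AGE_STRATA)
        pyramid = np.asarray(config.age_pyramid if config.age_pyramid is not None
                             else [1.0 / len(strata)] * len(strata))
        pyramid = pyramid / pyramid.sum()
        totals = rng.lognormal(config.population_log_mean, config.population_log_sd,
                               len(theta))
        sex_pops = np.floor(totals[:, None] * 0.5 * pyramid[None, :]).astype(int)
        parts = {}
        for name, mult in SEX_RATE_MULTIPLIERS.items():
            # both sexes share one population surface, halved
            parts[name] = simulate_counts(config, theta, rng,
                                          rate_multiplier=mult, populations=sex_pops)
        all_counts = (
            pd.concat([parts["men"][0], parts["women"][0]])
            .groupby(["region_id", "year", "age_stratum"], as_index=False, sort=True)
            .sum()
        )
        all_rates = parts["men"][1].copy()
        all_rates["rate"] = (parts["men"][1]["rate"] + parts["women"][1]["rate"]) / 2.0
        slices["all"] = (all_counts, all_rates)
        slices["men"] = parts["men"]
        slices["women"] = parts["women"]
    return SyntheticStudy(config, hierarchy, feats, adjacency, theta, slices)


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write the study in the exact on-disk formats the readers consume."""
    import os

    from . import io_geo

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    io_geo.write_hierarchy(study.hierarchy, _p("hierarchy.csv"))
    io_geo.write_geojson(study.features, _p("lattice.geojson"))
    study.adjacency.to_edgelist(_p("adjacency.tsv"))
    study.theta.rename("theta").to_csv(_p("true_theta.csv"), lineterminator="\n")
    for name, (counts, rates) in study.slices.items():
        io_geo.write_counts(counts, _p(f"counts_{name}.csv"))
        rates.to_csv(_p(f"rates_{name}.csv"), index=False, lineterminator="\n")
    return paths
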