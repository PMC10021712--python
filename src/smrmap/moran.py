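"""Global Moran's I with binary contiguity weights and randomization inference.

The statistic, for mean-centered values z_i = x_i - mean(x) and a binary
symmetric weight matrix w_ij (1 if regions i and j are adjacent, 0 otherwise)::

    I = [ sum_i sum_j w_ij z_i z_j / sum_i sum_j w_ij ] / [ sum_i z_i^2 / n ]

Positive I means adjacent regions carry similar values.  Inference treats the
observed values as fixed and their assignment to regions as random
(randomization): E[I] = -1/(n-1), with the classical closed-form variance in
the weight-matrix sums S0, S1, S2 and the sample kurtosis b2; a Monte-Carlo
permutation test is provided as the assumption-free alternative.

Weights are deliberately binary (not row-standardized): the global
sum-of-weights normalization in the formula above is the raw-adjacency "B"
convention.  I is invariant under affine maps of the values, so computing it
on x100-scale SMRs changes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_geo import Adjacency

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """All values equal, no neighbor pairs, or too few regions."""


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_i: float
    variance_i: float
    z: float
    p_value: float
    n_used: int
    n_islands: int
    island_policy: str
    method: str          # "randomization" | "permutation"
    alternative: str


def _align(values, adjacency: Adjacency, island_policy: str):
    """Align values to the adjacency, drop undefined entries, apply island policy.

    Returns (x, adjacency, n_islands).  ``island_policy``:

    - "keep": islands stay in n and the denominator (their weight rows are
      zero, so they contribute nothing to the numerator);
    - "drop": islands are removed and the mean recomputed.

    Regions with undefined (NaN) values are always removed, with the induced
    sub-relation on the remainder.
    """
    if island_policy not in ("keep", "drop"):
        raise ValueError(f"island_policy must be 'keep' or 'drop', got {island_policy!r}")
    if isinstance(values, pd.Series):
        missing = set(adjacency.region_ids) - set(values.index.astype(str))
        if missing:
            raise ValueError(f"values missing for region(s): {sorted(missing)[:5]}")
        x = values.reindex(list(adjacency.region_ids)).to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        if x.size != adjacency.n:
            raise ValueError(f"{x.size} values for {adjacency.n} regions")
    if np.isnan(x).any():
        keep = [r for r, v in zip(adjacency.region_ids, x) if not np.isnan(v)]
        logger.info("dropping %d region(s) with undefined values", int(np.isnan(x).sum()))
        adjacency = adjacency.subset(keep)
        x = x[~np.isnan(x)]
    n_islands = len(adjacency.islands)
    if island_policy == "drop" and n_islands:
        keep = sorted(set(adjacency.region_ids) - set(adjacency.islands))
        pos = {r: i for i, r in enumerate(adjacency.region_ids)}
        x = x[[pos[r] for r in keep]]
        adjacency = adjacency.subset(keep)
    return x, adjacency, n_islands


def moran_i(values, adjacency: Adjacency, island_policy: str = "keep") -> float:
    """Global Moran's I of ``values`` (Series keyed by region id, or an array
    aligned to ``adjacency.region_ids``)."""
    x, adj, _ = _align(values, adjacency, island_policy)
    return _moran_i_aligned(x, adj)


def _moran_i_aligned(x: np.ndarray, adj: Adjacency) -> float:
    n = x.size
    if n < 2:
        raise DegenerateInputError("need at least 2 regions with defined values")
    z = x - x.mean()
    szz = float(z @ z)
    if szz == 0.0:
        raise DegenerateInputError("all values equal: Moran's I undefined (zero variance)")
    i_idx, j_idx = adj.edge_arrays()
    s0 = i_idx.size  # number of directed neighbor pairs = sum of weights
    if s0 == 0:
        raise DegenerateInputError("no neighbor pairs: Moran's I undefined")
    num = float(z[i_idx] @ z[j_idx])
    return (n / s0) * num / szz


def _weight_sums(adj: Adjacency) -> tuple[float, float, float]:
    """S0 = sum w_ij; S1 = 1/2 sum (w_ij + w_ji)^2; S2 = sum_i (row_i + col_i)^2.

    For a binary symmetric relation with m unordered pairs these reduce to
    S0 = 2m, S1 = 4m, S2 = 4 * sum_i degree_i^2.
    """
    deg = np.zeros(adj.n)
    i_idx, _ = adj.edge_arrays()
    np.add.at(deg, i_idx, 1.0)
    m = len(adj.pairs)
    return 2.0 * m, 4.0 * m, float(4.0 * (deg ** 2).sum())


def moran_test_randomization(values, adjacency: Adjacency,
                             alternative: str = "greater",
                             island_policy: str = "keep") -> MoranResult:
    """Analytic Moran's I test under randomization.

    The null holds the observed values fixed and assigns them to regions
    uniformly at random; the moments of I under that scheme are closed-form.
    One-sided "greater" is the default (positive autocorrelation is the
    alternative of interest in disease mapping); "less" and "two-sided" are
    available.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x, adj, n_isl = _align(values, adjacency, island_policy)
    n = x.size
    if n <= 3:
        raise DegenerateInputError("randomization variance needs n > 3")
    obs = _moran_i_aligned(x, adj)
    z = x - x.mean()
    szz = float(z @ z)
    b2 = n * float((z ** 4).sum()) / szz ** 2
    s0, s1, s2 = _weight_sums(adj)
    e_i = -1.0 / (n - 1)
    e_i2 = (
        n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
        - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0 * s0)
    var_i = e_i2 - e_i * e_i
    if var_i <= 0:
        raise DegenerateInputError("randomization variance non-positive")
    zstat = (obs - e_i) / np.sqrt(var_i)
    if alternative == "greater":
        p = float(stats.norm.sf(zstat))
    elif alternative == "less":
        p = float(stats.norm.cdf(zstat))
    else:
        p = float(2.0 * stats.norm.sf(abs(zstat)))
    return MoranResult(I=obs, expected_i=e_i, variance_i=var_i, z=float(zstat),
                       p_value=p, n_used=n, n_islands=n_isl,
                       island_policy=island_policy, method="randomization",
                       alternative=alternative)


def moran_permutation_test(values, adjacency: Adjacency, n_perm: int = 999,
                           seed: int | None = None,
                           alternative: str = "greater",
                           island_policy: str = "keep") -> MoranResult:
    """Monte-Carlo permutation test: shuffle values over regions ``n_perm``
    times; p = (1 + #{I_perm >= I_obs}) / (1 + n_perm) for "greater"."""
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x, adj, n_isl = _align(values, adjacency, island_policy)
    n = x.size
    obs = _moran_i_aligned(x, adj)
    z = x - x.mean()
    szz = float(z @ z)
    i_idx, j_idx = adj.edge_arrays()
    s0 = i_idx.size
    rng = np.random.default_rng(seed)
    # vectorized: all permutations at once via argsort of random keys
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    zp = z[perms]
    nums = np.einsum("ke,ke->k", zp[:, i_idx], zp[:, j_idx])
    i_perm = (n / s0) * nums / szz
    e_hat = float(i_perm.mean())
    v_hat = float(i_perm.var(ddof=1))
    if alternative == "greater":
        p = (1.0 + int((i_perm >= obs).sum())) / (1.0 + n_perm)
    elif alternative == "less":
        p = (1.0 + int((i_perm <= obs).sum())) / (1.0 + n_perm)
    else:
        dev = np.abs(i_perm - e_hat)
        p = (1.0 + int((dev >= abs(obs - e_hat)).sum())) / (1.0 + n_perm)
    zstat = (obs - e_hat) / np.sqrt(v_hat) if v_hat > 0 else np.nan
    return MoranResult(I=obs, expected_i=e_hat, variance_i=v_hat, z=float(zstat),
                       p_value=float(p), n_used=n, n_islands=n_isl,
                       island_policy=island_policy, method="permutation",
                       alternative=alternative)
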