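"""Quartile classification, bivariate cross-classification, and the
raw-vs-shrunken distribution comparison.

SMRs are split into Low / Middle / High at the first and third quartiles of
the tier's distribution (the split points of the bivariate choropleth
scheme).  Cross-classifying a child tier against its parent tier yields nine
classes; the two discordant corners are highlighted — "red" where the parent
is Low but the child is High (a high-risk pocket invisible at the coarse
tier) and "blue" for the reverse.

Note on terminology: three classes built from quartile split points are
sometimes loosely called "tertiles" in the applied literature; they are not
equal-thirds tertiles.  This module implements the quartile split points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("Low", "Middle", "High")
PAIR_LABELS = tuple(f"{p}-{c}" for p in ("High", "Middle", "Low") for c in ("Low", "Middle", "High"))


def classify_q1q3(values, boundary: str = "middle") -> pd.Series:
    """Three-class split at the first and third quartiles.

    Quartiles use linear interpolation between order statistics.  With the
    default boundary convention, values strictly below Q1 are "Low", strictly
    above Q3 "High", everything else (boundaries included) "Middle";
    ``boundary="outer"`` closes the boundaries outward instead.  Undefined
    (NaN) values propagate as NaN, unclassified.

    Requires at least 4 defined values.
    """
    if boundary not in ("middle", "outer"):
        raise ValueError(f"boundary must be 'middle' or 'outer', got {boundary!r}")
    ser = values if isinstance(values, pd.Series) else pd.Series(np.asarray(values, float))
    defined = ser.dropna()
    if len(defined) < 4:
        raise ValueError(f"need at least 4 defined values to classify, got {len(defined)}")
    q1, q3 = np.quantile(defined.to_numpy(dtype=float), [0.25, 0.75])
    if boundary == "middle":
        low, high = ser < q1, ser > q3
    else:
        low, high = ser <= q1, ser >= q3
    out = pd.Series(np.where(low, "Low", np.where(high, "High", "Middle")),
                    index=ser.index, dtype=object)
    out[ser.isna()] = np.nan
    out.name = "smr_class"
    return out


def bivariate_classify(child_classes: pd.Series, parent_classes: pd.Series,
                       hierarchy: pd.DataFrame, parent_key: str) -> pd.DataFrame:
    """Label each child region with its (parent class, child class) pair.

    ``parent_key`` is the hierarchy column holding the parent id ("middle_id"
    or "top_id") when children are the smallest units; for middle-tier
    children against the top tier, pass a two-column frame mapping
    ``unit_id`` -> parent directly via ``hierarchy``.

    Returns one row per child with columns region_id, parent_id, child_class,
    parent_class, pair_label, highlight (red = Low parent-High child,
    blue = High parent-Low child, none otherwise).
    """
    mapping = hierarchy.set_index(hierarchy.columns[0])[parent_key]
    rows = []
    for rid, cclass in child_classes.items():
        if rid not in mapping.index:
            raise ValueError(f"child region {rid!r} has no parent in the hierarchy")
        pid = mapping.loc[rid]
        if pid not in parent_classes.index:
            raise ValueError(f"parent region {pid!r} of child {rid!r} is unclassified")
        pclass = parent_classes.loc[pid]
        if pd.isna(cclass) or pd.isna(pclass):
            pair, highlight = np.nan, np.nan
        else:
            pair = f"{pclass}-{cclass}"
            highlight = ("red" if (pclass, cclass) == ("Low", "High")
                         else "blue" if (pclass, cclass) == ("High", "Low")
                         else "none")
        rows.append((rid, pid, cclass, pclass, pair, highlight))
    return pd.DataFrame(rows, columns=["region_id", "parent_id", "child_class",
                                       "parent_class", "pair_label", "highlight"])


def bivariate_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Nine-cell count/percentage summary of a bivariate class table.

    Percentages are of the number of classified child regions, rounded to one
    decimal (display precision of the usual cross-tabulation reports).
    """
    classified = table.dropna(subset=["pair_label"])
    n = len(classified)
    counts = classified["pair_label"].value_counts()
    rows = [(lab, int(counts.get(lab, 0)),
             round(100.0 * counts.get(lab, 0) / n, 1) if n else np.nan)
            for lab in PAIR_LABELS]
    return pd.DataFrame(rows, columns=["pair_label", "count", "percent"])


def compare_raw_vs_shrunk(raw, shrunk, paired: bool = False) -> dict:
    """Compare the raw and shrunken SMR distributions.

    Default is the two-sample Wilcoxon rank-sum test (normal approximation
    with tie correction, no continuity correction), treating the two vectors
    as independent samples; undefined entries are dropped from each vector
    independently.  ``paired=True`` switches to the Wilcoxon signed-rank test
    on the per-region differences, which respects the natural pairing but is
    a different hypothesis — see the methods note.

    Returns statistic, p_value, medians and IQRs of both vectors, and n's.
    """
    raw = pd.Series(raw).dropna().to_numpy(dtype=float)
    shrunk = pd.Series(shrunk).dropna().to_numpy(dtype=float)
    if raw.size == 0 or shrunk.size == 0:
        raise ValueError("empty vector after dropping undefined SMRs")
    if paired:
        if raw.size != shrunk.size:
            raise ValueError("paired comparison needs equal-length vectors")
        diff = shrunk - raw
        if np.all(diff == 0):
            statistic, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(shrunk, raw, zero_method="wilcox",
                                 alternative="two-sided")
            statistic, p = float(res.statistic), float(res.pvalue)
        method = "wilcoxon-signed-rank"
    else:
        res = stats.mannwhitneyu(raw, shrunk, alternative="two-sided",
                                 use_continuity=False, method="asymptotic")
        statistic, p = float(res.statistic), float(res.pvalue)
        method = "wilcoxon-rank-sum"

    def _msum(v):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"median": float(med), "iqr": (float(q1), float(q3))}

    return {
        "method": method,
        "statistic": statistic,
        "p_value": p,
        "raw": {"n": int(raw.size), **_msum(raw)},
        "shrunk": {"n": int(shrunk.size), **_msum(shrunk)},
    }
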