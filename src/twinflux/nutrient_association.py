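"""Diet-microbe association screen via intra-twin nutrient differences.

For each environment-susceptible genus the co-twins in every pair are
ordered by that genus's abundance (Twin1 = higher), and the intra-twin
nutrient difference ITND = intake(Twin1) - intake(Twin2) is computed per
nutrient.  The genus's ITD column is then rank-correlated (Spearman) with
its genus-specific ITND column, one coefficient per (genus, nutrient).

Because genetic background and pair-shared environment cancel inside a
monozygotic pair, a monotone ITD-ITND association points at the nutrient as
a candidate driver of the genus's within-pair divergence.

Significance rules: "pvalue" (two-sided p < alpha from the t approximation,
default) or "threshold" (|rs| >= fixed cutoff, default 0.27).  No correction
is applied across the genus-by-nutrient grid; a Benjamini-Hochberg matrix
can be requested separately.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    AssociationTable,
    ITDMatrix,
    NutrientTable,
    ORDER_B_IS_TWIN1,
    ORDER_TIE,
    SusceptibilityTable,
    TwinfluxError,
)

__all__ = ["compute_itnd", "spearman", "spearman_exact_p", "screen", "bh_matrix"]


def _signs_for_genus(itd: ITDMatrix, taxon: tuple[str, str]) -> np.ndarray:
    """Per-pair +/-1 signs mapping (a - b) differences onto (Twin1 - Twin2).

    Ties (identical abundance) are broken deterministically: the
    lexicographically smaller sample id acts as Twin1.
    """
    codes = itd.ordering[taxon].to_numpy().astype(int)
    signs = np.where(codes == ORDER_B_IS_TWIN1, -1, 1)
    ties = codes == ORDER_TIE
    if ties.any():
        for k in np.flatnonzero(ties):
            _, a, b = itd.pair_map.pairs[k]
            signs[k] = 1 if a < b else -1
    return signs


def compute_itnd(
    nutrients: NutrientTable,
    itd: ITDMatrix,
    taxon: tuple[str, str],
    genus_specific: bool = True,
) -> pd.DataFrame:
    """Pairs-by-nutrients matrix of ITND for one focal genus.

    ``genus_specific=False`` switches to a fixed global ordering (member a
    is always Twin1), provided because the difference equation alone does
    not pin the labelling down; the genus-specific ordering is the default.
    """
    a_ids, b_ids = itd.pair_map.members()
    missing = [s for s in itd.pair_map.samples if s not in set(nutrients.samples)]
    if missing:
        raise TwinfluxError(f"nutrient table missing samples: {missing}")
    va = nutrients.values.loc[a_ids].to_numpy()
    vb = nutrients.values.loc[b_ids].to_numpy()
    diff = va - vb
    if genus_specific:
        diff = diff * _signs_for_genus(itd, taxon)[:, None]
    return pd.DataFrame(
        diff, index=itd.itd.index, columns=nutrients.values.columns
    )


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p via the t approximation.

    rs is the Pearson correlation of mid-ranks (average ranks for ties);
    p uses t = rs * sqrt((n-2)/(1-rs^2)) on n-2 degrees of freedom.  If
    either vector has zero rank variance the correlation is undefined and
    (nan, nan) is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise TwinfluxError("spearman needs two equal-length vectors, n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std(ddof=1)
    sy = ry.std(ddof=1)
    if sx == 0 or sy == 0:
        warnings.warn("zero rank variance: Spearman rs undefined", stacklevel=2)
        return math.nan, math.nan
    rs = float(np.clip(
        ((rx - rx.mean()) * (ry - ry.mean())).sum() / ((n - 1) * sx * sy), -1, 1
    ))
    if abs(rs) == 1.0:
        return rs, 0.0
    t = rs * math.sqrt((n - 2) / (1 - rs * rs))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return rs, p


def spearman_exact_p(x: np.ndarray, y: np.ndarray, mid_p: bool = False) -> float:
    """Exact two-sided permutation p-value for Spearman rs (n <= 8 only).

    Enumerates all n! orderings of y; p = fraction of permutations with
    |rs| at least the observed magnitude.  ``mid_p=True`` counts permutations
    tied with the observed magnitude at half weight — the appropriate
    convention when comparing the discrete permutation distribution against
    a continuous approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 8:
        raise TwinfluxError("exact permutation p restricted to n <= 8")
    rs_obs, _ = spearman(x, y)
    if math.isnan(rs_obs):
        return math.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    denom = (n - 1) * rx.std(ddof=1) * ry.std(ddof=1)
    above = 0
    tied = 0
    total = 0
    for perm in permutations(range(n)):
        rs = (rx_c * (ry[list(perm)] - ry.mean())).sum() / denom
        if abs(rs) > abs(rs_obs) + 1e-12:
            above += 1
        elif abs(rs) >= abs(rs_obs) - 1e-12:
            tied += 1
        total += 1
    if mid_p:
        return (above + 0.5 * tied) / total
    return (above + tied) / total


def screen(
    itd: ITDMatrix,
    susceptibility: SusceptibilityTable,
    nutrients: NutrientTable,
    rule: str = "pvalue",
    alpha: float = 0.05,
    threshold: float = 0.27,
    nutrient_codes: list[str] | None = None,
    genus_specific: bool = True,
) -> AssociationTable:
    """Run the Spearman screen for every environment-susceptible genus.

    Parameters
    ----------
    rule : "pvalue" flags p < alpha; "threshold" flags |rs| >= threshold.
    nutrient_codes : restrict/reorder the nutrient columns (default: all
        columns present in the nutrient table).
    """
    if rule not in ("pvalue", "threshold"):
        raise ValueError(f"unknown significance rule {rule!r}")
    targets = susceptibility.environment_susceptible
    cols = list(nutrient_codes) if nutrient_codes is not None else nutrients.nutrients
    missing = [c for c in cols if c not in set(nutrients.nutrients)]
    if missing:
        raise TwinfluxError(f"nutrient table lacks columns: {missing}")
    if itd.n_pairs < 3:
        raise TwinfluxError("screen needs at least 3 pairs")

    idx = pd.MultiIndex.from_tuples(targets, names=["family", "genus"])
    rs_mat = pd.DataFrame(np.nan, index=idx, columns=cols)
    p_mat = pd.DataFrame(np.nan, index=idx, columns=cols)
    for taxon in targets:
        itnd = compute_itnd(nutrients, itd, taxon, genus_specific=genus_specific)
        x = itd.itd[taxon].to_numpy()
        for c in cols:
            rs, p = spearman(x, itnd[c].to_numpy())
            rs_mat.loc[taxon, c] = rs
            p_mat.loc[taxon, c] = p
    if rule == "pvalue":
        flagged = p_mat < alpha
    else:
        flagged = rs_mat.abs() >= threshold
    flagged = flagged.fillna(False).astype(bool)
    return AssociationTable(rs=rs_mat, p=p_mat, flagged=flagged, rule=rule)


def bh_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment applied across the whole grid."""
    flat = p.to_numpy().ravel()
    ok = np.isfinite(flat)
    adj = np.full(flat.shape, np.nan)
    if ok.any():
        q = flat[ok]
        order = np.argsort(q)
        m = q.size
        ranked = q[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        adj[ok] = out
    return pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
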