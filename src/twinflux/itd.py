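"""Intra-twin difference (ITD) analysis.

The procedure separates environment-susceptible from genetically constrained
genera in a monozygotic-twin cohort.  Per genus, abundances are z-scored
across all samples (Q values); within each pair the higher-abundance co-twin
is labelled Twin1 and the intra-twin difference is

    ITDx = Q(Twin1) - Q(Twin2) = |Q(a) - Q(b)|  >= 0.

A genus's mean ITD over pairs (mean ITDx) is compared against the grand mean
of all pair-by-genus ITD cells (MD) with Welch's two-sample t-test.  A genus
significantly above MD varies more within genetically identical pairs than
the cohort at large — i.e. is environment-susceptible; significantly below,
genetically constrained.

Statistical caveats (deliberately mirrored, not corrected): the pooled
comparator treats all pair-by-genus cells as one flat sample despite
within-pair and between-genus dependence, it includes the focal genus by
default, and no multiple-testing correction is applied across genera (a
Benjamini-Hochberg column is emitted for transparency only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    ITDMatrix,
    ORDER_A_IS_TWIN1,
    ORDER_B_IS_TWIN1,
    ORDER_TIE,
    PairMap,
    StandardizedTable,
    SusceptibilityTable,
    TwinfluxError,
)

__all__ = [
    "standardize",
    "compute_itd",
    "mean_itdx",
    "grand_md",
    "welch_test",
    "classify_genus",
    "extract_susceptible",
]


def standardize(values: pd.DataFrame) -> StandardizedTable:
    """Z-score each taxon (row) across samples: Q = (x - mean) / sample SD.

    The denominator is the sample standard deviation (n-1).  Standardization
    is invariant to any positive affine rescaling of a taxon's values, so the
    same Q values result from compositions or from equal-depth raw counts.

    Raises on zero-SD taxa, listing them; callers may drop those and retry.
    """
    if values.shape[1] < 2:
        raise TwinfluxError("standardization needs at least 2 samples")
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    zero = np.where(sd.ravel() == 0)[0]
    if zero.size:
        taxa = [values.index[i] for i in zero]
        raise TwinfluxError(f"zero-variance taxa cannot be standardized: {taxa}")
    q = (arr - mu) / sd
    return StandardizedTable(pd.DataFrame(q, index=values.index, columns=values.columns))


def compute_itd(std: StandardizedTable, pairs: PairMap) -> ITDMatrix:
    """Compute the pairs-by-taxa ITD matrix and the per-cell twin ordering.

    Twin1 is the pair member with the higher value for that taxon; the
    ordering (+1: member a, -1: member b, 0: tie) is recorded for reuse by
    the nutrient-difference screen.
    """
    sample_set = set(std.samples)
    missing = [s for s in pairs.samples if s not in sample_set]
    if missing or len(pairs.samples) != len(std.samples):
        raise TwinfluxError(
            f"pair map does not partition the sample set (missing: {missing})"
        )
    a_ids, b_ids = pairs.members()
    q = std.q_values
    qa = q[a_ids].to_numpy().T  # pairs x taxa
    qb = q[b_ids].to_numpy().T
    diff = qa - qb
    itd = np.abs(diff)
    ordering = np.sign(diff).astype(np.int8)  # +1 a, -1 b, 0 tie
    idx = pd.Index(pairs.pair_ids, name="pair_id")
    cols = q.index
    return ITDMatrix(
        itd=pd.DataFrame(itd, index=idx, columns=cols),
        ordering=pd.DataFrame(ordering, index=idx, columns=cols),
        pair_map=pairs,
    )


def mean_itdx(itd: ITDMatrix) -> pd.Series:
    """Per-taxon mean ITD across pairs."""
    return itd.itd.mean(axis=0)


def grand_md(itd: ITDMatrix) -> float:
    """Grand mean of all pair-by-taxon ITD cells (the pooled comparator MD)."""
    return float(itd.itd.to_numpy().mean())


def welch_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Returns (t, df, p) with t = (mean(x) - mean(y)) / sqrt(sx2/nx + sy2/ny)
    and Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise TwinfluxError("welch_test needs at least 2 observations per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise TwinfluxError("welch_test undefined: both samples have zero variance")
    se2x = vx / nx
    se2y = vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2x + se2y)
    df = (se2x + se2y) ** 2 / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def classify_genus(
    mean_itdx: float, md: float, p: float, alpha: float = 0.05
) -> str:
    """Apply the susceptibility decision rule.

    p < alpha and mean ITDx > MD  -> environment_susceptible
    p < alpha and mean ITDx < MD  -> genetic_susceptible
    otherwise                     -> indeterminate
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < alpha:
        if mean_itdx > md:
            return "environment_susceptible"
        if mean_itdx < md:
            return "genetic_susceptible"
    return "indeterminate"


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def extract_susceptible(
    itd: ITDMatrix, alpha: float = 0.05, exclude_focal: bool = False
) -> SusceptibilityTable:
    """Welch-test each taxon's ITD column against the pooled ITD cells.

    By default the pooled comparator includes the focal taxon (the reported
    MD is a single cohort-wide grand mean); ``exclude_focal=True`` removes
    the focal column from its own comparator.
    """
    mat = itd.itd.to_numpy()
    n_pairs, n_taxa = mat.shape
    md = grand_md(itd)
    pool = mat.ravel()

    rows = []
    for g in range(n_taxa):
        x = mat[:, g]
        if exclude_focal:
            comp = np.delete(mat, g, axis=1).ravel()
            comp_mean = comp.mean()
        else:
            comp = pool
            comp_mean = md
        if x.var(ddof=1) == 0 and comp.var(ddof=1) == 0:
            # degenerate all-tied cohort: focal cells are a subset of the
            # pool, so equal-variance-zero implies equal means — no signal
            t, df, p = 0.0, float(x.size + comp.size - 2), 1.0
        else:
            t, df, p = welch_test(x, comp)
        rows.append((x.mean(), comp_mean, t, df, p))

    arr = np.array(rows)
    p_bh = _bh_adjust(arr[:, 4])
    table = pd.DataFrame(
        {
            "mean_ITDx": arr[:, 0],
            "MD": md,
            "t": arr[:, 2],
            "df": arr[:, 3],
            "p": arr[:, 4],
            "p_bh": p_bh,
        },
        index=itd.itd.columns,
    )
    comparator = arr[:, 1]
    table["significant"] = table["p"] < alpha
    table["classification"] = [
        classify_genus(m, c, p, alpha)
        for m, c, p in zip(table["mean_ITDx"], comparator, table["p"])
    ]
    return SusceptibilityTable(table=table, md=md)
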