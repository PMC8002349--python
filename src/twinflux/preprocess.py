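"""Noise processing: per-sample rarefaction and low-mean taxon filtering.

Rarefaction draws exactly ``depth`` reads per sample without replacement
from that sample's read multiset (multivariate hypergeometric), so each
rarefied count is bounded by the original count and column sums equal the
depth exactly.  Taxa whose mean rarefied count falls below the floor
(default 1 read) are then removed as sequencing noise; the boundary case
(mean exactly at the floor) is kept.  The pipeline order is fixed:
rarefy first, filter second.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import GenusCountTable, TwinfluxError

__all__ = ["PreprocessParams", "rarefy", "filter_low_mean_taxa", "to_composition"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessParams:
    """Noise-processing parameters.

    depth: reads retained per sample (default 10,000).
    mean_read_floor: minimum mean rarefied count for a taxon to survive
        (default 1.0; taxa strictly below are eliminated).
    seed: RNG seed for the subsampling step.
    low_depth_policy: what to do with samples holding fewer than ``depth``
        reads — "drop_sample_with_warning" (default) or "error".
    """

    depth: int = 10_000
    mean_read_floor: float = 1.0
    seed: int = 0
    low_depth_policy: str = "drop_sample_with_warning"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.mean_read_floor < 0:
            raise ValueError("mean_read_floor must be >= 0")
        if self.low_depth_policy not in ("drop_sample_with_warning", "error"):
            raise ValueError(f"unknown low_depth_policy {self.low_depth_policy!r}")


def rarefy(table: GenusCountTable, params: PreprocessParams) -> GenusCountTable:
    """Subsample every sample to exactly ``params.depth`` reads.

    Sampling is without replacement per sample.  Deterministic for a given
    seed and independent of taxon order (each sample's draw consumes one
    dedicated child RNG stream).
    """
    counts = table.counts
    totals = counts.sum(axis=0)
    low = totals[totals < params.depth].index.tolist()
    if len(low) == len(table.samples):
        raise TwinfluxError(
            f"all samples have fewer than {params.depth} reads; cannot rarefy"
        )
    if low:
        if params.low_depth_policy == "error":
            raise TwinfluxError(
                f"samples below rarefaction depth {params.depth}: {low}"
            )
        msg = (
            f"dropping {len(low)} sample(s) below rarefaction depth "
            f"{params.depth}: {low}"
        )
        warnings.warn(msg, stacklevel=2)
        log.warning(msg)

    keep = [s for s in table.samples if s not in set(low)]
    root = np.random.default_rng(params.seed)
    # one child stream per retained sample so results do not depend on which
    # samples were dropped upstream of this call
    streams = root.spawn(len(keep))
    # draw in canonical (sorted-label) taxon order so the result is
    # equivariant under permutations of the input's taxon rows
    order = np.argsort(counts.index.to_flat_index())
    unorder = np.argsort(order)
    out = np.empty((table.n_taxa, len(keep)), dtype=np.int64)
    for j, (sid, rng) in enumerate(zip(keep, streams)):
        col = counts[sid].to_numpy()
        if col.sum() == params.depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col[order], params.depth)[unorder]
    return GenusCountTable(pd.DataFrame(out, index=counts.index, columns=keep))


def filter_low_mean_taxa(
    table: GenusCountTable, params: PreprocessParams
) -> GenusCountTable:
    """Remove taxa whose mean count across samples is below the floor.

    The boundary (mean exactly equal to the floor) is retained; taxon order
    is preserved.
    """
    means = table.counts.mean(axis=1)
    keep = means >= params.mean_read_floor
    if not keep.any():
        raise TwinfluxError(
            f"no taxa have mean count >= {params.mean_read_floor}; nothing survives"
        )
    n_removed = int((~keep).sum())
    log.info(
        "taxon filter: %d -> %d taxa (%d removed at floor %g)",
        table.n_taxa, int(keep.sum()), n_removed, params.mean_read_floor,
    )
    return GenusCountTable(table.counts.loc[keep.to_numpy()])


def to_composition(table: GenusCountTable) -> pd.DataFrame:
    """Convert counts to per-sample proportions (columns sum to 1)."""
    counts = table.counts
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise TwinfluxError(f"samples with zero total reads: {zero}")
    return counts / totals
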