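"""Domain containers for the twin-cohort microbiota analysis.

All tabular types wrap :class:`pandas.DataFrame` objects with a fixed
orientation (taxa are rows, samples are columns for abundance-like tables)
and validate their invariants on construction.  Taxa are identified by a
``(family, genus)`` label pair because genus names are not unique across
families in standard 16S taxonomies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TwinfluxError",
    "FormatError",
    "ReconciliationError",
    "GenusCountTable",
    "PairMap",
    "NutrientTable",
    "StandardizedTable",
    "ITDMatrix",
    "SusceptibilityTable",
    "AssociationTable",
    "DEFAULT_NUTRIENT_CODES",
]

#: Energy-adjusted nutrient codes of the default diet-questionnaire panel
#: (per-1000 kcal units; energy itself is deliberately not part of the panel).
DEFAULT_NUTRIENT_CODES = (
    "PRT", "FAT", "SFA", "CHO", "TDF", "NA", "K", "CA", "FE",
    "RTE", "VD", "ATC", "VK", "VB1", "VB2", "VB6", "VB12", "VC",
)


class TwinfluxError(Exception):
    """Base class for all package errors."""


class FormatError(TwinfluxError):
    """An input table violates its format contract."""


class ReconciliationError(TwinfluxError):
    """Sample sets of the input tables do not agree."""


def taxon_index(taxa: Iterable[tuple[str, str]]) -> pd.MultiIndex:
    """Build the canonical (family, genus) row index."""
    return pd.MultiIndex.from_tuples(list(taxa), names=["family", "genus"])


@dataclass(frozen=True)
class GenusCountTable:
    """Genus-level read counts, taxa (rows) by samples (columns).

    Invariants: counts are non-negative integers, genus labels are unique
    within the table, and there are at least two samples.
    """

    counts: pd.DataFrame  # index: MultiIndex (family, genus); columns: sample ids

    def __post_init__(self) -> None:
        df = self.counts
        if not isinstance(df.index, pd.MultiIndex) or df.index.names != ["family", "genus"]:
            raise FormatError("count table index must be a (family, genus) MultiIndex")
        if df.shape[1] < 2:
            raise FormatError("count table needs at least 2 samples")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        genus = df.index.get_level_values("genus")
        if genus.duplicated().any():
            dups = sorted(set(genus[genus.duplicated()]))
            raise FormatError(f"duplicate genus labels: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric")
        bad = np.argwhere((arr < 0) | (arr != np.floor(arr)) | ~np.isfinite(arr))
        if bad.size:
            i, j = bad[0]
            raise FormatError(
                f"count for taxon {df.index[i]} in sample {df.columns[j]!r} "
                f"is {arr[i, j]!r}: counts must be non-negative integers"
            )
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def taxa(self) -> list[tuple[str, str]]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PairMap:
    """Partition of the sample set into twin pairs."""

    pairs: tuple[tuple[str, str, str], ...]  # (pair_id, member_a, member_b)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        pair_ids = set()
        for pair_id, a, b in self.pairs:
            if pair_id in pair_ids:
                raise FormatError(f"duplicate pair id {pair_id!r}")
            pair_ids.add(pair_id)
            if a == b:
                raise FormatError(f"pair {pair_id!r} lists sample {a!r} twice")
            for s in (a, b):
                if s in seen:
                    raise FormatError(
                        f"sample {s!r} appears in pairs {seen[s]!r} and {pair_id!r}"
                    )
                seen[s] = pair_id

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_ids(self) -> list[str]:
        return [p for p, _, _ in self.pairs]

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for _, a, b in self.pairs:
            out.extend((a, b))
        return out

    def members(self) -> tuple[list[str], list[str]]:
        """Column-aligned member lists (a-members, b-members)."""
        return [a for _, a, _ in self.pairs], [b for _, _, b in self.pairs]


@dataclass(frozen=True)
class NutrientTable:
    """Energy-adjusted nutrient intakes, samples (rows) by nutrient codes."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.columns.duplicated().any():
            raise FormatError("duplicate nutrient codes")
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids in nutrient table")
        arr = df.to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(arr))
        if bad.size:
            i, j = bad[0]
            raise FormatError(
                f"missing value for sample {df.index[i]!r}, nutrient {df.columns[j]!r}"
            )
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise FormatError(
                f"negative intake {arr[i, j]} for sample {df.index[i]!r}, "
                f"nutrient {df.columns[j]!r}: intakes must be non-negative"
            )
        object.__setattr__(self, "values", df.astype(float))

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def nutrients(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class StandardizedTable:
    """Per-taxon z-scores (Q values) of composition across all samples.

    Each taxon row has mean 0 and sample standard deviation (n-1 denominator)
    1 across samples.
    """

    q_values: pd.DataFrame  # same orientation as GenusCountTable.counts

    @property
    def taxa(self) -> list[tuple[str, str]]:
        return list(self.q_values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.q_values.columns)


# Twin-ordering codes used in ITDMatrix.ordering
ORDER_A_IS_TWIN1 = 1
ORDER_B_IS_TWIN1 = -1
ORDER_TIE = 0


@dataclass(frozen=True)
class ITDMatrix:
    """Non-negative intra-twin differences, pairs (rows) by taxa (columns).

    ``itd[p, g]`` is the Q value of the higher-abundance co-twin minus the
    lower one for genus g in pair p, i.e. ``|Q_a - Q_b|``.  ``ordering``
    records, per cell, which member was the higher-abundance twin (Twin1):
    +1 = member a, -1 = member b, 0 = exact tie (where itd is exactly 0).
    """

    itd: pd.DataFrame        # index: pair ids, columns: (family, genus)
    ordering: pd.DataFrame   # same shape, int8 codes
    pair_map: PairMap

    def __post_init__(self) -> None:
        a = self.itd.to_numpy()
        if (a < 0).any():
            raise TwinfluxError("ITD values must be non-negative")
        o = self.ordering.to_numpy()
        if ((o == ORDER_TIE) != (a == 0)).any():
            raise TwinfluxError("ITD is zero exactly at ordering ties")

    @property
    def taxa(self) -> list[tuple[str, str]]:
        return list(self.itd.columns)

    @property
    def n_pairs(self) -> int:
        return self.itd.shape[0]


@dataclass(frozen=True)
class SusceptibilityTable:
    """Per-genus environmental-susceptibility summary (mean ITDx vs. MD)."""

    table: pd.DataFrame
    # columns: mean_ITDx, MD, t, df, p, p_bh, significant, classification
    md: float

    @property
    def environment_susceptible(self) -> list[tuple[str, str]]:
        t = self.table
        return list(t.index[t["classification"] == "environment_susceptible"])

    @property
    def genetic_susceptible(self) -> list[tuple[str, str]]:
        t = self.table
        return list(t.index[t["classification"] == "genetic_susceptible"])


@dataclass(frozen=True)
class AssociationTable:
    """Genus-by-nutrient rank-correlation screen results.

    ``rs``/``p`` hold Spearman coefficients and two-sided p-values; ``flagged``
    marks cells that satisfy the active significance rule.  Undefined
    correlations (zero rank variance) are NaN in ``rs``/``p`` and False in
    ``flagged``.
    """

    rs: pd.DataFrame
    p: pd.DataFrame
    flagged: pd.DataFrame
    rule: str = "pvalue"

    def __post_init__(self) -> None:
        arr = self.rs.to_numpy()
        finite = arr[np.isfinite(arr)]
        if finite.size and np.abs(finite).max() > 1 + 1e-12:
            raise TwinfluxError("Spearman rs out of [-1, 1]")


def reconcile_samples(
    counts: GenusCountTable, pairs: PairMap, nutrients: NutrientTable | None = None
) -> None:
    """Check that all inputs describe exactly the same sample set.

    Raises :class:`ReconciliationError` listing the symmetric difference.
    """
    ref = set(counts.samples)
    others: list[tuple[str, set[str]]] = [("pair map", set(pairs.samples))]
    if nutrients is not None:
        others.append(("nutrient table", set(nutrients.samples)))
    problems = []
    for name, got in others:
        if got != ref:
            only_counts = sorted(ref - got)
            only_other = sorted(got - ref)
            problems.append(
                f"{name}: only in counts {only_counts}, only in {name} {only_other}"
            )
    if problems:
        raise ReconciliationError("sample sets differ; " + "; ".join(problems))
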