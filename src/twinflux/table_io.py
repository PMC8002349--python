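"""Readers and writers for the three input tables and the result tables.

Canonical dialect is UTF-8 TSV.  Count tables carry one taxonomy column
("Family;Genus") followed by one column per sample; pair maps are three
columns (pair_id, member_a, member_b); nutrient tables have samples as rows
and nutrient codes as columns.  A read-only BIOM-JSON (format 1.0) dialect is
accepted for count tables; BIOM 1.0 is plain JSON, so it is parsed directly.

Note the nutrient code "NA" (sodium) — readers must not treat it as a
missing-value token, so all pandas parsing here disables default NA handling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (
    AssociationTable,
    FormatError,
    GenusCountTable,
    NutrientTable,
    PairMap,
    SusceptibilityTable,
    taxon_index,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_pairs",
    "write_pairs",
    "read_nutrients",
    "write_nutrients",
    "write_susceptibility",
    "read_susceptibility",
    "write_associations",
    "read_associations",
]

_TAXONOMY_COL = 0


def _split_taxonomy(labels: list[str]) -> list[tuple[str, str]]:
    taxa: list[tuple[str, str]] = []
    for lab in labels:
        parts = [p.strip() for p in str(lab).split(";")]
        if len(parts) == 1:
            taxa.append(("", parts[0]))
        else:
            # keep the last two ranks; deeper prefixes are upstream's business
            taxa.append((parts[-2], parts[-1]))
    # disambiguate duplicate genus labels across families by prefixing family
    genus = [g for _, g in taxa]
    dup = {g for g in genus if genus.count(g) > 1}
    out = []
    for fam, gen in taxa:
        out.append((fam, f"{fam} {gen}" if gen in dup and fam else gen))
    return out


def read_counts(path: str | Path, dialect: str = "tsv") -> GenusCountTable:
    """Read a genus count table (taxa x samples).

    Parameters
    ----------
    path : file path
    dialect : "tsv" (canonical) or "biom-json" (BIOM format 1.0, read-only)
    """
    path = Path(path)
    if dialect == "tsv":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
        dups = {h for h in header[1:] if header[1:].count(h) > 1}
        if dups:
            raise FormatError(f"duplicate sample ids in header: {sorted(dups)}")
        df = pd.read_csv(
            path, sep="\t", header=0, dtype=str, keep_default_na=False
        )
        if df.shape[1] < 3:
            raise FormatError("count table needs a taxonomy column and >= 2 samples")
        tax_labels = df.iloc[:, _TAXONOMY_COL].tolist()
        samples = [str(c) for c in df.columns[1:]]
        raw = df.iloc[:, 1:]
        mat = np.empty(raw.shape, dtype=float)
        for j, col in enumerate(raw.columns):
            for i, cell in enumerate(raw[col]):
                try:
                    v = float(cell)
                except ValueError:
                    raise FormatError(
                        f"non-numeric count {cell!r} at taxon {tax_labels[i]!r}, "
                        f"sample {col!r}"
                    ) from None
                if v < 0 or v != int(v):
                    raise FormatError(
                        f"invalid count {cell!r} at taxon {tax_labels[i]!r}, "
                        f"sample {col!r}: counts must be non-negative integers"
                    )
                mat[i, j] = v
        counts = pd.DataFrame(
            mat, index=taxon_index(_split_taxonomy(tax_labels)), columns=samples
        )
        return GenusCountTable(counts)
    if dialect == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_biom_json(path: Path) -> GenusCountTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=float)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    if (mat < 0).any() or (mat != np.floor(mat)).any():
        raise FormatError(f"{path}: BIOM counts must be non-negative integers")
    counts = pd.DataFrame(mat, index=taxon_index(_split_taxonomy(rows)), columns=cols)
    return GenusCountTable(counts)


def write_counts(table: GenusCountTable, path: str | Path) -> None:
    """Write a genus count table in the canonical TSV layout."""
    df = table.counts.copy()
    labels = [f"{fam};{gen}" if fam else gen for fam, gen in df.index]
    out = df.reset_index(drop=True)
    out.insert(0, "Family;Genus", labels)
    out.to_csv(path, sep="\t", index=False)


def write_pairs(pairs: PairMap, path: str | Path) -> None:
    df = pd.DataFrame(list(pairs.pairs), columns=["pair_id", "member_a", "member_b"])
    df.to_csv(path, sep="\t", index=False)


def write_nutrients(nutrients: NutrientTable, path: str | Path) -> None:
    df = nutrients.values.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_pairs(path: str | Path) -> PairMap:
    """Read a twin-pair map TSV (pair_id, member_a, member_b)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] != 3:
        raise FormatError("pair map must have exactly 3 columns")
    pairs = tuple(
        (str(r.iloc[0]), str(r.iloc[1]), str(r.iloc[2])) for _, r in df.iterrows()
    )
    return PairMap(pairs)


def read_nutrients(path: str | Path) -> NutrientTable:
    """Read a nutrient intake TSV (samples as rows, nutrient codes as columns).

    Unknown nutrient codes are retained; the screen later runs over whatever
    columns exist.  Missing or negative cells are format errors.
    """
    df = pd.read_csv(
        path, sep="\t", header=0, index_col=0, dtype=str, keep_default_na=False
    )
    df.index = df.index.astype(str)
    vals = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for sid, cell in df[col].items():
            if cell == "":
                raise FormatError(f"missing value for sample {sid!r}, nutrient {col!r}")
            try:
                vals.loc[sid, col] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric intake {cell!r} for sample {sid!r}, nutrient {col!r}"
                ) from None
    return NutrientTable(vals)


def write_susceptibility(table: SusceptibilityTable, path: str | Path) -> None:
    """Write a susceptibility table as TSV (floats to 3 decimals)."""
    df = table.table.reset_index()
    out = pd.DataFrame(
        {
            "Family": df["family"],
            "Genus": df["genus"],
            "mean_ITDx": df["mean_ITDx"].map(lambda v: f"{v:.3f}"),
            "MD": df["MD"].map(lambda v: f"{v:.3f}"),
            "t": df["t"].map(lambda v: f"{v:.3f}"),
            "df": df["df"].map(lambda v: f"{v:.3f}"),
            "p": df["p"].map(lambda v: f"{v:.3f}"),
            "p_bh": df["p_bh"].map(lambda v: f"{v:.3f}"),
            "significant": np.where(df["significant"], "*", ""),
            "classification": df["classification"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_susceptibility(path: str | Path) -> pd.DataFrame:
    """Read back a susceptibility TSV (display precision)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("mean_ITDx", "MD", "t", "df", "p", "p_bh"):
        df[col] = df[col].astype(float)
    df["significant"] = df["significant"] == "*"
    return df.set_index(["Family", "Genus"])


def write_associations(table: AssociationTable, path: str | Path) -> None:
    """Write the rs matrix as TSV (2 decimals) plus a parallel .flags.tsv.

    Undefined correlations are written as "NA" (never 0).
    """
    path = Path(path)

    def fmt(v: float) -> str:
        return "NA" if not np.isfinite(v) else f"{v:.2f}"

    rs = table.rs.copy()
    out = pd.DataFrame(
        {c: [fmt(v) for v in rs[c]] for c in rs.columns},
        index=rs.index,
    )
    out.index.names = ["Family", "Genus"]
    out.reset_index().to_csv(path, sep="\t", index=False)

    flags = table.flagged.astype(int).copy()
    flags.index.names = ["Family", "Genus"]
    fpath = path.with_suffix(".flags.tsv") if path.suffix == ".tsv" else Path(str(path) + ".flags.tsv")
    flags.reset_index().to_csv(fpath, sep="\t", index=False)


def read_associations(path: str | Path) -> pd.DataFrame:
    """Read back an association rs TSV; "NA" cells become NaN."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.set_index(["Family", "Genus"])
    return df.apply(lambda col: col.map(lambda v: np.nan if v == "NA" else float(v)))
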