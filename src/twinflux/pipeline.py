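"""End-to-end orchestration: rarefy -> filter -> composition -> Q values
-> ITD -> susceptibility extraction -> nutrient-difference screen.

Every run emits a JSON manifest (parameters, library versions, stage
dimensions, warnings) sufficient to reproduce it exactly; no timestamps
are recorded so reruns with identical config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .itd import classify_genus, compute_itd, extract_susceptible, standardize
from .nutrient_association import bh_matrix, screen
from .preprocess import PreprocessParams, filter_low_mean_taxa, rarefy, to_composition
from .table_io import (
    read_counts,
    read_nutrients,
    read_pairs,
    write_associations,
    write_susceptibility,
)
from .tables import (
    AssociationTable,
    GenusCountTable,
    NutrientTable,
    PairMap,
    SusceptibilityTable,
    TwinfluxError,
    reconcile_samples,
)

__all__ = ["RunConfig", "run_pipeline", "classify_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run (YAML-loadable)."""

    counts_path: str
    pairs_path: str
    nutrients_path: str
    out_dir: str = "twinflux_out"
    depth: int = 10_000
    mean_read_floor: float = 1.0
    seed: int = 0
    low_depth_policy: str = "drop_sample_with_warning"
    alpha: float = 0.05
    correlation_rule: str = "pvalue"  # or "threshold"
    threshold: float = 0.27
    exclude_focal: bool = False
    counts_dialect: str = "tsv"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, TwinfluxError):
                return False
            if isinstance(exc, TwinfluxError):
                raise TwinfluxError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(
    config: RunConfig,
    inputs: tuple[GenusCountTable, PairMap, NutrientTable] | None = None,
) -> tuple[SusceptibilityTable, AssociationTable, dict]:
    """Execute the full analysis and write result tables plus a manifest.

    ``inputs`` may supply already-loaded tables (e.g. a simulated cohort);
    otherwise the three paths in ``config`` are read.
    """
    manifest: dict = {
        "tool": "twinflux",
        "version": __version__,
        "libraries": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "config": asdict(config),
        "decisions": {
            "rarefaction": "without replacement (multivariate hypergeometric)",
            "filter_order": "rarefy first, then mean-read filter",
            "mean_read_floor_boundary": "mean exactly at floor is kept",
            "q_value_sd": "sample SD (n-1 denominator)",
            "pooled_comparator": (
                "excludes focal genus" if config.exclude_focal else "includes focal genus"
            ),
            "itnd_ordering": "genus-specific; ties broken by sample-id order",
        },
        "stages": {},
        "warnings": [],
    }

    params = PreprocessParams(
        depth=config.depth,
        mean_read_floor=config.mean_read_floor,
        seed=config.seed,
        low_depth_policy=config.low_depth_policy,
    )

    with _stage("read"):
        if inputs is None:
            counts = read_counts(config.counts_path, dialect=config.counts_dialect)
            pairs = read_pairs(config.pairs_path)
            nutrients = read_nutrients(config.nutrients_path)
        else:
            counts, pairs, nutrients = inputs
    manifest["stages"]["input"] = {
        "taxa": counts.n_taxa, "samples": counts.n_samples, "pairs": len(pairs),
    }

    with _stage("rarefy"), warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rarefied = rarefy(counts, params)
    manifest["warnings"] += [str(w.message) for w in caught]
    manifest["stages"]["rarefy"] = {
        "depth": params.depth, "samples": rarefied.n_samples,
        "samples_dropped": counts.n_samples - rarefied.n_samples,
    }

    with _stage("filter"):
        filtered = filter_low_mean_taxa(rarefied, params)
    manifest["stages"]["filter"] = {
        "taxa_before": rarefied.n_taxa, "taxa_after": filtered.n_taxa,
    }

    with _stage("reconcile"):
        dropped = set(counts.samples) - set(filtered.samples)
        if dropped:
            kept_pairs = tuple(
                p for p in pairs.pairs if p[1] not in dropped and p[2] not in dropped
            )
            lost = [p for p in pairs.pairs if p not in kept_pairs]
            if lost:
                msg = f"dropping {len(lost)} pair(s) with a low-depth member: {[p[0] for p in lost]}"
                warnings.warn(msg, stacklevel=2)
                manifest["warnings"].append(msg)
            pairs = PairMap(kept_pairs)
            keep_samples = [s for s in filtered.samples if s in set(pairs.samples)]
            filtered = GenusCountTable(filtered.counts[keep_samples])
        reconcile_samples(filtered, pairs, nutrients_subset(nutrients, filtered.samples))
        nutrients = nutrients_subset(nutrients, filtered.samples)

    with _stage("composition"):
        comp = to_composition(filtered)

    with _stage("standardize"):
        std = standardize(comp)

    with _stage("itd"):
        itd = compute_itd(std, pairs)
        n_ties = int((itd.ordering.to_numpy() == 0).sum())
        if n_ties:
            manifest["warnings"].append(
                f"{n_ties} ITD tie cell(s); tie-broken by sample-id order for ITND"
            )
    manifest["stages"]["itd"] = {"pairs": itd.n_pairs, "taxa": len(itd.taxa)}

    with _stage("extract_susceptible"):
        susc = extract_susceptible(itd, alpha=config.alpha, exclude_focal=config.exclude_focal)
    manifest["stages"]["extract_susceptible"] = {
        "md": susc.md,
        "environment_susceptible": len(susc.environment_susceptible),
        "genetic_susceptible": len(susc.genetic_susceptible),
    }
    log.info(
        "susceptibility funnel: %d taxa -> %d significant (env %d, genetic %d)",
        len(itd.taxa),
        int(susc.table["significant"].sum()),
        len(susc.environment_susceptible),
        len(susc.genetic_susceptible),
    )

    with _stage("screen"):
        assoc = screen(
            itd,
            susc,
            nutrients,
            rule=config.correlation_rule,
            alpha=config.alpha,
            threshold=config.threshold,
        )
    manifest["stages"]["screen"] = {
        "genera": assoc.rs.shape[0],
        "nutrients": assoc.rs.shape[1],
        "flagged": int(assoc.flagged.to_numpy().sum()),
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_susceptibility(susc, out / "susceptibility.tsv")
    write_associations(assoc, out / "associations.tsv")
    bh = bh_matrix(assoc.p)
    bh.to_csv(out / "associations.bh.tsv", sep="\t", float_format="%.4f")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return susc, assoc, manifest


def nutrients_subset(nutrients: NutrientTable, samples: list[str]) -> NutrientTable:
    missing = [s for s in samples if s not in set(nutrients.samples)]
    if missing:
        raise TwinfluxError(f"nutrient table missing samples: {missing}")
    return NutrientTable(nutrients.values.loc[samples])


def classify_table(
    table: pd.DataFrame, md: float, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the susceptibility decision rule to an already-printed table.

    ``table`` needs columns ``mean_ITDx`` and ``p`` (display precision is
    fine).  Returns a copy with a ``classification`` column.
    """
    out = table.copy()
    out["classification"] = [
        classify_genus(m, md, p, alpha) for m, p in zip(out["mean_ITDx"], out["p"])
    ]
    return out
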