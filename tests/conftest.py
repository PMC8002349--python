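import numpy as np
import pandas as pd
import pytest

from twinflux.tables import GenusCountTable, NutrientTable, PairMap, taxon_index


def make_counts(mat, taxa=None, samples=None) -> GenusCountTable:
    mat = np.asarray(mat)
    n_t, n_s = mat.shape
    if taxa is None:
        taxa = [("Fam", f"g{i}") for i in range(n_t)]
    if samples is None:
        samples = [f"S{j}" for j in range(n_s)]
    return GenusCountTable(pd.DataFrame(mat, index=taxon_index(taxa), columns=samples))


@pytest.fixture
def tiny_counts() -> GenusCountTable:
    """3 taxa x 4 samples (two twin pairs)."""
    return make_counts(
        [[5, 3, 8, 1], [2, 4, 0, 6], [3, 3, 2, 3]],
        taxa=[("FamA", "gA"), ("FamA", "gB"), ("FamB", "gC")],
        samples=["P1A", "P1B", "P2A", "P2B"],
    )


@pytest.fixture
def tiny_pairs() -> PairMap:
    return PairMap((("P1", "P1A", "P1B"), ("P2", "P2A", "P2B")))


@pytest.fixture
def tiny_nutrients() -> NutrientTable:
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.uniform(1, 10, size=(4, 3)),
        index=["P1A", "P1B", "P2A", "P2B"],
        columns=["PRT", "FAT", "NA"],
    )
    return NutrientTable(vals)


@pytest.fixture
def counts_tsv(tmp_path, tiny_counts):
    path = tmp_path / "counts.tsv"
    lines = ["Family;Genus\t" + "\t".join(tiny_counts.samples)]
    for (fam, gen), row in tiny_counts.counts.iterrows():
        lines.append(f"{fam};{gen}\t" + "\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path
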