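"""Published summary tables from the reference 28-pair MZ twin cohort.

The original study deposited no raw data, but its printed summary tables
are usable as inputs: the final susceptibility table (13 genera selected
out of 133, with mean intra-twin differences and Welch p-values against
the cohort grand mean MD = 0.668) and the genus-by-nutrient Spearman
matrix for the 12 environment-susceptible genera.  These feed the
``classify-table`` command and serve as worked examples for the decision
rules.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "REFERENCE_MD",
    "reference_susceptibility",
    "reference_associations",
    "REFERENCE_NUTRIENT_ORDER",
]

#: Grand mean intra-twin difference over all 28 pairs x 133 genera ("ALL" row).
REFERENCE_MD = 0.668

_SUSCEPTIBILITY_TSV = """\
family\tgenus\tmean_ITDx\tp
Lactobacillaceae\tLactobacillus\t0.380\t0.015
Bacteroidaceae\tBacteroides\t1.338\t0.000
Bifidobacteriaceae\tGardnerella\t1.073\t0.035
Lachnospiraceae\tLachnospiraceae UCG-008 group\t1.163\t0.006
Lachnospiraceae\tLachnospiraceae UCG-004 group\t1.075\t0.018
Lachnospiraceae\tLachnospiraceae ND3007 group\t1.063\t0.022
Lachnospiraceae\tLachnospiraceae FCS020 group\t1.060\t0.026
Lachnospiraceae\tRoseburia\t1.146\t0.020
Lachnospiraceae\tEubacterium hallii group\t0.987\t0.032
Lachnospiraceae\tLachnospira\t1.037\t0.041
Porphyromonadaceae\tParabacteroides\t1.064\t0.028
Ruminococcaceae\tFaecalibacterium\t1.043\t0.028
Ruminococcaceae\tRuminococcaceae UCG-003 group\t1.030\t0.038
"""

#: Nutrient column order of the published correlation matrix.
REFERENCE_NUTRIENT_ORDER = (
    "PRT", "FAT", "SFA", "CHO", "TDF", "NA", "K", "CA", "FE",
    "RTE", "VD", "ATC", "VK", "VB1", "VB2", "VB6", "VB12", "VC",
)

_ASSOCIATIONS_TSV = """\
family\tgenus\tPRT\tFAT\tSFA\tCHO\tTDF\tNA\tK\tCA\tFE\tRTE\tVD\tATC\tVK\tVB1\tVB2\tVB6\tVB12\tVC
Bacteroidaceae\tBacteroides\t0.11\t-0.10\t0.00\t0.10\t0.01\t-0.12\t-0.05\t0.27\t-0.06\t0.38\t0.12\t-0.03\t-0.07\t-0.10\t0.13\t0.00\t0.14\t-0.14
Bifidobacteriaceae\tGardnerella\t0.13\t0.02\t0.07\t-0.20\t-0.20\t0.11\t-0.14\t-0.15\t-0.21\t-0.23\t0.19\t-0.24\t-0.23\t-0.10\t-0.15\t0.01\t0.17\t-0.33
Porphyromonadaceae\tParabacteroides\t0.19\t-0.21\t0.01\t-0.08\t0.13\t0.13\t0.14\t0.16\t0.08\t-0.14\t0.28\t0.00\t-0.06\t0.09\t0.02\t0.06\t0.10\t0.19
Lachnospiraceae\tEubacterium hallii group\t-0.10\t-0.06\t-0.02\t0.08\t-0.15\t-0.17\t-0.05\t0.07\t-0.10\t0.33\t-0.21\t-0.13\t-0.18\t-0.14\t0.10\t-0.24\t-0.23\t-0.08
Lachnospiraceae\tLachnospira\t-0.38\t0.11\t0.14\t0.22\t-0.31\t-0.41\t-0.37\t-0.20\t-0.39\t0.15\t-0.63\t-0.32\t-0.25\t-0.36\t-0.10\t-0.42\t-0.49\t-0.32
Lachnospiraceae\tLachnospiraceae FCS020 group\t-0.14\t-0.19\t-0.24\t0.11\t-0.14\t-0.26\t-0.12\t-0.31\t-0.17\t-0.31\t-0.30\t-0.21\t0.07\t-0.16\t-0.18\t-0.11\t-0.29\t0.07
Lachnospiraceae\tLachnospiraceae ND3007 group\t0.16\t0.39\t0.32\t-0.28\t0.25\t-0.04\t0.12\t0.24\t0.16\t0.02\t0.00\t0.15\t0.32\t0.22\t0.12\t0.11\t0.03\t0.16
Lachnospiraceae\tLachnospiraceae UCG-004 group\t0.23\t0.13\t0.20\t-0.25\t0.14\t0.09\t0.15\t0.22\t0.14\t0.06\t0.16\t0.07\t0.18\t0.15\t0.21\t0.17\t0.13\t-0.02
Lachnospiraceae\tLachnospiraceae UCG-008 group\t-0.08\t-0.32\t-0.45\t0.12\t-0.04\t-0.20\t0.04\t-0.10\t-0.08\t0.03\t0.05\t0.05\t-0.05\t-0.02\t-0.23\t-0.04\t-0.02\t0.12
Lachnospiraceae\tRoseburia\t0.05\t-0.08\t-0.15\t0.01\t-0.03\t-0.20\t-0.04\t-0.07\t-0.02\t0.01\t-0.04\t-0.03\t-0.01\t0.03\t-0.08\t-0.06\t-0.08\t0.14
Ruminococcaceae\tFaecalibacterium\t-0.16\t0.00\t0.07\t0.16\t-0.14\t-0.10\t-0.09\t0.00\t-0.14\t-0.14\t-0.26\t-0.17\t-0.30\t-0.17\t0.02\t-0.30\t-0.31\t-0.02
Ruminococcaceae\tRuminococcaceae UCG-003 group\t-0.03\t0.17\t0.16\t-0.18\t0.09\t0.03\t0.14\t-0.02\t0.10\t-0.18\t-0.13\t0.04\t0.27\t0.17\t0.10\t0.15\t-0.11\t0.19
"""


def reference_susceptibility() -> pd.DataFrame:
    """The 13 selected genera: (family, genus) index, mean_ITDx and p columns."""
    df = pd.read_csv(
        io.StringIO(_SUSCEPTIBILITY_TSV), sep="\t", keep_default_na=False
    )
    return df.set_index(["family", "genus"])


def reference_associations() -> pd.DataFrame:
    """Published Spearman rs matrix: 12 genera x 18 nutrients."""
    df = pd.read_csv(
        io.StringIO(_ASSOCIATIONS_TSV), sep="\t", keep_default_na=False
    )
    return df.set_index(["family", "genus"]).astype(float)
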