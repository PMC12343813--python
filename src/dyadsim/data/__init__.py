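"""Packaged worked-example fixture: the 8-SNP parent/child genotype pair.

The dosage vectors are the published worked example of the similarity score
(parent 0,1,1,2,1,2,2,1 vs child 1,1,2,2,0,1,1,1 -> 3/8 = 0.375). Panel
weights, frequencies, alleles and the child's sex are synthetic placeholders:
only the dosages enter the similarity statistic.
"""

from importlib import resources
from pathlib import Path

TABLE1_PARENT = (0, 1, 1, 2, 1, 2, 2, 1)
TABLE1_CHILD = (1, 1, 2, 2, 0, 1, 1, 1)


def table1_paths() -> dict[str, Path]:
    """Paths to the packaged worked-example files (panel, genotypes, dyads)."""
    base = resources.files(__package__)
    return {
        "panel": Path(str(base / "table1_panel.tsv")),
        "genotypes": Path(str(base / "table1_genotypes.tsv")),
        "dyads": Path(str(base / "table1_dyads.csv")),
    }
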