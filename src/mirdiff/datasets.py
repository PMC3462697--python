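"""Bundled reference dataset.

The package ships the published counts/RPKM table of the 61 canonical
miRNAs detected in two whole-body small-RNA libraries of *Blattella
germanica*: the penultimate, pre-metamorphic nymphal instar (N5) and the
last, metamorphic instar (N6), each sampled around its moulting-hormone
peak. Raw reads for these libraries were never deposited, so this table is
the entry point for reproducing the published library comparison.

One row (miR-275-3p in N5) is numerically inconsistent with the
normalization implied by every other row (back-solved effective length
~8.8 nt against ~17–21 nt elsewhere) and is flagged here as a probable
typo in the source table; consistency checks exclude it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: miRNA/library cell excluded from normalization-consistency checks.
FLAGGED_INCONSISTENT = [("miR-275-3p", "N5")]


@dataclass(frozen=True)
class TwoLibraryExperiment:
    """A two-library miRNA expression table with its sequencing depths."""

    expression: pd.DataFrame  # index mirna; counts_/rpkm_ per library
    library_1: str
    library_2: str
    total_raw_reads: dict[str, int]
    total_clean_reads: dict[str, int]

    @property
    def libraries(self) -> tuple[str, str]:
        return self.library_1, self.library_2


def load_nymphal_libraries() -> TwoLibraryExperiment:
    """Load the bundled N5/N6 cockroach nymphal miRNA table (61 miRNAs)."""
    pkg = resources.files("mirdiff.data")
    with (pkg / "nymphal_expression.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="mirna")
    with (pkg / "nymphal_expression.json").open() as fh:
        meta = json.load(fh)
    return TwoLibraryExperiment(
        expression=df,
        library_1=meta["library_1"],
        library_2=meta["library_2"],
        total_raw_reads={k: int(v) for k, v in meta["total_raw_reads"].items()},
        total_clean_reads={k: int(v) for k, v in meta["total_clean_reads"].items()},
    )
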