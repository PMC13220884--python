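"""The 76-SNP variant catalog and the four reconstructed phage genotypes.

The catalog ships as a plain TSV transcribed from the published variant
table of the outbreak phage ("Theomophage", a 63,535 bp *Schitoviridae*
genome).  Each row is one SNP with its genomic position (1-based), ref/alt
alleles, predicted effect, ORF and function labels, presence flags for the
four genotypes G1-G4, a display colour matching the trajectory-linkage
groups, and observation flags per community condition (closed/open x
community type A/B).

Rows that the source table aggregates by multiplicity ("14 SNPs in
ORF0077") are expanded to placeholder positions inside the labelled ORF
with identical flags; placeholder rows are marked so.  Six placeholder
SNPs carry an explicit ``unassigned`` flag: they represent type-A-restricted
microdiversity within genotype G2 that the published table could not place
on a genotype (the genotype columns account for 70 of the 76 SNPs).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

GENOME_LENGTH = 63_535
GENOTYPE_COLUMNS = ("G1", "G2", "G3", "G4")
PRESENCE_COLUMNS = ("closed_A", "open_A", "closed_B", "open_B")


@dataclass(frozen=True)
class VariantRecord:
    """One catalogued SNP."""

    position: int
    ref: str
    alt: str
    effect: str = "Unknown"
    orf: str = "-"
    function: str = "-"

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position}")


def load_table1_catalog() -> pd.DataFrame:
    """Return the transcribed 76-SNP catalog as a DataFrame.

    Indexed by genomic position; genotype columns are 0/1 flags, presence
    columns mark the community conditions in which each SNP was observed.
    """
    with resources.files("phagetrace.data").joinpath("table1_catalog.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("position", verify_integrity=True)


def genotype_haplotypes(catalog: pd.DataFrame) -> dict[str, np.ndarray]:
    """Binary haplotype vector over the catalog for each genotype column."""
    return {g: catalog[g].to_numpy(dtype=int) for g in GENOTYPE_COLUMNS if g in catalog}


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("haplotypes differ in length")
    return int(np.sum(a != b))
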