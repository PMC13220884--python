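"""Detection and abundance metrics for a phage in shotgun metagenomes.

Covers the read-fraction and breadth-of-coverage quantities used to call a
phage present/absent across samples, plus the first-order "is this read
fraction biologically plausible" arithmetic relating a phage's share of
metagenomic nucleotides to the virion-to-host genome-copy ratio and the
burst size that ratio would require.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "relative_abundance",
    "breadth_of_coverage",
    "detection_call",
    "required_genome_ratio",
    "required_burst_size",
]


def relative_abundance(mapped_reads: int, total_reads: int) -> float:
    """Fraction of sample reads mapping to the target genome."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0 <= mapped_reads <= total_reads:
        raise ValueError("mapped_reads must be in [0, total_reads]")
    return mapped_reads / total_reads


def breadth_of_coverage(depths, min_depth: int = 1) -> float:
    """Fraction of genome positions covered by >= min_depth reads."""
    depths = np.asarray(depths)
    if depths.size == 0:
        raise ValueError("empty coverage profile")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if (depths < 0).any():
        raise ValueError("negative depths in coverage profile")
    return float(np.mean(depths >= min_depth))


def detection_call(depths, breadth_threshold: float = 0.5, min_depth: int = 1) -> bool:
    """Present iff breadth at min_depth reaches the threshold (inclusive)."""
    if not 0 <= breadth_threshold <= 1:
        raise ValueError("breadth_threshold must be in [0, 1]")
    return breadth_of_coverage(depths, min_depth) >= breadth_threshold


def required_genome_ratio(
    read_fraction: float,
    phage_genome_length: int,
    host_genome_length: int,
) -> float:
    """Phage:bacterium genome-copy ratio implied by a phage read fraction.

    With fraction ``f`` of sequenced nucleotides from a phage of genome
    length ``g_p`` and the remainder from bacteria of genome length ``g_b``
    (the first-order approximation: all non-phage reads are bacterial), the
    number of phage genome copies per bacterial genome is

        ratio = f / (1 - f) * g_b / g_p

    e.g. an outbreak at 74% of reads for a 63.5 kb phage against 4 Mb hosts
    implies a ratio of ~179 phage genomes per bacterial genome.
    """
    if not 0 <= read_fraction < 1:
        raise ValueError("read_fraction must be in [0, 1)")
    if phage_genome_length <= 0 or host_genome_length <= 0:
        raise ValueError("genome lengths must be positive")
    return (read_fraction / (1.0 - read_fraction)) * (
        host_genome_length / phage_genome_length
    )


def required_burst_size(genome_ratio: float, host_fraction: float) -> float:
    """Virions per host cell needed if only a fraction of bacteria are hosts.

    If the phage's host constitutes ``host_fraction`` of the bacterial
    community, every host-lineage cell must on average account for
    ``genome_ratio / host_fraction`` virion genome copies.
    """
    if not 0 < host_fraction <= 1:
        raise ValueError("host_fraction must be in (0, 1]")
    if genome_ratio < 0:
        raise ValueError("genome_ratio must be non-negative")
    return genome_ratio / host_fraction
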