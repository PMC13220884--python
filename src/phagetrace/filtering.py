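"""SNP-retention rules applied to raw per-sample allele-depth tables.

A sample qualifies for variant analysis when enough of the phage genome is
covered (breadth at a depth threshold); a variant enters the catalog when,
in at least one qualifying sample, its alternative-allele frequency reaches
the minimum frequency AND is supported by a minimum number of alt reads.
All thresholds are inclusive.  The output is the variant catalog plus a
samples x variants allele-frequency matrix, with frequencies masked
(missing) in non-qualifying samples and at zero-depth sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the SNP-retention filter (all inclusive boundaries)."""

    min_allele_freq: float = 0.10
    min_alt_reads: int = 4
    min_breadth_fraction: float = 0.30
    breadth_depth_threshold: int = 10

    def __post_init__(self):
        if not 0 <= self.min_allele_freq <= 1:
            raise ValueError("min_allele_freq must be in [0, 1]")
        if not 0 <= self.min_breadth_fraction <= 1:
            raise ValueError("min_breadth_fraction must be in [0, 1]")
        if self.min_alt_reads < 0 or self.breadth_depth_threshold < 0:
            raise ValueError("read-count thresholds must be >= 0")


@dataclass(frozen=True)
class AlleleObservation:
    """Read support for one variant in one sample."""

    sample: str
    position: int
    ref_depth: int
    alt_depth: int
    ref: str = "N"
    alt: str = "N"

    def __post_init__(self):
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError(
                f"negative depth at {self.sample}:{self.position}"
            )

    @property
    def depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def frequency(self) -> float:
        """alt/(ref+alt); NaN at zero depth."""
        return self.alt_depth / self.depth if self.depth else float("nan")


def qualify_samples(coverage: pd.DataFrame, params: FilterParams | None = None):
    """Samples whose breadth at the configured depth meets the threshold.

    ``coverage`` must provide a ``breadth_at_{d}x`` column (or ``breadth``)
    for the configured depth threshold, indexed by sample or with a
    ``sample`` column.
    """
    params = params or FilterParams()
    cov = coverage.set_index("sample") if "sample" in coverage.columns else coverage
    col = f"breadth_at_{params.breadth_depth_threshold}x"
    if col not in cov.columns:
        if "breadth" in cov.columns:
            col = "breadth"
        else:
            missing = list(cov.index[:1])
            raise KeyError(
                f"coverage summary lacks '{col}' (first sample: {missing})"
            )
    bad = cov.index[cov[col].isna()]
    if len(bad):
        raise ValueError(f"missing breadth for sample(s): {list(bad)}")
    return set(cov.index[cov[col] >= params.min_breadth_fraction])


def observations_to_frame(observations) -> pd.DataFrame:
    rows = [
        (o.sample, o.position, o.ref, o.alt, o.ref_depth, o.alt_depth)
        for o in observations
    ]
    return pd.DataFrame(
        rows, columns=["sample", "position", "ref", "alt", "ref_depth", "alt_depth"]
    )


def filter_variants(
    observations,
    qualifying_samples,
    params: FilterParams | None = None,
    genome_mean_depth: float | None = None,
    irregular_depth_factor: float = 5.0,
):
    """Apply the retention rules; return (catalog, allele-frequency matrix).

    A variant is retained iff some qualifying sample shows frequency
    >= min_allele_freq with >= min_alt_reads alt reads.  The matrix covers
    every input sample restricted to catalog variants; entries in
    non-qualifying samples, and zero-depth entries, are missing (NaN).

    When ``genome_mean_depth`` is given, variants whose mean site depth
    deviates from it by more than ``irregular_depth_factor`` (either way)
    are flagged ``irregular_coverage`` in the catalog — flagged for manual
    review, never removed.
    """
    params = params or FilterParams()
    if not isinstance(observations, pd.DataFrame):
        observations = observations_to_frame(observations)
    cols = ["position", "ref", "alt"]
    if observations.empty:
        catalog = pd.DataFrame(columns=cols + ["max_freq", "max_alt_reads"])
        return catalog, pd.DataFrame()
    obs = observations.copy()
    if (obs[["ref_depth", "alt_depth"]].to_numpy() < 0).any():
        raise ValueError("negative depths in observations")
    depth = obs["ref_depth"] + obs["alt_depth"]
    obs["freq"] = np.where(depth > 0, obs["alt_depth"] / depth.replace(0, 1), np.nan)
    obs.loc[depth == 0, "freq"] = np.nan

    qual = obs[obs["sample"].isin(qualifying_samples)]
    passing = qual[
        (qual["freq"] >= params.min_allele_freq)
        & (qual["alt_depth"] >= params.min_alt_reads)
    ]
    catalog = (
        passing.groupby("position", as_index=False)
        .agg(
            ref=("ref", "first"),
            alt=("alt", "first"),
            max_freq=("freq", "max"),
            max_alt_reads=("alt_depth", "max"),
        )
        .sort_values("position")
        .reset_index(drop=True)
    )
    if catalog.empty:
        return catalog, pd.DataFrame()

    kept = obs[obs["position"].isin(catalog["position"])]
    matrix = kept.pivot_table(
        index="sample", columns="position", values="freq", aggfunc="first"
    ).reindex(columns=catalog["position"].to_numpy())
    matrix = matrix.reindex(index=sorted(obs["sample"].unique()))
    matrix.loc[~matrix.index.isin(qualifying_samples)] = np.nan

    if genome_mean_depth is not None and genome_mean_depth > 0:
        site_depth = kept.groupby("position").apply(
            lambda g: (g["ref_depth"] + g["alt_depth"]).mean(), include_groups=False
        )
        ratio = site_depth.reindex(catalog["position"]).to_numpy() / genome_mean_depth
        catalog["irregular_coverage"] = (ratio > irregular_depth_factor) | (
            ratio < 1.0 / irregular_depth_factor
        )
    return catalog, matrix
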