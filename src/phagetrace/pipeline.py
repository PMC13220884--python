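"""End-to-end pipeline: simulate (optional) -> filter -> genotypes ->
decompose -> events -> report, with a manifest for reproducibility."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__, io
from .filtering import FilterParams, filter_variants, qualify_samples
from .genotypes import (
    ClonalityParams,
    cluster_trajectories,
    decompose_all,
    derive_genotypes,
    detect_clonal_samples,
    detect_novel_blocks,
    detect_recombination,
)
from .simulate import SimulationConfig, mesocosm_experiment_config, simulate_metacommunity


@dataclass
class PipelineConfig:
    """All stage parameters plus input locations.

    Either ``simulate`` is true (the synthetic metacommunity provides the
    inputs) or ``vcf``/``coverage``/``metadata`` paths must be given.
    Unknown keys in a config mapping are rejected.
    """

    simulate: bool = True
    seed: int = 0
    vcf: str | None = None
    coverage: str | None = None
    metadata: str | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    clonality: ClonalityParams = field(default_factory=ClonalityParams)
    coupling_delta: float = 0.10
    decoupling_threshold: float = 0.30
    decomposition_mode: str = "simplex_lsq"
    #: genotypes are derived only from samples at or above this mean phage
    #: depth; clonality calls on shallower samples are noise-prone
    min_genotype_depth: float = 100.0
    simulation: SimulationConfig | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if isinstance(data.get("filter_params"), dict):
            data["filter_params"] = FilterParams(**data["filter_params"])
        if isinstance(data.get("clonality"), dict):
            data["clonality"] = ClonalityParams(**data["clonality"])
        if isinstance(data.get("simulation"), dict):
            data["simulation"] = SimulationConfig(**data["simulation"])
        return cls(**data)


def augment_genotypes(genotypes, events, blocks, matrix) -> list:
    """Extend the clonal/pigeonhole genotype set with haplotypes implied by
    detected recombination events and unattributed novel blocks."""
    from .genotypes import Genotype

    out = list(genotypes)
    seen = {tuple(g.haplotype) for g in out}

    def register(hap, provenance, source):
        key = tuple(int(x) for x in hap)
        if key in seen or not any(key):
            return
        seen.add(key)
        out.append(
            Genotype(
                id=f"G{len(out) + 1}",
                haplotype=hap,
                provenance=provenance,
                source_samples=[source],
            )
        )

    for e in events:
        register(e.child_haplotype, "recombinant", f"{e.mesocosm}_w{e.first_week}")
    for b in blocks:
        if b.carrier is None:
            hap = matrix.columns.isin(b.variants).astype(int)
            register(hap, "mutational", f"block_w{b.first_week}")
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, write artifacts + manifest, return the bundle."""
    if not config.simulate and not (config.vcf and config.coverage and config.metadata):
        raise ValueError("without simulation, vcf/coverage/metadata are required")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    if config.simulate:
        sim = config.simulation or mesocosm_experiment_config(rng_seed=config.seed)
        dataset, truth = simulate_metacommunity(sim)
        io.write_truth(truth, outdir / "truth.json")
        bundle["truth"] = truth
    else:
        obs = io.read_vcf_minimal(config.vcf)
        dataset = {
            "allele_depths": io.observations_long_frame(obs),
            "coverage": io.read_tsv(config.coverage),
            "metadata": io.read_tsv(config.metadata),
        }

    qualifying = qualify_samples(dataset["coverage"], config.filter_params)
    catalog, matrix = filter_variants(
        dataset["allele_depths"], qualifying, config.filter_params
    )
    io.write_tsv(catalog, outdir / "catalog.tsv")
    io.write_matrix(matrix, outdir / "frequency_matrix.tsv")
    bundle.update(catalog=catalog, matrix=matrix, qualifying=qualifying)

    cov = dataset["coverage"]
    if "mean_depth" in cov.columns:
        deep = set(cov.loc[cov["mean_depth"] >= config.min_genotype_depth, "sample"])
        genotype_matrix = matrix.loc[matrix.index.isin(deep & qualifying)]
    else:
        genotype_matrix = matrix
    clonal = detect_clonal_samples(genotype_matrix, config.clonality)
    genotypes = (
        derive_genotypes(clonal, genotype_matrix, config.clonality) if clonal else []
    )
    groups = cluster_trajectories(matrix, delta=config.coupling_delta)
    bundle.update(clonal=clonal, genotypes=genotypes, groups=groups)

    meta = dataset["metadata"]
    events = detect_recombination(
        matrix, meta, groups, genotypes,
        delta=config.coupling_delta,
        decoupling_threshold=config.decoupling_threshold,
    )
    blocks = detect_novel_blocks(
        matrix, meta, genotypes,
        clonality=config.clonality,
        min_allele_freq=config.filter_params.min_allele_freq,
        delta=config.coupling_delta,
        observations=dataset["allele_depths"],
        support_reads=config.filter_params.min_alt_reads,
    )
    genotypes = augment_genotypes(genotypes, events, blocks, matrix)
    bundle["genotypes"] = genotypes
    abundances = (
        decompose_all(matrix, genotypes, mode=config.decomposition_mode)
        if genotypes
        else pd.DataFrame(index=matrix.index)
    )
    io.write_matrix(abundances, outdir / "genotype_abundance.tsv")
    genotype_table = pd.DataFrame(
        {g.id: g.haplotype for g in genotypes}, index=matrix.columns
    )
    genotype_table.to_csv(outdir / "genotypes.tsv", sep="\t", index_label="variant")
    bundle.update(abundances=abundances, recombination_events=events, novel_blocks=blocks)
    io.write_json(
        {
            "recombination": [
                {
                    "mesocosm": e.mesocosm,
                    "first_week": e.first_week,
                    "parents": list(e.parents),
                    "decoupled_pairs": e.decoupled_pairs,
                    "gap": e.gap,
                }
                for e in events
            ],
            "novel_blocks": [
                {
                    "variants": b.variants,
                    "first_week": b.first_week,
                    "carrier": b.carrier,
                    "n_assigned_to_carrier": sum(
                        1 for v in b.member_assignments.values() if v == b.carrier
                    ),
                }
                for b in blocks
            ],
        },
        outdir / "events.json",
    )

    report = {
        "n_samples": int(matrix.shape[0]),
        "n_qualifying_samples": len(qualifying),
        "n_variants": int(matrix.shape[1]),
        "n_clonal_samples": len(clonal),
        "n_genotypes": len(genotypes),
        "genotype_ids": [g.id for g in genotypes],
        "n_linkage_groups": len(groups),
        "n_recombination_events": len(events),
        "n_novel_blocks": len(blocks),
    }
    io.write_json(report, outdir / "report.json")
    bundle["report"] = report

    manifest = {
        "package": "phagetrace",
        "version": __version__,
        "seed": config.seed,
        "filter_params": asdict(config.filter_params),
        "clonality": asdict(config.clonality),
        "coupling_delta": config.coupling_delta,
        "decoupling_threshold": config.decoupling_threshold,
        "decomposition_mode": config.decomposition_mode,
        "min_genotype_depth": config.min_genotype_depth,
        "simulate": config.simulate,
    }
    if config.simulate:
        sim = config.simulation or mesocosm_experiment_config(rng_seed=config.seed)
        manifest["simulation"] = json.loads(
            json.dumps(asdict(sim), default=io._jsonable)
        )
    io.write_json(manifest, outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
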