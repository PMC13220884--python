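"""Ground-truthed serial-transfer metacommunity simulator.

Emulates the mesocosm experiment that produced the outbreak dataset: 10
founding compost communities, each split into a paired *closed* mesocosm
(propagated in isolation) and an *open* mesocosm that receives, at every
2-week 1/20-dilution transfer, an MGE cocktail pooled from all open
mesocosms and passed through a 0.2-um filter (so the cocktail carries phage
but no cells).  Two founder phage genotypes differ at a small set of marker
SNPs; programmed recombination events and a programmed block of novel SNPs
create derived genotypes whose spread the downstream inference stages must
recover.

Phage dynamics follow a discrete per-transfer update: hosts regrow
logistically toward carrying capacity, phage of each genotype infect
susceptible cells in proportion to genotype abundance with burst size
``beta``, free virions carry over, and 1/20 of cells+virions survives the
transfer.  Observed allele depths are binomial draws from the true
within-sample genotype mixture plus symmetric sequencing error; per-sample
depth scales with the true phage read fraction.

Everything is deterministic given the configuration seed, and the hidden
state (true genotypes, abundances, event log, read fractions) is returned
as :class:`GroundTruth` for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GENOME_LENGTH

#: marker positions of the second founder genotype in the study system
DEFAULT_MARKER_POSITIONS = (
    1276, 24224, 24375, 24378, 54689, 54853, 54856, 55320, 55814,
)

_TYPE_A_DOMINANTS = ("Rhodanobacter", "Nitrosomonas")
_TYPE_B_DOMINANTS = ("Cellvibrio", "Azospirillum")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class RecombinationSpec:
    """A programmed crossover between two coexisting genotypes.

    The child haplotype alternates parental segments at the crossover
    positions, starting with ``parents[0]``; at the event transfer a
    fraction of each parent population converts to the child, which then
    enjoys a per-transfer fitness advantage (recombinants replaced their
    parents in the study).
    """

    mesocosm: str  # community key, e.g. "3_open"
    transfer: int
    parents: tuple[str, str]
    crossovers: tuple[int, ...]
    conversion_fraction: float = 0.5
    fitness_advantage: float = 2.0
    #: restrict the advantage to mesocosms of one community type (None = all)
    advantage_community_type: str | None = None
    child_id: str | None = None

    def resolved_child_id(self) -> str:
        return self.child_id or f"R_{self.mesocosm}_t{self.transfer}"


@dataclass(frozen=True)
class NovelBlockSpec:
    """A block of novel SNPs appearing instantaneously on a carrier genotype.

    Models recombination with an unassembled rare virus as a replacement
    event: the carrier population is converted to a derived genotype that
    additionally carries ``n_snps`` alt alleles at positions drawn
    uniformly inside ``interval``.
    """

    mesocosm: str
    transfer: int
    carrier: str
    n_snps: int = 61
    interval: tuple[int, int] = (56000, 63000)
    fitness_advantage: float = 1.5  # compounds the carrier's own advantage
    advantage_community_type: str | None = None
    child_id: str | None = None

    def resolved_child_id(self) -> str:
        return self.child_id or f"M_{self.mesocosm}_t{self.transfer}"


@dataclass(frozen=True)
class SimulationConfig:
    n_mesocosms: int = 10
    community_type_assignment: dict = field(
        default_factory=lambda: {
            m: ("A" if m in {"1", "2", "5", "6"} else "B")
            for m in (str(i) for i in range(1, 11))
        }
    )
    regimes: tuple[str, ...] = ("closed", "open")
    transfer_interval_weeks: int = 2
    total_weeks: int = 48
    dilution_factor: float = 1.0 / 20.0
    sampling_weeks: tuple[int, ...] = (0, 2, 4, 6, 8, 20, 32, 40, 48)
    founder_genotype_map: dict = field(
        default_factory=lambda: {"2": "G1", "1": "G2", "5": "G2", "6": "G2"}
    )
    n_marker_snps: int = 9
    marker_positions: tuple[int, ...] | None = None
    recombination_events: tuple[RecombinationSpec, ...] = ()
    novel_block: NovelBlockSpec | None = None
    reads_per_sample: int = 1_000_000
    mean_depth_at_peak: float = 1000.0
    sequencing_error_rate: float = 0.001
    genome_length: int = GENOME_LENGTH
    host_genome_length: int = 4_000_000
    rng_seed: int = 0
    # dynamics parameters (dimensionless densities; carrying capacity = 1)
    burst_size: float = 100.0
    adsorption: float = 5.0
    host_growth: float = 6.0  # r*T of the within-cycle logistic regrowth
    susceptible_fraction: dict = field(
        default_factory=lambda: {"A": 1.0, "B": 0.1}
    )
    initial_phage: float = 0.01
    #: non-host bacterial density contributing nucleotides to each sample
    background_bacteria: float = 1.0
    include_cocktail_samples: bool = True
    # genus-count observation (community typing input)
    n_genera: int = 20
    genus_reads: int = 20_000
    dirichlet_concentration: float = 200.0

    def __post_init__(self):
        if not 0 < self.dilution_factor < 1:
            raise ConfigurationError("dilution_factor must be in (0, 1)")
        if self.reads_per_sample <= 0:
            raise ConfigurationError("reads_per_sample must be positive")
        if any(w % self.transfer_interval_weeks for w in self.sampling_weeks):
            raise ConfigurationError(
                "sampling_weeks must be multiples of transfer_interval_weeks"
            )
        if max(self.sampling_weeks, default=0) > self.total_weeks:
            raise ConfigurationError("sampling week beyond total_weeks")
        if not 0 <= self.sequencing_error_rate < 0.5:
            raise ConfigurationError("sequencing_error_rate must be in [0, 0.5)")
        for m in self.founder_genotype_map:
            if m not in self.community_type_assignment:
                raise ConfigurationError(f"founder mesocosm {m} not assigned a type")


@dataclass
class GroundTruth:
    """The simulator's hidden state, for parameter-recovery tests."""

    genotypes: dict  # id -> binary haplotype over the catalog
    positions: tuple[int, ...]
    abundances: pd.DataFrame  # sample x genotype simplex (zero rows: absent)
    phage_fraction: pd.Series  # sample -> true fraction of reads
    event_log: list  # dicts: type, mesocosm, transfer, week, details


def _logistic(h: float, growth: float) -> float:
    if h <= 0:
        return 0.0
    e = np.exp(growth)
    return h * e / (1.0 + h * (e - 1.0))


def _crossover_haplotype(hap_a, hap_b, positions, crossovers):
    """Alternate parental segments at crossover positions, starting with a."""
    child = np.empty_like(hap_a)
    cuts = sorted(crossovers)
    for i, pos in enumerate(positions):
        seg = int(np.searchsorted(cuts, pos, side="left"))
        child[i] = hap_a[i] if seg % 2 == 0 else hap_b[i]
    return child


def _build_catalog(config: SimulationConfig, rng: np.random.Generator):
    """Catalog positions + per-genotype haplotypes implied by the config."""
    if config.marker_positions is not None:
        markers = tuple(config.marker_positions)
    elif config.n_marker_snps == len(DEFAULT_MARKER_POSITIONS):
        markers = DEFAULT_MARKER_POSITIONS
    else:
        markers = tuple(
            sorted(
                rng.choice(
                    np.arange(1, config.genome_length + 1),
                    size=config.n_marker_snps,
                    replace=False,
                )
            )
        )
    block_positions: tuple[int, ...] = ()
    if config.novel_block is not None:
        lo, hi = config.novel_block.interval
        pool = np.setdiff1d(np.arange(lo, hi + 1), np.array(markers))
        if len(pool) < config.novel_block.n_snps:
            raise ConfigurationError("novel_block interval too small for n_snps")
        block_positions = tuple(
            sorted(rng.choice(pool, size=config.novel_block.n_snps, replace=False))
        )
    positions = tuple(sorted(set(markers) | set(block_positions)))
    idx = {p: i for i, p in enumerate(positions)}
    n = len(positions)
    genotypes = {"G1": np.zeros(n, dtype=int), "G2": np.zeros(n, dtype=int)}
    for p in markers:
        genotypes["G2"][idx[p]] = 1
    return positions, genotypes, set(block_positions)


def _alleles_for_positions(positions, rng: np.random.Generator):
    known = {
        1276: ("T", "G"), 24224: ("T", "C"), 24375: ("G", "A"),
        24378: ("T", "C"), 54689: ("T", "C"), 54853: ("T", "C"),
        54856: ("C", "T"), 55320: ("A", "C"), 55814: ("C", "T"),
    }
    bases = np.array(list("ACGT"))
    out = {}
    for p in positions:
        if p in known:
            out[p] = known[p]
        else:
            ref, alt = rng.choice(bases, size=2, replace=False)
            out[p] = (str(ref), str(alt))
    return out


def _genus_profiles(config: SimulationConfig, rng: np.random.Generator):
    shared = [f"genus_{i:02d}" for i in range(config.n_genera - 4)]
    genera = list(_TYPE_A_DOMINANTS) + list(_TYPE_B_DOMINANTS) + shared
    base = rng.dirichlet(np.full(len(shared), 5.0)) * 0.4
    prof = {}
    for ctype, dominants in (("A", _TYPE_A_DOMINANTS), ("B", _TYPE_B_DOMINANTS)):
        p = np.full(len(genera), 0.0)
        p[4:] = base
        for i, g in enumerate(genera[:4]):
            p[i] = 0.02  # minority presence of the other type's dominants
        for g in dominants:
            p[genera.index(g)] = 0.28
        prof[ctype] = p / p.sum()
    return genera, prof


def simulate_metacommunity(config: SimulationConfig):
    """Run the serial-transfer metacommunity; return (dataset, truth).

    ``dataset`` is a dict of DataFrames: ``allele_depths`` (long form:
    sample, position, ref, alt, ref_depth, alt_depth), ``coverage``
    (sample, mean_depth, breadth_at_1x, breadth_at_10x, phage_reads,
    total_reads), ``metadata`` (sample, mesocosm, regime, community_type,
    week) and ``genus_counts`` (samples x genera; cellular taxa only, so no
    cocktail rows).  Coverage breadths follow the Poisson depth model
    analytically.
    """
    rng = np.random.default_rng(config.rng_seed)
    positions, genotypes, block_set = _build_catalog(config, rng)
    alleles = _alleles_for_positions(positions, rng)
    genera, profiles = _genus_profiles(config, rng)
    idx = {p: i for i, p in enumerate(positions)}

    mesocosms = sorted(config.community_type_assignment, key=lambda m: (len(m), m))
    communities = [f"{m}_{r}" for m in mesocosms for r in config.regimes]
    host = {c: 1.0 for c in communities}
    phage: dict[str, dict[str, float]] = {c: {} for c in communities}
    for m, gid in config.founder_genotype_map.items():
        if gid not in genotypes:
            raise ConfigurationError(f"founder genotype {gid} undefined")
        for r in config.regimes:
            phage[f"{m}_{r}"][gid] = config.initial_phage
    advantage: dict[str, tuple[float, str | None]] = {}
    event_log: list[dict] = []

    def advantage_factor(gid: str, ctype: str) -> float:
        factor, restrict = advantage.get(gid, (1.0, None))
        return factor if restrict in (None, ctype) else 1.0

    recomb_by_transfer: dict[int, list[RecombinationSpec]] = {}
    for ev in config.recombination_events:
        recomb_by_transfer.setdefault(ev.transfer, []).append(ev)

    snapshots = []  # (sample, mesocosm, regime, ctype, week, host, {gid: p})

    def snapshot(week):
        for c in communities:
            m, r = c.rsplit("_", 1)
            snapshots.append(
                (
                    f"{c}_w{week}", m, r, config.community_type_assignment[m],
                    week, host[c], dict(phage[c]),
                )
            )

    def cocktail_pool():
        open_cs = [c for c in communities if c.endswith("_open")]
        pool: dict[str, float] = {}
        for c in open_cs:
            for gid, p in phage[c].items():
                pool[gid] = pool.get(gid, 0.0) + p / len(open_cs)
        return pool

    snapshot(0)
    n_transfers = config.total_weeks // config.transfer_interval_weeks
    for t in range(1, n_transfers + 1):
        week = t * config.transfer_interval_weeks
        # within-cycle growth and phage replication
        for c in communities:
            m, _ = c.rsplit("_", 1)
            ctype = config.community_type_assignment[m]
            sigma = config.susceptible_fraction[ctype]
            host[c] = _logistic(host[c], config.host_growth)
            ptot = sum(phage[c].values())
            if ptot > 0:
                infected = sigma * host[c] * (1.0 - np.exp(-config.adsorption * ptot))
                host[c] -= infected
                for gid in list(phage[c]):
                    share = phage[c][gid] / ptot
                    phage[c][gid] += config.burst_size * infected * share
                    phage[c][gid] *= advantage_factor(gid, ctype)
        # programmed events act on the grown, pre-dilution populations
        for ev in recomb_by_transfer.get(t, ()):
            pool = phage.get(ev.mesocosm)
            if pool is None:
                raise ConfigurationError(f"recombination event in unknown {ev.mesocosm}")
            pa, pb = ev.parents
            if pool.get(pa, 0.0) <= 0 or pool.get(pb, 0.0) <= 0:
                raise ConfigurationError(
                    f"recombination at transfer {t} in {ev.mesocosm}: "
                    f"parents {ev.parents} do not coexist"
                )
            child = ev.resolved_child_id()
            genotypes[child] = _crossover_haplotype(
                genotypes[pa], genotypes[pb], positions, ev.crossovers
            )
            moved = 0.0
            for p in (pa, pb):
                take = ev.conversion_fraction * pool[p]
                pool[p] -= take
                moved += take
            pool[child] = pool.get(child, 0.0) + moved
            advantage[child] = (ev.fitness_advantage, ev.advantage_community_type)
            event_log.append(
                {
                    "type": "recombination", "mesocosm": ev.mesocosm,
                    "transfer": t, "week": week, "parents": list(ev.parents),
                    "child": child, "crossovers": list(ev.crossovers),
                }
            )
        nb = config.novel_block
        if nb is not None and nb.transfer == t:
            pool = phage.get(nb.mesocosm)
            if pool is None or pool.get(nb.carrier, 0.0) <= 0:
                raise ConfigurationError(
                    f"novel block at transfer {t}: carrier {nb.carrier} "
                    f"absent from {nb.mesocosm}"
                )
            child = nb.resolved_child_id()
            hap = genotypes[nb.carrier].copy()
            for p in block_set:
                hap[idx[p]] = 1
            genotypes[child] = hap
            pool[child] = pool.pop(nb.carrier)
            carrier_adv, _ = advantage.get(nb.carrier, (1.0, None))
            advantage[child] = (
                carrier_adv * nb.fitness_advantage, nb.advantage_community_type
            )
            event_log.append(
                {
                    "type": "novel_block", "mesocosm": nb.mesocosm,
                    "transfer": t, "week": week, "carrier": nb.carrier,
                    "child": child, "positions": sorted(block_set),
                }
            )
        # sampling happens on the grown culture, before the transfer
        if week in config.sampling_weeks:
            snapshot(week)
            if config.include_cocktail_samples and t <= 4:
                pool = cocktail_pool()
                snapshots.append(
                    (f"cocktail_w{week}", "cocktail", "cocktail", "-", week, 0.0, pool)
                )
        # serial transfer: dilution, plus the filtered cocktail in the open regime
        pool = cocktail_pool()
        for c in communities:
            host[c] *= config.dilution_factor
            for gid in list(phage[c]):
                phage[c][gid] *= config.dilution_factor
            if c.endswith("_open"):
                for gid, p in pool.items():
                    if p > 0:
                        phage[c][gid] = (
                            phage[c].get(gid, 0.0) + config.dilution_factor * p
                        )
            phage[c] = {g: p for g, p in phage[c].items() if p > 1e-15}

    # ---- observation model -------------------------------------------------
    gp, gb = config.genome_length, config.host_genome_length
    frac = {}
    for sample, m, r, ct, week, h, pool in snapshots:
        ptot = sum(pool.values())
        bacteria = h + (config.background_bacteria if m != "cocktail" else 0.0)
        denom = ptot * gp + bacteria * gb
        frac[sample] = (ptot * gp / denom) if denom > 0 else 0.0
    # depth anchor: the deepest mesocosm sample (the filtered cocktail is
    # nearly pure phage, so it would otherwise dominate the normalisation)
    peak = max(
        (frac[s[0]] for s in snapshots if s[1] != "cocktail"), default=0.0
    )

    gids = sorted(genotypes)
    abund_rows, cov_rows, meta_rows, depth_rows = [], [], [], []
    genus_counts = {}
    eps = config.sequencing_error_rate
    for sample, m, r, ct, week, h, pool in snapshots:
        ptot = sum(pool.values())
        shares = np.array([pool.get(g, 0.0) for g in gids])
        shares = shares / ptot if ptot > 0 else shares
        abund_rows.append(shares)
        meta_rows.append((sample, m, r, ct, week))
        lam = config.mean_depth_at_peak * frac[sample] / peak if peak > 0 else 0.0
        hap_matrix = np.array([genotypes[g] for g in gids])
        true_freq = shares @ hap_matrix if ptot > 0 else np.zeros(len(positions))
        depths = rng.poisson(lam, size=len(positions))
        p_alt = true_freq * (1 - eps) + (1 - true_freq) * eps
        alts = rng.binomial(depths, p_alt)
        for p, d, a in zip(positions, depths, alts):
            ref, alt = alleles[p]
            depth_rows.append((sample, p, ref, alt, int(d - a), int(a)))
        phage_reads = int(rng.binomial(config.reads_per_sample, frac[sample]))
        cov_rows.append(
            (
                sample, lam, 1.0 - np.exp(-lam), float(stats.poisson.sf(9, lam)),
                phage_reads, config.reads_per_sample,
            )
        )
        if m != "cocktail":
            alpha = config.dirichlet_concentration * profiles[ct]
            genus_counts[sample] = rng.multinomial(
                config.genus_reads, rng.dirichlet(alpha)
            )

    dataset = {
        "allele_depths": pd.DataFrame(
            depth_rows,
            columns=["sample", "position", "ref", "alt", "ref_depth", "alt_depth"],
        ),
        "coverage": pd.DataFrame(
            cov_rows,
            columns=[
                "sample", "mean_depth", "breadth_at_1x", "breadth_at_10x",
                "phage_reads", "total_reads",
            ],
        ),
        "metadata": pd.DataFrame(
            meta_rows, columns=["sample", "mesocosm", "regime", "community_type", "week"]
        ),
        "genus_counts": pd.DataFrame.from_dict(
            genus_counts, orient="index", columns=genera
        ),
    }
    truth = GroundTruth(
        genotypes={g: genotypes[g].tolist() for g in gids},
        positions=positions,
        abundances=pd.DataFrame(
            abund_rows, index=[s[0] for s in snapshots], columns=gids
        ),
        phage_fraction=pd.Series(frac),
        event_log=event_log,
    )
    return dataset, truth


def mesocosm_experiment_config(rng_seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-like scenario: two founder genotypes, one
    recombinant arising in a type-A open mesocosm, one recombinant plus a
    61-SNP novel block arising after invasion of a type-B open mesocosm."""
    events = (
        # pink-only recombinant (HNH-endonuclease segment from G2 on a G1
        # background); sweeps its native community type
        RecombinationSpec(
            mesocosm="6_open", transfer=4, parents=("G1", "G2"),
            crossovers=(24000, 24400), child_id="G3",
            advantage_community_type="A",
        ),
        # blue-carrying recombinant on a mostly-G1 background; immediately
        # acquires the novel block below, so the intermediate never spreads
        RecombinationSpec(
            mesocosm="3_open", transfer=3, parents=("G2", "G1"),
            crossovers=(2000, 55700), child_id="G4pre",
            advantage_community_type="B",
        ),
    )
    block = NovelBlockSpec(
        mesocosm="3_open", transfer=3, carrier="G4pre", n_snps=61,
        interval=(56000, 63000), child_id="G4",
        advantage_community_type="B",
    )
    cfg = SimulationConfig(
        recombination_events=events, novel_block=block, rng_seed=rng_seed
    )
    return replace(cfg, **overrides) if overrides else cfg
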