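"""Genotype reconstruction from longitudinal allele-frequency matrices.

Short reads cannot phase SNPs directly, but a longitudinal design offers
two substitutes for physical linkage:

* **near-clonal samples** — samples in which every catalogued site is near
  fixation (>0.97) or near absence (<0.03) expose a complete haplotype of
  the single dominant genotype;
* **trajectory linkage** — SNPs whose allele-frequency trajectories move
  together across samples reside on the same genome; in a sample where
  several variants each exceed frequency f, the pigeonhole principle puts
  a lower bound max(0, sum(f_i) - (k-1)) on the fraction of genomes
  carrying all of them at once.

Mixed samples are then decomposed over the reconstructed genotypes (the
published marker-group averaging recipe, or a simplex-constrained least
squares), decoupling of previously linked trajectory groups is read as
recombination, and novel SNPs absent from every founding/closed sample are
collected into blocks and attributed to the genotype whose abundance
trajectory they shadow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

_UNMERGEABLE = 9.0  # larger than any |f_u - f_v|; pairs with <2 co-observations
_PALETTE = (
    "blue", "pink", "green", "yellow", "orange", "purple",
    "red", "teal", "brown", "olive",
)


@dataclass(frozen=True)
class ClonalityParams:
    high_threshold: float = 0.97
    low_threshold: float = 0.03
    high_freq_linkage_threshold: float = 0.8

    def __post_init__(self):
        if not 0 <= self.low_threshold < self.high_threshold <= 1:
            raise ValueError("require 0 <= low < high <= 1")


@dataclass
class Genotype:
    """A binary haplotype over the variant catalog, with provenance."""

    id: str
    haplotype: np.ndarray
    provenance: str = "founder"  # reference|founder|recombinant|mutational|pigeonhole
    source_samples: list = field(default_factory=list)
    cooccurrence_bound: float | None = None

    def __post_init__(self):
        self.haplotype = np.asarray(self.haplotype, dtype=int)

    @property
    def is_reference(self) -> bool:
        return not self.haplotype.any()


@dataclass
class LinkageGroup:
    """SNPs whose trajectories move together; id doubles as display colour."""

    id: str
    members: list
    representative: pd.Series  # per-sample mean frequency of members


@dataclass
class RecombinationEvent:
    mesocosm: str
    first_week: int
    parents: tuple
    child_id: str
    child_haplotype: np.ndarray
    decoupled_pairs: list
    gap: float
    #: earliest event producing this child haplotype; later decouplings with
    #: the same child are arrivals of an existing genotype by migration
    primary: bool = True


@dataclass
class NovelBlock:
    variants: list
    first_week: int
    carrier: str | None  # None -> new mutational genotype
    member_assignments: dict  # variant -> carrier id or None
    distance: float


# ---------------------------------------------------------------------------
# clonal samples and genotype derivation


def detect_clonal_samples(matrix: pd.DataFrame, params: ClonalityParams | None = None):
    """Samples in which every catalog frequency is >high or <low.

    Returns ``[(sample, haplotype)]`` with the implied binary haplotype
    (1 where frequency exceeds the high threshold).  Samples with any
    missing entry are never called clonal.
    """
    params = params or ClonalityParams()
    out = []
    for sample, row in matrix.iterrows():
        f = row.to_numpy(dtype=float)
        if np.isnan(f).any():
            continue
        if np.all((f > params.high_threshold) | (f < params.low_threshold)):
            out.append((sample, (f > params.high_threshold).astype(int)))
    return out


def cooccurrence_lower_bound(frequencies) -> float:
    """Pigeonhole lower bound on the fraction of genomes carrying all k
    variants: max(0, sum(f) - (k - 1))."""
    f = np.asarray(list(frequencies), dtype=float)
    if f.size == 0:
        raise ValueError("need at least one frequency")
    if ((f < 0) | (f > 1)).any():
        raise ValueError("frequencies must be in [0, 1]")
    return float(max(0.0, f.sum() - (f.size - 1)))


def derive_genotypes(
    clonal,
    matrix: pd.DataFrame | None = None,
    params: ClonalityParams | None = None,
):
    """Deduplicate clonal haplotypes into genotypes; add pigeonhole proposals.

    Clonal haplotypes sharing the same allele pattern collapse into a
    single genotype listing every source sample.  If ``matrix`` is given,
    each fully observed non-clonal sample in which >= 2 variants all exceed
    the high-frequency linkage threshold proposes an additional genotype
    carrying exactly those variants (the pigeonhole co-occurrence bound
    must be positive); such proposals carry provenance "pigeonhole" and
    record the bound.
    """
    params = params or ClonalityParams()
    if not clonal:
        raise ValueError("need at least one clonal haplotype")
    genotypes: list[Genotype] = []
    seen: dict[tuple, Genotype] = {}

    def register(hap, sample, provenance, bound=None):
        key = tuple(int(x) for x in hap)
        if key in seen:
            seen[key].source_samples.append(sample)
            return seen[key]
        g = Genotype(
            id=f"G{len(seen) + 1}",
            haplotype=np.asarray(hap, dtype=int),
            provenance="reference" if not any(key) else provenance,
            source_samples=[sample],
            cooccurrence_bound=bound,
        )
        seen[key] = g
        genotypes.append(g)
        return g

    for sample, hap in clonal:
        register(hap, sample, "founder")

    if matrix is not None:
        clonal_names = {s for s, _ in clonal}
        thr = params.high_freq_linkage_threshold
        for sample, row in matrix.iterrows():
            if sample in clonal_names:
                continue
            f = row.to_numpy(dtype=float)
            if np.isnan(f).any():
                continue
            high = f > thr
            if high.sum() < 2:
                continue
            # any two variants above the threshold must co-occur (pairwise
            # bound 2*thr - 1 > 0); the k-wise bound is reported but can
            # reach 0 for large marker sets
            bound = cooccurrence_lower_bound(f[high])
            register(high.astype(int), sample, "pigeonhole", bound)
    return genotypes


# ---------------------------------------------------------------------------
# trajectory clustering


def trajectory_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """d(u, v) = max over co-observed samples of |f_u - f_v|.

    Variant pairs with fewer than two co-observed samples get a sentinel
    distance that no cut threshold reaches, so they are never merged.
    """
    X = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n = X.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[:, i] & obs[:, j]
            if both.sum() < 2:
                d = _UNMERGEABLE
            else:
                d = float(np.max(np.abs(X[both, i] - X[both, j])))
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=matrix.columns, columns=matrix.columns)


def cluster_trajectories(matrix: pd.DataFrame, delta: float = 0.10):
    """Partition variants into linkage groups by trajectory similarity.

    Complete-linkage agglomeration on the max-abs-difference distance,
    cut at the coupling tolerance ``delta``; every member of a group stays
    within ``delta`` of every other on co-observed samples.  Group ids are
    display colours assigned in genomic order.
    """
    variants = list(matrix.columns)
    if not variants:
        return []
    if len(variants) == 1:
        labels = np.array([1])
    else:
        D = trajectory_distance_matrix(matrix)
        Z = linkage(squareform(D.to_numpy(), checks=False), method="complete")
        labels = fcluster(Z, t=delta, criterion="distance")
    groups = []
    order = {}
    for v, lab in zip(variants, labels):
        order.setdefault(lab, []).append(v)
    sorted_labels = sorted(order, key=lambda lab: min(order[lab]))
    for rank, lab in enumerate(sorted_labels):
        members = order[lab]
        name = _PALETTE[rank] if rank < len(_PALETTE) else f"group_{rank + 1}"
        rep = matrix[members].mean(axis=1, skipna=True)
        groups.append(LinkageGroup(id=name, members=members, representative=rep))
    return groups


# ---------------------------------------------------------------------------
# mixture decomposition


def _simplex_nnls(H: np.ndarray, f: np.ndarray, weight: float = 100.0) -> np.ndarray:
    """Non-negative least squares with a soft sum-to-one constraint,
    renormalised to an exact simplex."""
    A = np.vstack([H.T, weight * np.ones(H.shape[0])])
    b = np.concatenate([f, [weight]])
    a, _ = nnls(A, b)
    total = a.sum()
    return a / total if total > 0 else np.full(H.shape[0], 1.0 / H.shape[0])


def decompose_sample(
    frequencies: pd.Series,
    genotypes,
    mode: str = "simplex_lsq",
    presence_delta: float = 0.10,
    complement_tolerance: float = 0.05,
) -> pd.Series:
    """Genotype fractions explaining one sample's allele frequencies.

    ``simplex_lsq`` fits f ~ H a with a on the probability simplex (H the
    genotype x variant alt-allele matrix).  ``paper_averaging`` follows the
    published recipe: each non-reference genotype's abundance is the mean
    frequency of the marker variants exclusive to it among the genotypes
    present in the sample (presence judged by exclusive markers exceeding
    ``presence_delta``), and the reference genotype absorbs the remainder;
    when some present genotype has no exclusive marker the sharing is
    ambiguous and the simplex fit is used instead.  A complement more
    negative than ``complement_tolerance`` raises a warning before
    clipping.  Both modes return an exact simplex.
    """
    if not genotypes:
        raise ValueError("genotype set is empty")
    f_all = frequencies.to_numpy(dtype=float)
    obs = ~np.isnan(f_all)
    if not obs.any():
        raise ValueError("sample has no observed frequencies")
    f = f_all[obs]
    ids = [g.id for g in genotypes]
    H_full = np.array([g.haplotype for g in genotypes], dtype=float)
    if H_full.shape[1] != f_all.size:
        raise ValueError("haplotype length does not match the variant set")
    H = H_full[:, obs]
    if not any(g.is_reference for g in genotypes):
        ids = ids + ["REF"]
        H = np.vstack([H, np.zeros(H.shape[1])])
        H_full = np.vstack([H_full, np.zeros(H_full.shape[1])])

    if mode == "simplex_lsq":
        return pd.Series(_simplex_nnls(H, f), index=ids)
    if mode != "paper_averaging":
        raise ValueError(f"unknown mode {mode!r}")

    nonref = [i for i in range(len(ids)) if H[i].any()]
    ref_rows = [i for i in range(len(ids)) if not H[i].any()]
    present = list(nonref)
    estimates = dict.fromkeys(range(len(ids)), 0.0)
    for _ in range(len(nonref) + 1):
        excl = {}
        for i in present:
            others = [j for j in present if j != i]
            mask = H[i] == 1
            if others:
                mask &= H[others].sum(axis=0) == 0
            excl[i] = mask
        if any(not m.any() for m in excl.values()):
            return pd.Series(_simplex_nnls(H, f), index=ids)
        est = {i: float(f[excl[i]].mean()) for i in present}
        still = [i for i in present if est[i] > presence_delta]
        if still == present:
            estimates.update(est)
            break
        for i in present:
            estimates[i] = est[i] if i in still else 0.0
        present = still
        if not present:
            break
    a = np.array([max(0.0, estimates[i]) for i in range(len(ids))])
    remainder = 1.0 - a.sum()
    if remainder < -complement_tolerance:
        warnings.warn(
            f"marker averaging overshoots the simplex by {-remainder:.3f}",
            stacklevel=2,
        )
    if ref_rows:
        a[ref_rows[0]] = max(0.0, remainder)
    total = a.sum()
    if total > 0:
        a = a / total
    return pd.Series(a, index=ids)


def decompose_all(
    matrix: pd.DataFrame, genotypes, mode: str = "simplex_lsq", **kwargs
) -> pd.DataFrame:
    """Per-sample genotype abundance table (rows: samples on the simplex;
    samples with no observed frequency become all-NaN rows)."""
    rows = {}
    for sample, row in matrix.iterrows():
        if row.isna().all():
            rows[sample] = None
            continue
        rows[sample] = decompose_sample(row, genotypes, mode=mode, **kwargs)
    ids = [g.id for g in genotypes]
    if not any(g.is_reference for g in genotypes):
        ids = ids + ["REF"]
    out = pd.DataFrame(index=matrix.index, columns=ids, dtype=float)
    for sample, series in rows.items():
        if series is not None:
            out.loc[sample] = series
    return out


# ---------------------------------------------------------------------------
# recombination and novel-mutation blocks


def _group_trajectories(matrix: pd.DataFrame, groups, samples) -> pd.DataFrame:
    cols = {}
    for g in groups:
        members = [m for m in g.members if m in matrix.columns]
        cols[g.id] = matrix.loc[samples, members].mean(axis=1, skipna=True)
    return pd.DataFrame(cols)


def detect_recombination(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    groups,
    genotypes=None,
    delta: float = 0.10,
    decoupling_threshold: float = 0.30,
):
    """Scan each mesocosm for decoupling of previously linked groups.

    Two linkage groups are coupled while their mean trajectories stay
    within ``delta``.  An event is emitted at the first sampled week where
    their gap exceeds ``decoupling_threshold``, provided at some earlier
    week both groups were simultaneously segregating (each frequency in
    (delta, 1 - delta)) and not yet decoupled — i.e. both parent genotypes
    were present before the trajectories diverged.  The child haplotype is
    proposed by rounding the frequencies at the event week; decoupled
    pairs sharing a mesocosm and week merge into a single event.
    """
    meta = metadata.set_index("sample") if "sample" in metadata.columns else metadata
    events: dict[tuple, RecombinationEvent] = {}
    for (mes, regime), sub in meta.groupby(["mesocosm", "regime"], sort=True):
        samples = [s for s in sub.sort_values("week").index if s in matrix.index]
        if len(samples) < 2:
            continue
        weeks = sub.loc[samples, "week"].to_numpy()
        traj = _group_trajectories(matrix, groups, samples)
        key = f"{mes}_{regime}" if regime not in str(mes) else str(mes)
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                a = traj[ga.id].to_numpy(dtype=float)
                b = traj[gb.id].to_numpy(dtype=float)
                both = ~np.isnan(a) & ~np.isnan(b)
                gap = np.abs(a - b)
                hit = None
                for k in np.flatnonzero(both):
                    if gap[k] > decoupling_threshold:
                        hit = k
                        break
                if hit is None:
                    continue
                earlier = [
                    k
                    for k in np.flatnonzero(both)
                    if k < hit
                    and delta < a[k] < 1 - delta
                    and delta < b[k] < 1 - delta
                    and gap[k] <= decoupling_threshold
                ]
                if not earlier:
                    continue
                week = int(weeks[hit])
                sample_at = samples[hit]
                child_hap = (
                    matrix.loc[sample_at].to_numpy(dtype=float) >= 0.5
                ).astype(int)
                parents = _match_parents(ga, gb, genotypes, matrix.columns)
                ekey = (key, week)
                if ekey not in events:
                    events[ekey] = RecombinationEvent(
                        mesocosm=key,
                        first_week=week,
                        parents=parents,
                        child_id=f"child_{key}_w{week}",
                        child_haplotype=child_hap,
                        decoupled_pairs=[],
                        gap=float(gap[hit]),
                    )
                ev = events[ekey]
                ev.decoupled_pairs.append((ga.id, gb.id))
                ev.gap = max(ev.gap, float(gap[hit]))
    ordered = sorted(events.values(), key=lambda e: (e.first_week, e.mesocosm))
    seen_children: set[tuple] = set()
    for ev in ordered:
        key = tuple(ev.child_haplotype)
        ev.primary = key not in seen_children
        seen_children.add(key)
    return ordered


def _match_parents(ga, gb, genotypes, variant_index):
    if not genotypes:
        return (None, None)
    pos = {v: i for i, v in enumerate(variant_index)}
    members = [pos[m] for m in ga.members + gb.members if m in pos]
    carrier = absent = None
    for g in genotypes:
        sub = g.haplotype[members]
        if carrier is None and sub.all():
            carrier = g.id
        if absent is None and not sub.any():
            absent = g.id
    return (carrier, absent)


def detect_novel_blocks(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    genotypes,
    clonality: ClonalityParams | None = None,
    min_allele_freq: float = 0.10,
    delta: float = 0.10,
    observations: pd.DataFrame | None = None,
    support_reads: int = 4,
):
    """Collect SNPs absent from all founding/closed samples and attribute
    them to the genotype whose abundance trajectory they shadow.

    Candidates must stay below the clonality low threshold in every closed
    or week-0 sample yet reach ``min_allele_freq`` somewhere later.  When
    the long-form allele-depth table is supplied, baseline presence also
    requires ``support_reads`` alt reads, so a stray error read in a
    shallow baseline sample does not disqualify a genuinely novel SNP (the
    same read-support rule the retention filter applies).  Candidates
    are clustered by trajectory; each cluster is compared, over the
    samples from its first appearance onward, against every genotype's
    abundance trajectory (simplex least squares on the non-candidate
    variants).  A cluster within ``delta`` of a genotype is assigned to
    it; otherwise it founds a new genotype of provenance "mutational".
    """
    clonality = clonality or ClonalityParams()
    meta = metadata.set_index("sample") if "sample" in metadata.columns else metadata
    meta = meta.loc[[s for s in meta.index if s in matrix.index]]
    baseline = meta[(meta["regime"] == "closed") | (meta["week"] == 0)]
    baseline = baseline[baseline["mesocosm"].astype(str) != "cocktail"]
    base_rows = matrix.loc[matrix.index.intersection(baseline.index)]

    supported = None
    if observations is not None:
        sup = observations[observations["alt_depth"] >= support_reads]
        supported = set(zip(sup["sample"], sup["position"]))

    candidates = []
    for v in matrix.columns:
        base = base_rows[v].dropna()
        present = base[base >= clonality.low_threshold]
        if supported is not None:
            present = present[[(s, v) in supported for s in present.index]]
        if len(present):
            continue
        if matrix[v].max(skipna=True) >= min_allele_freq:
            candidates.append(v)
    if not candidates:
        return []

    weeks = meta["week"]
    backbone = [v for v in matrix.columns if v not in candidates]
    abund = None
    if genotypes and backbone:
        sub_genotypes = [
            Genotype(
                id=g.id,
                haplotype=g.haplotype[[matrix.columns.get_loc(v) for v in backbone]],
                provenance=g.provenance,
            )
            for g in genotypes
        ]
        abund = decompose_all(matrix[backbone], sub_genotypes, mode="simplex_lsq")

    blocks = []
    for cluster in cluster_trajectories(matrix[candidates], delta=delta):
        rep = cluster.representative
        first_week = None
        for s in rep.index:
            if s in weeks.index and rep[s] >= min_allele_freq:
                w = int(weeks[s])
                first_week = w if first_week is None else min(first_week, w)
        if first_week is None:
            continue
        window = [
            s for s in rep.index if s in weeks.index and weeks[s] >= first_week
        ]
        carrier, dist = None, np.inf
        assignments = {}
        if abund is not None:
            # attribution uses the mean-abs distance: the max metric used
            # for coupling is dominated by single-sample binomial noise at
            # moderate depths, while the mean averages it out
            for g in genotypes:
                if g.is_reference:
                    continue
                d = _mean_abs(rep[window], abund.loc[window, g.id])
                if d < dist:
                    carrier, dist = g.id, d
            if dist > delta:
                carrier = None
            for v in cluster.members:
                best, bd = None, np.inf
                for g in genotypes:
                    if g.is_reference:
                        continue
                    d = _mean_abs(matrix.loc[window, v], abund.loc[window, g.id])
                    if d < bd:
                        best, bd = g.id, d
                assignments[v] = best if bd <= delta else None
        blocks.append(
            NovelBlock(
                variants=list(cluster.members),
                first_week=first_week,
                carrier=carrier,
                member_assignments=assignments,
                distance=float(dist) if np.isfinite(dist) else float("nan"),
            )
        )
    return blocks


def _max_abs(a: pd.Series, b: pd.Series) -> float:
    x = a.to_numpy(dtype=float)
    y = b.reindex(a.index).to_numpy(dtype=float)
    both = ~np.isnan(x) & ~np.isnan(y)
    if not both.any():
        return np.inf
    return float(np.max(np.abs(x[both] - y[both])))


def _mean_abs(a: pd.Series, b: pd.Series) -> float:
    x = a.to_numpy(dtype=float)
    y = b.reindex(a.index).to_numpy(dtype=float)
    both = ~np.isnan(x) & ~np.isnan(y)
    if not both.any():
        return np.inf
    return float(np.mean(np.abs(x[both] - y[both])))


# ---------------------------------------------------------------------------
# catalog accounting


def summarize_catalog(
    catalog: pd.DataFrame,
    genotype_cols=("G1", "G2", "G3", "G4"),
    presence_cols=("closed_A", "open_A", "closed_B", "open_B"),
    cluster_orfs=("0080", "0081", "0082"),
) -> dict:
    """Accounting report over a flagged variant catalog.

    Expects 0/1 genotype columns, optional per-condition presence flags,
    an optional ``unassigned`` flag, and optional ``orf`` labels.  Reports
    totals, per-genotype marker counts, the fraction of SNPs assigned to
    any genotype, community-type-exclusive counts, per-ORF counts, and the
    number of novel (derived-genotype-only) SNPs falling in the genomic
    span of the ``cluster_orfs`` gene cluster.
    """
    n = len(catalog)
    report: dict = {"total_snps": n}
    gcols = [g for g in genotype_cols if g in catalog.columns]
    unassigned = (
        catalog["unassigned"].astype(bool)
        if "unassigned" in catalog.columns
        else pd.Series(False, index=catalog.index)
    )
    assigned = catalog[gcols].any(axis=1) & ~unassigned if gcols else ~unassigned
    report["per_genotype"] = {
        g: int((catalog[g].astype(bool) & ~unassigned).sum()) for g in gcols
    }
    report["assigned_count"] = int(assigned.sum())
    report["assigned_pct"] = round(100.0 * assigned.sum() / n, 1) if n else 0.0

    if all(c in catalog.columns for c in presence_cols):
        inA = catalog[["closed_A", "open_A"]].any(axis=1)
        inB = catalog[["closed_B", "open_B"]].any(axis=1)
        report["per_condition"] = {
            c: int(catalog[c].sum()) for c in presence_cols
        }
        report["type_A_exclusive_count"] = int((inA & ~inB).sum())
        report["type_B_exclusive_count"] = int((inB & ~inA).sum())
        report["type_B_exclusive_pct"] = (
            round(100.0 * (inB & ~inA).sum() / n, 1) if n else 0.0
        )

    if "orf" in catalog.columns:
        report["per_orf"] = (
            catalog.groupby("orf").size().sort_index().to_dict()
        )
        if gcols and cluster_orfs:
            in_cluster = catalog["orf"].isin(cluster_orfs)
            if in_cluster.any():
                lo = catalog.index[in_cluster].min()
                hi = catalog.index[in_cluster].max()
                span = (catalog.index >= lo) & (catalog.index <= hi)
                novel = assigned & ~catalog.get(
                    "G2", pd.Series(0, index=catalog.index)
                ).astype(bool)
                if "G4" in catalog.columns:
                    novel &= catalog["G4"].astype(bool)
                report["novel_snp_count"] = int(novel.sum())
                report["cluster_novel_snp_count"] = int((novel & span).sum())
    return report
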