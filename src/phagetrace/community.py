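"""Genus-level community composition: CLR transform, community typing,
Bray-Curtis dissimilarity, and resilience of composition to phage outbreaks.

The mesocosms fall into two alternative stable genus-level compositions
(type A, *Rhodanobacter*-dominated, vs type B, *Cellvibrio*-dominated).
Typing reduces a PCA of CLR-transformed genus counts to a transparent
largest-gap partition along the first principal axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from scipy.stats import rankdata
from sklearn.decomposition import PCA


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of a samples x genera count matrix.

    Zeros are handled by adding ``pseudocount`` to every count before the
    log; each row is centered on its mean log so rows sum to 0.
    """
    if counts.shape[1] < 1:
        raise ValueError("need at least one genus")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    logs = np.log(counts.to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


@dataclass
class CommunityTyping:
    """Two-way community typing along the first principal axis."""

    types: dict  # mesocosm -> "A" | "B"
    pc1_scores: pd.Series  # per sample
    mesocosm_means: pd.Series  # per mesocosm, sorted along PC1
    gap: float  # largest gap between consecutive mesocosm means
    gap_fraction: float  # gap relative to the PC1 span of mesocosm means
    stable: bool  # False when the gap does not dominate the spread
    top_genera: dict = field(default_factory=dict)  # axis -> list of genera
    explained_variance_ratio: tuple = ()


def assign_community_types(
    clr: pd.DataFrame,
    sample_mesocosm: pd.Series | None = None,
    min_gap_fraction: float = 0.7,
    n_top: int = 10,
) -> CommunityTyping:
    """Partition mesocosms into two community types along PC1.

    Samples are projected on the first principal axis of the CLR matrix;
    mesocosm means along PC1 are split at the midpoint of the largest gap
    between consecutive means.  The partition is flagged unstable when that
    gap is less than ``min_gap_fraction`` of the PC1 span: with genuine
    two-cluster structure the between-cluster gap consumes most of the
    span, whereas order statistics of unstructured means leave it well
    below half.  Type "A" is the group containing the first mesocosm in
    sorted label order, so labels are deterministic but arbitrary: compare
    partitions, not label strings, against external truth.
    """
    if sample_mesocosm is None:
        sample_mesocosm = pd.Series(clr.index, index=clr.index)
    mesocosms = pd.unique(sample_mesocosm)
    if len(mesocosms) < 2:
        raise ValueError("need >= 2 mesocosms to partition")
    X = clr.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate (rank-0) CLR matrix")
    n_comp = min(2, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    pc1 = pd.Series(scores[:, 0], index=clr.index)

    means = pc1.groupby(sample_mesocosm.reindex(clr.index)).mean().sort_values()
    diffs = means.diff().dropna()
    gap = float(diffs.max()) if len(diffs) else 0.0
    span = float(means.iloc[-1] - means.iloc[0])
    gap_fraction = gap / span if span > 0 else 0.0
    cut = means.index.get_loc(diffs.idxmax()) if len(diffs) else 1
    low = set(means.index[:cut])
    first = sorted(str(m) for m in means.index)[0]
    a_side_low = any(str(m) == first for m in low)
    types = {
        m: ("A" if (m in low) == a_side_low else "B") for m in means.index
    }

    top = {}
    for axis in range(pca.n_components_):
        load = pd.Series(np.abs(pca.components_[axis]), index=clr.columns)
        top[f"PC{axis + 1}"] = list(load.sort_values(ascending=False).index[:n_top])
    return CommunityTyping(
        types=types,
        pc1_scores=pc1,
        mesocosm_means=means,
        gap=gap,
        gap_fraction=gap_fraction,
        stable=gap_fraction >= min_gap_fraction,
        top_genera=top,
        explained_variance_ratio=tuple(pca.explained_variance_ratio_),
    )


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/sum(a+b) on abundance vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must share the genus set")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("both vectors are all-zero")
    return float(braycurtis(a, b))


def outbreak_resilience_test(
    series: dict,
    outbreak_windows: dict,
) -> dict:
    """Compare compositional shifts across outbreaks with control shifts.

    ``series`` maps mesocosm -> DataFrame of relative abundances indexed by
    week (rows) over a shared genus set; ``outbreak_windows`` maps outbreak
    mesocosms to (start_week, end_week).  For each outbreak window the
    Bray-Curtis dissimilarity between the compositions at its endpoints is
    computed; control dissimilarities come from week pairs of the same span
    in mesocosms without outbreaks (falling back to the nearest available
    span).  A rank-based comparison (rank-sum of the outbreak values in the
    pooled ranking, plus the fraction of outbreak>control pairs) is reported
    descriptively; no p-value is attached.
    """
    if not outbreak_windows:
        raise ValueError("need at least one outbreak window")
    controls = [m for m in series if m not in outbreak_windows]
    if not controls:
        raise ValueError("need at least one control mesocosm")

    outbreak_d = {}
    spans = []
    for m, (w0, w1) in outbreak_windows.items():
        df = series[m]
        if w0 not in df.index or w1 not in df.index:
            raise ValueError(f"mesocosm {m}: weeks {w0}/{w1} not sampled")
        outbreak_d[m] = bray_curtis(df.loc[w0], df.loc[w1])
        spans.append(w1 - w0)

    control_d = []
    for m in controls:
        weeks = sorted(series[m].index)
        pairs = [
            (a, b)
            for i, a in enumerate(weeks)
            for b in weeks[i + 1 :]
            if (b - a) in spans
        ]
        if not pairs:  # fall back to the closest available span
            target = min(spans)
            best = None
            for i, a in enumerate(weeks):
                for b in weeks[i + 1 :]:
                    key = abs((b - a) - target)
                    if best is None or key < best[0]:
                        best = (key, a, b)
            pairs = [(best[1], best[2])] if best else []
        for a, b in pairs:
            control_d.append(bray_curtis(series[m].loc[a], series[m].loc[b]))
    if not control_d:
        raise ValueError("no matched control windows")

    ob = np.array(list(outbreak_d.values()))
    ct = np.array(control_d)
    pooled = rankdata(np.concatenate([ob, ct]))
    rank_sum = float(pooled[: len(ob)].sum())
    exceed = float(np.mean(ob[:, None] > ct[None, :]))
    return {
        "outbreak": outbreak_d,
        "control": control_d,
        "rank_sum": rank_sum,
        "exceedance_fraction": exceed,
        "outbreak_within_control_range": bool(ob.max() <= ct.max()),
    }
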