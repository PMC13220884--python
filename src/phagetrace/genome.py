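"""Sequence-level completeness and taxonomy checks for phage assemblies.

A complete linear phage genome assembled from replication concatemers shows
direct terminal repeats (DTRs), and independent assemblies of the same
genome are circular permutations of each other.  Taxonomic rank demarcation
follows the ICTV intergenomic-similarity thresholds for *Schitoviridae*
(species >= 95%, genus >= 70%, subfamily >= 40%).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

ALPHABET = set("ACGTN")

#: ICTV rank demarcation thresholds (percent intergenomic similarity).
ICTV_THRESHOLDS = {"species": 95.0, "genus": 70.0, "subfamily": 40.0}

#: Identity contract: global (Needleman-Wunsch) edit distance with unit
#: costs, normalised by the longer sequence — identity is then unique,
#: whereas matches/columns differs between co-optimal alignments.
ALIGN_SCORING = {"mode": "NW", "match": 0, "mismatch": 1, "gap": 1}


@dataclass(frozen=True)
class GenomeSequence:
    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(f"{self.id}: illegal characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def _seq(x) -> str:
    return x.sequence if isinstance(x, GenomeSequence) else str(x).upper()


def detect_dtr(seq, min_len: int = 20) -> int:
    """Length of the longest exact direct terminal repeat, or 0.

    Returns the largest k with min_len <= k <= floor(L/2) such that the
    k-bp prefix equals the k-bp suffix.  The L/2 cap keeps the two repeat
    copies disjoint.
    """
    s = _seq(seq)
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if len(s) < 2 * min_len:
        raise ValueError(f"sequence length {len(s)} < 2 x min_len {min_len}")
    for k in range(len(s) // 2, min_len - 1, -1):
        if s[:k] == s[-k:]:
            return k
    return 0


def is_circular_permutation(a, b) -> bool:
    """True iff b is a rotation of a (equal lengths, substring of a+a)."""
    sa, sb = _seq(a), _seq(b)
    if len(sa) != len(sb):
        return False
    if len(sa) == 0:
        return True
    return sb in sa + sa


def rotate(seq, offset: int) -> str:
    s = _seq(seq)
    offset %= len(s)
    return s[offset:] + s[:offset]


def _global_identity(a: str, b: str) -> float:
    distance = edlib.align(a, b, mode=ALIGN_SCORING["mode"])["editDistance"]
    return 100.0 * (1.0 - distance / max(len(a), len(b)))


def _candidate_rotations(a: str, b: str, seed_len: int, n_seeds: int) -> set[int]:
    """Rotation offsets of b suggested by exact seed k-mers taken from a."""
    doubled = b + b
    offsets = {0}
    step = max(1, len(a) // n_seeds)
    for start in range(0, max(1, len(a) - seed_len + 1), step):
        seed = a[start : start + seed_len]
        if len(seed) < seed_len:
            break
        hit = doubled.find(seed)
        while hit != -1 and hit < len(b):
            offsets.add((hit - start) % len(b))
            hit = doubled.find(seed, hit + 1)
    return offsets


def pairwise_identity(a, b, rotation_invariant: bool = False,
                      seed_len: int = 16, n_seeds: int = 8) -> float:
    """Percent identity from a global alignment (optionally over rotations).

    Identity is 100 * (1 - editDistance / max(len(a), len(b))) under a
    global unit-cost alignment, which is unique for a sequence pair.  With
    ``rotation_invariant``, candidate rotations of ``b`` are located by
    exact seed k-mers sampled along ``a`` and the best-scoring rotation's
    identity is returned; this recovers circular permutations without
    aligning every rotation.
    """
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    if not rotation_invariant:
        return _global_identity(sa, sb)
    best = 0.0
    for off in sorted(_candidate_rotations(sa, sb, seed_len, n_seeds)):
        best = max(best, _global_identity(sa, rotate(sb, off)))
        if best == 100.0:
            break
    return best


def demarcate_rank(similarity: float, thresholds: dict[str, float] | None = None) -> str:
    """Finest ICTV rank whose similarity threshold is met (inclusive).

    Returns "species", "genus", "subfamily", or "new_subfamily" when the
    similarity falls below every threshold (a new-subfamily candidate).
    """
    if not 0 <= similarity <= 100:
        raise ValueError("similarity must be a percentage in [0, 100]")
    thresholds = thresholds or ICTV_THRESHOLDS
    for rank in sorted(thresholds, key=thresholds.__getitem__, reverse=True):
        if similarity >= thresholds[rank]:
            return rank
    return "new_subfamily"
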