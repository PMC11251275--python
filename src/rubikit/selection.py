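"""Representative-variant selection by greedy identity clustering.

Pairwise identity comes from an exhaustive global (Needleman-Wunsch style,
affine-gap) alignment; clustering is centroid-greedy at an identity
threshold; an iterative scheme unions centroids picked from tagged
subsets at stage-specific thresholds.

Identity here is canonical: among all maximum-score alignments we take
the one with the most matched columns (shortest alignment breaking the
remaining tie), and report ``matches / alignment_length``.  This makes
the value well defined and testable against an independent brute-force
oracle; a ``shorter``-sequence denominator is available as an option
because cluster counts depend on the convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_VALID_AA = set("ABCDEFGHIKLMNPQRSTUVWXYZ*")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with optional subset tags."""

    id: str
    residues: str
    subset_tags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("residues must be non-empty")
        if not self.residues.isupper():
            raise ValueError("residues must be uppercase")
        bad = set(self.residues) - _VALID_AA
        if bad:
            raise ValueError(f"invalid residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentScoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -5  # cost of the first column of a gap
    gap_extend: int = -1  # cost of each further column

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


DEFAULT_SCORING = AlignmentScoring()

_NEG = -(1 << 50)


def _align_stats(a: str, b: str, scoring: AlignmentScoring):
    """Gotoh alignment returning (score, matches, alignment_length).

    The three-field objective (score, then matches, then -length) is
    packed into one int64 so the whole DP stays in vectorized numpy; no
    traceback is needed because matches and length are carried in the
    value itself.
    """
    n, m = len(a), len(b)
    lmax = n + m
    B = lmax + 1                      # room for (lmax - length)
    A = min(n, m) + 2                 # room for matches
    off = -scoring.gap_open * lmax + abs(scoring.mismatch) * lmax + 8
    AB = A * B

    def enc(score: int, matches: int, length: int) -> int:
        return ((score + off) * A + matches) * B + (lmax - length)

    ai = np.frombuffer(a.encode(), dtype=np.uint8)
    bi = np.frombuffer(b.encode(), dtype=np.uint8)

    d_open = scoring.gap_open * AB - 1
    d_ext = scoring.gap_extend * AB - 1
    d_match = scoring.match * AB + B - 1
    d_mismatch = scoring.mismatch * AB - 1

    # state rows over j = 0..m
    M = np.full(m + 1, _NEG, dtype=np.int64)   # last column consumes a_i and b_j
    X = np.full(m + 1, _NEG, dtype=np.int64)   # last column is a gap in b
    Y = np.full(m + 1, _NEG, dtype=np.int64)   # last column is a gap in a
    M[0] = enc(0, 0, 0)
    if m >= 1:
        Y[1:] = M[0] + d_open + d_ext * np.arange(m, dtype=np.int64)

    jj = np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where(bi == ai[i - 1], d_match, d_mismatch).astype(np.int64)
        prev_best = np.maximum(np.maximum(M, X), Y)
        newM = np.full(m + 1, _NEG, dtype=np.int64)
        newM[1:] = prev_best[:-1] + sub
        newX = np.maximum(np.maximum(M, Y) + d_open, X + d_ext)
        newY = np.full(m + 1, _NEG, dtype=np.int64)
        if m >= 1:
            z = np.maximum(newM, newX) + d_open  # first gap column after col j
            w = z - d_ext * jj
            newY[1:] = np.maximum.accumulate(w[:-1]) + d_ext * (jj[1:] - 1)
        M, X, Y = newM, newX, newY

    best = int(max(M[m], X[m], Y[m]))
    rem, lml = divmod(best, B)
    score_off, matches = divmod(rem, A)
    return score_off - off, matches, lmax - lml


def pairwise_identity(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    denominator: str = "alignment",
) -> float:
    """Fraction of identical columns in the optimal global alignment.

    ``denominator="alignment"`` divides by alignment length (default);
    ``"shorter"`` divides by the shorter sequence's length.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    _, matches, length = _align_stats(sa, sb, scoring)
    if denominator == "alignment":
        return matches / length
    if denominator == "shorter":
        return matches / min(len(sa), len(sb))
    raise ValueError(f"unknown denominator: {denominator!r}")


@dataclass
class ClusterAssignment:
    """Result of greedy clustering at one identity threshold."""

    threshold: float
    centroid_ids: list
    member_to_centroid: dict  # member id -> centroid id
    identities: dict  # member id -> identity to its centroid
    denominator: str = "alignment"

    @property
    def n_clusters(self) -> int:
        return len(self.centroid_ids)

    def members_of(self, centroid_id: str) -> list:
        return sorted(
            mid for mid, cid in self.member_to_centroid.items()
            if cid == centroid_id
        )


def _canonical_order(seqs: Sequence[SequenceRecord]) -> list:
    """Length-descending, id ascending: the deterministic processing order."""
    return sorted(seqs, key=lambda s: (-len(s), s.id))


def greedy_cluster(
    seqs: Sequence[SequenceRecord],
    threshold: float,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    denominator: str = "alignment",
) -> ClusterAssignment:
    """Centroid-greedy clustering at an identity threshold.

    Sequences are processed longest-first (ties by id); each joins the
    first existing centroid it matches at >= threshold, otherwise founds a
    new cluster.  Deterministic and order-insensitive (the canonical sort
    is applied internally).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    centroids: list[SequenceRecord] = []
    member_to_centroid: dict[str, str] = {}
    identities: dict[str, float] = {}
    for s in _canonical_order(seqs):
        for c in centroids:
            ident = pairwise_identity(s, c, scoring, denominator)
            if ident >= threshold:
                member_to_centroid[s.id] = c.id
                identities[s.id] = ident
                break
        else:
            centroids.append(s)
            member_to_centroid[s.id] = s.id
            identities[s.id] = 1.0
    return ClusterAssignment(
        threshold=threshold,
        centroid_ids=[c.id for c in centroids],
        member_to_centroid=member_to_centroid,
        identities=identities,
        denominator=denominator,
    )


@dataclass
class StageReport:
    subset_tag: str
    threshold: float
    n_input: int
    n_representatives: int
    representative_ids: list


@dataclass
class SelectionResult:
    representative_ids: list  # unique, sorted
    stages: list  # StageReport per scheme stage

    @property
    def n_unique(self) -> int:
        return len(self.representative_ids)


def iterative_select(
    seqs: Sequence[SequenceRecord],
    scheme: Sequence[tuple],
    scoring: AlignmentScoring = DEFAULT_SCORING,
    denominator: str = "alignment",
) -> SelectionResult:
    """Union of centroids from per-subset clustering stages.

    ``scheme`` is an ordered list of ``(subset_tag, threshold)`` pairs;
    each stage clusters the sequences carrying that tag at its threshold
    and contributes the centroids.  Overlapping picks across stages are
    de-duplicated in the final set; per-stage counts are reported.
    """
    reps: set[str] = set()
    stages = []
    for tag, threshold in scheme:
        subset = [s for s in seqs if tag in s.subset_tags]
        if not subset:
            warnings.warn(f"scheme stage {tag!r}: empty subset, skipped")
            stages.append(StageReport(tag, threshold, 0, 0, []))
            continue
        assignment = greedy_cluster(subset, threshold, scoring, denominator)
        reps |= set(assignment.centroid_ids)
        stages.append(StageReport(
            tag, threshold, len(subset),
            assignment.n_clusters, sorted(assignment.centroid_ids),
        ))
    return SelectionResult(sorted(reps), stages)
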