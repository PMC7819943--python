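"""Seed-template clustering of ranked k-mers and PWM construction.

The top-ranked k-mer serves as a seed template.  Any other k-mer joins its
cluster when some ungapped sliding alignment against the seed contains an
exact match of at least ``core_len`` consecutive bases and at most
``max_mismatch`` mismatches within the aligned overlap (overhanging bases are
neither matches nor mismatches).  Clusters are grown greedily and
non-overlapping: each k-mer belongs to the first seed it matches.  Stacking
the members at their alignment offsets gives a position count matrix, the
column-normalised position weight matrix (PWM), and a majority-base consensus
whose weakly supported end columns are trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kmer_stats import KmerStat

__all__ = [
    "ClusterMember",
    "MotifCluster",
    "is_cluster_member",
    "build_cluster",
    "cluster_all",
    "build_pwm",
    "BASES",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True, slots=True)
class ClusterMember:
    """One k-mer aligned to its cluster seed.

    ``offset`` is the shift of the member relative to the seed: member base j
    aligns with seed position j + offset.
    """

    kmer: str
    offset: int
    mismatches: int
    intensity_ave: float = 0.0
    occurrence_total: int = 0


@dataclass
class MotifCluster:
    """A seed template with its aligned members and derived PWM."""

    seed: str
    members: list[ClusterMember]
    pwm_counts: np.ndarray | None = None  # 4 x width, rows A/C/G/T
    pwm_probs: np.ndarray | None = None
    consensus: str = ""
    column_start: int = 0  # seed coordinate of the first (untrimmed) column
    support: np.ndarray | None = None  # members covering each column
    tie_columns: list[int] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def core_consensus(self, occupancy_min: float = 0.5) -> str:
        """Occupancy-filtered consensus: the high-information core of the PWM.

        Emits a base only where its column probability strictly exceeds
        ``occupancy_min`` (N otherwise) and trims N's off both ends — the
        same occupancy rule used for database letter-probability matrices.
        Reads the trimmed logo down to its strong columns, e.g. an 8-nt core
        out of a 9-mer seed cluster.
        """
        if self.pwm_probs is None:
            raise ValueError("build_pwm must run before core_consensus")
        raw = "".join(
            BASES[int(np.argmax(col))] if np.max(col) > occupancy_min else "N"
            for col in self.pwm_probs.T
        )
        return raw.strip("N")

    def scan_motif(self, occupancy_min: float = 0.5, min_len: int = 5) -> str:
        """Longest N-free stretch of the core consensus, for substring scans.

        Falls back to the plain consensus when the core is shorter than
        ``min_len``.
        """
        core = self.core_consensus(occupancy_min)
        segments = [s for s in core.split("N") if s]
        best = max(segments, key=len, default="")
        return best if len(best) >= min_len else self.consensus


def _alignment(candidate: str, seed: str, offset: int, core_len: int):
    """(mismatches, longest exact run) for one ungapped offset, or None.

    Overlap bases are compared pairwise; overhangs are ignored.  Returns
    ``None`` when the overlap is shorter than ``core_len``.
    """
    k = len(seed)
    lo = max(0, offset)
    hi = min(k, len(candidate) + offset)
    if hi - lo < core_len:
        return None
    mism = 0
    run = best_run = 0
    for i in range(lo, hi):
        if seed[i] == candidate[i - offset]:
            run += 1
            if run > best_run:
                best_run = run
        else:
            mism += 1
            run = 0
    return mism, best_run


def is_cluster_member(
    candidate: str,
    seed: str,
    max_mismatch: int | None = 2,
    core_len: int = 5,
) -> tuple[bool, int, int]:
    """Test whether ``candidate`` clusters with ``seed``.

    True iff some offset in ``[-(k - core_len), k - core_len]`` yields an
    overlap containing an exact run of >= ``core_len`` bases with at most
    ``max_mismatch`` mismatches (pass ``max_mismatch=None`` to require the
    core match only).  Returns ``(member, best_offset, mismatches)`` where
    the best offset has the fewest mismatches, then the smallest magnitude,
    negative before positive.
    """
    if len(candidate) != len(seed):
        raise ValueError(
            f"candidate length {len(candidate)} != seed length {len(seed)}"
        )
    k = len(seed)
    span = k - core_len
    best: tuple[int, int, int] | None = None  # (mism, |o|, o-sign-key), offset
    best_off = 0
    for off in range(-span, span + 1):
        res = _alignment(candidate, seed, off, core_len)
        if res is None:
            continue
        mism, run = res
        if run < core_len:
            continue
        if max_mismatch is not None and mism > max_mismatch:
            continue
        key = (mism, abs(off), 0 if off < 0 else 1)
        if best is None or key < best:
            best = key
            best_off = off
    if best is None:
        return False, 0, 0
    return True, best_off, best[0]


def build_cluster(
    ranked: Sequence[KmerStat],
    max_mismatch: int | None = 2,
    core_len: int = 5,
) -> MotifCluster:
    """Cluster ranked k-mers around the top-ranked seed (greedy single pass)."""
    if not ranked:
        raise ValueError("ranked k-mer list is empty")
    seed = ranked[0].kmer
    members: list[ClusterMember] = []
    for stat in ranked:
        ok, off, mism = is_cluster_member(stat.kmer, seed, max_mismatch, core_len)
        if ok:
            members.append(
                ClusterMember(
                    kmer=stat.kmer,
                    offset=off,
                    mismatches=mism,
                    intensity_ave=stat.intensity_ave,
                    occurrence_total=stat.occurrence_total,
                )
            )
    cluster = MotifCluster(seed=seed, members=members)
    build_pwm(cluster)
    return cluster


def cluster_all(
    ranked: Sequence[KmerStat],
    max_mismatch: int | None = 2,
    core_len: int = 5,
    max_clusters: int = 10,
    min_cluster_size: int = 1,
) -> list[MotifCluster]:
    """Greedy non-overlapping clustering of the whole ranked list.

    Repeatedly seeds a new cluster with the highest-ranked unassigned k-mer
    and removes its members; stops when everything is assigned, when
    ``max_clusters`` clusters have been emitted, or when the newest cluster
    falls below ``min_cluster_size``.
    """
    remaining = list(ranked)
    clusters: list[MotifCluster] = []
    while remaining and len(clusters) < max_clusters:
        cluster = build_cluster(remaining, max_mismatch, core_len)
        if cluster.n_members < min_cluster_size:
            break
        clusters.append(cluster)
        taken = {m.kmer for m in cluster.members}
        remaining = [s for s in remaining if s.kmer not in taken]
    return clusters


def build_pwm(
    cluster: MotifCluster,
    trim_support: float = 0.25,
    intensity_weighted: bool = False,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Stack members at their offsets into count/probability matrices.

    Each member casts one vote per base (or its pseudo-intensity as weight
    when ``intensity_weighted``).  Columns are seed coordinates extended by
    the member offsets; end columns supported by fewer than ``trim_support``
    of the members are trimmed so the reported consensus drops weak flanks.
    Consensus ties go to the alphabetically earliest base and the tied
    columns are flagged.  The cluster is updated in place and the
    ``(counts, probs, consensus)`` triple returned.
    """
    if not cluster.members:
        raise ValueError("cannot build a PWM from an empty cluster")
    k = len(cluster.seed)
    offs = [m.offset for m in cluster.members]
    col_lo = min(offs)
    col_hi = max(offs) + k  # exclusive, seed coordinates
    width = col_hi - col_lo
    counts = np.zeros((4, width))
    support = np.zeros(width, dtype=int)
    for m in cluster.members:
        w = m.intensity_ave if intensity_weighted else 1.0
        for j, base in enumerate(m.kmer):
            col = m.offset + j - col_lo
            counts[_BASE_INDEX[base], col] += w
            support[col] += 1

    min_support = trim_support * cluster.n_members
    lo, hi = 0, width
    while lo < hi and support[lo] < min_support:
        lo += 1
    while hi > lo and support[hi - 1] < min_support:
        hi -= 1
    if hi == lo:  # pathological: keep everything rather than nothing
        lo, hi = 0, width
    counts = counts[:, lo:hi]
    support = support[lo:hi]

    col_sums = counts.sum(axis=0)
    probs = np.where(col_sums > 0, counts / np.where(col_sums == 0, 1, col_sums), 0.25)

    consensus_chars = []
    ties = []
    for j in range(counts.shape[1]):
        col = counts[:, j]
        if support[j] == 0:
            consensus_chars.append("N")
            continue
        top = int(np.argmax(col))
        if int(np.sum(col == col[top])) > 1:
            ties.append(j)
        consensus_chars.append(BASES[top])
    consensus = "".join(consensus_chars)

    if not intensity_weighted:
        counts = counts.astype(int)
    cluster.pwm_counts = counts
    cluster.pwm_probs = probs
    cluster.consensus = consensus
    cluster.column_start = col_lo + lo
    cluster.support = support
    cluster.tie_columns = ties
    return counts, probs, consensus
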