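"""K-mer decomposition of strong-binding probes with pseudo-intensities.

Each 40-nt probe core is split into overlapping k-mers by a one-base shift
(k = 9 gives 32 per probe) and the probe's fluorescence intensity is assigned
to every occurrence.  A k-mer's *pseudo-intensity* is the mean of the
intensities over all its occurrences across probes.  Nonspecific G/C-rich
k-mers (homopolymer runs of >= 4 G or >= 4 C) are discarded, and the survivors
are ranked either by pseudo-intensity or by the product of pseudo-intensity
and occurrence count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .array_design import revcomp
from .signal_threshold import IntensityTable

__all__ = [
    "KmerStat",
    "KmerTable",
    "decompose",
    "gc_run_filter",
    "rank_kmers",
    "resolve_min_occurrence",
]


@dataclass(frozen=True, slots=True)
class KmerStat:
    """Aggregate statistics for one k-mer across the strong-probe set."""

    kmer: str
    intensity_ave: float  # pseudo-intensity: mean over all occurrences, AU
    occurrence_total: int
    distinct_positions: int  # distinct probe offsets (1-based, <= 40-k+1)

    @property
    def score_product(self) -> float:
        """intensity_ave x occurrence_total, the product ranking score."""
        return self.intensity_ave * self.occurrence_total


@dataclass
class KmerTable:
    """All k-mer statistics from one decomposition run."""

    k: int
    stats: dict[str, KmerStat]
    n_probes: int
    n_skipped_n: int = 0  # occurrences skipped for containing N
    collapse_rc: bool = False
    sort_mode: str | None = None

    @property
    def n_distinct(self) -> int:
        return len(self.stats)

    @property
    def total_occurrence(self) -> int:
        return sum(s.occurrence_total for s in self.stats.values())

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.stats

    def intensity_of(self, kmer: str) -> float | None:
        s = self.stats.get(kmer)
        return None if s is None else s.intensity_ave

    def to_frame(self) -> pd.DataFrame:
        """Tabular view mirroring the published k-mer table columns."""
        rows = [
            (
                s.kmer,
                s.intensity_ave,
                s.occurrence_total,
                s.score_product,
                s.distinct_positions,
            )
            for s in self.stats.values()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "kmer",
                "intensity_ave",
                "occurrence_total",
                "int_ave_x_occur_tot",
                "occur_diff_pos",
            ],
        )


def decompose(
    probes: IntensityTable,
    k: int,
    collapse_rc: bool = False,
    per_probe_unique: bool = False,
) -> KmerTable:
    """Split probe cores into k-mers and aggregate pseudo-intensities.

    Each probe of length L yields ``L - k + 1`` occurrences (32 for k = 9 on a
    40-nt core), every occurrence carrying the probe's intensity.  Counting is
    forward-strand only unless ``collapse_rc`` merges each k-mer with its
    reverse complement (canonical representative = lexicographic minimum).
    With ``per_probe_unique`` a probe contributes at most one occurrence per
    k-mer regardless of how many offsets it appears at; the default counts
    every offset, so a k-mer at m offsets receives the intensity m times.
    K-mers containing N are skipped and tallied in ``n_skipped_n``.
    """
    if not 5 <= k <= 11:
        raise ValueError(f"k must be in [5, 11], got {k}")
    if probes.core_seqs is None:
        raise ValueError("intensity table must carry probe core sequences")

    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    positions: dict[str, set[int]] = {}
    n_skipped = 0

    for pid, inten in zip(probes.probe_ids, probes.intensities):
        core = probes.core_seqs[pid]
        if len(core) < k:
            raise ValueError(
                f"probe {pid!r} core is {len(core)} nt, shorter than k={k}"
            )
        seen_here: set[str] = set()
        for off in range(len(core) - k + 1):
            kmer = core[off : off + k]
            if "N" in kmer:
                n_skipped += 1
                continue
            if collapse_rc:
                rc = revcomp(kmer)
                if rc < kmer:
                    kmer = rc
            if per_probe_unique:
                if kmer in seen_here:
                    positions.setdefault(kmer, set()).add(off + 1)
                    continue
                seen_here.add(kmer)
            if kmer in sums:
                sums[kmer] += inten
                counts[kmer] += 1
                positions[kmer].add(off + 1)
            else:
                sums[kmer] = float(inten)
                counts[kmer] = 1
                positions[kmer] = {off + 1}

    stats = {
        kmer: KmerStat(
            kmer=kmer,
            intensity_ave=sums[kmer] / counts[kmer],
            occurrence_total=counts[kmer],
            distinct_positions=len(positions[kmer]),
        )
        for kmer in sums
    }
    return KmerTable(
        k=k,
        stats=stats,
        n_probes=probes.n,
        n_skipped_n=n_skipped,
        collapse_rc=collapse_rc,
    )


_GC_RUN = {m: re.compile("G{%d,}|C{%d,}" % (m, m)) for m in range(2, 12)}


def gc_run_filter(table: KmerTable, min_run: int = 4) -> tuple[KmerTable, int]:
    """Drop k-mers with a homopolymer run of >= ``min_run`` G's or C's.

    These G/C-rich oligomers bind nonspecifically across unrelated proteins
    on the array.  Returns the filtered table and the discarded count.
    """
    pat = _GC_RUN.get(min_run) or re.compile("G{%d,}|C{%d,}" % (min_run, min_run))
    kept = {kmer: s for kmer, s in table.stats.items() if not pat.search(kmer)}
    discarded = table.n_distinct - len(kept)
    return replace(table, stats=kept), discarded


def resolve_min_occurrence(table: KmerTable, rule: int | str) -> int:
    """Resolve an occurrence floor; ``"auto4x"`` means ceil(4 x mean occurrence)."""
    if isinstance(rule, int):
        return rule
    if rule == "auto4x":
        if table.n_distinct == 0:
            return 1
        mean_occ = table.total_occurrence / table.n_distinct
        return int(np.ceil(4.0 * mean_occ))
    raise ValueError(f"unknown min-occurrence rule {rule!r}")


def rank_kmers(
    table: KmerTable,
    mode: str = "intensity",
    min_occurrence: int | str = 1,
) -> list[KmerStat]:
    """Rank k-mers by pseudo-intensity or by intensity x occurrence.

    ``mode`` is ``"intensity"`` (sort key ``intensity_ave``) or ``"product"``
    (sort key ``intensity_ave * occurrence_total``); descending, ties broken
    lexicographically by k-mer.  K-mers below the occurrence floor are
    dropped first (``min_occurrence`` may be the string ``"auto4x"``).
    """
    if mode not in ("intensity", "product"):
        raise ValueError(f"unknown sort mode {mode!r}; use 'intensity' or 'product'")
    floor = resolve_min_occurrence(table, min_occurrence)
    stats = [s for s in table.stats.values() if s.occurrence_total >= floor]
    key = (
        (lambda s: (-s.intensity_ave, s.kmer))
        if mode == "intensity"
        else (lambda s: (-s.score_product, s.kmer))
    )
    table.sort_mode = mode
    return sorted(stats, key=key)
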