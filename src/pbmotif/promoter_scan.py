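"""Motif scanning over probes and promoters; consensus from letter matrices.

Maps an inferred motif back to putative target genes: substring scans over
the strong-binding probe cores (gene ids parsed from ``geneID_index`` probe
ids) or over full promoter sets, forward strand with optional
reverse-complement.  Also extracts representative consensus elements from
database-style letter-probability matrices by an occupancy rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .array_design import PromoterRecord, revcomp
from .signal_threshold import IntensityTable

__all__ = [
    "MotifHit",
    "GeneHitList",
    "LetterProbabilityMatrix",
    "ConsensusResult",
    "gene_id_of_probe",
    "scan_probes",
    "scan_promoters",
    "lpm_to_consensus",
    "count_with_secondary",
]

_BASES = "ACGT"


def gene_id_of_probe(probe_id: str) -> str:
    """Gene id = probe id up to the last underscore (``Os08g0536300_14``)."""
    gene, sep, idx = probe_id.rpartition("_")
    if not sep or not gene or not idx:
        raise ValueError(
            f"malformed probe_id {probe_id!r}: expected '<gene>_<index>'"
        )
    return gene


def _find_all(seq: str, motif: str) -> list[int]:
    out = []
    start = seq.find(motif)
    while start != -1:
        out.append(start)
        start = seq.find(motif, start + 1)
    return out


@dataclass(frozen=True, slots=True)
class MotifHit:
    """Occurrences of one motif in one sequence on one strand."""

    seq_id: str  # probe_id or gene_id depending on the scan
    offsets: tuple[int, ...]
    strand: str  # "+" or "-"


@dataclass
class GeneHitList:
    """Result of scanning a motif over probes or promoters."""

    motif: str
    hits: list[MotifHit] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)  # deduplicated, first-seen order

    @property
    def n_probes(self) -> int:
        """Number of distinct sequences (probes) with at least one hit."""
        return len({h.seq_id for h in self.hits})

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def scan_probes(
    strong: IntensityTable, motif: str, include_rc: bool = False
) -> GeneHitList:
    """Find probes whose 40-nt core contains the motif; list their genes.

    Forward-strand substring search, plus the reverse complement when
    ``include_rc``; gene ids are parsed from probe ids and deduplicated in
    first-hit order.
    """
    if strong.core_seqs is None:
        raise ValueError("intensity table must carry probe core sequences")
    if len(motif) > max((len(s) for s in strong.core_seqs.values()), default=0):
        return GeneHitList(motif=motif)
    rc = revcomp(motif)
    result = GeneHitList(motif=motif)
    seen_genes = set()
    for pid in strong.probe_ids:
        core = strong.core_seqs[pid]
        hit = False
        fwd = _find_all(core, motif)
        if fwd:
            result.hits.append(MotifHit(pid, tuple(fwd), "+"))
            hit = True
        if include_rc and rc != motif:
            rev = _find_all(core, rc)
            if rev:
                result.hits.append(MotifHit(pid, tuple(rev), "-"))
                hit = True
        if hit:
            gene = gene_id_of_probe(pid)
            if gene not in seen_genes:
                seen_genes.add(gene)
                result.genes.append(gene)
    return result


def scan_promoters(
    promoters: list[PromoterRecord], motif: str, include_rc: bool = False
) -> GeneHitList:
    """Find promoters containing the motif; each gene counted once."""
    rc = revcomp(motif)
    result = GeneHitList(motif=motif)
    for rec in promoters:
        hit = False
        fwd = _find_all(rec.sequence, motif)
        if fwd:
            result.hits.append(MotifHit(rec.gene_id, tuple(fwd), "+"))
            hit = True
        if include_rc and rc != motif:
            rev = _find_all(rec.sequence, rc)
            if rev:
                result.hits.append(MotifHit(rec.gene_id, tuple(rev), "-"))
                hit = True
        if hit:
            result.genes.append(rec.gene_id)
    return result


@dataclass
class LetterProbabilityMatrix:
    """A database-style motif matrix: one row per position, columns A/C/G/T."""

    probs: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("letter-probability matrix must be width x 4")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("letter-probability entries must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("letter-probability rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class ConsensusResult:
    consensus: str | None
    accepted: bool
    reason: str = ""


def lpm_to_consensus(
    lpm: LetterProbabilityMatrix,
    occupancy_min: float = 0.5,
    min_distinct: int = 6,
) -> ConsensusResult:
    """Representative consensus element from a letter-probability matrix.

    Each position emits the base whose probability strictly exceeds
    ``occupancy_min``, otherwise ``N``.  After trimming leading and trailing
    N's the element is accepted iff it has at least ``min_distinct`` non-N
    positions and no two adjacent N's.
    """
    raw = "".join(
        _BASES[int(np.argmax(row))] if np.max(row) > occupancy_min else "N"
        for row in lpm.probs
    )
    trimmed = raw.strip("N")
    n_distinct = sum(1 for c in trimmed if c != "N")
    if n_distinct < min_distinct:
        return ConsensusResult(
            None, False, f"only {n_distinct} distinct nucleotides (< {min_distinct})"
        )
    if "NN" in trimmed:
        return ConsensusResult(None, False, "consecutive ambiguous (N) positions")
    return ConsensusResult(trimmed, True)


def count_with_secondary(
    strong: IntensityTable,
    primary: str,
    secondary: str,
    min_count: int = 2,
    include_rc: bool = False,
) -> int:
    """Probes containing ``primary`` and >= ``min_count`` copies of ``secondary``.

    Occurrences of the secondary motif may overlap each other; with
    ``include_rc`` its reverse-complement occurrences count too.  Used for
    co-occurring element reports such as double W-box (TGAC core) counts.
    """
    if strong.core_seqs is None:
        raise ValueError("intensity table must carry probe core sequences")
    rc2 = revcomp(secondary)
    n = 0
    for pid in strong.probe_ids:
        core = strong.core_seqs[pid]
        if primary not in core:
            continue
        occ = len(_find_all(core, secondary))
        if include_rc and rc2 != secondary:
            occ += len(_find_all(core, rc2))
        if occ >= min_count:
            n += 1
    return n
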