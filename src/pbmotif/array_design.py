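"""Promoter tiling array design.

A promoter-tiling protein-binding microarray (PBM) covers the region upstream
of each gene's translation start with overlapping fixed-length probes.  Each
probe carries a gene-specific 40-nt core followed by a PCR primer linker and a
short poly-T spacer.  With the default 40-nt probe length and 20-nt step, a
1-kb promoter yields 49 probes, consecutive probes overlapping by 20 nt.

Coordinates are 0-based half-open internally; exported tables use 1-based
inclusive coordinates.  Promoters are stored 5'->3' with the last base
adjacent to the anchor point (translation or transcription start), so tile 1
is the most distal window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "AnchorClass",
    "PromoterRecord",
    "Probe",
    "ArrayDesign",
    "DEFAULT_LINKER",
    "DEFAULT_POLYT",
    "tile_promoter",
    "design_array",
    "kmer_space_size",
    "revcomp",
]

DEFAULT_LINKER = "CGGAGTCACCTAGTGCAG"
DEFAULT_POLYT = "TTTTT"

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnchorClass(str, Enum):
    """How the promoter's 3' end was anchored during upstream extraction.

    Metadata only: sequences arrive pre-extracted.  ``no_utr`` anchors at the
    translation start of a transcript without a 5'-UTR; ``long_utr`` anchors
    200 bp into a 5'-UTR longer than 200 bp; ``default`` is the ordinary
    translation-start anchor.
    """

    no_utr = "no_utr"
    long_utr = "long_utr"
    default = "default"


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter sequence, 5'->3', ending at the anchor point."""

    gene_id: str
    sequence: str
    anchor_class: AnchorClass = AnchorClass.default

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(
                f"promoter {self.gene_id!r} contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"promoter {self.gene_id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class Probe:
    """One tiled array feature: a gene-anchored core plus linker and poly-T."""

    probe_id: str
    gene_id: str
    tile_index: int  # 1-based
    start: int  # 0-based half-open within the promoter
    end: int
    core_seq: str
    full_seq: str

    @property
    def has_n(self) -> bool:
        return "N" in self.core_seq


@dataclass
class ArrayDesign:
    """A full tiling design over a set of promoters."""

    probes: list[Probe]
    n_genes: int
    probe_length: int
    step: int
    linker: str = DEFAULT_LINKER
    polyT: str = DEFAULT_POLYT
    gene_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def core_seqs(self) -> dict[str, str]:
        """Mapping probe_id -> 40-nt core sequence."""
        return {p.probe_id: p.core_seq for p in self.probes}


def tile_promoter(
    promoter: PromoterRecord,
    probe_length: int = 40,
    step: int = 20,
    linker: str = DEFAULT_LINKER,
    polyT: str = DEFAULT_POLYT,
) -> list[Probe]:
    """Tile one promoter into overlapping probes.

    Probe ``i`` (1-based tile index) covers ``[(i-1)*step, (i-1)*step + probe_length)``;
    the number of probes is ``floor((L - probe_length)/step) + 1``.  A 1,000-nt
    promoter with the defaults yields 49 probes.
    """
    if probe_length <= 0 or step <= 0:
        raise ValueError("probe_length and step must be positive")
    L = promoter.length
    if L < probe_length:
        raise ValueError(
            f"promoter {promoter.gene_id!r} is {L} nt, shorter than the "
            f"{probe_length}-nt probe length"
        )
    n = (L - probe_length) // step + 1
    seq = promoter.sequence
    suffix = linker + polyT
    probes = []
    for i in range(n):
        start = i * step
        core = seq[start : start + probe_length]
        probes.append(
            Probe(
                probe_id=f"{promoter.gene_id}_{i + 1}",
                gene_id=promoter.gene_id,
                tile_index=i + 1,
                start=start,
                end=start + probe_length,
                core_seq=core,
                full_seq=core + suffix,
            )
        )
    return probes


def design_array(
    promoters: Sequence[PromoterRecord] | Iterable[PromoterRecord],
    probe_length: int = 40,
    step: int = 20,
    linker: str = DEFAULT_LINKER,
    polyT: str = DEFAULT_POLYT,
) -> ArrayDesign:
    """Tile every promoter and assemble the complete array design.

    Deterministic: probes appear in promoter input order, tiles in 5'->3'
    order.  Duplicate gene ids and empty input are rejected.
    """
    promoters = list(promoters)
    if not promoters:
        raise ValueError("no promoters supplied")
    seen: set[str] = set()
    probes: list[Probe] = []
    for rec in promoters:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r} in promoter set")
        seen.add(rec.gene_id)
        probes.extend(tile_promoter(rec, probe_length, step, linker, polyT))
    return ArrayDesign(
        probes=probes,
        n_genes=len(promoters),
        probe_length=probe_length,
        step=step,
        linker=linker,
        polyT=polyT,
        gene_ids=[r.gene_id for r in promoters],
    )


def kmer_space_size(k: int, collapse_rc: bool = False) -> int:
    """Number of DNA k-mers, optionally merging reverse-complement pairs.

    Without collapsing there are ``4**k`` k-mers.  Collapsing each sequence
    with its reverse complement leaves ``4**k / 2`` classes for odd k (no
    k-mer is its own reverse complement) and ``(4**k + 4**(k/2)) / 2`` for
    even k (palindromic k-mers are singleton classes).  For k = 9 this is
    262,144 -> 131,072.
    """
    if not 1 <= k <= 16:
        raise ValueError(f"k must be in [1, 16], got {k}")
    total = 4**k
    if not collapse_rc:
        return total
    if k % 2 == 1:
        return total // 2
    return (total + 4 ** (k // 2)) // 2


def enumerate_rc_classes(k: int) -> int:
    """Count reverse-complement classes by explicit enumeration.

    Brute-force companion to :func:`kmer_space_size`; linear in ``4**k``.
    """
    if not 1 <= k <= 16:
        raise ValueError(f"k must be in [1, 16], got {k}")
    classes = set()
    for tup in itertools.product("ACGT", repeat=k):
        kmer = "".join(tup)
        rc = revcomp(kmer)
        classes.add(min(kmer, rc))
    return len(classes)
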