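"""Positional mutation scans, greedy motif extension, flank preferences.

Once a candidate motif is in hand, three refinements quantify it further:

* a *mutation scan* compares the motif k-mer's pseudo-intensity with the mean
  pseudo-intensity of its three single-base mutants at each position — a
  large drop marks a base the protein needs;
* *greedy extension* slides a same-length window one base 5' or 3' at a time,
  keeping whichever of the four flanking bases gives the highest
  pseudo-intensity, to reveal preferred bases just outside the motif;
* *flanking preference* tallies the bases observed around motif occurrences
  in a promoter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_design import PromoterRecord, revcomp
from .kmer_stats import KmerTable
from .motif_discovery import BASES

__all__ = [
    "MutationProfile",
    "ExtensionStep",
    "ExtensionTrace",
    "mutation_scan",
    "extend_motif",
    "flanking_preference",
]


@dataclass
class MutationProfile:
    """Per-position intensity deltas for single-base substitutions.

    ``mutant_intensities`` is k x 4 (columns A/C/G/T): pseudo-intensity of
    the k-mer with that base substituted at that position; the wild-type
    base's own column and any mutant absent from the k-mer table are NaN.
    ``position_delta[i]`` is wild-type intensity minus the mean of the
    *available* mutants at position i (NaN when none are available).
    """

    motif: str
    wt_intensity: float
    mutant_intensities: np.ndarray
    position_delta: np.ndarray
    use_sum: bool = False

    @property
    def max_delta_position(self) -> int:
        """0-based position of the largest intensity drop."""
        return int(np.nanargmax(self.position_delta))

    @property
    def min_delta_position(self) -> int:
        return int(np.nanargmin(self.position_delta))

    def to_frame(self) -> pd.DataFrame:
        k = len(self.motif)
        df = pd.DataFrame(
            {
                "position": np.arange(1, k + 1),
                "wt_base": list(self.motif),
                "delta": self.position_delta,
            }
        )
        for j, b in enumerate(BASES):
            df[f"mut_{b}"] = self.mutant_intensities[:, j]
        return df


def mutation_scan(motif: str, table: KmerTable, use_sum: bool = False) -> MutationProfile:
    """Scan every single-base substitution of ``motif`` against the k-mer table.

    The wild-type and each mutant are looked up by pseudo-intensity; at each
    position the wild-type is compared with the mean (or, with ``use_sum``,
    the sum) of the mutants found in the table.  Mutant k-mers absent from
    the table are excluded from the comparison rather than imputed as zero —
    absence from the strong-binder set does not mean zero affinity.
    """
    if len(motif) != table.k:
        raise ValueError(f"motif length {len(motif)} != table k {table.k}")
    wt = table.intensity_of(motif)
    if wt is None:
        raise ValueError(f"motif {motif!r} is not present in the k-mer table")
    k = len(motif)
    mut = np.full((k, 4), np.nan)
    delta = np.full(k, np.nan)
    for i in range(k):
        vals = []
        for j, b in enumerate(BASES):
            if b == motif[i]:
                continue
            v = table.intensity_of(motif[:i] + b + motif[i + 1 :])
            if v is not None:
                mut[i, j] = v
                vals.append(v)
        if vals:
            agg = np.sum(vals) if use_sum else np.mean(vals)
            delta[i] = wt - agg
    return MutationProfile(
        motif=motif,
        wt_intensity=wt,
        mutant_intensities=mut,
        position_delta=delta,
        use_sum=use_sum,
    )


@dataclass(frozen=True, slots=True)
class ExtensionStep:
    direction: str  # "5p" or "3p"
    chosen_base: str
    window: str  # the winning same-length window
    intensity_ave: float


@dataclass
class ExtensionTrace:
    """Record of a greedy 5'/3' extension run."""

    start_motif: str
    steps: list[ExtensionStep] = field(default_factory=list)
    final_motif: str = ""
    truncated_5p: bool = False
    truncated_3p: bool = False

    def to_dict(self) -> dict:
        return {
            "start_motif": self.start_motif,
            "final_motif": self.final_motif,
            "truncated_5p": self.truncated_5p,
            "truncated_3p": self.truncated_3p,
            "steps": [
                {
                    "direction": s.direction,
                    "chosen_base": s.chosen_base,
                    "window": s.window,
                    "intensity_ave": s.intensity_ave,
                }
                for s in self.steps
            ],
        }


def extend_motif(
    motif: str,
    table: KmerTable,
    max_steps_each_side: int = 2,
    direction_order: str = "alternate",
) -> ExtensionTrace:
    """Greedily extend a motif one base at a time in the 5' and 3' directions.

    Each 5' step forms the four windows ``b + w[:-1]`` from the current 5'
    window ``w`` (3' steps mirror this) and keeps the one with the highest
    pseudo-intensity in the table; ties resolve to the alphabetically first
    base.  The windows stay length k; the final motif is the chosen 5' bases,
    the start motif, then the chosen 3' bases.  ``direction_order`` is
    ``"alternate"`` (5', 3', 5', 3', ...), ``"5p_first"`` or ``"3p_first"``.
    A side with no candidate window in the table is marked truncated.
    """
    if len(motif) != table.k:
        raise ValueError(f"motif length {len(motif)} != table k {table.k}")
    if table.intensity_of(motif) is None:
        raise ValueError(f"motif {motif!r} is not present in the k-mer table")

    if direction_order == "alternate":
        order = [d for _ in range(max_steps_each_side) for d in ("5p", "3p")]
    elif direction_order == "5p_first":
        order = ["5p"] * max_steps_each_side + ["3p"] * max_steps_each_side
    elif direction_order == "3p_first":
        order = ["3p"] * max_steps_each_side + ["5p"] * max_steps_each_side
    else:
        raise ValueError(f"unknown direction_order {direction_order!r}")

    trace = ExtensionTrace(start_motif=motif)
    win5 = win3 = motif
    prefix: list[str] = []
    suffix: list[str] = []
    dead = {"5p": False, "3p": False}
    for direction in order:
        if dead[direction]:
            continue
        best_base = None
        best_val = -np.inf
        best_win = ""
        for b in BASES:
            w = b + win5[:-1] if direction == "5p" else win3[1:] + b
            v = table.intensity_of(w)
            if v is not None and v > best_val:
                best_base, best_val, best_win = b, v, w
        if best_base is None:
            dead[direction] = True
            if direction == "5p":
                trace.truncated_5p = True
            else:
                trace.truncated_3p = True
            continue
        if direction == "5p":
            win5 = best_win
            prefix.insert(0, best_base)
        else:
            win3 = best_win
            suffix.append(best_base)
        trace.steps.append(
            ExtensionStep(direction, best_base, best_win, float(best_val))
        )
    trace.final_motif = "".join(prefix) + motif + "".join(suffix)
    return trace


def flanking_preference(
    promoters: list[PromoterRecord],
    motif: str,
    window: int = 3,
    include_rc: bool = False,
) -> pd.DataFrame:
    """Base counts at positions around motif occurrences in promoters.

    Rows are flank positions -window..-1 and +1..+window relative to the
    motif (negative = 5' of it), columns A/C/G/T.  Occurrences truncated at a
    promoter edge contribute only the positions that exist.  Forward-strand
    occurrences only by default; with ``include_rc`` the reverse-complement
    occurrences are tallied in the motif's own orientation.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    positions = [p for p in range(-window, window + 1) if p != 0]
    counts = pd.DataFrame(
        0, index=positions, columns=list(BASES), dtype=int
    )

    def tally(seq: str) -> None:
        m = len(motif)
        start = seq.find(motif)
        while start != -1:
            for p in positions:
                idx = start + p if p < 0 else start + m - 1 + p
                if 0 <= idx < len(seq):
                    base = seq[idx]
                    if base in counts.columns:
                        counts.loc[p, base] += 1
            start = seq.find(motif, start + 1)

    for rec in promoters:
        tally(rec.sequence)
        if include_rc:
            tally(revcomp(rec.sequence))
    counts.index.name = "position"
    return counts
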