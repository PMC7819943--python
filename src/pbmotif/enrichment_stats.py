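"""Rank-based motif significance and steep/tail distribution summaries.

The significance of a candidate motif is tested by a two-sided
Wilcoxon–Mann–Whitney test comparing the intensity ranks of probes whose
cores contain the motif against those that do not.  A companion summary
partitions the above-background probes into the steep (strong-binding) zone
— intensity above the extrapolated tail intercept — and the tail, and
cross-tabulates forward-motif, reverse-complement-motif and motif-free
probes with group means, fold changes and the strong-zone fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .array_design import revcomp
from .signal_threshold import IntensityTable, SegmentFit

__all__ = ["MotifEnrichment", "mwu_motif_test", "enrichment_summary", "P_FLOOR"]

# Double-precision underflow floor: p-values below this are reported as the
# floor itself, never as a literal zero.
P_FLOOR = 2.220446049250313e-16


def _motif_mask(table: IntensityTable, motif: str, include_rc: bool) -> np.ndarray:
    if table.core_seqs is None:
        raise ValueError("intensity table must carry probe core sequences")
    rc = revcomp(motif)
    use_rc = include_rc and rc != motif
    mask = np.empty(table.n, dtype=bool)
    for i, pid in enumerate(table.probe_ids):
        core = table.core_seqs[pid]
        mask[i] = motif in core or (use_rc and rc in core)
    return mask


def mwu_motif_test(
    table: IntensityTable, motif: str, include_rc: bool = False
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: motif-containing vs motif-free probes.

    The exact null distribution is used when the smaller group has at most 8
    observations and there are no ties; otherwise the tie-corrected normal
    approximation.  P-values below :data:`P_FLOOR` are reported as the floor.
    """
    mask = _motif_mask(table, motif, include_rc)
    with_m = table.intensities[mask]
    without = table.intensities[~mask]
    if len(with_m) == 0:
        raise ValueError(f"no probe contains the motif {motif!r}")
    if len(without) == 0:
        raise ValueError(f"every probe contains the motif {motif!r}")
    pooled = np.concatenate([with_m, without])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(with_m), len(without)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(with_m, without, alternative="two-sided", method=method)
    return float(res.statistic), max(float(res.pvalue), P_FLOOR)


@dataclass
class MotifEnrichment:
    """Cross-tabulation of motif presence against the steep/tail partition."""

    motif: str
    rc_motif: str
    palindromic: bool
    counts: dict[tuple[str, str], int]  # (group, zone) -> count
    means_sd: dict[str, tuple[float, float]]  # group -> (mean, sd)
    fold_forward: float | None
    fold_reverse: float | None
    strong_fraction: float | None
    n_both: int  # probes containing motif and its RC (assigned to forward)
    mwu_statistic: float
    p_value: float

    def group_total(self, group: str) -> int:
        return self.counts[(group, "steep")] + self.counts[(group, "tail")]

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "rc_motif": self.rc_motif,
            "palindromic": self.palindromic,
            "counts": {f"{g}_{z}": v for (g, z), v in self.counts.items()},
            "means_sd": {g: list(v) for g, v in self.means_sd.items()},
            "fold_forward": self.fold_forward,
            "fold_reverse": self.fold_reverse,
            "strong_fraction": self.strong_fraction,
            "n_both": self.n_both,
            "mwu_statistic": self.mwu_statistic,
            "p_value": self.p_value,
        }


def enrichment_summary(
    table: IntensityTable, fit: SegmentFit, motif: str
) -> MotifEnrichment:
    """Summarise how motif-bearing probes distribute over steep vs tail.

    Every above-background probe is classified as steep (intensity strictly
    above the cutoff) or tail, and as forward (motif in core), reverse
    (reverse complement in core) or none.  Probes containing both
    orientations are assigned to the forward group and counted in
    ``n_both``; a palindromic motif collapses forward and reverse into one
    forward group.  Fold changes are ratios of arithmetic group means over
    the motif-free mean; ``strong_fraction`` is the share of motif-bearing
    probes (either orientation) that fall in the steep zone.  The
    Mann–Whitney test compares motif-bearing (either orientation) against
    motif-free probes.
    """
    if table.core_seqs is None:
        raise ValueError("intensity table must carry probe core sequences")
    rc = revcomp(motif)
    palindromic = rc == motif
    groups = []
    n_both = 0
    for pid in table.probe_ids:
        core = table.core_seqs[pid]
        fwd = motif in core
        rev = (not palindromic) and rc in core
        if fwd and rev:
            n_both += 1
        groups.append("forward" if fwd else ("reverse" if rev else "none"))
    groups = np.array(groups)
    steep = table.intensities > fit.cutoff

    counts = {}
    means_sd = {}
    for g in ("forward", "reverse", "none"):
        sel = groups == g
        counts[(g, "steep")] = int(np.sum(sel & steep))
        counts[(g, "tail")] = int(np.sum(sel & ~steep))
        vals = table.intensities[sel]
        if len(vals):
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            means_sd[g] = (float(np.mean(vals)), sd)
        else:
            means_sd[g] = (float("nan"), float("nan"))

    none_mean = means_sd["none"][0]
    def fold(g: str) -> float | None:
        if counts[(g, "steep")] + counts[(g, "tail")] == 0 or not np.isfinite(none_mean) or none_mean == 0:
            return None
        return means_sd[g][0] / none_mean

    n_with = int(np.sum(groups != "none"))
    strong_fraction = (
        float(np.sum((groups != "none") & steep) / n_with) if n_with else None
    )

    if n_with and n_with < table.n:
        stat, p = mwu_motif_test(table, motif, include_rc=not palindromic)
    else:
        stat, p = float("nan"), float("nan")

    return MotifEnrichment(
        motif=motif,
        rc_motif=rc,
        palindromic=palindromic,
        counts=counts,
        means_sd=means_sd,
        fold_forward=fold("forward"),
        fold_reverse=None if palindromic else fold("reverse"),
        strong_fraction=strong_fraction,
        n_both=n_both,
        mwu_statistic=stat,
        p_value=p,
    )
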