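"""Rank-intensity segmentation and the strong-binder cutoff.

On a PBM the rank-ordered probe intensities show two regimes: a steep head of
specific binders falling quickly with rank, then a long, nearly flat tail of
background binding.  Each regime is modelled with an ordinary least-squares
line ``y = a*x + b`` in (rank, intensity) coordinates; the split between them
is chosen by exhaustive search minimising the summed squared error of the two
fits.  The extrapolated y-intercept of the tail line (``b2``) is the
strong-binding intensity cutoff: probes above it are called strong binders.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = [
    "IntensityTable",
    "SegmentFit",
    "filter_background",
    "fit_rank_segments",
    "select_strong_probes",
]


@dataclass
class IntensityTable:
    """Probe fluorescence intensities, optionally with background and cores.

    Parameters
    ----------
    probe_ids
        Unique probe identifiers (``geneID_index`` style).
    intensities
        Non-negative finite fluorescence values, one per probe.
    background
        Scalar background intensity, or one value per probe, or ``None``.
    core_seqs
        Optional mapping probe_id -> core sequence, carried along so that
        downstream k-mer and motif stages can look sequences up.
    """

    probe_ids: np.ndarray
    intensities: np.ndarray
    background: float | np.ndarray | None = None
    core_seqs: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.probe_ids.shape != self.intensities.shape:
            raise ValueError("probe_ids and intensities must have equal length")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if len(set(self.probe_ids.tolist())) != len(self.probe_ids):
            raise ValueError("probe_ids must be unique")
        if isinstance(self.background, np.ndarray) and (
            self.background.shape != self.intensities.shape
        ):
            raise ValueError("per-probe background must match table length")

    @classmethod
    def from_mapping(
        cls,
        entries: Mapping[str, float],
        background: float | None = None,
        core_seqs: dict[str, str] | None = None,
    ) -> "IntensityTable":
        ids = list(entries)
        return cls(
            probe_ids=np.array(ids, dtype=object),
            intensities=np.array([entries[i] for i in ids], dtype=float),
            background=background,
            core_seqs=core_seqs,
        )

    def __len__(self) -> int:
        return len(self.probe_ids)

    @property
    def n(self) -> int:
        return len(self.probe_ids)

    def mean(self) -> float:
        return float(np.mean(self.intensities))

    def sd(self) -> float:
        return float(np.std(self.intensities, ddof=1)) if self.n > 1 else 0.0

    def subset(self, mask: np.ndarray) -> "IntensityTable":
        bg = self.background
        if isinstance(bg, np.ndarray):
            bg = bg[mask]
        return replace(
            self,
            probe_ids=self.probe_ids[mask],
            intensities=self.intensities[mask],
            background=bg,
            core_seqs=self.core_seqs,
        )

    def sorted_desc(self) -> "IntensityTable":
        """Stable sort by decreasing intensity, ties broken by probe_id."""
        order = np.lexsort((self.probe_ids, -self.intensities))
        return self.subset(order)

    def core_of(self, probe_id: str) -> str:
        if self.core_seqs is None:
            raise ValueError("table carries no core sequences")
        return self.core_seqs[probe_id]


@dataclass(frozen=True)
class SegmentFit:
    """Two-line fit of the rank-ordered intensity curve.

    ``(steep_slope, steep_intercept)`` describe the steep head over ranks
    ``1..breakpoint_rank``; ``(tail_slope, tail_intercept)`` the tail over the
    remaining ranks.  ``cutoff`` is the tail intercept evaluated at rank 0 —
    the extrapolated tail line value used as the strong-binding threshold.
    """

    steep_slope: float
    steep_intercept: float
    tail_slope: float
    tail_intercept: float
    breakpoint_rank: int
    cutoff: float
    n_above_background: int
    sse: float

    def to_dict(self) -> dict:
        return {
            "steep_slope": self.steep_slope,
            "steep_intercept": self.steep_intercept,
            "tail_slope": self.tail_slope,
            "tail_intercept": self.tail_intercept,
            "breakpoint_rank": self.breakpoint_rank,
            "cutoff": self.cutoff,
            "n_above_background": self.n_above_background,
            "sse": self.sse,
        }


def filter_background(table: IntensityTable) -> IntensityTable:
    """Keep only probes with intensity strictly above background.

    The returned table's ``n``/``mean()``/``sd()`` summarise the survivors.
    """
    if table.background is None:
        raise ValueError(
            "no background supplied: provide a scalar or per-probe background "
            "in the intensity table"
        )
    mask = table.intensities > table.background
    return table.subset(mask)


def _segment_sse(pref: dict[str, np.ndarray], i: np.ndarray, j: np.ndarray):
    """OLS SSE and coefficients for rank segments [i, j) via prefix sums."""
    n = (j - i).astype(float)
    sx = pref["x"][j] - pref["x"][i]
    sy = pref["y"][j] - pref["y"][i]
    sxx = pref["xx"][j] - pref["xx"][i]
    sxy = pref["xy"][j] - pref["xy"][i]
    syy = pref["yy"][j] - pref["yy"][i]
    sxx_c = sxx - sx * sx / n
    sxy_c = sxy - sx * sy / n
    syy_c = syy - sy * sy / n
    slope = sxy_c / sxx_c
    sse = syy_c - sxy_c * slope
    return np.maximum(sse, 0.0)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of the least-squares line through (x, y)."""
    xm, ym = x.mean(), y.mean()
    xc = x - xm
    slope = float(np.dot(xc, y - ym) / np.dot(xc, xc))
    return slope, float(ym - slope * xm)


def fit_rank_segments(
    table: IntensityTable,
    min_points: int = 100,
    min_segment: int = 50,
    breakpoint_range: tuple[float, float] = (0.001, 0.5),
    max_candidates: int = 10_000,
) -> SegmentFit:
    """Fit the steep-head / heavy-tail two-line model to ranked intensities.

    Probes are sorted by decreasing intensity; x is the 1-based rank and y the
    intensity.  Every admissible breakpoint (steep segment length) within
    ``breakpoint_range`` of the ranks, with both segments at least
    ``min_segment`` points, is scored by the total OLS squared error of the
    two independent line fits; when more than ``max_candidates`` breakpoints
    are admissible a uniform stride is searched first and the neighbourhood of
    the best stride point is then searched exhaustively.  Ties go to the
    smaller breakpoint.
    """
    if table.n < min_points:
        raise ValueError(
            f"need at least {min_points} above-background probes to fit the "
            f"two-segment model, got {table.n}"
        )
    ordered = table.sorted_desc()
    y = ordered.intensities
    if np.ptp(y) == 0:
        raise ValueError(
            "degenerate intensity table: all intensities are identical, the "
            "rank-intensity model is undefined"
        )
    n = len(y)
    x = np.arange(1, n + 1, dtype=float)
    pref = {
        "x": np.concatenate(([0.0], np.cumsum(x))),
        "y": np.concatenate(([0.0], np.cumsum(y))),
        "xx": np.concatenate(([0.0], np.cumsum(x * x))),
        "xy": np.concatenate(([0.0], np.cumsum(x * y))),
        "yy": np.concatenate(([0.0], np.cumsum(y * y))),
    }

    lo = max(min_segment, int(np.ceil(breakpoint_range[0] * n)), 2)
    hi = min(int(np.floor(breakpoint_range[1] * n)), n - min_segment, n - 2)
    if hi < lo:
        raise ValueError(
            f"no admissible breakpoint: segments need >= {min_segment} points "
            f"within the [{breakpoint_range[0]:g}, {breakpoint_range[1]:g}] "
            f"rank fraction window (n={n})"
        )

    def total_sse(ms: np.ndarray) -> np.ndarray:
        z = np.zeros(len(ms), dtype=np.intp)
        return _segment_sse(pref, z, ms) + _segment_sse(
            pref, ms, np.full(len(ms), n, dtype=np.intp)
        )

    n_cand = hi - lo + 1
    stride = max(1, int(np.ceil(n_cand / max_candidates)))
    coarse = np.arange(lo, hi + 1, stride, dtype=np.intp)
    best_coarse = coarse[int(np.argmin(total_sse(coarse)))]
    if stride > 1:
        fine = np.arange(
            max(lo, best_coarse - stride), min(hi, best_coarse + stride) + 1, dtype=np.intp
        )
        best = int(fine[int(np.argmin(total_sse(fine)))])
    else:
        best = int(best_coarse)

    a1, b1 = _ols(x[:best], y[:best])
    a2, b2 = _ols(x[best:], y[best:])
    sse = float(
        np.sum((y[:best] - (a1 * x[:best] + b1)) ** 2)
        + np.sum((y[best:] - (a2 * x[best:] + b2)) ** 2)
    )
    return SegmentFit(
        steep_slope=a1,
        steep_intercept=b1,
        tail_slope=a2,
        tail_intercept=b2,
        breakpoint_rank=best,
        cutoff=b2,
        n_above_background=n,
        sse=sse,
    )


def select_strong_probes(table: IntensityTable, fit: SegmentFit) -> IntensityTable:
    """Probes with intensity strictly above the extrapolated tail intercept.

    Returned in decreasing intensity order (ties broken by probe_id).
    """
    ordered = table.sorted_desc()
    return ordered.subset(ordered.intensities > fit.cutoff)
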