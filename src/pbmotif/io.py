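"""Readers and writers for the pipeline's external formats.

Interchange formats are deliberately plain: FASTA for sequences (via
Biopython), tab-separated tables with header rows for probe designs,
intensities and k-mer statistics, JSON for fits, configs and summaries, and
MEME minimal motif format for PWMs.  Tables use 1-based inclusive
coordinates; intensity averages are written with 2 decimals, JSON keeps full
precision.  All writers are deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .array_design import ArrayDesign, Probe, PromoterRecord
from .kmer_stats import KmerStat
from .promoter_scan import GeneHitList, LetterProbabilityMatrix
from .signal_threshold import IntensityTable, SegmentFit

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_design_tsv",
    "read_design_tsv",
    "write_intensity_tsv",
    "read_intensity_tsv",
    "write_kmer_tsv",
    "write_fit_json",
    "read_fit_json",
    "write_meme_motif",
    "read_meme_motif",
    "read_lpm",
    "write_hits_tsv",
    "PipelineConfig",
    "setup_logging",
]

log = logging.getLogger("pbmotif")


def setup_logging(level: str = "INFO") -> None:
    """Timestamped logging to stderr; results go to stdout/files only."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("pbmotif")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


# ---------------------------------------------------------------- sequences


def read_fasta(path: str | Path) -> list[PromoterRecord]:
    """Read promoters from FASTA; ids must be unique, sequences non-empty.

    Sequences are case-folded to upper; validation (ACGTN alphabet) happens
    in :class:`PromoterRecord`.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        records.append(PromoterRecord(gene_id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[PromoterRecord], path: str | Path) -> None:
    out = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def write_probe_fasta(design: ArrayDesign, path: str | Path) -> None:
    """FASTA of full probe sequences (core + linker + poly-T)."""
    out = [
        SeqRecord(Seq(p.full_seq), id=p.probe_id, description="")
        for p in design.probes
    ]
    SeqIO.write(out, str(path), "fasta")


# ------------------------------------------------------------------- tables


def write_design_tsv(design: ArrayDesign, path: str | Path) -> None:
    """Design table; coordinates exported 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_id\ttile_index\tstart\tend\tcore_seq\tfull_seq\n")
        for p in design.probes:
            fh.write(
                f"{p.probe_id}\t{p.gene_id}\t{p.tile_index}\t{p.start + 1}\t"
                f"{p.end}\t{p.core_seq}\t{p.full_seq}\n"
            )


def read_design_tsv(path: str | Path) -> ArrayDesign:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    probes = [
        Probe(
            probe_id=r.probe_id,
            gene_id=r.gene_id,
            tile_index=int(r.tile_index),
            start=int(r.start) - 1,
            end=int(r.end),
            core_seq=r.core_seq,
            full_seq=r.full_seq,
        )
        for r in df.itertuples()
    ]
    gene_ids = list(dict.fromkeys(p.gene_id for p in probes))
    probe_length = probes[0].end - probes[0].start if probes else 40
    step = 20
    per_gene = [p for p in probes if p.gene_id == probes[0].gene_id] if probes else []
    if len(per_gene) > 1:
        step = per_gene[1].start - per_gene[0].start
    return ArrayDesign(
        probes=probes,
        n_genes=len(gene_ids),
        probe_length=probe_length,
        step=step,
        gene_ids=gene_ids,
    )


def write_intensity_tsv(table: IntensityTable, path: str | Path) -> None:
    bg = table.background
    with open(path, "w") as fh:
        if bg is None:
            fh.write("probe_id\tintensity\n")
            for pid, v in zip(table.probe_ids, table.intensities):
                fh.write(f"{pid}\t{v:.6g}\n")
        else:
            bgs = (
                bg
                if isinstance(bg, np.ndarray)
                else np.full(table.n, float(bg))
            )
            fh.write("probe_id\tintensity\tbackground\n")
            for pid, v, b in zip(table.probe_ids, table.intensities, bgs):
                fh.write(f"{pid}\t{v:.6g}\t{b:.6g}\n")


def read_intensity_tsv(
    path: str | Path, core_seqs: dict[str, str] | None = None
) -> IntensityTable:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    bg = None
    if "background" in df.columns:
        vals = df["background"].to_numpy(dtype=float)
        bg = float(vals[0]) if np.all(vals == vals[0]) else vals
    return IntensityTable(
        probe_ids=df["probe_id"].to_numpy(dtype=object),
        intensities=df["intensity"].to_numpy(dtype=float),
        background=bg,
        core_seqs=core_seqs,
    )


def write_kmer_tsv(ranked: Sequence[KmerStat], path: str | Path) -> None:
    """Ranked k-mer table mirroring the published table columns."""
    with open(path, "w") as fh:
        fh.write(
            "rank\tkmer\tintensity_ave\toccurrence_total\t"
            "int_ave_x_occur_tot\toccur_diff_pos\n"
        )
        for rank, s in enumerate(ranked, start=1):
            fh.write(
                f"{rank}\t{s.kmer}\t{s.intensity_ave:.2f}\t{s.occurrence_total}\t"
                f"{s.score_product:.2f}\t{s.distinct_positions}\n"
            )


def write_hits_tsv(hits: GeneHitList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tseq_id\toffset\tstrand\n")
        for h in hits.hits:
            gene = h.seq_id.rpartition("_")[0] or h.seq_id
            for off in h.offsets:
                fh.write(f"{gene}\t{h.seq_id}\t{off + 1}\t{h.strand}\n")


# --------------------------------------------------------------------- JSON


def write_fit_json(fit: SegmentFit, path: str | Path, extra: dict | None = None) -> None:
    payload = fit.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_fit_json(path: str | Path) -> SegmentFit:
    data = json.loads(Path(path).read_text())
    return SegmentFit(
        steep_slope=data["steep_slope"],
        steep_intercept=data["steep_intercept"],
        tail_slope=data["tail_slope"],
        tail_intercept=data["tail_intercept"],
        breakpoint_rank=data["breakpoint_rank"],
        cutoff=data["cutoff"],
        n_above_background=data["n_above_background"],
        sse=data.get("sse", float("nan")),
    )


# ------------------------------------------------------------- MEME motifs


def write_meme_motif(
    pwm_probs: np.ndarray, name: str, nsites: int = 20, path: str | Path | None = None
) -> str:
    """MEME minimal motif format for a 4 x w probability matrix (rows ACGT)."""
    pwm = np.asarray(pwm_probs, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4:
        raise ValueError("PWM must be a 4 x w matrix with rows A/C/G/T")
    if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("PWM columns must each sum to 1")
    w = pwm.shape[1]
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25",
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {w} nsites= {nsites} E= 0",
    ]
    for j in range(w):
        lines.append("  " + "  ".join(f"{pwm[i, j]:.6f}" for i in range(4)))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_meme_motif(path: str | Path) -> LetterProbabilityMatrix:
    """Parse the first motif from a MEME minimal format file."""
    lines = Path(path).read_text().splitlines()
    name = ""
    rows: list[list[float]] = []
    in_matrix = False
    expect_w = None
    for line in lines:
        s = line.strip()
        if s.startswith("MOTIF"):
            name = s.split()[1] if len(s.split()) > 1 else ""
        elif s.startswith("letter-probability matrix"):
            in_matrix = True
            m = re.search(r"w=\s*(\d+)", s)
            if m:
                expect_w = int(m.group(1))
            continue
        elif in_matrix:
            if not s:
                break
            parts = s.split()
            try:
                rows.append([float(x) for x in parts[:4]])
            except ValueError:
                break
            if expect_w is not None and len(rows) == expect_w:
                break
    if not rows:
        raise ValueError(f"no letter-probability matrix found in {path}")
    # rows may sum slightly off 1 in published matrices; renormalise gently
    probs = np.array(rows, dtype=float)
    sums = probs.sum(axis=1, keepdims=True)
    if np.any(np.abs(sums - 1.0) > 1e-3):
        raise ValueError(f"letter-probability rows in {path} do not sum to 1")
    return LetterProbabilityMatrix(probs=probs / sums, source_id=name)


def read_lpm(path: str | Path) -> LetterProbabilityMatrix:
    """Read a letter-probability matrix: MEME minimal or bare w x 4 numbers."""
    text = Path(path).read_text()
    if "MEME version" in text:
        return read_meme_motif(path)
    rows = []
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if parts[0].upper() in ("A", "C", "G", "T", "POS", "POSITION"):
            continue
        vals = [float(x) for x in parts[-4:]]
        rows.append(vals)
    if not rows:
        raise ValueError(f"no matrix rows found in {path}")
    return LetterProbabilityMatrix(probs=np.array(rows), source_id=str(path))


# ------------------------------------------------------------------ config


@dataclass
class PipelineConfig:
    """All tunable stage parameters plus paths for one pipeline run."""

    # stage parameters
    probe_length: int = 40
    step: int = 20
    k: int = 9
    sort_mode: str = "product"  # or "intensity"
    min_occurrence: int | str = 1  # integer floor or "auto4x"
    gc_min_run: int = 4
    max_mismatch: int | None = 2
    core_len: int = 5
    max_clusters: int = 10
    extend_steps: int = 2
    occupancy_min: float = 0.5
    min_distinct: int = 6
    include_rc_scan: bool = False
    # paths
    fasta: str | None = None
    intensities: str | None = None
    design: str | None = None
    out_dir: str = "pbmotif_run"
    # misc
    seed: int | None = None
    log_level: str = "INFO"

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
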