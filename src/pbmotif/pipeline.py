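"""The umbrella pipeline: threshold -> k-mers -> cluster -> refine -> map.

Chains the analysis stages in order on a probe intensity table plus design:
background filtering and the two-segment rank fit, strong-probe selection,
k-mer decomposition with the G/C-run filter and ranking, seed clustering with
PWM/consensus, mutation scan and greedy extension of the top seed, the
Mann–Whitney enrichment summary for the consensus, and the probe/gene scan.
Every stage's outputs are written into the run directory and a summary JSON
collects the headline numbers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as pio
from .enrichment_stats import enrichment_summary
from .kmer_stats import decompose, gc_run_filter, rank_kmers
from .motif_discovery import cluster_all
from .motif_refine import extend_motif, mutation_scan
from .promoter_scan import scan_probes
from .signal_threshold import filter_background, fit_rank_segments, select_strong_probes

log = logging.getLogger("pbmotif.pipeline")

__all__ = ["run_pipeline"]


def run_pipeline(config: "pio.PipelineConfig") -> dict:
    """Execute the full analysis and return the machine-readable summary.

    Requires ``config.intensities`` and ``config.design`` (TSV paths).  Any
    stage failure aborts with the stage name prefixed to the cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    stage = "load"
    try:
        if config.intensities is None or config.design is None:
            raise ValueError("config must provide 'intensities' and 'design' paths")
        design = pio.read_design_tsv(config.design)
        table = pio.read_intensity_tsv(config.intensities, core_seqs=design.core_seqs())
        log.info("loaded %d probes from %d genes", table.n, design.n_genes)

        stage = "threshold"
        above = filter_background(table)
        fit = fit_rank_segments(above)
        strong = select_strong_probes(above, fit)
        pio.write_fit_json(
            fit,
            out / "fit.json",
            extra={
                "n_strong": strong.n,
                "above_mean": above.mean(),
                "above_sd": above.sd(),
            },
        )
        pio.write_intensity_tsv(strong, out / "strong.tsv")
        log.info(
            "cutoff %.1f at breakpoint rank %d; %d strong probes",
            fit.cutoff,
            fit.breakpoint_rank,
            strong.n,
        )

        stage = "kmers"
        kt = decompose(strong, config.k)
        kt, n_discarded = gc_run_filter(kt, config.gc_min_run)
        ranked = rank_kmers(kt, config.sort_mode, config.min_occurrence)
        if not ranked:
            raise ValueError("no k-mers survive the occurrence floor")
        pio.write_kmer_tsv(ranked[:1000], out / "kmers.tsv")

        stage = "cluster"
        clusters = cluster_all(
            ranked,
            max_mismatch=config.max_mismatch,
            core_len=config.core_len,
            max_clusters=config.max_clusters,
        )
        top = clusters[0]
        for i, cl in enumerate(clusters, start=1):
            pio.write_meme_motif(
                cl.pwm_probs,
                name=f"cluster{i}_{cl.consensus}",
                nsites=cl.n_members,
                path=out / f"cluster_{i}.meme",
            )
        log.info(
            "%d clusters; top seed %s -> consensus %s (%d members)",
            len(clusters),
            top.seed,
            top.consensus,
            top.n_members,
        )

        stage = "refine"
        profile = mutation_scan(top.seed, kt)
        trace = extend_motif(top.seed, kt, config.extend_steps)
        profile.to_frame().to_csv(out / "mutation_profile.tsv", sep="\t", index=False)
        (out / "extension.json").write_text(
            json.dumps(trace.to_dict(), indent=2) + "\n"
        )

        stage = "stats"
        scan_motif = top.scan_motif()
        enrich = enrichment_summary(above, fit, scan_motif)
        (out / "enrichment.json").write_text(
            json.dumps(enrich.to_dict(), indent=2) + "\n"
        )

        stage = "scan"
        hits = scan_probes(strong, scan_motif, include_rc=config.include_rc_scan)
        pio.write_hits_tsv(hits, out / "hits.tsv")
        (out / "genes.txt").write_text("".join(g + "\n" for g in hits.genes))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "n_probes": table.n,
        "n_above_background": above.n,
        "cutoff": fit.cutoff,
        "breakpoint_rank": fit.breakpoint_rank,
        "n_strong": strong.n,
        "k": config.k,
        "n_distinct_kmers": kt.n_distinct,
        "total_occurrence": kt.total_occurrence,
        "n_gc_discarded": n_discarded,
        "top_kmers": [s.kmer for s in ranked[:10]],
        "n_clusters": len(clusters),
        "cluster_sizes": [c.n_members for c in clusters],
        "seed": top.seed,
        "consensus": top.consensus,
        "core_motif": scan_motif,
        "extended_motif": trace.final_motif,
        "max_delta_position": profile.max_delta_position + 1,
        "mwu_p_value": enrich.p_value,
        "strong_fraction": enrich.strong_fraction,
        "n_hit_probes": hits.n_probes,
        "n_hit_genes": hits.n_genes,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
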