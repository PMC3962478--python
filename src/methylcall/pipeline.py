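"""End-to-end orchestration: counts -> conversion -> calling -> annotation
-> report, with a JSON manifest of every artifact written."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import annotate, calling, counts as counts_mod, report, seq
from .calling import CallingConfig
from .counts import QualityRule

log = logging.getLogger("methylcall")


@dataclass
class PipelineConfig:
    genome_fasta: str
    gff3: str
    reads_fastq: Optional[str] = None
    counts_tsv: Optional[str] = None
    spike_in_name: str = "lambda_spike"
    quality_rule: QualityRule = field(default_factory=QualityRule)
    calling: CallingConfig = field(default_factory=CallingConfig)
    conversion_source: str = "spike_in"   # or "non_cpg"
    outdir: str = "methylcall_out"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run every stage and write all artifacts under ``config.outdir``.

    Any stage failure is re-raised with the stage name attached. Returns a
    result dict with the in-memory tables plus the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    try:
        genome = seq.read_fasta(config.genome_fasta)
        models = annotate.read_gff3(config.gff3)

        stage = "counts"
        if config.counts_tsv is not None:
            table = counts_mod.read_counts(config.counts_tsv)
        elif config.reads_fastq is not None:
            from .simulate import read_reads_fastq

            reads = read_reads_fastq(config.reads_fastq)
            table = counts_mod.tally_counts(reads, genome, config.quality_rule)
        else:
            raise ValueError("config names neither reads_fastq nor counts_tsv")
        counts_path = outdir / "counts.tsv"
        counts_mod.write_counts(table, counts_path)

        stage = "conversion"
        estimates: Dict[str, Optional[calling.ConversionEstimate]] = {
            "spike_in": None, "non_cpg": None,
        }
        try:
            estimates["spike_in"] = calling.estimate_conversion_spikein(
                table, config.spike_in_name
            )
        except ValueError:
            log.warning("no spike-in observations; spike-in estimate unavailable")
        try:
            estimates["non_cpg"] = calling.estimate_conversion_noncpg(
                table, exclude_contigs=[config.spike_in_name]
            )
        except ValueError:
            log.warning("no non-CpG observations; non-CpG estimate unavailable")
        conversion = estimates.get(config.conversion_source)
        if conversion is None:
            other = "non_cpg" if config.conversion_source == "spike_in" else "spike_in"
            conversion = estimates.get(other)
        if conversion is None:
            raise ValueError("no conversion-rate estimate available")
        for name, est in estimates.items():
            if est is not None:
                log.info("conversion estimate (%s): %.4f%% of %d observations",
                         name, 100 * est.rate, est.n_total)

        stage = "calling"
        calls = calling.call_methylation(table, conversion, config.calling)
        calls_path = outdir / "calls.tsv"
        calling.write_calls(calls, calls_path)

        stage = "annotation"
        index = annotate.RegionIndex(models)
        census = counts_mod.context_census(genome, exclude=[config.spike_in_name])
        genome_calls = calls[calls["contig"] != config.spike_in_name]
        ctx_summary = report.context_summary_from_calls(census, genome_calls)
        region_census = annotate.region_cg_census(
            genome, index, spike_in_name=config.spike_in_name
        )
        region_cg = report.region_summary_from_calls(
            region_census, genome_calls, index, site_scope="cg_only"
        )
        region_all = report.region_summary_from_calls(
            region_census, genome_calls, index, site_scope="all_contexts"
        )
        pairs, both_strand_sites = annotate.pair_symmetric_cpgs(genome_calls)
        stats = annotate.gene_methylation_stats(genome_calls, models)
        ranks = annotate.rank_genes(stats, by="proportion")
        cov = counts_mod.coverage_distribution(table)

        stage = "report"
        region_cg.to_csv(outdir / "region_summary_cg.tsv", sep="\t", index=False)
        region_all.to_csv(outdir / "region_summary_all.tsv", sep="\t", index=False)
        ctx_summary["table"].to_csv(outdir / "context_summary.tsv", sep="\t", index=False)
        stats.to_csv(outdir / "gene_stats.tsv", sep="\t", index=False)
        pairs.to_csv(outdir / "symmetric_pairs.tsv", sep="\t", index=False)
        text = report.render_tables(
            context=ctx_summary, region=region_cg, gene_ranks=ranks.head(20),
            coverage_dist=cov, pair_count=both_strand_sites,
        )
        report_path = outdir / "report.txt"
        report_path.write_text(text)
        run_report = {
            "conversion_estimates": {
                name: None if est is None else {
                    "rate": est.rate, "n_converted": est.n_converted,
                    "n_total": est.n_total,
                }
                for name, est in estimates.items()
            },
            "conversion_used": conversion.method,
            "m_tests": int(len(calls)),
            "fdr_alpha": config.calling.fdr_alpha,
            "correction": config.calling.correction,
            "coverage_window": [config.calling.min_coverage,
                                config.calling.max_coverage],
            "significant_per_context": {
                k: int(v) for k, v in
                calls[calls["significant"]].groupby("context").size().items()
            },
            "both_strand_methylated_sites": int(both_strand_sites),
            "median_coverage": cov["median"],
            "fraction_ge2": cov["fraction_ge2"],
        }
        (outdir / "run_report.json").write_text(
            json.dumps(run_report, indent=2, sort_keys=True) + "\n"
        )
        artifacts = [
            counts_path, calls_path, report_path,
            outdir / "context_summary.tsv", outdir / "region_summary_cg.tsv",
            outdir / "region_summary_all.tsv", outdir / "gene_stats.tsv",
            outdir / "symmetric_pairs.tsv", outdir / "run_report.json",
        ]
        manifest = {p.name: _sha256(p) for p in artifacts}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {
        "counts": table,
        "calls": calls,
        "conversion_estimates": estimates,
        "conversion_used": conversion,
        "context_summary": ctx_summary,
        "region_summary_cg": region_cg,
        "region_summary_all": region_all,
        "gene_stats": stats,
        "gene_ranks": ranks,
        "pairs": pairs,
        "both_strand_sites": both_strand_sites,
        "coverage": cov,
        "run_report": run_report,
        "manifest": manifest,
    }
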