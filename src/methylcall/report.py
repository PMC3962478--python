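"""Summary tables in the study's reporting conventions.

Builds the three headline summaries — methylation by sequence context,
methylation by genomic region, and top methylated transcripts — plus the
coverage distribution, and renders them deterministically as TSV. Rounding
is half-away-from-zero at the printed precision: context shares and
per-region methylation percentages to 3 significant figures, region shares
to 2 decimal places, gene proportions to 5 decimal places.
"""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Mapping

import pandas as pd

CONTEXT_ORDER = ["CG", "CHG", "CHH", "UNCLASSIFIED"]
REGION_ORDER = ["exon", "intron", "intergenic"]


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero at a fixed number of decimals."""
    x = float(x)
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 3) -> float:
    """Round half away from zero to ``sig`` significant figures."""
    x = float(x)
    if x == 0 or math.isnan(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exponent)


# ---------------------------------------------------------------------------
# Context summary (sequence-context accounting)


def context_summary(sites_per_context: Mapping[str, int],
                    methylated_per_context: Mapping[str, int]) -> Dict[str, object]:
    """Per-context site and methylated-site totals with shares.

    Returns the table (one row per context plus a total row) and the two
    global rates: methylated percentage of all cytosines, and of CpG sites.
    """
    for ctx, m in methylated_per_context.items():
        if m > sites_per_context.get(ctx, 0):
            raise ValueError(f"more methylated than total sites in context {ctx}")
    total_sites = sum(sites_per_context.get(c, 0) for c in CONTEXT_ORDER)
    total_meth = sum(methylated_per_context.get(c, 0) for c in CONTEXT_ORDER)
    rows = []
    for ctx in CONTEXT_ORDER:
        m = methylated_per_context.get(ctx, 0)
        share = 100.0 * m / total_meth if total_meth else 0.0
        rows.append(
            {
                "context": ctx,
                "sites_in_genome": sites_per_context.get(ctx, 0),
                "methylated_sites": m,
                "pct_of_all_mC": share,
            }
        )
    table = pd.DataFrame(rows)
    cg_sites = sites_per_context.get("CG", 0)
    cg_meth = methylated_per_context.get("CG", 0)
    return {
        "table": table,
        "total_sites": total_sites,
        "total_methylated": total_meth,
        "pct_all_C_methylated": 100.0 * total_meth / total_sites if total_sites else 0.0,
        "pct_CG_methylated": 100.0 * cg_meth / cg_sites if cg_sites else 0.0,
        "empty_total": total_meth == 0,
    }


def context_summary_from_calls(census: Mapping[str, int],
                               calls: pd.DataFrame) -> Dict[str, object]:
    sig = calls[calls["significant"].astype(bool)]
    meth = sig.groupby("context").size().to_dict()
    return context_summary(census, meth)


# ---------------------------------------------------------------------------
# Region summary (genomic-region accounting)


def region_summary(cg_per_region: Mapping[str, int],
                   mcg_per_region: Mapping[str, int]) -> pd.DataFrame:
    """Per-region CpG and methylated-CpG counts with the two percentage
    columns: percent of the region's CpGs methylated, and the region's
    share of all methylated CpGs."""
    total_mcg = sum(mcg_per_region.get(r, 0) for r in REGION_ORDER)
    rows = []
    for region in REGION_ORDER:
        n_cg = cg_per_region.get(region, 0)
        n_mcg = mcg_per_region.get(region, 0)
        if n_mcg > n_cg:
            raise ValueError(f"more methylated CpGs than CpGs in {region}")
        rows.append(
            {
                "region": region,
                "n_CG": n_cg,
                "n_mCG": n_mcg,
                "pct_mCG_of_region": 100.0 * n_mcg / n_cg if n_cg else float("nan"),
                "pct_of_all_mCG": 100.0 * n_mcg / total_mcg if total_mcg else 0.0,
            }
        )
    return pd.DataFrame(rows)


def region_summary_from_calls(region_census: Mapping[str, int],
                              calls: pd.DataFrame,
                              region_index,
                              site_scope: str = "cg_only") -> pd.DataFrame:
    """Region summary from a call table.

    ``site_scope`` selects whether the methylated-site column counts only
    CG-context calls or significant calls of every context (both views are
    reported by the pipeline because published context and region tallies
    need not agree on scope).
    """
    if site_scope not in ("cg_only", "all_contexts"):
        raise ValueError(f"unknown site_scope {site_scope!r}")
    sig = calls[calls["significant"].astype(bool)]
    if site_scope == "cg_only":
        sig = sig[sig["context"] == "CG"]
    meth: Dict[str, int] = {r: 0 for r in REGION_ORDER}
    for contig, sub in sig.groupby("contig"):
        labels = region_index.classify(contig, sub["position0"].to_numpy())
        for lab in labels:
            meth[str(lab)] += 1
    return region_summary(
        {r: region_census.get(r, 0) for r in REGION_ORDER}, meth
    )


# ---------------------------------------------------------------------------
# Rendering


def _fmt_sig3(x: float) -> str:
    if math.isnan(x):
        return "NA"
    v = round_sig(x, 3)
    if v != 0 and abs(v) < 0.01:
        return f"{v:.2e}"
    return f"{v:g}"


def render_tables(context: Dict[str, object] | None = None,
                  region: pd.DataFrame | None = None,
                  gene_ranks: pd.DataFrame | None = None,
                  coverage_dist: Dict[str, object] | None = None,
                  pair_count: int | None = None) -> str:
    """Deterministic plain-text report of the available summaries."""
    blocks = []
    if context is not None:
        lines = ["# Methylated cytosines by sequence context",
                 "context\tsites_in_genome\tmethylated_sites\tpct_of_all_mC"]
        for _, r in context["table"].iterrows():
            lines.append(
                f"{r['context']}\t{r['sites_in_genome']}\t"
                f"{r['methylated_sites']}\t{_fmt_sig3(r['pct_of_all_mC'])}"
            )
        lines.append(
            f"Total\t{context['total_sites']}\t{context['total_methylated']}\t"
        )
        lines.append(
            "global: "
            f"{round_half_up(context['pct_all_C_methylated'], 2):.2f}% of all "
            "cytosines methylated, "
            f"{round_half_up(context['pct_CG_methylated'], 2):.2f}% of CpGs"
        )
        if context.get("empty_total"):
            lines.append("note: no methylated sites (shares reported as 0)")
        blocks.append("\n".join(lines))
    if region is not None:
        lines = ["# Methylation by genomic region",
                 "region\tn_CG\tn_mCG\tpct_mCG_of_region\tpct_of_all_mCG"]
        for _, r in region.iterrows():
            pct_reg = ("NA" if math.isnan(r["pct_mCG_of_region"])
                       else _fmt_sig3(r["pct_mCG_of_region"]))
            lines.append(
                f"{r['region']}\t{r['n_CG']}\t{r['n_mCG']}\t{pct_reg}\t"
                f"{round_half_up(r['pct_of_all_mCG'], 2):.2f}"
            )
        blocks.append("\n".join(lines))
    if pair_count is not None:
        blocks.append(
            "# Symmetric CpG methylation\n"
            f"both_strand_methylated_sites\t{pair_count}"
        )
    if gene_ranks is not None:
        lines = ["# Top methylated transcripts",
                 "transcript\tcontig\tproportion\tsites\tpct_sites_in_introns"]
        for _, r in gene_ranks.iterrows():
            pct_in = ("NA" if math.isnan(r["pct_sites_in_introns"])
                      else _fmt_sig3(r["pct_sites_in_introns"]))
            lines.append(
                f"{r['transcript_id']}\t{r['contig']}\t"
                f"{round_half_up(r['proportion'], 5):.5f}\t"
                f"{r['n_meth_sites']}\t{pct_in}"
            )
        blocks.append("\n".join(lines))
    if coverage_dist is not None:
        lines = ["# Coverage distribution",
                 "coverage\tproportion\tcumulative_ge"]
        for _, r in coverage_dist["distribution"].iterrows():
            lines.append(
                f"{int(r['coverage'])}\t{r['proportion']:.6f}\t{r['cumulative_ge']:.6f}"
            )
        lines.append(f"median\t{coverage_dist['median']:g}")
        lines.append(f"fraction_ge2\t{coverage_dist['fraction_ge2']:.4f}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
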