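"""Gene models and region-level annotation of methylation calls.

Maps called sites onto exon/intron/intergenic regions, pairs symmetric CpG
sites across strands, and ranks transcripts by gene-body methylation. The
ranking unit is the transcript (isoforms rank independently), and a gene's
"length" is its genomic span including introns, so intronic methylated
sites can be reported for the same ranked entity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .counts import CONTEXT_CG, context_code_arrays

REGION_EXON = "exon"
REGION_INTRON = "intron"
REGION_INTERGENIC = "intergenic"


@dataclass
class GeneModel:
    """A transcript: contiguous genomic span plus ordered disjoint exons.

    Coordinates are 0-based inclusive internally; GFF3 I/O converts from the
    1-based inclusive convention on ingest/egress.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    start0: int
    end0: int
    exons: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s, e) in self.exons:
            if s < self.start0 or e > self.end0:
                raise ValueError(
                    f"exon ({s},{e}) outside span ({self.start0},{self.end0}) "
                    f"for {self.transcript_id}"
                )
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    @property
    def span_length(self) -> int:
        return self.end0 - self.start0 + 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def intron_intervals(self) -> List[Tuple[int, int]]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


# ---------------------------------------------------------------------------
# GFF3 I/O


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: Dict[str, List[GeneModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gene_id, isoforms in by_gene.items():
            g0 = min(m.start0 for m in isoforms)
            g1 = max(m.end0 for m in isoforms)
            m0 = isoforms[0]
            fh.write(
                f"{m0.contig}\tmethylcall\tgene\t{g0 + 1}\t{g1 + 1}\t.\t"
                f"{m0.strand}\t.\tID={gene_id}\n"
            )
            for m in isoforms:
                fh.write(
                    f"{m.contig}\tmethylcall\tmRNA\t{m.start0 + 1}\t{m.end0 + 1}\t.\t"
                    f"{m.strand}\t.\tID={m.transcript_id};Parent={gene_id}\n"
                )
                for i, (s, e) in enumerate(m.exons, 1):
                    fh.write(
                        f"{m.contig}\tmethylcall\texon\t{s + 1}\t{e + 1}\t.\t"
                        f"{m.strand}\t.\tID={m.transcript_id}.exon{i};"
                        f"Parent={m.transcript_id}\n"
                    )


def read_gff3(path: str | Path) -> List[GeneModel]:
    """Parse gene models (gene/mRNA/exon features) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: List[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        exons = [
            (ex.start - 1, ex.end - 1)
            for ex in db.children(mrna, featuretype="exon", order_by="start")
        ]
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                contig=mrna.seqid,
                strand=mrna.strand,
                start0=mrna.start - 1,
                end0=mrna.end - 1,
                exons=exons,
            )
        )
    models.sort(key=lambda m: (m.contig, m.start0, m.transcript_id))
    return models


# ---------------------------------------------------------------------------
# Region assignment

def _merge_intervals(ivs: Iterable[Tuple[int, int]]) -> Tuple[np.ndarray, np.ndarray]:
    ivs = sorted(ivs)
    starts: List[int] = []
    ends: List[int] = []
    for s, e in ivs:
        if starts and s <= ends[-1] + 1:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


class RegionIndex:
    """Merged exon and transcript-span intervals per contig for O(log n)
    position classification with exon > intron > intergenic precedence."""

    def __init__(self, models: Sequence[GeneModel]):
        exons: Dict[str, List[Tuple[int, int]]] = {}
        spans: Dict[str, List[Tuple[int, int]]] = {}
        for m in models:
            spans.setdefault(m.contig, []).append((m.start0, m.end0))
            exons.setdefault(m.contig, []).extend(m.exons)
        self._exons = {c: _merge_intervals(v) for c, v in exons.items()}
        self._spans = {c: _merge_intervals(v) for c, v in spans.items()}

    @staticmethod
    def _inside(starts: np.ndarray, ends: np.ndarray, pos: np.ndarray) -> np.ndarray:
        if len(starts) == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(pos), dtype=bool)
        hit[ok] = pos[ok] <= ends[idx[ok]]
        return hit

    def classify(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Return an array of region labels for 0-based positions."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(len(positions), REGION_INTERGENIC, dtype=object)
        es, ee = self._exons.get(contig, (np.empty(0, np.int64), np.empty(0, np.int64)))
        ss, se = self._spans.get(contig, (np.empty(0, np.int64), np.empty(0, np.int64)))
        in_span = self._inside(ss, se, positions)
        out[in_span] = REGION_INTRON
        in_exon = self._inside(es, ee, positions)
        out[in_exon] = REGION_EXON
        return out


def assign_region(contig: str, position0: int, models: Sequence[GeneModel] | RegionIndex) -> str:
    """Classify one genomic position as exon, intron or intergenic.

    Exonic in any transcript wins over intronic in another (overlapping
    isoforms disagree exon-vs-intron; the partition keeps no ambiguous
    class).
    """
    index = models if isinstance(models, RegionIndex) else RegionIndex(models)
    return str(index.classify(contig, np.asarray([position0]))[0])


def region_cg_census(genome: Mapping[str, np.ndarray],
                     models: Sequence[GeneModel] | RegionIndex,
                     spike_in_name: str | None = None) -> Dict[str, int]:
    """Count CpG-context cytosine sites (both strands) per region class.

    The three class counts partition the genome's total CG-site count.
    """
    index = models if isinstance(models, RegionIndex) else RegionIndex(models)
    census = {REGION_EXON: 0, REGION_INTRON: 0, REGION_INTERGENIC: 0}
    for contig, arr in genome.items():
        if spike_in_name is not None and contig == spike_in_name:
            continue
        plus, minus = context_code_arrays(arr)
        for codes in (plus, minus):
            pos = np.nonzero(codes == CONTEXT_CG)[0]
            labels, counts = np.unique(index.classify(contig, pos), return_counts=True)
            for lab, n in zip(labels, counts):
                census[str(lab)] += int(n)
    return census


# ---------------------------------------------------------------------------
# Symmetric CpG pairs


def pair_symmetric_cpgs(calls: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Pair plus-strand CpG calls at i with minus-strand calls at i+1.

    Returns the pair table (one row per CpG dinucleotide with significant
    calls on both strands) and the both-strand methylated site count, which
    is twice the number of such pairs.
    """
    cg = calls[calls["context"] == "CG"]
    sig = cg[cg["significant"].astype(bool)]
    plus = sig[sig["strand"] == "+"]
    minus = sig[sig["strand"] == "-"]
    left = plus[["contig", "position0"]].copy()
    left["partner0"] = left["position0"] + 1
    right = minus[["contig", "position0"]].rename(columns={"position0": "partner0"})
    pairs = left.merge(right, on=["contig", "partner0"], how="inner")
    pairs = pairs.rename(columns={"position0": "plus_position0", "partner0": "minus_position0"})
    pairs = pairs.sort_values(["contig", "plus_position0"]).reset_index(drop=True)
    return pairs, 2 * len(pairs)


# ---------------------------------------------------------------------------
# Per-transcript methylation statistics


def gene_methylation_stats(calls: pd.DataFrame,
                           models: Sequence[GeneModel],
                           collapse_cpg: bool = False) -> pd.DataFrame:
    """Per-transcript methylation: site count, proportion per bp of span,
    and the percentage of methylated sites falling in introns.

    Significant sites on either strand and in any context count toward a
    transcript if they lie within its genomic span; ``pct_sites_in_introns``
    is NaN for single-exon transcripts (no introns to report). With
    ``collapse_cpg`` the two strands of one CpG dinucleotide count as a
    single site at the plus-strand C's position.
    """
    sig = calls[calls["significant"].astype(bool)]
    if collapse_cpg:
        sig = sig.copy()
        minus_cg = (sig["context"] == "CG") & (sig["strand"] == "-")
        sig.loc[minus_cg, "position0"] = sig.loc[minus_cg, "position0"] - 1
        sig = sig.drop_duplicates(subset=["contig", "position0"])
    pos_by_contig = {
        contig: np.sort(sub["position0"].to_numpy())
        for contig, sub in sig.groupby("contig")
    }
    rows = []
    for m in models:
        if m.span_length <= 0:
            raise ValueError(f"zero-length span for {m.transcript_id}")
        pos = pos_by_contig.get(m.contig, np.empty(0, dtype=np.int64))
        lo = np.searchsorted(pos, m.start0, side="left")
        hi = np.searchsorted(pos, m.end0, side="right")
        inside = pos[lo:hi]
        n_sites = len(inside)
        if m.n_exons > 1:
            in_exon = np.zeros(n_sites, dtype=bool)
            for s, e in m.exons:
                in_exon |= (inside >= s) & (inside <= e)
            n_intronic = int((~in_exon).sum())
            pct_introns = 100.0 * n_intronic / n_sites if n_sites else 0.0
        else:
            pct_introns = float("nan")
        rows.append(
            {
                "transcript_id": m.transcript_id,
                "gene_id": m.gene_id,
                "contig": m.contig,
                "length_bp": m.span_length,
                "n_meth_sites": n_sites,
                "proportion": n_sites / m.span_length,
                "pct_sites_in_introns": pct_introns,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene_id", "contig", "length_bp",
            "n_meth_sites", "proportion", "pct_sites_in_introns",
        ],
    )


def rank_genes(stats: pd.DataFrame, by: str = "proportion",
               top_n: int | None = None) -> pd.DataFrame:
    """Rank transcripts by methylation proportion or by site count.

    Descending on the chosen key, ties broken by the other key descending,
    then by transcript_id ascending, so the ranking is invariant to input
    order. Isoforms rank independently.
    """
    if by not in ("proportion", "count"):
        raise ValueError(f"unknown ranking key: {by!r}")
    if top_n is not None and top_n < 0:
        raise ValueError("top_n must be >= 0")
    primary = "proportion" if by == "proportion" else "n_meth_sites"
    secondary = "n_meth_sites" if by == "proportion" else "proportion"
    ranked = stats.sort_values(
        [primary, secondary, "transcript_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if top_n is not None:
        ranked = ranked.head(top_n).reset_index(drop=True)
    return ranked
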