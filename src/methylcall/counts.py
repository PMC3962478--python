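"""Strand-aware per-cytosine bisulfite tallies.

Every cytosine in the reference (a C on the plus strand, or a G position
read as C on the minus strand) is a potential site. Reads inform only
cytosines on their strand of bisulfite origin: an unconverted base reads C,
a converted one reads T. Read bases pass into the tally only under a
base-quality rule: the focal base needs Phred >= 20 and its neighbors
(up to three per side) must match the reference in bisulfite space with
Phred >= 15.

Sequence context is classified from the two bases 3' of the cytosine on its
own strand: CG, CHG, CHH (H = A, T or C), or UNCLASSIFIED when the window
runs off the contig end or contains an ambiguous base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Tuple

import numpy as np
import pandas as pd

CONTEXT_NONE = 0
CONTEXT_CG = 1
CONTEXT_CHG = 2
CONTEXT_CHH = 3
CONTEXT_UNCLASSIFIED = 4

CONTEXT_NAMES = {
    CONTEXT_CG: "CG",
    CONTEXT_CHG: "CHG",
    CONTEXT_CHH: "CHH",
    CONTEXT_UNCLASSIFIED: "UNCLASSIFIED",
}
CONTEXT_CODES = {v: k for k, v in CONTEXT_NAMES.items()}

# TSV dialect uses the short token
_CTX_TO_TSV = {"CG": "CG", "CHG": "CHG", "CHH": "CHH", "UNCLASSIFIED": "UNK"}
_TSV_TO_CTX = {v: k for k, v in _CTX_TO_TSV.items()}

COUNTS_COLUMNS = ["contig", "position0", "strand", "context", "count_C", "count_T"]


@dataclass(frozen=True)
class CytosineSite:
    contig: str
    position0: int
    strand: str
    context: str


@dataclass(frozen=True)
class QualityRule:
    """Base filter: focal Phred >= min_base_quality; every existing read
    base within neighbor_window positions per side must match the reference
    in bisulfite space with Phred >= neighbor_min_quality."""

    min_base_quality: int = 20
    neighbor_min_quality: int = 15
    neighbor_window: int = 3

    def __post_init__(self) -> None:
        for name in ("min_base_quality", "neighbor_min_quality", "neighbor_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Context classification


def context_code_arrays(contig_seq: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised context codes for one contig.

    Returns (plus, minus) int8 arrays over all positions: nonzero exactly at
    cytosine sites of that strand (C on plus; G on plus = C on minus, indexed
    at the G's plus-strand position).
    """
    n = len(contig_seq)
    plus = np.zeros(n, dtype=np.int8)
    minus = np.zeros(n, dtype=np.int8)
    if n == 0:
        return plus, minus
    is_c = contig_seq == b"C"
    is_g = contig_seq == b"G"
    is_h = is_c | (contig_seq == b"A") | (contig_seq == b"T")       # H = A,C,T
    is_hc = is_g | (contig_seq == b"A") | (contig_seq == b"T")      # complement is H
    is_acgt = is_c | is_g | (contig_seq == b"A") | (contig_seq == b"T")

    # plus strand: look at +1, +2
    plus[is_c] = CONTEXT_UNCLASSIFIED
    c_idx = np.nonzero(is_c)[0]
    has1 = c_idx + 1 < n
    i1 = c_idx[has1]
    plus[i1[is_g[i1 + 1]]] = CONTEXT_CG
    h1 = i1[is_h[i1 + 1]]
    has2 = h1 + 2 < n
    h12 = h1[has2]
    plus[h12[is_g[h12 + 2]]] = CONTEXT_CHG
    plus[h12[is_h[h12 + 2]]] = CONTEXT_CHH
    # non-ACGT at +1, or +1 exists but is ambiguous -> stays UNCLASSIFIED
    bad1 = i1[~is_acgt[i1 + 1]]
    plus[bad1] = CONTEXT_UNCLASSIFIED

    # minus strand: C at plus-strand G positions; 3' direction is -1, -2
    minus[is_g] = CONTEXT_UNCLASSIFIED
    g_idx = np.nonzero(is_g)[0]
    has1m = g_idx - 1 >= 0
    j1 = g_idx[has1m]
    minus[j1[is_c[j1 - 1]]] = CONTEXT_CG
    hm1 = j1[is_hc[j1 - 1]]
    has2m = hm1 - 2 >= 0
    hm12 = hm1[has2m]
    minus[hm12[is_c[hm12 - 2]]] = CONTEXT_CHG
    minus[hm12[is_hc[hm12 - 2]]] = CONTEXT_CHH
    badm = j1[~is_acgt[j1 - 1]]
    minus[badm] = CONTEXT_UNCLASSIFIED
    return plus, minus


def classify_context(genome: Mapping[str, np.ndarray], contig: str,
                     position0: int, strand: str) -> str:
    """Sequence context of one cytosine site."""
    arr = genome[contig]
    base = arr[position0]
    if strand == "+":
        if base != b"C":
            raise ValueError(
                f"{contig}:{position0}+ holds {base.decode()}, not C"
            )
        plus, _ = context_code_arrays(arr)
        return CONTEXT_NAMES[int(plus[position0])]
    elif strand == "-":
        if base != b"G":
            raise ValueError(
                f"{contig}:{position0}- holds {base.decode()}, not G"
            )
        _, minus = context_code_arrays(arr)
        return CONTEXT_NAMES[int(minus[position0])]
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def enumerate_cytosines(genome: Mapping[str, np.ndarray]) -> Iterator[CytosineSite]:
    """Yield every cytosine site of the genome, both strands, with context,
    sorted by (contig, position0, strand)."""
    for contig, arr in genome.items():
        plus, minus = context_code_arrays(arr)
        pos = np.nonzero((plus > 0) | (minus > 0))[0]
        for p in pos:
            if plus[p]:
                yield CytosineSite(contig, int(p), "+", CONTEXT_NAMES[int(plus[p])])
            if minus[p]:
                yield CytosineSite(contig, int(p), "-", CONTEXT_NAMES[int(minus[p])])


def context_census(genome: Mapping[str, np.ndarray],
                   exclude: Iterable[str] = ()) -> Dict[str, int]:
    """Per-context counts of cytosine sites across both strands."""
    skip = set(exclude)
    census = {name: 0 for name in CONTEXT_NAMES.values()}
    for contig, arr in genome.items():
        if contig in skip:
            continue
        for codes in context_code_arrays(arr):
            vals, cnts = np.unique(codes[codes > 0], return_counts=True)
            for v, c in zip(vals, cnts):
                census[CONTEXT_NAMES[int(v)]] += int(c)
    return census


# ---------------------------------------------------------------------------
# Tallying reads


def _aligned_plus_coords(read) -> Tuple[np.ndarray, np.ndarray]:
    """Read sequence and qualities laid out on plus-strand coordinates.

    Minus-strand reads come back reverse-complemented, so a converted
    minus-strand cytosine (reference G on plus) shows as A in this layout.
    """
    from .seq import revcomp_array, seq_to_array

    seq = seq_to_array(read.sequence)
    qual = np.asarray(read.phred_qualities, dtype=np.int16)
    if read.strand == "-":
        return revcomp_array(seq), qual[::-1]
    return seq, qual


def tally_counts(reads: Iterable, genome: Mapping[str, np.ndarray],
                 rule: QualityRule | None = None) -> pd.DataFrame:
    """Tally converted (T) / unconverted (C) read bases per cytosine site.

    Each read contributes only to cytosines on its strand of origin. A base
    passes the filter iff its own quality >= rule.min_base_quality and every
    existing read base within rule.neighbor_window positions on each side
    matches the reference in bisulfite space (T matching a reference C of
    the read's strand counts as a match) with quality >=
    rule.neighbor_min_quality. Bases other than C/T at a cytosine are
    discarded. Returns the counts table restricted to covered sites, sorted
    by (contig, position0, strand).
    """
    rule = rule or QualityRule()
    w = rule.neighbor_window
    acc: Dict[str, Dict[str, np.ndarray]] = {}
    for read in reads:
        arr = genome[read.contig]
        L = len(read.sequence)
        if read.start0 < 0 or read.start0 + L > len(arr):
            raise ValueError(
                f"read {read.id} extends past contig {read.contig} end"
            )
        ref = arr[read.start0: read.start0 + L]
        aligned, qual = _aligned_plus_coords(read)
        if read.strand == "+":
            cyt = ref == b"C"
            unconverted = aligned == b"C"
            converted = aligned == b"T"
        else:
            cyt = ref == b"G"
            unconverted = aligned == b"G"
            converted = aligned == b"A"
        match = (aligned == ref) | (cyt & converted)
        neighbor_ok = match & (qual >= rule.neighbor_min_quality)
        # window check including the focal base; a focal base that itself
        # passes (C/T at a cytosine, Q >= 20 >= 15) never fails on itself
        if w > 0:
            padded = np.concatenate(
                [np.ones(w, bool), neighbor_ok, np.ones(w, bool)]
            )
            window_ok = (
                np.lib.stride_tricks.sliding_window_view(padded, 2 * w + 1)
                .all(axis=1)
            )
        else:
            window_ok = np.ones(L, dtype=bool)
        keep = cyt & (qual >= rule.min_base_quality) & window_ok
        if not keep.any():
            continue
        store = acc.setdefault(
            read.contig,
            {
                "+C": np.zeros(len(arr), np.int32),
                "+T": np.zeros(len(arr), np.int32),
                "-C": np.zeros(len(arr), np.int32),
                "-T": np.zeros(len(arr), np.int32),
            },
        )
        pos = read.start0 + np.nonzero(keep & unconverted)[0]
        np.add.at(store[read.strand + "C"], pos, 1)
        pos = read.start0 + np.nonzero(keep & converted)[0]
        np.add.at(store[read.strand + "T"], pos, 1)

    frames = []
    for contig in sorted(acc):
        store = acc[contig]
        plus_ctx, minus_ctx = context_code_arrays(genome[contig])
        for strand, ctx in (("+", plus_ctx), ("-", minus_ctx)):
            c = store[strand + "C"]
            t = store[strand + "T"]
            pos = np.nonzero((c > 0) | (t > 0))[0]
            if len(pos) == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "position0": pos,
                        "strand": strand,
                        "context": [CONTEXT_NAMES[int(v)] for v in ctx[pos]],
                        "count_C": c[pos],
                        "count_T": t[pos],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=COUNTS_COLUMNS)
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["contig", "position0", "strand"], kind="mergesort")
    return table.reset_index(drop=True)


def coverage(table: pd.DataFrame) -> pd.Series:
    return table["count_C"] + table["count_T"]


# ---------------------------------------------------------------------------
# Counts TSV I/O (1-based positions on disk)


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    out = table.sort_values(["contig", "position0", "strand"], kind="mergesort").copy()
    out["position"] = out["position0"] + 1
    out["context"] = out["context"].map(_CTX_TO_TSV)
    out[["contig", "position", "strand", "context", "count_C", "count_T"]].to_csv(
        path, sep="\t", index=False
    )


def read_counts(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"contig": str, "strand": str, "context": str})
    required = ["contig", "position", "strand", "context", "count_C", "count_T"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"counts file {path} lacks columns: {missing}")
    for col in ("count_C", "count_T"):
        bad = table.index[table[col] < 0]
        if len(bad):
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(
                f"negative {col} at line {int(bad[0]) + 2} of {path}"
            )
    bad_strand = table.index[~table["strand"].isin(["+", "-"])]
    if len(bad_strand):
        raise ValueError(f"invalid strand at line {int(bad_strand[0]) + 2} of {path}")
    table["position0"] = table["position"] - 1
    table["context"] = table["context"].map(lambda c: _TSV_TO_CTX.get(c, c))
    return table[COUNTS_COLUMNS].copy()


def write_bedgraph(table: pd.DataFrame, path: str | Path) -> None:
    """Methylation level (count_C / coverage) per covered site, bedGraph."""
    cov = coverage(table)
    level = table["count_C"] / cov
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="methylation_level"\n')
        for (contig, pos), lv in zip(
            zip(table["contig"], table["position0"]), level
        ):
            fh.write(f"{contig}\t{pos}\t{pos + 1}\t{lv:.4f}\n")


# ---------------------------------------------------------------------------
# Coverage distribution


def coverage_distribution(table: pd.DataFrame,
                          n_zero_sites: int = 0) -> Dict[str, object]:
    """Per-coverage proportions and cumulative (>=) proportions.

    ``n_zero_sites`` adds uncovered cytosines so the distribution can be
    taken over the whole site census rather than only covered sites.
    Reports the median coverage and the fraction of sites with >= 2 reads.
    """
    if len(table) == 0 and n_zero_sites == 0:
        raise ValueError("empty counts table")
    cov = coverage(table).to_numpy()
    if n_zero_sites:
        cov = np.concatenate([cov, np.zeros(n_zero_sites, dtype=cov.dtype)])
    values, counts = np.unique(cov, return_counts=True)
    total = counts.sum()
    prop = counts / total
    cumulative = prop[::-1].cumsum()[::-1]  # P(coverage >= value)
    dist = pd.DataFrame(
        {"coverage": values, "proportion": prop, "cumulative_ge": cumulative}
    )
    return {
        "distribution": dist,
        "median": float(np.median(cov)),
        "fraction_ge2": float((cov >= 2).sum() / total),
    }
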