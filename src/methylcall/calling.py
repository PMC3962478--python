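"""Conversion-rate estimation and binomial methylation calling.

Bisulfite conversion deaminates unmethylated cytosines so they sequence as
T; methylated cytosines resist and sequence as C. Conversion is imperfect,
so an unmethylated site still shows C in a read with probability
``p_e = 1 - c`` where ``c`` is the conversion rate. ``c`` is estimated two
ways: from the unmethylated spike-in contig (lambda phage control), and
from non-CpG cytosines, which are essentially unmethylated in hymenopteran
genomes.

A site with ``k`` unconverted reads out of ``n`` is tested against
``X ~ Binomial(n, p_e)`` with the one-sided exact tail ``P(X >= k)``;
p-values are corrected for multiple testing across all coverage-eligible
sites (2-30 reads by default) and a site is called methylated when its
adjusted value is at or below the FDR level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import coverage

CALLS_COLUMNS = [
    "contig", "position0", "strand", "context", "count_C", "count_T",
    "coverage", "level", "p_value", "q_value", "significant",
]


@dataclass(frozen=True)
class ConversionEstimate:
    rate: float
    method: str               # "spike_in" or "non_cpg"
    n_converted: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be > 0")

    @property
    def failure_probability(self) -> float:
        """The binomial null parameter p_e = 1 - rate."""
        return 1.0 - self.rate


@dataclass(frozen=True)
class CallingConfig:
    min_coverage: int = 2
    max_coverage: int = 30
    fdr_alpha: float = 0.05
    correction: str = "fdr_bh"   # statsmodels method name; holm/bonferroni also valid

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= self.max_coverage:
            raise ValueError("need 0 < min_coverage <= max_coverage")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0,1)")


def estimate_conversion_spikein(counts: pd.DataFrame,
                                spike_in_contig: str) -> ConversionEstimate:
    """Pooled C-to-T conversion rate over every covered cytosine of the
    spike-in contig (no coverage window: the control pools raw tallies)."""
    sub = counts[counts["contig"] == spike_in_contig]
    total = int(coverage(sub).sum())
    if total == 0:
        raise ValueError(
            f"no covered cytosines on spike-in contig {spike_in_contig!r}"
        )
    converted = int(sub["count_T"].sum())
    return ConversionEstimate(converted / total, "spike_in", converted, total)


def estimate_conversion_noncpg(counts: pd.DataFrame,
                               exclude_contigs: Sequence[str] = ()) -> ConversionEstimate:
    """Pooled conversion rate over CHG+CHH sites (UNCLASSIFIED excluded),
    exploiting that non-CpG cytosines are virtually unmethylated."""
    sub = counts[counts["context"].isin(["CHG", "CHH"])]
    if exclude_contigs:
        sub = sub[~sub["contig"].isin(list(exclude_contigs))]
    total = int(coverage(sub).sum())
    if total == 0:
        raise ValueError("no covered non-CpG cytosines")
    converted = int(sub["count_T"].sum())
    return ConversionEstimate(converted / total, "non_cpg", converted, total)


def binomial_upper_pvalue(k, n, p_e):
    """Exact one-sided tail P(X >= k) for X ~ Binomial(n, p_e).

    Vectorised over k and n. At p_e = 0 the tail degenerates to 1 for
    k = 0 and 0 for k >= 1.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p_e <= 1.0:
        raise ValueError("p_e must lie in [0,1]")
    out = stats.binom.sf(k - 1, n, p_e)
    return out if out.ndim else float(out)


def bh_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Step-up adjusted values q_(i) = min_{j>=i}(p_(j) * m / j), capped at
    1, returned in input order. ``method`` may select Holm or Bonferroni
    instead of Benjamini-Hochberg."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    _, q, _, _ = multipletests(p, alpha=0.05, method=method)
    return q


def call_methylation(counts: pd.DataFrame, conversion: ConversionEstimate,
                     config: CallingConfig | None = None) -> pd.DataFrame:
    """Call significantly methylated cytosines.

    Sites outside the coverage window are dropped before testing, so the
    multiple-testing family size m is the number of eligible sites. Output
    is sorted by (contig, position0, strand).
    """
    config = config or CallingConfig()
    if not 0.0 < conversion.rate <= 1.0:
        raise ValueError("conversion rate must lie in (0,1]")
    table = counts.copy()
    cov = coverage(table)
    table["coverage"] = cov
    eligible = table[(cov >= config.min_coverage) & (cov <= config.max_coverage)].copy()
    if len(eligible) == 0:
        import warnings

        warnings.warn("no coverage-eligible sites; returning empty call table")
        return pd.DataFrame(columns=CALLS_COLUMNS)
    k = eligible["count_C"].to_numpy()
    n = eligible["coverage"].to_numpy()
    eligible["level"] = k / n
    eligible["p_value"] = binomial_upper_pvalue(k, n, conversion.failure_probability)
    eligible["q_value"] = bh_adjust(eligible["p_value"].to_numpy(), config.correction)
    eligible["significant"] = eligible["q_value"] <= config.fdr_alpha
    eligible = eligible.sort_values(
        ["contig", "position0", "strand"], kind="mergesort"
    ).reset_index(drop=True)
    return eligible[CALLS_COLUMNS]


def write_calls(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out["position"] = out["position0"] + 1
    cols = ["contig", "position", "strand", "context", "count_C", "count_T",
            "coverage", "level", "p_value", "q_value", "significant"]
    out[cols].to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"contig": str, "strand": str})
    table["position0"] = table["position"] - 1
    table["significant"] = table["significant"].astype(bool)
    return table[CALLS_COLUMNS]
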