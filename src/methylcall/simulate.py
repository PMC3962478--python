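"""Bisulfite-sequencing simulator with full ground truth.

Generates a multi-contig genome of configurable GC and CpG composition, an
unmethylated spike-in contig standing in for the lambda phage conversion
control, non-overlapping gene models, a true methylome concentrated at
exonic CpGs, and single-end bisulfite reads with Phred qualities. Every
read records its true origin (contig, start, strand), so alignment is
replaced by truth-tracking and every downstream stage can be validated
against known answers.

Read chemistry: on the strand of bisulfite origin, a cytosine reads as C
with probability ``meth_state * meth_level + (1 - meth_state) * (1 -
conversion_rate)`` and as T otherwise; all other bases are copied (an
optional independent sequencing-error rate can disturb them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Sequence, Tuple

import numpy as np

from .annotate import GeneModel, RegionIndex, REGION_EXON, REGION_INTRON
from .seq import Genome, revcomp_bytes, seq_to_array, write_fasta

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass(frozen=True)
class QualityProfile:
    """Two-component Phred profile: a high-quality body and a low-quality
    tail, so the Q20/Q15 base filter is actually exercised."""

    q_high: int = 35
    q_low: int = 10
    p_low: float = 0.02
    sd: float = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 100_000
    gc_fraction: float = 0.42
    cpg_enrichment: float = 1.0
    n_genes: int = 30
    exons_per_gene: Tuple[int, int] = (1, 6)
    exon_length: Tuple[int, int] = (80, 400)
    intron_length: Tuple[int, int] = (60, 500)
    p_meth_exon: float = 0.04
    p_meth_intron: float = 0.004
    p_meth_intergenic: float = 0.002
    meth_level: float = 1.0
    non_cpg_meth: float = 0.0
    cpg_symmetry: float = 1.0
    conversion_rate: float = 0.9928
    sequencing_error: float = 0.0
    read_length: int = 100
    mean_depth: float = 8.0
    quality_profile: QualityProfile = field(default_factory=QualityProfile)
    spike_in_length: int = 20_000
    spike_in_name: str = "lambda_spike"

    def validate(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.contig_length < 1:
            raise ValueError("contig_length must be >= 1")
        if self.contig_length < self.read_length:
            raise ValueError("contig_length must be >= read_length")
        if self.spike_in_length < self.read_length:
            raise ValueError("spike_in_length must be >= read_length")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie in (0,1)")
        if self.cpg_enrichment < 0:
            raise ValueError("cpg_enrichment must be >= 0")
        if self.cpg_enrichment * self.gc_fraction / 2.0 > 1.0:
            raise ValueError("cpg_enrichment too large for gc_fraction")
        for name in ("p_meth_exon", "p_meth_intron", "p_meth_intergenic",
                     "non_cpg_meth", "cpg_symmetry", "sequencing_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if not 0.0 < self.meth_level <= 1.0:
            raise ValueError("meth_level must lie in (0,1]")
        if not 0.5 < self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate must lie in (0.5,1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("exons_per_gene", "exon_length", "intron_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range invalid: ({lo},{hi})")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


@dataclass
class TrueMethylome:
    """Per-strand arrays of true methylation state.

    ``states[contig][strand]`` is a float32 array over positions: NaN off
    cytosines, else the site's methylation probability (0 or 1 under the
    default binary assignment). Spike-in entries are all zero.
    """

    states: Dict[str, Dict[str, np.ndarray]]

    def get(self, contig: str, position0: int, strand: str) -> float:
        return float(self.states[contig][strand][position0])

    def sites(self) -> Iterator[Tuple[str, int, str, float]]:
        for contig in self.states:
            for strand in ("+", "-"):
                arr = self.states[contig][strand]
                for p in np.nonzero(~np.isnan(arr))[0]:
                    yield contig, int(p), strand, float(arr[p])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tposition\tstrand\ttrue_prob\n")
            for contig, p, strand, prob in self.sites():
                fh.write(f"{contig}\t{p + 1}\t{strand}\t{prob:g}\n")


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    contig: str
    start0: int
    strand: str
    sequence: bytes           # as sequenced, 5'->3' of the bisulfite strand
    phred_qualities: np.ndarray
    truth: bytes              # pre-conversion bases on the read strand


# ---------------------------------------------------------------------------
# Genome


def _markov_contig(length: int, gc: float, enrich: float,
                   rng: np.random.Generator) -> np.ndarray:
    """First-order Markov sequence: stationary base mix set by gc, with the
    C->G transition scaled by the CpG enrichment so the CpG dinucleotide
    frequency targets (gc/2)^2 * enrichment."""
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if enrich == 1.0:
        return _BASES[rng.choice(4, size=length, p=pi)]
    row_c = pi.copy()
    row_c[2] = pi[2] * enrich
    others = [0, 1, 3]
    rest = 1.0 - row_c[2]
    scale = rest / (pi[others].sum())
    row_c[others] = pi[others] * scale
    cum_default = np.cumsum(pi)
    cum_c = np.cumsum(row_c)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    prev = int(np.searchsorted(cum_default, u[0], side="right"))
    out[0] = prev
    for i in range(1, length):
        cum = cum_c if prev == 1 else cum_default
        prev = int(np.searchsorted(cum, u[i], side="right"))
        out[i] = prev
    return _BASES[out]


def simulate_genome(config: SimulationConfig) -> Tuple[Genome, "TrueMethylome"]:
    """Emit named contigs plus the spike-in contig, and an all-NaN methylome
    skeleton with cytosine positions initialised to 0."""
    config.validate()
    rng = _rng(config, 1)
    genome: Genome = {}
    for i in range(config.n_contigs):
        genome[f"contig{i + 1:02d}"] = _markov_contig(
            config.contig_length, config.gc_fraction, config.cpg_enrichment, rng
        )
    # spike-in mimics lambda phage: GC ~ 0.5, no CpG enrichment
    genome[config.spike_in_name] = _markov_contig(
        config.spike_in_length, 0.50, 1.0, rng
    )
    methylome = _empty_methylome(genome)
    return genome, methylome


def _empty_methylome(genome: Genome) -> TrueMethylome:
    states: Dict[str, Dict[str, np.ndarray]] = {}
    for contig, arr in genome.items():
        plus = np.full(len(arr), np.nan, dtype=np.float32)
        minus = np.full(len(arr), np.nan, dtype=np.float32)
        plus[arr == b"C"] = 0.0
        minus[arr == b"G"] = 0.0
        states[contig] = {"+": plus, "-": minus}
    return TrueMethylome(states)


# ---------------------------------------------------------------------------
# Gene models


def simulate_gene_models(genome: Genome, config: SimulationConfig) -> List[GeneModel]:
    """Place non-overlapping single-isoform genes on the non-spike contigs.

    Exon/intron structure is sampled from the configured ranges; leftover
    contig space is spread randomly over the intergenic gaps.
    """
    config.validate()
    rng = _rng(config, 2)
    contigs = [c for c in genome if c != config.spike_in_name]
    if config.n_genes == 0:
        return []
    if not contigs:
        raise ValueError("no non-spike contigs to place genes on")
    per_contig = [config.n_genes // len(contigs)] * len(contigs)
    for i in range(config.n_genes % len(contigs)):
        per_contig[i] += 1
    models: List[GeneModel] = []
    serial = 0
    for contig, n_here in zip(contigs, per_contig):
        if n_here == 0:
            continue
        L = len(genome[contig])
        structures = []
        for _ in range(n_here):
            n_ex = int(rng.integers(config.exons_per_gene[0],
                                    config.exons_per_gene[1] + 1))
            ex_lens = rng.integers(config.exon_length[0],
                                   config.exon_length[1] + 1, size=n_ex)
            in_lens = rng.integers(config.intron_length[0],
                                   config.intron_length[1] + 1,
                                   size=max(n_ex - 1, 0))
            structures.append((ex_lens, in_lens))
        gene_lens = [int(e.sum() + i.sum()) for e, i in structures]
        leftover = L - sum(gene_lens) - (n_here + 1)
        if leftover < 0:
            raise ValueError(
                f"contig {contig} ({L} bp) too short for {n_here} genes "
                f"totalling {sum(gene_lens)} bp"
            )
        gaps = rng.multinomial(leftover, np.full(n_here + 1, 1.0 / (n_here + 1)))
        cursor = 0
        for k, (ex_lens, in_lens) in enumerate(structures):
            cursor += int(gaps[k]) + 1
            start = cursor
            exons = []
            p = start
            for j, el in enumerate(ex_lens):
                exons.append((p, p + int(el) - 1))
                p += int(el)
                if j < len(in_lens):
                    p += int(in_lens[j])
            end = p - 1
            serial += 1
            gene_id = f"gene{serial:04d}"
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}-RA",
                    contig=contig,
                    strand="+" if rng.random() < 0.5 else "-",
                    start0=start,
                    end0=end,
                    exons=exons,
                )
            )
            cursor = end + 1
    return models


# ---------------------------------------------------------------------------
# True methylome


def assign_true_methylome(genome: Genome, models: Sequence[GeneModel],
                          config: SimulationConfig) -> TrueMethylome:
    """Assign a binary methylation state to every cytosine.

    CpG cytosines are methylated with the probability of their region class
    (exon/intron/intergenic, from the plus-strand C's position); the two
    strands of a CpG share their state with probability ``cpg_symmetry``.
    Non-CpG cytosines use ``non_cpg_meth``. The spike-in contig stays all
    zero.
    """
    config.validate()
    rng = _rng(config, 3)
    methylome = _empty_methylome(genome)
    index = RegionIndex(models)
    p_by_region = {
        REGION_EXON: config.p_meth_exon,
        REGION_INTRON: config.p_meth_intron,
    }
    for contig, arr in genome.items():
        if contig == config.spike_in_name:
            continue
        plus = methylome.states[contig]["+"]
        minus = methylome.states[contig]["-"]
        is_c = arr == b"C"
        is_g = arr == b"G"
        cpg_plus = np.nonzero(is_c[:-1] & is_g[1:])[0]
        probs = np.full(len(cpg_plus), config.p_meth_intergenic)
        regions = index.classify(contig, cpg_plus)
        for region, p in p_by_region.items():
            probs[regions == region] = p
        state = (rng.random(len(cpg_plus)) < probs).astype(np.float32)
        plus[cpg_plus] = state
        symmetric = rng.random(len(cpg_plus)) < config.cpg_symmetry
        partner = np.where(
            symmetric, state,
            (rng.random(len(cpg_plus)) < probs).astype(np.float32),
        )
        minus[cpg_plus + 1] = partner
        if config.non_cpg_meth > 0:
            # plus-strand C not followed by G; minus-strand C (plus-strand G)
            # not preceded by C
            mask = is_c.copy()
            mask[cpg_plus] = False
            noncpg_plus = np.nonzero(mask)[0]
            plus[noncpg_plus] = (
                rng.random(len(noncpg_plus)) < config.non_cpg_meth
            ).astype(np.float32)
            mask = is_g.copy()
            mask[cpg_plus + 1] = False
            noncpg_minus = np.nonzero(mask)[0]
            minus[noncpg_minus] = (
                rng.random(len(noncpg_minus)) < config.non_cpg_meth
            ).astype(np.float32)
    return methylome


# ---------------------------------------------------------------------------
# Reads


def _phred_block(n: int, profile: QualityProfile,
                 rng: np.random.Generator) -> np.ndarray:
    low = rng.random(n) < profile.p_low
    q = rng.normal(
        np.where(low, profile.q_low, profile.q_high), profile.sd, size=n
    )
    return np.clip(np.rint(q), 2, 41).astype(np.int16)


def simulate_bisulfite_reads(genome: Genome, methylome: TrueMethylome,
                             config: SimulationConfig) -> List[SimulatedRead]:
    """Draw single-end reads with Poisson(mean_depth) per-site strand
    coverage and apply bisulfite conversion on the strand of origin."""
    config.validate()
    rng = _rng(config, 4)
    rl = config.read_length
    lam = config.mean_depth / rl
    reads: List[SimulatedRead] = []
    serial = 0
    for contig, arr in genome.items():
        n_starts = len(arr) - rl + 1
        for strand in ("+", "-"):
            meth = methylome.states[contig][strand]
            counts = rng.poisson(lam, size=n_starts)
            starts = np.repeat(np.arange(n_starts), counts)
            for s in starts:
                seg = arr[s: s + rl].copy()
                m = meth[s: s + rl]
                if strand == "+":
                    cyt = seg == b"C"
                else:
                    cyt = seg == b"G"
                truth_plus = seg.copy()
                state = np.nan_to_num(m[cyt])
                p_c = state * config.meth_level \
                    + (1.0 - state) * (1.0 - config.conversion_rate)
                stays_c = rng.random(len(p_c)) < p_c
                conv = np.nonzero(cyt)[0][~stays_c]
                # a converted cytosine reads T on its own strand; in
                # plus-coordinate layout that is T (+ reads) or A (- reads)
                seg[conv] = b"T" if strand == "+" else b"A"
                if config.sequencing_error > 0:
                    err = np.nonzero(rng.random(rl) < config.sequencing_error)[0]
                    if len(err):
                        shift = rng.integers(1, 4, size=len(err)).astype(np.int8)
                        codes = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
                        cur = np.array([codes.get(b, 0) for b in seg[err]],
                                       dtype=np.int8)
                        seg[err] = _BASES[(cur + shift) % 4]
                qual = _phred_block(rl, config.quality_profile, rng)
                if strand == "+":
                    sequence = seg.tobytes()
                    truth = truth_plus.tobytes()
                else:
                    # emit in read orientation (5'->3' of the minus strand)
                    sequence = revcomp_bytes(seg.tobytes())
                    truth = revcomp_bytes(truth_plus.tobytes())
                    qual = qual[::-1]
                serial += 1
                reads.append(
                    SimulatedRead(
                        id=f"sim:{contig}:{s}:{strand}:{serial}",
                        contig=contig,
                        start0=int(s),
                        strand=strand,
                        sequence=sequence,
                        phred_qualities=qual,
                        truth=truth,
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# I/O


def write_reads_fastq(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """FASTQ (Phred+33); the header encodes the true origin as
    ``sim:<contig>:<start0>:<strand>:<serial>``."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.phred_qualities)
            fh.write(f"@{r.id}\n{r.sequence.decode('ascii')}\n+\n{qual}\n")


def read_reads_fastq(path: str | Path) -> List[SimulatedRead]:
    """Parse reads written by :func:`write_reads_fastq`, recovering origins
    from the header."""
    from Bio import SeqIO

    reads: List[SimulatedRead] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        parts = rec.id.split(":")
        if len(parts) != 5 or parts[0] != "sim":
            raise ValueError(
                f"read id {rec.id!r} does not encode a simulated origin"
            )
        _, contig, start0, strand, _ = parts
        seq = str(rec.seq).encode("ascii")
        qual = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16)
        reads.append(
            SimulatedRead(
                id=rec.id, contig=contig, start0=int(start0), strand=strand,
                # pre-conversion truth is not representable in FASTQ; the
                # tally never consumes it
                sequence=seq, phred_qualities=qual, truth=seq,
            )
        )
    return reads


def simulate_dataset(config: SimulationConfig, outdir: str | Path | None = None):
    """Run the full generator; optionally write FASTA/GFF3/FASTQ/TSV."""
    genome, _ = simulate_genome(config)
    models = simulate_gene_models(genome, config)
    methylome = assign_true_methylome(genome, models, config)
    reads = simulate_bisulfite_reads(genome, methylome, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa")
        from .annotate import write_gff3

        write_gff3(models, outdir / "genes.gff3")
        write_reads_fastq(reads, outdir / "reads.fastq")
        methylome.write_tsv(outdir / "true_methylome.tsv")
    return genome, models, methylome, reads
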