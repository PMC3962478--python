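import numpy as np
import pandas as pd
import pytest

from methylcall import (
    QualityRule,
    classify_context,
    context_census,
    coverage_distribution,
    enumerate_cytosines,
    read_counts,
    tally_counts,
    write_counts,
)
from methylcall.counts import COUNTS_COLUMNS, coverage
from methylcall.seq import seq_to_array

from conftest import make_read


def genome_of(**contigs):
    return {name: seq_to_array(s) for name, s in contigs.items()}


# ---------------------------------------------------------------------------
# Context classification


@pytest.mark.parametrize(
    "seq,pos,strand,expected",
    [
        ("ACGT", 1, "+", "CG"),
        ("ACAG", 1, "+", "CHG"),
        ("ACAT", 1, "+", "CHH"),
        ("ACGT", 2, "-", "CG"),          # G preceded by C: CpG partner
        ("TAGA", 2, "-", "CHH"),         # minus-strand context reads 5'<-3'
        ("CAGT", 2, "-", "CHG"),         # 3' neighbor is H on minus, then C
        ("AAAC", 3, "+", "UNCLASSIFIED"),  # C at contig end
        ("GAAA", 0, "-", "UNCLASSIFIED"),  # G at contig start
        ("ACNT", 1, "+", "UNCLASSIFIED"),  # ambiguous neighbor
        ("ACAN", 1, "+", "UNCLASSIFIED"),  # H then N
    ],
)
def test_classify_context(seq, pos, strand, expected):
    genome = genome_of(c=seq)
    assert classify_context(genome, "c", pos, strand) == expected


def test_classify_context_rejects_non_cytosine():
    genome = genome_of(c="ACGT")
    with pytest.raises(ValueError, match="not C"):
        classify_context(genome, "c", 0, "+")
    with pytest.raises(ValueError, match="not G"):
        classify_context(genome, "c", 1, "-")


def test_enumerate_cytosines_small():
    sites = list(enumerate_cytosines(genome_of(c="ACGT")))
    assert [(s.position0, s.strand, s.context) for s in sites] == [
        (1, "+", "CG"),
        (2, "-", "CG"),
    ]
    assert list(enumerate_cytosines(genome_of(c="AAAA"))) == []


def test_context_partition_on_simulated_genome(small_dataset):
    """Per-context totals sum to the genome's C+G base count."""
    genome = small_dataset["genome"]
    census = context_census(genome)
    direct = sum(
        int((arr == b"C").sum() + (arr == b"G").sum())
        for arr in genome.values()
    )
    assert sum(census.values()) == direct


# ---------------------------------------------------------------------------
# Tallying


def test_single_clean_read_counts_one_unconverted():
    genome = genome_of(c="AACGTTAA")
    # plus-strand read, the C at position 2 retained as C (unconverted)
    read = make_read("c", 0, "+", "AACGTTAA", [40] * 8)
    table = tally_counts([read], genome)
    row = table[(table["position0"] == 2) & (table["strand"] == "+")]
    assert int(row["count_C"].iloc[0]) == 1
    assert int(row["count_T"].iloc[0]) == 0


def test_low_focal_quality_discards_base():
    genome = genome_of(c="AACGTTAA")
    quals = [40] * 8
    quals[2] = 10
    read = make_read("c", 0, "+", "AACGTTAA", quals)
    table = tally_counts([read], genome)
    assert len(table[(table["position0"] == 2) & (table["strand"] == "+")]) == 0


def test_low_neighbor_quality_discards_base():
    genome = genome_of(c="AACGTTAA")
    quals = [40] * 8
    quals[4] = 10  # within 3 bases of the focal C at 2
    read = make_read("c", 0, "+", "AACGTTAA", quals)
    table = tally_counts([read], genome)
    assert len(table[(table["position0"] == 2) & (table["strand"] == "+")]) == 0


def test_neighbor_mismatch_discards_base():
    genome = genome_of(c="AACGTTAA")
    read = make_read("c", 0, "+", "AACGGTAA", [40] * 8)  # T->G mismatch at 4
    table = tally_counts([read], genome)
    assert len(table[(table["position0"] == 2) & (table["strand"] == "+")]) == 0


def test_converted_t_counts_and_matches_as_neighbor():
    genome = genome_of(c="AACGTTAA")
    read = make_read("c", 0, "+", "AATGTTAA", [40] * 8)  # C read as T
    table = tally_counts([read], genome)
    row = table[(table["position0"] == 2) & (table["strand"] == "+")]
    assert int(row["count_T"].iloc[0]) == 1


def test_minus_strand_read_counts_minus_site():
    genome = genome_of(c="AACGTTAA")
    # minus-strand cytosine sits at the G (position 3); an unconverted
    # minus read is the reverse complement of the reference
    read = make_read("c", 0, "-", "TTAACGTT", [40] * 8)
    table = tally_counts([read], genome)
    assert set(table["strand"]) == {"-"}
    row = table[table["position0"] == 3]
    assert int(row["count_C"].iloc[0]) == 1


def test_hand_tally_three_c_five_t():
    genome = genome_of(c="AACGTTAA")
    reads = [
        make_read("c", 0, "+", "AACGTTAA", [40] * 8, f"c{i}") for i in range(3)
    ] + [
        make_read("c", 0, "+", "AATGTTAA", [40] * 8, f"t{i}") for i in range(5)
    ]
    table = tally_counts(reads, genome)
    row = table[(table["position0"] == 2) & (table["strand"] == "+")]
    assert int(row["count_C"].iloc[0]) == 3
    assert int(row["count_T"].iloc[0]) == 5


def test_non_ct_base_at_cytosine_discarded():
    genome = genome_of(c="AAACAAAA")
    read = make_read("c", 0, "+", "AAAGAAAA", [40] * 8)
    table = tally_counts([read], genome)
    assert len(table) == 0


def test_read_past_contig_end_errors():
    genome = genome_of(c="ACGT")
    read = make_read("c", 2, "+", "GTAA", [40] * 4)
    with pytest.raises(ValueError, match="past contig"):
        tally_counts([read], genome)


def _oracle_tally(reads, genome, rule):
    """Direct per-base re-statement of the filter, independent of the
    vectorised implementation. Works in plus-strand coordinate layout: a
    converted minus-strand cytosine (reference G) shows as A there."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    out = {}
    for read in reads:
        ref = genome[read.contig].tobytes().decode()
        L = len(read.sequence)
        seq = read.sequence.decode()
        quals = list(read.phred_qualities)
        if read.strand == "-":
            seq = "".join(comp[b] for b in reversed(seq))
            quals = quals[::-1]
        cyt = "C" if read.strand == "+" else "G"
        conv = "T" if read.strand == "+" else "A"

        def matches(j):
            rb = ref[read.start0 + j]
            return seq[j] == rb or (rb == cyt and seq[j] == conv)

        for i in range(L):
            p = read.start0 + i
            if ref[p] != cyt:
                continue
            if seq[i] not in (cyt, conv):
                continue  # sequencing error at the cytosine: discarded
            if quals[i] < rule.min_base_quality:
                continue
            ok = all(
                matches(j) and quals[j] >= rule.neighbor_min_quality
                for j in range(max(0, i - rule.neighbor_window),
                               min(L, i + rule.neighbor_window + 1))
                if j != i
            )
            if not ok:
                continue
            key = (read.contig, p, read.strand)
            c, t = out.get(key, (0, 0))
            out[key] = (c + 1, t) if seq[i] == cyt else (c, t + 1)
    return out


def test_tally_matches_exhaustive_oracle():
    """Randomized small reads vs a direct per-base oracle."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    ref = "".join(rng.choice(bases, size=60))
    genome = genome_of(c=ref)
    rule = QualityRule()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    reads = []
    for i in range(10):
        start = int(rng.integers(0, 40))
        L = 20
        strand = "+" if rng.random() < 0.5 else "-"
        plus_seg = list(ref[start: start + L])
        # randomly convert / corrupt bases
        for j in range(L):
            target = "C" if strand == "+" else "G"
            if plus_seg[j] == target and rng.random() < 0.5:
                plus_seg[j] = "T" if strand == "+" else "A"
            elif rng.random() < 0.05:
                plus_seg[j] = str(rng.choice(bases))
        seq = "".join(plus_seg)
        if strand == "-":
            seq = "".join(comp[b] for b in reversed(seq))
        quals = rng.choice([8, 14, 18, 25, 40], size=L)
        reads.append(make_read("c", start, strand, seq, quals, f"r{i}"))
    table = tally_counts(reads, genome, rule)
    expected = _oracle_tally(reads, genome, rule)
    got = {
        (r.contig, int(r.position0), r.strand): (int(r.count_C), int(r.count_T))
        for r in table.itertuples()
    }
    assert got == expected


def test_relaxing_quality_rule_never_reduces_coverage(small_dataset):
    reads = small_dataset["reads"][:500]
    genome = small_dataset["genome"]
    strict = tally_counts(reads, genome, QualityRule(20, 15, 3))
    loose = tally_counts(reads, genome, QualityRule(0, 0, 0))
    merged = strict.merge(
        loose, on=["contig", "position0", "strand"], how="left",
        suffixes=("_strict", "_loose"),
    )
    cov_strict = merged["count_C_strict"] + merged["count_T_strict"]
    cov_loose = merged["count_C_loose"] + merged["count_T_loose"]
    assert (cov_loose >= cov_strict).all()


# ---------------------------------------------------------------------------
# Counts I/O


def test_counts_round_trip(tmp_path, small_counts):
    path = tmp_path / "counts.tsv"
    write_counts(small_counts, path)
    back = read_counts(path)
    pd.testing.assert_frame_equal(
        back, small_counts[COUNTS_COLUMNS], check_dtype=False
    )


def test_empty_table_writes_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    write_counts(pd.DataFrame(columns=COUNTS_COLUMNS), path)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == 1
    assert lines[0].startswith("contig\t")


def test_negative_count_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "contig\tposition\tstrand\tcontext\tcount_C\tcount_T\n"
        "c\t5\t+\tCG\t1\t2\n"
        "c\t9\t+\tCG\t-1\t2\n"
    )
    with pytest.raises(ValueError, match="line 3"):
        read_counts(path)


# ---------------------------------------------------------------------------
# Coverage distribution


def test_coverage_distribution_uniform_eight():
    table = pd.DataFrame(
        {
            "contig": "c", "position0": range(10), "strand": "+",
            "context": "CG", "count_C": 4, "count_T": 4,
        }
    )
    dist = coverage_distribution(table)
    assert dist["median"] == 8
    assert dist["fraction_ge2"] == 1.0


def test_coverage_distribution_hand_case():
    table = pd.DataFrame(
        {
            "contig": "c", "position0": [0, 1, 2], "strand": "+",
            "context": "CG", "count_C": [1, 2, 3], "count_T": 0,
        }
    )
    dist = coverage_distribution(table)
    d = dist["distribution"].set_index("coverage")
    assert d.loc[2, "cumulative_ge"] == pytest.approx(2 / 3)
    assert d["proportion"].sum() == pytest.approx(1.0)
    assert (np.diff(d["cumulative_ge"]) <= 0).all()


def test_coverage_distribution_empty_errors():
    with pytest.raises(ValueError, match="empty"):
        coverage_distribution(pd.DataFrame(columns=COUNTS_COLUMNS))


def test_simulated_depth_regime(small_counts):
    """Post-filter coverage at simulated depth 8 keeps median near the
    configured depth with nearly all covered sites at >= 2 reads."""
    dist = coverage_distribution(small_counts)
    assert 6 <= dist["median"] <= 9
    assert dist["fraction_ge2"] >= 0.85
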