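"""tRNA pool parsing, tAI weights, optimality classes and directed pairs."""

import itertools
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonsel.genetic_code import BASES, revcomp, standard_code
from codonsel.trna_tai import (
    TRNAPool,
    WobblePenalties,
    anticodon_from_header,
    build_tai_table,
    codon_weight,
    decoding_pairs,
    enumerate_directed_pairs,
    parse_trna_pool,
    read_trna_counts_tsv,
    single_base_synonymous_neighbors,
    unused_anticodons,
    wobble_pair_census,
)

CODE = standard_code()
WC_ANTICODONS = sorted({revcomp(c) for c in CODE.sense_codons})

# independent third-base wobble rule used by oracle checks below:
# anticodon position-34 base of the penalised decoder, per codon third base
ORACLE_WOBBLE = {"T": "G", "C": "A", "A": "A", "G": "T"}
ORACLE_PAIR_NAME = {"T": "G:U", "C": "I:C", "A": "I:A", "G": "U:G"}


# ---------------------------------------------------------------- parsing

def _write_fasta(path, records):
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


def test_empty_trna_file_gives_empty_pool(tmp_path):
    f = tmp_path / "trna.fa"
    f.write_text("")
    pool = parse_trna_pool(f)
    assert pool.n_anticodons == 0
    assert pool.total_loci == 0


def test_parse_counts_records_per_anticodon(tmp_path):
    f = tmp_path / "trna.fa"
    _write_fasta(
        f,
        [
            ("Zea_mays_tRNA-Ala-AGC-1-1 Ala (AGC) 73 bp", "GGGCACGT"),
            ("Zea_mays_tRNA-Ala-AGC-2-1 Ala (AGC) 73 bp", "GGGCACGT"),
            ("Zea_mays_tRNA-Gly-GGC-1-1 Gly (GGC) 72 bp", "GGGCACGT"),
        ],
    )
    pool = parse_trna_pool(f)
    assert pool.copies == {"AGC": 2, "GGC": 1}
    assert pool.total_loci == 3


def test_undetermined_and_malformed_headers(tmp_path):
    f = tmp_path / "trna.fa"
    _write_fasta(
        f,
        [
            ("Zea_mays_tRNA-Und-NNN-1-1 Und (NNN)", "ACGT"),
            ("random_contig_without_annotation", "ACGT"),
            ("Zea_mays_tRNA-Met-CAT-1-1 Met (CAT)", "ACGT"),
        ],
    )
    pool = parse_trna_pool(f)
    assert pool.copies == {"CAT": 1}
    assert pool.undetermined == 1


def test_legacy_header_dialect():
    assert anticodon_from_header("chr1.trna5-AlaAGC (123-456)") == "AGC"
    assert anticodon_from_header("tRNA-SeC-TCA-1-1") == "TCA"
    assert anticodon_from_header("tRNA-Ala-UGC-1-1") == "TGC"  # RNA alphabet in


def test_counts_tsv_roundtrip(tmp_path, toy_pool):
    f = tmp_path / "counts.tsv"
    f.write_text("AGC\t2\nGGC\t3\n")
    assert read_trna_counts_tsv(f).copies == toy_pool.copies


def test_negative_copies_rejected():
    with pytest.raises(ValueError):
        TRNAPool({"AGC": -1})


# ------------------------------------------------------- decoding and W

def test_decoding_pairs_examples(toy_pool):
    assert decoding_pairs("GCT", toy_pool) == [("AGC", 0.0), ("GGC", 0.7861)]
    assert decoding_pairs("GCC", toy_pool) == [("GGC", 0.0), ("AGC", 0.4659)]
    assert decoding_pairs("GCT", TRNAPool({})) == []


def test_decoding_rejects_stop_codons(toy_pool):
    with pytest.raises(ValueError):
        decoding_pairs("TAA", toy_pool)
    with pytest.raises(ValueError):
        codon_weight("TGA", toy_pool)


def test_codon_weight_hand_arithmetic(toy_pool):
    assert codon_weight("GCT", toy_pool) == pytest.approx(2 * 1 + 3 * (1 - 0.7861))
    assert codon_weight("GCC", toy_pool) == pytest.approx(3 * 1 + 2 * (1 - 0.4659))
    assert codon_weight("GCA", TRNAPool({})) == 0.0


@pytest.mark.parametrize(
    "codon,third,s_attr",
    [("TTT", "T", "s_GU"), ("TTC", "C", "s_IC"), ("GCA", "A", "s_IA"), ("GCG", "G", "s_UG")],
)
def test_wobble_decoder_geometry(codon, third, s_attr):
    """The penalised decoder differs from Watson-Crick only at position 34."""
    assert codon[2] == third
    wc = revcomp(codon)
    wobble = ORACLE_WOBBLE[third] + wc[1:]
    pool = TRNAPool({wc: 1, wobble: 1})
    pairs = dict(decoding_pairs(codon, pool))
    assert pairs[wc] == 0.0
    assert pairs[wobble] == getattr(WobblePenalties(), s_attr)


def test_wobble_penalties_validated():
    with pytest.raises(ValueError):
        WobblePenalties(s_GU=1.5)


# ------------------------------------------------------------ tAI table

def test_class_split_is_32_high_29_low_for_any_pool(toy_pool):
    for pool in (toy_pool, TRNAPool({}), TRNAPool({a: 1 for a in WC_ANTICODONS})):
        table = build_tai_table(pool)
        classes = Counter(table.optimality.values())
        assert classes == {"high": 32, "low": 29}
        for family in CODE.families.values():
            ranks = sorted(table.rank[c] for c in family)
            assert ranks == list(range(1, len(family) + 1))


@given(
    st.dictionaries(st.sampled_from(WC_ANTICODONS), st.integers(1, 40), max_size=30),
    st.integers(2, 11),
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_scale_invariance_of_ranks_classes_directions(copies, factor):
    base = build_tai_table(TRNAPool(copies))
    scaled = build_tai_table(TRNAPool(copies).scaled(factor))
    assert base.rank == scaled.rank
    assert base.optimality == scaled.optimality
    assert [p.direction for p in enumerate_directed_pairs(base)] == [
        p.direction for p in enumerate_directed_pairs(scaled)
    ]


def test_within_ala_ranks_follow_weights(toy_pool):
    table = build_tai_table(toy_pool)
    assert table.rank["GCC"] < table.rank["GCT"]  # W 4.0682 > 2.6417


def test_normalized_weights_preserve_within_family_order(toy_pool):
    table = build_tai_table(toy_pool)
    norm = table.normalized()
    assert max(norm.values()) == pytest.approx(1.0)
    assert (norm["GCC"] > norm["GCT"]) == (table.W["GCC"] > table.W["GCT"])
    assert all(v > 0 for v in norm.values())


# ------------------------------------------------------- directed pairs

def _brute_force_unordered_pairs():
    """Independent enumeration over all 61x9 single-base neighbours."""
    found = set()
    for codon in CODE.sense_codons:
        for pos, base in itertools.product(range(3), BASES):
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if CODE.is_sense(alt) and CODE.amino_acid(alt) == CODE.amino_acid(codon):
                found.add(frozenset((codon, alt)))
    return found


def test_pair_enumeration_matches_brute_force(toy_pool):
    pairs = enumerate_directed_pairs(build_tai_table(toy_pool))
    unordered = {frozenset((p.from_codon, p.to_codon)) for p in pairs}
    oracle = _brute_force_unordered_pairs()
    assert unordered == oracle
    assert len(pairs) == 2 * len(oracle)
    for p in pairs:
        assert sum(a != b for a, b in zip(p.from_codon, p.to_codon)) == 1
        assert p.from_codon[p.position - 1] != p.to_codon[p.position - 1]
        assert CODE.amino_acid(p.from_codon) == CODE.amino_acid(p.to_codon)


def test_ala_gcg_to_gcc_is_tai_up_with_alanine_pool(toy_pool):
    # GGC decodes GCC at full weight while GCG is only wobble-decoded, so
    # the GCG -> GCC mutation increases tAI with this pool
    table = build_tai_table(toy_pool)
    pairs = {(p.from_codon, p.to_codon): p.direction for p in enumerate_directed_pairs(table)}
    assert pairs[("GCG", "GCC")] == "tai_up"


def test_direction_antisymmetry(toy_pool):
    table = build_tai_table(toy_pool)
    directions = {
        (p.from_codon, p.to_codon): p.direction for p in enumerate_directed_pairs(table)
    }
    flip = {"tai_up": "tai_down", "tai_down": "tai_up", "tie": "tie"}
    for (a, b), d in directions.items():
        assert directions[(b, a)] == flip[d]


# ------------------------------------------------------------ census

@given(st.dictionaries(st.sampled_from(WC_ANTICODONS), st.integers(1, 5), max_size=40))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_wobble_census_matches_definition(copies):
    pool = TRNAPool(copies)
    census = wobble_pair_census(pool)
    oracle = Counter()
    for codon in CODE.sense_codons:
        wobble = ORACLE_WOBBLE[codon[2]] + revcomp(codon)[1:]
        if wobble != revcomp(codon) and pool.tgcn(wobble) > 0:
            oracle[ORACLE_PAIR_NAME[codon[2]]] += 1
    assert census == {"G:U": 0, "I:C": 0, "I:A": 0, "U:G": 0} | dict(oracle)


def test_full_pool_census_totals():
    """With every Watson-Crick anticodon present, the census counts each
    sense codon whose penalised wobble decoder is itself a WC anticodon of
    some codon (brute-force upper structure of the pairing scheme)."""
    pool = TRNAPool({a: 1 for a in WC_ANTICODONS})
    census = wobble_pair_census(pool)
    assert sum(census.values()) > 0
    assert set(census) == {"G:U", "I:C", "I:A", "U:G"}
    assert unused_anticodons(pool) == set()
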