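"""Promoter extraction and IUPAC degenerate scanning."""

import numpy as np
import pytest

from matekit.io import GeneModel
from matekit.motifs import (
    GGNVS,
    MotifMatch,
    MotifPattern,
    PromoterSeq,
    expected_count,
    extract_promoter,
    iupac_matcher,
    reverse_complement,
    scan,
    scan_catalog,
)
from matekit.simulate import plant_motifs

# independent literal code sets for the oracle (not imported from the package)
ORACLE_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def test_ggnvs_examples():
    matches = iupac_matcher("GGNVS")
    assert matches("GGAAC")       # A in N, A in V, C in S
    assert not matches("GGATT")   # T not in S
    assert matches("ggcgc")       # case-insensitive


def test_invalid_code_fails_at_compile_time():
    with pytest.raises(ValueError):
        iupac_matcher("GGZ")


def test_matcher_agrees_with_set_membership_oracle(rng):
    matches = iupac_matcher("GGNVS")
    bases = list("ACGT")
    for _ in range(2000):
        word = "".join(rng.choice(bases, size=5))
        oracle = all(b in ORACLE_SETS[c] for b, c in zip(word, "GGNVS"))
        assert matches(word) == oracle, word


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def test_plus_strand_window_coordinates():
    chrom = "".join("ACGT"[i % 4] for i in range(5000))
    gene = GeneModel("g", "Chr01", 2001, 3000, "+")
    promoter = extract_promoter(chrom, gene, 1500)
    assert promoter.sequence == chrom[500:2000]  # bases 501..2000
    assert promoter.window_length == 1500 and not promoter.truncated


def test_minus_strand_window_is_reverse_complement_of_downstream_flank():
    chrom = "".join("ACGT"[i % 4] for i in range(5000))
    gene = GeneModel("g", "Chr01", 1001, 2000, "-")
    promoter = extract_promoter(chrom, gene, 1500)
    assert promoter.sequence == reverse_complement(chrom[2000:3500])


def test_truncated_window_is_flagged():
    chrom = "A" * 600
    gene = GeneModel("g", "Chr01", 301, 400, "+")
    promoter = extract_promoter(chrom, gene, 1500)
    assert promoter.truncated and promoter.window_length == 300


def test_out_of_bounds_gene_is_an_error():
    with pytest.raises(ValueError):
        extract_promoter("A" * 100, GeneModel("g", "Chr01", 50, 150, "+"), 20)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_planted_promoter_round_trips_through_extraction(strand, rng):
    planted = "".join(rng.choice(list("ACGT"), size=200))
    body = "".join(rng.choice(list("ACGT"), size=300))
    pad = "".join(rng.choice(list("ACGT"), size=100))
    if strand == "+":
        chrom = pad + planted + body + pad
        gene = GeneModel("g", "c", len(pad) + 201, len(pad) + 200 + 300, "+")
    else:
        chrom = pad + body + reverse_complement(planted) + pad
        gene = GeneModel("g", "c", len(pad) + 1, len(pad) + 300, "-")
    assert extract_promoter(chrom, gene, 200).sequence == planted


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def test_overlapping_matches_are_both_reported():
    seq = "A" * 10 + "GGGGCC" + "A" * 10
    promoter = PromoterSeq("g", seq, len(seq))
    positions = [m.position for m in scan(promoter, GGNVS)]
    assert positions == [10 - 26, 11 - 26]  # adjacent overlapping occurrences


def test_scan_positions_revalidate_and_are_sorted(rng):
    seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=1500))
    promoter = PromoterSeq("g", seq, 1500)
    matches = scan(promoter, GGNVS)
    matcher = iupac_matcher("GGNVS")
    positions = [m.position for m in matches]
    assert positions == sorted(positions)
    for p in positions:
        assert -1500 <= p <= -5
        assert matcher(seq[1500 + p : 1500 + p + 5])


def test_scan_equals_bruteforce_oracle(rng):
    pattern = MotifPattern("SWY", "SWY")
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        promoter = PromoterSeq("g", seq, 60)
        oracle = [
            i - 60
            for i in range(58)
            if seq[i] in "CG" and seq[i + 1] in "AT" and seq[i + 2] in "CT"
        ]
        assert [m.position for m in scan(promoter, pattern)] == oracle


def test_match_count_monotone_under_appending(rng):
    seq = "".join(rng.choice(list("ACGT"), size=400))
    longer = seq + "".join(rng.choice(list("ACGT"), size=100))
    n_short = len(scan(PromoterSeq("g", seq, 400), GGNVS))
    n_long = len(scan(PromoterSeq("g", longer, 500), GGNVS))
    assert n_long >= n_short


def test_planted_motifs_recovered_exactly(rng):
    positions = [-1400, -900, -404, -77, -10]
    seq = plant_motifs(rng, 1500, [(GGNVS, p) for p in positions], 0.35, collision_free=True)
    assert [m.position for m in scan(PromoterSeq("g", seq, 1500), GGNVS)] == positions


def test_both_strands_flag_adds_reverse_hits():
    # plant the reverse complement of a GGNVS instance whose forward image
    # ("CTACC") is itself not a GGNVS match
    seq = "A" * 20 + reverse_complement("GGTAG") + "A" * 20
    promoter = PromoterSeq("g", seq, len(seq))
    assert scan(promoter, GGNVS) == []
    both = scan(promoter, GGNVS, both_strands=True)
    assert len(both) == 1
    assert both[0].position == 20 - len(seq)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


def test_empty_catalog_gives_empty_table():
    promoter = PromoterSeq("g", "ACGT" * 100, 400)
    assert scan_catalog([promoter], []).empty


def test_single_pattern_catalog_reduces_to_scan(rng):
    seq = "".join(rng.choice(list("ACGT"), size=800))
    promoter = PromoterSeq("g", seq, 800)
    table = scan_catalog([promoter], [GGNVS])
    assert list(table["position"]) == [m.position for m in scan(promoter, GGNVS)]


def test_duplicate_catalog_names_error():
    with pytest.raises(ValueError):
        scan_catalog([], [MotifPattern("X", "ACGT"), MotifPattern("X", "TTTT")])


def test_planted_multi_element_promoter_recovered(rng):
    e1 = MotifPattern("E1", "ACGTAC")
    e2 = MotifPattern("E2", "TGGCAA")
    layout = [(e1, -300), (e2, -150), (e1, -20)]
    seq = plant_motifs(rng, 400, layout, 0.4, collision_free=True)
    table = scan_catalog([PromoterSeq("g", seq, 400)], [e1, e2])
    found = {(r.element, r.position) for r in table.itertuples()}
    assert found == {("E1", -300), ("E2", -150), ("E1", -20)}


# ---------------------------------------------------------------------------
# expected counts
# ---------------------------------------------------------------------------


def test_expected_count_closed_form_uniform():
    uniform = {b: 0.25 for b in "ACGT"}
    value = expected_count(GGNVS, 1500, uniform)
    assert value == pytest.approx(1496 * 0.25 * 0.25 * 1.0 * 0.75 * 0.5, abs=1e-9)
    assert value == pytest.approx(35.0625, abs=1e-4)


def test_expected_count_of_n_pattern_is_window_length():
    assert expected_count(MotifPattern("any", "N"), 10, {"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4}) == 10


def test_expected_count_frequencies_must_sum_to_one():
    with pytest.raises(ValueError):
        expected_count(GGNVS, 100, {"A": 0.5, "C": 0.5, "G": 0.5, "T": 0.5})
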