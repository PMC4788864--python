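"""Tandem rule, anchor chaining, and the alignment similarity metric.

The alignment oracle enumerates every global alignment of two short
sequences, scores them with the same BLOSUM62/affine-gap scheme, and
derives the percent-similarity values of all co-optimal alignments —
independently of the production aligner.
"""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from matekit.duplication import (
    anchors_from_hits,
    call_tandem,
    classify,
    find_collinear_blocks,
    gene_ranks,
    percent_similarity,
)
from matekit.io import GeneModel, HomologyHit

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 10.0, 0.5


# ---------------------------------------------------------------------------
# exhaustive alignment oracle
# ---------------------------------------------------------------------------


def _enumerate_alignments(a: str, b: str):
    """Yield every global alignment as a list of (x, y) columns ('-' = gap)."""
    def recurse(i, j, cols):
        if i == len(a) and j == len(b):
            yield cols
            return
        if i < len(a) and j < len(b):
            yield from recurse(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            yield from recurse(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            yield from recurse(i, j + 1, cols + [("-", b[j])])

    yield from recurse(0, 0, [])


def _score(cols):
    total, prev_gap = 0.0, None
    for x, y in cols:
        if x == "-" or y == "-":
            side = "x" if x == "-" else "y"
            total -= GAP_EXTEND if prev_gap == side else GAP_OPEN
            prev_gap = side
        else:
            total += BLOSUM62[x, y]
            prev_gap = None
    return total


def _similarity(cols):
    pos = sum(1 for x, y in cols if x != "-" and y != "-" and BLOSUM62[x, y] > 0)
    return 100.0 * pos / len(cols)


@pytest.mark.parametrize(
    "a,b",
    [("MKTAY", "MKTAY"), ("MKTAY", "MKT"), ("ACDEFG", "AWDEG"), ("KKKK", "DDDD"), ("MK", "WWWWW")],
)
def test_similarity_matches_exhaustive_alignment_oracle(a, b):
    alignments = list(_enumerate_alignments(a, b))
    best = max(_score(c) for c in alignments)
    optimal_sims = {
        round(_similarity(c), 9) for c in alignments if abs(_score(c) - best) < 1e-9
    }
    assert round(percent_similarity(a, b), 9) in optimal_sims


def test_identical_sequences_are_100_percent():
    assert percent_similarity("MKTAYIAKQR", "MKTAYIAKQR") == 100.0


def test_similarity_is_symmetric(rng):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(10):
        a = "".join(rng.choice(list(aas), size=30))
        b = "".join(rng.choice(list(aas), size=25))
        assert percent_similarity(a, b) == pytest.approx(percent_similarity(b, a))


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        percent_similarity("", "MKT")


# ---------------------------------------------------------------------------
# tandem calling
# ---------------------------------------------------------------------------


def _chromosome(n_loci, family_ranks, chrom="Chr01"):
    genes = [
        GeneModel(f"L{r:03d}", chrom, 1000 * r + 1, 1000 * r + 500, "+")
        for r in range(n_loci)
    ]
    family = [f"L{r:03d}" for r in family_ranks]
    return genes, family


def test_adjacent_identical_genes_are_tandem():
    genes, family = _chromosome(20, [3, 4])
    calls = call_tandem(family, genes, lambda a, b: 100.0)
    assert {c.gene_id for c in calls} == set(family)
    assert calls[0].partners == [family[1]]


def test_exactly_ten_intervening_loci_is_not_tandem():
    genes, family = _chromosome(30, [3, 14])  # ranks 3 and 14: 10 loci between
    assert call_tandem(family, genes, lambda a, b: 100.0) == []


def test_nine_intervening_loci_is_tandem():
    genes, family = _chromosome(30, [3, 13])
    calls = call_tandem(family, genes, lambda a, b: 100.0)
    assert {c.gene_id for c in calls} == set(family)


def test_similarity_threshold_is_strict():
    genes, family = _chromosome(20, [3, 4])
    assert call_tandem(family, genes, lambda a, b: 50.0) == []
    assert call_tandem(family, genes, lambda a, b: 50.1) != []


def test_missing_family_gene_is_an_error():
    genes, _ = _chromosome(5, [])
    with pytest.raises(KeyError, match="ghost"):
        call_tandem(["ghost"], genes, lambda a, b: 100.0)


def test_tandem_calls_recover_planted_clusters(small_genome):
    seqs = dict(small_genome.proteins)

    def sim(a, b):
        return percent_similarity(seqs[a], seqs[b])

    calls = call_tandem(small_genome.family_ids, small_genome.genes, sim)
    called = {c.gene_id for c in calls}
    planted = {g for cluster in small_genome.tandem_truth for g in cluster}
    assert called == planted  # precision and recall both 1.0
    for cluster in small_genome.tandem_truth:
        for g in cluster:
            call = next(c for c in calls if c.gene_id == g)
            assert set(call.partners) == set(cluster) - {g}


# ---------------------------------------------------------------------------
# anchors and blocks
# ---------------------------------------------------------------------------


def _anchor_hit(q, s, evalue):
    return HomologyHit(q, s, 80.0, 300, 50, 2, 1, 300, 1, 300, evalue, 300.0)


def test_anchor_filter_keeps_top5_below_cutoff():
    hits = [_anchor_hit("q", f"s{i}", 10.0 ** -(30 - i)) for i in range(8)]
    hits.append(_anchor_hit("q", "weak", 1e-5))  # not strictly below cutoff
    hits.append(_anchor_hit("q", "q", 1e-40))    # self hit
    anchors = anchors_from_hits(hits)
    assert len(anchors) == 5
    assert {a.gene_b for a in anchors} == {f"s{i}" for i in range(5)}


def _rank_map(pairs):
    """pairs: list of (chrom, rank) per synthetic gene g0, g1, ..."""
    return {f"g{i}": cr for i, cr in enumerate(pairs)}


def test_planted_six_anchor_block_is_recovered():
    ranks = {}
    anchors = []
    for i in range(6):
        ranks[f"a{i}"] = ("Chr01", 10 + 3 * i)
        ranks[f"b{i}"] = ("Chr02", 40 + 2 * i)
        anchors.append(_anchor_hit(f"a{i}", f"b{i}", 1e-20))
    blocks = find_collinear_blocks(anchors_from_hits(anchors), ranks, min_block=5)
    assert len(blocks) == 1
    assert len(blocks[0].anchors) == 6
    assert blocks[0].orientation == "same"


def test_inverted_block_is_detected_and_labeled():
    ranks = {}
    anchors = []
    for i in range(6):
        ranks[f"a{i}"] = ("Chr01", 10 + 3 * i)
        ranks[f"b{i}"] = ("Chr02", 90 - 4 * i)
        anchors.append(_anchor_hit(f"a{i}", f"b{i}", 1e-20))
    blocks = find_collinear_blocks(anchors_from_hits(anchors), ranks, min_block=5)
    assert len(blocks) == 1
    assert blocks[0].orientation == "inverted"


def test_shuffled_anchors_yield_no_blocks():
    rng = np.random.default_rng(2)
    ranks = {}
    anchors = []
    perm = rng.permutation(20)
    for i in range(20):
        ranks[f"a{i}"] = ("Chr01", int(i))
        ranks[f"b{i}"] = ("Chr02", int(perm[i]))
        anchors.append(_anchor_hit(f"a{i}", f"b{i}", 1e-20))
    blocks = find_collinear_blocks(anchors_from_hits(anchors), ranks, min_block=5, max_gap=3)
    assert blocks == []


def test_single_anchor_is_below_min_block():
    ranks = {"a0": ("Chr01", 1), "b0": ("Chr02", 1)}
    anchors = anchors_from_hits([_anchor_hit("a0", "b0", 1e-20)])
    assert find_collinear_blocks(anchors, ranks, min_block=5) == []


def test_block_recovery_on_simulated_genome(small_genome):
    anchors = anchors_from_hits(small_genome.hits)
    blocks = find_collinear_blocks(anchors, gene_ranks(small_genome.genes))
    assert len(blocks) == len(small_genome.block_truth)
    recovered = {
        frozenset((a.gene_a, a.gene_b)) for b in blocks for a in b.anchors
    }
    planted = {
        frozenset(pair) for pairs in small_genome.block_truth for pair in pairs
    }
    assert recovered == planted  # recall 1.0 on planted anchors


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def test_classification_counts_and_identity(small_genome):
    seqs = dict(small_genome.proteins)
    tandem = call_tandem(
        small_genome.family_ids,
        small_genome.genes,
        lambda a, b: percent_similarity(seqs[a], seqs[b]),
    )
    blocks = find_collinear_blocks(
        anchors_from_hits(small_genome.hits), gene_ranks(small_genome.genes)
    )
    summary = classify(small_genome.family_ids, tandem, blocks)
    assert summary.n_tandem == sum(len(c) for c in small_genome.tandem_truth)
    assert summary.n_segmental == sum(2 * len(p) for p in small_genome.block_truth)
    assert summary.n_duplicated == summary.n_tandem + summary.n_segmental - summary.n_both
    assert summary.pct_duplicated == round(100 * summary.n_duplicated / summary.n_family, 2)


def test_no_evidence_means_all_none():
    summary = classify(["g1", "g2"], [], [])
    assert all(c.label == "none" for c in summary.calls)
    assert summary.pct_duplicated == 0.0


def test_gene_in_both_categories_is_counted_once():
    from matekit.duplication import AnchorPair, CollinearBlock, DuplicationCall

    tandem = [DuplicationCall("g1", "tandem", ["g2"], "t"),
              DuplicationCall("g2", "tandem", ["g1"], "t")]
    block = CollinearBlock("Chr01", "Chr02", [AnchorPair("g1", "g3", 1e-20)], "same")
    summary = classify(["g1", "g2", "g3"], tandem, [block])
    labels = {c.gene_id: c.label for c in summary.calls}
    assert labels == {"g1": "both", "g2": "tandem", "g3": "segmental"}
    assert summary.n_duplicated == 3
    assert summary.n_both == 1
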