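"""Tandem and segmental duplication calling for a gene family.

Tandem duplicates are family pairs on one chromosome separated by fewer
than ``max_intervening`` annotated loci (strict, over ALL loci by default)
whose proteins exceed a similarity threshold (strict >). Segmental
duplicates are family genes participating in collinear (syntenic) blocks,
found here by simplified anchor chaining: significant homologous pairs
("anchors", E < 1e-5, top 5 matches per query) are chained into maximal
runs that are monotone in gene rank on both chromosomes with bounded rank
gaps. This chaining deliberately omits the statistical block E-value of
MCScan-style tools; block calls are controlled instead by ``min_block``
anchors and ``max_gap`` ranks, both configurable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import GeneModel, HomologyHit, natural_key

Label = Literal["tandem", "segmental", "both", "none"]


@dataclass
class DuplicationCall:
    gene_id: str
    label: Label
    partners: list[str]
    evidence: str


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    evalue: float


@dataclass
class CollinearBlock:
    chromosome_a: str
    chromosome_b: str
    anchors: list[AnchorPair]
    orientation: Literal["same", "inverted"]


# ---------------------------------------------------------------------------
# protein similarity
# ---------------------------------------------------------------------------


def _global_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def percent_similarity(
    protein_a: str,
    protein_b: str,
    *,
    metric: Literal["similarity", "identity"] = "similarity",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Percent similarity over a global (end-to-end, affine-gap) alignment.

    ``similarity`` counts BLOSUM62-positive aligned residue pairs,
    ``identity`` counts identical pairs; both divide by the total number
    of alignment columns (gap columns included).
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    aligner = _global_aligner(gap_open, gap_extend)
    alignment = aligner.align(protein_a.upper(), protein_b.upper())[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matrix = aligner.substitution_matrix
    matched = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        if metric == "identity":
            matched += x == y
        else:
            matched += matrix[x, y] > 0
    return 100.0 * matched / len(row_a)


# ---------------------------------------------------------------------------
# gene ranks
# ---------------------------------------------------------------------------


def gene_ranks(all_genes: Sequence[GeneModel]) -> dict[str, tuple[str, int]]:
    """Map gene_id -> (chromosome, rank) with rank = 0-based position of the
    locus along its chromosome ordered by (start, gene_id)."""
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in all_genes:
        by_chrom[g.chromosome].append(g)
    ranks: dict[str, tuple[str, int]] = {}
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(genes):
            ranks[g.gene_id] = (chrom, i)
    return ranks


# ---------------------------------------------------------------------------
# tandem duplication
# ---------------------------------------------------------------------------


def call_tandem(
    family_ids: Sequence[str],
    all_genes: Sequence[GeneModel],
    similarity: Callable[[str, str], float],
    *,
    max_intervening: int = 10,
    min_similarity: float = 50.0,
    count_loci: Literal["all", "family"] = "all",
) -> list[DuplicationCall]:
    """Tandem calls: same chromosome, < ``max_intervening`` loci in between
    (strict; the count excludes both family genes), similarity strictly
    above ``min_similarity``.

    ``count_loci='all'`` counts every annotated locus between the pair
    (the literal reading); ``'family'`` counts family loci only.
    """
    ranks = gene_ranks(all_genes)
    for gid in family_ids:
        if gid not in ranks:
            raise KeyError(f"family gene {gid!r} missing from the full locus table")
    family_set = set(family_ids)

    by_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for gid in family_ids:
        chrom, rank = ranks[gid]
        by_chrom[chrom].append((rank, gid))

    fam_pos: dict[str, int] = {}
    if count_loci == "family":
        for chrom, members in by_chrom.items():
            for i, (_, gid) in enumerate(sorted(members)):
                fam_pos[gid] = i

    partners: dict[str, set[str]] = defaultdict(set)
    for chrom, members in by_chrom.items():
        members.sort()
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                rank_i, gid_i = members[i]
                rank_j, gid_j = members[j]
                if count_loci == "all":
                    intervening = rank_j - rank_i - 1
                else:
                    intervening = fam_pos[gid_j] - fam_pos[gid_i] - 1
                if intervening >= max_intervening:
                    if count_loci == "all":
                        break  # ranks only grow with j
                    continue
                if similarity(gid_i, gid_j) > min_similarity:
                    partners[gid_i].add(gid_j)
                    partners[gid_j].add(gid_i)

    return [
        DuplicationCall(
            gene_id=gid,
            label="tandem",
            partners=sorted(partners[gid]),
            evidence=f"tandem: <{max_intervening} intervening loci, >{min_similarity}% similarity",
        )
        for gid in sorted(partners)
    ]


# ---------------------------------------------------------------------------
# anchors and collinear blocks
# ---------------------------------------------------------------------------


def anchors_from_hits(
    hits: Iterable[HomologyHit],
    *,
    evalue_max: float = 1e-5,
    top_n: int = 5,
) -> list[AnchorPair]:
    """Candidate anchors: per query keep the top ``top_n`` non-self matches
    with E strictly below ``evalue_max``; pairs are deduplicated unordered."""
    per_query: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in hits:
        if h.query_id != h.subject_id and h.evalue < evalue_max:
            per_query[h.query_id].append(h)
    pairs: dict[tuple[str, str], float] = {}
    for query, qhits in per_query.items():
        qhits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        for h in qhits[:top_n]:
            key = tuple(sorted((h.query_id, h.subject_id)))
            if key not in pairs or h.evalue < pairs[key]:
                pairs[key] = h.evalue
    return [AnchorPair(a, b, e) for (a, b), e in sorted(pairs.items())]


def _chain(
    points: list[tuple[int, int, AnchorPair]],
    max_gap: int,
    direction: int,
) -> list[list[AnchorPair]]:
    """Greedy monotone chaining of (rank_a, rank_b) points sorted by rank_a.

    ``direction`` +1 chains rank_b increasing, -1 decreasing. Each point
    joins the open chain with the closest compatible tail, else starts a
    new chain; every anchor lands in at most one chain.
    """
    chains: list[list[tuple[int, int, AnchorPair]]] = []
    for ra, rb, anchor in sorted(points, key=lambda p: (p[0], p[1] * direction)):
        best = None
        best_cost = None
        for chain in chains:
            la, lb, _ = chain[-1]
            if ra <= la:
                continue
            if direction * (rb - lb) <= 0:
                continue
            if ra - la > max_gap or abs(rb - lb) > max_gap:
                continue
            cost = (ra - la) + abs(rb - lb)
            if best_cost is None or cost < best_cost:
                best, best_cost = chain, cost
        if best is not None:
            best.append((ra, rb, anchor))
        else:
            chains.append([(ra, rb, anchor)])
    return [[p[2] for p in chain] for chain in chains]


def find_collinear_blocks(
    anchors: Sequence[AnchorPair],
    ranks: dict[str, tuple[str, int]],
    *,
    min_block: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks, same and inverted orientation.

    Anchors are grouped by (sorted) chromosome pair; within a group,
    same-orientation chains are formed first and leftover anchors are
    offered to the inverted pass, so each anchor joins at most one block.
    Chains with at least ``min_block`` anchors are reported.
    """
    groups: dict[tuple[str, str], list[tuple[int, int, AnchorPair]]] = defaultdict(list)
    for anchor in anchors:
        if anchor.gene_a not in ranks or anchor.gene_b not in ranks:
            continue
        chrom_a, rank_a = ranks[anchor.gene_a]
        chrom_b, rank_b = ranks[anchor.gene_b]
        if (natural_key(chrom_a), rank_a) <= (natural_key(chrom_b), rank_b):
            groups[(chrom_a, chrom_b)].append((rank_a, rank_b, anchor))
        else:
            groups[(chrom_b, chrom_a)].append((rank_b, rank_a, anchor))

    blocks: list[CollinearBlock] = []
    for (chrom_a, chrom_b), points in sorted(groups.items()):
        same_chains = _chain(points, max_gap, direction=+1)
        used = {id(a) for chain in same_chains if len(chain) >= min_block for a in chain}
        leftover = [p for p in points if id(p[2]) not in used]
        inverted_chains = _chain(leftover, max_gap, direction=-1)
        for chain in same_chains:
            if len(chain) >= min_block:
                blocks.append(CollinearBlock(chrom_a, chrom_b, chain, "same"))
        for chain in inverted_chains:
            if len(chain) >= min_block:
                blocks.append(CollinearBlock(chrom_a, chrom_b, chain, "inverted"))
    return blocks


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class DuplicationSummary:
    calls: list[DuplicationCall]
    n_family: int
    n_tandem: int
    n_segmental: int
    n_both: int
    n_duplicated: int
    pct_tandem: float
    pct_segmental: float
    pct_duplicated: float


def classify(
    family_ids: Sequence[str],
    tandem_calls: Sequence[DuplicationCall],
    blocks: Sequence[CollinearBlock],
) -> DuplicationSummary:
    """Merge tandem and block evidence into one call per family gene.

    A gene is segmental iff it appears in an anchor of some block whose
    partner is also a family gene. Percentages are reported at 2 decimals
    of the family size.
    """
    family_set = set(family_ids)
    tandem_map = {c.gene_id: c for c in tandem_calls}
    seg_partners: dict[str, set[str]] = defaultdict(set)
    for block in blocks:
        for anchor in block.anchors:
            if anchor.gene_a in family_set and anchor.gene_b in family_set:
                seg_partners[anchor.gene_a].add(anchor.gene_b)
                seg_partners[anchor.gene_b].add(anchor.gene_a)

    calls: list[DuplicationCall] = []
    n_tandem = n_segmental = n_both = 0
    for gid in family_ids:
        is_tandem = gid in tandem_map
        is_seg = gid in seg_partners
        if is_tandem and is_seg:
            label: Label = "both"
            n_both += 1
            n_tandem += 1
            n_segmental += 1
            partners = sorted(set(tandem_map[gid].partners) | seg_partners[gid])
            evidence = "tandem+segmental"
        elif is_tandem:
            label = "tandem"
            n_tandem += 1
            partners = tandem_map[gid].partners
            evidence = tandem_map[gid].evidence
        elif is_seg:
            label = "segmental"
            n_segmental += 1
            partners = sorted(seg_partners[gid])
            evidence = "segmental: collinear-block anchor with family partner"
        else:
            label = "none"
            partners = []
            evidence = ""
        calls.append(DuplicationCall(gid, label, partners, evidence))

    n_dup = n_tandem + n_segmental - n_both
    n_family = len(family_ids)

    def pct(n: int) -> float:
        return round(100.0 * n / n_family, 2) if n_family else 0.0

    return DuplicationSummary(
        calls=calls,
        n_family=n_family,
        n_tandem=n_tandem,
        n_segmental=n_segmental,
        n_both=n_both,
        n_duplicated=n_dup,
        pct_tandem=pct(n_tandem),
        pct_segmental=pct(n_segmental),
        pct_duplicated=pct(n_dup),
    )


def write_calls(summary: DuplicationSummary, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tlabel\tpartners\tevidence\n")
        for c in summary.calls:
            handle.write(f"{c.gene_id}\t{c.label}\t{','.join(c.partners)}\t{c.evidence}\n")


def write_blocks(blocks: Sequence[CollinearBlock], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("block\tchromosome_a\tchromosome_b\torientation\tn_anchors\tanchors\n")
        for i, b in enumerate(blocks, start=1):
            pairs = ";".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors)
            handle.write(
                f"{i}\t{b.chromosome_a}\t{b.chromosome_b}\t{b.orientation}"
                f"\t{len(b.anchors)}\t{pairs}\n"
            )


def write_chromosome_map(
    family_ids: Sequence[str],
    all_genes: Sequence[GeneModel],
    summary: DuplicationSummary,
    path: str | Path,
) -> None:
    """Per-chromosome position/label table (a text stand-in for a karyotype plot)."""
    labels = {c.gene_id: c.label for c in summary.calls}
    fam = [g for g in all_genes if g.gene_id in set(family_ids)]
    fam.sort(key=lambda g: (natural_key(g.chromosome), g.start, g.gene_id))
    with open(path, "w") as handle:
        handle.write("chromosome\tgene_id\tstart\tend\tlabel\n")
        for g in fam:
            handle.write(
                f"{g.chromosome}\t{g.gene_id}\t{g.start}\t{g.end}\t{labels.get(g.gene_id, 'none')}\n"
            )
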