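"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its downstream stage
assumes — gene loci on multiple chromosomes with planted tandem clusters
and collinear anchor blocks, promoters of configurable GC content with
degenerate motifs planted at known signed positions, FPKM-like expression
matrices with tissue-specific blocks and all-zero rows, and Ct tables
derived from true fold changes and a true amplification efficiency with
Gaussian replicate noise — and records every planted relationship in a
truth table, so planted-recovery tests have exhaustive ground truth.

Default shapes mirror the soybean MATE study design: 20 chromosomes,
117 family genes, 1500 bp promoters, 9 tissues with 4 silent genes, and a
2-genotype x 2-treatment x 3-timepoint x 3-replicate qPCR layout.

Randomness: one integer seed; each stage draws from an independent
substream derived by hashing the stage name, so stages can be regenerated
independently and identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DomainHit, GeneModel, HomologyHit, write_blast_tab, write_domain_table, write_expression_tsv, write_fasta, write_gene_table
from .motifs import IUPAC_CODES, MotifPattern

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_BASES = np.array(list("ACGT"))


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible generator for one named stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(stage.encode()),))
    )


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AMINO_ACIDS, size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(_AMINO_ACIDS))
    return "".join(out)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class TandemSpec:
    n_clusters: int = 4
    cluster_size: int = 2
    intervening_loci: int = 0       # non-family loci between cluster members
    mutation_rate: float = 0.05     # divergence of cluster members


@dataclass
class BlockSpec:
    n_blocks: int = 3
    anchors_per_block: int = 6
    rank_step: int = 11             # spacing so block genes never look tandem


@dataclass
class GenomeSpec:
    n_chromosomes: int = 20
    loci_per_chromosome: int = 100
    n_family: int = 117
    gene_length: int = 3000
    intergenic: int = 2000
    gc: float = 0.35
    protein_length_range: tuple[int, int] = (80, 593)  # study-like span
    tandem: TandemSpec = field(default_factory=TandemSpec)
    blocks: BlockSpec = field(default_factory=BlockSpec)
    domain_id: str = "PF01554"


@dataclass
class PromoterSpec:
    length: int = 1500
    gc: float = 0.35
    n_genes: int = 8
    pattern: str = "GGNVS"
    planted_per_gene: int = 6
    collision_free: bool = False


@dataclass
class ExpressionSpec:
    n_genes: int = 117
    tissues: tuple[str, ...] = (
        "root", "root_hair", "nodule", "stem", "leaf",
        "flower", "pod", "seed", "SAM",
    )
    n_all_zero: int = 4
    block_effect: float = 8.0       # fold elevation in the gene's home tissue
    log_sd: float = 0.5


@dataclass
class QpcrSpec:
    genotypes: tuple[str, ...] = ("T", "S")
    timepoints: tuple[str, ...] = ("6h", "12h", "24h")
    replicates: int = 3
    noise_sd: float = 0.2
    true_efficiency: float = 0.95
    dilution_factors: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0, 30.0)
    # gene -> genotype -> timepoint -> true fold (treated vs control);
    # the default candidate gene mimics a strongly Al-induced transporter
    # with much larger induction in the tolerant genotype
    true_folds: dict = field(default_factory=lambda: {
        "target1": {
            "T": {"6h": 127.0, "12h": 274.0, "24h": 335.0},
            "S": {"6h": 10.0, "12h": 39.0, "24h": 33.0},
        },
        "target2": {
            "T": {"6h": 1.0, "12h": 2.0, "24h": 1.5},
            "S": {"6h": 1.2, "12h": 2.5, "24h": 2.0},
        },
    })
    reference_gene: str = "EF1a"


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    promoters: PromoterSpec = field(default_factory=PromoterSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    qpcr: QpcrSpec = field(default_factory=QpcrSpec)


# ---------------------------------------------------------------------------
# genome with planted tandem clusters and collinear blocks
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGenome:
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    family_ids: list[str]
    proteins: list[tuple[str, str]]        # family proteins only
    hits: list[HomologyHit]                # all-vs-all style anchor evidence
    family_hits: list[HomologyHit]         # query-set homology for identification
    domain_hits: list[DomainHit]
    tandem_truth: list[list[str]]          # clusters of gene ids
    block_truth: list[list[tuple[str, str]]]  # anchor pair lists per block


def _make_hit(query: str, subject: str, evalue: float, rng: np.random.Generator) -> HomologyHit:
    ident = float(np.round(60 + 35 * rng.random(), 1))
    return HomologyHit(query, subject, ident, 300, 30, 2, 1, 300, 1, 300, evalue, 400.0)


def gen_genome(config: SimConfig) -> SimulatedGenome:
    """Chromosomes + loci with planted tandem clusters and anchor blocks.

    Family genes are placed so that only planted cluster members fall
    within the tandem distance of another family gene: singles and block
    genes are spaced at least 11 loci apart, hence planted-cluster
    precision/recall is 1.0 by construction at default thresholds.
    """
    spec = config.genome
    rng = substream(config.seed, "genome")
    t, b = spec.tandem, spec.blocks

    n_cluster_genes = t.n_clusters * t.cluster_size
    n_block_genes = b.n_blocks * b.anchors_per_block * 2
    n_singles = spec.n_family - n_cluster_genes - n_block_genes
    if n_singles < 0:
        raise ValueError(
            "n_family too small for the requested tandem clusters and blocks"
        )

    # per-chromosome rank slots reserved for family genes
    L = spec.loci_per_chromosome
    free_from = {c: 2 for c in range(spec.n_chromosomes)}

    def reserve(chrom: int, n_ranks: int) -> int | None:
        """Reserve n consecutive ranks on chrom; returns start rank or None."""
        start = free_from[chrom]
        if start + n_ranks > L - 2:
            return None
        # next family gene starts >= 10 intervening loci away: at the strict
        # "less than ten in-between" boundary, never tandem
        free_from[chrom] = start + n_ranks + 10
        return start

    family_slots: dict[tuple[int, int], str] = {}  # (chrom, rank) -> gene id
    counter = [0]

    def new_family_gene(chrom: int, rank: int) -> str:
        counter[0] += 1
        gid = f"fam{counter[0]:04d}"
        family_slots[(chrom, rank)] = gid
        return gid

    tandem_truth: list[list[str]] = []
    chrom_cycle = 0

    def next_chrom_with(n_ranks: int) -> int:
        nonlocal chrom_cycle
        for _ in range(spec.n_chromosomes):
            c = chrom_cycle % spec.n_chromosomes
            chrom_cycle += 1
            if free_from[c] + n_ranks <= L - 2:
                return c
        raise ValueError("loci do not fit: increase loci_per_chromosome")

    for _ in range(t.n_clusters):
        span = t.cluster_size + (t.cluster_size - 1) * t.intervening_loci
        c = next_chrom_with(span)
        start = reserve(c, span)
        cluster = [
            new_family_gene(c, start + i * (t.intervening_loci + 1))
            for i in range(t.cluster_size)
        ]
        tandem_truth.append(cluster)

    block_truth: list[list[tuple[str, str]]] = []
    for _ in range(b.n_blocks):
        span = (b.anchors_per_block - 1) * b.rank_step + 1
        ca = next_chrom_with(span)
        sa = reserve(ca, span)
        cb = next_chrom_with(span)
        sb = reserve(cb, span)
        pairs = []
        for i in range(b.anchors_per_block):
            ga = new_family_gene(ca, sa + i * b.rank_step)
            gb = new_family_gene(cb, sb + i * b.rank_step)
            pairs.append((ga, gb))
        block_truth.append(pairs)

    for _ in range(n_singles):
        c = next_chrom_with(1)
        rank = reserve(c, 1)
        new_family_gene(c, rank)

    # materialise loci
    genes: list[GeneModel] = []
    chromosomes: dict[str, str] = {}
    for c in range(spec.n_chromosomes):
        chrom_name = f"Chr{c + 1:02d}"
        pitch = spec.gene_length + spec.intergenic
        chrom_len = L * pitch + spec.intergenic
        chromosomes[chrom_name] = _random_dna(rng, chrom_len, spec.gc)
        for rank in range(L):
            start = spec.intergenic + rank * pitch + 1
            end = start + spec.gene_length - 1
            gid = family_slots.get((c, rank), f"loc{c:02d}_{rank:03d}")
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gid, chrom_name, start, end, strand))

    # family proteins: cluster members diverge slightly from a shared
    # ancestor; block partners share a sequence; singles are independent
    proteins: dict[str, str] = {}
    lo, hi = spec.protein_length_range

    def draw_length() -> int:
        return int(rng.integers(lo, hi + 1))

    for cluster in tandem_truth:
        base = _random_protein(rng, draw_length())
        for gid in cluster:
            proteins[gid] = _mutate_protein(rng, base, t.mutation_rate)
    for pairs in block_truth:
        for ga, gb in pairs:
            base = _random_protein(rng, draw_length())
            proteins[ga] = base
            proteins[gb] = _mutate_protein(rng, base, t.mutation_rate)
    family_ids = sorted(family_slots.values())
    for gid in family_ids:
        if gid not in proteins:
            proteins[gid] = _random_protein(rng, draw_length())

    # homology evidence: strong hits for planted anchors (both directions),
    # plus non-significant background hits
    hits: list[HomologyHit] = []
    for pairs in block_truth:
        for ga, gb in pairs:
            hits.append(_make_hit(ga, gb, 1e-30, rng))
            hits.append(_make_hit(gb, ga, 1e-30, rng))
    non_family = [g.gene_id for g in genes if g.gene_id not in family_slots.values()]
    for _ in range(len(family_ids)):
        q, s = rng.choice(non_family, size=2, replace=False)
        hits.append(_make_hit(str(q), str(s), 10.0 ** rng.uniform(-4.9, -1), rng))

    domain_hits = [
        DomainHit(gid, spec.domain_id, 10, max(11, len(proteins[gid]) - 10))
        for gid in family_ids
    ]

    # identification evidence: every family gene gets a strong query-set hit;
    # decoys exercise both filters (good E-value but no domain, and domain-less
    # weak hits above the cutoff)
    family_hits: list[HomologyHit] = []
    for i, gid in enumerate(family_ids):
        query = f"query{i % 57 + 1:02d}"
        family_hits.append(_make_hit(query, gid, 10.0 ** rng.uniform(-60, -9), rng))
    decoys = list(rng.choice(non_family, size=min(20, len(non_family)), replace=False))
    for j, decoy in enumerate(decoys):
        if j % 2 == 0:  # passes E-value, lacks the domain
            family_hits.append(_make_hit("query01", str(decoy), 1e-12, rng))
        else:           # carries a decoy domain but fails the E-value filter
            family_hits.append(_make_hit("query02", str(decoy), 1e-6, rng))
            domain_hits.append(DomainHit(str(decoy), "PF00001", 5, 80))

    return SimulatedGenome(
        chromosomes=chromosomes,
        genes=genes,
        family_ids=family_ids,
        proteins=[(gid, proteins[gid]) for gid in family_ids],
        hits=hits,
        family_hits=family_hits,
        domain_hits=domain_hits,
        tandem_truth=tandem_truth,
        block_truth=block_truth,
    )


# ---------------------------------------------------------------------------
# promoters with planted motifs
# ---------------------------------------------------------------------------


class PlantingError(ValueError):
    """Planted motifs overlap with incompatible base requirements."""


def _brute_force_matches(sequence: str, pattern: MotifPattern) -> list[int]:
    """Independent position-by-position scan; signed 5'-most positions."""
    sets = pattern.position_sets
    k = len(sets)
    L = len(sequence)
    out = []
    for offset in range(L - k + 1):
        ok = True
        for j in range(k):
            if sequence[offset + j] not in sets[j]:
                ok = False
                break
        if ok:
            out.append(offset - L)
    return out


def plant_motifs(
    rng: np.random.Generator,
    length: int,
    planted: Sequence[tuple[MotifPattern, int]],
    gc: float,
    *,
    collision_free: bool = False,
    max_tries: int = 500,
) -> str:
    """One promoter of ``length`` bp with motif instances planted at the
    given signed positions (5'-most base; -1 adjacent to the ATG).

    Overlapping planted motifs are reconciled by intersecting their IUPAC
    base sets position-wise; an empty intersection raises
    :class:`PlantingError`. With ``collision_free=True`` the background is
    resampled/repaired until a brute-force scan finds each planted pattern
    exactly at its planted positions and nowhere else.
    """
    allowed: list[frozenset[str] | None] = [None] * length
    for pattern, pos in planted:
        k = len(pattern)
        if not (-length <= pos <= -k):
            raise ValueError(
                f"planted position {pos} outside [-{length}, -{k}] for {pattern.name}"
            )
        offset = length + pos
        for j, sets in enumerate(pattern.position_sets):
            cur = allowed[offset + j]
            merged = sets if cur is None else cur & sets
            if not merged:
                raise PlantingError(
                    f"incompatible overlap at window offset {offset + j} "
                    f"planting {pattern.name} at {pos}"
                )
            allowed[offset + j] = merged

    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    wanted: dict[str, set[int]] = {}
    patterns: dict[str, MotifPattern] = {}
    for pattern, pos in planted:
        wanted.setdefault(pattern.name, set()).add(pos)
        patterns[pattern.name] = pattern

    for _ in range(max_tries):
        seq = [
            str(rng.choice(_BASES, p=probs)) if allow is None
            else str(rng.choice(sorted(allow)))
            for allow in allowed
        ]
        if not collision_free:
            return "".join(seq)
        ok = _repair_collisions(rng, seq, allowed, wanted, patterns, length)
        if ok:
            return "".join(seq)
    raise PlantingError(
        f"could not build a collision-free promoter in {max_tries} tries"
    )


def _repair_collisions(
    rng: np.random.Generator,
    seq: list[str],
    allowed: list[frozenset[str] | None],
    wanted: Mapping[str, set[int]],
    patterns: Mapping[str, MotifPattern],
    length: int,
) -> bool:
    """Break spurious matches by mutating free background positions;
    returns False when a spurious match has no free position to break."""
    for _ in range(20):
        spurious: list[tuple[MotifPattern, int]] = []
        for name, positions in wanted.items():
            found = set(_brute_force_matches("".join(seq), patterns[name]))
            if not positions <= found:
                return False  # a planted instance was destroyed: resample
            spurious.extend((patterns[name], p) for p in found - positions)
        if not spurious:
            return True
        progressed = False
        for pattern, pos in spurious:
            offset = length + pos
            for j, sets in enumerate(pattern.position_sets):
                idx = offset + j
                if allowed[idx] is None and len(sets) < 4:
                    breakers = sorted(set("ACGT") - sets)
                    seq[idx] = str(rng.choice(breakers))
                    progressed = True
                    break
        if not progressed:
            return False
    return False


@dataclass
class SimulatedPromoters:
    promoters: list[tuple[str, str]]               # (gene_id, sequence)
    truth: pd.DataFrame                            # gene_id, motif, position, planted


def gen_promoters(config: SimConfig, planted_positions: Mapping[str, Sequence[int]] | None = None) -> SimulatedPromoters:
    """Promoter FASTA + exhaustive match truth.

    By default each of ``n_genes`` promoters receives ``planted_per_gene``
    instances of the configured pattern at random non-overlapping
    positions; ``planted_positions`` (gene -> signed positions) overrides
    the layout. Truth lists every match a brute-force scan finds, so
    background collisions are included (flagged planted=False), unless the
    spec requests collision-free backgrounds.
    """
    spec = config.promoters
    rng = substream(config.seed, "promoters")
    pattern = MotifPattern(spec.pattern, spec.pattern)
    k = len(pattern)

    if planted_positions is None:
        planted_positions = {}
        for i in range(spec.n_genes):
            gid = f"prom{i + 1:03d}"
            taken: list[int] = []
            while len(taken) < spec.planted_per_gene:
                pos = int(rng.integers(-spec.length, -k + 1))
                if all(abs(pos - q) >= k for q in taken):
                    taken.append(pos)
            planted_positions[gid] = sorted(taken)

    promoters: list[tuple[str, str]] = []
    rows = []
    for gid, positions in planted_positions.items():
        seq = plant_motifs(
            rng,
            spec.length,
            [(pattern, p) for p in positions],
            spec.gc,
            collision_free=spec.collision_free,
        )
        promoters.append((gid, seq))
        planted_set = set(positions)
        for pos in _brute_force_matches(seq, pattern):
            rows.append(
                {
                    "gene_id": gid,
                    "motif": pattern.name,
                    "position": pos,
                    "planted": pos in planted_set,
                }
            )
    truth = pd.DataFrame(rows, columns=["gene_id", "motif", "position", "planted"])
    return SimulatedPromoters(promoters=promoters, truth=truth)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExpression:
    matrix: pd.DataFrame
    block_membership: dict[str, str]   # gene -> home tissue ("" for silent)
    all_zero: list[str]


def gen_expression(config: SimConfig) -> SimulatedExpression:
    """Log-normal FPKM-like matrix with tissue-specific blocks and exactly
    ``n_all_zero`` silent rows."""
    spec = config.expression
    rng = substream(config.seed, "expression")
    genes = [f"gene{i + 1:03d}" for i in range(spec.n_genes)]
    zero_idx = rng.choice(spec.n_genes, size=spec.n_all_zero, replace=False)
    zero_set = {genes[i] for i in zero_idx}
    tissues = list(spec.tissues)

    values = np.zeros((spec.n_genes, len(tissues)))
    membership: dict[str, str] = {}
    for i, gid in enumerate(genes):
        if gid in zero_set:
            membership[gid] = ""
            continue
        home = tissues[i % len(tissues)]
        membership[gid] = home
        base = rng.lognormal(mean=1.0, sigma=spec.log_sd, size=len(tissues))
        base[tissues.index(home)] *= spec.block_effect
        values[i] = np.round(base, 3)

    matrix = pd.DataFrame(values, index=genes, columns=tissues)
    return SimulatedExpression(
        matrix=matrix,
        block_membership=membership,
        all_zero=sorted(zero_set),
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables and dilution series
# ---------------------------------------------------------------------------


@dataclass
class SimulatedQpcr:
    ct: pd.DataFrame
    dilutions: pd.DataFrame
    true_folds: dict
    true_efficiency: float


def gen_qpcr(config: SimConfig) -> SimulatedQpcr:
    """Ct tables generated from true folds, plus a dilution series from the
    true amplification efficiency.

    Treated-group target Cts sit log2(fold) cycles below the control
    baseline; the reference gene is constant across all samples up to
    noise, mimicking a well-behaved housekeeping control.
    """
    spec = config.qpcr
    rng = substream(config.seed, "qpcr")
    rows = []
    base_ct = {
        gene: float(np.round(rng.uniform(24, 30), 2)) for gene in spec.true_folds
    }
    ref_ct = 18.0

    def noise() -> float:
        return float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0

    for gene, per_genotype in spec.true_folds.items():
        for genotype, per_tp in per_genotype.items():
            for tp, fold in per_tp.items():
                for rep in range(1, spec.replicates + 1):
                    rows.append(
                        (gene, genotype, "control", tp, rep, base_ct[gene] + noise())
                    )
                    rows.append(
                        (
                            gene, genotype, "treated", tp, rep,
                            base_ct[gene] - float(np.log2(fold)) + noise(),
                        )
                    )
    for genotype in spec.genotypes:
        for treatment in ("control", "treated"):
            for tp in spec.timepoints:
                for rep in range(1, spec.replicates + 1):
                    rows.append(
                        (spec.reference_gene, genotype, treatment, tp, rep, ref_ct + noise())
                    )
    ct = pd.DataFrame(
        rows, columns=["gene", "genotype", "treatment", "timepoint", "replicate", "ct"]
    )

    slope = -1.0 / np.log10(1.0 + spec.true_efficiency)
    dil_rows = []
    all_genes = list(spec.true_folds) + [spec.reference_gene]
    for gene in all_genes:
        intercept = base_ct.get(gene, ref_ct)
        for factor in spec.dilution_factors:
            x = np.log10(1.0 / factor)
            for rep in range(1, spec.replicates + 1):
                dil_rows.append((gene, factor, rep, float(intercept + slope * x) + noise()))
    dilutions = pd.DataFrame(
        dil_rows, columns=["gene", "dilution_factor", "replicate", "ct"]
    )
    return SimulatedQpcr(
        ct=ct,
        dilutions=dilutions,
        true_folds=spec.true_folds,
        true_efficiency=spec.true_efficiency,
    )


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def simulate_bundle(config: SimConfig, out_dir: str | Path) -> None:
    """Write a complete input bundle + truth/ directory for the pipeline."""
    out = Path(out_dir)
    truth = out / "truth"
    truth.mkdir(parents=True, exist_ok=True)

    genome = gen_genome(config)
    write_fasta(
        ((name, seq) for name, seq in sorted(genome.chromosomes.items())),
        out / "genome.fasta",
    )
    write_gene_table(genome.genes, out / "genes.tsv")
    write_fasta(genome.proteins, out / "family_proteins.fasta")
    write_blast_tab(genome.hits, out / "anchor_hits.tsv")
    write_blast_tab(genome.family_hits, out / "family_hits.tsv")
    write_domain_table(genome.domain_hits, out / "domain_hits.tsv")
    with open(truth / "tandem_clusters.tsv", "w") as handle:
        handle.write("cluster\tgenes\n")
        for i, cluster in enumerate(genome.tandem_truth, start=1):
            handle.write(f"{i}\t{','.join(cluster)}\n")
    with open(truth / "blocks.tsv", "w") as handle:
        handle.write("block\tanchors\n")
        for i, pairs in enumerate(genome.block_truth, start=1):
            handle.write(f"{i}\t{';'.join(f'{a}|{b}' for a, b in pairs)}\n")

    promoters = gen_promoters(config)
    write_fasta(promoters.promoters, out / "promoters.fasta")
    promoters.truth.to_csv(truth / "motif_matches.tsv", sep="\t", index=False)

    expression = gen_expression(config)
    write_expression_tsv(expression.matrix, out / "expression.tsv")
    with open(truth / "expression_truth.tsv", "w") as handle:
        handle.write("gene_id\thome_tissue\tall_zero\n")
        for gid, home in expression.block_membership.items():
            handle.write(f"{gid}\t{home}\t{int(gid in set(expression.all_zero))}\n")

    qpcr = gen_qpcr(config)
    qpcr.ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)
    qpcr.dilutions.to_csv(out / "dilutions.tsv", sep="\t", index=False)
    fold_rows = []
    for gene, per_genotype in qpcr.true_folds.items():
        for genotype, per_tp in per_genotype.items():
            for tp, fold in per_tp.items():
                fold_rows.append(f"{gene}\t{genotype}\t{tp}\t{fold}")
    (truth / "qpcr_truth.tsv").write_text(
        "gene\tgenotype\ttimepoint\ttrue_fold\n" + "\n".join(fold_rows) + "\n"
    )
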