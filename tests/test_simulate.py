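"""Synthetic-data generators: determinism, planted structure, truth tables."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from matekit.atlas import drop_all_zero
from matekit.motifs import GGNVS, MotifPattern, PromoterSeq, scan
from matekit.simulate import (
    PlantingError,
    PromoterSpec,
    QpcrSpec,
    SimConfig,
    gen_expression,
    gen_promoters,
    gen_qpcr,
    plant_motifs,
    simulate_bundle,
    substream,
)


def test_bundle_is_byte_identical_for_same_seed(small_config, tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_bundle(small_config, a)
    simulate_bundle(small_config, b)
    files = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
    assert files
    for rel in files:
        assert filecmp.cmp(a / rel, b / rel, shallow=False), rel


def test_different_seeds_differ(small_config, tmp_path):
    import dataclasses
    other = dataclasses.replace(small_config, seed=small_config.seed + 1)
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_bundle(small_config, a)
    simulate_bundle(other, b)
    assert not filecmp.cmp(a / "genome.fasta", b / "genome.fasta", shallow=False)


def test_genome_gc_within_three_standard_errors(small_genome):
    seq = "".join(small_genome.chromosomes.values())
    n = len(seq)
    gc = (seq.count("G") + seq.count("C")) / n
    p = 0.35
    se = np.sqrt(p * (1 - p) / n)
    assert abs(gc - p) < 3 * se


def test_planted_tandem_truth_matches_config(small_genome, small_config):
    spec = small_config.genome.tandem
    assert len(small_genome.tandem_truth) == spec.n_clusters
    assert all(len(c) == spec.cluster_size for c in small_genome.tandem_truth)


def test_gene_loci_do_not_overlap(small_genome):
    by_chrom = {}
    for g in small_genome.genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.start)
        for a, b in zip(genes[:-1], genes[1:]):
            assert a.end < b.start


def test_loci_that_do_not_fit_raise():
    from matekit.simulate import GenomeSpec

    cfg = SimConfig(genome=GenomeSpec(n_chromosomes=1, loci_per_chromosome=10, n_family=50))
    with pytest.raises(ValueError):
        from matekit.simulate import gen_genome

        gen_genome(cfg)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


def test_planted_position_is_always_reported(rng):
    seq = plant_motifs(rng, 500, [(GGNVS, -383)], 0.35)
    assert -383 in [m.position for m in scan(PromoterSeq("g", seq, 500), GGNVS)]


def test_incompatible_overlap_raises(rng):
    a = MotifPattern("a", "AAAA")
    c = MotifPattern("c", "CCCC")
    with pytest.raises(PlantingError):
        plant_motifs(rng, 100, [(a, -50), (c, -49)], 0.5)


def test_truth_is_exhaustive_and_scanner_agrees():
    cfg = SimConfig(seed=5, promoters=PromoterSpec(n_genes=6, planted_per_gene=4))
    sim = gen_promoters(cfg)
    for gid, seq in sim.promoters:
        found = {m.position for m in scan(PromoterSeq(gid, seq, len(seq)), GGNVS)}
        truth = set(sim.truth.loc[sim.truth["gene_id"] == gid, "position"])
        assert found == truth
        planted = set(
            sim.truth.loc[(sim.truth["gene_id"] == gid) & sim.truth["planted"], "position"]
        )
        assert planted <= found and len(planted) == 4


def test_collision_free_truth_equals_planted():
    cfg = SimConfig(
        seed=5, promoters=PromoterSpec(n_genes=6, planted_per_gene=4, collision_free=True)
    )
    sim = gen_promoters(cfg)
    assert sim.truth["planted"].all()
    assert len(sim.truth) == 24


def test_mean_count_matches_closed_form_expectation(rng):
    from matekit.motifs import expected_count

    gc = 0.4
    freqs = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    L, n = 600, 300
    counts = []
    bases = np.array(list("ACGT"))
    p = [freqs[b] for b in "ACGT"]
    for _ in range(n):
        seq = "".join(rng.choice(bases, size=L, p=p))
        counts.append(len(scan(PromoterSeq("g", seq, L), GGNVS)))
    expected = expected_count(GGNVS, L, freqs)
    se = np.std(counts, ddof=1) / np.sqrt(n)
    assert abs(np.mean(counts) - expected) < 3 * se


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def test_expression_shape_and_zero_rows():
    sim = gen_expression(SimConfig(seed=2))
    assert sim.matrix.shape == (117, 9)
    retained, dropped = drop_all_zero(sim.matrix)
    assert len(retained) == 113
    assert sorted(dropped) == sim.all_zero


def test_same_block_genes_correlate_more_than_cross_block():
    sim = gen_expression(SimConfig(seed=8))
    by_tissue = {}
    for gid, home in sim.block_membership.items():
        if home:
            by_tissue.setdefault(home, []).append(gid)
    logged = np.log10(sim.matrix + 1)
    within, across = [], []
    tissues = sorted(by_tissue)
    for t in tissues[:4]:
        genes = by_tissue[t][:4]
        other = by_tissue[tissues[(tissues.index(t) + 1) % len(tissues)]][:4]
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                within.append(np.corrcoef(logged.loc[genes[i]], logged.loc[genes[j]])[0, 1])
            for g2 in other:
                across.append(np.corrcoef(logged.loc[genes[i]], logged.loc[g2])[0, 1])
    assert np.mean(within) > np.mean(across)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def test_noise_free_efficiency_inverts_exactly():
    from matekit.qpcr import efficiency_table

    sim = gen_qpcr(SimConfig(seed=3, qpcr=QpcrSpec(noise_sd=0.0, true_efficiency=1.0)))
    eff = efficiency_table(sim.dilutions)
    assert np.allclose(eff["efficiency"], 1.0, atol=1e-9)


def test_strong_genotype_contrast_is_detected():
    from matekit.qpcr import analyze_al_response

    spec = QpcrSpec(
        noise_sd=0.2,
        true_folds={
            "tgt": {
                "T": {"6h": 300.0, "12h": 300.0, "24h": 300.0},
                "S": {"6h": 30.0, "12h": 30.0, "24h": 30.0},
            }
        },
    )
    sim = gen_qpcr(SimConfig(seed=9, qpcr=spec))
    results = analyze_al_response(sim.ct, ["tgt"], "EF1a")
    marks = results.drop_duplicates(["gene", "timepoint"])["mark"]
    assert (marks == "**").sum() >= 2


def test_substreams_are_independent_and_stable():
    a = substream(5, "genome").integers(1000, size=4)
    b = substream(5, "genome").integers(1000, size=4)
    c = substream(5, "promoters").integers(1000, size=4)
    assert (a == b).all()
    assert not (a == c).all()
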