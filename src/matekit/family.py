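"""Family-member selection and physical-position nomenclature.

A gene family is identified from precomputed evidence tables: homology hits
against a query set of known family proteins (blast-tabular), then a hard
requirement for the family's diagnostic domain (e.g. the MATE domain,
Pfam PF01554). Retained members are named ``<prefix>1 ... <prefix>N`` in
order of physical position along the chromosomes, the convention used for
soybean gene families (e.g. GmMATE1-GmMATE117).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import DomainHit, GeneModel, HomologyHit, natural_key


@dataclass(frozen=True)
class FamilyMember:
    protein_id: str
    gene: GeneModel
    assigned_name: str
    rank: int


def filter_candidates(hits: Iterable[HomologyHit], evalue_max: float) -> set[str]:
    """Subject ids with at least one hit at ``evalue <= evalue_max``.

    The inclusive cutoff matches the usual reporting convention
    ("E-value <= 1e-7" keeps a hit at exactly the threshold).
    """
    if evalue_max <= 0:
        raise ValueError(f"evalue_max must be > 0, got {evalue_max}")
    return {h.subject_id for h in hits if h.evalue <= evalue_max}


def require_domain(
    candidates: set[str],
    domains: Iterable[DomainHit],
    required_domain: str,
) -> set[str]:
    """Keep only candidates with at least one hit of ``required_domain``."""
    if not required_domain:
        raise ValueError("required_domain must be non-empty")
    with_domain = {d.protein_id for d in domains if d.domain_id == required_domain}
    return candidates & with_domain


def assign_names(
    members: Sequence[tuple[str, GeneModel]],
    prefix: str,
) -> list[FamilyMember]:
    """Name members ``prefix+1 .. prefix+N`` by physical position.

    Order is (chromosome in natural order, start, gene_id); the gene_id
    tie-break makes the numbering deterministic when two loci share a start.
    Unanchored scaffolds sort after real chromosomes only insofar as their
    names do under natural order; they are named like any other sequence.
    """
    keys = [
        (natural_key(gene.chromosome), gene.start, gene.gene_id)
        for _, gene in members
    ]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(
            f"cannot order members: identical (chromosome, start, gene_id) for {dupes}"
        )
    order = sorted(range(len(members)), key=lambda i: keys[i])
    named = []
    for rank, i in enumerate(order, start=1):
        protein_id, gene = members[i]
        named.append(FamilyMember(protein_id, gene, f"{prefix}{rank}", rank))
    return named


def identify_family(
    hits: Iterable[HomologyHit],
    domains: Iterable[DomainHit],
    genes: Sequence[GeneModel],
    *,
    evalue_max: float = 1e-7,
    required_domain: str = "PF01554",
    prefix: str = "GmMATE",
    protein_to_gene: dict[str, str] | None = None,
) -> list[FamilyMember]:
    """Full identification stage: homology filter, domain filter, naming.

    ``protein_to_gene`` maps protein ids to gene ids when they differ;
    by default protein and gene ids are taken to be identical (one
    representative protein per locus — duplicate mappings are flagged).
    """
    candidates = require_domain(filter_candidates(hits, evalue_max), domains, required_domain)
    gene_by_id = {g.gene_id: g for g in genes}
    members: list[tuple[str, GeneModel]] = []
    seen_genes: set[str] = set()
    for pid in sorted(candidates):
        gene_id = protein_to_gene.get(pid, pid) if protein_to_gene else pid
        if gene_id not in gene_by_id:
            raise KeyError(f"family protein {pid!r} has no locus {gene_id!r} in the gene table")
        if gene_id in seen_genes:
            raise ValueError(
                f"two family proteins map to locus {gene_id!r}; supply one "
                "representative protein per gene"
            )
        seen_genes.add(gene_id)
        members.append((pid, gene_by_id[gene_id]))
    return assign_names(members, prefix)


def write_membership(members: Sequence[FamilyMember], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("protein_id\tassigned_name\tchromosome\tstart\tend\tstrand\n")
        for m in members:
            g = m.gene
            handle.write(
                f"{m.protein_id}\t{m.assigned_name}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\n"
            )
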