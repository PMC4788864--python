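"""Packaged reference tables and the synthetic promoter set built from them."""

from __future__ import annotations

from importlib import resources

from .motifs import GGNVS, MotifPattern
from .simulate import plant_motifs, substream

PROMOTER_LENGTH = 1500


def _data_text(name: str) -> str:
    return (resources.files("matekit") / "data" / name).read_text()


def reference_ggnvs_positions() -> dict[str, list[int]]:
    """Published per-gene signed GGNVS positions for the eight C4-3 promoters."""
    table: dict[str, list[int]] = {}
    for line in _data_text("ggnvs_reference_positions.tsv").splitlines():
        if not line or line.startswith("#") or line.startswith("gene_id"):
            continue
        gene, count, positions = line.split("\t")
        parsed = [int(p) for p in positions.split(",") if p]
        if len(parsed) != int(count):
            raise ValueError(f"reference table corrupt for {gene}")
        table[gene] = parsed
    return table


def default_cis_element_catalog() -> list[MotifPattern]:
    """Editable default catalog of stress/hormone-responsive elements."""
    patterns = []
    for line in _data_text("cis_element_catalog.tsv").splitlines():
        if not line or line.startswith("#") or line.startswith("name"):
            continue
        name, consensus = line.split("\t")[:2]
        patterns.append(MotifPattern(name, consensus))
    return patterns


def default_subgroup_anchors() -> dict[str, str]:
    """Default reference-anchor map (characterized MATE proteins -> subgroup)."""
    anchors: dict[str, str] = {}
    for line in _data_text("subgroup_anchors.tsv").splitlines():
        if not line or line.startswith("#") or line.startswith("leaf"):
            continue
        leaf, subgroup = line.split("\t")[:2]
        anchors[leaf] = subgroup
    return anchors


def synthetic_reference_promoters(seed: int = 0, gc: float = 0.35) -> list[tuple[str, str]]:
    """SYNTHETIC stand-in for the eight C4-3 promoter sequences.

    The real promoter sequences are not redistributable here, so this
    builds 1500 bp promoters with GGNVS instances planted at exactly the
    published positions and a background repaired to contain no other
    occurrence: scanning them reproduces the published counts and position
    lists, which exercises the full position convention end to end.
    """
    rng = substream(seed, "reference-promoters")
    out = []
    for gene, positions in reference_ggnvs_positions().items():
        seq = plant_motifs(
            rng,
            PROMOTER_LENGTH,
            [(GGNVS, p) for p in positions],
            gc,
            collision_free=True,
        )
        out.append((gene, seq))
    return out
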