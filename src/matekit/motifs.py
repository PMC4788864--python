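"""Promoter extraction and degenerate cis-element scanning.

Promoter windows are the ``length`` bases immediately 5' of the translation
start codon on the gene's sense strand, indexed -length ... -1 with -1 the
base adjacent to the ATG. Consensi use IUPAC one-letter nucleotide codes
(e.g. the ART1-binding element GGNVS: N = any base, V = A/C/G, S = C/G);
scanning is case-insensitive, reports every overlapping occurrence on the
given strand, and positions refer to the 5'-most base of the match.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .io import GeneModel

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate consensus over the IUPAC nucleotide alphabet."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name!r}: empty consensus")
        bad = sorted(set(self.consensus.upper()) - set(IUPAC_CODES))
        if bad:
            raise ValueError(f"motif {self.name!r}: invalid IUPAC codes {bad}")

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def position_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(IUPAC_CODES[c] for c in self.consensus.upper())


GGNVS = MotifPattern("GGNVS", "GGNVS")


@dataclass(frozen=True)
class MotifMatch:
    gene_id: str
    motif: str
    position: int  # signed, 5'-most base; -1 is adjacent to the start codon


@dataclass(frozen=True)
class PromoterSeq:
    gene_id: str
    sequence: str
    window_length: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.window_length:
            raise ValueError(
                f"promoter {self.gene_id!r}: sequence length {len(self.sequence)} "
                f"!= window_length {self.window_length}"
            )


def promoters_from_fasta(records: Iterable[tuple[str, str]]) -> list[PromoterSeq]:
    return [PromoterSeq(gid, seq, len(seq)) for gid, seq in records]


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_promoter(
    chromosome_seq: str,
    gene: GeneModel,
    length: int = 1500,
) -> PromoterSeq:
    """Upstream window of ``length`` bp on the gene's sense strand.

    For ``+`` genes this is the sequence ending immediately before ``start``;
    for ``-`` genes, the reverse complement of the bases immediately after
    ``end``. Windows truncated by a chromosome edge are returned shorter
    with ``truncated=True``.
    """
    chrom = chromosome_seq.upper()
    if gene.end > len(chrom):
        raise ValueError(
            f"gene {gene.gene_id!r} coordinates exceed chromosome length {len(chrom)}"
        )
    if gene.strand == "+":
        lo = max(0, gene.start - 1 - length)
        window = chrom[lo:gene.start - 1]
    else:
        window = reverse_complement(chrom[gene.end:gene.end + length])
    return PromoterSeq(gene.gene_id, window, len(window), truncated=len(window) < length)


# ---------------------------------------------------------------------------
# matching and scanning
# ---------------------------------------------------------------------------


def iupac_matcher(consensus: str) -> Callable[[str], bool]:
    """Compile a consensus into a predicate over equal-length strings."""
    sets = MotifPattern("<anonymous>", consensus).position_sets

    def matches(candidate: str) -> bool:
        if len(candidate) != len(sets):
            return False
        return all(base in allowed for base, allowed in zip(candidate.upper(), sets))

    return matches


def scan(
    promoter: PromoterSeq,
    pattern: MotifPattern,
    *,
    both_strands: bool = False,
) -> list[MotifMatch]:
    """All (overlapping) occurrences of ``pattern``, most-negative first.

    A match at signed position p covers p .. p+len-1 with p the 5'-most
    base; p = -window_length + offset for a 0-based offset into the window.
    With ``both_strands`` the reverse complement of the window is also
    scanned and matches are mapped back to sense-strand 5'-most positions.
    """
    sets = pattern.position_sets
    k = len(sets)
    L = promoter.window_length
    seq = promoter.sequence.upper()
    matches = [
        MotifMatch(promoter.gene_id, pattern.name, offset - L)
        for offset in range(L - k + 1)
        if all(seq[offset + j] in sets[j] for j in range(k))
    ]
    if both_strands:
        rc = reverse_complement(seq)
        for offset in range(L - k + 1):
            if all(rc[offset + j] in sets[j] for j in range(k)):
                # 5'-most sense-strand base of the reverse-strand hit
                matches.append(
                    MotifMatch(promoter.gene_id, pattern.name, (L - k - offset) - L)
                )
        matches.sort(key=lambda m: m.position)
    return matches


def scan_catalog(
    promoters: Sequence[PromoterSeq],
    catalog: Sequence[MotifPattern],
    *,
    both_strands: bool = False,
) -> pd.DataFrame:
    """Long-format (gene, element, position) table over a motif catalog."""
    names = [p.name for p in catalog]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate element names in catalog: {dupes}")
    rows = [
        (m.gene_id, m.motif, m.position)
        for promoter in promoters
        for pattern in catalog
        for m in scan(promoter, pattern, both_strands=both_strands)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "element", "position"])


def element_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-element occurrence counts from a long-format scan table."""
    if table.empty:
        return pd.DataFrame(columns=["gene_id", "element", "count"])
    counts = (
        table.groupby(["gene_id", "element"], sort=True).size().reset_index(name="count")
    )
    return counts


def expected_count(
    pattern: MotifPattern,
    window_length: int,
    base_frequencies: dict[str, float],
) -> float:
    """Expected match count per window under an i.i.d. background model.

    (L - k + 1) times the product over consensus positions of the summed
    frequencies of that position's allowed bases.
    """
    total = sum(base_frequencies.get(b, 0.0) for b in "ACGT")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"base frequencies sum to {total}, expected 1")
    k = len(pattern)
    if window_length < k:
        return 0.0
    per_site = 1.0
    for allowed in pattern.position_sets:
        per_site *= sum(base_frequencies[b] for b in allowed)
    return (window_length - k + 1) * per_site


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def write_count_position_table(
    promoters: Sequence[PromoterSeq],
    pattern: MotifPattern,
    path: str | Path,
    *,
    both_strands: bool = False,
) -> pd.DataFrame:
    """Per-gene count + comma-joined signed positions for one element."""
    rows = []
    for promoter in promoters:
        hits = scan(promoter, pattern, both_strands=both_strands)
        rows.append(
            {
                "gene_id": promoter.gene_id,
                "count": len(hits),
                "positions": ",".join(str(m.position) for m in hits),
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "count", "positions"])
    with open(path, "w") as handle:
        handle.write(f"# element: {pattern.name} consensus: {pattern.consensus}\n")
        handle.write("# position convention: 5'-most base of the match; -1 adjacent to ATG\n")
        handle.write(f"# strands scanned: {'both' if both_strands else 'sense only'}\n")
        df.to_csv(handle, sep="\t", index=False)
    return df
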