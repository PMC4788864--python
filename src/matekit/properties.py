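"""Protein physicochemical properties: length, average MW, pI, and a
hydropathy-based transmembrane-segment estimate.

MW is the sum of average (not monoisotopic) residue masses plus one water,
as computed by the ExPASy Compute pI/Mw tool. The isoelectric point is the
root of the Henderson-Hasselbalch net-charge function over the termini and
the ionizable side chains (D, E, C, Y, H, K, R), found by bisection; two pK
sets are provided because pI values are pK-set dependent: the Bjellqvist
set used by ExPASy (default) and the EMBOSS iep set for sensitivity checks.

The transmembrane estimate is a Kyte-Doolittle sliding-window heuristic.
It is NOT an HMM topology predictor and is not expected to reproduce
TMHMM counts; it exists so a membrane-protein table can be completed from
sequence alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

# average residue (monomer-in-chain) masses, Da
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524
# average over the 20 canonical residues, used for X only when explicitly allowed
_X_AVERAGE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / 20.0

# pK sets. "bjellqvist" mirrors the ExPASy Compute pI/Mw constants:
# residue-specific N-terminal pKs and side-chain pKs for the ionizable set.
PK_SETS = {
    "bjellqvist": {
        "nterm_default": 7.5,
        "nterm": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7},
        "cterm_default": 3.55,
        "cterm": {"D": 4.55, "E": 4.75},
        "positive": {"K": 10.0, "R": 12.0, "H": 5.98},
        "negative": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    },
    "emboss": {
        "nterm_default": 8.6,
        "nterm": {},
        "cterm_default": 3.6,
        "cterm": {},
        "positive": {"K": 10.8, "R": 12.5, "H": 6.5},
        "negative": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    },
}

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

_CANONICAL = set(AVERAGE_RESIDUE_MASS)


def _validate(sequence: str, allow_x: bool) -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    allowed = _CANONICAL | ({"X"} if allow_x else set())
    bad = sorted(set(seq) - allowed)
    if bad:
        raise ValueError(f"invalid amino-acid letters {bad} in sequence")
    return seq


def molecular_weight(sequence: str, *, allow_x: bool = False) -> float:
    """Average molecular weight in Da: sum of residue masses + one water.

    ``X`` is a hard error unless ``allow_x=True``, in which case it
    contributes the mean canonical residue mass.
    """
    seq = _validate(sequence, allow_x)
    total = WATER_MASS
    for aa in seq:
        total += _X_AVERAGE_MASS if aa == "X" else AVERAGE_RESIDUE_MASS[aa]
    return total


def net_charge(sequence: str, pH: float, *, pk_set: str = "bjellqvist") -> float:
    """Net charge at ``pH`` from Henderson-Hasselbalch over termini + side chains.

    Strictly decreasing in pH, so the isoelectric point is unique.
    ``X`` residues are tolerated (non-ionizable).
    """
    seq = _validate(sequence, allow_x=True)
    pk = PK_SETS[pk_set]

    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))

    def neg(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - pH))

    charge = pos(pk["nterm"].get(seq[0], pk["nterm_default"]))
    charge += neg(pk["cterm"].get(seq[-1], pk["cterm_default"]))
    for aa in seq:
        if aa in pk["positive"]:
            charge += pos(pk["positive"][aa])
        elif aa in pk["negative"]:
            charge += neg(pk["negative"][aa])
    return charge


def isoelectric_point(
    sequence: str,
    *,
    pk_set: str = "bjellqvist",
    tolerance: float = 1e-4,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Converges for every sequence because the termini are always ionizable
    and the charge function is strictly decreasing.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pk_set=pk_set)
        if abs(q) < tolerance:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def tm_segment_estimate(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    min_gap: int = 5,
) -> int:
    """Heuristic transmembrane-segment count from Kyte-Doolittle hydropathy.

    Counts maximal runs of window positions whose mean hydropathy is at or
    above ``threshold``; runs separated by fewer than ``min_gap`` window
    positions merge into one segment. A sliding-window heuristic, not a
    topology predictor.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    seq = _validate(sequence, allow_x=True)
    if len(seq) < window:
        warnings.warn(
            f"sequence length {len(seq)} < window {window}; returning 0 segments",
            stacklevel=2,
        )
        return 0
    values = np.array([KYTE_DOOLITTLE[aa] for aa in seq])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    above = means >= threshold
    starts = np.flatnonzero(above)
    if starts.size == 0:
        return 0
    segments = 1
    for prev, cur in zip(starts[:-1], starts[1:]):
        if cur - prev >= min_gap + 1:
            segments += 1
    return segments


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    length: int
    molecular_weight: float
    isoelectric_point: float
    tm_segments: int


def profile_proteins(
    records: Sequence[tuple[str, str]],
    *,
    pk_set: str = "bjellqvist",
    allow_x: bool = False,
    tm_window: int = 19,
    tm_threshold: float = 1.6,
) -> list[ProteinProperties]:
    """Length / MW / pI / TM-estimate table for a protein record set."""
    out = []
    for pid, seq in records:
        out.append(
            ProteinProperties(
                protein_id=pid,
                length=len(seq),
                molecular_weight=molecular_weight(seq, allow_x=allow_x),
                isoelectric_point=isoelectric_point(seq, pk_set=pk_set),
                tm_segments=tm_segment_estimate(seq, tm_window, tm_threshold),
            )
        )
    return out


def write_properties(props: Sequence[ProteinProperties], path) -> None:
    with open(path, "w") as handle:
        handle.write("protein_id\tlength\tMW_Da\tpI\tTM_estimate\n")
        for p in props:
            handle.write(
                f"{p.protein_id}\t{p.length}\t{p.molecular_weight:.2f}"
                f"\t{p.isoelectric_point:.2f}\t{p.tm_segments}\n"
            )
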