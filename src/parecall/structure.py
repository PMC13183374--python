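"""Stem-loop detection and RNase III cleavage geometry.

RNase III-family enzymes cleave double-stranded stems capped by a
terminal tetranucleotide loop matching [AU]GNN, cutting 14 nt upstream
and 16 nt downstream of the loop and leaving a 2-nt 3' overhang across
the stem. This module scans sequence windows for such stem-loops (greedy
zipping outward from each candidate loop, allowing Watson-Crick and G.U
pairs and small interior bulges), scores stem stability with a simple
additive pair-count score, verifies the -14/+16/2-nt geometry of called
cuts, and builds tetraloop consensus matrices.

The stem score is an arbitrary-unit stability proxy (lower = more
stable), not comparable to nearest-neighbor free energies in kcal/mol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

DEFAULT_LOOP_PATTERN = "[AU]GNN"
PERMISSIVE_LOOP_PATTERN = "NGNN"
DEFAULT_MIN_STEM_BP = 10
DEFAULT_MAX_BULGES = 4
DEFAULT_WINDOW_LENGTH = 60

_PAIRS: Set[Tuple[str, str]] = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}
_PAIR_WEIGHT = {
    frozenset(("G", "C")): 3,
    frozenset(("A", "U")): 2,
    frozenset(("G", "U")): 1,
}
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class StructureError(ValueError):
    pass


def _as_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not set(seq) <= set("ACGUN"):
        raise StructureError(
            f"non-nucleotide characters in sequence: {sorted(set(seq) - set('ACGUN'))}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    return _as_rna(seq).translate(_COMPLEMENT)[::-1]


def is_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def _loop_regex(pattern: str) -> re.Pattern:
    expanded = pattern.replace("N", "[ACGU]")
    return re.compile(f"(?=({expanded}))")


@dataclass
class Hairpin:
    """A detected stem-loop within a sequence window."""

    window: str
    loop_start: int  # 0-based, within window
    loop_end: int  # half-open; loop_end - loop_start == 4
    pairs: List[Tuple[int, int]] = field(default_factory=list)
    bulged: Set[int] = field(default_factory=set)

    @property
    def loop_seq(self) -> str:
        return self.window[self.loop_start:self.loop_end]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def bulges(self) -> int:
        return len(self.bulged)

    @property
    def stem_score(self) -> float:
        return stem_score(self)

    def dot_bracket(self) -> str:
        chars = ["." for _ in self.window]
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


def scan_hairpins(
    window_seq: str,
    loop_pattern: str = DEFAULT_LOOP_PATTERN,
    min_stem_bp: int = DEFAULT_MIN_STEM_BP,
    max_bulges: int = DEFAULT_MAX_BULGES,
) -> List[Hairpin]:
    """Find tetraloop stem-loops in a window (T is read as U).

    Every 4-mer matching ``loop_pattern`` seeds a stem zipped greedily
    outward from the loop; Watson-Crick and G.U pairs extend it, and up
    to ``max_bulges`` interior unpaired nucleotides (each bulge at most
    2 nt, on either arm) may be skipped. Hairpins with at least
    ``min_stem_bp`` pairs are returned ranked by stem score (most stable
    first).
    """
    seq = _as_rna(window_seq)
    hairpins: List[Hairpin] = []
    for match in _loop_regex(loop_pattern).finditer(seq):
        loop_start = match.start()
        loop_end = loop_start + 4
        i, j = loop_start - 1, loop_end
        pairs: List[Tuple[int, int]] = []
        bulged: Set[int] = set()
        while i >= 0 and j < len(seq):
            if is_pair(seq[i], seq[j]):
                pairs.append((i, j))
                i, j = i - 1, j + 1
                continue
            # try the smallest interior bulge (1-2 nt on one arm) or a
            # 1x1 mismatch that restores pairing
            advanced = False
            for skip_i, skip_j in ((1, 0), (0, 1), (1, 1), (2, 0), (0, 2)):
                if len(bulged) + skip_i + skip_j > max_bulges:
                    continue
                ni, nj = i - skip_i, j + skip_j
                if ni >= 0 and nj < len(seq) and is_pair(seq[ni], seq[nj]):
                    bulged.update(range(ni + 1, i + 1))
                    bulged.update(range(j, nj))
                    pairs.append((ni, nj))
                    i, j = ni - 1, nj + 1
                    advanced = True
                    break
            if not advanced:
                break
        if len(pairs) >= min_stem_bp:
            hairpins.append(
                Hairpin(window=seq, loop_start=loop_start, loop_end=loop_end,
                        pairs=pairs, bulged=bulged)
            )
    hairpins.sort(key=lambda h: (stem_score(h), h.loop_start))
    return hairpins


def stem_score(hairpin: Hairpin) -> float:
    """Additive stem-stability score: -(3 GC + 2 AU + 1 GU) + 2 per
    bulged nucleotide. Arbitrary units; lower is more stable."""
    if not hairpin.pairs:
        raise StructureError("stem_score requires a non-empty pair list")
    total = 0
    for i, j in hairpin.pairs:
        total += _PAIR_WEIGHT[frozenset((hairpin.window[i], hairpin.window[j]))]
    return float(-total + 2 * len(hairpin.bulged))


@dataclass
class GeometryReport:
    """Distances of the cuts from the loop, in paired-stem register."""

    dist5: int | None  # expected 14
    dist3: int | None  # expected 16
    overhang3: int | None  # expected 2

    @property
    def canonical(self) -> bool:
        if self.dist5 is None and self.dist3 is None:
            return False
        if self.dist5 is not None and not 13 <= self.dist5 <= 15:
            return False
        if self.dist3 is not None and not 15 <= self.dist3 <= 17:
            return False
        if self.overhang3 is not None and self.overhang3 != 2:
            return False
        return True


def check_geometry(
    hairpin: Hairpin,
    site5: int | None = None,
    site3: int | None = None,
) -> GeometryReport:
    """Measure cut-to-loop distances, excluding bulged nucleotides.

    ``site5``/``site3`` are window coordinates of the product starts
    (the first nucleotide 3' of each cut). dist5 counts nucleotides from
    the 5' cut to the loop and dist3 from the loop to the 3' cut, in
    both cases skipping interior bulges so that a 15-nt genomic distance
    over a one-bulge arm still registers as the canonical 14. The 3'
    overhang implied by projecting the 3' cut across the stem equals
    dist3 - dist5.
    """
    if site5 is None and site3 is None:
        raise StructureError("at least one of site5/site3 is required")
    for name, site in (("site5", site5), ("site3", site3)):
        if site is not None and not 0 <= site < len(hairpin.window):
            raise StructureError(f"{name}={site} outside window of length {len(hairpin.window)}")
    dist5 = dist3 = overhang3 = None
    if site5 is not None:
        span = range(site5, hairpin.loop_start)
        dist5 = len(span) - sum(1 for p in span if p in hairpin.bulged)
    if site3 is not None:
        span = range(hairpin.loop_end, site3)
        dist3 = len(span) - sum(1 for p in span if p in hairpin.bulged)
    if dist5 is not None and dist3 is not None:
        overhang3 = dist3 - dist5
    return GeometryReport(dist5=dist5, dist3=dist3, overhang3=overhang3)


#: row labels of the aligned tetraloop matrix: 3-nt flanks around the loop
PFM_POSITIONS = ("-3", "-2", "-1", "L1", "L2", "L3", "L4", "+1", "+2", "+3")
NUCLEOTIDES = ("A", "C", "G", "U")


@dataclass
class TetraloopPFM:
    """Position-count matrix of aligned tetraloops with 3-nt flanks."""

    counts: pd.DataFrame  # index PFM_POSITIONS, columns NUCLEOTIDES
    n_loops: int

    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.n_loops


def tetraloop_pfm(aligned: Sequence[str]) -> TetraloopPFM:
    """Count nucleotides per position over 10-nt aligned loop strings
    (3-nt 5' flank + 4-nt loop + 3-nt 3' flank)."""
    counts = pd.DataFrame(
        np.zeros((len(PFM_POSITIONS), len(NUCLEOTIDES)), dtype=np.int64),
        index=list(PFM_POSITIONS),
        columns=list(NUCLEOTIDES),
    )
    for loop in aligned:
        seq = _as_rna(loop)
        if len(seq) != len(PFM_POSITIONS):
            raise StructureError(
                f"aligned loop strings must be {len(PFM_POSITIONS)} nt, got {len(seq)}"
            )
        for pos, nt in zip(PFM_POSITIONS, seq):
            counts.loc[pos, nt] += 1
    return TetraloopPFM(counts=counts, n_loops=len(aligned))


def site_window(
    genome_seq: str,
    position: int,
    strand: str,
    length: int = DEFAULT_WINDOW_LENGTH,
) -> Tuple[str, int]:
    """Extract a window centered on a genomic position, in transcript
    orientation. Returns (sequence, window coordinate of the position).
    """
    half = length // 2
    lo = max(0, position - half)
    hi = min(len(genome_seq), position + half)
    seq = _as_rna(genome_seq[lo:hi])
    offset = position - lo
    if strand == "-":
        seq = reverse_complement(seq)
        offset = len(seq) - 1 - offset
    return seq, offset
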