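"""comPARE scoring and dual-replicate cleavage-site calling.

The comPARE score is a modified log2 fold change between wild-type and
nuclease-deletion 5'-end coverage at a single base:

    score = log2((wt_cpm + c) / (mut_cpm + c)),   c = 0.01 cpm

The pseudocount ``c`` keeps positions with zero deletion-strain reads —
exactly the positions a nuclease-dependent cut produces — finite. A base
is called a cleavage site when, in *every* replicate pair, wild-type
coverage is at least 1 cpm and the score is at least 4 (a 16-fold
coverage drop in the deletion strain). The reported mean score averages
over replicates and is used for ranking only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .tracks import STRANDS, GenomicPosition, NormalizedTrack, TrackError

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.01


class ScoringError(ValueError):
    pass


def compare_score(wt_cpm, mut_cpm, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log2 of the pseudocounted cpm ratio. Accepts scalars or arrays.

    Antisymmetric under argument swap; strictly increasing in ``wt_cpm``
    and strictly decreasing in ``mut_cpm``.
    """
    if pseudocount <= 0:
        raise ScoringError(f"pseudocount must be positive, got {pseudocount}")
    wt = np.asarray(wt_cpm, dtype=np.float64)
    mut = np.asarray(mut_cpm, dtype=np.float64)
    if np.any(wt < 0) or np.any(mut < 0):
        raise ScoringError("cpm values must be non-negative")
    out = np.log2((wt + pseudocount) / (mut + pseudocount))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class ScoreTrack:
    """Per-base comPARE scores for one replicate pair."""

    reference_lengths: Dict[str, int]
    values: Dict[Tuple[str, str], np.ndarray]

    def get(self, reference: str, strand: str) -> np.ndarray:
        return self.values[(reference, strand)]


def _check_compatible(a: NormalizedTrack, b: NormalizedTrack) -> None:
    if a.reference_lengths != b.reference_lengths:
        raise TrackError(
            f"tracks {a.sample_id!r} and {b.sample_id!r} have mismatched references"
        )


def score_tracks(
    wt: NormalizedTrack, mut: NormalizedTrack, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ScoreTrack:
    """Positionwise comPARE score of two cpm tracks (same references)."""
    _check_compatible(wt, mut)
    values = {
        key: compare_score(wt.values[key], mut.values[key], pseudocount)
        for key in wt.values
    }
    return ScoreTrack(dict(wt.reference_lengths), values)


@dataclass(frozen=True)
class CallThresholds:
    """Per-replicate calling thresholds (each replicate must pass)."""

    min_wt_cpm: float = 1.0
    min_score: float = 4.0
    pseudocount: float = DEFAULT_PSEUDOCOUNT


@dataclass
class ScoredPosition:
    """One genomic base with per-replicate cpm values and scores."""

    position: GenomicPosition
    wt_cpm: Tuple[float, ...]
    mut_cpm: Tuple[float, ...]
    score: Tuple[float, ...]
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.score))

    @property
    def mean_wt_cpm(self) -> float:
        return float(np.mean(self.wt_cpm))


@dataclass
class CleavageSite:
    """A called nuclease-dependent site."""

    position: GenomicPosition
    scored: ScoredPosition
    category: str | None = None
    is_secondary: bool = False
    pair_id: str | None = None
    gene: str | None = None

    @property
    def mean_score(self) -> float:
        return self.scored.mean_score

    @property
    def mean_wt_cpm(self) -> float:
        return self.scored.mean_wt_cpm


def _stack(
    replicate_pairs: Sequence[Tuple[NormalizedTrack, NormalizedTrack]],
    key: Tuple[str, str],
) -> Tuple[np.ndarray, np.ndarray]:
    wt = np.stack([pair[0].values[key] for pair in replicate_pairs])
    mut = np.stack([pair[1].values[key] for pair in replicate_pairs])
    return wt, mut


def call_sites(
    replicate_pairs: Sequence[Tuple[NormalizedTrack, NormalizedTrack]],
    thresholds: CallThresholds = CallThresholds(),
) -> List[CleavageSite]:
    """Call cleavage sites requiring every replicate to pass both cutoffs.

    A base is called iff wt_cpm >= min_wt_cpm in every replicate AND
    score >= min_score in every replicate. Output is sorted by
    (reference, position, strand).
    """
    if not replicate_pairs:
        raise ScoringError("at least one replicate pair is required")
    first_wt = replicate_pairs[0][0]
    for wt, mut in replicate_pairs:
        _check_compatible(wt, mut)
        _check_compatible(wt, first_wt)

    sites: List[CleavageSite] = []
    n_census = 0  # positions passing the cpm filter alone (logged)
    for ref in sorted(first_wt.reference_lengths):
        for strand in STRANDS:
            key = (ref, strand)
            wt_stack, mut_stack = _stack(replicate_pairs, key)
            scores = compare_score(wt_stack, mut_stack, thresholds.pseudocount)
            cpm_ok = (wt_stack >= thresholds.min_wt_cpm).all(axis=0)
            n_census += int(cpm_ok.sum())
            called = cpm_ok & (scores >= thresholds.min_score).all(axis=0)
            for pos in np.flatnonzero(called):
                gpos = GenomicPosition(ref, int(pos), strand)
                scored = ScoredPosition(
                    position=gpos,
                    wt_cpm=tuple(float(x) for x in wt_stack[:, pos]),
                    mut_cpm=tuple(float(x) for x in mut_stack[:, pos]),
                    score=tuple(float(x) for x in scores[:, pos]),
                    pseudocount=thresholds.pseudocount,
                )
                sites.append(CleavageSite(position=gpos, scored=scored))
    sites.sort(key=lambda s: (s.position.reference, s.position.position, s.position.strand))
    logger.info(
        "call_sites: %d positions >= %.3g cpm in every replicate, %d called",
        n_census, thresholds.min_wt_cpm, len(sites),
    )
    return sites


def call_gained_sites(
    replicate_pairs: Sequence[Tuple[NormalizedTrack, NormalizedTrack]],
    thresholds: CallThresholds = CallThresholds(),
) -> List[CleavageSite]:
    """Mirror-image calls: positions *gained* in the deletion strain.

    Positions with score <= -min_score and mut_cpm >= min_wt_cpm in every
    replicate. Reported separately from calls — such sites are rare and
    treated as noise, never as cleavage sites.
    """
    mirrored = [(mut, wt) for wt, mut in replicate_pairs]
    gained = call_sites(mirrored, thresholds)
    for site in gained:
        sc = site.scored
        site.scored = ScoredPosition(
            position=sc.position,
            wt_cpm=sc.mut_cpm,
            mut_cpm=sc.wt_cpm,
            score=tuple(-x for x in sc.score),
            pseudocount=sc.pseudocount,
        )
    return gained
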