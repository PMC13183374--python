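"""Strand-specific per-base 5'-monophosphate end tracks.

A PARE library reduces to, for every reference and strand, a vector of
read-start counts: the number of sequenced fragments whose biological 5'
end falls on each base. The first nucleotide of a 3' cleavage (or
decapping) product is where a read begins, so these vectors are the raw
material for all downstream cleavage-site inference.

Internal coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, NamedTuple, Tuple

import numpy as np
import pysam

logger = logging.getLogger(__name__)

STRANDS: Tuple[str, str] = ("+", "-")

#: suffixes used for the canonical two-files-per-sample on-disk layout
PLUS_SUFFIX = ".plus.bedgraph"
MINUS_SUFFIX = ".minus.bedgraph"


class TrackError(ValueError):
    """Raised for malformed inputs or inconsistent track operations."""


class GenomicPosition(NamedTuple):
    """0-based coordinate of the first nucleotide of a 3' product."""

    reference: str
    position: int
    strand: str


def _zero_counts(reference_lengths: Dict[str, int], dtype) -> Dict[Tuple[str, str], np.ndarray]:
    return {
        (ref, strand): np.zeros(length, dtype=dtype)
        for ref, length in reference_lengths.items()
        for strand in STRANDS
    }


@dataclass
class EndCountTrack:
    """Per-base counts of read 5' ends for one sample, both strands."""

    sample_id: str
    reference_lengths: Dict[str, int]
    counts: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = _zero_counts(self.reference_lengths, np.int64)
        for key, vec in self.counts.items():
            ref, strand = key
            if ref not in self.reference_lengths or strand not in STRANDS:
                raise TrackError(f"unknown reference/strand {key!r}")
            arr = np.asarray(vec)
            if arr.shape != (self.reference_lengths[ref],):
                raise TrackError(
                    f"counts for {key!r} have length {arr.shape}, expected "
                    f"{self.reference_lengths[ref]}"
                )
            if np.any(arr < 0):
                raise TrackError(f"negative counts for {key!r}")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(arr == np.floor(arr)):
                    raise TrackError(f"non-integer counts for {key!r}")
                arr = arr.astype(np.int64)
            full[key] = arr.astype(np.int64)
        self.counts = full

    def get(self, reference: str, strand: str) -> np.ndarray:
        return self.counts[(reference, strand)]

    @property
    def total_ends(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))


@dataclass
class NormalizedTrack:
    """Same shape as :class:`EndCountTrack` but values in cpm."""

    sample_id: str
    reference_lengths: Dict[str, int]
    values: Dict[Tuple[str, str], np.ndarray]
    source_total: int

    def get(self, reference: str, strand: str) -> np.ndarray:
        return self.values[(reference, strand)]

    @property
    def total_cpm(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def cpm_normalize(track: EndCountTrack) -> NormalizedTrack:
    """Scale counts to counts-per-million of the whole library.

    The denominator is the sample's total 5'-end count over both strands
    and all references, so per-sample cpm sums to 1e6.
    """
    total = track.total_ends
    if total <= 0:
        raise TrackError(f"cannot cpm-normalize {track.sample_id!r}: total_ends is 0")
    values = {
        key: vec.astype(np.float64) / total * 1e6 for key, vec in track.counts.items()
    }
    return NormalizedTrack(
        sample_id=track.sample_id,
        reference_lengths=dict(track.reference_lengths),
        values=values,
        source_total=total,
    )


def read_sam_five_prime_ends(
    sam_path,
    reference_lengths: Dict[str, int] | None = None,
    sample_id: str | None = None,
    multimapped: str = "primary",
) -> EndCountTrack:
    """Count read 5' ends per base from a text SAM file.

    For a plus-strand alignment the biological 5' end is the leftmost
    aligned reference base (POS - 1, 0-based); for a minus-strand
    alignment it is the rightmost aligned base, computed from the CIGAR
    span. Unmapped and supplementary records are always skipped;
    secondary records are skipped under ``multimapped="primary"`` (the
    default: one 5' end per sequenced fragment) and counted under
    ``multimapped="all"``.
    """
    if multimapped not in ("primary", "all"):
        raise TrackError(f"multimapped must be 'primary' or 'all', got {multimapped!r}")
    sam_path = str(sam_path)
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        header_lengths = dict(zip(sam.references, sam.lengths))
        if reference_lengths is None:
            reference_lengths = header_lengths
        else:
            for ref in header_lengths:
                if ref not in reference_lengths:
                    raise TrackError(f"SAM reference {ref!r} not in reference_lengths")
        track = EndCountTrack(
            sample_id=sample_id or Path(sam_path).stem,
            reference_lengths=dict(reference_lengths),
        )
        accepted = 0
        n_record = 0
        record_iter = iter(sam)
        while True:
            try:
                rec = next(record_iter)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:  # malformed record (e.g. bad CIGAR)
                raise TrackError(f"malformed SAM record #{n_record + 1}: {exc}") from exc
            n_record += 1
            if rec.is_unmapped or rec.is_supplementary:
                continue
            if rec.is_secondary and multimapped == "primary":
                continue
            ref = rec.reference_name
            if ref not in reference_lengths:
                raise TrackError(f"record #{n_record} maps to unknown reference {ref!r}")
            if rec.is_reverse:
                idx, strand = rec.reference_end - 1, "-"
            else:
                idx, strand = rec.reference_start, "+"
            track.counts[(ref, strand)][idx] += 1
            accepted += 1
    logger.info("%s: %d of %d SAM records counted", track.sample_id, accepted, n_record)
    return track


def read_bedgraph(
    path,
    strand: str,
    reference_lengths: Dict[str, int],
    sample_id: str | None = None,
) -> EndCountTrack:
    """Read one strand's per-base counts from a bedGraph file.

    Intervals are 0-based half-open; overlapping intervals or negative
    values are fatal. The returned track has the other strand all-zero.
    """
    if strand not in STRANDS:
        raise TrackError(f"strand must be '+' or '-', got {strand!r}")
    track = EndCountTrack(
        sample_id=sample_id or Path(str(path)).stem,
        reference_lengths=dict(reference_lengths),
    )
    seen = {ref: np.zeros(n, dtype=bool) for ref, n in reference_lengths.items()}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise TrackError(f"{path}:{lineno}: expected 4 bedGraph columns")
            ref, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if ref not in reference_lengths:
                raise TrackError(f"{path}:{lineno}: unknown reference {ref!r}")
            if not 0 <= start < end <= reference_lengths[ref]:
                raise TrackError(f"{path}:{lineno}: interval [{start},{end}) out of bounds")
            if value < 0:
                raise TrackError(f"{path}:{lineno}: negative value {value}")
            if value != int(value):
                raise TrackError(f"{path}:{lineno}: non-integer count {value}")
            if seen[ref][start:end].any():
                raise TrackError(f"{path}:{lineno}: overlapping interval [{start},{end})")
            seen[ref][start:end] = True
            track.counts[(ref, strand)][start:end] = int(value)
    return track


def _iter_runs(vec: np.ndarray) -> Iterable[Tuple[int, int, int]]:
    """Yield (start, end, value) runs of equal non-zero values."""
    nz = np.flatnonzero(vec)
    if nz.size == 0:
        return
    # break runs where position is non-contiguous or value changes
    breaks = np.flatnonzero((np.diff(nz) != 1) | (np.diff(vec[nz]) != 0))
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [nz.size - 1]))
    for s, e in zip(starts, ends):
        yield int(nz[s]), int(nz[e]) + 1, int(vec[nz[s]])


def write_bedgraph(track: EndCountTrack, path, strand: str) -> None:
    """Write one strand of a track as bedGraph, omitting zero runs."""
    if strand not in STRANDS:
        raise TrackError(f"strand must be '+' or '-', got {strand!r}")
    with open(path, "w") as out:
        for ref in track.reference_lengths:
            for start, end, value in _iter_runs(track.counts[(ref, strand)]):
                out.write(f"{ref}\t{start}\t{end}\t{value}\n")


def write_track(track: EndCountTrack, out_prefix) -> Tuple[Path, Path]:
    """Write both strands using the canonical plus/minus suffixes."""
    plus = Path(str(out_prefix) + PLUS_SUFFIX)
    minus = Path(str(out_prefix) + MINUS_SUFFIX)
    write_bedgraph(track, plus, "+")
    write_bedgraph(track, minus, "-")
    return plus, minus


def read_track(out_prefix, reference_lengths: Dict[str, int], sample_id: str | None = None) -> EndCountTrack:
    """Read a sample's plus/minus bedGraph pair back into one track."""
    sample_id = sample_id or Path(str(out_prefix)).name
    plus = read_bedgraph(str(out_prefix) + PLUS_SUFFIX, "+", reference_lengths, sample_id)
    minus = read_bedgraph(str(out_prefix) + MINUS_SUFFIX, "-", reference_lengths, sample_id)
    merged = EndCountTrack(sample_id, dict(reference_lengths))
    for ref in reference_lengths:
        merged.counts[(ref, "+")] = plus.counts[(ref, "+")]
        merged.counts[(ref, "-")] = minus.counts[(ref, "-")]
    return merged
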