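"""Ground-truthed synthetic PARE libraries.

The generator emulates the statistical structure a degradome analysis
assumes: a synthetic genome of random-sequence transcripts; stem-loops
(18-bp stem, [AU]GNN tetraloop) planted into chosen CDSs, cleaved on
both sides of the loop so their 5'-monophosphate product starts sit
exactly 34 nt apart (14 + 4 + 16); decapping 5' ends at transcript
start sites, depleted by poly(A) selection; optional 1-5 nt 5'->3'
nibbling of the cleavage products; and a low uniform background of 5'
ends over transcribed sense-strand bases. Libraries are drawn by
multinomial sampling to a fixed total depth per sample; deletion-strain
samples are generated from the identical model with the cleavage rate
forced to zero.

Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

from .annotation import AnnotationSet, Feature
from .tracks import STRANDS, EndCountTrack

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23  # per mol

_DNA = np.array(list("ACGT"))
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STEM_ARM = 18  # nt per stem arm; cuts at -14/+16 stay inside the duplex
LOOP_LEN = 4
HAIRPIN_LEN = 2 * STEM_ARM + LOOP_LEN


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters; defaults are the standard study conditions."""

    n_transcripts: int = 50
    transcript_length: Tuple[int, int] = (800, 2000)
    n_planted_sites: int = 20  # planted stem-loops, one per transcript
    cleavage_fraction: float = 0.3  # fraction of molecules cut (wild type)
    decap_fraction: float = 0.5  # fraction of molecules decapped
    background_rate: float = 0.2  # mean background 5' ends per base, cpm
    nibble_prob: float = 0.0  # P(cleavage read starts 1-5 nt downstream)
    polyA_retention_decapped: float = 0.2  # decapped survival, poly(A)+ view
    depth: int = 2_000_000  # total 5'-end reads per library
    n_replicates: int = 2
    seed: int = 0
    utr_length: int = 50
    spacer_length: int = 300  # intergenic gap between transcripts

    def validate(self) -> None:
        for name in ("cleavage_fraction", "decap_fraction", "nibble_prob",
                     "polyA_retention_decapped"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.n_transcripts <= 0:
            raise ConfigError("n_transcripts must be positive")
        if self.n_planted_sites > self.n_transcripts:
            raise ConfigError("n_planted_sites cannot exceed n_transcripts")
        lo, hi = self.transcript_length
        # the hairpin needs a CDS slot plus room for nibble offsets
        min_len = 2 * self.utr_length + HAIRPIN_LEN + 20
        if lo > hi or lo < min_len:
            raise ConfigError(
                f"transcript_length range {self.transcript_length} too short; "
                f"need at least {min_len} nt for a planted stem-loop"
            )


@dataclass
class TranscriptModel:
    transcript_id: str
    reference: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcript's first base."""
        return self.start if self.strand == "+" else self.end - 1

    def to_genomic(self, t: int) -> int:
        """Map a transcript coordinate to a genomic coordinate."""
        return self.start + t if self.strand == "+" else self.end - 1 - t


@dataclass
class PlantedSite:
    """Ground truth for one planted stem-loop cleaved on both sides."""

    transcript_id: str
    reference: str
    strand: str
    site5: int  # genomic product start of the upstream (-14) cut
    site3: int  # genomic product start of the downstream (+16) cut
    loop_seq: str
    hairpin_seq: str  # transcript orientation
    cleavage_fraction: float

    @property
    def spacing(self) -> int:
        return abs(self.site3 - self.site5)


@dataclass
class SyntheticTruth:
    reference_lengths: Dict[str, int]
    transcripts: List[TranscriptModel] = field(default_factory=list)
    planted_sites: List[PlantedSite] = field(default_factory=list)

    @property
    def tss_positions(self) -> List[Tuple[str, str, int, str]]:
        return [(t.transcript_id, t.reference, t.tss, t.strand) for t in self.transcripts]

    @property
    def hairpins(self) -> List[str]:
        return [p.hairpin_seq for p in self.planted_sites]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "transcript_id": p.transcript_id,
                    "reference": p.reference,
                    "strand": p.strand,
                    "site5": p.site5,
                    "site3": p.site3,
                    "spacing": p.spacing,
                    "loop_seq": p.loop_seq,
                    "cleavage_fraction": p.cleavage_fraction,
                }
                for p in self.planted_sites
            ]
        )


def _reverse_complement_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def _random_hairpin(rng: np.random.Generator) -> Tuple[str, str]:
    """An 18-bp stem capped by an [AU]GNN loop, in DNA letters.

    Returns (hairpin sequence, loop sequence in RNA letters)."""
    arm = "".join(rng.choice(_DNA, size=STEM_ARM))
    loop_dna = rng.choice(["A", "T"]) + "G" + "".join(rng.choice(_DNA, size=2))
    hairpin = arm + loop_dna + _reverse_complement_dna(arm)
    return hairpin, loop_dna.replace("T", "U")


def simulate_transcriptome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> Tuple[Dict[str, str], AnnotationSet, SyntheticTruth]:
    """Lay random transcripts on a synthetic chromosome and plant
    stem-loops. Returns (genome sequences, annotation, truth)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ref = "chrS"
    lengths = rng.integers(
        config.transcript_length[0], config.transcript_length[1] + 1,
        size=config.n_transcripts,
    )
    strands = rng.choice(np.array(["+", "-"]), size=config.n_transcripts)
    planted_idx = set(
        rng.choice(config.n_transcripts, size=config.n_planted_sites, replace=False).tolist()
    )
    genome_parts: List[str] = []
    annotation = AnnotationSet()
    truth = SyntheticTruth(reference_lengths={})
    cursor = config.spacer_length
    genome_parts.append("".join(rng.choice(_DNA, size=config.spacer_length)))
    for idx in range(config.n_transcripts):
        tx_id = f"TX{idx + 1:03d}"
        length = int(lengths[idx])
        strand = str(strands[idx])
        tx_seq = "".join(rng.choice(_DNA, size=length))
        planted: PlantedSite | None = None
        if idx in planted_idx:
            cds_lo = config.utr_length
            cds_hi = length - config.utr_length
            # keep nibble offsets (up to +5) inside the CDS
            hp_start = int(rng.integers(cds_lo + 10, cds_hi - HAIRPIN_LEN - 10))
            hairpin, loop_seq = _random_hairpin(rng)
            tx_seq = tx_seq[:hp_start] + hairpin + tx_seq[hp_start + HAIRPIN_LEN:]
            loop_start_t = hp_start + STEM_ARM
            t5 = loop_start_t - 14  # product start of the upstream cut
            t3 = loop_start_t + LOOP_LEN + 16  # product start of the downstream cut
            planted = (tx_id, t5, t3, loop_seq, hairpin)
        tx = TranscriptModel(tx_id, ref, cursor, cursor + length, strand)
        genome_parts.append(tx_seq if strand == "+" else _reverse_complement_dna(tx_seq))
        cursor += length
        genome_parts.append("".join(rng.choice(_DNA, size=config.spacer_length)))
        cursor += config.spacer_length
        truth.transcripts.append(tx)
        if planted is not None:
            tx_id, t5, t3, loop_seq, hairpin = planted
            g5, g3 = tx.to_genomic(t5), tx.to_genomic(t3)
            truth.planted_sites.append(
                PlantedSite(
                    transcript_id=tx_id, reference=ref, strand=strand,
                    site5=g5, site3=g3, loop_seq=loop_seq,
                    hairpin_seq=hairpin.replace("T", "U"),
                    cleavage_fraction=config.cleavage_fraction,
                )
            )
        u = config.utr_length
        if strand == "+":
            annotation.add(Feature(ref, tx.start, tx.start + u, strand, "five_prime_UTR", tx_id))
            annotation.add(Feature(ref, tx.start + u, tx.end - u, strand, "CDS", tx_id))
            annotation.add(Feature(ref, tx.end - u, tx.end, strand, "three_prime_UTR", tx_id))
        else:
            annotation.add(Feature(ref, tx.end - u, tx.end, strand, "five_prime_UTR", tx_id))
            annotation.add(Feature(ref, tx.start + u, tx.end - u, strand, "CDS", tx_id))
            annotation.add(Feature(ref, tx.start, tx.start + u, strand, "three_prime_UTR", tx_id))
        annotation.add(Feature(ref, tx.tss, tx.tss + 1, strand, "TSS", tx_id))
    genome = {ref: "".join(genome_parts)}
    truth.reference_lengths = {ref: len(genome[ref])}
    return genome, annotation, truth


def _expected_weights(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    condition: str,
    view: str,
) -> Dict[Tuple[str, str], np.ndarray]:
    """Per-base expected 5'-end weights for one library condition."""
    weights = {
        (ref, strand): np.zeros(n, dtype=np.float64)
        for ref, n in truth.reference_lengths.items()
        for strand in STRANDS
    }
    decap_retention = (
        config.polyA_retention_decapped if view == "polyA+" else 1.0
    )
    cleave_retention = 1.0 if view == "polyA+" else config.polyA_retention_decapped
    for tx in truth.transcripts:
        weights[(tx.reference, tx.strand)][tx.tss] += config.decap_fraction * decap_retention
    if condition == "wildtype":
        for site in truth.planted_sites:
            vec = weights[(site.reference, site.strand)]
            step = 1 if site.strand == "+" else -1  # transcript 3' direction
            w = site.cleavage_fraction * cleave_retention
            for g in (site.site5, site.site3):
                vec[g] += w * (1.0 - config.nibble_prob)
                for k in range(1, 6):
                    vec[g + step * k] += w * config.nibble_prob / 5.0
    signal = float(sum(v.sum() for v in weights.values()))
    # background: uniform over transcribed sense-strand bases, scaled so
    # its per-base share of the library equals background_rate cpm
    n_bg = sum(tx.length for tx in truth.transcripts)
    bg_share = config.background_rate * n_bg / 1e6
    if bg_share >= 1.0:
        raise ConfigError("background_rate too high for the transcriptome size")
    per_base = config.background_rate / 1e6 * signal / (1.0 - bg_share)
    for tx in truth.transcripts:
        weights[(tx.reference, tx.strand)][tx.start:tx.end] += per_base
    return weights


@dataclass
class SimulatedLibraries:
    """Replicated wild-type and deletion 5'-end count tracks."""

    wildtype: List[EndCountTrack]
    deletion: List[EndCountTrack]
    view: str

    @property
    def replicate_pairs(self) -> List[Tuple[EndCountTrack, EndCountTrack]]:
        return list(zip(self.wildtype, self.deletion))


def _draw_library(
    weights: Dict[Tuple[str, str], np.ndarray],
    depth: int,
    sample_id: str,
    reference_lengths: Dict[str, int],
    rng: np.random.Generator,
) -> EndCountTrack:
    keys = sorted(weights)
    flat = np.concatenate([weights[k] for k in keys])
    total = flat.sum()
    if total <= 0:
        raise ConfigError(
            f"library {sample_id!r} has no expected 5'-end signal; raise "
            "background_rate, decap_fraction or cleavage_fraction"
        )
    probs = flat / total
    counts = rng.multinomial(depth, probs)
    track = EndCountTrack(sample_id, dict(reference_lengths))
    offset = 0
    for key in keys:
        n = len(weights[key])
        track.counts[key] = counts[offset:offset + n].astype(np.int64)
        offset += n
    return track


def simulate_pare_tracks(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    view: str = "polyA+",
) -> SimulatedLibraries:
    """Draw replicated wild-type and deletion libraries by multinomial
    sampling of the expected 5'-end weights, ``depth`` reads each."""
    config.validate()
    if view not in ("polyA+", "polyA-"):
        raise ConfigError(f"view must be 'polyA+' or 'polyA-', got {view!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    wt_weights = _expected_weights(truth, config, "wildtype", view)
    mut_weights = _expected_weights(truth, config, "deletion", view)
    wildtype = [
        _draw_library(wt_weights, config.depth, f"wt_rep{i + 1}",
                      truth.reference_lengths, rng)
        for i in range(config.n_replicates)
    ]
    deletion = [
        _draw_library(mut_weights, config.depth, f"mut_rep{i + 1}",
                      truth.reference_lengths, rng)
        for i in range(config.n_replicates)
    ]
    return SimulatedLibraries(wildtype=wildtype, deletion=deletion, view=view)


@dataclass
class SyntheticDataset:
    genome: Dict[str, str]
    annotation: AnnotationSet
    truth: SyntheticTruth
    libraries: SimulatedLibraries


def simulate_dataset(config: SyntheticConfig, view: str = "polyA+") -> SyntheticDataset:
    """Transcriptome + libraries from one seeded generator chain."""
    rng = np.random.default_rng(config.seed)
    genome, annotation, truth = simulate_transcriptome(config, rng)
    libraries = simulate_pare_tracks(truth, config, rng, view=view)
    return SyntheticDataset(genome, annotation, truth, libraries)


def write_fasta(genome: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as out:
        for ref in sorted(genome):
            out.write(f">{ref}\n")
            seq = genome[ref]
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def nucleolar_concentration(molecules: float, volume_fl: float) -> float:
    """Concentration in uM of ``molecules`` copies in ``volume_fl``
    femtoliters (e.g. an enzyme confined to the nucleolus)."""
    if volume_fl <= 0:
        raise ConfigError(f"volume must be positive, got {volume_fl}")
    moles = molecules / AVOGADRO
    liters = volume_fl * 1e-15
    return moles / liters * 1e6
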