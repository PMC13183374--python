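"""End-to-end orchestration: tracks -> scoring -> sites -> structure.

The pipeline consumes a sample manifest of per-strand bedGraph pairs
(or SAM files) for >=1 replicate pair of wild-type vs deletion
libraries, plus a GFF3 annotation and genome FASTA, and writes the
called sites, substrates, stem-loop pairs, hairpin geometry, tetraloop
consensus and degradome fractions as plain-text tables. Re-running on
identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd
import yaml

from . import sites as sitemod
from . import structure as structmod
from .annotation import AnnotationSet, read_gff, write_gff
from .scoring import CallThresholds, CleavageSite, call_sites
from .simulate import SyntheticConfig, simulate_dataset, write_fasta
from .tracks import (
    EndCountTrack,
    NormalizedTrack,
    cpm_normalize,
    read_sam_five_prime_ends,
    read_track,
    write_track,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class StructureParams:
    window_length: int = structmod.DEFAULT_WINDOW_LENGTH
    loop_pattern: str = structmod.DEFAULT_LOOP_PATTERN
    min_stem_bp: int = structmod.DEFAULT_MIN_STEM_BP
    max_bulges: int = structmod.DEFAULT_MAX_BULGES


@dataclass
class PipelineParams:
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    max_nibble_gap: int = sitemod.DEFAULT_MAX_NIBBLE_GAP
    expected_spacing: int = sitemod.DEFAULT_EXPECTED_SPACING
    pair_tolerance: int = sitemod.DEFAULT_PAIR_TOLERANCE
    intergenic_gap: int = sitemod.DEFAULT_INTERGENIC_GAP
    tss_window: int = sitemod.DEFAULT_TSS_WINDOW
    structure: StructureParams = field(default_factory=StructureParams)

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineParams":
        params = cls()
        thr = data.get("thresholds", {})
        params.thresholds = CallThresholds(
            min_wt_cpm=float(thr.get("min_wt_cpm", 1.0)),
            min_score=float(thr.get("min_score", 4.0)),
            pseudocount=float(thr.get("pseudocount", 0.01)),
        )
        params.max_nibble_gap = int(data.get("collapse", {}).get("max_gap", params.max_nibble_gap))
        pairing = data.get("pairing", {})
        params.expected_spacing = int(pairing.get("expected_spacing", params.expected_spacing))
        params.pair_tolerance = int(pairing.get("tolerance", params.pair_tolerance))
        params.intergenic_gap = int(
            data.get("clustering", {}).get("intergenic_gap", params.intergenic_gap)
        )
        params.tss_window = int(data.get("degradome", {}).get("tss_window", params.tss_window))
        st = data.get("structure", {})
        params.structure = StructureParams(
            window_length=int(st.get("window_length", structmod.DEFAULT_WINDOW_LENGTH)),
            loop_pattern=str(st.get("loop_pattern", structmod.DEFAULT_LOOP_PATTERN)),
            min_stem_bp=int(st.get("min_stem_bp", structmod.DEFAULT_MIN_STEM_BP)),
            max_bulges=int(st.get("max_bulges", structmod.DEFAULT_MAX_BULGES)),
        )
        return params


def read_genome_sizes(path) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.split()
            if len(fields) >= 2:
                sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise PipelineError(f"no reference sizes parsed from {path}")
    return sizes


def load_manifest_tracks(
    samples: Sequence[dict], reference_lengths: Dict[str, int]
) -> List[Tuple[NormalizedTrack, NormalizedTrack]]:
    """Load and normalize manifest samples into ordered replicate pairs."""
    by_condition: Dict[str, Dict[int, EndCountTrack]] = {"wildtype": {}, "deletion": {}}
    for entry in samples:
        condition = entry.get("condition")
        if condition not in by_condition:
            raise PipelineError(
                f"sample condition must be 'wildtype' or 'deletion', got {condition!r}"
            )
        replicate = int(entry.get("replicate", 1))
        sample_id = entry.get("sample_id", f"{condition}_rep{replicate}")
        if "sam" in entry:
            track = read_sam_five_prime_ends(entry["sam"], reference_lengths, sample_id)
        elif "prefix" in entry:
            track = read_track(entry["prefix"], reference_lengths, sample_id)
        else:
            raise PipelineError(f"sample {sample_id!r} needs a 'sam' or 'prefix' path")
        if replicate in by_condition[condition]:
            raise PipelineError(f"duplicate {condition} replicate {replicate}")
        by_condition[condition][replicate] = track
    wt, mut = by_condition["wildtype"], by_condition["deletion"]
    if not wt or not mut:
        raise PipelineError("manifest needs both wildtype and deletion samples")
    if sorted(wt) != sorted(mut):
        raise PipelineError(
            f"replicate indices differ between conditions: {sorted(wt)} vs {sorted(mut)}"
        )
    return [(cpm_normalize(wt[i]), cpm_normalize(mut[i])) for i in sorted(wt)]


def _site_rows(sites_list: Sequence[CleavageSite]) -> pd.DataFrame:
    rows = []
    for i, site in enumerate(sites_list):
        row = {
            "site_id": f"site_{i + 1:05d}",
            "reference": site.position.reference,
            "position": site.position.position,
            "strand": site.position.strand,
            "mean_wt_cpm": site.mean_wt_cpm,
            "mean_score": site.mean_score,
            "category": site.category or "",
            "gene": site.gene or "",
            "is_secondary": site.is_secondary,
            "pair_id": site.pair_id or "",
        }
        for r, (w, m, s) in enumerate(
            zip(site.scored.wt_cpm, site.scored.mut_cpm, site.scored.score), start=1
        ):
            row[f"wt_cpm_rep{r}"] = w
            row[f"mut_cpm_rep{r}"] = m
            row[f"score_rep{r}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def read_sites_tsv(path) -> List[CleavageSite]:
    """Reconstruct called sites from a sites.tsv written by the pipeline."""
    from .scoring import ScoredPosition
    from .tracks import GenomicPosition

    frame = pd.read_csv(path, sep="\t")
    rep_cols = sorted(
        int(c.split("rep")[1]) for c in frame.columns if c.startswith("wt_cpm_rep")
    )
    out: List[CleavageSite] = []
    for _, row in frame.iterrows():
        pos = GenomicPosition(str(row["reference"]), int(row["position"]), str(row["strand"]))
        scored = ScoredPosition(
            position=pos,
            wt_cpm=tuple(float(row[f"wt_cpm_rep{r}"]) for r in rep_cols),
            mut_cpm=tuple(float(row[f"mut_cpm_rep{r}"]) for r in rep_cols),
            score=tuple(float(row[f"score_rep{r}"]) for r in rep_cols),
        )
        site = CleavageSite(position=pos, scored=scored)
        if isinstance(row.get("category"), str) and row["category"]:
            site.category = row["category"]
        if isinstance(row.get("gene"), str) and row["gene"]:
            site.gene = row["gene"]
        site.is_secondary = bool(row.get("is_secondary", False))
        pair_id = row.get("pair_id")
        if isinstance(pair_id, str) and pair_id:
            site.pair_id = pair_id
        out.append(site)
    return out


def _write_sites_bed(frame: pd.DataFrame, path) -> None:
    with open(path, "w") as out:
        for _, row in frame.iterrows():
            score = int(row["mean_score"] * 100)  # mean comPARE x100, truncated
            out.write(
                f"{row['reference']}\t{row['position']}\t{row['position'] + 1}"
                f"\t{row['site_id']}\t{score}\t{row['strand']}\n"
            )


def _write_pairs_bed(pairs: Sequence[sitemod.SitePair], path) -> None:
    with open(path, "w") as out:
        for pair in pairs:
            a = pair.site5.position
            b = pair.site3.position
            lo, hi = sorted((a.position, b.position))
            score = int((pair.site5.mean_score + pair.site3.mean_score) / 2 * 100)
            out.write(f"{a.reference}\t{lo}\t{hi + 1}\t{pair.pair_id}\t{score}\t{a.strand}\n")


def analyze_pair_structure(
    genome: Dict[str, str],
    pair: sitemod.SitePair,
    params: StructureParams,
) -> dict:
    """Scan the window midway between a pair's cuts for the stem-loop
    and report its cleavage geometry (transcript orientation)."""
    a, b = pair.site5.position, pair.site3.position
    seq = genome[a.reference]
    mid = (a.position + b.position) // 2
    half = params.window_length // 2
    lo = max(0, mid - half)
    hi = min(len(seq), mid + half)
    window = seq[lo:hi]

    def to_window(g: int) -> int:
        return g - lo if a.strand == "+" else (hi - 1) - g

    if a.strand == "-":
        window = structmod.reverse_complement(window)
    w5, w3 = to_window(a.position), to_window(b.position)
    hairpins = structmod.scan_hairpins(
        window, params.loop_pattern, params.min_stem_bp, params.max_bulges
    )
    # the relevant stem-loop has its loop between the two cuts
    hairpins = [h for h in hairpins if w5 < h.loop_start and h.loop_end <= w3]
    row = {
        "pair_id": pair.pair_id,
        "reference": a.reference,
        "strand": a.strand,
        "site5": a.position,
        "site3": b.position,
        "spacing": pair.spacing,
        "hairpin_found": bool(hairpins),
    }
    if hairpins:
        hp = hairpins[0]
        report = structmod.check_geometry(hp, site5=w5, site3=w3)
        row.update(
            loop_seq=hp.loop_seq,
            n_pairs=hp.n_pairs,
            bulges=hp.bulges,
            stem_score=hp.stem_score,
            dist5=report.dist5,
            dist3=report.dist3,
            overhang3=report.overhang3,
            canonical=report.canonical,
            dot_bracket=hp.dot_bracket(),
            aligned_loop=hp.window[hp.loop_start - 3:hp.loop_end + 3],
        )
    return row


def run_pipeline(
    replicate_pairs: Sequence[Tuple[NormalizedTrack, NormalizedTrack]],
    annotation: AnnotationSet,
    genome: Dict[str, str] | None,
    out_dir,
    params: PipelineParams | None = None,
) -> dict:
    """Run scoring -> site interpretation -> structure, writing outputs.

    Returns a summary dict (also written to ``summary.yaml``).
    """
    params = params or PipelineParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage scoring: calling sites on %d replicate pairs", len(replicate_pairs))
    called = call_sites(replicate_pairs, params.thresholds)

    logger.info("stage sites: collapse, pair, classify, cluster")
    called = sitemod.collapse_secondary(called, params.max_nibble_gap)
    pairs, singles = sitemod.pair_sites(
        called, params.expected_spacing, params.pair_tolerance
    )
    for site in called:
        sitemod.classify_site(site, annotation)
    substrates = sitemod.cluster_substrates(called, annotation, params.intergenic_gap)
    fractions = sitemod.degradome_fraction(
        replicate_pairs[0][0], annotation, called, params.tss_window
    )

    frame = _site_rows(called)
    frame.to_csv(out_dir / "sites.tsv", sep="\t", index=False)
    _write_sites_bed(frame, out_dir / "sites.bed")
    _write_pairs_bed(pairs, out_dir / "pairs.bed")
    pd.DataFrame(
        [
            {
                "substrate_id": sub.substrate_id,
                "category": sub.category,
                "n_sites": len(sub.sites),
                "known": sub.known_flag,
                "max_mean_score": max(s.mean_score for s in sub.sites),
            }
            for sub in substrates
        ]
    ).to_csv(out_dir / "substrates.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "transcript_id": f.transcript_id,
                "endo_cpm": f.endo_reads,
                "decap_cpm": f.decap_reads,
                "fraction_endo": f.fraction,
            }
            for f in fractions
        ]
    ).to_csv(out_dir / "degradome.tsv", sep="\t", index=False)

    hairpin_rows: List[dict] = []
    n_canonical = 0
    if genome is not None:
        logger.info("stage structure: %d pairs", len(pairs))
        for pair in pairs:
            row = analyze_pair_structure(genome, pair, params.structure)
            hairpin_rows.append(row)
            n_canonical += int(bool(row.get("canonical")))
        pd.DataFrame(hairpin_rows).to_csv(out_dir / "hairpins.tsv", sep="\t", index=False)
        aligned = [
            r["aligned_loop"] for r in hairpin_rows
            if r.get("hairpin_found") and len(r.get("aligned_loop", "")) == 10
        ]
        if aligned:
            pfm = structmod.tetraloop_pfm(aligned)
            pfm.counts.to_csv(out_dir / "tetraloop_pfm.tsv", sep="\t")

    n_secondary = sum(s.is_secondary for s in called)
    categories = frame["category"].value_counts().to_dict() if len(frame) else {}
    summary = {
        "n_replicate_pairs": len(replicate_pairs),
        "n_sites": len(called),
        "n_secondary": int(n_secondary),
        "n_pairs": len(pairs),
        "n_single_primary": len(singles),
        "n_substrates": len(substrates),
        "n_hairpins_found": sum(1 for r in hairpin_rows if r.get("hairpin_found")),
        "n_canonical_geometry": n_canonical,
        "n_degradome_transcripts": len(fractions),
        "categories": {k: int(v) for k, v in sorted(categories.items())},
    }
    with open(out_dir / "summary.yaml", "w") as out:
        yaml.safe_dump(summary, out, sort_keys=True)
    for key, value in summary.items():
        logger.info("summary %s = %s", key, value)
    return summary


def run_from_config(config_path, out_dir) -> dict:
    """Run the full pipeline from a YAML config file."""
    with open(config_path) as handle:
        config = yaml.safe_load(handle)
    params = PipelineParams.from_mapping(config)
    reference_lengths = read_genome_sizes(config["genome_sizes"])
    replicate_pairs = load_manifest_tracks(config["samples"], reference_lengths)
    annotation = read_gff(config["gff"])
    genome = None
    if config.get("fasta"):
        from pyfaidx import Fasta

        with Fasta(config["fasta"]) as fasta:
            genome = {name: str(fasta[name][:]) for name in fasta.keys()}
    return run_pipeline(replicate_pairs, annotation, genome, out_dir, params)


def write_synthetic_inputs(config: SyntheticConfig, out_dir, view: str = "polyA+") -> dict:
    """Generate a synthetic dataset and write it as pipeline inputs
    (FASTA, GFF3, genome sizes, per-sample bedGraph pairs, truth TSV).
    Returns a manifest-style dict describing the written files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = simulate_dataset(config, view=view)
    write_fasta(dataset.genome, out_dir / "genome.fa")
    write_gff(dataset.annotation, out_dir / "annotation.gff3")
    with open(out_dir / "genome.sizes", "w") as out:
        for ref, n in sorted(dataset.truth.reference_lengths.items()):
            out.write(f"{ref}\t{n}\n")
    dataset.truth.to_frame().to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    samples = []
    for condition, tracks in (
        ("wildtype", dataset.libraries.wildtype),
        ("deletion", dataset.libraries.deletion),
    ):
        for i, track in enumerate(tracks, start=1):
            prefix = out_dir / track.sample_id
            write_track(track, prefix)
            samples.append(
                {
                    "sample_id": track.sample_id,
                    "condition": condition,
                    "replicate": i,
                    "prefix": str(prefix),
                }
            )
    manifest = {
        "samples": samples,
        "genome_sizes": str(out_dir / "genome.sizes"),
        "gff": str(out_dir / "annotation.gff3"),
        "fasta": str(out_dir / "genome.fa"),
    }
    with open(out_dir / "config.yaml", "w") as out:
        yaml.safe_dump(manifest, out, sort_keys=True)
    return manifest


def run_synthetic(
    config: SyntheticConfig,
    out_dir,
    params: PipelineParams | None = None,
    view: str = "polyA+",
) -> dict:
    """Simulate a dataset in memory and run the full pipeline on it."""
    dataset = simulate_dataset(config, view=view)
    replicate_pairs = [
        (cpm_normalize(wt), cpm_normalize(mut))
        for wt, mut in dataset.libraries.replicate_pairs
    ]
    return run_pipeline(
        replicate_pairs, dataset.annotation, dataset.genome, out_dir, params
    )
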