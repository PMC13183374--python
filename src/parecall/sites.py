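"""Site-level interpretation of called cleavage positions.

Raw per-base calls are redundant: 5'->3' nibbling of a primary cleavage
product scatters satellite 5' ends 1-5 nt downstream of the true cut,
and one stem-loop cleaved on both sides of its tetraloop yields two
calls ~34 nt apart (14 nt of 5' arm + 4 nt loop + 16 nt of 3' arm).
This module collapses nibbled satellites, pairs cuts across a loop,
classifies sites against the annotation, clusters them into substrates,
and computes the endonuclease-vs-decapping degradome fraction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .annotation import GENIC_KINDS, AnnotationSet
from .scoring import CleavageSite
from .tracks import NormalizedTrack

logger = logging.getLogger(__name__)

DEFAULT_EXPECTED_SPACING = 34  # nt: 14 + 4-nt loop + 16
DEFAULT_PAIR_TOLERANCE = 2  # nt: absorbs bulged stems
DEFAULT_MAX_NIBBLE_GAP = 5  # nt: nibbled satellites sit 1-5 nt downstream
DEFAULT_INTERGENIC_GAP = 200  # nt: single-linkage radius off-annotation
DEFAULT_MATCH_WINDOW = 2  # nt: jitter window when comparing site sets
DEFAULT_TSS_WINDOW = 5  # nt: decapping-peak window around the TSS

#: classification precedence for same-strand overlaps (first wins)
CATEGORY_PRECEDENCE = (
    "ncRNA",
    "mRNA_CDS",
    "intron",
    "five_prime_UTR",
    "three_prime_UTR",
    "antisense",
    "intergenic",
)

_KIND_TO_CATEGORY = {
    "ncRNA": "ncRNA",
    "CDS": "mRNA_CDS",
    "intron": "intron",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
}


def _site_sort_key(site: CleavageSite):
    return (site.position.reference, site.position.strand, site.position.position)


def _is_upstream(a: CleavageSite, b: CleavageSite) -> bool:
    """True if ``a`` is 5' of ``b`` in transcript orientation."""
    if a.position.strand == "+":
        return a.position.position < b.position.position
    return a.position.position > b.position.position


def collapse_secondary(
    sites: Sequence[CleavageSite], max_gap: int = DEFAULT_MAX_NIBBLE_GAP
) -> List[CleavageSite]:
    """Flag nibbled satellite calls, keeping the primary per run.

    Within any run of same-reference, same-strand sites whose
    consecutive gaps are <= ``max_gap``, the site with the highest mean
    wild-type cpm is primary (ties: 5'-most, strand-aware); the rest are
    flagged secondary but not removed. Returns the sites sorted by
    reference, strand, position.
    """
    ordered = sorted(sites, key=_site_sort_key)
    runs: List[List[CleavageSite]] = []
    for site in ordered:
        if (
            runs
            and runs[-1][-1].position.reference == site.position.reference
            and runs[-1][-1].position.strand == site.position.strand
            and site.position.position - runs[-1][-1].position.position <= max_gap
        ):
            runs[-1].append(site)
        else:
            runs.append([site])
    for run in runs:
        best = run[0]
        for site in run[1:]:
            if site.mean_wt_cpm > best.mean_wt_cpm or (
                site.mean_wt_cpm == best.mean_wt_cpm and _is_upstream(site, best)
            ):
                best = site
        for site in run:
            site.is_secondary = site is not best
    return ordered


@dataclass
class SitePair:
    """Two cuts flanking one tetraloop: upstream (5') and downstream (3')."""

    site5: CleavageSite
    site3: CleavageSite
    spacing: int
    expected_spacing: int = DEFAULT_EXPECTED_SPACING

    @property
    def pair_id(self) -> str:
        p = self.site5.position
        return f"{p.reference}:{min(p.position, self.site3.position.position)}:{p.strand}"


def pair_sites(
    sites: Sequence[CleavageSite],
    expected_spacing: int = DEFAULT_EXPECTED_SPACING,
    tolerance: int = DEFAULT_PAIR_TOLERANCE,
) -> Tuple[List[SitePair], List[CleavageSite]]:
    """Pair primary sites cut on both sides of one stem-loop.

    Same-reference, same-strand primary sites whose product-start
    coordinates differ by ``expected_spacing +/- tolerance`` are paired
    greedily by ascending deviation from the expected spacing; each site
    joins at most one pair. Returns (pairs, unpaired_sites); secondary
    sites are ignored entirely.
    """
    primaries = [s for s in sites if not s.is_secondary]
    candidates = []
    by_group: Dict[Tuple[str, str], List[CleavageSite]] = {}
    for site in sorted(primaries, key=_site_sort_key):
        by_group.setdefault(
            (site.position.reference, site.position.strand), []
        ).append(site)
    for group in by_group.values():
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                spacing = b.position.position - a.position.position
                if spacing > expected_spacing + tolerance:
                    break
                if abs(spacing - expected_spacing) <= tolerance:
                    candidates.append((abs(spacing - expected_spacing), a, b, spacing))
    candidates.sort(key=lambda c: (c[0], _site_sort_key(c[1])))
    used: set = set()
    pairs: List[SitePair] = []
    for _dev, a, b, spacing in candidates:
        if id(a) in used or id(b) in used:
            continue
        used.add(id(a))
        used.add(id(b))
        site5, site3 = (a, b) if _is_upstream(a, b) else (b, a)
        pair = SitePair(site5=site5, site3=site3, spacing=spacing,
                        expected_spacing=expected_spacing)
        site5.pair_id = site3.pair_id = pair.pair_id
        pairs.append(pair)
    singles = [s for s in primaries if id(s) not in used]
    return pairs, singles


def classify_site(site: CleavageSite, annotation: AnnotationSet) -> str:
    """Assign a feature category to one site (precedence on overlaps).

    Same-strand overlaps win by ncRNA > CDS > intron > 5'UTR > 3'UTR;
    a site overlapping only opposite-strand features is antisense; no
    overlap at all is intergenic. Sets ``site.category`` (and
    ``site.gene`` for genic sites) and returns the category.
    """
    feats = annotation.overlapping(site.position.reference, site.position.position)
    same = [f for f in feats if f.strand == site.position.strand and f.kind in GENIC_KINDS]
    if same:
        best = min(same, key=lambda f: GENIC_KINDS.index(f.kind))
        site.category = _KIND_TO_CATEGORY[best.kind]
        site.gene = best.gene
    elif any(f.kind in GENIC_KINDS for f in feats):
        site.category = "antisense"
    else:
        site.category = "intergenic"
    return site.category


@dataclass
class Substrate:
    """A cleaved RNA: one gene or one positional cluster of sites."""

    substrate_id: str
    sites: List[CleavageSite] = field(default_factory=list)
    category: str = "intergenic"
    known_flag: bool = False


def _modal_category(members: Sequence[CleavageSite]) -> str:
    counts = Counter(s.category for s in members)
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    return min(tied, key=CATEGORY_PRECEDENCE.index)


def cluster_substrates(
    sites: Sequence[CleavageSite],
    annotation: AnnotationSet | None = None,
    intergenic_gap: int = DEFAULT_INTERGENIC_GAP,
) -> List[Substrate]:
    """Group called sites into cleaved substrates.

    Sites sharing a parent gene (any genic category) form one substrate;
    intergenic/antisense sites cluster by single-linkage within
    ``intergenic_gap`` nt on the same strand. The substrate category is
    the modal category of its members (precedence breaks ties). Sites
    not yet classified are classified first when an annotation is given.
    """
    sites = list(sites)
    if annotation is not None:
        for site in sites:
            if site.category is None:
                classify_site(site, annotation)
    substrates: List[Substrate] = []
    by_gene: Dict[str, Substrate] = {}
    orphans: List[CleavageSite] = []
    for site in sorted(sites, key=_site_sort_key):
        if site.category is None:
            # no annotation available: treat as a bare positional site
            site.category = "intergenic"
        if site.gene:
            sub = by_gene.get(site.gene)
            if sub is None:
                sub = Substrate(substrate_id=site.gene)
                by_gene[site.gene] = sub
                substrates.append(sub)
            sub.sites.append(site)
        else:
            orphans.append(site)
    cluster: List[CleavageSite] = []

    def _flush():
        if cluster:
            p = cluster[0].position
            sub = Substrate(substrate_id=f"cluster:{p.reference}:{p.position}:{p.strand}")
            sub.sites = list(cluster)
            substrates.append(sub)
            cluster.clear()

    for site in orphans:  # already sorted by (ref, strand, pos)
        if cluster and (
            site.position.reference != cluster[-1].position.reference
            or site.position.strand != cluster[-1].position.strand
            or site.position.position - cluster[-1].position.position > intergenic_gap
        ):
            _flush()
        cluster.append(site)
    _flush()
    for sub in substrates:
        sub.category = _modal_category(sub.sites)
    logger.info("clustered %d sites into %d substrates", len(sites), len(substrates))
    return substrates


def mark_known(
    substrates: Sequence[Substrate],
    known_sites: Sequence[Tuple[str, int, str]],
    match_window: int = DEFAULT_MATCH_WINDOW,
) -> int:
    """Flag substrates containing a site within ``match_window`` nt of a
    published site (reference, 0-based position, strand). Returns the
    number of substrates flagged."""
    n = 0
    for sub in substrates:
        for site in sub.sites:
            p = site.position
            if any(
                p.reference == ref and p.strand == strand
                and abs(p.position - pos) <= match_window
                for ref, pos, strand in known_sites
            ):
                sub.known_flag = True
                n += 1
                break
    return n


@dataclass
class OverlapReport:
    a_only: int
    b_only: int
    shared: int
    a_substrates: int
    b_substrates: int

    @property
    def substrate_ratio(self) -> float:
        """Substrate-count ratio b/a (e.g. in vitro over in vivo)."""
        if self.a_substrates == 0:
            return float("inf") if self.b_substrates else float("nan")
        return self.b_substrates / self.a_substrates


def compare_site_sets(
    set_a: Sequence[CleavageSite],
    set_b: Sequence[CleavageSite],
    match_window: int = DEFAULT_MATCH_WINDOW,
    annotation: AnnotationSet | None = None,
    intergenic_gap: int = DEFAULT_INTERGENIC_GAP,
) -> OverlapReport:
    """Overlap two called-site lists (e.g. in vivo vs in vitro).

    Sites match when same reference and strand and their positions
    differ by at most ``match_window`` nt; matching is greedy by
    ascending distance. Substrate counts come from clustering each set.
    """
    candidates = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if (
                a.position.reference == b.position.reference
                and a.position.strand == b.position.strand
                and abs(a.position.position - b.position.position) <= match_window
            ):
                candidates.append((abs(a.position.position - b.position.position), i, j))
    candidates.sort()
    used_a: set = set()
    used_b: set = set()
    for _d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
    subs_a = cluster_substrates(list(set_a), annotation, intergenic_gap)
    subs_b = cluster_substrates(list(set_b), annotation, intergenic_gap)
    return OverlapReport(
        a_only=len(set_a) - len(used_a),
        b_only=len(set_b) - len(used_b),
        shared=len(used_a),
        a_substrates=len(subs_a),
        b_substrates=len(subs_b),
    )


@dataclass
class DegradomeFraction:
    """Endonucleolytic share of one transcript's decay intermediates."""

    transcript_id: str
    endo_reads: float  # summed wt cpm at called sites in the CDS
    decap_reads: float  # summed wt cpm at the transcript-start peak
    @property
    def fraction(self) -> float:
        return self.endo_reads / (self.endo_reads + self.decap_reads)


def degradome_fraction(
    wt_track: NormalizedTrack,
    annotation: AnnotationSet,
    called_sites: Sequence[CleavageSite],
    tss_window: int = DEFAULT_TSS_WINDOW,
) -> List[DegradomeFraction]:
    """Per transcript: nuclease-peak cpm over nuclease + decapping cpm.

    endo_reads sums wild-type cpm at called-site positions inside the
    transcript's CDS; decap_reads sums wild-type cpm within
    ``+/- tss_window`` nt of its TSS. Transcripts without a TSS, or with
    no reads in either class, are skipped with a log entry.
    """
    out: List[DegradomeFraction] = []
    genes = annotation.genes()
    for gene in sorted(genes):
        feats = genes[gene]
        tss = next((f for f in feats if f.kind == "TSS"), None)
        cds = [f for f in feats if f.kind == "CDS"]
        if tss is None:
            logger.warning("degradome_fraction: %s has no TSS annotation, skipped", gene)
            continue
        if not cds:
            continue
        vec = wt_track.get(tss.reference, tss.strand)
        endo = 0.0
        for site in called_sites:
            p = site.position
            if p.strand == tss.strand and any(
                f.reference == p.reference and f.start <= p.position < f.end
                for f in cds
            ):
                endo += float(vec[p.position])
        lo = max(0, tss.start - tss_window)
        hi = min(len(vec), tss.start + tss_window + 1)
        decap = float(vec[lo:hi].sum())
        if endo + decap == 0:
            logger.info("degradome_fraction: %s has no 5'-end signal, skipped", gene)
            continue
        out.append(DegradomeFraction(transcript_id=gene, endo_reads=endo, decap_reads=decap))
    return out


@dataclass
class ConcordanceFlag:
    site: CleavageSite
    assessable: bool
    concordant: bool
    netseq_value: float
    background: float


@dataclass
class ConcordanceSummary:
    flags: List[ConcordanceFlag]

    @property
    def n_assessable(self) -> int:
        return sum(f.assessable for f in self.flags)

    @property
    def n_concordant(self) -> int:
        return sum(f.concordant for f in self.flags)

    @property
    def fraction_concordant(self) -> float:
        n = self.n_assessable
        return self.n_concordant / n if n else float("nan")


def netseq_concordance(
    pare_sites: Sequence[CleavageSite],
    netseq_track: NormalizedTrack,
    window: int = 0,
    flank: int = 50,
    min_enrichment: float = 5.0,
) -> ConcordanceSummary:
    """Check for a nascent 3' end exactly 1 nt upstream of each cut.

    Co-transcriptional cleavage leaves the polymerase-bound RNA with a 3'
    end one nucleotide 5' of the 5'-end peak, so a PARE site at p is
    concordant when the NET-seq 3'-end signal at p-1 (p+1 on the minus
    strand; ``window`` widens the probe symmetrically) exceeds
    ``min_enrichment`` times the local background, estimated as the
    median over a ``+/- flank`` nt neighbourhood. Sites whose expected
    position falls off the reference are flagged not assessable.
    """
    flags: List[ConcordanceFlag] = []
    for site in pare_sites:
        p = site.position
        vec = netseq_track.get(p.reference, p.strand)
        expect = p.position - 1 if p.strand == "+" else p.position + 1
        lo, hi = expect - window, expect + window
        if lo < 0 or hi >= len(vec):
            flags.append(ConcordanceFlag(site, False, False, 0.0, 0.0))
            continue
        value = float(vec[lo:hi + 1].max())
        flo, fhi = max(0, expect - flank), min(len(vec), expect + flank + 1)
        background = float(np.median(vec[flo:fhi]))
        concordant = value > 0 and value > min_enrichment * background
        flags.append(ConcordanceFlag(site, True, concordant, value, background))
    return ConcordanceSummary(flags)
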