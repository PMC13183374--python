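"""Genome annotation: feature intervals for site classification.

Features are stored 0-based half-open regardless of the source format;
GFF3's 1-based closed intervals are converted on read and restored on
write. Introns are not required in the input — they can be derived as
the gaps between a transcript's exons.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, NamedTuple

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: feature kinds the classifier understands, in classification precedence order
GENIC_KINDS = ("ncRNA", "CDS", "intron", "five_prime_UTR", "three_prime_UTR")

#: GFF3 type -> internal kind (non-coding RNA types collapse onto ncRNA)
_KIND_ALIASES = {
    "CDS": "CDS",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "intron": "intron",
    "ncRNA": "ncRNA",
    "snoRNA": "ncRNA",
    "snRNA": "ncRNA",
    "rRNA": "ncRNA",
    "tRNA": "ncRNA",
    "TSS": "TSS",
}


class Feature(NamedTuple):
    reference: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    kind: str
    gene: str


class AnnotationError(ValueError):
    pass


class AnnotationSet:
    """Interval-indexed collection of annotation features."""

    def __init__(self, features: Iterable[Feature] = ()):
        self.features: List[Feature] = []
        self._trees: Dict[str, IntervalTree] = {}
        for feat in features:
            self.add(feat)

    def add(self, feat: Feature) -> None:
        if feat.start >= feat.end:
            raise AnnotationError(f"empty or inverted interval in {feat}")
        self.features.append(feat)
        self._trees.setdefault(feat.reference, IntervalTree()).addi(
            feat.start, feat.end, feat
        )

    def __len__(self) -> int:
        return len(self.features)

    def overlapping(self, reference: str, position: int) -> List[Feature]:
        tree = self._trees.get(reference)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(position)), key=lambda f: (f.start, f.kind))

    def by_kind(self, kind: str) -> List[Feature]:
        return [f for f in self.features if f.kind == kind]

    def genes(self) -> Dict[str, List[Feature]]:
        out: Dict[str, List[Feature]] = {}
        for feat in self.features:
            out.setdefault(feat.gene, []).append(feat)
        return out

    def tss_of(self, gene: str) -> Feature | None:
        for feat in self.features:
            if feat.gene == gene and feat.kind == "TSS":
                return feat
        return None


def _parse_attributes(text: str) -> Dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff(path, derive_introns: bool = True) -> AnnotationSet:
    """Parse GFF3 into an :class:`AnnotationSet`.

    Unparseable lines are skipped with a warning and counted. Exons are
    collected per Parent and their internal gaps emitted as introns when
    ``derive_introns`` is set and no explicit introns are present.
    """
    annotation = AnnotationSet()
    exons: Dict[str, List[Feature]] = {}
    skipped = 0
    has_introns = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                logger.warning("%s:%d: expected 9 columns, skipping", path, lineno)
                skipped += 1
                continue
            ref, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start = int(start_s) - 1  # GFF is 1-based closed
                end = int(end_s)
            except ValueError:
                logger.warning("%s:%d: non-numeric coordinates, skipping", path, lineno)
                skipped += 1
                continue
            if start >= end or strand not in ("+", "-", "."):
                logger.warning("%s:%d: bad interval or strand, skipping", path, lineno)
                skipped += 1
                continue
            attrs = _parse_attributes(attr_s)
            gene = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID") or ""
            if ftype == "exon":
                exons.setdefault(gene, []).append(
                    Feature(ref, start, end, strand, "exon", gene)
                )
                continue
            kind = _KIND_ALIASES.get(ftype)
            if kind is None:
                continue  # genes, mRNAs etc. carry no classification weight
            if kind == "intron":
                has_introns = True
            annotation.add(Feature(ref, start, end, strand, kind, gene))
    if derive_introns and not has_introns:
        for gene, gene_exons in exons.items():
            gene_exons.sort(key=lambda f: f.start)
            for left, right in zip(gene_exons, gene_exons[1:]):
                if left.end < right.start:
                    annotation.add(
                        Feature(left.reference, left.end, right.start, left.strand,
                                "intron", gene)
                    )
    if skipped:
        logger.warning("%s: skipped %d unparseable lines", path, skipped)
    return annotation


def write_gff(annotation: AnnotationSet, path, source: str = "parecall") -> None:
    """Write features as GFF3 (restoring 1-based closed coordinates)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for feat in annotation.features:
            out.write(
                f"{feat.reference}\t{source}\t{feat.kind}\t{feat.start + 1}\t{feat.end}"
                f"\t.\t{feat.strand}\t.\tID={feat.gene}_{feat.kind}_{feat.start};"
                f"gene_id={feat.gene}\n"
            )
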