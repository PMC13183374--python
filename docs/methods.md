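# Methods

## Coordinates and counting

All internal coordinates are 0-based half-open, on both strands. bedGraph and
BED are native; GFF3's 1-based closed intervals are converted on read and
restored on write. A "site" is always the first nucleotide of a 3′ cleavage
or decapping product — the base a PARE read starts on. For a plus-strand SAM
record that is the leftmost aligned reference base; for a minus-strand record
the rightmost aligned base, computed from the CIGAR span so skips and
deletions are handled. Unmapped and supplementary records are never counted;
secondary records are excluded by default (one 5′ end per sequenced fragment)
and included with `multimapped="all"`.

cpm normalization divides by the sample's total 5′-end count over both
strands and all references, so per-sample cpm sums to 1e6. The comPARE
pseudocount (0.01) is applied on the cpm scale, after normalization,
matching the order normalize → ratio.

## Calling model and its assumptions

The caller is a fixed empirical threshold rule, not a statistical test: a
base is called when every replicate pair has wild-type coverage ≥ 1 cpm and
comPARE score ≥ 4. There is no multiple-testing correction and no dispersion
model; this is deliberate — the score-4 cutoff corresponds to a 16-fold
coverage drop, far outside biological replicate variation for a genuine
nuclease-dependent end, and per-replicate gating already suppresses most
sampling artifacts. Sites *gained* in the deletion strain (score ≤ −4) are
rare, treated as noise, and available separately via `call_gained_sites`.

A consequence worth stating precisely: at a base whose true 5′-end rate is
identical in both strains (pure background), a false call requires ≥ 1 cpm
in every wild-type replicate and ~0 deletion reads in every deletion
replicate, which is a sampling coincidence with small but nonzero
probability per base. At the generator's default depth (2×10⁶ reads) a
1-cpm threshold is only 2 reads, and a 0.2 cpm/base background means
Poisson(0.4) reads per base per library, so across ~10⁵ transcribed bases on
the order of a hundred such coincidences occur per run. These false calls
are unpaired, near-threshold (≈1 cpm vs thousands of cpm at planted cuts),
and the recovery tests quantify them; a depth-aware minimum read count or a
count-based error model would remove them but would depart from the fixed
cpm-threshold rule this package implements. Users filtering real data can
raise `min_wt_cpm` or require paired/structured sites.

## Site interpretation parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_wt_cpm` | 1 | cpm | eliminates very rare 5′ ends; applied per replicate |
| `min_score` | 4 | log2 units | 16-fold drop; per replicate |
| `pseudocount` | 0.01 | cpm | keeps zero-read deletion bases finite |
| `max_gap` (collapse) | 5 | nt | nibbled satellites sit 1–5 nt 3′ of a cut |
| `expected_spacing` | 34 | nt | 14 + 4-nt loop + 16 between product starts |
| `tolerance` (pairing) | 2 | nt | absorbs one-bulge stems (15-nt upstream arms) |
| `intergenic_gap` | 200 | nt | single-linkage radius for off-annotation sites; no principled value exists, exposed in config |
| `match_window` (set overlap, known sites) | 2 | nt | replicate jitter |
| `tss_window` (degradome) | 5 | nt | decapping-peak width around the TSS; invented, config-exposed |

Collapse keeps the highest mean wild-type cpm site as primary within a run
of calls spaced ≤ `max_gap`; ties break to the 5′-most position,
strand-aware. Pairing is greedy by |spacing − 34| with each site in at most
one pair; on the minus strand "upstream" is the larger genomic coordinate.
Classification precedence on same-strand overlaps is ncRNA > CDS > intron >
5′UTR > 3′UTR; opposite-strand-only overlap is antisense; none is
intergenic. A substrate's category is the modal category of its member
sites, ties broken by the same precedence — a substrate spanning CDS and UTR
sites is therefore labelled by its majority, a choice the per-site table
preserves for re-interpretation.

## Structure model

Hairpin detection zips a stem greedily outward from each 4-mer matching the
loop pattern (`[AU]GNN` by default, `NGNN` permissive mode), accepting
Watson–Crick and G·U pairs. On a mismatch it tries, in order, a 1-nt bulge
on either arm, a 1×1 internal mismatch, then a 2-nt bulge, up to
`max_bulges` (4) unpaired interior nucleotides in total; hairpins with ≥
`min_stem_bp` (10) pairs are kept. Multibranch structures and pseudoknots
are out of scope: a substrate whose cuts flank a multi-stem junction is
reported as "no hairpin found" rather than modelled.

Stem stability is scored additively: −(3·GC + 2·AU + 1·GU) + 2 per bulged
nucleotide, in arbitrary units (lower = more stable). This is a ranking
proxy only and is not comparable to nearest-neighbor free energies in
kcal/mol.

Cleavage geometry counts nucleotides from the cut to the loop in
paired-stem register: interior bulges are excluded, so a 15-nt genomic arm
containing one bulge registers as the canonical 14. The implied 3′ overhang
is dist3 − dist5, which equals 2 exactly for −14/+16 cuts around a 4-nt
loop. "Canonical" means dist5 ∈ 14±1 (when a 5′ cut exists), dist3 ∈ 16±1
(when a 3′ cut exists), and overhang 2 when both exist. Windows are 60 nt,
centered on the cut or on the midpoint of a pair.

## Synthetic data: what it emulates and what it does not

The generator lays `n_transcripts` (50) random-sequence transcripts of
800–2000 nt, 50-nt UTRs, random strand, on one synthetic chromosome with
300-nt spacers. `n_planted_sites` (20) transcripts receive an 18-bp
perfect-stem hairpin with an [A/U]GNN loop inside the CDS; the truth table
records both product starts (−14/+16 of the loop, always 34 nt apart).
Libraries are drawn per replicate by a single multinomial of `depth`
(2×10⁶) reads over per-base expected weights:

- cleavage (wild type only): weight `cleavage_fraction` (0.3) at each of the
  two product starts; with probability `nibble_prob` a read shifts 1–5 nt in
  the transcript 3′ direction (uniform over offsets);
- decapping: weight `decap_fraction` (0.5) at the TSS, multiplied in the
  poly(A)+ view by `polyA_retention_decapped` (0.2) because decapped,
  deadenylated RNA is depleted by oligo(dT) selection (in the poly(A)−
  view decapped species are kept and cleavage products are depleted by the
  same factor — a deliberately symmetric, invented parameterization);
- background: uniform over transcribed sense-strand bases, scaled so a
  background base's expected share is `background_rate` (0.2) cpm. Background
  is restricted to transcripts because PARE background is RNA-derived;
  intergenic and antisense bases carry no signal.

Deletion libraries use the identical model with the cleavage term zeroed.
Fixed config + seed gives byte-identical output; all randomness flows from
one `numpy` generator chain.

Not modelled, hence not validated by passing tests: sequence-dependent
ligation/PCR bias, transcript abundance variation (all transcripts have
equal abundance), fragment-length effects, rRNA/snoRNA processing
intermediates, overlapping genes, introns in the synthetic annotation, and
biological replicate dispersion beyond multinomial sampling. Recovery
results on this generator show the pipeline's arithmetic and thresholds are
correct, not that the thresholds are optimal for real libraries.

## Numerical and degenerate-input choices

- Scoring positions with zero coverage in both samples give exactly 0.
- `cpm_normalize` refuses empty libraries; bedGraph readers reject
  overlapping intervals, negative and non-integer values.
- Pair matching, set overlap and greedy pairing break ties deterministically
  (ascending deviation, then reference/strand/position), so outputs are
  stable across runs and platforms.
- NET-seq concordance calls a site concordant when the 3′-end signal 1 nt
  upstream (strand-aware) exceeds 5× the median of a ±50-nt flank and is
  nonzero; sites at reference edges are flagged not assessable.
- The molar-concentration utility uses Avogadro's number 6.02214076e23.
- The tetraloop consensus is emitted as a count/frequency matrix (TSV); no
  logo rendering is bundled.

## Known limitations

- The caller's per-base fixed thresholds admit background sampling false
  positives at high depth (quantified above); they are reported, not
  suppressed.
- Hairpin zipping is greedy and can miss the optimal structure when a large
  asymmetric internal loop interrupts the stem; it reports the best zipped
  register only.
- Substrate clustering off-annotation is a heuristic radius; "166
  substrates"-style counts on real data depend on annotation completeness.
- bigWig input is not parsed; convert to bedGraph first (the track interface
  is format-agnostic beyond that).
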