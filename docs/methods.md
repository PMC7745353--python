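# Methods

## Coordinate model

All internal coordinates are 0-based half-open (BED convention); the GTF
reader converts Ensembl's 1-based closed exon coordinates at the boundary.
Spliced-transcript coordinates always run 5'→3' of the mRNA, so on a
minus-strand model the genomic base `end − 1` of the 3'-most genomic exon is
transcript position 0. This orientation is chosen because binding motifs
are RNA-oriented; every sequence the package emits reads 5'→3' on the
molecule of interest.

`genome_to_transcript` returns a plain transcript interval only when the
input is fully exonic. Partial intron overlap returns a mapping report with
the exonic fraction and the spliced image of the exonic bases; the decision
of what to do with partial overlaps (e.g. the ≥ 90 % rule) belongs to the
site layer, not the mapper. `transcript_to_genome` is the exact inverse on
exonic bases; an interval crossing k junctions yields k + 1 blocks whose
gaps are whole introns of the model.

## Isoform selection

One representative isoform per gene is chosen by hierarchical quality
filtering of Ensembl annotation: candidates must be GENCODE-basic and carry
both an APPRIS label and a transcript support level (TSL); the APPRIS label
dominates (principal1 best), ties break by TSL (1 best). APPRIS
`alternative1/2` labels are accepted but rank below all `principal` labels —
a conservative extension, since the source hierarchy names only
principal1-5. Remaining ties break by longer spliced length, then
lexicographic transcript id; these two final tie-breaks are this package's
own choice, added because reproducible output requires a total order.
Genes with no fully labelled isoform are excluded entirely.

## Site algebra

- **Filtering** uses inclusive bounds (length ≤ max, LFC ≥ min,
  p ≤ max); each criterion can be disabled independently. Two presets
  matter in practice: LFC ≥ 1 for overlap statistics, and
  length ≤ 80 / LFC ≥ 3 / p ≤ 0.01 when building classifier context sets.
- **Replicate merging** keeps, per connected component of (transitively)
  overlapping same-strand sites, only the single highest-LFC site with its
  original coordinates. **Nearby merging** is the same single-winner rule
  with components linked when the end-to-start gap is strictly below the
  merge distance (default 10 nt). The strict `<` reading is a deliberate
  resolution of an ambiguous inequality in the source description of
  "nearby" merging; a gap of exactly 10 nt does not merge. Ties within a
  component go to the longer site, then the lower start, then the id.
- **Exon-overlap classification** computes the fraction of site bases inside
  the merged exon union of the retained isoforms (denominator = site
  length, i.e. intersect fraction-of-A semantics, matching `intersectBed
  -f`). Default threshold 0.90. Sites only count exons on a compatible
  strand; strand `.` matches both.
- **Border distance** is measured per site end against the containing exon's
  corresponding border, 0 meaning flush; a site is near-border at threshold
  d when the minimum over both ends is ≤ d (default 50 nt). The ≤ reading
  follows the usage for border-proximity selections; pair detection below
  uses strict < per its own stated rule.
- **Pair detection** pairs two sites when their inner ends lie strictly
  < 10 nt (default) from the adjacent borders of consecutive exons of one
  model. Each site joins at most one pair; junctions are processed in order
  and the highest-LFC candidate on each side wins.

## Context extraction

Sites are reduced to their center base (odd length: middle base; even
length: the more 5' of the two central bases — chosen so that
reverse-complementing the input mirrors the choice consistently) and
extended ±80 nt, giving 161 nt total. Genomic context extends on the
genome and truncates only at chromosome ends; transcript context extends in
spliced coordinates, reading through junctions and truncating at transcript
ends. Truncated sequences are kept, never re-padded or dropped, with the
lost lengths recorded per side (`len == 2·ext + 1 − up − dn`); full
extension near transcript ends is by construction only possible in the
genomic space. Ns in the genome propagate untouched. FASTA output carries
site id, space, viewpoint offsets and truncation in the header; the
viewpoint is not case-marked in the sequence.

## Motif model

A motif is an ordered list of IUPAC blocks, each preceded by a bounded
unspecified spacer (`N{a-b}`; the first block has none), with `[XY]k`
repeat shorthand and RNA `U` normalised to `T` at parse time. Scanning
reports **one hit per admissible start position**, choosing the
minimal-total-gap assignment (shorter gaps tried first, leftmost-greedy):
positional hit counts must not be inflated by spacer-assignment
multiplicity. A sequence `N` matches only a motif `N`, so masked regions
cannot produce phantom hits under degenerate letters. Hits found in
transcript space map back to genomic block structures; a hit is
junction-split iff it has ≥ 2 blocks. Duplicate hits at identical absolute
positions (from overlapping context windows) are counted once per
(space, target, strand, start, end, motif). Frequency comparison divides
deduplicated hit counts by total context-set length; the percent change
`100·(density_t/density_g − 1)` is flagged undefined when the genomic count
is zero. Scanning is done on the sense strand only — context sequences are
already strand-resolved.

## Negative sampling

Negatives for classifier training are drawn uniformly over all start
positions that keep a site of the requested length (default 161 nt,
matching the positive context length) fully inside the span of a gene
covered by ≥ 1 positive, with zero base overlap with any positive on that
chromosome. Sampled negatives additionally exclude each other's
neighbourhood, so the output is mutually non-overlapping — a choice made
here to avoid duplicate training examples. Sampling is deterministic for a
fixed seed; an exhausted eligible space returns fewer sites with an
explicit flag rather than failing.

## Dataset statistics

`dataset_stats` composes classification, border distances and pair
detection. Near-border and pair ratios use the number of **exonic** sites
as denominator; ratios are undefined (None) when there are no exonic
sites. Site scores are the peak caller's log2 fold changes; mean scores
are arithmetic means. The multi-dataset helpers bin exonic-site
percentages into quartile ranges `[0,25), [25,50), [50,75), [75,100]`
(right-closed top bin) and report the squared Pearson correlation of
exonic ratios between cell lines, undefined under zero variance.

## Synthetic data generator

The generator emulates the *geometry* of peak-called CLIP data on a toy
genome: two chromosomes, by default 16 genes (~1/3 minus-strand, one
single-exon gene, 3–6 exons of 150–300 nt per gene, introns of 80–200 nt,
300 nt intergenic padding). Three genes are reserved for isoform-selection
scenarios: an APPRIS-dominates-TSL case, a TSL tie-break case and an
unlabelled gene that must be excluded. The planted site set defaults to
100 sites — 20 exonic far from borders (> 50 nt), 12 near-border
(10–50 nt), 4 adjacent-border pairs (8 members, < 10 nt) and 60
non-exonic — giving exactly 40 % exonic, 50 % of exonic near borders and
20 % of exonic in pairs as integer-count ratios. Single-base sites at 5,
20, 50 and 79 nt from transcript 5' ends exercise truncation arithmetic.
Site scores are uniform LFCs in [1, 5] (pair members [2, 5]) with p-values
below 0.01.

Motif instances (3× PUM2 PRE, 2× IGF2BP3 compound by default) are written
into the genome at spliced positions straddling distinct splice junctions,
with every spacer at its minimum length so that the scanner's
minimal-total-gap rule recovers the planted span exactly. Because an 8-mer
can also occur by chance in ~30 kb of uniform background, the generator
then scans the genomic context window of every split instance and mutates
any chance match away (one disallowed base per match, never touching
planted block bases), iterating to a fixed point. The
"split motifs are invisible in genomic context" property therefore holds
by construction, not probabilistically.

What the generator does **not** emulate: read-level signal (no alignments,
coverage or crosslink profiles), natural base composition, overlapping
genes, alternative isoform diversity beyond the selection scenarios, and
chromosome-scale sizes. Passing tests demonstrate the correctness of the
interval algebra, mapping, scanning and bookkeeping — not performance
claims about real eCLIP data, whose published summary percentages depend on
specific external datasets and annotation releases and are out of scope
here.

## Problem sizes and numerics

The test suite and the acceptance script run on fixture-scale data: 1,000
random intervals for round-trip and block-conservation checks over a
~50-transcript annotation, 1,000 random sites for the overlap oracle, 200
random (sequence ≤ 1 kb, ≤ 3 blocks) instances for the scanner oracle.
These sizes make the whole pipeline run in seconds while exercising both
strands, junction-crossing intervals and truncation edges. All randomness
flows through seeded numpy generators; every generator output is
byte-reproducible for a fixed seed. Degenerate inputs are defined rather
than accidental: empty BED files yield empty lists, genes without labelled
isoforms vanish from selection, zero-variance correlation and
zero-genomic-hit frequency changes are flagged undefined (None), and
single-exon transcripts have empty intron lists.

## Known limitations

- Multi-isoform mapping assigns a site to the retained isoform with maximal
  exon overlap (tie: lexicographic transcript id); sites genuinely
  ambiguous between isoforms of different genes are resolved, not reported
  as ambiguous.
- GFF3, CDS/UTR features, fusion and circular transcripts are unsupported.
- The scanner is exact but exponential in the number of gapped blocks in
  the worst case; intended motif sizes (≤ ~5 blocks, gaps ≤ ~25 nt) are
  unproblematic.
- Negative sampling matches genomic space only; it does not produce
  composition-matched or dinucleotide-shuffled controls.
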