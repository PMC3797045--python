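# Methods

This note documents the models and procedures mitomap implements, the
parameters that matter, what the simulator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Coordinate model

All public coordinates are 1-based inclusive, the convention of printed
mitochondrial annotation tables; SAM's 0-based half-open frame is converted
only inside the pysam adapters, and BED-style export states its 0-based
convention in the header. Circularity is explicit: any integer position is
meaningful modulo the genome length, windows may span the origin, and a
feature wrapping the origin carries a `wraps` flag rather than being
inferred from `low > high`, so malformed input stays detectable. Features
bundled from printed tables that lack coordinates (the gene/intron catalog)
are coordinate-less records (`low = high = None`); only located features can
be written to GFF3 or quantified.

## Motif scanning

Patterns are strings over the 15 IUPAC codes; a symbol matches a base iff
the base is in its set, and `N` in the genome matches no symbol (unknown
sequence never yields a hit — a conservative choice). Scanning is
plus-strand by default because the promoter and ori models are defined on
the non-template strand of the majority-plus-strand gene set; both-strand
scanning is an explicit flag, minus-strand hits being windows whose reverse
complement matches. All overlapping matches are reported, and a
self-complementary window scanned on both strands yields two hits with
distinct strand labels. The scanner is vectorised (per-column boolean
lookup over the doubled sequence) and is property-tested against a
per-window brute-force matcher.

Consensus derivation takes equal-length ungapped sequences and emits, per
column, the unique IUPAC symbol covering exactly the observed base set —
minimal by construction (any proper subset would un-match an input).

Two literal motifs are configurable rather than hard-coded. The dodecamer
defaults to the canonical yeast mitochondrial 3'-UTR element
`AATAATATTCTT` (non-template strand); its directed cleavage site is 2 nt
downstream of the motif end. The 17-base heptakaidecamer cleavage element is
shipped with a **synthetic stand-in literal** (`TAGTCGGTTCGAACCGA`, cut
after base 9): the element's published sequence exists only in figure
artwork, so the default marks the element's length and internal-cut
geometry, and real-genome work must supply the true literal in the config.
The same applies to the ori G-rich 17-mer: detection therefore defaults to a
composition rule (≥15/17 G), with an exact-literal mode used when the
literal is known (the simulator always knows its own literals and the test
suite exercises the exact mode).

## Promoter model

The consensus promoter is 20 bp spanning −12..+8 with the transcription
start (+1) at pattern offset 13; the −8..+1 core is the nonanucleotide
`ATATAAGTA`. On top of the degenerate consensus, +1 = A is enforced as a
hard filter, since the initiating nucleotide is adenosine in vivo even
though the column symbol alone would admit more. Nonanucleotide-only
scanning (0–2 mismatches) annotates each hit with whether its surrounding
window extends to the full consensus, separating genuine promoters from
orphan nonanucleotides.

## Ori model

Active calls require, downstream of an intact promoter and in order on one
strand: the G-rich 17-mer starting within −4..+4 of the promoter end
(negative offsets mean overlap with the promoter's last bases — the spacing
is flexible in the real genome); an A/T spacer whose length is searched over
150–260 nt at ≥0.80 A+T (the "~200 bp" of the structural model, widened to a
window so the three real active oris would all pass while random sequence
does not); then 7-bp arm, 29-nt gap, and the reverse-complement arm.

Inactive calls use a single-gap alignment of the consensus: positions where
the first *s* columns match, an insert of length *L* (searched 10–60 nt)
intervenes, and the remaining columns match. One planted insert can align
several ways when upstream background happens to match leading consensus
columns; all such variants share the window end, and the most parsimonious
(smallest-insert) variant per cluster is the true alignment, so that one is
kept — this recovers planted insert lengths exactly across the tested range.
By default an inactive call also requires the downstream four parts, which
suppresses chance gapped matches in A/T-rich background. Active and
inactive calls partition: windows overlapping an intact active promoter are
never re-reported as disrupted.

Promoter serving is assigned after ori detection: a promoter anchoring an
active ori serves "ori"; otherwise it serves "gene" if at least one
gene-class feature starts downstream on its strand before the next promoter
(circular distance), else "unassigned".

## Read evidence

Only the 5' mate of each directional pair is used (the 3' mate would double
count inserts shorter than two read lengths); strandedness is declared by a
small library config. Per strand, the pileup records where transcript 5'
ends start, where 3' ends stop, and base coverage.

**tRNA 3' ends.** Evidence reads end at a position with a soft-clip
beginning `C`, `CA` or `CCA` — partial tails are accepted because
fragmentation truncates them — but a call requires at least one full-CCA
read and a configurable support minimum (default 5). Clips are discounted
wherever the genome itself reads CCA immediately downstream, so templated
CCA can never fake a boundary. Ties on support go to the downstream-most
position and are logged.

**tRNA 5' ends.** For each candidate tRNA length in 60–95 nt, the first 7
bases are scored against the 7 bases preceding the discriminator
(antiparallel; Watson–Crick pairs 1.0, G·U 0.5); the best score wins, ties
resolve toward the canonical 72 nt, and a best score below 5.0 yields a
flagged no-call. This is a deliberate simplification of full cloverleaf
structure prediction: the acceptor stem alone fixes the 5' end once the 3'
end is known at nucleotide resolution.

**Cleavage sites.** A cut after position *p* (transcript orientation — an
explicit convention) requires ≥ `min_reads` (default 20) read ends at *p*,
≥ `min_reads` read starts at the next transcript position, and enrichment ≥
`min_enrichment` (default 10) over the local background. The background is
the median per-position read-end event rate (mean of start and end counts)
in a 101-nt window: random fragmentation scatters read ends roughly
uniformly, so genuine processing sites stand out as sharp stacks against
that rate. Base coverage cannot serve as the denominator — a stack of read
ends never exceeds the coverage it sits under, so a coverage ratio would be
pinned near 1 inside any covered transcript. Calls are optionally linked to
motif-annotated cuts (heptakaidecamer internal cut; dodecamer end + 2).
Raising either threshold never adds calls.

## Quantification and comparison

RPKM follows the printed formula: reads / (transcript kb × total mappable
reads in millions), where "total mappable reads" is defined as the retained
5'-mate alignments of the sample (stated in every report header). Counting
is strand-resolved with a minimum-overlap parameter (default 1 nt); a read
overlapping two same-strand features counts for both, because introns and
exons of one gene are quantified as separate features. Antisense counts of
a feature are its mirror-RNA signal.

The two-condition comparison reports the fold change of replicate-mean RPKM
and a permutation p-value: the fraction of replicate-label assignments
(identity included) whose |log2 fold change| reaches the observed one. All
C(n_a+n_b, n_a) assignments are enumerated when feasible, otherwise a
seeded subsample. With 2 vs 2 replicates, label-swap symmetry makes 2/6 the
smallest attainable p-value. This is deliberately not a negative-binomial
test and is labelled accordingly in the reports. Zero-denominator fold
changes are infinite unless a pseudo-RPKM (suggested 0.1) is requested.

Note one property of plain library-size normalisation: if a condition adds
reads (e.g. stabilised introns), every other feature's RPKM deflates, so a
true k-fold change is recovered slightly below k. The simulator's
rRNA-dominated libraries keep this compositional bias to roughly 10% at the
default study conditions; correcting it (median-of-ratios and the like) is
out of scope by design.

## The simulator

The generator plants the full architecture on an A/T-biased background
(default 80% A+T, emulating the extreme A/T richness of the real genome):
consensus promoters with an adenosine +1 (windows drawn from the bundled
promoter table); active oris (all five parts; hairpin arms GC-only so the
planted pair is unambiguous, enforced by rejection sampling); inactive oris
(35-nt GC insert after promoter column 8); tRNA genes of 72 nt with perfect
7-bp acceptor stems and guaranteed non-templated context after the
discriminator; ORFs starting ATG, ending TAA, with the dodecamer placing the
mature 3' end 2 nt downstream of its end; an rRNA-style unit at high
abundance (libraries are rRNA-dominated, as real un-subtracted directional
libraries are); an RNase-P-like 483-nt transcript cut internally at a
planted heptakaidecamer into an 89-nt 5' fragment and a 3' remainder; and
extra heptakaidecamers in untranscribed background, so that only the
expressed subset acquires read support. One gene sits on the minus strand;
one gene carries an 800-nt intron (group I/II introns are kilobase-scale)
whose excised form is a separate molecule at half the host's steady state
(free introns are decay substrates), with a minor (20%) alternative splice
form retaining 30 nt of intron. Mirror molecules are emitted at 2% of host
abundance for mRNAs and tRNAs. Condition "b" multiplies intron and mirror
abundances (default 4×) and changes nothing else.

Reads are written from provenance, not an aligner: each molecule copy is cut
into consecutive fragments with lengths uniform in 30–300 nt, and the 5'
mate (101 nt, or the whole fragment if shorter) is emitted with per-base
substitutions at the configured rate (default 0.005). Non-genomic CCA tails
soft-clip. Fragmentation is per contiguous genomic block, so no read spans
a splice junction and alignments stay gap-free; excised-intron boundaries
are themselves recorded as true processing sites, since intron release
genuinely stacks read ends there. Because every copy contributes one
fragment starting at its 5' terminus and one ending at its 3' terminus,
processing sites show exactly the co-stacking signature the callers detect —
but only fragments shorter than the read length yield exact 3'-end reads,
which is why the default depth (1000 reads per expressed kilobase at unit
abundance; real libraries run near 10⁵) is chosen to power the default
cleavage thresholds comfortably. One seed governs genome construction,
transcription sampling, fragmentation and errors, in that order; built
genomes are validated (planted promoters are the only consensus matches,
planted heptakaidecamers the only literal occurrences) with bounded,
seed-derived retries.

What the simulator does not emulate: realistic base-quality models, PCR
duplication, reads spanning splice junctions, rRNA abundance profiles
beyond "dominant", RNA secondary structure, or sequence-dependent
fragmentation. Closure tests therefore demonstrate correctness of the
inference logic under the stated read model, not performance on real
libraries — in particular, real aligner artefacts (multimapping in repeats,
clipped junction reads) are absent by construction.

## Problem sizes

The default study uses a 30-kb genome, six transcription units plus two
active and two inactive oris, six tRNAs, and roughly 20,000 reads per
sample; the acceptance study simulates one zero-noise and one default-noise
sample for closure, and five independent 2-vs-2 replicate rounds for the
fold-change recovery (the recovered multiplier is reported as the median
over rounds, which is how a recovery band around the true 4× should be
read given the compositional bias above).

## Known limitations

* The heptakaidecamer and G-rich defaults are synthetic stand-ins (above);
  real-genome runs must configure the true literals.
* The acceptor-stem heuristic can mis-place a 5' end when a spurious
  equally-good stem exists in the search window; ties are broken toward
  canonical length, and low-scoring regions yield flagged no-calls rather
  than guesses.
* Cleavage calling assumes processing products are stable enough to
  sequence on both sides of the cut; a site whose upstream or downstream
  product decays completely is invisible by design.
* The permutation test's resolution is limited by replicate count (p ≥ 2/6
  at n=2+2); it substitutes for, and does not reproduce, shrinkage-based
  count tests.
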