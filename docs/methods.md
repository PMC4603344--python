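# Methods

This note documents the models and procedures implemented in `ssrmine`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate
about real EST collections.

## Redundancy reduction

EST libraries oversample abundant transcripts, so repeat mining on raw reads
would count the same locus many times. We collapse each genus's reads with a
greedy representative-based clustering rather than a full overlap-layout
assembler — redundancy removal is the goal, not contig building.

Procedure: sort reads by (length descending, id ascending); each read joins
the first existing cluster whose representative shares ≥1 exact k-mer
(default k = 12) and into which it aligns — as an infix of the
representative, in either orientation (reverse-complement joining on by
default, since EST libraries mix orientations) — at identity ≥
`min_identity` (default 0.95, computed as 1 − edit-distance/length via
edlib). Otherwise it founds a new cluster. Because the infix alignment spans
the whole shorter sequence, the `min_overlap_fraction` parameter (default
0.80 of the shorter sequence) is satisfied by construction under this
containment criterion; it is kept in the interface and enforced formally so
that a future partial-overlap criterion inherits it. Consequence of the
containment criterion: two reads that overlap only partially (staggered
fragments of one transcript) stay separate unique sequences. That is
conservative for marker mining — it can only split, never wrongly merge —
but it means "unique sequences" over-counts transcripts at high coverage,
and one planted repeat may surface on more than one unique sequence.

Contig consensus is the per-column majority over members star-aligned to the
representative; ties keep the representative's base; insertions relative to
the representative are dropped. The fixed processing order makes cluster
memberships independent of input order, and member conservation (every read
in exactly one cluster) is asserted by tests.

The length filter keeps sequences **strictly** longer than 100 bp ("larger
than" read literally).

## Perfect-repeat detection

For each period p ∈ {2..6} we scan the self-match profile s[i] = s[i+p] and
emit every maximal run of whole-motif copies whose motif is *primitive* (not
a power of a shorter motif — so (AT)×10 is never reported as (ATAT)×5) and
whose copy number meets the threshold. Class-I thresholds (≥ 20 bp):
{2: 10, 3: 7, 4: 5, 5: 4, 6: 4}; the relaxed profile is 4 for every period.
Mononucleotide runs are never reported. Runs are broken at non-ACGT
characters: repeat identity over ambiguity codes is uninterpretable.

When runs of different periods overlap (e.g. a dinucleotide run abutting a
trinucleotide run sharing bases), the longer run wins; ties go to the
smaller period. The published catalogs report each repeat once with a single
motif, and no finer rule is attributable, so this deterministic resolution
is our choice; tests enforce that emitted loci never overlap.

Motif families: the equivalence class of a motif under cyclic rotation and
reverse complementation, named by its lexicographic minimum ("canonical
family"). A small fixed alias table maps three families to the display names
conventional in the literature (CCG → "GGC", CG → "GC", ATC → "TGA"); every
other family is displayed by its canonical name. Note that ATG and TGA
rotate into the same family (canonical ATC): the package keeps one family
and does not attempt to distinguish them.

## Primer design

The designer enumerates every forward window wholly left of the repeat and
every reverse window wholly right of it (primers never overlap the run — a
primer inside the repeat cannot size alleles), within the geometric bounds
implied by the product-size window. Hard constraints: length 18–23 nt,
Tm 55–65 °C, GC 30–70 %, product 90–320 bp, ambiguity-free sequence, pair
ΔTm ≤ 3 °C (default), and longest self-complementary run ≤ 8 nt (default).
Survivors are ranked by

penalty = w_len(|len_f−20| + |len_r−20|) + w_tm(|Tm_f−60| + |Tm_r−60|)
        + w_gc(|GC_f−50| + |GC_r−50| in % points) + w_pair·|ΔTm|

with default weights 1.0 / 1.0 / 0.5 / 1.0; ties break to the smaller
product, then the leftmost forward primer. The ΔTm and self-complementarity
caps are robustness defaults of this package (both configurable and
reported); full primer-picker thermodynamics (hairpins, dimers, mispriming
libraries) are intentionally out of scope, since only the four constraint
windows above are well-attributed design inputs.

Two Tm models are provided and recorded in output metadata: the default
nearest-neighbor two-state estimate (Biopython `Tm_NN`, 50 mM monovalent
salt, 500 nM total oligonucleotide, split 250/250 between strands), and the
closed-form GC-linear approximation Tm = 64.9 + 41·(n_GC − 16.4)/N, which is
exactly testable by hand and useful below its ~14 nt validity floor checks.

## Genomic-context classification

Each SSR-bearing unique sequence is aligned to the annotated reference.
The internal aligner is toy-scale seed-and-chain: exact 11-mer seeds grouped
by diagonal, ungapped X-drop extension (match +1, mismatch −2, X-drop 10),
then dynamic-programming chaining of collinear segments into one
multi-block hit per subject and strand, allowing subject gaps up to 20 kb so
spliced queries produce blocks flanking introns. Chance matches across a
splice junction let neighbouring segments overlap slightly in the query; the
chain scoring charges twice the overlap (so stacks of mutually overlapping
low-complexity segments never outscore a genuine long alignment) and the
winning chain's overlaps are trimmed on both axes. Because the read
simulator introduces substitutions only, affine-gap extension is
unnecessary: diagonals are preserved and indel-free HSPs plus chaining
reproduce the needed block structure. Externally computed 12-column tabular
alignments (with gaps, E-values) are ingested interchangeably.

Significance: external hits use E-value ≤ 1e−5; the internal aligner, which
has no E-value model (Karlin–Altschul calibration is out of proportion at
toy scale), requires identity ≥ 0.90 over ≥ 50 aligned bases. Sequences with
no significant hit are excluded from context statistics and reported as an
exclusion fraction — the analogue of database ESTs that fail to match their
nominal source genome.

The best hit (lowest E-value, tie → highest identity×length) projects the
repeat interval through the block list (minus-strand blocks reflected);
the projection is absent when fewer than half the repeat's bases are
aligned. Category = majority feature overlap of the projected interval
among CDS (→ exon), 5'/3' UTR (→ UTR, merged in reports, split retained
internally), intron; ties break exon > UTR > intron; no feature overlap →
genomic. The majority-with-priority rule is our choice for repeats spanning
feature boundaries, where no published rule exists. Classification is
single-best-hit; there is no voting across secondary hits.

## Summaries

Count tables are long-form pandas frames with explicit axes and margin
checks. Percentages round half away from zero at the printed precision
(2 decimals for shares, 1 for rates); tests assert that shares over a full
partition sum to 100 ± 0.05.

Empirical PCR-screen semantics: a locus **amplifies** when any tested
species yields a product — stutter profiles included, since a stutter peak
is an amplicon. For **transferability**, stutter loci are discarded from the
denominator; a retained locus transfers iff it amplified in both congeneric
species and the union of observed alleles across the genus has ≥ 2 members
(at least one species with ≥ 2 alleles, or differing product-size ranges
between species). This pair of rules is the unique reading under which the
packaged empirical tables are internally consistent. One printed per-genus
rate in the source tables is arithmetically inconsistent with its own
counts (8/12 printed as 58.3 %); the package always reports the rate
computed from the counts (66.7 %).

The packaged genus → taxonomic-group table covers the genera named in the
running text; the full several-hundred-genus list lives in external
supplements, so the map is deliberately small and user-extensible
(`load_taxonomy(extra={...})`); unmapped genera are reported, never
silently dropped. The grand total of the per-group EST-count column in the
packaged group table does not equal its printed total (a typographic issue
in the source); the fixture validator therefore checks all SSR-count sums,
genus counts and totals, but exempts that one column's grand total.

## Synthetic data generator

The generator emulates, at toy scale, a plant EST study with an annotated
control genome. One numpy Generator seeded once drives every draw; identical
(params, seed) give byte-identical FASTA/GFF3/TSV outputs.

Genome: `n_genes` (default 100) genes on one plus-strand chromosome,
separated by intergenic spacers (300–800 bp), each gene 5'UTR + 2–5 CDS
exons (150–400 bp) with introns (130–350 bp) + 3'UTR (UTRs 130–250 bp), on
an i.i.d. background of GC 0.44 (a typical plant exome-neighbourhood
value). With probability `ssr_plant_rate` (default 0.5) a gene receives one
SSR, in a context drawn from `context_mix` (defaults CDS 0.43, UTR 0.33,
intron 0.12, intergenic 0.12 — echoing the location distribution observed
in the rice control). Motifs are drawn from context-conditional
`family_freqs` (tri-rich in CDS, di-rich in UTR/non-coding, matching the
well-replicated biological pattern), with Class-I repeat counts (di 10–16,
tri 7–12, tetra 5–8, penta 4–6, hexa 4–5).

Repeats are *inserted* (flanks displaced, never overwritten) at least 60 bp
from feature edges, and the single base on each side of the run is forced
off the repeat's periodicity, so the planted repeat count is exactly what a
maximal-run miner must report. Because random backgrounds occasionally
contain genuine Class-I runs, the final genome is re-mined and any
non-planted locus is recorded in the ground truth as "spontaneous", so
recall and precision are computed against the union.

ESTs: per gene, Poisson(`coverage_per_transcript`, default 3) fragments of
250–700 bp from the spliced mRNA; per fragment, minority fates — intergenic
genomic fragment (rate 0.05, emulating contaminating non-transcribed DNA),
intron-retaining pre-mRNA fragment (0.05), truncation below 100 bp (0.05,
to exercise the length filter), exact duplication (0.15) — then i.i.d.
substitutions at `error_rate` (default 0.002, single-pass-read scale) and a
random strand. With `guarantee_ssr_coverage` (default on) each planted SSR
additionally gets one fragment covering the run plus 60 bp flanks from the
appropriate source, so recall denominators are well-defined.

Ground truth records every planted SSR's coordinates in genome, pre-mRNA
and mRNA space, and every fragment's source interval, strand, error
positions and duplicate group. Recall bookkeeping: a planted SSR counts as
*covered* when some retained fragment spans run + flanks; at nonzero error
rates the default denominator additionally requires at least one covering
fragment with no error inside the run, because a substitution in the run
genuinely destroys the perfect repeat (this is a property of the data, not
a miner failure). A mined locus matches a planted SSR when its unique
sequence contains a covering fragment and the (family, period, count)
signatures agree.

What the generator does **not** emulate: realistic expression-level
skew (coverage is homogeneous across genes), platform-specific error
profiles and indels, quality scores, vector/adapter contamination, chimeric
reads, paralogy, and alternative splicing. Passing tests therefore
demonstrate algorithmic correctness under a clean, substitution-only error
model — not performance on raw archival EST data, where trimming and
masking would precede this pipeline.

## Test and acceptance problem sizes

The oracle-based checks run at sizes chosen to keep the default suite
fast while remaining informative: miner vs brute-force maximality/
primitivity oracle on 120 random 2 kb sequences (plus 40 × 800 bp in unit
tests); canonical-family enumeration over all primitive motifs of length
2–6; primer designer vs exhaustive window-pair oracle on 25 random 600 bp
templates; context classifier vs per-base projection oracle and planted
truth on a 100-gene genome; and the full pipeline on a 200-gene, plant-rate
1.0, zero-error study (recall 1.0, exact context cross-tab recovery,
family-frequency recovery within two standard errors, byte-identical
re-runs).

## Known limitations

* Clustering is containment-based; deep EST sets with staggered reads
  produce more unique sequences than transcripts (redundancy is still
  removed; counts are conservative).
* The internal aligner assumes substitution-dominated divergence; queries
  with real indels relative to the reference should be aligned externally
  and supplied as tabular alignments.
* Catalog counts depend on unspecified internals of the original mining
  software (assembler parameters, primer-picker defaults), so genus-scale
  catalog sizes from the source study are not reproduction targets; the
  fixture tables and planted-truth recovery are.
* The nearest-neighbor Tm uses a fixed salt/oligo condition set; no
  divalent-cation or dNTP corrections.
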