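# Methods

## Model and procedure

`hexprime` quantifies substitution errors introduced by random-hexamer
mispriming during cDNA synthesis. The analysis assumes a
non-strand-specific paired-end library aligned to references whose
sequence is known with certainty (spike-in controls), so that every
read-vs-reference mismatch is a technical artifact rather than biology.

**Strand model.** The reference forward strand is taken as the transcript
sense strand (true for ERCC-style spike references, the intended use).
A reverse-mapping read was sequenced from first-strand cDNA — synthesized
directly on the RNA, so its errors are RNA–DNA mispairs — and a
forward-mapping read from second-strand cDNA (DNA–DNA mispairs). Both
mates of a pair are profiled independently, each classified by its own
orientation flag: in a non-strand-specific protocol each mate's 5' end is
a priming site. A `--mates 1|2|both` switch restricts to one mate.

**Synthesis coordinates.** For each aligned base, position is counted
1-based from the raw read's 5' end (the priming site): for forward reads
this is the SAM query position; for reverse reads it is L − q + 1 over
the full query length L, because the raw read is the reverse complement
of the SAM-orientation sequence. Positions 1–6 are the hexamer footprint
and position 7 the first extension base; the "hexamer region" defaults to
1–7 with the downstream window starting at 8. The template base is the
reference base (T shown as U) for first-strand reads and the complement
of the reference base (the first-strand cDNA actually copied) for
second-strand reads; the incorporated base is the base physically present
in the sequenced strand (the query base for forward reads, its complement
for reverse reads). A base matches iff incorporated equals the
Watson–Crick partner of the template; the 12 mispair classes per strand
are the 4 templates × 3 non-complementary incorporated bases.

**Column reconstruction.** Reference bases under a read are reconstructed
from the MD tag when present, from the reference FASTA otherwise; when
both are available they must agree exactly and any disagreement is
treated as corrupt input. Insertions, soft clips and deletions produce no
aligned column (the analysis concerns substitutions only); bases with N
on either side are excluded from both numerators and denominators.

**Read filters.** Defaults follow the profiling use case: unmapped,
secondary/supplementary, unpaired and non-proper-pair reads are dropped;
pairs with insert size outside [read length + 1, 1000] are dropped,
because inserts at or below the read length imply 3' adapter read-through
whose bases would be scored as spurious mismatches; reads soft-clipped at
the 5' (synthesis-start) end are dropped because the priming site itself
was not observed (3'-only clips are tolerated). Per-base quality
filtering is off by default (`min_base_quality = 0`): misprimed bases are
called at high quality, and quality trimming belongs upstream.

**Statistics.** All rates are mismatches/coverage with explicit
denominators; undefined quantities (zero denominators) are reported as
`None`/`NA`, never 0. The headline statistics are: the pooled position-1
mispriming rate of A/U-template bases ("reads starting with A or T",
where the start base is taken from the *reference* because the read's own
first base is corrupted by the very errors measured — `--start-by read`
pools by the observed base instead, and the statistic pools A- and
T-starts together, with per-template rates also emitted); the fraction of
position 2–6 mispriming events that are rU-dG or rG-dT; and the fraction
of template-U events at positions 3–4 incorporating G. Cross-dataset
comparison pools (position, class) percentage pairs within a window and
reports Pearson r (matching the scatter-plot reading of such comparisons)
with Spearman as a secondary statistic; cells undefined in either dataset
are dropped pairwise rather than imputed as 0, since a zero-mismatch
position carries no distributional information; windows with fewer than 3
pairs are undefined. Per-position r values are also emitted. No
significance testing of rate differences or correlations is performed.

## The simulator and its default model

The simulator emulates exactly the features the profiler measures:
fragmentation (uniform fragment starts, truncated-normal lengths — only
the 5'-end identity matters for error profiling, so no sequence-biased
fragmentation model is attempted), hexamer-primed synthesis of both
strands with position-specific 4×4 template × incorporated matrices over
positions 1–7, and a flat downstream substitution rate. Mispriming is
applied as independent per-position draws, not joint hexamer-sequence
draws: the analysis is per-position marginal, so marginals suffice.
Errors are injected in synthesis coordinates before the first-strand read
is reverse-complemented into SAM orientation, which makes coordinate
round-trips through the profiler meaningful. Base qualities are a
constant Q40 (configurable): misprimed bases are high-quality calls, so
no quality model is needed. No PCR duplication, hexamer-abundance
(priming-site preference) bias, adapter read-through or FASTQ emission is
simulated; filters are exercised with hand-built fixtures instead.

**Default parameters** (and why): 100 bp reads, fragment length
~N(300, 60²) truncated to ≥150, references 250–2000 bp at GC 0.5 —
ordinary short-insert bulk RNA-seq geometry over an ERCC-scale reference
set (92 sequences, ≥100 kb total). Background error 0.001, a typical
post-filtering Illumina substitution rate. The default first-strand
matrix (`src/hexprime/data/default_model.yaml`, loaded with row-sum
validation) is pinned so that, analytically: the pooled A/U-template
off-complement mass at position 1 is 0.20; rU-dG + rG-dT are 65% of
expected events at positions 2–6 (at equal template frequencies); the
template-U row sends 88% of its off-complement mass to G (0.0704 of
0.08), covering positions 3–4; the template-C row has the smallest
off-complement mass at every position 1–7; and rA-dC/rU-dC are the most
common classes at position 1. Entries not pinned by those constraints are
fixed, documented constants chosen to keep rows stochastic. Position 7 is
mildly elevated (≈6× background) but nearly uniform across classes, so
the structured, reproducible signature lives in positions 1–6 while
7+ behaves like background for distribution-correlation purposes.
The default second-strand matrix is a uniform 0.004 off-complement mass
at positions 1–7 — a slight elevation over background, deliberately
structureless, as no claim is made about the true DNA–DNA mispriming
spectrum. `default_error_model(second_strand="background")` instead sets
the second-strand off-complement mass equal to the background rate:
"mispriming confined to first-strand synthesis" is modelled as the second
strand carrying only the flat error floor, so its hexamer-region rate is
statistically indistinguishable from background (a literally zero matrix
would give exactly zero, since the background applies only beyond
position 7, and would make that comparison vacuous).

## Numerical and interface choices

- Bases are encoded A=0, C=1, G=2, T/U=3 so the complement is `3 − code`;
  counting uses a single (position, template, incorporated) integer
  tensor per strand, and profile merging is element-wise addition (exact,
  associative). The object-level route (`reconstruct_columns` →
  `to_synthesis_coords` → `accumulate`) and the vectorised route
  (`profile_reads`) produce identical tensors and are tested against each
  other.
- SAM text is the canonical alignment format; BAM is read via pysam.
  The text parser skips malformed records individually, logging line
  numbers, rather than aborting a whole run. MD parsing is validated
  against CIGAR extent; an MD tag that runs off the read, or disagrees
  with the reference, is a hard per-read error naming the read.
- Reads shorter than 7 bases, or with indels, are processed normally
  (they contribute to fewer positions / skip inserted bases). No length
  normalization is applied across positions — counts carry denominators.
- Spliced (`N` CIGAR) alignments are handled positionally, but no
  transcript model is built; unspliced spike-style references are the
  intended input.
- Distributions sum to 100 within 1e-9 by construction (exact integer
  counts divided once).
- Fragment-length rejection sampling retries 100 rounds, then clamps into
  the feasible window; references shorter than the minimum fragment are
  excluded from sampling.

## Test scale and what passing shows

Full-scale checks use 200,000 read pairs per library (three seeds for
recovery, two for the window-correlation contrast), the scale at which
every per-position per-class cell has coverage in the tens of thousands;
recovery is asserted within 3 binomial standard errors with the nominal
≤1% 3-SE exceedance allowance, with the stable-pair expectation computed
conditionally on the observed template coverage to remove reference
base-composition wobble. Unit tests run at 2,000 pairs.

Passing these tests shows the pipeline is internally correct (exact
truth-log bijection, MD/reference oracle equivalence, parameter recovery)
— it does not show that real libraries follow the default matrix. The
simulator's i.i.d. references, uniform fragmentation, constant quality
and marginal (per-position-independent) mispriming are idealizations;
real data add hexamer-abundance bias, quality structure, PCR duplicates
and reference mismannotation, none of which are modelled. Conclusions
about a real library should come from profiling its own spike-in
alignments.

## Known limitations

- Strand inference relies on the reference forward strand being the
  transcript sense strand; transcriptome-wide references with antisense
  transcription would need strand-aware annotation, which is out of scope.
- The second-strand mispriming spectrum is represented only as a
  structureless elevation; the profiler measures it, but the simulator
  makes no claim about its true shape.
- No post-hoc correction or masking of misprimed bases is provided; the
  package measures the artifact, it does not repair reads.
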