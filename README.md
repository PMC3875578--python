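# hexprime

Strand-aware, position- and nucleotide-resolved mismatch profiling of
RNA-seq reads against references of known sequence — built to detect and
quantify **random-hexamer mispriming errors** in the first bases of cDNA.

## The problem

Most RNA-seq libraries are built by fragmenting RNA and reverse-transcribing
it into first-strand cDNA primed by random hexamers; second-strand cDNA is
then synthesized on the first strand, again hexamer-primed. A hexamer can
anneal imperfectly, and its mismatched bases are copied into the library:
the first six read positions (the hexamer footprint) plus the first
extension base carry position- and nucleotide-specific substitution errors
that are *not* sequencing error — they are called at high base quality and
reproduce across independent libraries. Left unrecognized, they inflate
false SNP and RNA-editing calls and pollute k-mer assemblies.

Reads mapping to spike-in controls of known sequence (e.g. the ERCC set)
make these errors measurable: every read-vs-reference mismatch there is a
technical artifact. `hexprime` profiles such alignments:

- **Strand classification.** Reverse-mapping reads are first-strand cDNA
  (RNA–DNA mispriming, "rX-dY" mispairs); forward-mapping reads are
  second-strand cDNA (DNA–DNA, "dX-dY").
- **Synthesis coordinates.** Each aligned base (reconstructed from the SAM
  MD tag, cross-checked against the reference FASTA) is re-expressed as
  (position from the 5' priming site, template base, incorporated base).
- **Profiles.** A per-strand, per-position, template × incorporated count
  tensor yields mismatch rates per position, the 12-class mispair
  distribution (4 templates × 3 non-complementary bases, summing to 100%
  per position), per-template panels, and headline statistics — the
  A/U-start mispriming rate at position 1, the share of position 2–6
  events that are the thermodynamically stable rU-dG / rG-dT pairs, and
  the share of template-U events at positions 3–4 incorporating G.
- **Cross-dataset comparison.** Pooled Pearson/Spearman correlation of
  per-position mispair distributions between two libraries, inside
  (positions 1–6) versus outside (7–20) the hexamer window.
- **Simulator.** A paired-end library generator with a configurable
  position-specific mispriming matrix and ground-truth event log, so the
  entire pipeline is validated by exact parameter recovery.

## Worked example

```bash
python examples/01_simulate_library.py
python examples/02_profile_mismatches.py
```

The second script profiles a 5,000-pair simulated library and prints:

```
mismatch rate by synthesis position (first strand):
  position   1:  12.42% <- hexamer region
  position   2:   3.70% <- hexamer region
  position   3:   3.58% <- hexamer region
  position   7:   0.82% <- hexamer region
  position   8:   0.14%
  position  50:   0.18%

headline statistics:
  A/U-start mispriming rate (pos 1):   19.5%
  rU-dG + rG-dT share (pos 2-6):       62.1%
  U->G share of U events (pos 3-4):    89.1%
  hexamer-region rate (pos 1-7):       4.53%
  downstream rate (pos 8+):            0.106%
```

Reading this: mismatch rates are an order of magnitude higher across the
hexamer region than downstream; about a fifth of first-strand reads whose
template starts with A or U carry a misprimed first base; two-thirds of
position 2–6 events are the stable rU-dG/rG-dT pairs; and a uracil
template at positions 3–4 is misread as G almost nine times out of ten —
the recovered values match the simulator's injected model within sampling
error. `examples/03_compare_datasets.py` shows the same signature
reproducing between two independent libraries (Pearson r ≈ 1 across
positions 1–6, r ≈ 0 downstream).

The same analyses are available from the shell:

```bash
hexprime simulate --refs 92 --pairs 200000 --seed 1 --out sim/
hexprime profile  --sam sim/reads.sam --ref sim/refs.fa --out prof/
hexprime compare  --profile-a prof/profile.tsv --profile-b other/profile.tsv --out cmp/
```

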