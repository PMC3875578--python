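"""Correlate mispair distributions between two independent libraries.

Simulates two libraries with different seeds (different references,
fragments and error draws) under the same mispriming model, then pools
the per-position 12-class mispair percentages within two windows.  Inside
the hexamer window (positions 1-6) the distributions are strongly
correlated — the mispriming signature is a property of the chemistry, not
of one dataset — while downstream (positions 7-20), where errors are flat
sequencing noise, the correlation collapses.
"""
from pathlib import Path

import hexprime as hx
from hexprime.dataset_compare import correlate_windows, distribution_matrix

out = Path("example_output/compare")
out.mkdir(parents=True, exist_ok=True)

profiles = []
for seed in (1, 2):
    model = hx.default_error_model(seed=seed)
    refs = hx.simulate_references(12, seed=seed)
    cfg = hx.LibraryConfig(n_read_pairs=20_000, references=refs, model=model)
    sam = out / f"reads_{seed}.sam"
    hx.simulate_library(cfg, sam, seed=seed)
    profiles.append(hx.profile_reads(hx.parse_sam(sam), refs))

first = hx.StrandClass.FIRST_STRAND
m1 = distribution_matrix(profiles[0], first, range(1, 101))
m2 = distribution_matrix(profiles[1], first, range(1, 101))
res = correlate_windows(m1, m2, window_a=(1, 6), window_b=(7, 20))
res.to_json(out / "comparison.json")
res.pairs_to_tsv(out / "pairs.tsv")

print(f"hexamer window (positions 1-6):    pearson r = {res.r_a:.3f} "
      f"over {res.n_a} (position, class) pairs")
print(f"downstream window (positions 7-20): pearson r = {res.r_b:.3f} "
      f"over {res.n_b} pairs")
print("\nr near 1 inside the hexamer window means the position- and "
      "nucleotide-specific\nmispriming signature reproduces across "
      "independent libraries; r near 0 downstream\nmeans those errors are "
      "unstructured noise.")
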