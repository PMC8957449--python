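"""Simulate a seven-type SV benchmark and look at the ground truth.

Builds a 200 kb genome with 3 SVs of each category, samples 30x paired-end
reads, projects them to reference coordinates, and writes the whole
benchmark (FASTA/FASTQ/SAM/BED/TSV) to ./scratch_example_sim.
"""

from collections import Counter

from svbreak import SimConfig, simulate_dataset

cfg = SimConfig(genome_len=200_000, n_per_type=3, coverage=30, seed=42)
sim = simulate_dataset(cfg, out_dir="scratch_example_sim")

print(f"reference: {cfg.genome_len} bp   donor: {len(sim.donor)} bp")
print(f"read pairs: {len(sim.reads)}   mapped records: "
      f"{int(sim.projected.is_mapped.sum())} / {2 * len(sim.reads)}")
print(f"SVs: {Counter(r.svtype.name for r in sim.truths)}")
print(f"truth breakpoints: {len(sim.truth_breakpoints)}")
print("\nfirst five truth records (type, reference breakpoints, size):")
for r in sim.truths[:5]:
    print(f"  {r.svtype.name:7s} {r.breakpoints}  {r.size} bp")
# The donor differs from the reference only inside the implanted SVs; the
# SAM file contains split (soft-clipped) records at every junction.
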