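"""Scaffold- and contig-level assembly statistics from an AGP layout.

Contig N50 breaks scaffolds at their gap rows, so the two N50 values
bracket how much of the assembly's contiguity comes from gap-joined
scaffolding rather than contiguous sequence.
"""

from chromanchor.report import assembly_stats
from chromanchor.simulate import SimulationParams, simulate_genome

truth = simulate_genome(SimulationParams(seed=42, chimera_rate=0.05))
s = assembly_stats(truth.layout, min_length=1000)

print(f"scaffolds (>=1 kb): {s.n_scaffolds}")
print(f"total length:       {s.total_length:,} bp")
print(f"gap fraction:       {s.gap_fraction:.4%}")
print(f"scaffold N50:       {s.scaffold_n50:,} bp")
print(f"contig N50:         {s.contig_n50:,} bp")
print(f"longest scaffold:   {s.max_scaffold:,} bp")
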