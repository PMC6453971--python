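"""Sliding-window recombination analysis on a simulated alignment.

Simulates eight lineages on a tree, plants recombination events that
replace the second half of three genomes with segments from deeply
diverged donors, and runs both analyses: the phylogenetic compatibility
matrix (300 nt windows, 100 nt step; entries are normalized
Robinson-Foulds distances between per-window neighbor-joining trees
under TN93) and the breakpoint-density permutation profile (400 nt
window, 1 nt step, 1,000 uniform permutations, 95/99% envelopes).
"""

import tempfile

import numpy as np

import smacotype as st
from smacotype.simulate import SimulationConfig, emit_dataset, true_breakpoints

cfg = SimulationConfig(
    n_lineages=8,
    genome_length=2400,
    tree_height=0.3,
    events=[("L01", "L05", 1200, 2400),
            ("L02", "L06", 1200, 2400),
            ("L03", "L07", 1200, 2400)],
    seed=61,
)
with tempfile.TemporaryDirectory() as td:
    out = emit_dataset(cfg, td)
aln = out["alignment"]

cm = st.compatibility_matrix(aln)
k = len(cm.window_starts)
print(f"compatibility matrix: {k} windows of "
      f"{cm.config.window} nt (step {cm.config.step})")
# summarize incongruence of each window against the first window
row0 = cm.values[0]
print("nRF of each window vs window 0:")
print("  " + "  ".join(f"{s}:{v:.2f}" for s, v in zip(cm.window_starts, row0)))

bps = true_breakpoints(out["truth"]["scaffold"], L=aln.length)
prof = st.breakpoint_profile(bps, aln.length, st.BreakpointConfig(seed=7))
print(f"\nbreakpoint profile over {len(bps)} true breakpoints:")
print(f"  hot intervals (observed > 99% envelope): {prof.hot}")
print(f"  cold intervals (observed < 95% envelope): {prof.cold}")
print()
print("Windows on opposite sides of column 1200 disagree strongly "
      "(nRF near 1) because the planted transfers gave the two genome "
      "halves different histories; the hot interval sits at the planted "
      "crossover, where the three transfer edges pile up (the segment "
      "ends at the alignment end carry no crossover and are excluded).")
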