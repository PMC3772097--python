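"""Scan a genome for the ACS motif and measure origin-set enrichment.

Builds an 11 bp ACS position weight matrix with a 4th-order Markov genome
background, scans both strands at a 70% LOD cutoff, and compares the match
density inside origin intervals with the genome-wide density (one-tailed
Fisher exact test).
"""

import numpy as np

from oriclass import SimulationConfig, generate_study
from oriclass.motif_enrichment import build_motif, density_fold, fisher_enrichment, scan

study = generate_study(
    SimulationConfig(
        seed=4,
        n_per_class={"chromatin_dependent": 10, "dna_dependent": 10, "weak": 10, "complex": 0},
    )
)
motif = build_motif(study.acs_training_sequences, study.genome, order=4)
matches = scan(study.genome, motif, lod_cutoff_pct=70.0)

regions = [(o.chrom, o.start, o.end) for o in study.origins]
in_set = sum(1 for m in matches if any(s <= m.pos < e for _, s, e in regions))
set_bp = sum(e - s for _, s, e in regions)
genome_bp = sum(len(g) for g in study.genome.values())

fold = density_fold(in_set, set_bp, len(matches), genome_bp)
width = motif.width
positions_set = 2 * sum((e - s) - width + 1 for _, s, e in regions)
positions_genome = 2 * sum(len(g) - width + 1 for g in study.genome.values())
p = fisher_enrichment(in_set, positions_set, len(matches), positions_genome)

print(f"motif consensus: {motif.consensus} ({motif.width} bp)")
print(f"matches: {len(matches)} genome-wide, {in_set} inside origins")
print(f"density fold over genome = {fold:.1f}, one-tailed Fisher P = {p:.2e}")
print("A fold well above 1 with a tiny P shows the ORC binding motif is")
print("concentrated in origins, as expected for a sequence-specific binder.")
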