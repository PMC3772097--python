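"""Measure nucleosome-depleted regions and their dependence on ORC.

Anchors nucleosome occupancy on the ACS of each origin, measures NDR
widths in wild-type and ORC-loss conditions, and tests whether
chromatin-dependent origins lose less NDR than DNA-dependent origins when
ORC is removed.
"""

from oriclass import SimulationConfig, generate_study
from oriclass.nucleosome_architecture import compare_group_deltas, delta_ndr, measure_ndrs

study = generate_study(SimulationConfig(seed=5))
wt = measure_ndrs(study.nucleosome_wt, study.origins)
mut = measure_ndrs(study.nucleosome_orc_mutant, study.origins)

groups = dict(zip(study.truth.index, study.truth["true_class"]))
deltas = delta_ndr(wt, mut, groups)
summary = deltas.groupby("group")[["wt_width", "delta"]].mean().round(1)
print(summary)

diff, t, p = compare_group_deltas(deltas, "dna_dependent", "chromatin_dependent")
print(f"\nmean NDR loss (DNA-dep - chromatin-dep) = {diff:.0f} bp, "
      f"Welch t = {t:.1f}, P = {p:.2e}")
print("Chromatin-dependent origins keep their NDR when ORC binding is lost,")
print("consistent with other chromatin features maintaining the open region.")
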