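"""Relate origin classes to replication timing and checkpoint phenotypes.

Classifies a synthetic study, then compares the classes' mean replication
times (Trep), their hydroxyurea firing behaviour (combined over two
simulated studies), and the in-vivo/in-vitro affinity correlation among
the earliest- and latest-firing origins.
"""

import numpy as np

from oriclass import SimulationConfig, analyze_study, generate_study
from oriclass.timing_association import (
    EARLY_TREP_MAX,
    LATE_TREP_MIN,
    affinity_correlation,
    timing_report,
)

study = generate_study(SimulationConfig(seed=6))
results = analyze_study(study, kmeans_restarts=5000, kmeans_seed=6)
report = timing_report(study.timing, results.gemsa_calls)

print("mean Trep (min) per class:")
for cls, mean in sorted(report["group_mean_trep"].items()):
    print(f"  {cls:20s} {mean:5.1f}")
cmp = report["trep_chromatin_dependent_vs_dna_dependent"]
print(f"chromatin- vs DNA-dependent: t = {cmp.t_statistic:.1f}, P = {cmp.p_value:.2e}")
hu = report["hu_chromatin_dependent"]
print(f"chromatin-dependent HU firing: {hu['group_HUr_WT']} HUr-WT vs "
      f"{hu['group_HUr_rad53']} HUr-rad53 (Fisher P = {hu['fisher_p']:.2e})")

# affinity correlation among the latest- and earliest-firing origins
table = results.table().join(study.timing["trep_min"])
for label, mask in (
    ("latest", table["trep_min"] > LATE_TREP_MIN),
    ("earliest", table["trep_min"] < EARLY_TREP_MAX),
):
    sub = table[mask & table["ratio"].notna() & table["total_gemsa"].notna()]
    corr = affinity_correlation(sub["ratio"], sub["total_gemsa"])
    print(f"{label}-firing origins (n={corr['n']}): "
          f"Pearson r = {corr['pearson_r']:.2f} (P = {corr['pearson_p']:.2g})")
print("Early firers are enriched for chromatin-dependent ORC binding, so")
print("their in-vivo occupancy decouples from naked-DNA affinity.")
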