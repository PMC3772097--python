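# oriclass

Classify budding-yeast DNA replication origins by the *mechanism* of ORC
binding — sequence-specific ORC–DNA affinity versus extrinsic "chromatin"
interactions — and relate those mechanisms to origin activation time.

In *S. cerevisiae* the origin recognition complex (ORC) selects replication
origins in G1 by binding the ARS consensus sequence (ACS). But an origin's
ORC occupancy in vivo is not always explained by its naked-DNA affinity:
at some origins, features extrinsic to the binding site — nucleosomes and
non-histone chromosomal proteins — supply much of the binding energy.
`oriclass` implements a genome-scale comparison of the two affinities:

* **in vivo**: the *orc2-1/ORC2* ratio — the ratio of an origin's ChIP
  peak area under ~10-fold ORC depletion (*orc2-1*) to its wild-type peak
  area. Ratios ≥ 0.8 mark high in-vivo affinity (*orc2-1*-resistant),
  ratios ≤ 0.3 low affinity (*orc2-1*-sensitive).
* **in vitro**: apparent dissociation constants from EMSA titrations,
  fitted to the one-site hyperbola θ(c) = c/(K_d + c) with B_max = 1, and
  genome-wide EMSA (gEMSA) binding signals of purified ORC against sheared
  naked genomic DNA at 0.3, 3 and 30 nM.

An origin that is *orc2-1*-resistant but binds naked DNA weakly (K_d > 10×
the ARS317 reference, or the Weak k-means cluster of the gEMSA signal
matrix) is called **chromatin-dependent**; a resistant origin whose
in-vitro binding is tight (≤ 3×, or the Moderate/Strong clusters) is
**DNA-dependent**. Downstream analyses compare the classes' ACS motif
content (PWM scans with a 4th-order Markov genome background at LOD
cutoffs, Fisher enrichment), nucleosome architecture (ACS-anchored
profiles, NDR widths and their ORC dependence) and replication timing
(Trep group tests, hydroxyurea firing behaviour, affinity correlations).

The package is a library for epigenomics/replication researchers working
from Python; a synthetic-study generator with planted per-origin binding
parameters provides ground truth for every stage.

## Worked example

`examples/03_classify_synthetic_study.py` generates a 120-origin synthetic
study (40 origins per mechanism class, per-probe noise SD 0.15), runs the
whole pipeline — track normalisation, sliding-window peak calling
(240 bp/60 bp, Bonferroni p ≤ 1e-5), peak-area ratios, gEMSA signal
clustering (k-means, k = 3, 10,000 restarts) — and scores the calls
against the planted truth:

```
gemsa_call           chromatin_dependent  dna_dependent  unclassified  weak
true_class
chromatin_dependent                   40              0             0     0
dna_dependent                          0             40             0     0
weak                                   0              0             2    38

gEMSA-route accuracy: 98.3%
EMSA-route accuracy:  98.3%
```

Rows are planted mechanisms, columns the recovered calls. The two
"unclassified" weak origins drew measured ratios inside the moderate
0.3–0.8 band, which the method deliberately never force-classifies. The
other examples cover K_d fitting (`01`), peak calling (`02`), motif
enrichment (`04`), NDR analysis (`05`) and timing association (`06`); each
prints the numbers it computes and a line on what they mean.

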