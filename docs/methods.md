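# Methods

This note documents the models, numerical choices and limitations behind
`oriclass`, in the order the pipeline uses them.

## Binding model and the two affinity axes

All binding is modelled as one-site equilibrium occupancy
θ(c, K_d) = c/(c + K_d) with B_max fixed at 1. Apparent K_d values are
least-squares fits of this hyperbola to EMSA titrations
(`emsa_affinity.fit_apparent_kd`, scipy `curve_fit`, positivity bounds,
standard error from the fit curvature). Replicates are fitted
independently and summarised as mean ± SEM. Fits above a censor bound
(default 420 nM — just beyond what titrations up to 30 nM can constrain)
or non-convergent fits are reported censored ("ND", binding too weak to
determine); a censored estimate compares as greater than any finite
threshold, so it satisfies every ">" fold rule but never a "≤" rule.
Degenerate all-zero titrations yield a censored estimate, not an error.

K_d values are expressed as folds over a reference origin (the
high-affinity ARS317/HMR-E site, 7.223 nM in the bundled panel). The fold
bands are: tight ≤ 3×, intermediate 3–4×, weak > 4×, weak > 5×, very weak
> 10× (censored estimates land in the last band). The bundled 40-origin
panel records the published panel design: the low-affinity arm comprises
the 18 confirmed-ACS origins with ratio ≤ 0.3 (the predicted-ACS origin
ARS1215 was assayed but is flagged outside the panel; with it excluded the
> 4× and > 5× counts are 14 and 13, matching the published tallies, and
with it included they are not), while the high-affinity arm keeps all 20
origins regardless of ACS provenance.

The in-vivo axis is the *orc2-1/ORC2* ratio: the mutant-condition peak
area over the wild-type peak's coordinates divided by the wild-type area.
Computing the mutant area over the *wild-type* span avoids a mutant peak
call and allows negative ratios where the mutant signal is depleted.
Bounds are inclusive: sensitive ≤ 0.3, resistant ≥ 0.8. The 0.3–0.8 band
is never mechanism-classified — a single depleted ORC concentration
cannot resolve mechanisms there — and origins with non-positive wild-type
areas are flagged unclassifiable.

## Peak calling

Windows of 240 bp tiled every 60 bp per chromosome; a window is evaluated
when it holds ≥ 2 probes (a probe belongs to a window iff its interval
midpoint lies in the half-open span). The window statistic is the mean
probe value; the null is Gaussian with SD σ/√n_w, where σ is estimated by
reflecting the negative half of the centred probe-value distribution
about zero (σ = RMS of the negative values — after centring, negatives
are assumed pure background). One-sided p-values are Bonferroni-multiplied
by the number of evaluated windows *genome-wide* (per-chromosome
correction was the open alternative; genome-wide is the stricter choice
and matches a single-array experiment). Windows passing the corrected
cutoff (default 1e-5) merge when overlapping or book-ended; the peak area
is the probe-value sum over the merged span and the peak p is the best
member window's. A σ of exactly zero (noise-free input) degenerates to
p = 0 for positive-mean windows and p = 1 otherwise.

Before calling, tracks are normalised: the most extreme 1.1% of probes by
|value| are removed (repetitive probes hybridise promiscuously and report
garbage), then the median of the retained values is subtracted. Removal
is exact-count (round(n × fraction)) with deterministic tie-breaking.

Peaks are assigned to the origin with the largest bp overlap; ties break
by smaller midpoint distance, then lexicographic origin name.

## gEMSA signals and clustering

Per origin, the in-vitro signal at each ORC concentration is either the
area of the gEMSA track's own called peak (absent peak ⇒ 0) or the gEMSA
track's area over the wild-type ChIP peak coordinates (negative totals
permitted); their sum is the Total gEMSA signal. The n×3 signal matrix is
clustered by Euclidean k-means on the raw (unstandardised) vectors, k = 3,
with random-partition initialisation per restart and 10,000 restarts, the
best-SSE solution kept. Restarts run as one batched Lloyd iteration over
all restarts simultaneously, so the default budget costs about a second
at n ≈ 120. Origins are put in canonical name order before clustering, so
the result is deterministic given the seed and invariant to input
permutation. Clusters are labelled Weak < Moderate < Strong by ascending
centroid mean, which resolves label-permutation ambiguity.

Joint calls (gEMSA route): chromatin-dependent = resistant ∧ Weak;
DNA-dependent = resistant ∧ (Moderate ∨ Strong); weak = sensitive ∧ Weak;
everything else unclassified. Core-X telomeric origins are dropped before
classification. The EMSA route replaces the cluster with the K_d fold:
≤ 3× ⇒ DNA-dependent, > 10× or censored ⇒ chromatin-dependent, the 3–10×
band ⇒ complex (a mixture of intrinsic and extrinsic interactions; only
this route can emit the complex call, since the cluster geometry has no
analogue of the band).

## Motif scanning

A motif is a position frequency matrix with pseudocounts (default 1 per
base per column) paired with a k-th order Markov background (default
k = 4) estimated from the genome with add-one smoothing. A window's score
in bits is Σ_i log2(f_i(b_i) / q(b_i | k preceding bases)), with the
context of the first k window positions taken from the genomic bases
preceding the window; windows containing N or starting within k bases of
a contig start are skipped, and both strands are scanned (overlaps
permitted). Match strength for thresholding is the LOD percent: the PWM
component Σ log2 f_i(b_i), min–max normalised over the motif's own column
range and clamped to [0, 100]. This makes the consensus score exactly
100% wherever it occurs, makes the percent invariant to any per-column
constant (including the background term), and is the package's pivotal
interoperability assumption, since the scanning tool it emulates does not
publish its normalisation. Bipartite motifs (e.g. the 17 bp EACS plus the
3 bp WTW of the B1 element separated by a fixed 13 bp degenerate spacer)
score the two parts and ignore the spacer.

Enrichment uses match densities (matches per bp, expressed as fold over
the genome-wide density) and one-tailed Fisher exact tests on 2×2 tables
whose position counts are scanned windows on both strands, not raw bp —
the second interoperability choice, flagged here.

## Nucleosome architecture

Occupancy signals are anchored on the start of the EACS on the T-rich
strand, flipped for minus-strand origins so +x is always 3′ of the
element, binned at 4 bp over ±1000 bp, and averaged per group (origins
without a predicted ACS are omitted). Nucleosomes are maximal runs of
occupancy above a threshold (default 0.5 × the whole-track median — the
original study's run-calling script is unpublished, so the threshold is a
package choice and configurable). Within a ±600 bp search window, the +1
nucleosome is the first run starting at or 3′ of the anchor and the −1
nucleosome the last run ending at or before the +1 start; the NDR width
is plus1_start − minus1_end. Missing flanking runs flag the measurement
unbounded. Condition deltas (wild type − ORC-loss mutant) are compared
between groups by two-sided Welch t-tests; the degenerate case (zero
variance in both groups, equal means) returns P = 1 by convention.

## Timing association

HU firing calls from two studies combine by precedence: firing in HU in
wild-type cells in either study ⇒ HUr-WT; otherwise firing only in rad53
cells in one or both ⇒ HUr-rad53; otherwise unknown. Group Trep
comparisons use Welch's t-test (two-sided throughout, except the
one-tailed Fisher motif enrichment and hypergeometric overlaps). Correlations report both Pearson and Spearman (tie-averaged
ranks) with two-sided p-values; zero-variance inputs are flagged rather
than tested. The earliest/latest-firing subsets use Trep < 20 and
> 30 min. Missing timing values are excluded pairwise, never imputed.
Contingency analyses exclude unknown-status origins and use Fisher's
exact test (the original figure does not state its test; Fisher is exact
at these group sizes).

## The synthetic study generator

The generator (`synthetic_study.generate_study`) emulates the complete
measurement design with a per-origin ground truth: a random-sequence
genome (default ~363 kb) with one planted 11 bp ACS consensus per origin
on a random strand; probe tracks at 10 bp spacing carrying a raised-cosine
signal arch (240 bp footprint, amplitude 2.0 log2 units at full
occupancy) plus i.i.d. Gaussian probe noise (SD 0.15); 1.1% planted
repetitive probes per track (same positions on every array, garbage
values of magnitude 3–6) that the normalisation step is expected to
strip; triplicate EMSA titrations at 0.3/3/15/30 nM with truncated
Gaussian noise (SD 0.02); rectangular nucleosome occupancy with a planted
NDR 3′ of each ACS (20 bp offset; widths 230–280 bp for
chromatin-dependent origins, 190–240 bp otherwise) that an ORC-loss track
shrinks by 10 bp/side at chromatin-dependent origins versus 60 bp/side
elsewhere; and a timing table with class Trep means of 18 min
(chromatin-dependent) versus 30 min (DNA-dependent and weak), SD 4, plus
two simulated HU studies thresholding noisy Treps at 24 min.

Each origin carries an intrinsic K_d (naked DNA) and a chromatin boost
≥ 1 dividing it in vivo. In-vitro signals (gEMSA, titrations) depend on
the intrinsic K_d only — the naked-DNA contract. The in-vivo ratio is
θ(C/10, K_eff)/θ(C, K_eff) with C the notional wild-type ORC
availability. Under this model resistance (≥ 0.8) requires
K_eff ≤ C/35 and sensitivity (≤ 0.3) requires K_eff ≥ 0.35 C, so the
resistant and sensitive K_eff bands are 12.25-fold apart no matter what C
is. No single C can therefore make 4–20 nM sites resistant *and*
50–300 nM sites sensitive with unit boosts; published K_d ranges simply
cannot be carried verbatim into a one-concentration equilibrium model.
The defaults resolve this deliberately: C = 1000 nM (C is declared
notional — the model only constrains ratios of K_eff to C);
DNA-dependent origins draw K_d 4–20 nM with boost 1 (expected ratios
0.85–0.97); weak origins draw 500–2000 nM with boost 1 (ratios
0.14–0.25); chromatin-dependent origins draw intrinsic K_d 300–1200 nM
with a boost coupled as uniform(max(10, K_d/12), 100), keeping K_eff
≤ 12 nM and expected ratios ≥ 0.9 while staying within a 10–100× boost
range; complex origins (off by default) draw 25–70 nM with boost 2–5.
The chromatin-dependent and weak intrinsic ranges overlap on purpose:
naked DNA cannot tell the two classes apart, which is exactly why the
k = 3 clustering groups them into one Weak cluster and splits the
DNA-dependent continuum into Moderate and Strong — mirroring the
structure the method exploits on real data. One DNA-dependent origin is
planted at exactly the reference K_d (7.2 nM) and serves as the
normalisation reference for the EMSA route.

What the generator does *not* emulate: spatially correlated probe noise,
dye and amplification biases, shearing/recovery losses (the real gEMSA's
main failure mode), fuzzy or sequence-encoded nucleosome positioning, and
any coupling between binding mechanism and timing other than the planted
class means. Passing tests therefore show the pipeline recovers planted
structure under idealised noise, not that the biological classification
of real arrays is correct.

## Problem sizes and tolerances

Default synthetic studies use 120 origins (40 per class) on one ~363 kb
chromosome with 10 bp probe spacing — large enough that every stage runs
at its real operating point while a full study analyses in about two
seconds. Oracle comparisons use: a 10,000-point log-spaced K_d grid
(0.1–1000 nM, 1% agreement tolerance); brute-force window enumeration on
10 kb tracks (exact agreement); exhaustive set partitions at n = 6 for
the clustering SSE; per-position window rescoring on 5 kb for the
scanner; and a run-length scanner for NDR widths (exact). End-to-end
recovery is scored over 10 seeds (mean accuracy ≥ 90%, unclassified
counted as wrong) and the timing separation over 100 generator seeds
(α = 0.01 rejection in ≥ 95%).

## Known limitations

* The LOD normalisation and Fisher position basis are assumptions (above);
  absolute match counts against other scanners will differ even when
  rankings agree.
* Censored K_d estimates carry no information beyond "weaker than the
  bound"; fold-based rules treat them as arbitrarily weak.
* k-means with k = 3 is inherited from the study design; nothing in the
  package selects k.
* The in-vivo ratio model is a single-site equilibrium caricature of
  ChIP; it reproduces the ratio *bands*, not absolute ChIP efficiencies.
* The moderate-affinity band (ratio 0.3–0.8), by design, is never
  assigned a mechanism.
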