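"""Origin classification by ORC binding mechanism.

Two routes produce the same vocabulary of calls
(``chromatin_dependent`` / ``dna_dependent`` / ``weak`` / ``complex`` /
``unclassified``):

* the EMSA-threshold route combines each origin's in-vivo affinity class
  (the orc2-1/ORC2 ChIP peak-area ratio) with its apparent-Kd fold over the
  reference origin;
* the gEMSA-cluster route combines the in-vivo class with the origin's
  k-means cluster (Weak / Moderate / Strong) over its in-vitro binding
  signals at 0.3, 3 and 30 nM ORC.

A chromatin-dependent origin binds ORC strongly in vivo (ratio >= 0.8)
although its naked-DNA affinity is weak — features extrinsic to the ORC
binding site must supply the missing binding energy.  A DNA-dependent
origin's in-vivo binding is explained by a tight sequence-specific ORC-DNA
interaction.  The moderate in-vivo band (0.3 < ratio < 0.8) is never
force-classified: the depletion assay cannot resolve mechanisms there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .emsa_affinity import KdEstimate
from .peak_analysis import Peak, peak_area_over
from .tracks_io import OriginAnnotation, ProbeTrack

RATIO_SENSITIVE_MAX = 0.3  # ratio <= 0.3: low in-vivo affinity (orc2-1 sensitive)
RATIO_RESISTANT_MIN = 0.8  # ratio >= 0.8: high in-vivo affinity (orc2-1 resistant)

CLUSTER_LABELS = ("Weak", "Moderate", "Strong")
CALLS = ("chromatin_dependent", "dna_dependent", "weak", "complex", "unclassified")


def ratio_class(ratio: float) -> str:
    """sensitive iff ratio <= 0.3, resistant iff ratio >= 0.8, else moderate.

    Both bounds are inclusive.
    """
    if ratio <= RATIO_SENSITIVE_MAX:
        return "sensitive"
    if ratio >= RATIO_RESISTANT_MIN:
        return "resistant"
    return "moderate"


@dataclass(frozen=True)
class InVivoAffinity:
    origin: str
    orc2_area: float
    orc21_area: float
    ratio: float
    ratio_class: str
    unclassifiable: bool = False


@dataclass(frozen=True)
class GemsaProfile:
    origin: str
    signals: tuple[float, float, float]  # at 0.3, 3 and 30 nM ORC
    mode: str  # called_peaks | chip_coordinates
    cluster: str | None = None

    @property
    def total(self) -> float:
        """Total gEMSA signal: the sum over the three ORC concentrations."""
        return float(sum(self.signals))


@dataclass(frozen=True)
class OriginClassification:
    origin: str
    call: str
    route: str  # emsa_thresholds | gemsa_clusters


def in_vivo_ratio(
    orc2_track: ProbeTrack,
    orc21_track: ProbeTrack,
    orc2_peaks: Mapping[str, Peak],
    origins: Sequence[OriginAnnotation],
) -> list[InVivoAffinity]:
    """orc2-1/ORC2 peak-area ratios over the wild-type peak coordinates.

    ``orc2_peaks`` maps origin name -> the wild-type peak assigned to it.
    The mutant area is computed over the *wild-type* peak's span, so no
    mutant peak call is needed and depleted regions may give negative
    ratios.  Origins with non-positive wild-type area are flagged
    unclassifiable.
    """
    out = []
    for o in origins:
        peak = orc2_peaks.get(o.name)
        if peak is None:
            continue
        wt = peak_area_over(orc2_track, peak.chrom, peak.start, peak.end)
        mut = peak_area_over(orc21_track, peak.chrom, peak.start, peak.end)
        if wt.area <= 0:
            out.append(InVivoAffinity(o.name, wt.area, mut.area, float("nan"), "moderate", True))
            continue
        r = mut.area / wt.area
        out.append(InVivoAffinity(o.name, wt.area, mut.area, r, ratio_class(r)))
    return out


def total_gemsa_signal(
    gemsa_tracks: Mapping[float, ProbeTrack],
    origins: Sequence[OriginAnnotation],
    mode: str = "chip_coordinates",
    orc2_peaks: Mapping[str, Peak] | None = None,
    gemsa_peaks: Mapping[float, Mapping[str, Peak]] | None = None,
    concs: Sequence[float] = (0.3, 3.0, 30.0),
) -> list[GemsaProfile]:
    """Per-origin in-vitro ORC binding signals at each ORC concentration.

    ``chip_coordinates`` mode sums each gEMSA track over the wild-type ChIP
    peak span assigned to the origin (depleted regions give negative
    signals).  ``called_peaks`` mode uses the peak called on each gEMSA
    track itself; an origin with no called peak at a concentration gets
    signal 0 there.
    """
    for c in concs:
        if c not in gemsa_tracks:
            raise ValueError(f"missing gEMSA track at {c} nM")
    if mode not in ("chip_coordinates", "called_peaks"):
        raise ValueError(f"unknown mode {mode!r}")
    profiles = []
    for o in origins:
        signals = []
        for c in concs:
            track = gemsa_tracks[c]
            if mode == "chip_coordinates":
                if orc2_peaks is None:
                    raise ValueError("chip_coordinates mode needs orc2_peaks")
                peak = orc2_peaks.get(o.name)
                if peak is None:
                    signals = None
                    break
                signals.append(peak_area_over(track, peak.chrom, peak.start, peak.end).area)
            else:
                if gemsa_peaks is None:
                    raise ValueError("called_peaks mode needs gemsa_peaks")
                peak = gemsa_peaks[c].get(o.name)
                signals.append(peak.area if peak is not None else 0.0)
        if signals is None:
            continue
        profiles.append(GemsaProfile(o.name, tuple(signals), mode))
    return profiles


# ---------------------------------------------------------------------------
# k-means clustering of the gEMSA signal matrix
# ---------------------------------------------------------------------------

def _kmeans_restarts(
    X: np.ndarray, k: int, restarts: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    """Batched Lloyd iterations from random-partition initialisations.

    All restarts run simultaneously; returns (labels of the best-SSE
    restart, best SSE).  Deterministic given the generator state.
    """
    n, d = X.shape
    assign = rng.integers(0, k, size=(restarts, n))
    # guarantee every cluster non-empty at init: place one point per cluster
    first = rng.permuted(np.tile(np.arange(n), (restarts, 1)), axis=1)[:, :k]
    for j in range(k):
        assign[np.arange(restarts), first[:, j]] = j
    active = np.ones(restarts, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        sub = assign[idx]  # (r, n)
        onehot = (sub[:, :, None] == np.arange(k)[None, None, :]).astype(float)
        counts = onehot.sum(axis=1)  # (r, k)
        sums = np.einsum("rnk,nd->rkd", onehot, X)
        safe = np.maximum(counts, 1.0)[:, :, None]
        centroids = sums / safe
        # an emptied cluster keeps no points: park its centroid far away so
        # it attracts nothing (the cluster count can shrink)
        centroids[counts == 0] = 1e12
        d2 = (
            (X**2).sum(axis=1)[None, :, None]
            - 2.0 * np.einsum("nd,rkd->rnk", X, centroids)
            + (centroids**2).sum(axis=2)[:, None, :]
        )
        new_assign = d2.argmin(axis=2)
        changed = (new_assign != sub).any(axis=1)
        assign[idx] = new_assign
        active[idx] = changed
    # final SSE per restart
    sse = np.empty(restarts)
    for r in range(restarts):
        lab = assign[r]
        s = 0.0
        for j in np.unique(lab):
            pts = X[lab == j]
            s += float(((pts - pts.mean(axis=0)) ** 2).sum())
        sse[r] = s
    best = int(np.argmin(sse))
    return assign[best], float(sse[best])


def cluster_gemsa(
    profiles: Sequence[GemsaProfile],
    k: int = 3,
    restarts: int = 10000,
    seed: int = 0,
) -> list[GemsaProfile]:
    """Cluster origins by their per-concentration gEMSA signal 3-vectors.

    Euclidean k-means with random-partition initialisation, ``restarts``
    restarts, best SSE kept.  Clusters are labelled Weak < Moderate <
    Strong by ascending centroid mean.  Origins are put into a canonical
    (name-sorted) order first, so the result is deterministic given the
    seed and invariant to input permutation.
    """
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} origins, got {len(profiles)}")
    ordered = sorted(profiles, key=lambda p: p.origin)
    X = np.array([p.signals for p in ordered], dtype=float)
    rng = np.random.default_rng(seed)
    labels, _ = _kmeans_restarts(X, k, restarts, rng)
    # map cluster ids to Weak/Moderate/Strong by ascending centroid mean
    present = np.unique(labels)
    means = {int(j): float(X[labels == j].mean()) for j in present}
    order = sorted(present, key=lambda j: means[int(j)])
    if len(order) == 3:
        names = dict(zip(order, CLUSTER_LABELS))
    else:  # degenerate solution with emptied clusters
        names = {j: CLUSTER_LABELS[min(i, 2)] for i, j in enumerate(order)}
    return [
        GemsaProfile(p.origin, p.signals, p.mode, names[int(lab)])
        for p, lab in zip(ordered, labels)
    ]


def best_sse(profiles: Sequence[GemsaProfile], k: int = 3, restarts: int = 100,
             seed: int = 0) -> float:
    """Best k-means SSE over the given restart budget (diagnostic)."""
    ordered = sorted(profiles, key=lambda p: p.origin)
    X = np.array([p.signals for p in ordered], dtype=float)
    rng = np.random.default_rng(seed)
    _, sse = _kmeans_restarts(X, k, restarts, rng)
    return sse


# ---------------------------------------------------------------------------
# Joint classification
# ---------------------------------------------------------------------------

def classify_joint(
    affinities: Sequence[InVivoAffinity],
    profiles: Sequence[GemsaProfile],
    exclusions: Iterable[str] = (),
) -> list[OriginClassification]:
    """gEMSA-cluster route.

    chromatin_dependent = resistant and Weak cluster;
    dna_dependent = resistant and (Moderate or Strong);
    weak = sensitive and Weak cluster; everything else unclassified.
    Core-X telomeric origins in ``exclusions`` are dropped.
    """
    excl = set(exclusions)
    cluster_of = {p.origin: p.cluster for p in profiles}
    out = []
    for a in affinities:
        if a.origin in excl:
            continue
        cluster = cluster_of.get(a.origin)
        if a.unclassifiable or cluster is None:
            call = "unclassified"
        elif a.ratio_class == "resistant" and cluster == "Weak":
            call = "chromatin_dependent"
        elif a.ratio_class == "resistant" and cluster in ("Moderate", "Strong"):
            call = "dna_dependent"
        elif a.ratio_class == "sensitive" and cluster == "Weak":
            call = "weak"
        else:
            call = "unclassified"
        out.append(OriginClassification(a.origin, call, "gemsa_clusters"))
    return out


def classify_by_emsa(
    affinities: Sequence[InVivoAffinity],
    kd_folds: Mapping[str, float],
    exclusions: Iterable[str] = (),
) -> list[OriginClassification]:
    """EMSA-threshold route.

    Among resistant origins: fold <= 3 -> dna_dependent; fold > 10 or
    censored (infinite fold) -> chromatin_dependent; 3 < fold <= 10 ->
    complex (some combination of intrinsic DNA and extrinsic chromatin
    interactions).  Sensitive origins with fold > 4 -> weak.  Everything
    else is unclassified.
    """
    excl = set(exclusions)
    out = []
    for a in affinities:
        if a.origin in excl:
            continue
        fold = kd_folds.get(a.origin)
        if a.unclassifiable or fold is None:
            call = "unclassified"
        elif a.ratio_class == "resistant":
            if fold > 10 or np.isinf(fold):
                call = "chromatin_dependent"
            elif fold <= 3:
                call = "dna_dependent"
            else:
                call = "complex"
        elif a.ratio_class == "sensitive" and fold > 4:
            call = "weak"
        else:
            call = "unclassified"
        out.append(OriginClassification(a.origin, call, "emsa_thresholds"))
    return out
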