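"""Track normalisation, sliding-window peak calling and interval summaries.

The peak caller follows the classic tiled-array procedure: windows of 240 bp
tiled every 60 bp, a Gaussian null whose width is estimated by reflecting
the negative half of the probe-value distribution about zero, one-sided
window p-values Bonferroni-corrected over every evaluated window genome-wide,
and merging of overlapping or book-ended significant windows into peaks.
The peak area is the sum of the probe log2 signals inside the merged span.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.stats import norm

from .tracks_io import OriginAnnotation, ProbeTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakCallConfig:
    window: int = 240
    step: int = 60
    p_cutoff: float = 1e-5
    min_probes: int = 2

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if not (0.0 < self.p_cutoff < 1.0):
            raise ValueError("p_cutoff must be in (0, 1)")


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    area: float
    p_value: float
    n_probes: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("peak start must be < end")
        if not math.isfinite(self.area):
            raise ValueError("peak area must be finite")


class AreaResult(NamedTuple):
    area: float
    n_probes: int

    @property
    def empty(self) -> bool:
        return self.n_probes == 0


def normalize_track(track: ProbeTrack, repetitive_fraction: float = 0.011) -> ProbeTrack:
    """Centre a raw track and drop the most repetitive probes.

    The top ``repetitive_fraction`` of probes by |value| (track-wide) are
    removed — these are dominated by repeated sequence that hybridises
    promiscuously — then the median of the retained values is subtracted so
    the background centres on zero.
    """
    chrom_order = sorted(track.chroms)
    if not chrom_order:
        raise ValueError("cannot normalise an empty track")
    sizes = [track.chroms[c][0].size for c in chrom_order]
    values = np.concatenate([track.chroms[c][1] for c in chrom_order])
    if values.size == 0:
        raise ValueError("cannot normalise an empty track")
    n_remove = int(round(values.size * repetitive_fraction))
    keep = np.ones(values.size, dtype=bool)
    if n_remove > 0:
        # remove exactly n_remove probes; stable sort breaks |value| ties
        # deterministically by (chromosome, position) order
        keep[np.argsort(-np.abs(values), kind="stable")[:n_remove]] = False
    med = float(np.median(values[keep]))
    out = ProbeTrack(track.condition)
    offset = 0
    for chrom, size in zip(chrom_order, sizes):
        mask = keep[offset : offset + size]
        mids, vals = track.chroms[chrom]
        out.chroms[chrom] = (mids[mask], vals[mask] - med)
        offset += size
    return out


def estimate_null_sd(values: np.ndarray) -> float:
    """Null probe SD by reflecting the negative half of the distribution.

    After centring, negative values are assumed to be pure background; the
    symmetric null SD is the RMS of the negative values.
    """
    negs = values[values < 0]
    if negs.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(negs**2)))


def _window_stats(mids: np.ndarray, vals: np.ndarray, cfg: PeakCallConfig):
    """Tile windows over one chromosome; return starts, mean, n per window."""
    if mids.size == 0:
        return (np.empty(0, dtype=np.int64),) * 3
    last = int(mids[-1])
    starts = np.arange(0, last + 1, cfg.step, dtype=np.int64)
    lo = np.searchsorted(mids, starts, side="left")
    hi = np.searchsorted(mids, starts + cfg.window, side="left")
    n = hi - lo
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    sums = csum[hi] - csum[lo]
    keep = n >= cfg.min_probes
    means = np.zeros_like(sums)
    means[keep] = sums[keep] / n[keep]
    return starts[keep], means[keep], n[keep]


def call_peaks(track: ProbeTrack, cfg: PeakCallConfig | None = None) -> list[Peak]:
    """Call binding peaks on a normalised track.

    Windows with at least ``min_probes`` probes are scored by their mean
    probe value against a Gaussian null with SD sigma/sqrt(n_w); the
    one-sided p is Bonferroni-multiplied by the number of evaluated windows
    genome-wide.  Significant windows that overlap or are book-ended merge
    into peaks; the peak p-value is the best member window p and the area is
    the sum of probe values in the merged span.
    """
    cfg = cfg or PeakCallConfig()
    sigma = estimate_null_sd(track.values())
    per_chrom = {}
    n_windows = 0
    for chrom in sorted(track.chroms):
        mids, vals = track.chroms[chrom]
        if mids.size == 0:
            logger.info("no probes on %s; skipping", chrom)
            continue
        starts, means, n = _window_stats(mids, vals, cfg)
        per_chrom[chrom] = (starts, means, n)
        n_windows += starts.size
    peaks: list[Peak] = []
    for chrom, (starts, means, n) in per_chrom.items():
        if sigma == 0.0:
            raw_p = np.where(means > 0, 0.0, 1.0)
        else:
            z = means / (sigma / np.sqrt(n))
            raw_p = norm.sf(z)
        corr_p = np.minimum(raw_p * n_windows, 1.0)
        sig = corr_p <= cfg.p_cutoff
        if not np.any(sig):
            continue
        s_starts = starts[sig]
        s_p = corr_p[sig]
        mids, vals = track.chroms[chrom]
        # merge overlapping / book-ended significant windows
        run_start = int(s_starts[0])
        run_end = run_start + cfg.window
        run_p = float(s_p[0])
        for st, p in zip(s_starts[1:], s_p[1:]):
            st = int(st)
            if st <= run_end:
                run_end = st + cfg.window
                run_p = min(run_p, float(p))
            else:
                peaks.append(_make_peak(chrom, run_start, run_end, run_p, mids, vals))
                run_start, run_end, run_p = st, st + cfg.window, float(p)
        peaks.append(_make_peak(chrom, run_start, run_end, run_p, mids, vals))
    return peaks


def _make_peak(chrom, start, end, p, mids, vals) -> Peak:
    lo = np.searchsorted(mids, start, side="left")
    hi = np.searchsorted(mids, end, side="left")
    return Peak(chrom, start, end, float(vals[lo:hi].sum()), p, int(hi - lo))


def peak_area_over(track: ProbeTrack, chrom: str, start: int, end: int) -> AreaResult:
    """Sum of probe values with midpoint in [start, end); may be negative.

    Regions depleted relative to background legitimately yield negative
    areas.  Zero covered probes gives area 0 with the ``empty`` flag set.
    """
    _, vals = track.probes_in(chrom, start, end)
    return AreaResult(float(vals.sum()), int(vals.size))


# ---------------------------------------------------------------------------
# Interval overlap summaries
# ---------------------------------------------------------------------------

Interval = tuple[str, int, int]


def _merge(intervals: Iterable[Interval]) -> dict[str, np.ndarray]:
    """Merge intervals per chromosome into disjoint sorted [start, end) pairs."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        if s >= e:
            raise ValueError(f"degenerate interval {chrom}:{s}-{e}")
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=np.int64)
    return merged


def _overlap_bp(merged: dict[str, np.ndarray], chrom: str, start: int, end: int) -> int:
    if chrom not in merged:
        return 0
    ivs = merged[chrom]
    lo = np.maximum(ivs[:, 0], start)
    hi = np.minimum(ivs[:, 1], end)
    return int(np.clip(hi - lo, 0, None).sum())


def overlap_fraction(peaks: Sequence[Peak], features: Sequence[Interval]) -> float:
    """Fraction of features with >= 1 bp intersection with any peak."""
    if not features:
        raise ValueError("no features supplied")
    merged = _merge((p.chrom, p.start, p.end) for p in peaks) if peaks else {}
    hit = sum(1 for c, s, e in features if _overlap_bp(merged, c, s, e) > 0)
    return hit / len(features)


def bp_composition(
    peaks: Sequence[Peak],
    annotation_sets: Sequence[tuple[str, Sequence[Interval]]],
) -> dict[str, float]:
    """Partition peak base pairs across a priority-ordered annotation list.

    Each peak bp is assigned to the first annotation class (in the given
    order) that covers it; uncovered bases fall into ``"other"``.  Returns
    fractions of total peak bp per class.
    """
    merged_peaks = _merge((p.chrom, p.start, p.end) for p in peaks)
    total = sum(int((ivs[:, 1] - ivs[:, 0]).sum()) for ivs in merged_peaks.values())
    if total == 0:
        raise ValueError("no peak base pairs")
    remaining = {c: ivs.copy() for c, ivs in merged_peaks.items()}
    result: dict[str, float] = {}
    for label, features in annotation_sets:
        feat = _merge(features) if features else {}
        assigned = 0
        new_remaining: dict[str, np.ndarray] = {}
        for chrom, ivs in remaining.items():
            pieces = []
            for s, e in ivs:
                s, e = int(s), int(e)
                if chrom not in feat:
                    pieces.append((s, e))
                    continue
                cur = s
                for fs, fe in feat[chrom]:
                    fs, fe = max(int(fs), s), min(int(fe), e)
                    if fs >= fe or fe <= cur:
                        continue
                    if fs > cur:
                        pieces.append((cur, fs))
                    assigned += fe - max(fs, cur)
                    cur = fe
                if cur < e:
                    pieces.append((cur, e))
            if pieces:
                new_remaining[chrom] = np.array(pieces, dtype=np.int64)
        result[label] = assigned / total
        remaining = new_remaining
    result["other"] = sum(
        int((ivs[:, 1] - ivs[:, 0]).sum()) for ivs in remaining.values()
    ) / total
    return result


def assign_peaks_to_origins(
    peaks: Sequence[Peak], origins: Sequence[OriginAnnotation]
) -> dict[str, Peak]:
    """Assign each peak to the origin with the largest bp overlap.

    Ties break by smaller midpoint distance, then lexicographic origin name.
    Returns origin name -> peak; when several peaks map to one origin the
    peak with the larger overlap (same tie-breaks) wins.
    """
    best: dict[str, tuple[int, int, Peak]] = {}
    for peak in peaks:
        candidates = []
        pk_mid = (peak.start + peak.end) // 2
        for o in origins:
            if o.chrom != peak.chrom:
                continue
            ov = min(peak.end, o.end) - max(peak.start, o.start)
            if ov > 0:
                candidates.append((-ov, abs(pk_mid - o.midpoint), o.name, o))
        if not candidates:
            continue
        candidates.sort()
        neg_ov, dist, name, origin = candidates[0]
        prev = best.get(name)
        if prev is None or (neg_ov, dist) < (-(prev[0]), prev[1]):
            best[name] = (-neg_ov, dist, peak)
    return {name: rec[2] for name, rec in best.items()}
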