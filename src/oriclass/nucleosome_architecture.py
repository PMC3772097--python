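"""Nucleosome occupancy around ORC binding sites: anchored profiles,
nucleosome-depleted-region (NDR) calling and condition deltas.

Profiles are anchored on the start of the EACS on the T-rich strand and
oriented so that +x points 3' of it; minus-strand origins are
coordinate-flipped before averaging.  Signals are binned at 4 bp.  The NDR
of an origin is the gap in base pairs between the end of the -1 nucleosome
and the start of the +1 nucleosome, where nucleosomes are maximal runs of
occupancy above a threshold (a configurable fraction of the track median).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .tracks_io import OriginAnnotation, ProbeTrack


@dataclass(frozen=True)
class AnchoredProfile:
    group: str
    bin_centers: np.ndarray  # relative bp, +x is 3' of the EACS start
    mean_signal: np.ndarray  # NaN where no data fell in a bin
    n_origins: int


@dataclass(frozen=True)
class NdrMeasurement:
    origin: str
    ndr_width: float  # bp; NaN when unbounded
    minus1_end: float  # relative coordinate of the -1 nucleosome end
    plus1_start: float  # relative coordinate of the +1 nucleosome start
    unbounded: bool = False


def anchored_signal(
    track: ProbeTrack, origin: OriginAnnotation, span: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Signal around one origin in anchor-relative, strand-flipped
    coordinates (sorted ascending); origins lacking an ACS raise."""
    if origin.acs_pos is None or origin.acs_strand is None:
        raise ValueError(f"{origin.name}: no ACS anchor")
    pos, vals = track.probes_in(
        origin.chrom, origin.acs_pos - span, origin.acs_pos + span + 1
    )
    rel = pos - origin.acs_pos
    if origin.acs_strand == "-":
        rel = -rel
    order = np.argsort(rel)
    return rel[order], vals[order]


def anchor_profiles(
    track: ProbeTrack,
    origins: Sequence[OriginAnnotation],
    group: str = "origins",
    span: int = 1000,
    bin_width: int = 4,
) -> AnchoredProfile:
    """Average anchored signal over an origin group, binned at ``bin_width``.

    Origins lacking a predicted ACS are omitted; an empty group after
    omission is an error.
    """
    n_bins = (2 * span) // bin_width
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    used = 0
    for o in origins:
        if o.acs_pos is None or o.acs_strand is None:
            continue
        rel, vals = anchored_signal(track, o, span)
        mask = (rel >= -span) & (rel < -span + n_bins * bin_width)
        idx = (rel[mask] + span) // bin_width
        np.add.at(sums, idx, vals[mask])
        np.add.at(counts, idx, 1.0)
        used += 1
    if used == 0:
        raise ValueError(f"group {group!r}: no origins with an ACS anchor")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)
    centers = -span + bin_width * np.arange(n_bins) + bin_width / 2
    return AnchoredProfile(group, centers, mean, used)


def _runs_above(positions: np.ndarray, values: np.ndarray, threshold: float):
    """Maximal runs of consecutive samples above the threshold; returns a
    list of (start_rel, end_rel) using half-open sample spans."""
    above = values > threshold
    runs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((int(positions[start]), int(positions[i - 1]) + 1))
            start = None
    if start is not None:
        runs.append((int(positions[start]), int(positions[-1]) + 1))
    return runs


def call_ndr(
    rel_positions: np.ndarray,
    values: np.ndarray,
    origin: str = "",
    occupancy_threshold: float = 0.5,
    track_median: float | None = None,
    search_window: int = 600,
) -> NdrMeasurement:
    """Call the NDR from an anchored occupancy signal.

    The +1 nucleosome is the first above-threshold run starting at or 3' of
    the anchor (within ``search_window``); the -1 nucleosome is the last
    run ending at or before the +1 start.  The NDR width is
    plus1_start - minus1_end.  If either flanking nucleosome is missing the
    measurement is flagged unbounded.
    """
    if track_median is None:
        track_median = float(np.median(values))
    threshold = occupancy_threshold * track_median
    mask = (rel_positions >= -search_window) & (rel_positions <= search_window)
    pos, vals = rel_positions[mask], values[mask]
    if pos.size == 0:
        return NdrMeasurement(origin, float("nan"), float("nan"), float("nan"), True)
    runs = _runs_above(pos, vals, threshold)
    plus1 = next((r for r in runs if r[0] >= 0), None)
    if plus1 is None:
        return NdrMeasurement(origin, float("nan"), float("nan"), float("nan"), True)
    minus_candidates = [r for r in runs if r[1] <= plus1[0]]
    if not minus_candidates:
        return NdrMeasurement(origin, float("nan"), float("nan"), float(plus1[0]), True)
    minus1 = minus_candidates[-1]
    width = float(plus1[0] - minus1[1])
    return NdrMeasurement(origin, width, float(minus1[1]), float(plus1[0]))


def measure_ndrs(
    track: ProbeTrack,
    origins: Sequence[OriginAnnotation],
    occupancy_threshold: float = 0.5,
    span: int = 1000,
    search_window: int = 600,
) -> dict[str, NdrMeasurement]:
    """Per-origin NDR widths against the whole-track median occupancy."""
    med = float(np.median(track.values()))
    out = {}
    for o in origins:
        if o.acs_pos is None or o.acs_strand is None:
            continue
        rel, vals = anchored_signal(track, o, span)
        out[o.name] = call_ndr(
            rel, vals, o.name, occupancy_threshold, med, search_window
        )
    return out


def welch_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test; the degenerate case (zero variance in both
    groups, equal means) returns (0, 1) by convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def delta_ndr(
    wt: Mapping[str, NdrMeasurement],
    mutant: Mapping[str, NdrMeasurement],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-origin NDR change (wt - mutant) with group labels.

    Origins missing from either condition, unbounded in either, or absent
    from ``groups`` are dropped.
    """
    rows = []
    for name, w in wt.items():
        m = mutant.get(name)
        if m is None or w.unbounded or m.unbounded or name not in groups:
            continue
        rows.append(
            {
                "origin": name,
                "group": groups[name],
                "wt_width": w.ndr_width,
                "mutant_width": m.ndr_width,
                "delta": w.ndr_width - m.ndr_width,
            }
        )
    if not rows:
        raise ValueError("no matched origins between conditions")
    return pd.DataFrame(rows).set_index("origin")


def compare_group_deltas(
    deltas: pd.DataFrame, group_a: str, group_b: str
) -> tuple[float, float, float]:
    """Difference in mean NDR change between two groups with a two-sided
    Welch t-test; returns (mean_a - mean_b, t, p)."""
    a = deltas.loc[deltas["group"] == group_a, "delta"].to_numpy()
    b = deltas.loc[deltas["group"] == group_b, "delta"].to_numpy()
    t, p = welch_test(a, b)
    return float(a.mean() - b.mean()), t, p
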