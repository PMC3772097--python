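"""Association between origin classes and replication timing phenotypes.

Covers group Trep comparisons (Welch t-tests), in-vivo vs in-vitro affinity
correlations (Pearson and Spearman), hydroxyurea (HU) firing-status
analysis with the two-study combination rule, and hypergeometric set
overlaps.  Early-firing origins resist HU; late origins fire in HU only
when the Rad53 checkpoint is inactivated, so an origin's HU class is a
coarse proxy for its activation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom, pearsonr, spearmanr

from .nucleosome_architecture import welch_test

HU_STATUSES = ("HUr_WT", "HUr_rad53", "unknown")
STUDY_CALLS = ("fires_WT", "fires_rad53_only", "not_detected")

#: Trep thresholds (minutes) defining the earliest- and latest-firing subsets.
EARLY_TREP_MAX = 20.0
LATE_TREP_MIN = 30.0


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float


def combine_hu_status(study1: str, study2: str) -> str:
    """Combine two studies' HU-firing calls for one origin.

    Firing in HU in wild-type cells in either study makes the origin
    HU-resistant (HUr_WT); otherwise firing only in rad53 mutant cells in
    one or both studies makes it HU-sensitive (HUr_rad53); otherwise
    unknown.
    """
    for call in (study1, study2):
        if call not in STUDY_CALLS:
            raise ValueError(f"unknown study call {call!r}")
    if "fires_WT" in (study1, study2):
        return "HUr_WT"
    if "fires_rad53_only" in (study1, study2):
        return "HUr_rad53"
    return "unknown"


def group_trep_test(
    treps: Mapping[str, Sequence[float]], group_a: str, group_b: str
) -> GroupComparison:
    """Welch two-sided t-test on Trep values between two origin groups.

    Origins without a Trep must already be excluded; groups need >= 2
    values each.
    """
    a = np.asarray(treps[group_a], dtype=float)
    b = np.asarray(treps[group_b], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 Trep values per group")
    t, p = welch_test(a, b)
    return GroupComparison(
        group_a, group_b, float(a.mean()), float(b.mean()), a.size, b.size, t, p
    )


def affinity_correlation(
    in_vivo: Sequence[float], in_vitro: Sequence[float]
) -> dict[str, float]:
    """Pearson and Spearman correlation between paired in-vivo ratios and
    in-vitro (total gEMSA or Kd) affinity measures.

    Two-sided p-values; ranks are tie-averaged.  Zero variance in either
    variable is flagged (NaN coefficients).
    """
    x = np.asarray(in_vivo, dtype=float)
    y = np.asarray(in_vitro, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values; filter pairs first")
    if np.var(x) == 0 or np.var(y) == 0:
        return {"pearson_r": float("nan"), "pearson_p": float("nan"),
                "spearman_rho": float("nan"), "spearman_p": float("nan"),
                "n": int(x.size)}
    pr, pp = pearsonr(x, y)
    sr, sp = spearmanr(x, y)
    return {
        "pearson_r": float(pr),
        "pearson_p": float(pp),
        "spearman_rho": float(sr),
        "spearman_p": float(sp),
        "n": int(x.size),
    }


def contingency_distribution(
    hu_by_origin: Mapping[str, str], group_members: Iterable[str]
) -> dict[str, object]:
    """HU-status counts for a group against all other origins, with a
    two-tailed Fisher exact P.

    Origins with unknown status are excluded.  The 2x2 table is
    (HUr_WT vs HUr_rad53) x (group vs rest).
    """
    members = set(group_members)
    known = {o: s for o, s in hu_by_origin.items() if s != "unknown"}
    g_wt = sum(1 for o in members if known.get(o) == "HUr_WT")
    g_rad = sum(1 for o in members if known.get(o) == "HUr_rad53")
    r_wt = sum(1 for o, s in known.items() if o not in members and s == "HUr_WT")
    r_rad = sum(1 for o, s in known.items() if o not in members and s == "HUr_rad53")
    if g_wt + g_rad == 0:
        raise ValueError("group has no origins with known HU status")
    table = [[g_wt, g_rad], [r_wt, r_rad]]
    p = float(fisher_exact(table, alternative="two-sided")[1])
    return {
        "group_HUr_WT": g_wt,
        "group_HUr_rad53": g_rad,
        "rest_HUr_WT": r_wt,
        "rest_HUr_rad53": r_rad,
        "fisher_p": p,
    }


def hypergeometric_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric P for the overlap of two origin sets.

    P(X >= |A intersect B|) drawing |B| from a universe containing |A|
    successes.  Sets must be subsets of the universe.
    """
    u = set(universe)
    a = set(set_a)
    b = set(set_b)
    if not (a <= u and b <= u):
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    return float(hypergeom.sf(k - 1, len(u), len(a), len(b)))


# ---------------------------------------------------------------------------
# Timing table I/O and study-level association report
# ---------------------------------------------------------------------------

def read_timing_table(path: str | Path) -> pd.DataFrame:
    """Read a timing CSV (origin, trep_min, hu_study1, hu_study2, ...) and
    derive the combined HU status."""
    df = pd.read_csv(path).set_index("origin", drop=False)
    if {"hu_study1", "hu_study2"} <= set(df.columns):
        df["hu_status"] = [
            combine_hu_status(s1, s2)
            for s1, s2 in zip(df["hu_study1"], df["hu_study2"])
        ]
    return df


def timing_report(
    timing: pd.DataFrame,
    classes: Mapping[str, str],
    pairs: Sequence[tuple[str, str]] = (
        ("chromatin_dependent", "dna_dependent"),
        ("weak", "chromatin_dependent"),
    ),
) -> dict[str, object]:
    """Group mean Treps with pairwise Welch tests and HU contingencies."""
    df = timing.copy()
    df["call"] = [classes.get(o) for o in df.index]
    df = df[df["call"].notna()]
    if "hu_status" not in df.columns:
        df["hu_status"] = [
            combine_hu_status(s1, s2)
            for s1, s2 in zip(df["hu_study1"], df["hu_study2"])
        ]
    treps = {
        cls: grp["trep_min"].dropna().to_numpy()
        for cls, grp in df.groupby("call")
    }
    report: dict[str, object] = {"group_mean_trep": {
        cls: float(v.mean()) for cls, v in treps.items() if v.size
    }}
    for a, b in pairs:
        if a in treps and b in treps and treps[a].size >= 2 and treps[b].size >= 2:
            report[f"trep_{a}_vs_{b}"] = group_trep_test(treps, a, b)
    hu = dict(zip(df.index, df["hu_status"]))
    for cls in sorted(set(df["call"])):
        members = df.index[df["call"] == cls]
        try:
            report[f"hu_{cls}"] = contingency_distribution(hu, members)
        except ValueError:
            pass
    return report
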