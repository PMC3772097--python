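"""Apparent-Kd estimation from EMSA titrations and Kd-threshold rules.

The binding model is the one-site hyperbola with Bmax fixed at 1,

    theta(c) = c / (Kd + c),

fitted by least squares to (ORC concentration, fraction bound) points.
Estimates above a censor bound (default 420 nM, just above the largest
reliably measurable Kd with titrations up to 30 nM) are reported as
censored ("ND" / "> bound"): binding too weak to determine an apparent Kd.
Apparent Kds are normalised to a reference origin (the high-affinity
ARS317/HMR-E site in the reference panel) and classified against fold
thresholds (tight <= 3x, weak > 4x, > 5x, very weak > 10x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_CENSOR_BOUND = 420.0


@dataclass(frozen=True)
class TitrationCurve:
    """One EMSA titration: (conc nM, fraction bound) points for one origin."""

    origin: str
    points: tuple[tuple[float, float], ...]
    replicate: int = 1

    def __post_init__(self) -> None:
        pts = tuple((float(c), float(f)) for c, f in self.points)
        object.__setattr__(self, "points", pts)
        concs = {c for c, _ in pts}
        if len(concs) < 3:
            raise ValueError(
                f"{self.origin}: need >= 3 distinct concentrations, got {len(concs)}"
            )
        if any(c < 0 for c in concs):
            raise ValueError(f"{self.origin}: negative concentration")
        if any(not (0.0 <= f <= 1.0) for _, f in pts):
            raise ValueError(f"{self.origin}: fraction bound outside [0, 1]")

    @property
    def concs(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.points])


@dataclass(frozen=True)
class KdEstimate:
    """A fitted apparent dissociation constant in nM.

    ``censored`` marks estimates where binding was too weak to determine an
    apparent Kd (ND); censored estimates compare as greater than any finite
    threshold.  ``kd`` holds the censor bound for censored estimates so that
    comparisons are well defined.
    """

    kd: float
    stderr: float = float("nan")
    censored: bool = False
    censor_bound: float | None = None

    def __post_init__(self) -> None:
        if not self.censored and not (self.kd > 0):
            raise ValueError("kd must be positive for an uncensored estimate")

    def exceeds(self, threshold_nm: float) -> bool:
        """kd > threshold, with censored estimates exceeding everything."""
        return True if self.censored else self.kd > threshold_nm


def hyperbola(conc, kd):
    """One-site binding hyperbola with Bmax = 1."""
    conc = np.asarray(conc, dtype=float)
    return conc / (kd + conc)


def fit_apparent_kd(
    curve: TitrationCurve, censor_bound: float = DEFAULT_CENSOR_BOUND
) -> KdEstimate:
    """Least-squares fit of theta(c) = c/(Kd + c) to one titration.

    Degenerate all-near-zero data yields a censored estimate (ND), never an
    exception.  The standard error comes from the curvature of the fit.
    """
    c = curve.concs
    f = curve.fractions
    if np.all(f < 1e-12):
        return KdEstimate(censor_bound, float("nan"), True, censor_bound)
    # Initial guess: concentration at half saturation, from the largest
    # observed fraction (bounded away from 0 and 1).
    fmax = min(max(float(f.max()), 1e-3), 0.999)
    k0 = float(c.max()) * (1 - fmax) / fmax
    k0 = min(max(k0, 1e-3), 1e5)
    try:
        popt, pcov = curve_fit(
            hyperbola, c, f, p0=[k0], bounds=(1e-9, 1e9), maxfev=10000
        )
    except RuntimeError:
        return KdEstimate(censor_bound, float("nan"), True, censor_bound)
    kd = float(popt[0])
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    if kd > censor_bound:
        return KdEstimate(censor_bound, stderr, True, censor_bound)
    return KdEstimate(kd, stderr, False, censor_bound)


def fit_replicates(
    curves: Sequence[TitrationCurve], censor_bound: float = DEFAULT_CENSOR_BOUND
) -> KdEstimate:
    """Fit each replicate independently; report mean +/- SEM of the Kds.

    If any replicate is censored the pooled estimate is censored (binding
    too weak to determine reliably).
    """
    if not curves:
        raise ValueError("no replicate curves supplied")
    fits = [fit_apparent_kd(cv, censor_bound) for cv in curves]
    if any(f.censored for f in fits):
        return KdEstimate(censor_bound, float("nan"), True, censor_bound)
    kds = np.array([f.kd for f in fits])
    sem = float(kds.std(ddof=1) / math.sqrt(len(kds))) if len(kds) > 1 else fits[0].stderr
    return KdEstimate(float(kds.mean()), sem, False, censor_bound)


def normalize_kd(est: KdEstimate, reference: KdEstimate) -> float:
    """Fold affinity relative to a reference origin: kd / reference kd.

    A censored input gives an infinite (censored) fold, which satisfies
    every '>' threshold.  A censored reference is an error.
    """
    if reference.censored:
        raise ValueError("reference Kd is censored; cannot normalise")
    if est.censored:
        return float("inf")
    return est.kd / reference.kd


#: Default fold thresholds relative to the reference origin.
DEFAULT_FOLD_THRESHOLDS = {"tight": 3.0, "weak4": 4.0, "weak5": 5.0, "very_weak": 10.0}

KD_CLASSES = ("tight", "intermediate", "weak4x", "weak5x", "very_weak10x")


def kd_threshold_class(
    fold: float, thresholds: dict[str, float] | None = None
) -> str:
    """Classify a normalised Kd fold into affinity bands.

    tight: fold <= 3; intermediate: 3 < fold <= 4; weak4x: 4 < fold <= 5;
    weak5x: 5 < fold <= 10; very_weak10x: fold > 10 (censored folds land
    here, as infinite folds satisfy every '>' threshold).
    """
    t = {**DEFAULT_FOLD_THRESHOLDS, **(thresholds or {})}
    if fold <= t["tight"]:
        return "tight"
    if fold <= t["weak4"]:
        return "intermediate"
    if fold <= t["weak5"]:
        return "weak4x"
    if fold <= t["very_weak"]:
        return "weak5x"
    return "very_weak10x"


# ---------------------------------------------------------------------------
# CSV titration I/O (origin, conc_nM, fraction_bound, replicate)
# ---------------------------------------------------------------------------

def read_titrations(path: str | Path) -> list[TitrationCurve]:
    df = pd.read_csv(path)
    required = {"origin", "conc_nM", "fraction_bound", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for (origin, rep), grp in df.groupby(["origin", "replicate"], sort=True):
        pts = tuple(zip(grp["conc_nM"], grp["fraction_bound"]))
        curves.append(TitrationCurve(str(origin), pts, int(rep)))
    return curves


def write_titrations(curves: Iterable[TitrationCurve], path: str | Path) -> None:
    rows = [
        {"origin": cv.origin, "conc_nM": c, "fraction_bound": f, "replicate": cv.replicate}
        for cv in curves
        for c, f in cv.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
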