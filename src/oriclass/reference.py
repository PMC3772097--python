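"""Bundled reference panels of published yeast origin measurements.

Two curated EMSA panels ship with the package: a 40-origin panel pairing
each origin's in-vivo orc2-1/ORC2 ChIP peak-area ratio with its apparent
ORC-DNA Kd (the high-affinity ARS317/HMR-E site, apparent Kd 7.223 nM, is
the normalisation reference), and a 20-origin gEMSA-derived
chromatin-dependent panel of which seven origins with confirmed ORC
binding sites were EMSA-tested for validation.  A small table of 11-bp ACS
motif match counts per region set supports the density-fold arithmetic.

The 40-origin panel's ``panel`` column records the published study design:
18 low-ratio origins (ratio <= 0.3; the predicted-ACS origin ARS1215 was
assayed but sits outside the defined panel), ARS416 representing the
moderate band, and 20 high-ratio origins (ratio >= 0.8).  "ND" marks
binding too weak to determine an apparent Kd.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .emsa_affinity import KdEstimate, normalize_kd
from .motif_enrichment import density_fold
from .origin_classification import ratio_class

REFERENCE_ORIGIN = "ARS317"


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("oriclass.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, keep_default_na=False, na_values=[""])


def load_emsa_panel() -> pd.DataFrame:
    """The 40-origin EMSA reference panel (ratios, apparent Kds, panel)."""
    return _load_csv("emsa_reference_panel.csv").set_index("origin", drop=False)


def load_gemsa_validation_panel() -> pd.DataFrame:
    """The 20 gEMSA-derived chromatin-dependent origins with validation Kds."""
    return _load_csv("gemsa_validation_panel.csv").set_index("origin", drop=False)


def load_acs_match_counts() -> pd.DataFrame:
    """11-bp ACS match counts and region sizes per data set."""
    return _load_csv("acs_match_counts.csv").set_index("dataset", drop=False)


def _estimate(row) -> KdEstimate | None:
    raw = row["kd_nM"]
    if raw == "ND":
        return KdEstimate(420.0, float("nan"), censored=True, censor_bound=420.0)
    if raw == "" or (isinstance(raw, float) and np.isnan(raw)):
        return None  # not tested
    return KdEstimate(float(raw), float(row.get("kd_stderr_nM") or "nan"))


def panel_with_folds(panel: pd.DataFrame) -> pd.DataFrame:
    """Annotate a panel with Kd folds over ARS317 and affinity classes.

    Censored (ND) Kds yield infinite folds, which exceed every threshold.
    Untested origins get NaN folds.
    """
    emsa = load_emsa_panel()
    reference = _estimate(emsa.loc[REFERENCE_ORIGIN])
    out = panel.copy()
    estimates = [_estimate(row) for _, row in panel.iterrows()]
    out["censored"] = [e is not None and e.censored for e in estimates]
    out["fold_vs_reference"] = [
        normalize_kd(e, reference) if e is not None else float("nan")
        for e in estimates
    ]
    out["ratio_class"] = [ratio_class(r) for r in out["orc21_orc2_ratio"]]
    return out


def panel_affinity_counts() -> dict[str, int]:
    """Threshold-classification counts over the EMSA reference panel.

    Returns the number of tight (fold <= 3x) origins among the 20
    high-ratio panel origins; weak (> 4x) and weak (> 5x) origins among
    the low-ratio panel origins with determinable Kds; and very weak
    (> 10x, ND counted) origins among the high-ratio panel origins.
    """
    df = panel_with_folds(load_emsa_panel())
    high = df[df["panel"] == "high"]
    low = df[df["panel"] == "low"]
    fold = df["fold_vs_reference"]
    return {
        "tight_high": int(((high["fold_vs_reference"] <= 3) & ~high["censored"]).sum()),
        "weak4x_low": int(
            ((low["fold_vs_reference"] > 4) & ~low["censored"]).sum()
        ),
        "weak5x_low": int(
            ((low["fold_vs_reference"] > 5) & ~low["censored"]).sum()
        ),
        "very_weak10x_high": int((high["fold_vs_reference"] > 10).sum()),
        "n_high": int(len(high)),
        "n_low": int(len(low)),
    }


def validation_panel_counts() -> dict[str, int]:
    """How many newly EMSA-tested gEMSA-derived chromatin-dependent origins
    exceed 4x the reference Kd (censored Kds count as exceeding)."""
    df = panel_with_folds(load_gemsa_validation_panel())
    tested = df[df["newly_tested"] == 1]
    return {
        "n_newly_tested": int(len(tested)),
        "exceed_4x": int((tested["fold_vs_reference"] > 4).sum()),
    }


def acs_density_folds() -> dict[str, float]:
    """ACS match-density folds over the genome for each bundled region set."""
    counts = load_acs_match_counts()
    genome = counts.loc["genome"]
    out = {}
    for dataset, row in counts.iterrows():
        if dataset == "genome":
            continue
        out[dataset] = density_fold(
            int(row["matches"]), float(row["region_bp"]),
            int(genome["matches"]), float(genome["region_bp"]),
        )
    return out
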