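"""Synthetic study generator with planted per-origin binding mechanisms.

The generator emulates the complete measurement design around origin
classification: a genome with planted ORC binding sites (ACS instances), a
wild-type and an ORC-depleted ChIP track, naked-DNA binding (gEMSA) tracks
at three ORC concentrations, per-origin EMSA titrations, nucleosome
occupancy tracks in wild-type and ORC-loss conditions, and a replication
timing table — all driven by a per-origin ground truth.

Binding model
-------------
Equilibrium one-site occupancy theta(c, kd) = c / (c + kd).  Each origin
carries an intrinsic ORC-DNA dissociation constant ``kd_dna`` (what naked
DNA shows in vitro) and a ``chromatin_boost`` >= 1 that divides it to give
the effective in-vivo constant ``kd_eff = kd_dna / boost``.  In-vitro
(gEMSA, titration) signals depend on ``kd_dna`` only; in-vivo ChIP signals
depend on ``kd_eff``.  The orc2-1/ORC2 ratio of an origin is then

    theta(C / depletion, kd_eff) / theta(C, kd_eff)

with C the notional wild-type nuclear ORC availability.  Under this model
resistance (ratio >= 0.8) requires kd_eff <= C/35 and sensitivity
(ratio <= 0.3) requires kd_eff >= 0.35 C, which fixes the class parameter
ranges used below (see docs/methods.md for the derivation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .emsa_affinity import TitrationCurve, hyperbola
from .tracks_io import GenomeSequence, OriginAnnotation, ProbeTrack

#: 11-bp ACS consensus on the T-rich strand planted at every origin.
ACS_CONSENSUS = "TTTTATGTTTA"

ORIGIN_CLASSES = ("chromatin_dependent", "dna_dependent", "weak", "complex")

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design parameters; defaults define the standard conditions."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "chromatin_dependent": 40,
            "dna_dependent": 40,
            "weak": 40,
            "complex": 0,
        }
    )
    genome_length: int | None = None  # computed from layout when None
    origin_spacing: int = 3000
    origin_length: int = 300
    flank: int = 1500
    probe_spacing: int = 10
    orc_concs: tuple[float, ...] = (0.3, 3.0, 30.0)
    in_vivo_orc_conc: float = 1000.0  # notional wild-type ORC availability (nM)
    depletion_factor: float = 10.0  # orc2-1 reduces ORC ~10-fold
    noise_sd: float = 0.15  # per-probe Gaussian noise on the log2 scale
    amplitude: float = 2.0  # peak height (log2 ratio) at full occupancy
    footprint: int = 240  # raised-cosine signal footprint
    # repetitive probes hybridise promiscuously and report garbage; the
    # normalisation step removes the same fraction by |value|
    repetitive_fraction: float = 0.011
    repetitive_magnitude: tuple[float, float] = (3.0, 6.0)
    titration_concs: tuple[float, ...] = (0.3, 3.0, 15.0, 30.0)
    titration_noise_sd: float = 0.02
    titration_replicates: int = 3
    # intrinsic ORC-DNA Kd ranges (nM) and chromatin boosts per class
    kd_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "dna_dependent": (4.0, 20.0),
            "chromatin_dependent": (300.0, 1200.0),
            "weak": (500.0, 2000.0),
            "complex": (25.0, 70.0),
        }
    )
    boost_max: float = 100.0
    complex_boost_range: tuple[float, float] = (2.0, 5.0)
    reference_kd: float = 7.2  # the planted high-affinity reference origin
    # nucleosome architecture
    ndr_width_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "chromatin_dependent": (230, 280),
            "dna_dependent": (190, 240),
            "weak": (190, 240),
            "complex": (190, 240),
        }
    )
    ndr_offset: int = 20  # NDR begins this far 3' of the EACS start
    encroachment: dict[str, int] = field(
        default_factory=lambda: {
            "chromatin_dependent": 10,
            "dna_dependent": 60,
            "weak": 60,
            "complex": 60,
        }
    )
    # replication timing
    trep_means: dict[str, float] = field(
        default_factory=lambda: {
            "chromatin_dependent": 18.0,
            "dna_dependent": 30.0,
            "weak": 30.0,
            "complex": 24.0,
        }
    )
    trep_sd: float = 4.0
    hu_threshold_min: float = 24.0  # studies call fires_WT below this Trep
    hu_study_noise_sd: float = 2.0
    hu_not_detected_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depletion_factor <= 1:
            raise ValueError("depletion_factor must exceed 1")
        if min(self.probe_spacing, self.origin_spacing, self.footprint) <= 0:
            raise ValueError("layout parameters must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_origins(self) -> int:
        return sum(self.n_per_class.values())

    @property
    def required_length(self) -> int:
        return self.n_origins * self.origin_spacing + 2 * self.flank


@dataclass
class SyntheticStudy:
    """A generated study: inputs plus the ground truth that produced them."""

    config: SimulationConfig
    genome: dict[str, GenomeSequence]
    origins: list[OriginAnnotation]
    tracks: dict[str, ProbeTrack]  # ORC2, orc2-1, gEMSA_<c>nM
    gemsa_tracks: dict[float, ProbeTrack]
    nucleosome_wt: ProbeTrack
    nucleosome_orc_mutant: ProbeTrack
    titrations: list[TitrationCurve]
    timing: pd.DataFrame
    truth: pd.DataFrame
    acs_training_sequences: list[str]
    reference_origin: str


def occupancy(conc: float, kd: float) -> float:
    """Equilibrium fraction bound: theta = conc / (conc + kd)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    return conc / (conc + kd)


def simulate_in_vivo_ratio(
    kd_dna: float, boost: float, cfg: SimulationConfig | None = None
) -> float:
    """Expected (noise-free) orc2-1/ORC2 peak-area ratio of an origin."""
    cfg = cfg or SimulationConfig()
    if boost < 1:
        raise ValueError("chromatin_boost must be >= 1")
    kd_eff = kd_dna / boost
    c = cfg.in_vivo_orc_conc
    return occupancy(c / cfg.depletion_factor, kd_eff) / occupancy(c, kd_eff)


def _draw_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for cls in ORIGIN_CLASSES:
        for _ in range(cfg.n_per_class.get(cls, 0)):
            lo, hi = cfg.kd_ranges[cls]
            kd = float(rng.uniform(lo, hi))
            if cls == "chromatin_dependent":
                # couple the boost to kd_dna so kd_eff stays within the
                # resistant band (kd_eff <= 12 nM << C/35)
                boost = float(rng.uniform(max(10.0, kd / 12.0), cfg.boost_max))
            elif cls == "complex":
                boost = float(rng.uniform(*cfg.complex_boost_range))
            else:
                boost = 1.0
            wlo, whi = cfg.ndr_width_range[cls]
            rows.append(
                {
                    "origin": f"ORI{i:04d}",
                    "true_class": cls,
                    "kd_dna": kd,
                    "chromatin_boost": boost,
                    "true_trep": float(rng.normal(cfg.trep_means[cls], cfg.trep_sd)),
                    "ndr_width_true": int(rng.integers(wlo, whi + 1)),
                }
            )
            i += 1
    df = pd.DataFrame(rows)
    # plant the reference origin: first DNA-dependent origin, exact Kd
    ref_idx = df.index[df["true_class"] == "dna_dependent"]
    if len(ref_idx):
        df.loc[ref_idx[0], "kd_dna"] = cfg.reference_kd
    df["kd_eff"] = df["kd_dna"] / df["chromatin_boost"]
    df["expected_ratio"] = [
        simulate_in_vivo_ratio(k, b, cfg)
        for k, b in zip(df["kd_dna"], df["chromatin_boost"])
    ]
    # shuffle genomic placement so classes are interleaved along the genome
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    return df.set_index("origin", drop=False)


def _timing_table(truth: pd.DataFrame, cfg: SimulationConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Per-origin Trep plus two independent HU-firing study calls."""
    rows = []
    for origin, rec in truth.iterrows():
        calls = []
        for _ in range(2):
            if rng.random() < cfg.hu_not_detected_prob:
                calls.append("not_detected")
                continue
            observed = rec["true_trep"] + rng.normal(0.0, cfg.hu_study_noise_sd)
            calls.append(
                "fires_WT" if observed < cfg.hu_threshold_min else "fires_rad53_only"
            )
        rows.append(
            {
                "origin": origin,
                "trep_min": rec["true_trep"],
                "hu_study1": calls[0],
                "hu_study2": calls[1],
            }
        )
    return pd.DataFrame(rows).set_index("origin", drop=False)


def generate_timing_study(cfg: SimulationConfig | None = None):
    """Fast path: ground truth and timing table only (no genome/tracks)."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = _draw_truth(cfg, rng)
    timing = _timing_table(truth, cfg, rng)
    return truth, timing


def _signal_shape(mids: np.ndarray, center: int, footprint: int) -> np.ndarray:
    """Raised-cosine arch: 1 at the center, 0 beyond footprint/2."""
    x = (mids - center) / (footprint / 2)
    shape = np.where(np.abs(x) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return shape


def _acs_training_set(rng: np.random.Generator, n_total: int = 67,
                      n_variant: int = 17) -> list[str]:
    """Alignment used to train the ACS PWM: mostly consensus, plus
    single-mismatch variants, so the consensus is each column's mode."""
    seqs = [ACS_CONSENSUS] * (n_total - n_variant)
    bases = "ACGT"
    for _ in range(n_variant):
        pos = int(rng.integers(0, len(ACS_CONSENSUS)))
        alt = bases[int(rng.integers(0, 4))]
        s = list(ACS_CONSENSUS)
        if alt == s[pos]:
            alt = bases[(bases.index(alt) + 1) % 4]
        s[pos] = alt
        seqs.append("".join(s))
    return seqs


def generate_study(cfg: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study with known ground truth."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_origins
    if n == 0:
        raise ValueError("no origins requested")
    length = cfg.genome_length or cfg.required_length
    if length < cfg.required_length:
        raise ValueError(
            f"genome_length {length} too short for {n} origins with "
            f"spacing {cfg.origin_spacing} and flank {cfg.flank}"
        )
    truth = _draw_truth(cfg, rng)

    chrom = "chrS"
    seq = rng.choice(list("ACGT"), size=length)
    origins: list[OriginAnnotation] = []
    acs_meta = []
    half_len = cfg.origin_length // 2
    for i, (origin, rec) in enumerate(truth.iterrows()):
        mid = cfg.flank + i * cfg.origin_spacing + cfg.origin_spacing // 2
        strand = "+" if rng.random() < 0.5 else "-"
        acs = mid - 90 if strand == "+" else mid + 90
        # plant the consensus: T-rich strand start at `acs`
        if strand == "+":
            planted = ACS_CONSENSUS
            left = acs
        else:
            planted = ACS_CONSENSUS.translate(_COMP)[::-1]
            left = acs - len(ACS_CONSENSUS) + 1
        seq[left : left + len(planted)] = list(planted)
        origins.append(
            OriginAnnotation(
                name=origin,
                chrom=chrom,
                start=mid - half_len,
                end=mid + half_len,
                status="confirmed",
                acs_pos=acs,
                acs_strand=strand,
            )
        )
        acs_meta.append((origin, mid, acs, strand))
    genome = {chrom: GenomeSequence(chrom, "".join(seq))}

    mids = np.arange(cfg.probe_spacing // 2, length, cfg.probe_spacing, dtype=np.int64)
    # repetitive probes: the same probe positions misbehave on every array,
    # reporting large-magnitude garbage in place of the true signal
    n_repetitive = int(round(mids.size * cfg.repetitive_fraction))
    repetitive_idx = rng.choice(mids.size, size=n_repetitive, replace=False)

    def binding_track(name: str, conc: float, kd_col: np.ndarray) -> ProbeTrack:
        expected = np.zeros(mids.size)
        for (origin, mid, _, _), kd in zip(acs_meta, kd_col):
            theta = occupancy(conc, float(kd))
            lo = np.searchsorted(mids, mid - cfg.footprint // 2)
            hi = np.searchsorted(mids, mid + cfg.footprint // 2 + 1)
            expected[lo:hi] += (
                cfg.amplitude * theta * _signal_shape(mids[lo:hi], mid, cfg.footprint)
            )
        values = expected + rng.normal(0.0, cfg.noise_sd, size=mids.size)
        if n_repetitive:
            lo_m, hi_m = cfg.repetitive_magnitude
            magnitudes = rng.uniform(lo_m, hi_m, size=n_repetitive)
            signs = rng.choice([-1.0, 1.0], size=n_repetitive)
            values[repetitive_idx] = magnitudes * signs
        track = ProbeTrack(name)
        track.add_chromosome(chrom, mids, values)
        return track

    kd_eff = truth["kd_eff"].to_numpy()
    kd_dna = truth["kd_dna"].to_numpy()
    c_wt = cfg.in_vivo_orc_conc
    tracks = {
        "ORC2": binding_track("ORC2", c_wt, kd_eff),
        "orc2-1": binding_track("orc2-1", c_wt / cfg.depletion_factor, kd_eff),
    }
    gemsa_tracks = {}
    for conc in cfg.orc_concs:
        name = f"gEMSA_{conc:g}nM"
        tr = binding_track(name, conc, kd_dna)  # naked DNA: boost excluded
        tracks[name] = tr
        gemsa_tracks[conc] = tr

    # nucleosome occupancy: rectangular, NDR planted 3' of the ACS
    nuc_pos = np.arange(0, length, dtype=np.int64)

    def nucleosome_track(name: str, widths: dict[str, tuple[int, int]]) -> ProbeTrack:
        occ = np.ones(length)
        for origin, mid, acs, strand in acs_meta:
            lo_rel, hi_rel = widths[origin]
            if strand == "+":
                occ[acs + lo_rel : acs + hi_rel] = 0.0
            else:
                occ[acs - hi_rel + 1 : acs - lo_rel + 1] = 0.0
        track = ProbeTrack(name)
        track.add_chromosome(chrom, nuc_pos, occ)
        return track

    wt_widths = {}
    mut_widths = {}
    for origin, rec in truth.iterrows():
        w = int(rec["ndr_width_true"])
        e = cfg.encroachment[rec["true_class"]]
        wt_widths[origin] = (cfg.ndr_offset, cfg.ndr_offset + w)
        mut_widths[origin] = (cfg.ndr_offset + e, cfg.ndr_offset + w - e)
    nucleosome_wt = nucleosome_track("nucleosomes_WT_G1", wt_widths)
    nucleosome_mut = nucleosome_track("nucleosomes_orc_mutant_G1", mut_widths)

    # EMSA titrations against naked DNA (kd_dna, boost excluded)
    titrations: list[TitrationCurve] = []
    for origin, rec in truth.iterrows():
        for rep in range(1, cfg.titration_replicates + 1):
            pts = []
            for conc in cfg.titration_concs:
                f = occupancy(conc, float(rec["kd_dna"]))
                f = float(np.clip(f + rng.normal(0.0, cfg.titration_noise_sd), 0.0, 1.0))
                pts.append((conc, f))
            titrations.append(TitrationCurve(str(origin), tuple(pts), rep))

    timing = _timing_table(truth, cfg, rng)
    acs_train = _acs_training_set(rng)
    ref = truth.loc[truth["kd_dna"] == cfg.reference_kd, "origin"]
    reference_origin = str(ref.iloc[0]) if len(ref) else str(truth["origin"].iloc[0])

    return SyntheticStudy(
        config=cfg,
        genome=genome,
        origins=origins,
        tracks=tracks,
        gemsa_tracks=gemsa_tracks,
        nucleosome_wt=nucleosome_wt,
        nucleosome_orc_mutant=nucleosome_mut,
        titrations=titrations,
        timing=timing,
        truth=truth,
        acs_training_sequences=acs_train,
        reference_origin=reference_origin,
    )
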