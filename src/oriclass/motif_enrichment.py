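"""PWM construction, genome scanning with a Markov background, and
enrichment statistics.

A motif is a position frequency matrix (with pseudocounts) built from an
alignment of fixed-width sites, paired with a k-th order Markov model of the
genome (default order 4) that supplies the background term of the log-odds
score.  A window's score in bits is

    sum_i log2( f_i(b_i) / q(b_i | k preceding genomic bases) ).

Match strength is also expressed as an LOD percent: the PWM component of the
score, min-max normalised over the motif's own score range, so the consensus
sequence scores exactly 100% wherever it occurs and the percent is invariant
to adding a constant to all column scores.  Scanning covers both strands;
windows containing N, or starting within k bases of a contig start, are
skipped.

Bipartite motifs (e.g. the EACS followed 13 degenerate bases later by the
WTW of the B1 element) score the two parts and ignore the spacer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .tracks_io import GenomeSequence

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _encode(seq: str) -> np.ndarray:
    """DNA -> int codes; N (or any other letter) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


class MarkovBackground:
    """k-th order Markov model of a genome with add-one smoothing.

    ``logq(context_code, base)`` holds log2 conditional probabilities; the
    order-0 marginal is kept for column-wise score bounds.
    """

    def __init__(self, genome: Mapping[str, GenomeSequence], order: int = 4):
        if order < 0:
            raise ValueError("order must be >= 0")
        self.order = order
        n_ctx = 4**order
        counts = np.ones((n_ctx, 4), dtype=np.float64)  # add-one smoothing
        base_counts = np.zeros(4, dtype=np.float64)
        for g in genome.values():
            codes = _encode(g.sequence)
            valid = codes < 4
            for b in range(4):
                base_counts[b] += int(np.sum(codes == b))
            if codes.size <= order:
                continue
            ctx = self._context_codes(codes)
            ok = valid[order:].copy()
            # context must be N-free
            for j in range(order):
                ok &= valid[j : j + codes.size - order]
            np.add.at(counts, (ctx[ok], codes[order:][ok]), 1.0)
        self.logq = np.log2(counts / counts.sum(axis=1, keepdims=True))
        if base_counts.sum() == 0:
            raise ValueError("empty genome")
        self.marginal = (base_counts + 1.0) / (base_counts.sum() + 4.0)

    def _context_codes(self, codes: np.ndarray) -> np.ndarray:
        """Code of the k preceding bases for positions order..len-1."""
        if self.order == 0:
            return np.zeros(codes.size, dtype=np.int64)
        n = codes.size - self.order
        ctx = np.zeros(n, dtype=np.int64)
        clipped = np.clip(codes, 0, 3).astype(np.int64)
        for j in range(self.order):
            ctx = ctx * 4 + clipped[j : j + n]
        return ctx

    def position_logq(self, codes: np.ndarray) -> np.ndarray:
        """Per-position log2 q(base | preceding k bases); NaN where the base
        or its context contains N or falls within k of the contig start."""
        n = codes.size
        out = np.full(n, np.nan)
        if n <= self.order:
            return out
        ctx = self._context_codes(codes)
        pos = np.arange(self.order, n)
        ok = codes[pos] < 4
        for j in range(self.order):
            ok &= codes[pos - self.order + j] < 4
        valid_pos = pos[ok]
        out[valid_pos] = self.logq[ctx[ok], np.clip(codes[valid_pos], 0, 3)]
        return out


@dataclass(frozen=True)
class MotifModel:
    """A PWM with its background model and score bounds (bits)."""

    freqs: np.ndarray  # (width, 4), columns sum to 1
    background: MarkovBackground

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4:
            raise ValueError("freqs must be (width, 4)")
        if not np.allclose(f.sum(axis=1), 1.0):
            raise ValueError("PWM columns must sum to 1")
        object.__setattr__(self, "freqs", f)

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def _logf(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.freqs)

    @property
    def max_score(self) -> float:
        """Best attainable PWM component of the score (bits); the LOD
        percent of a match is min-max normalised over [min_score, max_score],
        which makes it invariant to any per-column constant offset such as
        the background term."""
        lf = self._logf
        return float(np.where(np.isfinite(lf), lf, -np.inf).max(axis=1).sum())

    @property
    def min_score(self) -> float:
        """Worst attainable PWM component over bases with non-zero
        frequency (bits)."""
        lf = self._logf
        return float(np.where(np.isfinite(lf), lf, np.inf).min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.freqs.argmax(axis=1))

    def information_content(self) -> float:
        """Total information content in bits against the genome marginal."""
        f = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * (np.log2(f) - np.log2(self.background.marginal)), 0.0)
        return float(terms.sum())


@dataclass(frozen=True)
class BipartiteMotif:
    """Two PWMs separated by a fixed-length degenerate spacer."""

    part_a: MotifModel
    gap: int
    part_b: MotifModel

    @property
    def width(self) -> int:
        return self.part_a.width + self.gap + self.part_b.width


@dataclass(frozen=True)
class MotifMatch:
    chrom: str
    pos: int  # 0-based match start on the + strand
    strand: str
    score: float  # bits, Markov-background log odds
    lod_pct: float  # min-max normalised PWM score, in [0, 100]


def build_motif(
    sequences: Sequence[str],
    genome: Mapping[str, GenomeSequence],
    order: int = 4,
    pseudocount: float = 1.0,
    background: MarkovBackground | None = None,
) -> MotifModel:
    """Build a PWM from an aligned fixed-width site set plus a genome
    background of the given Markov order."""
    if not sequences:
        raise ValueError("no sequences supplied")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("sequences have mixed widths")
    counts = np.full((width, 4), float(pseudocount))
    for s in sequences:
        codes = _encode(s)
        if np.any(codes >= 4):
            raise ValueError(f"non-ACGT base in motif sequence {s!r}")
        counts[np.arange(width), codes] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    bg = background if background is not None else MarkovBackground(genome, order)
    return MotifModel(freqs, bg)


def _pwm_scores(codes: np.ndarray, logf: np.ndarray) -> np.ndarray:
    """PWM-only score of every window start (NaN where the window has N)."""
    width = logf.shape[0]
    n = codes.size - width + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for i in range(width):
        col = codes[i : i + n]
        valid = col < 4
        bad |= ~valid
        scores += np.where(valid, logf[i, np.clip(col, 0, 3)], 0.0)
    scores[bad] = np.nan
    return scores


def _lod_pct(pwm_scores: np.ndarray, motif: MotifModel) -> np.ndarray:
    smax = motif.max_score
    smin = motif.min_score
    if smax == smin:
        return np.where(np.isnan(pwm_scores), np.nan, 100.0)
    pct = 100.0 * (pwm_scores - smin) / (smax - smin)
    return np.clip(pct, 0.0, 100.0)


def _scan_strand(
    codes: np.ndarray, motif: MotifModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (window starts, bits scores, lod percents) for one strand."""
    lf = motif._logf
    pwm = _pwm_scores(codes, lf)
    logq = motif.background.position_logq(codes)
    cq = np.concatenate([[0.0], np.nancumsum(logq)])
    width = motif.width
    n = pwm.size
    starts = np.arange(n)
    bgsum = cq[starts + width] - cq[starts]
    # windows whose own context is incomplete or N-containing are skipped
    invalid = np.isnan(pwm)
    win_nan = np.zeros(n, dtype=bool)
    isnan_q = np.isnan(logq)
    cnan = np.concatenate([[0], np.cumsum(isnan_q)])
    win_nan = (cnan[starts + width] - cnan[starts]) > 0
    score = pwm - bgsum
    score[invalid | win_nan] = np.nan
    lod = _lod_pct(pwm, motif)
    lod[invalid | win_nan] = np.nan
    return starts, score, lod


def scan(
    genome: Mapping[str, GenomeSequence],
    motif: MotifModel | BipartiteMotif,
    lod_cutoff_pct: float = 70.0,
) -> list[MotifMatch]:
    """Scan both strands for windows meeting the LOD percent cutoff.

    Match positions are reported as 0-based starts on the + strand;
    overlapping matches are permitted.
    """
    if isinstance(motif, BipartiteMotif):
        return _scan_bipartite(genome, motif, lod_cutoff_pct)
    matches: list[MotifMatch] = []
    width = motif.width
    for name in sorted(genome):
        seq = genome[name].sequence
        fwd = _encode(seq)
        rev = _encode(reverse_complement(seq))
        for strand, codes in (("+", fwd), ("-", rev)):
            starts, score, lod = _scan_strand(codes, motif)
            hits = np.flatnonzero(~np.isnan(lod) & (lod >= lod_cutoff_pct))
            for i in hits:
                pos = int(starts[i])
                if strand == "-":
                    pos = len(seq) - pos - width
                matches.append(
                    MotifMatch(name, pos, strand, float(score[i]), float(lod[i]))
                )
    matches.sort(key=lambda m: (m.chrom, m.pos, m.strand))
    return matches


def _scan_bipartite(
    genome: Mapping[str, GenomeSequence], motif: BipartiteMotif, lod_cutoff_pct: float
) -> list[MotifMatch]:
    matches: list[MotifMatch] = []
    wa, gap, wb = motif.part_a.width, motif.gap, motif.part_b.width
    total = motif.width
    for name in sorted(genome):
        seq = genome[name].sequence
        fwd = _encode(seq)
        rev = _encode(reverse_complement(seq))
        for strand, codes in (("+", fwd), ("-", rev)):
            sa, score_a, _ = _scan_strand(codes, motif.part_a)
            sb, score_b, _ = _scan_strand(codes, motif.part_b)
            pa = _pwm_scores(codes, motif.part_a._logf)
            pb = _pwm_scores(codes, motif.part_b._logf)
            n = codes.size - total + 1
            if n <= 0:
                continue
            idx_b = np.arange(n) + wa + gap
            score = score_a[:n] + score_b[idx_b]
            pwm = pa[:n] + pb[idx_b]
            lod = _combined_lod(pwm, motif)
            hits = np.flatnonzero(~np.isnan(score) & ~np.isnan(lod) & (lod >= lod_cutoff_pct))
            for i in hits:
                pos = int(i)
                if strand == "-":
                    pos = len(seq) - pos - total
                matches.append(
                    MotifMatch(name, pos, strand, float(score[i]), float(lod[i]))
                )
    matches.sort(key=lambda m: (m.chrom, m.pos, m.strand))
    return matches


def _combined_lod(pwm: np.ndarray, motif: BipartiteMotif) -> np.ndarray:
    smax = motif.part_a.max_score + motif.part_b.max_score
    smin = motif.part_a.min_score + motif.part_b.min_score
    if smax == smin:
        return np.where(np.isnan(pwm), np.nan, 100.0)
    return np.clip(100.0 * (pwm - smin) / (smax - smin), 0.0, 100.0)


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def density_fold(
    matches_set: int, set_bp: float, matches_genome: int, genome_bp: float
) -> float:
    """Match density in a region set relative to the whole genome.

    fold = (matches_set / set_bp) / (matches_genome / genome_bp).
    """
    if set_bp <= 0 or genome_bp <= 0:
        raise ValueError("region sizes must be positive")
    if matches_genome == 0:
        raise ValueError("zero genome matches; fold undefined")
    return (matches_set / set_bp) / (matches_genome / genome_bp)


def fisher_enrichment(
    matches_set: int, positions_set: int, matches_genome: int, positions_genome: int
) -> float:
    """One-tailed (over-representation) Fisher exact P for motif enrichment.

    The 2x2 table counts match vs non-match scanned positions in the region
    set against the genome-wide control.
    """
    if matches_set > positions_set or matches_genome > positions_genome:
        raise ValueError("match counts exceed position counts")
    if min(matches_set, positions_set, matches_genome, positions_genome) < 0:
        raise ValueError("negative counts")
    table = [
        [matches_set, positions_set - matches_set],
        [matches_genome, positions_genome - matches_genome],
    ]
    return float(fisher_exact(table, alternative="greater")[1])


def enrichment_table(
    motifs: Mapping[str, MotifModel | BipartiteMotif],
    genome: Mapping[str, GenomeSequence],
    region_sets: Mapping[str, Sequence[tuple[str, int, int]]],
    lod_cutoff_pct: float = 70.0,
):
    """Scan a battery of motifs and report per-region-set enrichment.

    Returns a list of dict rows (motif, region set, matches in set, set bp,
    genome matches, genome bp, density fold, one-tailed Fisher P) suitable
    for a DataFrame.  The Fisher table counts scanned windows (both strands).
    """
    import pandas as pd

    genome_bp = sum(len(g) for g in genome.values())
    rows = []
    for motif_name, motif in motifs.items():
        hits = scan(genome, motif, lod_cutoff_pct)
        width = motif.width
        genome_positions = 2 * sum(max(0, len(g) - width + 1) for g in genome.values())
        for set_name, regions in region_sets.items():
            set_bp = sum(e - s for _, s, e in regions)
            in_set = sum(
                1
                for m in hits
                if any(c == m.chrom and s <= m.pos < e for c, s, e in regions)
            )
            set_positions = 2 * sum(max(0, (e - s) - width + 1) for _, s, e in regions)
            rows.append(
                {
                    "motif": motif_name,
                    "region_set": set_name,
                    "matches_set": in_set,
                    "set_bp": set_bp,
                    "matches_genome": len(hits),
                    "genome_bp": genome_bp,
                    "density_fold": density_fold(in_set, set_bp, len(hits), genome_bp)
                    if len(hits)
                    else float("nan"),
                    "fisher_p": fisher_enrichment(
                        in_set, set_positions, len(hits), genome_positions
                    ),
                }
            )
    return pd.DataFrame(rows)
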