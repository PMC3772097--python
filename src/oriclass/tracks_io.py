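"""Data model and I/O for genomes, origin annotations and probe signal tracks.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open.  On-disk origin tables are
1-based inclusive (the convention of curated yeast origin annotations), and
``read_origin_table``/``write_origin_table`` convert at the boundary.
bedGraph tracks are 0-based half-open on disk already.

A probe is represented by its interval midpoint, ``(start + end) // 2``; a
probe belongs to a window or peak iff its midpoint lies in the half-open
interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ORIGIN_STATUSES = ("confirmed", "likely", "dubious")

_DNA_ALPHABET = set("ACGTN")


class TrackFormatError(ValueError):
    """A malformed on-disk track or annotation table."""


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome: an identifier and a DNA string over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.name!r}")
        bad = set(self.sequence.upper()) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"non-DNA characters in {self.name!r}: {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OriginAnnotation:
    """A replication origin interval with optional ACS anchor.

    ``acs_pos`` is the position of the EACS start on the T-rich strand
    (0-based); ``acs_strand`` gives the strand carrying the T-rich sequence.
    ``telomeric_core_x`` flags core-X telomere-associated origins which are
    excluded from comparative analyses.
    """

    name: str
    chrom: str
    start: int
    end: int
    status: str
    acs_pos: int | None = None
    acs_strand: str | None = None
    telomeric_core_x: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start {self.start} >= end {self.end}")
        if self.status not in ORIGIN_STATUSES:
            raise ValueError(f"{self.name}: unknown status {self.status!r}")
        if self.acs_strand is not None and self.acs_strand not in ("+", "-"):
            raise ValueError(f"{self.name}: bad strand {self.acs_strand!r}")
        if self.acs_pos is not None and not (
            self.start - 1000 <= self.acs_pos <= self.end + 1000
        ):
            raise ValueError(
                f"{self.name}: acs_pos {self.acs_pos} outside "
                f"[{self.start - 1000}, {self.end + 1000}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ProbeTrack:
    """Per-chromosome ordered probe midpoints with log2-ratio values.

    ``chroms`` maps chromosome name to ``(midpoints, values)`` arrays with
    strictly increasing midpoints and finite values.
    """

    condition: str
    chroms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_chromosome(self, chrom: str, midpoints, values) -> None:
        mids = np.asarray(midpoints, dtype=np.int64)
        vals = np.asarray(values, dtype=np.float64)
        if mids.shape != vals.shape or mids.ndim != 1:
            raise ValueError("midpoints and values must be 1-D and matched")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values on {chrom}")
        order = np.argsort(mids, kind="stable")
        mids, vals = mids[order], vals[order]
        if np.any(np.diff(mids) == 0):
            raise ValueError(f"duplicate probe midpoints on {chrom}")
        self.chroms[chrom] = (mids, vals)

    def values(self) -> np.ndarray:
        """All probe values, concatenated over chromosomes (sorted names)."""
        if not self.chroms:
            return np.empty(0)
        return np.concatenate([self.chroms[c][1] for c in sorted(self.chroms)])

    @property
    def n_probes(self) -> int:
        return sum(len(v[0]) for v in self.chroms.values())

    def probes_in(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """Probes whose midpoint lies in the half-open interval [start, end)."""
        if chrom not in self.chroms:
            return np.empty(0, dtype=np.int64), np.empty(0)
        mids, vals = self.chroms[chrom]
        lo = np.searchsorted(mids, start, side="left")
        hi = np.searchsorted(mids, end, side="left")
        return mids[lo:hi], vals[lo:hi]

    def copy(self, condition: str | None = None) -> "ProbeTrack":
        t = ProbeTrack(condition or self.condition)
        for c, (m, v) in self.chroms.items():
            t.chroms[c] = (m.copy(), v.copy())
        return t


# ---------------------------------------------------------------------------
# FASTA genomes
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a FASTA file into a name -> GenomeSequence mapping."""
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise TrackFormatError(f"duplicate chromosome name {rec.id!r}")
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    return genome


def write_genome(genome: Mapping[str, GenomeSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=name, description="")
        for name, g in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Origin annotation tables
# ---------------------------------------------------------------------------

_ORIGIN_COLUMNS = ("chrom", "start", "end", "name", "status")


def _split_row(line: str) -> list[str]:
    if "\t" in line:
        return [f.strip() for f in line.rstrip("\n").split("\t")]
    if "," in line:
        return [f.strip() for f in line.rstrip("\n").split(",")]
    return line.split()


def read_origin_table(path: str | Path) -> list[OriginAnnotation]:
    """Read a delimited origin table (1-based inclusive coordinates on disk).

    Expected columns: chrom, start, end, name, status and optionally
    acs_pos, acs_strand, telomeric_core_x.  Internal coordinates are 0-based
    half-open, so file row ``chrIII 39158 39706`` becomes start 39157,
    end 39706.
    """
    origins: list[OriginAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise TrackFormatError(f"{path}: empty file (header expected)")
    header = [h.lower() for h in _split_row(lines[0])]
    if header[:5] != list(_ORIGIN_COLUMNS):
        raise TrackFormatError(
            f"{path}: header must start with {' '.join(_ORIGIN_COLUMNS)}"
        )
    idx = {h: i for i, h in enumerate(header)}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = _split_row(line)
        try:
            start1 = int(fields[idx["start"]])
            end1 = int(fields[idx["end"]])
        except (ValueError, IndexError) as exc:
            raise TrackFormatError(f"{path}:{lineno}: malformed coordinates") from exc
        if start1 >= end1:
            raise TrackFormatError(
                f"{path}:{lineno}: start {start1} >= end {end1}"
            )
        name = fields[idx["name"]]
        if name in seen:
            raise TrackFormatError(f"{path}:{lineno}: duplicate origin name {name!r}")
        seen.add(name)
        status = fields[idx["status"]].lower()
        if status not in ORIGIN_STATUSES:
            raise TrackFormatError(f"{path}:{lineno}: unknown status {status!r}")
        acs_pos = acs_strand = None
        telo = False
        if "acs_pos" in idx and len(fields) > idx["acs_pos"]:
            raw = fields[idx["acs_pos"]]
            if raw not in ("", ".", "NA"):
                acs_pos = int(raw) - 1  # 1-based on disk
        if "acs_strand" in idx and len(fields) > idx["acs_strand"]:
            raw = fields[idx["acs_strand"]]
            if raw in ("+", "-"):
                acs_strand = raw
        if "telomeric_core_x" in idx and len(fields) > idx["telomeric_core_x"]:
            telo = fields[idx["telomeric_core_x"]].lower() in ("1", "true", "yes")
        origins.append(
            OriginAnnotation(
                name=name,
                chrom=fields[idx["chrom"]],
                start=start1 - 1,
                end=end1,
                status=status,
                acs_pos=acs_pos,
                acs_strand=acs_strand,
                telomeric_core_x=telo,
            )
        )
    return origins


def write_origin_table(origins: Iterable[OriginAnnotation], path: str | Path) -> None:
    """Write origins back to disk with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tstatus\tacs_pos\tacs_strand\ttelomeric_core_x\n")
        for o in origins:
            acs = "" if o.acs_pos is None else str(o.acs_pos + 1)
            strand = o.acs_strand or ""
            fh.write(
                f"{o.chrom}\t{o.start + 1}\t{o.end}\t{o.name}\t{o.status}\t"
                f"{acs}\t{strand}\t{int(o.telomeric_core_x)}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph probe tracks
# ---------------------------------------------------------------------------

def read_probe_track(path: str | Path, condition: str) -> ProbeTrack:
    """Read a 4-column bedGraph (chrom, start, end, value) into a ProbeTrack.

    The probe position is the interval midpoint rounded down.  Unsorted
    input is sorted silently with a logged notice; identical midpoints on
    one chromosome are rejected.
    """
    per_chrom: dict[str, tuple[list[int], list[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise TrackFormatError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise TrackFormatError(
                    f"{path}:{lineno}: non-numeric coordinate or value"
                ) from exc
            if not np.isfinite(value):
                raise TrackFormatError(f"{path}:{lineno}: non-finite value")
            mids, vals = per_chrom.setdefault(chrom, ([], []))
            mids.append((start + end) // 2)
            vals.append(value)
    track = ProbeTrack(condition)
    for chrom, (mids, vals) in per_chrom.items():
        if any(b <= a for a, b in zip(mids, mids[1:])):
            logger.info("%s: probes on %s not sorted; sorting", path, chrom)
        try:
            track.add_chromosome(chrom, mids, vals)
        except ValueError as exc:
            raise TrackFormatError(f"{path}: {exc}") from exc
    return track


def write_probe_track(track: ProbeTrack, path: str | Path, probe_width: int = 1) -> None:
    """Write a ProbeTrack as bedGraph; each probe becomes an interval of
    ``probe_width`` bp whose midpoint is the probe position."""
    half = probe_width // 2
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            mids, vals = track.chroms[chrom]
            for m, v in zip(mids, vals):
                start = int(m) - half
                fh.write(f"{chrom}\t{start}\t{start + probe_width}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

ND = "ND"  # censored-Kd encoding shared by all result tables


def write_result_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an origin-keyed result table as CSV.

    One row per origin, stable column order, NA encoded as the empty string.
    Censored Kd columns should already hold the string ``"ND"``.
    """
    if table.empty:
        raise ValueError("refusing to write an empty result table")
    if table.index.has_duplicates:
        raise ValueError("result table has duplicate origin keys")
    table.to_csv(path, index=True, index_label="origin", na_rep="")


def read_result_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="origin", keep_default_na=False, na_values=[""])
    return df
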