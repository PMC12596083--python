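"""Readers and writers for the plain-text formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals;
GFF3 (1-based inclusive) is converted at the boundary and nowhere else.
Soft-masked (lowercase) bases and Ns are preserved verbatim by the readers —
how they are treated during alignment is decided in :mod:`centrotrace.align`.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("centrotrace")

_VALID_BASES = set("ACGTNacgtn")


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


@dataclass
class GenomeSequence:
    """One chromosome / contig: an identifier plus its DNA string."""

    chrom_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Interval:
    """0-based half-open genomic interval."""

    chrom_id: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Number of shared bases with *other* (0 if different chromosome)."""
        if self.chrom_id != other.chrom_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class SignalTrack:
    """Per-bin non-negative signal over one chromosome.

    ``values[i]`` covers bases ``[i*bin_width, (i+1)*bin_width)``; the last
    bin may be partial.
    """

    chrom_id: str
    bin_width: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(self.values < 0):
            raise ValueError("signal values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class PipelineConfig:
    """Tunable thresholds shared across the pipeline.

    Defaults follow the study design: 1-kb signal bins, 100-bp alignment
    score bins, 10-bp origin-trace bins, a 376-bp FISH probe at a 3%
    mismatch tolerance, >70% clustering identity, a 100-copy family census
    floor, μ = 1.3e-8 substitutions/site/year and an enrichment-index
    cutoff of 2.0.
    """

    bin_width_signal: int = 1000
    bin_width_score: int = 100
    bin_width_trace: int = 10
    probe_len: int = 376
    probe_mismatch_frac: float = 0.03
    cluster_identity: float = 0.70
    min_family_count: int = 100
    mutation_rate_mu: float = 1.3e-8
    cri_threshold: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bin_width_signal", "bin_width_score", "bin_width_trace",
                     "probe_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("probe_mismatch_frac", "cluster_identity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records, order preserved."""
    path = Path(path)
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains illegal characters {sorted(bad)}"
            )
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, seq))
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path,
                width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.chrom_id, description="")
            for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3+ into intervals; coordinates are used verbatim (0-based)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected ≥3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from e
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start ≥ end ({start} ≥ {end})")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 else "."
            out.append(Interval(chrom, start, end, name, strand))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom_id, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand != ".":
                cols.append(iv.name if iv.name is not None else ".")
            if iv.strand != ".":
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# bedGraph / binned signal


def read_signal(path: str | Path, bin_width: int) -> list[SignalTrack]:
    """Read a bedGraph (or chrom/start/end/value TSV) of bin-aligned values.

    Records must start on multiples of *bin_width*; gaps between records
    are zero-filled.  One track per chromosome, in order of first appearance.
    """
    per_chrom: dict[str, dict[int, float]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = re.split(r"\s+", line)
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start_s, end_s, val_s = parts[:4]
            try:
                start, end, val = int(start_s), int(end_s), float(val_s)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: malformed record") from e
            if start % bin_width != 0 or (end - start) > bin_width:
                raise FormatError(
                    f"{path}:{lineno}: interval [{start},{end}) not aligned "
                    f"to bin width {bin_width}"
                )
            if chrom not in per_chrom:
                per_chrom[chrom] = {}
                order.append(chrom)
            per_chrom[chrom][start // bin_width] = val
    tracks = []
    for chrom in order:
        bins = per_chrom[chrom]
        values = np.zeros(max(bins) + 1, dtype=float)
        for b, v in bins.items():
            values[b] = v
        tracks.append(SignalTrack(chrom, bin_width, values))
    return tracks


def write_signal(tracks: Iterable[SignalTrack], path: str | Path,
                 chrom_lengths: dict[str, int] | None = None) -> None:
    """Write tracks as bedGraph; zero bins are omitted."""
    with open(path, "w") as fh:
        for tr in tracks:
            clen = None if chrom_lengths is None else chrom_lengths.get(tr.chrom_id)
            for i, v in enumerate(tr.values):
                if v == 0:
                    continue
                start = i * tr.bin_width
                end = start + tr.bin_width
                if clen is not None:
                    end = min(end, clen)
                fh.write(f"{tr.chrom_id}\t{start}\t{end}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Repeat annotations (GFF3 / RepeatMasker-style TSV)


def read_repeat_annotations(path: str | Path) -> list[tuple[Interval, str]]:
    """Read repeat annotations from GFF3 or a RepeatMasker-style TSV.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; the family label is taken from the
    ``Target`` or ``family_id``/``Name`` attribute (GFF3) or the family
    column (TSV: chrom, start0, end, family, strand).
    """
    path = Path(path)
    out: list[tuple[Interval, str]] = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("##gff") or _looks_gff3(first):
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                chrom, _src, _type, start_s, end_s, _score, strand, _frame, attrs = parts
                try:
                    start1, end1 = int(start_s), int(end_s)
                except ValueError as e:
                    raise FormatError(f"{path}:{lineno}: non-integer coordinate") from e
                family = _gff3_family(attrs)
                if family is None:
                    raise FormatError(
                        f"{path}:{lineno}: no family label (Target/family_id/Name/ID)"
                    )
                out.append(
                    (Interval(chrom, start1 - 1, end1, family,
                              strand if strand in "+-" else "."), family)
                )
        elif "\t" in first:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: expected ≥4 TSV columns")
                chrom, start_s, end_s, family = parts[:4]
                strand = parts[4] if len(parts) > 4 and parts[4] in "+-" else "."
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError as e:
                    raise FormatError(f"{path}:{lineno}: non-integer coordinate") from e
                out.append((Interval(chrom, start, end, family, strand), family))
        else:
            raise FormatError(
                f"{path}: unknown annotation dialect; supported: GFF3, "
                "tab-separated (chrom, start0, end, family[, strand])"
            )
    return out


def _looks_gff3(line: str) -> bool:
    parts = line.rstrip("\n").split("\t")
    return len(parts) == 9 and "=" in parts[8]


def _gff3_family(attrs: str) -> str | None:
    kv = {}
    for item in attrs.strip(";").split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            kv[k.strip()] = v.strip()
    if "Target" in kv:
        return kv["Target"].split()[0]
    for key in ("family_id", "Name", "ID"):
        if key in kv:
            return kv[key]
    return None


def write_repeat_annotations_gff3(
    annotations: Sequence[tuple[Interval, str]], path: str | Path,
    source: str = "centrotrace",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, family in annotations:
            fh.write(
                f"{iv.chrom_id}\t{source}\tdispersed_repeat\t{iv.start + 1}\t"
                f"{iv.end}\t.\t{iv.strand if iv.strand in '+-' else '.'}\t.\t"
                f"family_id={family}\n"
            )


# ---------------------------------------------------------------------------
# key=value config files


def read_config(path: str | Path) -> PipelineConfig:
    """Read a plain-text ``key = value`` file into a :class:`PipelineConfig`."""
    known = {f.name: f.type for f in fields(PipelineConfig)}
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = float(value) if "." in value or "e" in value.lower() \
                else int(value)
    return PipelineConfig(**kwargs)


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in intervals)


def overlap_fraction(iv: Interval, regions: Sequence[Interval]) -> float:
    """Fraction of *iv* covered by the union of *regions* (same chromosome)."""
    if len(iv) == 0:
        return 0.0
    covered = 0
    spans = sorted(
        (max(iv.start, r.start), min(iv.end, r.end))
        for r in regions
        if r.chrom_id == iv.chrom_id and r.start < iv.end and r.end > iv.start
    )
    last = -1
    for s, e in spans:
        s = max(s, last)
        if e > s:
            covered += e - s
            last = e
    return covered / len(iv)


def is_centromeric(iv: Interval, centromeres: Sequence[Interval],
                   min_frac: float = 0.5) -> bool:
    """Shared ≥50%-overlap rule used by the census, CRI classing and CTRs."""
    return overlap_fraction(iv, centromeres) >= min_frac
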