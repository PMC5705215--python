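"""Turning aligned nanopore reads into a time-ordered allele-observation stream.

The "sketch" is the core data object of the method: for each panel marker
covered by at least one aligned read base, a single observed allele label
(A or B, relative to the panel's allele pair) with a timestamp and a
per-observation error rate.  Because shotgun coverage at sketch depth is
far below 1x, each locus is covered by at most one read; when a second
read does cover an already-observed marker we keep the first observation
only, preserving the per-marker independence the matcher assumes.

Read bases that land on a panel position but show a nucleotide outside the
marker's two common alleles are counted as sequencing errors and dropped —
at nanopore error rates a third allele is overwhelmingly more likely to be
a miscall than a real tri-allelic variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pysam

from .panel import SnpPanel

logger = logging.getLogger(__name__)

MIN_MEAN_QUAL = 9.0     # reads at or below this mean Phred quality are discarded
EPSILON_FLOOR = 0.001   # clamp bounds keep the likelihood matrix well-conditioned
EPSILON_CEIL = 0.30
DEFAULT_MAX_SECONDS = 3600.0  # use at most one hour of data


@dataclass
class ReadRecord:
    """One aligned read with the per-base information the sketch needs.

    ``aligned_bases`` holds (chrom, 1-based ref pos, base) for aligned
    match/mismatch columns only; insertions, deletions and clips never
    contribute bases.
    """

    read_id: str
    chrom: str
    pos: int                      # 1-based leftmost aligned position
    mean_qual: Optional[float]
    is_unique: bool
    timestamp: Optional[float] = None   # seconds since run start
    aligned_bases: list[tuple[str, int, str]] = field(default_factory=list)


@dataclass(frozen=True)
class SketchObservation:
    """A single observed allele at one panel marker."""

    rsid: str
    observed: str       # 'A' or 'B', relative to the marker's allele pair
    timestamp: float    # seconds since run start (or observation index)
    epsilon: float      # symmetric per-observation allele error rate


@dataclass
class Sketch:
    """Time-ordered observation stream plus provenance counters."""

    observations: list[SketchObservation] = field(default_factory=list)
    reads_in: int = 0
    reads_pass_qc: int = 0
    bases_at_panel: int = 0
    bases_error: int = 0       # non-panel alleles discarded as sequencing errors
    bases_duplicate: int = 0   # later reads over an already-observed marker

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def error_fraction(self) -> float:
        return self.bases_error / self.bases_at_panel if self.bases_at_panel else 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rsid\tobserved\ttimestamp\tepsilon\n")
            for o in self.observations:
                fh.write(f"{o.rsid}\t{o.observed}\t{o.timestamp:.6g}\t{o.epsilon:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Sketch":
        sketch = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("rsid\t"):
                raise ValueError(f"{path}: not a sketch TSV")
            for line in fh:
                rsid, observed, ts, eps = line.rstrip("\n").split("\t")
                sketch.observations.append(
                    SketchObservation(rsid, observed, float(ts), float(eps))
                )
        return sketch


@dataclass
class FilterReport:
    total: int = 0
    kept: int = 0
    dropped_quality: int = 0
    dropped_multi: int = 0


def read_metadata(path: str | Path) -> dict[str, tuple[Optional[float], Optional[float]]]:
    """Read the optional per-read metadata TSV: read_id, mean_qual, timestamp_sec."""
    meta: dict[str, tuple[Optional[float], Optional[float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            fields = line.split("\t")
            rid = fields[0]
            q = float(fields[1]) if len(fields) > 1 and fields[1] != "" else None
            t = float(fields[2]) if len(fields) > 2 and fields[2] != "" else None
            meta[rid] = (q, t)
    return meta


def load_reads(
    sam_path: str | Path,
    metadata: Optional[dict[str, tuple[Optional[float], Optional[float]]]] = None,
) -> list[ReadRecord]:
    """Parse a SAM file into ReadRecords, resolving multi-alignment status.

    A read is unique only if it has a single alignment record: any name
    with secondary/supplementary records (or appearing more than once)
    marks all of its records non-unique.  Unmapped records are skipped.
    Mean quality and timestamp come from the metadata map when given,
    falling back to the mean of the stored base qualities.
    """
    metadata = metadata or {}
    records: list[tuple[pysam.AlignedSegment, list[tuple[str, int, str]]]] = []
    name_counts: dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            name_counts[aln.query_name] = name_counts.get(aln.query_name, 0) + 1
            if aln.is_secondary or aln.is_supplementary:
                records.append((aln, []))
                continue
            seq = aln.query_sequence
            bases: list[tuple[str, int, str]] = []
            if seq:
                try:
                    pairs = aln.get_aligned_pairs(matches_only=True)
                except ValueError:
                    logger.warning("skipping read %s: CIGAR/sequence mismatch", aln.query_name)
                    pairs = []
                chrom = aln.reference_name
                for qpos, rpos in pairs:
                    bases.append((chrom, rpos + 1, seq[qpos].upper()))
            records.append((aln, bases))
    reads: list[ReadRecord] = []
    for aln, bases in records:
        if aln.is_secondary or aln.is_supplementary:
            continue  # represented by the primary record, which is marked non-unique
        meta_q, meta_t = metadata.get(aln.query_name, (None, None))
        if meta_q is None and aln.query_qualities is not None and len(aln.query_qualities):
            meta_q = float(sum(aln.query_qualities)) / len(aln.query_qualities)
        reads.append(
            ReadRecord(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                pos=aln.reference_start + 1,
                mean_qual=meta_q,
                is_unique=name_counts[aln.query_name] == 1,
                timestamp=meta_t,
                aligned_bases=bases,
            )
        )
    return reads


def filter_reads(reads: Sequence[ReadRecord]) -> tuple[list[ReadRecord], FilterReport]:
    """Keep uniquely-aligned reads with mean base quality strictly above 9."""
    report = FilterReport(total=len(reads))
    kept: list[ReadRecord] = []
    for r in reads:
        if not r.is_unique:
            report.dropped_multi += 1
        elif r.mean_qual is None or r.mean_qual <= MIN_MEAN_QUAL:
            report.dropped_quality += 1
        else:
            kept.append(r)
    report.kept = len(kept)
    return kept, report


def read_epsilon(read: ReadRecord, global_override: Optional[float] = None) -> float:
    """Per-read allele error rate.

    Defaults to the Phred-implied error probability of the read's mean
    base quality, clamped to [0.001, 0.30]; a global override (e.g. a
    chemistry-wide measured mismatch rate) takes precedence.
    """
    if global_override is not None:
        return float(global_override)
    if read.mean_qual is None:
        raise ValueError(f"read {read.read_id}: no mean quality and no override")
    eps = 10.0 ** (-read.mean_qual / 10.0)
    return min(max(eps, EPSILON_FLOOR), EPSILON_CEIL)


def extract_observations(
    reads: Sequence[ReadRecord],
    panel: SnpPanel,
    epsilon_override: Optional[float] = None,
    max_seconds: Optional[float] = DEFAULT_MAX_SECONDS,
) -> Sketch:
    """Build the sketch: first observed allele per panel marker, in time order.

    Reads are consumed in timestamp order (input order when timestamps are
    absent) and only data within ``max_seconds`` of run start is used.
    Every read base landing on a panel position is accounted for exactly
    once: as an emitted observation, a discarded non-panel allele, or a
    duplicate over an already-observed marker.
    """
    sketch = Sketch(reads_in=len(reads))
    order = sorted(
        range(len(reads)),
        key=lambda i: (reads[i].timestamp is None, reads[i].timestamp or 0.0, i),
    )
    seen: set[str] = set()
    for rank, i in enumerate(order):
        read = reads[i]
        if (
            max_seconds is not None
            and read.timestamp is not None
            and read.timestamp > max_seconds
        ):
            continue
        sketch.reads_pass_qc += 1
        eps = read_epsilon(read, epsilon_override)
        ts = read.timestamp if read.timestamp is not None else float(rank)
        for chrom, pos, base in read.aligned_bases:
            marker = panel.at(chrom, pos)
            if marker is None:
                continue
            sketch.bases_at_panel += 1
            if marker.rsid in seen:
                sketch.bases_duplicate += 1
            elif base == marker.allele_a:
                seen.add(marker.rsid)
                sketch.observations.append(SketchObservation(marker.rsid, "A", ts, eps))
            elif base == marker.allele_b:
                seen.add(marker.rsid)
                sketch.observations.append(SketchObservation(marker.rsid, "B", ts, eps))
            else:
                sketch.bases_error += 1
    return sketch
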