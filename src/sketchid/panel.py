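"""Bi-allelic common-SNP panel: the marker reference against which sketches are read.

A panel row is one autosomal single-nucleotide variant with exactly two
segregating alleles, labelled A and B, plus the population frequency of
allele A.  Only markers with a common minor allele (frequency of either
allele between 1% and 99%) are informative for re-identification and are
retained; everything else is filtered at load time.

File dialect: tab-separated with a header line
``chrom  pos  rsid  allele_a  allele_b  freq_a``; lines starting with ``#``
are comments.  Coordinates are 1-based on the hg19 assembly, plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

VALID_BASES = frozenset("ACGT")
AUTOSOMES = tuple(str(c) for c in range(1, 23))

FREQ_MIN = 0.01
FREQ_MAX = 0.99

PANEL_COLUMNS = ("chrom", "pos", "rsid", "allele_a", "allele_b", "freq_a")


@dataclass(frozen=True)
class SnpMarker:
    """One bi-allelic autosomal SNP with its allele-A population frequency."""

    chrom: str
    pos: int
    rsid: str
    allele_a: str
    allele_b: str
    freq_a: float

    @property
    def freq_b(self) -> float:
        return 1.0 - self.freq_a


@dataclass
class PanelLoadReport:
    """Row accounting for a panel load: every input row lands in one bucket."""

    total: int = 0
    loaded: int = 0
    dropped_filter: int = 0  # frequency outside [0.01, 0.99]
    malformed: int = 0       # bad alleles, non-autosome, unparseable fields

    @property
    def dropped(self) -> int:
        return self.dropped_filter + self.malformed


class SnpPanel:
    """Ordered marker collection indexed by rsid and by (chrom, pos)."""

    def __init__(self, markers: Iterable[SnpMarker]):
        self.markers: list[SnpMarker] = list(markers)
        self._by_rsid: dict[str, int] = {}
        self._by_pos: dict[tuple[str, int], int] = {}
        for i, m in enumerate(self.markers):
            if m.rsid in self._by_rsid:
                raise ValueError(f"duplicate rsid in panel: {m.rsid}")
            key = (m.chrom, m.pos)
            if key in self._by_pos:
                raise ValueError(f"duplicate panel position: {m.chrom}:{m.pos}")
            self._by_rsid[m.rsid] = i
            self._by_pos[key] = i
        self.freq_a = np.array([m.freq_a for m in self.markers], dtype=float)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[SnpMarker]:
        return iter(self.markers)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def marker(self, rsid: str) -> SnpMarker:
        return self.markers[self._by_rsid[rsid]]

    def index_of(self, rsid: str) -> int:
        return self._by_rsid[rsid]

    def at(self, chrom: str, pos: int) -> Optional[SnpMarker]:
        """Marker at a 1-based genomic position, or None."""
        i = self._by_pos.get((_norm_chrom(chrom), pos))
        return None if i is None else self.markers[i]


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def _parse_panel_row(fields: list[str]) -> Optional[SnpMarker]:
    """Parse one data row; None means the row is malformed."""
    chrom = _norm_chrom(fields[0].strip())
    if chrom not in AUTOSOMES:
        return None
    try:
        pos = int(fields[1])
        freq_a = float(fields[5])
    except ValueError:
        return None
    a, b = fields[3].strip().upper(), fields[4].strip().upper()
    if a not in VALID_BASES or b not in VALID_BASES or a == b or pos < 1:
        return None
    return SnpMarker(chrom, pos, fields[2].strip(), a, b, freq_a)


def load_panel(path: str | Path) -> tuple[SnpPanel, PanelLoadReport]:
    """Load a marker panel, dropping rare and malformed rows.

    Markers whose allele-A frequency falls outside [0.01, 0.99] are dropped
    and counted as filtered; rows with identical or non-ACGT alleles,
    non-autosomal chromosomes or unparseable fields are counted as
    malformed.  Duplicate (chrom, pos) or rsid entries abort the load.
    """
    path = Path(path)
    markers: list[SnpMarker] = []
    report = PanelLoadReport()
    with open(path) as fh:
        header: Optional[list[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                if tuple(header) != PANEL_COLUMNS:
                    raise ValueError(
                        f"{path}: expected header {PANEL_COLUMNS}, got {tuple(header)}"
                    )
                continue
            report.total += 1
            if len(fields) != 6:
                report.malformed += 1
                continue
            marker = _parse_panel_row(fields)
            if marker is None:
                report.malformed += 1
            elif not (FREQ_MIN <= marker.freq_a <= FREQ_MAX):
                report.dropped_filter += 1
            else:
                markers.append(marker)
                report.loaded += 1
    if header is None:
        raise ValueError(f"{path}: empty panel file")
    return SnpPanel(markers), report


def write_panel(panel: SnpPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for m in panel:
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.rsid}\t{m.allele_a}\t{m.allele_b}\t{m.freq_a:.6g}\n"
            )
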