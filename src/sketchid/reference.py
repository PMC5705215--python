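"""Reference genotype databases in 23andMe-style raw-data format.

Each candidate sample is a genome-wide genotype profile (typically a
600K-900K SNP array export).  Genotypes are stored relative to the panel's
(allele_a, allele_b) labelling as ``AA``/``AB``/``BB``; heterozygote order
is normalized to ``AB``.  A marker whose file genotype uses alleles outside
the panel's pair — a different build, a different probe, a tri-allelic call
— is demoted to missing rather than treated as evidence, because reference
arrays are trusted per-call but not per-annotation.  Missing markers simply
never intersect a sketch.

File dialect (DTC raw-data convention): ``#`` comment lines, then four
tab-separated columns ``rsid  chromosome  position  genotype``, with ``--``
for a no-call.  Only autosomes are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .panel import AUTOSOMES, SnpPanel, _norm_chrom

#: integer genotype codes used throughout the matcher: count of B alleles
GENOTYPE_CODES = {"AA": 0, "AB": 1, "BB": 2}
MISSING = -1


@dataclass
class GenotypeLoadReport:
    total: int = 0
    kept: int = 0
    not_in_panel: int = 0
    no_call: int = 0
    non_autosomal: int = 0
    allele_mismatch: int = 0


@dataclass
class ReferenceGenotypes:
    """One candidate's panel-harmonized genotypes (rsid -> AA/AB/BB)."""

    sample_id: str
    genotypes: dict[str, str] = field(default_factory=dict)
    report: Optional[GenotypeLoadReport] = None

    def __len__(self) -> int:
        return len(self.genotypes)

    def get(self, rsid: str) -> Optional[str]:
        return self.genotypes.get(rsid)

    def codes(self, panel: SnpPanel) -> np.ndarray:
        """Panel-aligned int8 genotype vector; -1 marks missing markers."""
        out = np.full(len(panel), MISSING, dtype=np.int8)
        for rsid, g in self.genotypes.items():
            out[panel.index_of(rsid)] = GENOTYPE_CODES[g]
        return out


class ReferenceDatabase:
    """Collection of candidate genotype profiles with unique sample ids."""

    def __init__(self, entries: Iterable[ReferenceGenotypes]):
        self.entries: list[ReferenceGenotypes] = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.sample_id in seen:
                raise ValueError(f"duplicate sample_id: {e.sample_id}")
            seen.add(e.sample_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def get(self, sample_id: str) -> ReferenceGenotypes:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)

    def genotype_matrix(self, panel: SnpPanel) -> np.ndarray:
        """(n_samples, n_markers) int8 matrix of B-allele counts, -1 missing."""
        if not self.entries:
            return np.empty((0, len(panel)), dtype=np.int8)
        return np.stack([e.codes(panel) for e in self.entries])


def load_genotype_file(
    path: str | Path, panel: SnpPanel, sample_id: Optional[str] = None
) -> ReferenceGenotypes:
    """Load and harmonize one 23andMe-style genotype file against a panel.

    Retains a call only when the rsid is in the panel and both allele
    letters belong to that marker's {allele_a, allele_b}; everything else
    (no-calls, sex chromosomes, mitochondrial records, foreign alleles)
    is missing.  Raises on lines that do not have exactly four columns.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    genotypes: dict[str, str] = {}
    report = GenotypeLoadReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
                )
            rsid, chrom, _pos, call = (f.strip() for f in fields)
            report.total += 1
            if _norm_chrom(chrom) not in AUTOSOMES:
                report.non_autosomal += 1
                continue
            if call == "--" or len(call) != 2:
                report.no_call += 1
                continue
            if rsid not in panel:
                report.not_in_panel += 1
                continue
            marker = panel.marker(rsid)
            pair = {marker.allele_a, marker.allele_b}
            a1, a2 = call[0].upper(), call[1].upper()
            if a1 not in pair or a2 not in pair:
                report.allele_mismatch += 1
                continue
            n_b = (a1 == marker.allele_b) + (a2 == marker.allele_b)
            genotypes[rsid] = ("AA", "AB", "BB")[n_b]
            report.kept += 1
    return ReferenceGenotypes(sample_id=sample_id, genotypes=genotypes, report=report)


def write_genotype_file(
    geno: ReferenceGenotypes, panel: SnpPanel, path: str | Path
) -> None:
    """Write genotypes back to the 4-column raw-data dialect (actual bases)."""
    with open(path, "w") as fh:
        fh.write("# rsid\tchromosome\tposition\tgenotype\n")
        for m in panel:
            g = geno.genotypes.get(m.rsid)
            if g is None:
                continue
            letters = {
                "AA": m.allele_a + m.allele_a,
                "AB": m.allele_a + m.allele_b,
                "BB": m.allele_b + m.allele_b,
            }[g]
            fh.write(f"{m.rsid}\t{m.chrom}\t{m.pos}\t{letters}\n")


def load_database(directory: str | Path, panel: SnpPanel) -> ReferenceDatabase:
    """Load every genotype file in a directory; sample id = file name stem.

    Entry order is lexicographic by file name so repeated loads are
    deterministic.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.rglob("*") if p.is_file())
    if not files:
        raise ValueError(f"no reference files in {directory}")
    entries = []
    seen: dict[str, Path] = {}
    for p in files:
        if p.stem in seen:
            raise ValueError(
                f"duplicate sample_id {p.stem!r} from {seen[p.stem]} and {p}"
            )
        seen[p.stem] = p
        entries.append(load_genotype_file(p, panel))
    return ReferenceDatabase(entries)
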