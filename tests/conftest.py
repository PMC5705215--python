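"""Shared fixtures: tiny hand-built panels, genotype files and SAM fixtures.

All fixtures are generated programmatically; nothing is read from stored
data files.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from sketchid.panel import SnpMarker, SnpPanel

# 8 autosomal bi-allelic markers clustered on chr1 within one read length,
# plus two on chr2; frequencies chosen to exercise both common and skewed MAF.
SMALL_PANEL_MARKERS = [
    SnpMarker("1", 10_001, "rs001", "A", "G", 0.50),
    SnpMarker("1", 10_004, "rs002", "C", "T", 0.30),
    SnpMarker("1", 10_007, "rs003", "G", "T", 0.80),
    SnpMarker("1", 10_010, "rs004", "A", "C", 0.10),
    SnpMarker("1", 10_013, "rs005", "T", "G", 0.95),
    SnpMarker("1", 10_016, "rs006", "C", "G", 0.60),
    SnpMarker("2", 20_001, "rs007", "A", "T", 0.25),
    SnpMarker("2", 20_004, "rs008", "G", "C", 0.45),
]


@pytest.fixture()
def small_panel() -> SnpPanel:
    return SnpPanel(SMALL_PANEL_MARKERS)


@pytest.fixture()
def panel_file(tmp_path: Path) -> Path:
    """Valid panel TSV of the small panel plus comment lines."""
    path = tmp_path / "panel.tsv"
    lines = ["# synthetic test panel", "chrom\tpos\trsid\tallele_a\tallele_b\tfreq_a"]
    for m in SMALL_PANEL_MARKERS:
        lines.append(f"{m.chrom}\t{m.pos}\t{m.rsid}\t{m.allele_a}\t{m.allele_b}\t{m.freq_a}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_genotype_lines(path: Path, rows: list[tuple[str, str, int, str]]) -> Path:
    lines = ["# rsid\tchromosome\tposition\tgenotype"]
    for rsid, chrom, pos, call in rows:
        lines.append(f"{rsid}\t{chrom}\t{pos}\t{call}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_sam(path: Path, reads: list[dict]) -> Path:
    """Minimal single-contig-pair SAM writer for fixtures.

    Each read dict: name, flag, chrom, pos (1-based), cigar, seq, qual
    (either a string or an int applied to every base).
    """
    lines = ["@HD\tVN:1.6"] + [f"@SQ\tSN:{c}\tLN:1000000" for c in range(1, 23)]
    for r in reads:
        qual = r.get("qual", 20)
        if isinstance(qual, int):
            qual = chr(qual + 33) * len(r["seq"])
        lines.append(
            "\t".join(
                [
                    r["name"],
                    str(r.get("flag", 0)),
                    r["chrom"],
                    str(r["pos"]),
                    str(r.get("mapq", 60)),
                    r.get("cigar", f"{len(r['seq'])}M"),
                    "*",
                    "0",
                    "0",
                    r["seq"],
                    qual,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path
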