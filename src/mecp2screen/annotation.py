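"""Gene models and the three strand-aware analysis windows.

Each gene contributes three regions to the binding screen: a window
around the transcription start site (TSS), the gene body (the full
genomic span, exons and introns alike), and a window around the
transcription end site (TES).  For a minus-strand gene the TSS sits at
the right-hand coordinate, so the TSS and TES windows mirror.

Coordinates are 0-based half-open throughout; conversion from 1-based
GTF happens at parse time only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

logger = logging.getLogger(__name__)

WINDOW_NAMES = ("tss", "body", "tes")

Geometry = Literal["symmetric", "upstream"]


@dataclass(frozen=True)
class GeneModel:
    """A single-span gene: one interval per gene_id, strand-aware."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneWindows:
    """The three analysis windows of one gene, post-clipping.

    A window that is clipped away entirely (zero length) is stored as
    ``None`` and the gene is excluded from that window's ranking.
    """

    gene_id: str
    tss: Optional[Interval]
    body: Optional[Interval]
    tes: Optional[Interval]

    def window(self, name: str) -> Optional[Interval]:
        if name not in WINDOW_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (chromosome name, length in bp)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            name, length = fields[0], int(fields[1])
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {name}")
            sizes[name] = length
    return sizes


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.rstrip(";").split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, value = field.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def load_gene_models(path: str | Path, format: Optional[str] = None) -> list[GeneModel]:
    """Load gene models from a BED6 or GTF file (one span per gene).

    GTF: only ``gene`` feature lines are used (exon lines are ignored);
    1-based closed coordinates are converted to 0-based half-open.
    BED6: columns chrom, start, end, name, score, strand.

    Raises ``ValueError`` on malformed records, missing strand, or
    duplicate gene_ids.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "GTF" if suffix in (".gtf", ".gff") else "BED"
    format = format.upper()
    if format not in ("GTF", "BED"):
        raise ValueError(f"unknown annotation format {format!r}")

    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "BED":
                    if len(fields) < 6:
                        raise ValueError("BED6 requires 6 columns (strand missing?)")
                    chrom, start, end, name, _score, strand = fields[:6]
                    gene = GeneModel(name, chrom, int(start), int(end), strand)
                else:
                    if len(fields) < 9:
                        raise ValueError("GTF requires 9 columns")
                    chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
                    if feature != "gene":
                        continue
                    attr = _parse_gtf_attributes(attrs)
                    if "gene_id" not in attr:
                        raise ValueError("gene record lacks gene_id attribute")
                    if strand not in ("+", "-"):
                        raise ValueError(f"missing or invalid strand {strand!r}")
                    # GTF is 1-based closed; convert to 0-based half-open.
                    gene = GeneModel(attr["gene_id"], chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if gene.gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def _clip(start: int, end: int, chrom_len: int) -> tuple[int, int]:
    return max(start, 0), min(end, chrom_len)


def derive_windows(
    genes: Iterable[GeneModel],
    sizes: dict[str, int],
    flank_bp: int = 2000,
    geometry: Geometry = "symmetric",
) -> list[GeneWindows]:
    """Derive the TSS, body, and TES window of each gene.

    geometry="symmetric" (default): TSS window = TSS +/- flank_bp, TES
    window = TES +/- flank_bp.  geometry="upstream": flank on the
    upstream side only (TSS window ends at the TSS, TES window starts at
    the TES), reproducing an upstream-only reading of the flanks.

    Windows are clipped to [0, chromosome length); a window clipped to
    zero length is recorded as None with a warning, and the gene is
    excluded from that window's ranking downstream.  Order of the input
    gene list is preserved.
    """
    if flank_bp <= 0:
        raise ValueError(f"flank_bp must be positive, got {flank_bp}")
    out: list[GeneWindows] = []
    for g in genes:
        if g.chrom not in sizes:
            raise KeyError(f"chromosome {g.chrom!r} of gene {g.gene_id!r} absent from chrom sizes")
        clen = sizes[g.chrom]
        tss_pos = g.start if g.strand == "+" else g.end
        tes_pos = g.end if g.strand == "+" else g.start
        if geometry == "symmetric":
            tss_span = (tss_pos - flank_bp, tss_pos + flank_bp)
            tes_span = (tes_pos - flank_bp, tes_pos + flank_bp)
        elif geometry == "upstream":
            if g.strand == "+":
                tss_span = (tss_pos - flank_bp, tss_pos)
                tes_span = (tes_pos, tes_pos + flank_bp)
            else:
                tss_span = (tss_pos, tss_pos + flank_bp)
                tes_span = (tes_pos - flank_bp, tes_pos)
        else:
            raise ValueError(f"unknown geometry {geometry!r}")

        windows: dict[str, Optional[Interval]] = {}
        for name, (s, e) in (("tss", tss_span), ("body", (g.start, g.end)), ("tes", tes_span)):
            cs, ce = _clip(s, e, clen)
            if ce <= cs:
                logger.warning(
                    "gene %s: %s window fully clipped at chromosome boundary; "
                    "excluded from %s ranking",
                    g.gene_id, name, name,
                )
                windows[name] = None
            else:
                windows[name] = Interval(g.chrom, cs, ce)
        out.append(GeneWindows(g.gene_id, windows["tss"], windows["body"], windows["tes"]))
    return out


def write_windows_bed(windows: Iterable[GeneWindows], path: str | Path) -> None:
    """Export windows as BED6 named ``<gene_id>:<tss|body|tes>``."""
    with open(path, "w") as fh:
        for gw in windows:
            for name in WINDOW_NAMES:
                iv = gw.window(name)
                if iv is None:
                    continue
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gw.gene_id}:{name}\t0\t+\n")
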